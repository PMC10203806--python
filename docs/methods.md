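# Methods

This note documents the models behind each stage, the parameter defaults
and why they hold, the numerical choices, and what the synthetic
validation does and does not establish.

## Stimulus synthesis and prosody measurement

A pseudo-sentence is rendered as six harmonic-complex syllables (twelve
harmonics, 1/k roll-off, harmonics capped below 0.9 × Nyquist) whose
instantaneous frequency follows a per-sentence F0 contour, shaped by 15 ms
raised-cosine onset/offset ramps and per-syllable gains, separated by
silent gaps, at 48 kHz. Harmonic phases are drawn from the spec's seed, so
synthesis is bit-reproducible. The generator's per-emotion parameters
(mean F0, between-sentence F0 SD, level re the loudest sentence, syllable
rate) are the acoustic profile of the recorded material this surrogate
emulates: angry 241.47 Hz/−0.99 dB/4.50 syl/s, happy 243.31/−10.97/5.57,
sad 215.97/−17.76/4.70, unemotional 167.04/−15.04/4.68. Because those
per-emotion means are *measured properties* of the original stimulus bank,
the bank generator recentres its five per-emotion sentence-mean draws onto
the emotion mean (calibration), keeping the between-sentence spread; the
grand mean across emotions is then 216.95 Hz up to tracker error rather
than up to 5-draw sampling noise.

The F0 tracker is normalised autocorrelation on 40 ms frames with a 10 ms
hop, searching 75–400 Hz (covering the material's 76.5–355.1 Hz range),
with parabolic peak interpolation. A frame is voiced when the peak exceeds
0.5 and the frame carries non-negligible energy; white noise is ≥ 90 %
unvoiced under this rule. `measure_profile` reports F0 statistics over
voiced frames, level as `20·log10(RMS/ref)`, and rate as syllable count
over duration.

## Cue attenuation

* **F0 flattening** is time-domain pitch-synchronous overlap-add: analysis
  pitch marks at the local tracked period, synthesis marks at the constant
  217 Hz target period, Hann-windowed two-period grains, overlap-add
  normalised by the accumulated window envelope. Unvoiced and silent spans
  are untouched, so duration is preserved exactly. Any analysis/resynthesis
  method meeting the post-conditions would be conformant; PSOLA is the
  simplest that does.
* **Intensity flattening** equalises the 50 ms short-time RMS to
  −11.19 dB re the bank's maximum RMS. The gain is tracked at half that
  window (a 25 ms sliding RMS envelope) and smoothed over 5 ms, with three
  measure-correct passes; samples whose envelope sits below a −40 dB
  silence floor keep unit gain (the protocol does not say how silences
  were treated; leaving them untouched is the conservative choice). If the
  result would clip, the waveform is rescaled globally and the event
  logged. Frame-wise (rather than utterance-global) equalisation is the
  default reading of "equalised to the mean value"; the global variant is
  a trivial single gain and not separately shipped.
* **Rate scaling** is uniform per sentence, by waveform-similarity
  overlap-add (WSOLA: half-overlapping Hann frames of 45 ms, analysis
  position advanced at hop/ratio and refined within ±10 ms by normalised
  cross-correlation against the natural continuation). Segments are copied
  verbatim, so pitch statistics survive within ±3 Hz. Scale factors
  outside [0.25, 4] are rejected as a quality guard.

Composite conditions apply F0 → rate → intensity in that fixed order.

Measurement of the achieved level uses frames lying entirely inside
speech-active regions, eroded by half an envelope window from each
boundary: a frame straddling forced silence cannot reach the target by
construction, and within half a window of a boundary the envelope estimate
itself is contaminated. Spectral identity checks compare log energies in
24 log-spaced bands, masking bands more than 40 dB below the reference's
loudest band (empty bands otherwise amplify sub-audible resynthesis
artifacts).

## Designs

The 4-AFC assessment is practice trials followed by one trial per emotion
× condition × sentence in seeded random order. The fNIRS session puts the
four familiarisation blocks first — the protocol fixes that — then
randomly interleaves experimental and attention blocks; attention-block
placement is otherwise unconstrained. ISIs are uniform on 13–23 s (the
protocol states only the range; uniform is the maximum-entropy choice).
Events serialise to BIDS-style TSV.

## fNIRS forward model

Long channels carry `Σ_cond β[cond, roi, chrom] · (3 s boxcar ⊗ HRF)`
plus nuisance; short channels carry nuisance only. The nuisance is
(i) three shared sinusoidal latents (Mayer-like 0.1 Hz, amplitude 0.8 µM;
respiratory 0.25 Hz, 0.5 µM; cardiac 1.1 Hz, 0.4 µM) with per-channel
coupling weights ~ N(1, 0.3) clipped at zero — the "location-dependent
heterogeneity" that motivates per-location short channels; (ii) slow drift
as three random cosines below 0.008 Hz totalling 1.5 µM; (iii) AR(1)
sensor noise (ρ = 0.3, sd 0.4 µM). HbR is −⅓ of the HbO response
(typical physiology; configurable) and 0.3 × the systemic. Cardiac at
1.1 Hz is deliberately kept although the 0.6 Hz analysis rate removes it —
it stresses the resampling stage at the 2.6 Hz acquisition rate.
Default amplitudes put single-channel response SNR in the realistic
sub-unity range while keeping a 20-repetition session informative.

Concentrations map to raw intensities through the same modified
Beer–Lambert model the analysis inverts:
`I_λ = I0 · exp(−(ε_λ,HbO·C_HbO + ε_λ,HbR·C_HbR) · d · PPF)`, with the
standard tabulated haemoglobin extinction coefficients (760 nm: 586 /
1548.52; 850 nm: 1058 / 691.32 cm⁻¹ M⁻¹, converted to µM⁻¹ mm⁻¹) and
I0 = 1 (arbitrary units — OD uses only ratios). The default montage is 60
long channels at 30 mm (ten per ROI over bilateral STG, IFG, MFG) and 8
short channels at 8 mm (two per STG, one per IFG/MFG).

## First-level analysis

Resampling 2.6 → 0.6 Hz is polyphase at the rational ratio 3/13 with
*mean* padding — raw intensities sit on a non-zero baseline, and zero
padding would ring a large step through the anti-aliasing filter, which
the Beer–Lambert inversion then amplifies by ~10³.

OD uses the natural log with the per-channel temporal mean as reference;
recovery of concentration is therefore exact up to an additive constant
per channel, absorbed by the design's constant column. Channel selection
keeps 20–40 mm inclusive (the protocol rejects "<20 mm or >40 mm", so the
boundary is kept).

The canonical HRF is a difference of gamma densities peaking at 6 s and
16 s with undershoot ratio 1/6, peak-normalised to 1. Condition
regressors evaluate the continuous boxcar ⊗ HRF kernel (built on a 10 Hz
internal grid, unit peak) at the exact onset offsets — onsets are not
quantised to the 0.6 Hz grid, and a fitted β reads directly as the peak
response amplitude in µM at any sampling rate. Drift is a discrete-cosine
basis with frequencies ≤ 0.01 Hz (order ⌊2·T·0.01⌋) plus a constant; the
basis is a choice, the cutoff is the protocol's. All principal components
of the eight short channels (per chromophore, jointly across ROIs, unit
variance, degenerate directions dropped) join the design.

The GLM is iterated Prais–Winsten prewhitening: OLS, ρ from the lag-1
autocorrelation of the residuals, transform, refit, to |Δρ| < 10⁻³ (max
10 iterations). ρ estimated per channel. Near-perfect fits (residual
energy < 10⁻²⁰ of the signal) set ρ = 0 — the autocorrelation of rounding
error is meaningless. Fixing ρ = 0 reproduces OLS exactly.

ROI pooling weights channels by 1/SE (1/SE² available). The pooled SE is
the propagated error of the weighted mean using the measured
whitened-residual correlation between channels,
`SE²_roi = Σ_ij w_i w_j SE_i SE_j ρ_ij / (Σw)²`: all channels in a session
are fitted against the same design including the same (noisy)
short-channel components, so their errors are positively correlated, and
independence propagation understates the ROI SE (measured coverage ≈ 87 %
instead of 95 %; with the correlation-aware propagation, ≈ 96 %).

## Group statistics

The second level is a REML linear mixed model per chromophore:
`θ ~ 0 + ROI:Condition` with participant random intercepts and, by
default, uncorrelated random condition effects per participant (a shared
variance component, the structure the usual simplification policy tends to
reach; a singular or failed fit falls back to intercepts only, logged).
The suppressed intercept makes each of the 30 cells a test against zero.
Rows with Cook's distance above 4/N on the fixed-effects regression are
excluded first (the protocol names Cook's distance but no threshold; 4/N
is the common rule and is configurable). Contrast inference uses the
normal approximation on the cell covariance — at N ≈ 660 the difference
from Satterthwaite degrees of freedom is negligible. BH-FDR is applied per
contrast family (one family per chromophore per table of planned
contrasts).

Sliding-difference coding uses the closed form entry(i, j) = −(k−j)/k for
i ≤ j, else j/k, so the j-th coefficient estimates μ_{j+1} − μ_j; the
defining identity (difference matrix × coding = I) is tested for k = 2…6.
Treatment coding is the usual dummy coding against the first level.

Behavioural GLMMs (logit link) are fitted by the variational Bayes
approximation of statsmodels' `BinomialBayesMixedGLM` with random
intercepts per participant and sentence; random terms with posterior sd
< 0.01 are dropped and the model refitted, mirroring the standard
simplification policy, and an empty random structure reduces to an exact
logistic GLM. Coefficients are posterior means with normal inference on
the posterior sd. Nakagawa R² is computed from the variance components
(π²/3 latent residual for logit models).

The 4-AFC generator is a softmax over the four alternatives: the
presented emotion's alternative earns base log-odds 0.4 plus 2.2 (F0),
0.35 (intensity) and 0.25 (rate) for each cue left informative, the
"unemotional" alternative gains 1.2 log-odds whenever F0 is attenuated,
and participants carry a N(0, 0.5) intercept on the correct alternative.
These weights put natural-speech accuracy near 0.9, the intensity+rate
condition slightly below it, and the F0-attenuated conditions at 0.3–0.4
with confusions concentrated on "unemotional" — the qualitative structure
the cue-weighting literature reports, with F0 clearly dominant.

The brain–behaviour model regresses participant ROI amplitudes on
recognition accuracy (`θ ~ 0 + ROI + ROI:Accuracy`, participant random
intercepts, REML). Its validation generator couples accuracy to amplitude
only in right STG, at −6 µM per unit accuracy with 0.8 µM residual sd and
1 µM participant sd over accuracies ~ N(0.60, 0.15): a strong coupling of
the kind the motivating data show, which a cohort of 22 detects in ≈ 90 %
of runs while each uncoupled ROI stays null in ≈ 92–95 %. The unsigned
HbO–HbR difference reports |θ_HbO − θ_HbR| with the pair classed
negatively correlated when the two estimates have opposite signs (the
time-course-correlation reading of "negatively correlated pairs" is a
plausible alternative; sign opposition is the default because it needs
only the estimates).

Accuracy entering the brain–behaviour model is the pre-session
assessment's F0-condition accuracy.

## Validation scale and limits

Parameter-recovery checks run at desk scale: full-length sessions (five
conditions × 20 repetitions, ISIs 13–23 s, ≈ 48 min of signal, 68
channels × 2 wavelengths), pooled over 22 independently seeded sessions
for bias (< 5 % of truth) and 95 % CI coverage (within 90–99 %), with the
short-channel-regression benefit paired over 6 sessions under strong
systemic noise. Monte-Carlo checks of ρ̂ bias use 200 series of length
2000; FDR control uses 1000 null families of 24 tests; the
brain–behaviour power check uses 100 seeded cohorts of 22.

What passing these tests shows: the implementation inverts its own
forward models without bias and with calibrated uncertainty, and the
statistical machinery matches its closed-form and brute-force oracles.
What it does not show: robustness to phenomena the generators omit —
motion artifacts, scalp-coupling variation, non-sinusoidal or
non-stationary physiology, optode repositioning, real voice acoustics
(formants, jitter, breathiness), or listeners whose cue weighting departs
from the softmax form. Results on real recordings depend on those factors;
the pipeline's parameters (PPF, drift cutoff, boxcar length, distance
bounds) follow the published protocol so that real SNIRF data can be
analysed unchanged.
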