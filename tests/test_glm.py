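"""First-level GLM: resampling, HRF, design, AR(1) fit, ROI pooling."""
import numpy as np
import pandas as pd
import pytest

from emonirs import design, glm, synth


def events_frame(conditions=("speech", "control"), reps=4, seed=1,
                 isi=(8.0, 12.0)):
    return design.make_block_schedule(
        conditions, reps=reps, attention_reps=0, n_familiarization=0,
        isi_range_s=isi, seed=seed).to_frame()


class TestResample:
    def test_constant_stays_constant(self):
        out = glm.resample(np.full(1300, 2.5), 2.6, 0.6)
        assert np.allclose(out, 2.5, atol=1e-6)

    def test_slow_sinusoid_amplitude_preserved(self):
        t = np.arange(13_000) / 2.6
        x = np.sin(2 * np.pi * 0.05 * t)
        out = glm.resample(x, 2.6, 0.6)
        mid = out[len(out) // 4: 3 * len(out) // 4]
        assert abs(mid.max() - 1.0) < 0.01

    def test_length_scales_by_ratio(self):
        n = 1300
        out = glm.resample(np.zeros(n) + 1.0, 2.6, 0.6)
        assert abs(len(out) - n * 0.6 / 2.6) <= 1

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            glm.resample(np.zeros(100), 0.6, 2.6)


class TestHrf:
    def test_peak_at_six_seconds(self):
        t = np.linspace(0, 32, 32_001)
        h = glm.hrf_canonical(t)
        assert t[np.argmax(h)] == pytest.approx(6.0, abs=0.1)
        assert h.max() == pytest.approx(1.0, rel=1e-6)

    def test_zero_at_origin(self):
        assert glm.hrf_canonical(np.array([0.0]))[0] == 0.0

    def test_positive_net_response(self):
        t = np.linspace(0, 32, 32_001)
        assert np.trapezoid(glm.hrf_canonical(t), t) > 0

    def test_undershoot_present(self):
        t = np.linspace(0, 32, 3201)
        h = glm.hrf_canonical(t)
        assert h[t > 12].min() < 0


class TestDesign:
    def test_regressor_linearity_over_events(self):
        ev1 = pd.DataFrame({"onset": [10.0], "duration": [7.25],
                            "trial_type": ["a"]})
        ev2 = pd.DataFrame({"onset": [100.0], "duration": [7.25],
                            "trial_type": ["a"]})
        both = pd.concat([ev1, ev2], ignore_index=True)
        n = 200
        r1 = glm.condition_regressors(ev1, 0.6, n)["a"]
        r2 = glm.condition_regressors(ev2, 0.6, n)["a"]
        rb = glm.condition_regressors(both, 0.6, n)["a"]
        assert np.allclose(rb, r1 + r2, atol=1e-12)

    def test_drift_column_count_formula(self):
        n = int(3000 * 0.6)
        X = glm.dct_drift_basis(n, 0.6, 0.01)
        # floor(2 * 3000 s * 0.01 Hz) = 60 cosines plus the constant
        assert X.shape[1] == 61

    def test_zero_conditions_gives_drift_and_pcs_only(self):
        ev = pd.DataFrame({"onset": [], "duration": [], "trial_type": []})
        comps = np.vstack([np.sin(np.arange(100)),
                           np.cos(np.arange(100))])
        X = glm.build_design(ev, 0.6, 100, short_components=comps)
        assert all(c.startswith(("drift", "constant", "short_pc"))
                   for c in X.columns)

    def test_event_beyond_recording_rejected(self):
        ev = pd.DataFrame({"onset": [1e4], "duration": [7.25],
                           "trial_type": ["a"]})
        with pytest.raises(ValueError):
            glm.condition_regressors(ev, 0.6, 100)


class TestShortComponents:
    def test_identical_channels_yield_single_component(self):
        base = np.sin(np.arange(500) * 0.1)
        X = np.tile(base, (8, 1))
        comps = glm.short_channel_components(X)
        assert comps.shape[0] == 1

    def test_components_orthogonal_unit_variance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (8, 400))
        comps = glm.short_channel_components(X)
        assert comps.shape[0] == 8
        G = comps @ comps.T / comps.shape[1]
        assert np.allclose(G, np.diag(np.diag(G)), atol=1e-8)
        assert np.allclose(comps.std(axis=1), 1.0)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (5, 300))
        Xc = X - X.mean(axis=1, keepdims=True)
        comps = glm.short_channel_components(X)
        # centred data lie exactly in the span of all components
        coefs, *_ = np.linalg.lstsq(comps.T, Xc.T, rcond=None)
        assert np.abs(comps.T @ coefs - Xc.T).max() < 1e-9


class TestChannelSelection:
    def test_default_montage_retains_60(self):
        m = synth.make_montage()
        sel = glm.select_long_channels(m)
        assert len(sel) == 60

    def test_boundaries_inclusive(self):
        m = pd.DataFrame({
            "channel": ["a", "b", "c"],
            "distance_mm": [20.0, 19.9, 40.0],
            "roi": ["LSTG"] * 3, "is_short": [False] * 3,
        })
        sel = glm.select_long_channels(m)
        assert list(sel["channel"]) == ["a", "c"]

    def test_empty_selection_rejected(self):
        m = pd.DataFrame({"channel": ["s"], "distance_mm": [8.0],
                          "roi": ["LSTG"], "is_short": [True]})
        with pytest.raises(ValueError):
            glm.select_long_channels(m)


class TestAr1Glm:
    def test_noiseless_recovery_exact(self):
        ev = events_frame()
        n = 400
        X = glm.build_design(ev, 0.6, n)
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 1, X.shape[1])
        y = X.to_numpy() @ beta
        fit = glm.fit_ar1_glm(y, X)
        assert np.abs(fit.beta.to_numpy() - beta).max() < 1e-10
        assert abs(fit.rho) < 0.1

    def test_forcing_rho_zero_reproduces_ols(self):
        ev = events_frame()
        n = 400
        X = glm.build_design(ev, 0.6, n)
        rng = np.random.default_rng(1)
        y = X.to_numpy() @ rng.normal(0, 1, X.shape[1]) \
            + rng.normal(0, 0.5, n)
        fit = glm.fit_ar1_glm(y, X, rho=0.0)
        ols, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
        assert np.allclose(fit.beta.to_numpy(), ols, atol=1e-12)

    def test_rho_and_se_calibration(self):
        """Monte-Carlo: rho estimate within 0.05 of truth and reported SE
        within 15% of the empirical SE at n=2000."""
        n, rho_true = 2000, 0.6
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, n)
        X = pd.DataFrame({"const": np.ones(n), "x": x})
        n_rep = 60
        rhos, betas, ses = [], [], []
        for _ in range(n_rep):
            e = np.empty(n)
            innov = rng.normal(0, 1, n)
            e[0] = innov[0] / np.sqrt(1 - rho_true ** 2)
            for k in range(1, n):
                e[k] = rho_true * e[k - 1] + innov[k]
            y = 2.0 + 1.5 * x + e
            fit = glm.fit_ar1_glm(y, X)
            rhos.append(fit.rho)
            betas.append(fit.beta["x"])
            ses.append(fit.se["x"])
        assert abs(np.mean(rhos) - rho_true) < 0.05
        emp_se = np.std(betas, ddof=1)
        assert abs(np.mean(ses) / emp_se - 1) < 0.15

    def test_rank_deficiency_reported_with_columns(self):
        n = 100
        X = pd.DataFrame({"a": np.ones(n), "b": np.ones(n)})
        with pytest.raises(ValueError, match="rank deficient"):
            glm.fit_ar1_glm(np.zeros(n), X)


class TestRoiAggregate:
    def _frame(self, betas, ses):
        return pd.DataFrame({
            "channel": [f"c{i}" for i in range(len(betas))],
            "roi": ["LSTG"] * len(betas),
            "chromophore": ["hbo"] * len(betas),
            "condition": ["speech"] * len(betas),
            "beta": betas, "se": ses,
        })

    def test_equal_ses_give_arithmetic_mean(self):
        out = glm.roi_aggregate(self._frame([1.0, 3.0], [0.5, 0.5]))
        assert out["theta"].iloc[0] == pytest.approx(2.0)

    def test_huge_se_channel_ignored(self):
        out = glm.roi_aggregate(self._frame([1.0, 3.0], [1.0, 1e6]))
        assert abs(out["theta"].iloc[0] - 1.0) < 1e-3

    def test_single_channel_identity(self):
        out = glm.roi_aggregate(self._frame([2.5], [0.7]))
        assert out["theta"].iloc[0] == pytest.approx(2.5)
        assert out["se"].iloc[0] == pytest.approx(0.7)

    def test_inverse_variance_weighting_option(self):
        out = glm.roi_aggregate(self._frame([0.0, 1.0], [1.0, 2.0]),
                                weight="inverse_variance")
        assert out["theta"].iloc[0] == pytest.approx(0.2)


class TestEpochAverage:
    def test_identical_epochs_zero_ci_and_baseline(self):
        m = synth.make_montage({"LSTG": 1}, {"LSTG": 1})
        rate = 0.6
        ev = pd.DataFrame({"onset": [50.0, 150.0], "duration": [7.25] * 2,
                           "trial_type": ["speech"] * 2,
                           "kind": ["experimental"] * 2})
        n = int(250 * rate)
        kernel_t, kernel = glm.block_response_kernel()
        t = np.arange(n) / rate
        sig = sum(np.interp(t - o, kernel_t, kernel, left=0, right=0)
                  for o in ev["onset"])
        conc = np.zeros((2, 2, n))
        conc[0, 0] = sig
        out = glm.epoch_average(conc, rate, ev, m)
        hbo = out[(out["chromophore"] == "hbo") & (out["roi"] == "LSTG")]
        width = (hbo["ci_hi"] - hbo["ci_lo"]).abs().max()
        assert width < 1e-9
        base = hbo[hbo["time_s"] < 0]["mean"]
        assert np.abs(base.mean()) < 1e-9

    def test_noise_free_peak_equals_regressor_peak(self):
        m = synth.make_montage({"LSTG": 1}, {"LSTG": 1})
        ev = pd.DataFrame({"onset": [20.0, 70.0], "duration": [7.25] * 2,
                           "trial_type": ["speech"] * 2,
                           "kind": ["experimental"] * 2})
        truth = synth.GroundTruth({("speech", "LSTG"): 1.0})
        nf = synth.NoiseConfig(mayer_amp=0, resp_amp=0, cardiac_amp=0,
                               drift_amp=0, white_sd=0)
        conc = synth.simulate_concentrations(m, ev, truth, nf, seed=0)
        out = glm.epoch_average(conc, glm.ACQUISITION_RATE_HZ, ev, m)
        hbo = out[(out["chromophore"] == "hbo") & (out["roi"] == "LSTG")]
        assert hbo["mean"].max() == pytest.approx(1.0, abs=0.02)


class TestFirstLevelProperties:
    def test_linearity_doubling_betas(self):
        m = synth.make_montage({"LSTG": 2, "RSTG": 2}, {"LSTG": 1})
        ev = events_frame(reps=3)
        nf = synth.NoiseConfig(mayer_amp=0, resp_amp=0, cardiac_amp=0,
                               drift_amp=0, white_sd=0)
        t1 = synth.GroundTruth({("speech", "LSTG"): 1.0,
                                ("speech", "RSTG"): 0.5})
        t2 = synth.GroundTruth({("speech", "LSTG"): 2.0,
                                ("speech", "RSTG"): 1.0})
        out = []
        for truth in (t1, t2):
            rec = synth.simulate_session(m, ev, truth, noise=nf, seed=1)
            _, roi = glm.first_level(rec, use_short_regression=False)
            piv = roi.pivot_table(index=["roi", "condition"],
                                  columns="chromophore", values="theta")
            out.append(piv)
        ratio = out[1] / out[0]
        sub = ratio.loc[[("LSTG", "speech"), ("RSTG", "speech")]]
        assert np.allclose(sub.to_numpy(), 2.0, rtol=1e-6)

    def test_invariant_to_baseline_intensity(self):
        m = synth.make_montage({"LSTG": 1}, {"LSTG": 1})
        ev = events_frame(reps=2)
        truth = synth.GroundTruth({("speech", "LSTG"): 1.0})
        conc = synth.simulate_concentrations(m, ev, truth, seed=4)
        r1 = synth.concentrations_to_raw(conc, m, ev,
                                         baseline_intensity=1.0)
        r2 = synth.concentrations_to_raw(conc, m, ev,
                                         baseline_intensity=7.0)
        _, roi1 = glm.first_level(r1, use_short_regression=False)
        _, roi2 = glm.first_level(r2, use_short_regression=False)
        assert np.allclose(roi1["theta"], roi2["theta"], atol=1e-9)
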