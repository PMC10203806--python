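"""Modified Beer-Lambert law (MBLL) in both directions.

Dual-wavelength optical-density changes map linearly to oxy-/deoxy-
haemoglobin concentration changes through the haemoglobin extinction
matrix, the source-detector distance and a partial pathlength factor
(PPF). The analysis default PPF is 0.1, the ratio of a differential
pathlength factor of 6 to a partial volume correction of 60.

The extinction coefficients are the standard tabulated haemoglobin values
(Prahl/Cope compilation, in cm^-1 per mole/litre) converted here to
1/(uM*mm) so that concentrations come out in micromolar when channel
distances are given in millimetres.
"""
from __future__ import annotations

import numpy as np

WAVELENGTHS_NM = (760.0, 850.0)

# molar extinction, cm^-1 / (mole/litre); rows: wavelength
_EXTINCTION_MOLAR = {
    760.0: {"hbo": 586.0, "hbr": 1548.52},
    850.0: {"hbo": 1058.0, "hbr": 691.32},
}

# cm^-1/M -> mm^-1/uM : (1/10 mm per cm) * (1e-6 M per uM)
_UNIT = 1e-7

DEFAULT_PPF = 0.1  # = DPF 6 / partial volume correction 60


def extinction_matrix(
    wavelengths_nm: tuple[float, float] = WAVELENGTHS_NM,
) -> np.ndarray:
    """2x2 extinction matrix E (1/(uM*mm)); rows wavelengths, columns
    (HbO, HbR)."""
    rows = []
    for wl in wavelengths_nm:
        if wl not in _EXTINCTION_MOLAR:
            raise KeyError(f"no extinction entry for {wl} nm")
        e = _EXTINCTION_MOLAR[wl]
        rows.append([e["hbo"] * _UNIT, e["hbr"] * _UNIT])
    E = np.asarray(rows)
    if abs(np.linalg.det(E)) < 1e-18:
        raise ValueError("extinction matrix is singular")
    return E


def od_to_concentration(
    od: np.ndarray,
    distance_mm: float,
    ppf: float = DEFAULT_PPF,
    wavelengths_nm: tuple[float, float] = WAVELENGTHS_NM,
) -> np.ndarray:
    """Invert the MBLL: OD changes (2 x T) -> (HbO, HbR) in uM (2 x T).

    Solves ``od = E @ C * d * ppf`` for C in the least-squares sense
    (exactly, for the square dual-wavelength case).
    """
    if ppf <= 0 or distance_mm <= 0:
        raise ValueError("ppf and distance must be positive")
    od = np.atleast_2d(np.asarray(od, float))
    E = extinction_matrix(wavelengths_nm)
    sol, *_ = np.linalg.lstsq(E, od, rcond=None)
    return sol / (distance_mm * ppf)


def concentration_to_od(
    conc: np.ndarray,
    distance_mm: float,
    ppf: float = DEFAULT_PPF,
    wavelengths_nm: tuple[float, float] = WAVELENGTHS_NM,
) -> np.ndarray:
    """Forward MBLL: (HbO, HbR) in uM (2 x T) -> OD changes (2 x T)."""
    if ppf <= 0 or distance_mm <= 0:
        raise ValueError("ppf and distance must be positive")
    conc = np.atleast_2d(np.asarray(conc, float))
    E = extinction_matrix(wavelengths_nm)
    return (E @ conc) * distance_mm * ppf


def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """Raw intensity -> optical density, ``OD = -ln(I / mean(I))``.

    Uses the absolute raw intensities; the mean over time of each series is
    its own reference, so OD is invariant to per-channel scaling of I.
    """
    intensity = np.asarray(intensity, float)
    if np.any(intensity <= 0):
        raise ValueError("raw intensities must be strictly positive")
    ref = intensity.mean(axis=-1, keepdims=True)
    return -np.log(intensity / ref)


def od_to_intensity(od: np.ndarray, baseline: float = 1.0) -> np.ndarray:
    """OD changes -> strictly positive raw intensities, ``I = I0*exp(-OD)``."""
    od = np.asarray(od, float)
    if not np.all(np.isfinite(od)):
        raise ValueError("OD contains non-finite values")
    return baseline * np.exp(-od)
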