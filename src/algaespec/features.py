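"""The 14 spectral variables used for seaweed discrimination.

Eight *location/amplitude* variables come from window extrema of the
reflectance curve and its first-derivative spectrum:

====  =========================================================  ==========
name  definition                                                 window, nm
====  =========================================================  ==========
R_g   green-peak amplitude: max reflectance                      [510, 560]
L_g   green-peak location: wavelength of R_g                     [510, 560]
R_r   red-valley amplitude: MIN reflectance                      [640, 680]
L_r   red-valley location: wavelength of R_r                     [640, 680]
V_re  red-edge amplitude: max first derivative                   [680, 760]
L_re  red-edge location: wavelength of V_re                      [680, 760]
V_be  blue-edge amplitude: max first derivative                  [490, 530]
L_be  blue-edge location: wavelength of V_be                     [490, 530]
====  =========================================================  ==========

Note on R_r: some tabulations call it a "maximum", but a red *valley* is
by definition the chlorophyll absorption minimum; this package computes
the window minimum, consistent with the narrated example (Ulva pertusa:
minimum 5.78% at 669 nm).

Two *area* variables are the sums of first-derivative values over the edge
windows (A_re over [680, 760], A_be over [490, 530]; with a 1-nm step the
sum equals the area).  Four *vegetation indices* combine them:
RVI(x, y) = x/y and NDVI(x, y) = (x-y)/(x+y), for the pairs (R_g, R_r)
and (A_re, A_be).

The first derivative is the forward difference (R(l+1) - R(l)) / 1 nm
assigned to the left wavelength, which yields the exact telescoping
identity  sum_{l=a}^{b} D(l) = R(b+1) - R(a).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumSet

__all__ = [
    "DerivativeSpectrum",
    "WindowSpec",
    "FeatureVector",
    "WINDOWS",
    "FEATURE_NAMES",
    "SIGNIFICANCE_ORDER",
    "OPTIMAL_SUBSET_8",
    "first_derivative",
    "find_window_extremum",
    "window_area",
    "compute_indices",
    "extract_features",
    "build_feature_table",
    "write_feature_table",
    "read_feature_table",
]

#: Feature column order of the variable-definition table
#: (locations/amplitudes, then areas, then indices).
FEATURE_NAMES: tuple[str, ...] = (
    "R_g", "L_g", "R_r", "L_r", "V_re", "L_re", "V_be", "L_be",
    "A_re", "A_be", "RVI_RgRr", "RVI_AreAbe", "NDVI_RgRr", "NDVI_AreAbe",
)

#: Reference significance ordering (descending ANOVA/Tukey star count as
#: published); used as the fixed tie-break order when ranking and as the
#: column order of exported feature CSVs.
SIGNIFICANCE_ORDER: tuple[str, ...] = (
    "NDVI_RgRr", "RVI_RgRr", "V_re", "A_be", "R_g", "L_re", "L_g", "L_r",
    "R_r", "L_be", "NDVI_AreAbe", "A_re", "V_be", "RVI_AreAbe",
)

#: The 8-variable subset at which backward elimination peaked in the study.
OPTIMAL_SUBSET_8: tuple[str, ...] = SIGNIFICANCE_ORDER[:8]

LABEL_COLUMNS = ("sample_id", "species", "phylum", "dryness")


@dataclass(frozen=True)
class WindowSpec:
    """A named search window on the reflectance or derivative curve."""

    name: str
    lo: float
    hi: float
    source: str  # "reflectance" | "derivative"
    mode: str    # "max" | "min"

    def __post_init__(self) -> None:
        if not (400 <= self.lo < self.hi <= 900):
            raise ValueError(f"window {self.name}: need 400 <= lo < hi <= 900")
        if self.source not in ("reflectance", "derivative"):
            raise ValueError(f"window {self.name}: bad source {self.source!r}")
        if self.mode not in ("max", "min"):
            raise ValueError(f"window {self.name}: bad mode {self.mode!r}")


WINDOWS: dict[str, WindowSpec] = {
    "green_peak": WindowSpec("green_peak", 510, 560, "reflectance", "max"),
    "red_valley": WindowSpec("red_valley", 640, 680, "reflectance", "min"),
    "red_edge": WindowSpec("red_edge", 680, 760, "derivative", "max"),
    "blue_edge": WindowSpec("blue_edge", 490, 530, "derivative", "max"),
}


@dataclass
class DerivativeSpectrum:
    """First-derivative spectrum (forward difference, %/nm, left-assigned)."""

    wavelengths: np.ndarray
    values: np.ndarray
    convention: str = "forward"

    def __len__(self) -> int:
        return int(self.wavelengths.size)


class Indices(NamedTuple):
    RVI_RgRr: float
    RVI_AreAbe: float
    NDVI_RgRr: float
    NDVI_AreAbe: float


@dataclass
class FeatureVector:
    """The 14 spectral variables of one sample."""

    R_g: float
    L_g: float
    R_r: float
    L_r: float
    V_re: float
    L_re: float
    V_be: float
    L_be: float
    A_re: float
    A_be: float
    RVI_RgRr: float
    RVI_AreAbe: float
    NDVI_RgRr: float
    NDVI_AreAbe: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def first_derivative(s: Spectrum) -> DerivativeSpectrum:
    """Forward-difference first derivative on a uniform 1-nm grid."""
    steps = np.diff(s.wavelengths)
    if steps.size == 0:
        raise ValueError("need at least 2 points for a derivative")
    if not np.allclose(steps, steps[0]):
        raise ValueError("first_derivative requires a uniform wavelength grid")
    step = steps[0]
    return DerivativeSpectrum(
        wavelengths=s.wavelengths[:-1].copy(),
        values=np.diff(s.reflectance) / step,
    )


def _curve_arrays(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, Spectrum):
        return curve.wavelengths, curve.reflectance
    if isinstance(curve, DerivativeSpectrum):
        return curve.wavelengths, curve.values
    raise TypeError(f"expected Spectrum or DerivativeSpectrum, got {type(curve)!r}")


def find_window_extremum(curve, w: WindowSpec) -> tuple[float, float]:
    """(location, value) of the extremum over grid points with lo <= l <= hi.

    Ties break toward the smallest wavelength.
    """
    wl, vals = _curve_arrays(curve)
    mask = (wl >= w.lo) & (wl <= w.hi)
    if not mask.any():
        raise ValueError(f"window {w.name} [{w.lo}, {w.hi}] contains no grid points")
    sub_wl = wl[mask]
    sub = vals[mask]
    idx = int(np.argmin(sub)) if w.mode == "min" else int(np.argmax(sub))
    return float(sub_wl[idx]), float(sub[idx])


def window_area(d: DerivativeSpectrum, w: WindowSpec) -> float:
    """Sum of derivative values at grid points in [lo, hi] (area for 1-nm step)."""
    mask = (d.wavelengths >= w.lo) & (d.wavelengths <= w.hi)
    if not mask.any():
        raise ValueError(f"window {w.name} [{w.lo}, {w.hi}] contains no grid points")
    return float(np.sum(d.values[mask]))


def _safe_ratio(x: float, y: float, name: str) -> float:
    if y == 0:
        warnings.warn(f"{name}: zero denominator; feature flagged as missing", stacklevel=3)
        return math.nan
    return x / y


def compute_indices(R_g: float, R_r: float, A_re: float, A_be: float) -> Indices:
    """Ratio and normalized-difference indices from the amplitude/area pairs.

    RVI(x, y) = x/y; NDVI(x, y) = (x-y)/(x+y).  Zero denominators yield NaN
    (the sample is later excluded from fits that use the affected column).
    """
    return Indices(
        RVI_RgRr=_safe_ratio(R_g, R_r, "RVI_RgRr"),
        RVI_AreAbe=_safe_ratio(A_re, A_be, "RVI_AreAbe"),
        NDVI_RgRr=_safe_ratio(R_g - R_r, R_g + R_r, "NDVI_RgRr"),
        NDVI_AreAbe=_safe_ratio(A_re - A_be, A_re + A_be, "NDVI_AreAbe"),
    )


def extract_features(s: Spectrum) -> FeatureVector:
    """All 14 variables for one trimmed, 1-nm-resampled spectrum."""
    deriv = first_derivative(s)
    L_g, R_g = find_window_extremum(s, WINDOWS["green_peak"])
    L_r, R_r = find_window_extremum(s, WINDOWS["red_valley"])
    L_re, V_re = find_window_extremum(deriv, WINDOWS["red_edge"])
    L_be, V_be = find_window_extremum(deriv, WINDOWS["blue_edge"])
    A_re = window_area(deriv, WINDOWS["red_edge"])
    A_be = window_area(deriv, WINDOWS["blue_edge"])
    idx = compute_indices(R_g, R_r, A_re, A_be)
    return FeatureVector(
        R_g=R_g, L_g=L_g, R_r=R_r, L_r=L_r,
        V_re=V_re, L_re=L_re, V_be=V_be, L_be=L_be,
        A_re=A_re, A_be=A_be,
        RVI_RgRr=idx.RVI_RgRr, RVI_AreAbe=idx.RVI_AreAbe,
        NDVI_RgRr=idx.NDVI_RgRr, NDVI_AreAbe=idx.NDVI_AreAbe,
    )


def build_feature_table(sset: SpectrumSet) -> pd.DataFrame:
    """One row per sample: labels plus the 14 variables.

    Columns are ``sample_id, species, phylum, dryness`` followed by
    :data:`FEATURE_NAMES`.
    """
    rows = []
    for s in sset:
        rec = {
            "sample_id": s.sample_id,
            "species": s.species,
            "phylum": s.phylum,
            "dryness": s.dryness,
        }
        rec.update(extract_features(s).as_dict())
        rows.append(rec)
    columns = list(LABEL_COLUMNS) + list(FEATURE_NAMES)
    return pd.DataFrame(rows, columns=columns)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table CSV with columns in significance order."""
    cols = list(LABEL_COLUMNS) + [c for c in SIGNIFICANCE_ORDER if c in table.columns]
    table[cols].to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature CSV back into the canonical column order."""
    df = pd.read_csv(path, dtype={c: str for c in LABEL_COLUMNS})
    cols = list(LABEL_COLUMNS) + [c for c in FEATURE_NAMES if c in df.columns]
    return df[cols]
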