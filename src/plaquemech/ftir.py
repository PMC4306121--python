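"""FTIR-based grading of plaque calcification via the Ca:Li peak-area ratio.

ATR-FTIR absorbance spectra of the plaque luminal surface carry a lipid
signature (the CH2 stretch region 2972-2845 cm^-1 and, when present, the
lipid ester carbonyl near 1730 cm^-1) and a calcification signature (the
phosphate band 1180-900 cm^-1). The ratio of baseline-corrected phosphate
area to total lipid area (Ca:Li) grades plaques as lightly (1 < Ca:Li < 1.5),
moderately (1.5 <= Ca:Li < 2) or heavily (2 <= Ca:Li < 3) calcified; ratios
at or below 1 or at or above 3 are left unclassified. The open boundaries of
the published intervals are resolved half-open, assigning a boundary ratio
to the more calcified class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "FTIRSpectrum",
    "CaLiClassification",
    "LIPID_CH2_BAND",
    "LIPID_ESTER_BAND",
    "PHOSPHATE_BAND",
    "subtract_reference",
    "resample_uniform",
    "peak_area",
    "ca_li_ratio",
    "classify",
    "CalcificationClassifier",
    "read_spectrum",
    "classification_table",
]

LIPID_CH2_BAND = (2845.0, 2972.0)
LIPID_ESTER_BAND = (1710.0, 1750.0)
PHOSPHATE_BAND = (900.0, 1180.0)

ACQUISITION_RANGE = (700.0, 4000.0)
RESOLUTION = 2.0  # cm^-1, instrument resolution; integration grid step


@dataclass(frozen=True)
class FTIRSpectrum:
    """Absorbance spectrum: wavenumber (cm^-1, strictly monotone) vs absorbance."""

    wavenumber: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumber, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavenumber", wn)
        object.__setattr__(self, "absorbance", ab)
        if wn.ndim != 1 or wn.shape != ab.shape or wn.size < 2:
            raise ValueError("wavenumber and absorbance must be matching 1-D arrays")
        d = np.diff(wn)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber must be strictly monotone")
        lo, hi = float(wn.min()), float(wn.max())
        if lo < ACQUISITION_RANGE[0] - 1e-9 or hi > ACQUISITION_RANGE[1] + 1e-9:
            raise ValueError(
                f"wavenumbers must lie within {ACQUISITION_RANGE} cm^-1, got [{lo}, {hi}]"
            )

    def ascending(self) -> "FTIRSpectrum":
        """Copy with wavenumbers in ascending order."""
        if self.wavenumber[0] <= self.wavenumber[-1]:
            return self
        return FTIRSpectrum(
            self.wavenumber[::-1], self.absorbance[::-1], self.sample_id, dict(self.metadata)
        )

    @property
    def range(self) -> tuple[float, float]:
        return float(self.wavenumber.min()), float(self.wavenumber.max())


@dataclass(frozen=True)
class CaLiClassification:
    ca_li_ratio: float
    group: str


def subtract_reference(spectrum: FTIRSpectrum, reference: FTIRSpectrum) -> FTIRSpectrum:
    """Subtract a reference (e.g. water) spectrum, interpolated onto the sample grid."""
    s = spectrum.ascending()
    ref = reference.ascending()
    if ref.wavenumber[0] > s.wavenumber[0] + 1e-9 or ref.wavenumber[-1] < s.wavenumber[-1] - 1e-9:
        raise ValueError("reference spectrum does not cover the sample's wavenumber range")
    ref_interp = np.interp(s.wavenumber, ref.wavenumber, ref.absorbance)
    return FTIRSpectrum(
        s.wavenumber, s.absorbance - ref_interp, spectrum.sample_id, dict(spectrum.metadata)
    )


def resample_uniform(spectrum: FTIRSpectrum, step: float = RESOLUTION) -> FTIRSpectrum:
    """Resample onto a uniform ascending grid at the given step (default 2 cm^-1)."""
    s = spectrum.ascending()
    lo, hi = s.range
    n = int(np.floor((hi - lo) / step)) + 1
    grid = lo + step * np.arange(n)
    ab = np.interp(grid, s.wavenumber, s.absorbance)
    return FTIRSpectrum(grid, ab, spectrum.sample_id, dict(spectrum.metadata))


def peak_area(spectrum: FTIRSpectrum, band: tuple[float, float]) -> float:
    """Baseline-corrected band area (absorbance * cm^-1), clipped at zero.

    The spectrum is resampled to the uniform instrument grid, a straight
    baseline joining the absorbance at the two band edges is subtracted, and
    the remainder is integrated by the trapezoidal rule. This reproduces the
    endpoint-baseline area tool of instrument software and makes the result
    invariant to any global linear (offset + slope) baseline.
    """
    lo, hi = float(min(band)), float(max(band))
    s = resample_uniform(spectrum)
    rlo, rhi = s.range
    if lo < rlo - 1e-9 or hi > rhi + 1e-9:
        raise ValueError(f"band [{lo}, {hi}] lies outside spectrum range [{rlo}, {rhi}]")
    # sample exactly on [lo, hi], including the edges
    inner = s.wavenumber[(s.wavenumber > lo) & (s.wavenumber < hi)]
    grid = np.concatenate([[lo], inner, [hi]])
    ab = np.interp(grid, s.wavenumber, s.absorbance)
    baseline = ab[0] + (ab[-1] - ab[0]) * (grid - lo) / (hi - lo)
    area = float(np.trapezoid(ab - baseline, grid))
    return max(area, 0.0)


def ca_li_ratio(
    spectrum: FTIRSpectrum,
    ester_band: tuple[float, float] = LIPID_ESTER_BAND,
    include_ester: bool = True,
) -> float:
    """Phosphate area over total lipid (CH2 + ester) area.

    The ester carbonyl contribution is included when its baseline-corrected
    area is positive (it is not always detectable); set ``include_ester`` to
    False to use the CH2 stretch region alone.
    """
    phosphate = peak_area(spectrum, PHOSPHATE_BAND)
    lipid = peak_area(spectrum, LIPID_CH2_BAND)
    if include_ester:
        lipid += peak_area(spectrum, ester_band)
    if lipid <= 0.0:
        raise ValueError("lipid peak area is zero; Ca:Li ratio undefined")
    return phosphate / lipid


def classify(
    ratio: float,
    thresholds: tuple[float, float, float, float] = (1.0, 1.5, 2.0, 3.0),
) -> CaLiClassification:
    """Map a Ca:Li ratio to a calcification group.

    Half-open intervals [lo, hi) at the interior boundaries: lightly on
    (1, 1.5), moderately on [1.5, 2), heavily on [2, 3); anything at or
    outside the outer boundaries is 'unclassified'.
    """
    if not np.isfinite(ratio) or ratio <= 0:
        raise ValueError(f"Ca:Li ratio must be a positive number, got {ratio!r}")
    t0, t1, t2, t3 = thresholds
    if ratio <= t0 or ratio >= t3:
        group = "unclassified"
    elif ratio < t1:
        group = "lightly"
    elif ratio < t2:
        group = "moderately"
    else:
        group = "heavily"
    return CaLiClassification(float(ratio), group)


class CalcificationClassifier(ClassifierMixin, BaseEstimator):
    """Threshold classifier over Ca:Li ratios, scikit-learn compatible.

    A fixed-rule classifier: ``fit`` only records the class labels (the
    thresholds are parameters, not learned), so the estimator slots into
    sklearn pipelines and metrics. ``X`` is a single column of Ca:Li ratios.
    """

    def __init__(self, thresholds: tuple[float, float, float, float] = (1.0, 1.5, 2.0, 3.0)):
        self.thresholds = thresholds

    def fit(self, X=None, y=None):
        t = tuple(self.thresholds)
        if len(t) != 4 or any(a >= b for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be four strictly increasing values")
        self.classes_ = np.array(["heavily", "lightly", "moderately", "unclassified"])
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self)
        ratios = np.asarray(X, dtype=float)
        if ratios.ndim == 2:
            ratios = ratios[:, 0]
        return np.array([classify(r, self.thresholds).group for r in ratios])

    def predict_spectra(self, spectra: Iterable[FTIRSpectrum]):
        ratios = np.array([ca_li_ratio(s) for s in spectra])
        return self.predict(ratios)


def read_spectrum(path: str | Path, sample_id: str | None = None) -> FTIRSpectrum:
    """Read a two-column delimited text file (wavenumber cm^-1, absorbance)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavenumber, absorbance)")
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        df = df.iloc[1:].astype(float)  # tolerate a header row
    return FTIRSpectrum(
        df.iloc[:, 0].to_numpy(float),
        df.iloc[:, 1].to_numpy(float),
        sample_id or path.stem,
    )


def classification_table(spectra: Iterable[FTIRSpectrum]) -> pd.DataFrame:
    """Classify a set of spectra; columns sample_id, ca_li_ratio, group."""
    rows = []
    for s in spectra:
        ratio = ca_li_ratio(s)
        rows.append(
            {
                "sample_id": s.sample_id,
                "ca_li_ratio": ratio,
                "group": classify(ratio).group,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "ca_li_ratio", "group"])
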