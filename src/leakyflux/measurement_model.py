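"""From GC-MS observations to fit-ready quantities.

This module turns integrated, internal-standard-normalised GC-MS signals
into the inputs the flux fit consumes:

* natural-abundance correction of raw mass spectra to backbone mass
  isotopomer distributions (MIDs), via a fragment-specific correction
  matrix built from published isotope abundances;
* fractional labelling (% 13C atom enrichment) of a MID;
* calibration-curve fitting and inverse prediction of concentrations,
  with error variances propagated from the calibration residuals;
* the acetyl-CoA enrichment inferred from citrate and malate enrichment
  (citrate condenses a 4-carbon oxaloacetate, proxied by malate, with a
  2-carbon acetyl unit).

Chromatogram peak detection and integration are upstream of this module:
the input boundary is integrated, normalised peak areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .isotopes import P13C, formula_distribution

__all__ = [
    "FragmentSpec",
    "CalibrationCurve",
    "MeasurementSet",
    "MAB_FRAGMENTS",
    "ENRICHMENT_SIGMA",
    "correction_matrix",
    "correct_mid",
    "fractional_labelling",
    "fit_calibration",
    "quantify",
    "infer_acetylcoa_enrichment",
    "natural_backbone_mid",
]

#: uniform standard error assumed for every enrichment fraction,
#: derived from the worst measured-vs-theoretical discrepancy on
#: natural-abundance standards.
ENRICHMENT_SIGMA = 0.01


class MeasurementError(ValueError):
    """Raised for data-quality failures (e.g. strongly negative fractions)."""


@dataclass(frozen=True)
class FragmentSpec:
    """A monitored GC-MS fragment ion.

    ``formula`` counts the atoms of the measured ion *excluding* the
    backbone carbons (derivatization groups plus backbone H/O/N);
    backbone carbons are handled separately so labelled carbons do not
    double-count.
    """

    metabolite: str
    backbone_carbons: int
    formula: dict[str, int]
    mz: int

    def __post_init__(self):
        if self.backbone_carbons < 1:
            raise ValueError("backbone_carbons must be positive")
        if any(v < 0 for v in self.formula.values()):
            raise ValueError("element counts must be >= 0")


# Fragments of the methoximation-acetylation-butylation (MAB) derivatives
# monitored for pyruvate (m/z 142), lactate (m/z 115) and the
# gluconitrile derivative of glucose (m/z 314).  The exact elemental
# compositions of these ions are not published; the formulas below are
# documented assumptions consistent with the derivatization chemistry
# (methoxime + butyl ester for pyruvate, acetyl + butyl ester fragment
# for lactate, aldononitrile pentaacetate minus one acetate for glucose).
# They affect only the correction matrix, not the pipeline logic.
MAB_FRAGMENTS: dict[str, FragmentSpec] = {
    "pyruvate": FragmentSpec("pyruvate", 3, {"C": 4, "H": 8, "N": 1, "O": 3}, 142),
    "lactate": FragmentSpec("lactate", 3, {"C": 2, "H": 7, "O": 3}, 115),
    "glucose": FragmentSpec("glucose", 6, {"C": 6, "H": 16, "N": 1, "O": 8}, 314),
}


def correction_matrix(frag: FragmentSpec, natural_backbone: bool = True) -> np.ndarray:
    """Square matrix mapping a backbone MID to the observed mass spectrum.

    Column j is the predicted observed mass-shift distribution (window
    M+0 .. M+n, n = backbone carbons) of a species with exactly j
    labelled backbone carbons: the convolution of the non-backbone
    isotope pattern with the binomial natural-13C pattern of the n - j
    unlabelled backbone carbons, shifted by j.  Columns sum to <= 1
    because the window is truncated.

    ``natural_backbone=False`` disables natural 13C on unlabelled
    backbone carbons (then a fragment with an empty formula gives the
    identity matrix).
    """
    n = frag.backbone_carbons
    base = formula_distribution(frag.formula)
    M = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        dist = base
        if natural_backbone and n - j > 0:
            backbone = stats.binom.pmf(np.arange(n - j + 1), n - j, P13C)
            dist = np.convolve(dist, backbone)
        for i in range(j, n + 1):
            k = i - j
            if k < len(dist):
                M[i, j] = dist[k]
    return M


def correct_mid(raw: np.ndarray, matrix: np.ndarray,
                negative_tolerance: float = 1e-3) -> np.ndarray:
    """Invert the correction matrix by least squares to recover the MID.

    Components more negative than ``-negative_tolerance`` indicate a
    data-quality problem and raise; smaller negatives (GC-MS noise
    floor) are clipped to zero with a warning, and the result is
    renormalised to sum to 1.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape[0] != matrix.shape[0]:
        raise ValueError(
            f"raw spectrum length {raw.shape[0]} != matrix rows {matrix.shape[0]}"
        )
    mid, *_ = np.linalg.lstsq(matrix, raw, rcond=None)
    if mid.min() < -negative_tolerance:
        raise MeasurementError(
            f"corrected MID has component {mid.min():.4g} below tolerance "
            f"-{negative_tolerance}"
        )
    if mid.min() < -1e-9:  # real clip, not float noise
        warnings.warn(
            f"clipping small negative MID component ({mid.min():.2e})",
            stacklevel=2,
        )
    mid = np.clip(mid, 0.0, None)
    total = mid.sum()
    if total <= 0:
        raise MeasurementError("corrected MID sums to zero")
    return mid / total


def natural_backbone_mid(n: int) -> np.ndarray:
    """Binomial MID of an unenriched n-carbon backbone at natural 13C abundance."""
    return stats.binom.pmf(np.arange(n + 1), n, P13C)


def fractional_labelling(mid: np.ndarray, n: int) -> float:
    """% 13C atom enrichment: 100 * sum(i * M_i) / n."""
    if n == 0:
        raise ValueError("fragment must have at least one backbone carbon")
    mid = np.asarray(mid, dtype=float)
    return float(100.0 * np.dot(np.arange(len(mid)), mid) / n)


@dataclass(frozen=True)
class CalibrationCurve:
    """Ordinary least-squares response line for one analyte."""

    metabolite: str
    slope: float  # response per mM
    intercept: float
    residual_variance: float  # response^2
    r_squared: float
    conc_range: tuple[float, float]

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if self.residual_variance < 0:
            raise ValueError("residual variance must be >= 0")

    @property
    def concentration_sigma(self) -> float:
        """Standard error (mM) of an inverse-predicted concentration."""
        return float(np.sqrt(self.residual_variance) / self.slope)


def fit_calibration(standards, metabolite: str = "") -> CalibrationCurve:
    """Fit a calibration line to (mM, normalised response) pairs.

    Requires >= 3 distinct concentrations; residual variance is
    RSS / (n - 2), the OLS error-variance estimate.
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("standards must be (mM, response) pairs")
    conc, resp = arr[:, 0], arr[:, 1]
    if len(np.unique(conc)) < 3:
        raise ValueError("need >= 3 distinct standard concentrations")
    res = stats.linregress(conc, resp)
    pred = res.intercept + res.slope * conc
    rss = float(np.sum((resp - pred) ** 2))
    return CalibrationCurve(
        metabolite=metabolite,
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_variance=rss / (len(conc) - 2),
        r_squared=float(res.rvalue**2),
        conc_range=(float(conc.min()), float(conc.max())),
    )


def quantify(response: float, curve: CalibrationCurve,
             extrapolation_guard: float = 1.2) -> tuple[float, float]:
    """Inverse-predict (concentration mM, variance mM^2) from a response.

    Responses beyond ``extrapolation_guard`` times the calibrated range
    are refused rather than extrapolated.
    """
    hi = curve.intercept + curve.slope * curve.conc_range[1] * extrapolation_guard
    lo = curve.intercept + curve.slope * curve.conc_range[0] / extrapolation_guard
    if not (min(lo, 0.0) <= response <= hi):
        raise ValueError(
            f"response {response:.4g} outside calibrated range of {curve.metabolite}"
        )
    conc = (response - curve.intercept) / curve.slope
    return conc, curve.residual_variance / curve.slope**2


def infer_acetylcoa_enrichment(fl_citrate: float, fl_malate: float) -> float:
    """Acetyl-CoA % enrichment from citrate and malate fractional labelling.

    Citrate (6 C) is condensed from oxaloacetate (4 C, proxied by
    malate) and the acetyl unit (2 C), so carbon bookkeeping gives
    FL_AcCoA = (6*FL_cit - 4*FL_mal) / 2.  Values outside [0, 100] are
    clipped with a warning — they indicate the proxy assumption is
    strained for that sample.
    """
    for v in (fl_citrate, fl_malate):
        if not 0.0 <= v <= 100.0:
            raise ValueError("fractional labelling inputs must lie in [0, 100]")
    fl = (6.0 * fl_citrate - 4.0 * fl_malate) / 2.0
    if not 0.0 <= fl <= 100.0:
        warnings.warn(
            f"inferred acetyl-CoA enrichment {fl:.2f}% outside [0, 100]; clipped",
            stacklevel=2,
        )
        fl = float(np.clip(fl, 0.0, 100.0))
    return fl


@dataclass
class MeasurementSet:
    """Tidy time-course measurements for one experiment.

    ``data`` columns: time_min, metabolite, quantity, value, sigma.
    ``quantity`` is "M0".."Mn" for corrected MID fractions (sigma =
    ENRICHMENT_SIGMA) or "conc" for mM concentrations (sigma from the
    calibration curve).
    """

    label: str
    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    REQUIRED = ("time_min", "metabolite", "quantity", "value", "sigma")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"measurement table missing columns {missing}")
        if (self.data["sigma"] <= 0).any():
            raise ValueError("all measurement errors must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["time_min"].unique())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "MeasurementSet":
        return cls(label or str(path), pd.read_csv(path))


def correct_measurement_set(ms: MeasurementSet,
                            fragments: dict[str, FragmentSpec] | None = None,
                            negative_tolerance: float = 4 * ENRICHMENT_SIGMA,
                            ) -> MeasurementSet:
    """Replace raw-spectrum rows (quantity ``rawM<i>``) with corrected MIDs.

    Rows already carrying corrected quantities pass through unchanged.
    The negative-component cut sits at four enrichment sigmas: raw
    spectra carry ~0.01 noise per channel, so corrected fractions a few
    hundredths below zero are the noise floor, not a data-quality
    failure.
    """
    fragments = fragments or MAB_FRAGMENTS
    df = ms.data
    raw = df["quantity"].str.startswith("rawM")
    if not raw.any():
        return ms
    keep = df[~raw].copy()
    out_rows = [keep]
    for (t, met), grp in df[raw].groupby(["time_min", "metabolite"]):
        order = grp["quantity"].str.removeprefix("rawM").astype(int)
        spectrum = grp["value"].to_numpy()[np.argsort(order.to_numpy())]
        frag = fragments[met]
        mid = correct_mid(spectrum, correction_matrix(frag),
                          negative_tolerance=negative_tolerance)
        out_rows.append(pd.DataFrame({
            "time_min": t, "metabolite": met,
            "quantity": [f"M{i}" for i in range(len(mid))],
            "value": mid, "sigma": ENRICHMENT_SIGMA,
        }))
    data = pd.concat(out_rows, ignore_index=True).sort_values(
        ["time_min", "metabolite", "quantity"], kind="stable"
    )
    return MeasurementSet(ms.label, data.reset_index(drop=True), dict(ms.meta))
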