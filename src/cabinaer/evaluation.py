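"""Model-performance evaluation statistics for air-quality predictions.

The standard Hanna/Chang suite over paired observed (O) and predicted (P)
series:

    r     Pearson correlation coefficient
    FAC2  fraction of pairs with 0.5 <= P/O <= 2 (endpoints inclusive)
    FB    fractional bias, (Obar - Pbar) / (0.5 (Obar + Pbar));
          positive FB = underprediction
    MG    geometric mean bias, exp(mean ln O - mean ln P)
    NMSE  normalized mean square error, mean((O-P)^2) / (Obar * Pbar)
    VG    geometric variance, exp(mean (ln O - ln P)^2)

FB maps one-to-one onto the mean prediction/observation ratio:

    Pbar/Obar = (1 - 0.5 FB) / (1 + 0.5 FB)

so FB = 2/3 corresponds to underprediction by a factor of two.

A prediction is conventionally judged acceptable when 0.7 < MG < 1.3,
|FB| < 0.3, VG < 1.6, NMSE < 4, FAC2 > 0.7 and r > 0.7.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Published acceptance thresholds for a good atmospheric model prediction.
CRITERIA = {
    "mg": "0.7 < MG < 1.3",
    "fb": "|FB| < 0.3",
    "vg": "VG < 1.6",
    "nmse": "NMSE < 4",
    "fac2": "FAC2 > 0.7",
    "r": "r > 0.7",
}


@dataclass
class PairedSeries:
    """Paired observed/predicted values of equal length >= 2."""

    observed: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.observed.shape != self.predicted.shape or self.observed.ndim != 1:
            raise ValueError("observed and predicted must be 1-D of equal length")
        if len(self.observed) < 2:
            raise ValueError("need at least 2 pairs")
        if np.any(self.observed < 0) or np.any(self.predicted < 0):
            raise ValueError("concentrations must be non-negative")


@dataclass
class EvalReport:
    """The six evaluation metrics. ``r`` is NaN when a series has zero
    variance (correlation undefined)."""

    r: float
    fac2: float
    fb: float
    mg: float
    nmse: float
    vg: float

    def to_dict(self) -> dict:
        return {"r": self.r, "fac2": self.fac2, "fb": self.fb,
                "mg": self.mg, "nmse": self.nmse, "vg": self.vg}


def compute_metrics(series: PairedSeries) -> EvalReport:
    """Compute the full metric suite for one paired series.

    Pairs where either value is zero are excluded from the logarithmic
    metrics (MG, VG) with a logged count; if more than 10% of pairs are
    affected the log metrics are considered unreliable and an error is
    raised.
    """
    o, p = series.observed, series.predicted
    obar, pbar = float(np.mean(o)), float(np.mean(p))

    if np.ptp(o) == 0 or np.ptp(p) == 0:
        logger.warning("zero-variance series: Pearson r undefined, reported as NaN")
        r = float("nan")
    else:
        r = float(sps.pearsonr(o, p).statistic)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(o > 0, p / o, np.inf)
    fac2 = float(np.mean((ratio >= 0.5) & (ratio <= 2.0)))

    if obar + pbar == 0:
        fb = 0.0
        nmse = 0.0
    else:
        fb = (obar - pbar) / (0.5 * (obar + pbar))
        if obar == 0 or pbar == 0:
            raise ValueError("NMSE undefined: a series mean is zero")
        nmse = float(np.mean((o - p) ** 2) / (obar * pbar))

    pos = (o > 0) & (p > 0)
    n_excluded = int(np.sum(~pos))
    if n_excluded:
        logger.info("excluding %d pair(s) with zeros from MG/VG", n_excluded)
        if n_excluded > 0.1 * len(o):
            raise ValueError(
                f"{n_excluded}/{len(o)} pairs contain zeros (>10%): "
                "logarithmic metrics MG/VG are unreliable"
            )
    lo, lp = np.log(o[pos]), np.log(p[pos])
    mg = float(np.exp(np.mean(lo) - np.mean(lp)))
    vg = float(np.exp(np.mean((lo - lp) ** 2)))
    return EvalReport(r=r, fac2=fac2, fb=fb, mg=mg, nmse=nmse, vg=vg)


def fb_to_ratio(fb: float) -> float:
    """Mean prediction/observation ratio implied by a fractional bias:
    Pbar/Obar = (1 - 0.5 FB)/(1 + 0.5 FB). Defined on FB in (-2, 2)."""
    if not -2.0 < fb < 2.0:
        raise ValueError("FB must lie strictly inside (-2, 2)")
    return (1.0 - 0.5 * fb) / (1.0 + 0.5 * fb)


def ratio_to_fb(ratio: float) -> float:
    """Inverse of :func:`fb_to_ratio`: FB = 2 (1 - R)/(1 + R) for R > 0."""
    if ratio <= 0:
        raise ValueError("mean ratio must be positive")
    return 2.0 * (1.0 - ratio) / (1.0 + ratio)


def criteria_check(report: EvalReport) -> dict[str, bool]:
    """Evaluate the six published acceptance criteria on a report.

    Returns one boolean per criterion plus their conjunction under
    ``"overall"``. An undefined r fails its criterion.
    """
    checks = {
        "mg": 0.7 < report.mg < 1.3,
        "fb": abs(report.fb) < 0.3,
        "vg": report.vg < 1.6,
        "nmse": report.nmse < 4.0,
        "fac2": report.fac2 > 0.7,
        "r": (not math.isnan(report.r)) and report.r > 0.7,
    }
    checks["overall"] = all(checks.values())
    return checks


def evaluate(observed, predicted) -> tuple[EvalReport, dict[str, bool]]:
    """Convenience wrapper: metrics plus criteria for raw arrays."""
    report = compute_metrics(PairedSeries(observed, predicted))
    return report, criteria_check(report)
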