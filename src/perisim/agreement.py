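"""Pointwise agreement analysis between two perimeters.

Implements the method-comparison pipeline for paired per-location
sensitivities from a projection perimeter ("octopus", 0–33 dB) and a
head-mounted perimeter ("hmp", 0–16 dB raw scale):

* scale harmonization (+14 dB to HMP values, floor 0 stays 0);
* censoring to the HMP's measurable window (Octopus 14–30 dB, strict)
  before regression, because floor and ceiling effects outside that window
  would bias the fit;
* Deming errors-in-variables regression (both devices measure with error,
  so ordinary least squares would attenuate the slope);
* Bland-Altman limits of agreement on pairs above the HMP floor;
* a contingency table and diagnostic sensitivity/specificity for the HMP's
  ability to flag locations with low Octopus sensitivity (< 14 dB) by
  reaching its own floor (0 dB).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .devices import to_octopus_equivalent
from .zest import MeasuredField

__all__ = [
    "DemingFit",
    "BlandAltmanResult",
    "ContingencyCounts",
    "AgreementReport",
    "build_pairs",
    "censor_for_regression",
    "deming_fit",
    "bland_altman",
    "contingency",
    "diagnostic_metrics",
    "full_report",
]

REGRESSION_LOW_DB = 14.0
REGRESSION_HIGH_DB = 30.0
FLOOR_CUT_DB = 14.0


@dataclass(frozen=True)
class DemingFit:
    """Errors-in-variables line fit with jackknife 95% CIs."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n: int
    lam: float = 1.0


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference and 1.96-SD limits of agreement."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int

    @property
    def loa_halfwidth(self) -> float:
        return 1.96 * self.sd_diff


@dataclass(frozen=True)
class ContingencyCounts:
    """Floor-detection 2x2 table.

    Condition positive: Octopus sensitivity < 14 dB (low sensitivity the
    HMP cannot measure).  Test positive: HMP at its floor (raw 0 dB).
    """

    tn: int  # HMP above floor, Octopus >= 14
    fn: int  # HMP above floor, Octopus < 14
    fp: int  # HMP at floor,    Octopus >= 14
    tp: int  # HMP at floor,    Octopus < 14

    @property
    def total(self) -> int:
        return self.tn + self.fn + self.fp + self.tp


@dataclass(frozen=True)
class AgreementReport:
    """Bundle of all agreement statistics for one paired dataset."""

    deming: DemingFit
    bland_altman: BlandAltmanResult
    counts: ContingencyCounts
    diagnostic_sensitivity: float
    diagnostic_specificity: float
    n_pairs: int
    n_regression: int
    n_bland_altman: int
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        d, ba, c = self.deming, self.bland_altman, self.counts
        return "\n".join([
            f"Paired locations analyzed: {self.n_pairs}",
            f"Deming regression (Octopus {REGRESSION_LOW_DB:g}-"
            f"{REGRESSION_HIGH_DB:g} dB, n={d.n}):",
            f"  slope {d.slope:.2f} (95% CI {d.slope_ci[0]:.2f} to "
            f"{d.slope_ci[1]:.2f})",
            f"  intercept {d.intercept:.1f} dB (95% CI {d.intercept_ci[0]:.1f}"
            f" to {d.intercept_ci[1]:.1f})",
            f"Bland-Altman (Octopus > {FLOOR_CUT_DB:g} dB, n={ba.n}):",
            f"  mean difference {ba.mean_diff:.2f} dB, "
            f"LoA +/-{ba.loa_halfwidth:.1f} dB "
            f"[{ba.loa_low:.1f}, {ba.loa_high:.1f}]",
            f"Floor-detection contingency (n={c.total}): "
            f"tn={c.tn} fn={c.fn} fp={c.fp} tp={c.tp}",
            f"  diagnostic sensitivity {self.diagnostic_sensitivity:.2f}, "
            f"specificity {self.diagnostic_specificity:.2f}",
        ])


def build_pairs(octopus_fields: list[MeasuredField],
                hmp_fields: list[MeasuredField],
                offset: float = 14.0) -> pd.DataFrame:
    """Join per-location measurements of matched (subject, eye) exams.

    Returns one row per location with columns ``subject_id, eye, x_deg,
    y_deg, octopus_db, hmp_db_raw, hmp_db_equivalent`` where the
    equivalent column applies the +14 dB harmonization (floor stays 0).
    """
    if not octopus_fields or not hmp_fields:
        raise ValueError("need at least one field per device")
    oct_by_key = {(f.subject_id, f.eye): f for f in octopus_fields}
    hmp_by_key = {(f.subject_id, f.eye): f for f in hmp_fields}
    if set(oct_by_key) != set(hmp_by_key):
        raise ValueError(
            "unmatched (subject, eye) pairs between devices: "
            f"{sorted(set(oct_by_key) ^ set(hmp_by_key))}")
    rows = []
    for key in oct_by_key:
        fo, fh = oct_by_key[key], hmp_by_key[key]
        if not np.array_equal(fo.grid.xy, fh.grid.xy):
            raise ValueError(f"grid mismatch for {key}")
        rows.append(pd.DataFrame({
            "subject_id": fo.subject_id, "eye": fo.eye,
            "x_deg": fo.grid.x, "y_deg": fo.grid.y,
            "octopus_db": fo.sensitivity_db,
            "hmp_db_raw": fh.sensitivity_db,
        }))
    df = pd.concat(rows, ignore_index=True)
    df["hmp_db_equivalent"] = to_octopus_equivalent(
        df["hmp_db_raw"].to_numpy(), offset)
    return df


def censor_for_regression(pairs: pd.DataFrame,
                          low: float = REGRESSION_LOW_DB,
                          high: float = REGRESSION_HIGH_DB) -> pd.DataFrame:
    """Keep pairs with ``low < octopus_db < high`` (strict bounds).

    Outside this window the HMP is at its floor or ceiling, so including
    those pairs would fit the censoring mechanism rather than the scale
    relationship.  Order-preserving.
    """
    keep = (pairs["octopus_db"] > low) & (pairs["octopus_db"] < high)
    return pairs.loc[keep]


def deming_fit(x, y, lam: float = 1.0) -> DemingFit:
    """Deming errors-in-variables regression of ``y`` on ``x``.

    ``lam`` is the ratio of the error variances (y-error over x-error);
    with ``lam=1`` this is orthogonal (total least squares) regression.
    95% confidence intervals use the leave-one-out jackknife with a normal
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points for a Deming fit")
    if np.ptp(x) == 0:
        raise ValueError("x values are all identical")

    def _fit(xs, ys):
        sxx = np.var(xs, ddof=1)
        syy = np.var(ys, ddof=1)
        sxy = np.cov(xs, ys, ddof=1)[0, 1]
        if sxy == 0:
            # Degenerate geometry: no linear association; the Deming slope
            # is undefined (the perpendicular objective has no unique line).
            raise ValueError("zero covariance: Deming slope undefined")
        d = syy - lam * sxx
        slope = (d + math.sqrt(d * d + 4 * lam * sxy * sxy)) / (2 * sxy)
        return slope, ys.mean() - slope * xs.mean()

    slope, intercept = _fit(x, y)
    idx = np.arange(n)
    loo = np.array([_fit(x[idx != i], y[idx != i]) for i in range(n)])
    se = np.sqrt((n - 1) / n * ((loo - loo.mean(axis=0)) ** 2).sum(axis=0))
    z = 1.959963984540054
    return DemingFit(
        slope=slope, intercept=intercept,
        slope_ci=(slope - z * se[0], slope + z * se[0]),
        intercept_ci=(intercept - z * se[1], intercept + z * se[1]),
        n=n, lam=lam)


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman statistics of the differences ``d = x - y``.

    Mean and SD (n-1 denominator) of the paired differences, with limits
    of agreement at mean +/- 1.96 SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(mean_diff=m, sd_diff=sd,
                             loa_low=m - 1.96 * sd, loa_high=m + 1.96 * sd,
                             n=len(d))


def contingency(pairs: pd.DataFrame,
                octopus_cut: float = FLOOR_CUT_DB) -> ContingencyCounts:
    """Cross-classify locations by Octopus < cut vs HMP at floor (raw 0)."""
    low = pairs["octopus_db"].to_numpy() < octopus_cut
    floored = pairs["hmp_db_raw"].to_numpy() == 0.0
    return ContingencyCounts(
        tn=int(np.sum(~floored & ~low)),
        fn=int(np.sum(~floored & low)),
        fp=int(np.sum(floored & ~low)),
        tp=int(np.sum(floored & low)))


def diagnostic_metrics(counts: ContingencyCounts) -> tuple[float, float]:
    """Diagnostic sensitivity tp/(tp+fn) and specificity tn/(tn+fp)."""
    if counts.tp + counts.fn == 0:
        raise ZeroDivisionError(
            "diagnostic sensitivity undefined: no condition-positive pairs")
    if counts.tn + counts.fp == 0:
        raise ZeroDivisionError(
            "diagnostic specificity undefined: no condition-negative pairs")
    return (counts.tp / (counts.tp + counts.fn),
            counts.tn / (counts.tn + counts.fp))


def full_report(octopus_fields: list[MeasuredField],
                hmp_fields: list[MeasuredField],
                offset: float = 14.0,
                lam: float = 1.0,
                ba_drop_floored: bool = False) -> AgreementReport:
    """Run the complete agreement pipeline on matched field pairs.

    Deming regression uses pairs censored to the strict (14, 30) dB
    Octopus window.  Bland-Altman compares the *uncorrected* sensitivities
    (octopus_db minus hmp_db_raw) over pairs with Octopus > 14 dB; HMP
    floor values are kept as 0 unless ``ba_drop_floored`` drops them.
    The contingency table and diagnostic metrics use all pairs.
    """
    pairs = build_pairs(octopus_fields, hmp_fields, offset)
    reg = censor_for_regression(pairs)
    dem = deming_fit(reg["octopus_db"], reg["hmp_db_raw"], lam)
    ba_pairs = pairs.loc[pairs["octopus_db"] > FLOOR_CUT_DB]
    if ba_drop_floored:
        ba_pairs = ba_pairs.loc[ba_pairs["hmp_db_raw"] > 0]
    ba = bland_altman(ba_pairs["octopus_db"], ba_pairs["hmp_db_raw"])
    counts = contingency(pairs)
    sens, spec = diagnostic_metrics(counts)
    return AgreementReport(
        deming=dem, bland_altman=ba, counts=counts,
        diagnostic_sensitivity=sens, diagnostic_specificity=spec,
        n_pairs=len(pairs), n_regression=dem.n, n_bland_altman=ba.n,
        options={"offset": offset, "lambda": lam,
                 "ba_drop_floored": ba_drop_floored})
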