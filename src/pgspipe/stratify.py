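"""Odds-ratio risk stratification.

Top-percentile versus bottom-half odds ratios with Wald (normal
approximation) confidence intervals on the log scale, and the 3 BMI-band x
7 score-septile odds-ratio grid against the medium-BMI / median-septile
reference cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .scoring import ScoreVector
from .simulate import Cohort

__all__ = [
    "ContingencyTable",
    "OrEstimate",
    "StratumResult",
    "odds_ratio_wald",
    "or_from_wald_ci",
    "top_vs_bottom_or",
    "assign_septiles",
    "assign_bmi_band",
    "bmi_pgs_grid",
]

BMI_BANDS = ("low", "medium", "high")  # [18.5, 25), [25, 30), [30, inf)
N_SEPTILES = 7
REFERENCE_SEPTILE = 4


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: exposed (a cases, b controls) vs reference (c, d)."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("inestimable: a+b and c+d must both be positive")


@dataclass(frozen=True)
class OrEstimate:
    odds_ratio: float
    ci_low: float
    ci_high: float
    alpha: float
    cells: ContingencyTable
    zero_cell_corrected: bool = False

    def __post_init__(self) -> None:
        if not self.ci_low <= self.odds_ratio <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")
        gm = np.sqrt(self.ci_low * self.ci_high)
        if abs(gm - self.odds_ratio) > 1e-9 * max(1.0, self.odds_ratio):
            raise ValueError("Wald interval must be log-symmetric about the OR")


@dataclass(frozen=True)
class StratumResult:
    stratum_label: str
    estimate: OrEstimate


def odds_ratio_wald(table: ContingencyTable, alpha: float = 0.05) -> OrEstimate:
    """Odds ratio with a Wald interval on the log scale.

    OR = ad/bc; SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d);
    CI = exp(log OR +/- z_{1-alpha/2} SE). Any zero cell triggers the
    Haldane-Anscombe +0.5 correction on all four cells, flagged in the output.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_ = (a * d) / (b * c)
    se_log = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    log_or = np.log(or_)
    return OrEstimate(
        odds_ratio=float(or_),
        ci_low=float(np.exp(log_or - z * se_log)),
        ci_high=float(np.exp(log_or + z * se_log)),
        alpha=alpha,
        cells=table,
        zero_cell_corrected=corrected,
    )


def or_from_wald_ci(ci_low: float, ci_high: float) -> float:
    """Point estimate implied by a log-symmetric Wald interval: sqrt(L*U)."""
    if ci_low <= 0 or ci_high <= 0 or ci_high < ci_low:
        raise ValueError("CI bounds must be positive and ordered")
    return float(np.sqrt(ci_low * ci_high))


def top_vs_bottom_or(
    scores: ScoreVector,
    labels: np.ndarray,
    top_fraction: float,
    bottom_fraction: float = 0.5,
    alpha: float = 0.05,
) -> StratumResult:
    """Odds ratio of the top score percentile against the bottom half.

    Exposed: percentile rank >= 1 - top_fraction. Reference: rank <
    bottom_fraction.
    """
    if top_fraction + bottom_fraction > 1.0:
        raise ValueError("top_fraction + bottom_fraction must not exceed 1")
    y = np.asarray(labels)
    if y.dtype == object or y.dtype.kind in "US":
        y = y == "case"
    y = y.astype(bool)
    pr = scores.percentile_rank
    top = pr >= 1.0 - top_fraction
    bottom = pr < bottom_fraction
    if not top.any() or not bottom.any():
        raise ValueError("empty exposure or reference group after thresholding")
    table = ContingencyTable(
        a=int((top & y).sum()),
        b=int((top & ~y).sum()),
        c=int((bottom & y).sum()),
        d=int((bottom & ~y).sum()),
    )
    label = f"top {top_fraction:.0%} vs bottom {bottom_fraction:.0%}"
    return StratumResult(stratum_label=label, estimate=odds_ratio_wald(table, alpha))


def assign_septiles(scores: ScoreVector) -> np.ndarray:
    """Equal-frequency septile (1..7) from percentile ranks.

    Septile k covers ranks in [(k-1)/7, k/7), with the last interval closed;
    the middle septile spans ranks ~42.9-57.1%. Ties share a mid-rank and so
    share a septile.
    """
    if len(scores) < N_SEPTILES:
        raise ValueError(f"need at least {N_SEPTILES} samples")
    k = np.floor(scores.percentile_rank * N_SEPTILES).astype(int) + 1
    return np.minimum(k, N_SEPTILES)


def assign_bmi_band(bmi) -> np.ndarray:
    """BMI band: low [18.5, 25), medium [25, 30), high [30, inf).

    Values below 18.5 (or missing) must be filtered upstream and raise here.
    """
    arr = np.atleast_1d(np.asarray(bmi, dtype=float))
    if np.isnan(arr).any() or (arr < 18.5).any():
        raise ValueError("BMI below 18.5 or missing: filter before banding")
    bands = np.where(arr < 25.0, "low", np.where(arr < 30.0, "medium", "high"))
    return bands.astype(object)


def bmi_pgs_grid(cohort: Cohort, scores: ScoreVector, alpha: float = 0.05) -> list[StratumResult]:
    """21-cell odds-ratio grid over BMI bands x score septiles.

    Each cell's OR is computed against the (medium BMI, septile 4) reference
    cell; the reference itself is reported with OR = 1.
    """
    if not np.array_equal(cohort.sample_ids, scores.sample_ids):
        raise ValueError("cohort and scores must cover the same samples in order")
    y = cohort.is_case
    bands = assign_bmi_band(cohort.bmi)
    septiles = assign_septiles(scores)

    ref = (bands == "medium") & (septiles == REFERENCE_SEPTILE)
    ref_cases = int((ref & y).sum())
    ref_ctrls = int((ref & ~y).sum())
    if ref_cases < 1 or ref_ctrls < 1:
        raise ValueError("reference cell (medium BMI, septile 4) needs >=1 case and >=1 control")

    results: list[StratumResult] = []
    for band in BMI_BANDS:
        for k in range(1, N_SEPTILES + 1):
            cell = (bands == band) & (septiles == k)
            if not cell.any():
                raise ValueError(f"empty grid cell: (BMI {band}, septile {k})")
            label = f"(BMI {band}, septile {k})"
            if band == "medium" and k == REFERENCE_SEPTILE:
                table = ContingencyTable(a=ref_cases, b=ref_ctrls, c=ref_cases, d=ref_ctrls)
                est = OrEstimate(
                    odds_ratio=1.0, ci_low=1.0, ci_high=1.0, alpha=alpha, cells=table
                )
            else:
                table = ContingencyTable(
                    a=int((cell & y).sum()),
                    b=int((cell & ~y).sum()),
                    c=ref_cases,
                    d=ref_ctrls,
                )
                est = odds_ratio_wald(table, alpha)
            results.append(StratumResult(stratum_label=label, estimate=est))
    return results
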