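"""Two-sample Mendelian randomization from summary statistics.

Implements instrument selection at genome-wide significance, the
fixed-effect inverse-variance-weighted (IVW) estimator, Egger regression
with its intercept-based directional-pleiotropy test, and the odds-ratio
reporting filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import MrInstrumentSet

__all__ = [
    "MrResult",
    "INSTRUMENT_P_THRESHOLD",
    "PLEIOTROPY_ALPHA",
    "select_instruments",
    "ivw_estimate",
    "egger_estimate",
    "reporting_filter",
]

logger = logging.getLogger(__name__)

INSTRUMENT_P_THRESHOLD = 5e-8
PLEIOTROPY_ALPHA = 0.05
_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MrResult:
    method: str  # "IVW" | "Egger" | "ratio"
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n_instruments: int
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    intercept_p: float | None = None
    pleiotropy_flag: bool | None = None
    exposure: str = ""
    outcome: str = ""

    def __post_init__(self) -> None:
        if abs(self.odds_ratio - np.exp(self.beta)) > 1e-12 * max(1.0, self.odds_ratio):
            raise ValueError("odds_ratio must equal exp(beta)")
        if self.ci_low > self.ci_high:
            raise ValueError("CI bounds out of order")


def select_instruments(
    instruments: MrInstrumentSet, threshold: float = INSTRUMENT_P_THRESHOLD
) -> MrInstrumentSet:
    """Keep instruments with exposure p strictly below the threshold and
    harmonize signs so every exposure effect is positive (outcome effect
    flipped in tandem)."""
    keep = instruments.p_exposure < threshold
    sel = instruments.subset(keep)
    flip = sel.beta_exposure < 0
    sel.beta_exposure = np.abs(sel.beta_exposure)
    sel.beta_outcome = np.where(flip, -sel.beta_outcome, sel.beta_outcome)
    return sel


def _wald_or(beta: float, se: float) -> tuple[float, float, float]:
    return float(np.exp(beta)), float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se))


def ivw_estimate(instruments: MrInstrumentSet, random_effects: bool = False) -> MrResult:
    """Fixed-effect inverse-variance-weighted causal estimate.

    beta = sum(bx * by / sy^2) / sum(bx^2 / sy^2);
    se = sqrt(1 / sum(bx^2 / sy^2)). With ``random_effects`` the SE is
    inflated by the multiplicative over-dispersion factor (floored at 1).
    """
    if instruments.n_instruments < 2:
        raise ValueError("IVW needs at least 2 instruments")
    bx, by, sy = instruments.beta_exposure, instruments.beta_outcome, instruments.se_outcome
    if (sy == 0).any():
        raise ValueError("outcome SEs must be non-zero")
    w = 1.0 / (sy * sy)
    denom = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by) / denom)
    se = float(np.sqrt(1.0 / denom))
    if random_effects:
        resid = by - beta * bx
        n = instruments.n_instruments
        phi = float(np.sum(w * resid * resid) / (n - 1))
        se *= max(1.0, np.sqrt(phi))
    or_, lo, hi = _wald_or(beta, se)
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return MrResult(
        method="IVW", beta=beta, se=se, odds_ratio=or_, ci_low=lo, ci_high=hi,
        p=p, n_instruments=instruments.n_instruments,
    )


def egger_estimate(instruments: MrInstrumentSet) -> MrResult:
    """Egger regression: WLS of outcome on exposure effects, intercept free.

    Weights 1/sy^2; the slope is the causal estimate and the intercept the
    average directional pleiotropy, tested two-sided against zero with a
    t reference distribution on n-2 degrees of freedom. The pleiotropy flag
    is set when intercept_p < 0.05.
    """
    n = instruments.n_instruments
    if n < 3:
        raise ValueError("Egger regression needs at least 3 instruments")
    bx, by, sy = instruments.beta_exposure, instruments.beta_outcome, instruments.se_outcome
    if np.ptp(bx) == 0:
        raise ValueError("degenerate design: all exposure effects equal")
    w = 1.0 / (sy * sy)
    X = np.column_stack([np.ones(n), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    dof = n - 2
    s2 = float(np.sum(w * resid * resid) / dof)
    cov = s2 * np.linalg.inv(xtwx)
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    p_slope = float(2.0 * stats.t.sf(abs(slope / se_slope), dof)) if se_slope > 0 else 0.0
    p_int = float(2.0 * stats.t.sf(abs(intercept / se_int), dof)) if se_int > 0 else 0.0
    or_, lo, hi = _wald_or(slope, se_slope)
    return MrResult(
        method="Egger", beta=slope, se=se_slope, odds_ratio=or_, ci_low=lo, ci_high=hi,
        p=p_slope, n_instruments=n,
        egger_intercept=intercept, egger_intercept_se=se_int, intercept_p=p_int,
        pleiotropy_flag=p_int < PLEIOTROPY_ALPHA,
    )


def ratio_estimate(beta_exposure: float, beta_outcome: float, se_outcome: float) -> MrResult:
    """Single-instrument ratio estimate with the first-order delta-method SE."""
    if beta_exposure == 0:
        raise ValueError("ratio estimate undefined for zero exposure effect")
    beta = beta_outcome / beta_exposure
    se = abs(se_outcome / beta_exposure)
    or_, lo, hi = _wald_or(beta, se)
    p = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0
    return MrResult(
        method="ratio", beta=float(beta), se=float(se), odds_ratio=or_,
        ci_low=lo, ci_high=hi, p=p, n_instruments=1,
    )


def reporting_filter(results: list[MrResult], low: float = 0.9, high: float = 1.1) -> list[MrResult]:
    """Keep results whose OR moves at least 10%: OR >= 1.1 or OR <= 0.9
    (both boundaries inclusive). Dropped results are logged."""
    kept = []
    for r in results:
        if r.odds_ratio >= high or r.odds_ratio <= low:
            kept.append(r)
        else:
            logger.info(
                "dropped %s %s->%s: OR %.3f inside (%.2f, %.2f)",
                r.method, r.exposure, r.outcome, r.odds_ratio, low, high,
            )
    return kept
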