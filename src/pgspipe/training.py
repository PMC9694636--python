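"""Balanced-resampling logistic PGS training with cross-validated AUC model
selection, collinearity screening, and forward stepwise-AIC reduction.

The training procedure: draw ``n_subsets`` balanced designs (all cases plus a
without-replacement control sample at ``control_ratio`` controls per case),
screen each design for multicollinearity by iterative VIF pruning, fit an
unpenalized logistic regression, estimate discrimination by repeated
stratified k-fold cross-validation with a rank-statistic AUC, and keep the
design whose model has the highest mean cross-validated AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .simulate import Cohort, GenotypeMatrix

__all__ = [
    "PgsModel",
    "ResampleScheme",
    "LogisticFit",
    "SeparationError",
    "balance_controls",
    "collinearity_screen",
    "fit_logistic",
    "mann_whitney_auc",
    "cross_validated_auc",
    "train_pgs",
    "stepwise_aic",
]

DEFAULT_VIF_THRESHOLD = 10.0


class SeparationError(RuntimeError):
    """Raised when the logistic likelihood has no finite maximizer."""


@dataclass
class PgsModel:
    """An ordered SNP panel with learned log-odds weights."""

    snp_ids: np.ndarray
    weights: np.ndarray
    intercept: float
    effect_alleles: np.ndarray
    training_auc: float = float("nan")
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.weights = np.asarray(self.weights, dtype=float)
        self.effect_alleles = np.asarray(self.effect_alleles, dtype=object)
        if len(self.weights) != len(self.snp_ids):
            raise ValueError("weights length does not match snp_ids")
        if len(self.effect_alleles) != len(self.snp_ids):
            raise ValueError("effect_alleles length does not match snp_ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")
        if not (np.isnan(self.training_auc) or 0.0 <= self.training_auc <= 1.0):
            raise ValueError("training_auc must be in [0, 1]")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass(frozen=True)
class ResampleScheme:
    n_subsets: int = 10
    control_ratio: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.control_ratio < 1:
            raise ValueError("control_ratio must be >= 1")


def balance_controls(cohort: Cohort, scheme: ResampleScheme) -> list[np.ndarray]:
    """Index sets for balanced case/control designs.

    Each subset contains every case plus ``control_ratio * n_cases`` controls
    sampled without replacement (independently across subsets).
    """
    case_idx = np.flatnonzero(cohort.is_case)
    ctrl_idx = np.flatnonzero(cohort.status == "control")
    n_needed = scheme.control_ratio * len(case_idx)
    if len(ctrl_idx) < n_needed:
        raise ValueError(
            f"insufficient controls: need {n_needed} "
            f"({scheme.control_ratio} per case x {len(case_idx)} cases), "
            f"have {len(ctrl_idx)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(scheme.seed))
    subsets = []
    for _ in range(scheme.n_subsets):
        chosen = rng.choice(ctrl_idx, size=n_needed, replace=False)
        subsets.append(np.sort(np.concatenate([case_idx, chosen])))
    return subsets


def _vif_from_corr(corr: np.ndarray) -> np.ndarray:
    """Per-column VIFs; infinite where the correlation matrix is singular."""
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval[0] < 1e-10:
        null = eigvec[:, 0]
        vif = np.zeros(len(corr))
        vif[np.abs(null) > 1e-8] = np.inf
        return vif
    return np.diag(np.linalg.inv(corr))


def collinearity_screen(
    genotypes: GenotypeMatrix, vif_threshold: float = DEFAULT_VIF_THRESHOLD
) -> tuple[list[str], dict[str, float]]:
    """Iteratively drop the SNP with the largest variance-inflation factor
    until all VIFs are below ``vif_threshold``.

    Returns the retained snp_ids (original order) and a report of the VIF at
    which each SNP was dropped or last evaluated. Exactly collinear groups
    show infinite VIF and are pruned one member at a time.
    """
    if vif_threshold <= 1.0:
        raise ValueError("vif_threshold must be > 1")
    if genotypes.n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    x = genotypes.imputed()
    sd = x.std(axis=0)
    if (sd == 0.0).any():
        bad = genotypes.snp_ids[sd == 0.0][0]
        raise ValueError(f"zero-variance SNP in design: {bad}")

    active = list(range(genotypes.n_snps))
    report: dict[str, float] = {}
    while len(active) >= 2:
        corr = np.corrcoef(x[:, active].T)
        vif = _vif_from_corr(corr)
        worst = int(np.argmax(vif))
        # np.argmax returns the first max; for infinite ties drop the last
        # duplicate so the first-seen column survives
        if np.isinf(vif[worst]):
            worst = int(np.flatnonzero(np.isinf(vif))[-1])
        if vif[worst] < vif_threshold:
            for k, j in enumerate(active):
                report[str(genotypes.snp_ids[j])] = float(vif[k])
            break
        report[str(genotypes.snp_ids[active[worst]])] = float(vif[worst])
        del active[worst]
    retained = [str(genotypes.snp_ids[j]) for j in active]
    return retained, report


@dataclass
class LogisticFit:
    weights: np.ndarray
    intercept: float
    se: np.ndarray
    intercept_se: float
    z: np.ndarray
    p: np.ndarray
    loglik: float
    aic: float
    n_iter: int


def fit_logistic(dosages: np.ndarray, labels: np.ndarray) -> LogisticFit:
    """Unpenalized maximum-likelihood logistic regression.

    Newton/IRLS fit; standard errors from the inverse observed information;
    two-sided normal p-values. Perfect separation raises ``SeparationError``.
    """
    x = np.asarray(dosages, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels, dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing dosages must be imputed before fitting")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    design = sm.add_constant(x, has_constant="add")
    model = sm.Logit(y, design)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = model.fit(method="newton", tol=1e-8, maxiter=100, disp=0)
    except (
        sm.tools.sm_exceptions.PerfectSeparationError,
        sm.tools.sm_exceptions.PerfectSeparationWarning,
        np.linalg.LinAlgError,
    ) as exc:
        raise SeparationError(f"logistic fit failed (perfect separation?): {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    if not np.isfinite(params).all() or np.abs(params).max() > 1e3:
        raise SeparationError("diverging coefficients indicate perfect separation")
    bse = np.asarray(res.bse, dtype=float)
    z = params / bse
    p = 2.0 * stats.norm.sf(np.abs(z))
    return LogisticFit(
        weights=params[1:],
        intercept=float(params[0]),
        se=bse[1:],
        intercept_se=float(bse[0]),
        z=z[1:],
        p=p[1:],
        loglik=float(res.llf),
        aic=float(res.aic),
        n_iter=int(res.mle_retvals.get("iterations", -1)),
    )


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation, with mid-rank ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(scores)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _oof_scores(x: np.ndarray, y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Pooled out-of-fold linear predictor from stratified k-fold logistic fits."""
    out = np.empty(len(y))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(x, y):
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        clf.fit(x[train], y[train])
        out[test] = clf.decision_function(x[test])
    return out


def cross_validated_auc(
    dosages: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
) -> tuple[float, list[float]]:
    """Repeated stratified k-fold logistic CV; per-repeat pooled AUC.

    Returns ``(mean_auc, per_repeat_aucs)``.
    """
    x = np.asarray(dosages, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels, dtype=int)
    n_min = min(int(y.sum()), int((1 - y).sum()))
    if n_min < n_folds:
        raise ValueError(
            f"smallest class has {n_min} samples; stratified {n_folds}-fold CV "
            f"needs at least {n_folds} per class"
        )
    ss = np.random.SeedSequence(seed)
    repeat_seeds = ss.generate_state(n_repeats)
    aucs = []
    for r in range(n_repeats):
        scores = _oof_scores(x, y, n_folds, int(repeat_seeds[r] % (2**31 - 1)))
        aucs.append(mann_whitney_auc(scores, y.astype(bool)))
    return float(np.mean(aucs)), aucs


def _panel_columns(genotypes: GenotypeMatrix, snp_ids: list[str]) -> list[int]:
    index = {s: j for j, s in enumerate(genotypes.snp_ids)}
    missing = [s for s in snp_ids if s not in index]
    if missing:
        raise ValueError(f"panel SNPs absent from genotypes: {missing}")
    return [index[s] for s in snp_ids]


def train_pgs(
    cohort: Cohort,
    genotypes: GenotypeMatrix,
    scheme: ResampleScheme,
    panel_snp_ids: list[str] | None = None,
    n_folds: int = 10,
    n_repeats: int = 10,
    vif_threshold: float = DEFAULT_VIF_THRESHOLD,
) -> PgsModel:
    """Train a PGS by balanced resampling with CV-AUC model selection.

    For each balanced subset: VIF screen, unpenalized logistic fit, repeated
    stratified CV AUC. The subset with the highest mean CV AUC wins; ties are
    broken by fewer SNPs, then lower subset index. The winning model's
    coefficients are the PGS weights.
    """
    panel = list(panel_snp_ids) if panel_snp_ids is not None else [str(s) for s in genotypes.snp_ids]
    subsets = balance_controls(cohort, scheme)
    y_all = cohort.is_case.astype(int)
    panel_cols = _panel_columns(genotypes, panel)

    candidates = []
    for k, idx in enumerate(subsets):
        sub_geno = GenotypeMatrix(
            sample_ids=genotypes.sample_ids[idx],
            snp_ids=np.array(panel, dtype=object),
            dosages=genotypes.dosages[np.ix_(idx, panel_cols)],
            effect_alleles=_panel_alleles(genotypes, panel),
        )
        if len(panel) >= 2:
            retained, _ = collinearity_screen(sub_geno, vif_threshold)
        else:
            retained = list(panel)
        x = sub_geno.imputed()[:, _panel_columns(sub_geno, retained)]
        y = y_all[idx]
        fit = fit_logistic(x, y)
        cv_seed = int(np.random.SeedSequence(scheme.seed, spawn_key=(1000 + k,)).generate_state(1)[0])
        mean_auc, per_repeat = cross_validated_auc(
            x, y, n_folds=n_folds, n_repeats=n_repeats, seed=cv_seed
        )
        candidates.append(
            {
                "subset": k,
                "snp_ids": retained,
                "fit": fit,
                "mean_auc": mean_auc,
                "per_repeat_auc": per_repeat,
                "n_dropped_vif": len(panel) - len(retained),
            }
        )

    best = min(candidates, key=lambda c: (-c["mean_auc"], len(c["snp_ids"]), c["subset"]))
    alleles = _panel_alleles(genotypes, best["snp_ids"])
    return PgsModel(
        snp_ids=np.array(best["snp_ids"], dtype=object),
        weights=best["fit"].weights,
        intercept=best["fit"].intercept,
        effect_alleles=alleles,
        training_auc=best["mean_auc"],
        provenance={
            "scheme": {"n_subsets": scheme.n_subsets, "control_ratio": scheme.control_ratio,
                       "seed": scheme.seed},
            "cv": {"n_folds": n_folds, "n_repeats": n_repeats},
            "vif_threshold": vif_threshold,
            "selected_subset": best["subset"],
            "subset_mean_aucs": [c["mean_auc"] for c in candidates],
            "per_repeat_auc": best["per_repeat_auc"],
            "panel_size": len(panel),
            "n_dropped_vif": best["n_dropped_vif"],
        },
    )


def _panel_alleles(genotypes: GenotypeMatrix, snp_ids: list[str]) -> np.ndarray:
    index = {s: j for j, s in enumerate(genotypes.snp_ids)}
    return np.array([genotypes.effect_alleles[index[s]] for s in snp_ids], dtype=object)


def stepwise_aic(
    dosages: np.ndarray,
    labels: np.ndarray,
    candidate_snp_ids: list[str],
    effect_alleles: np.ndarray | None = None,
) -> PgsModel:
    """Forward stepwise selection by the Akaike Information Criterion.

    Starts from the intercept-only model; at each step adds the candidate
    that lowers AIC the most, stopping when no addition improves it. The
    returned weights are refit on the final selected set.
    """
    x = np.asarray(dosages, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels, dtype=int)
    if x.shape[1] != len(candidate_snp_ids):
        raise ValueError("dosage columns must match candidate_snp_ids")
    if not candidate_snp_ids:
        raise ValueError("need at least one candidate")

    # intercept-only AIC: 2*1 - 2*loglik at the empirical case fraction
    pbar = y.mean()
    ll0 = float(np.sum(y * np.log(pbar) + (1 - y) * np.log1p(-pbar)))
    current_aic = 2.0 - 2.0 * ll0
    selected: list[int] = []
    remaining = list(range(x.shape[1]))
    aic_path = [current_aic]
    best_fit: LogisticFit | None = None
    while remaining:
        trial_results = []
        for j in remaining:
            cols = selected + [j]
            try:
                fit = fit_logistic(x[:, cols], y)
            except SeparationError:
                continue
            trial_results.append((fit.aic, j, fit))
        if not trial_results:
            break
        trial_results.sort(key=lambda t: (t[0], t[1]))
        best_aic, best_j, fit = trial_results[0]
        if best_aic >= current_aic:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        current_aic = best_aic
        aic_path.append(current_aic)
        best_fit = fit

    ids = np.array([candidate_snp_ids[j] for j in selected], dtype=object)
    if best_fit is None:
        weights = np.empty(0)
        intercept = float(np.log(pbar / (1 - pbar)))
    else:
        weights = best_fit.weights
        intercept = best_fit.intercept
    alleles = (
        np.asarray(effect_alleles, dtype=object)[selected]
        if effect_alleles is not None
        else np.array(["A"] * len(ids), dtype=object)
    )
    return PgsModel(
        snp_ids=ids,
        weights=weights,
        intercept=intercept,
        effect_alleles=alleles,
        provenance={"method": "forward_aic", "aic_path": aic_path},
    )
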