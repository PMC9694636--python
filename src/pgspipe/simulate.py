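"""Synthetic case-control cohort generation with LD-structured genotypes.

Provides a fully specified generative model — blocked-LD genotypes, a sparse
logistic disease model calibrated to a marginal prevalence, a BMI covariate
correlated with the latent genetic score, and ICD-10-style diagnosis codes —
so that every downstream stage of the pipeline can be exercised and validated
against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "SimulationConfig",
    "GenotypeMatrix",
    "Cohort",
    "MrInstrumentSet",
    "simulate_cohort",
    "simulate_gwas_summary",
    "simulate_mr_instruments",
]

#: stage labels used to expand the global seed into independent child streams
_STAGES = ("genotypes", "effects", "bmi", "status", "codes", "missing", "sample")

# Draw bound for the rejection step that assembles the requested case/control
# counts: the pool is oversized by this factor relative to the expected
# requirement, and the draw fails explicitly if the pool still falls short.
_POOL_MARGIN = 1.35

_CASE_CODE_MENU = ("O14.0", "O14.9", "SR1073", "O15.0")
_CASE_SECONDARY_O13_PROB = 0.2
_CONTROL_CODE_MENU = (
    "Z37.0", "Z34.8", "Z37.2", "Z37.3", "Z37.5", "Z37.6",
    "Z38.1", "Z38.3", "Z38.6", "Z39", "O80.0",
)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic child generator for a named pipeline stage.

    The global seed expands into independent streams via
    ``SeedSequence(seed, spawn_key=(stage_index,))``.
    """
    idx = _STAGES.index(stage)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(idx,)))


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative specification for one synthetic cohort."""

    n_cases: int = 500
    n_controls: int = 2000
    n_snps: int = 100
    n_ld_blocks: int = 25
    within_block_r2: float = 0.5
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    causal_fraction: float = 0.1
    effect_sd: float = 0.3
    prevalence: float = 0.15
    bmi_mean: float = 27.0
    bmi_sd: float = 4.5
    bmi_genetic_corr: float = 0.2
    bmi_effect: float = 0.0
    missing_rate: float = 0.0
    max_pool_draws: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_snps, self.n_ld_blocks) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_ld_blocks > self.n_snps:
            raise ValueError("n_ld_blocks cannot exceed n_snps")
        if not 0.0 <= self.within_block_r2 < 1.0:
            raise ValueError("within_block_r2 must be in [0, 1)")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele_freq_range must be ordered and strictly inside (0, 1)")
        if not 0.0 <= self.causal_fraction <= 1.0:
            raise ValueError("causal_fraction must be in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if not -1.0 <= self.bmi_genetic_corr <= 1.0:
            raise ValueError("bmi_genetic_corr must be in [-1, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.bmi_sd <= 0 or self.effect_sd < 0:
            raise ValueError("scale parameters must be positive")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs effect-allele dosage matrix.

    Dosages are 0, 1, or 2 copies of the effect allele; missing entries are
    NaN.
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray
    effect_alleles: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.effect_alleles = np.asarray(self.effect_alleles, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("dosage matrix shape does not match id lists")
        if len(self.effect_alleles) != len(self.snp_ids):
            raise ValueError("effect_alleles length does not match snp_ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be exactly 0, 1, or 2")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-SNP mean."""
        out = self.dosages.copy()
        if np.isnan(out).any():
            col_mean = np.nanmean(out, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(out))
            out[idx] = col_mean[idx[1]]
        return out

    def column(self, snp_id: str) -> np.ndarray:
        j = int(np.flatnonzero(self.snp_ids == snp_id)[0])
        return self.dosages[:, j]


@dataclass
class Cohort:
    """Per-sample phenotype table: status, BMI, and diagnosis codes."""

    sample_ids: np.ndarray
    status: np.ndarray  # "case" / "control" (or "excluded" after rule labelling)
    bmi: np.ndarray  # NaN = missing
    diagnosis_codes: list[frozenset[str]]
    true_liability: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.status = np.asarray(self.status, dtype=object)
        self.bmi = np.asarray(self.bmi, dtype=float)
        n = len(self.sample_ids)
        if not (len(self.status) == len(self.bmi) == len(self.diagnosis_codes) == n):
            raise ValueError("cohort field lengths disagree")
        if any(s is None or s == "" for s in self.status):
            raise ValueError("status must be defined for every sample")
        present = self.bmi[~np.isnan(self.bmi)]
        if present.size and (present <= 0).any():
            raise ValueError("BMI, when present, must be positive")
        if self.true_liability is not None:
            self.true_liability = np.asarray(self.true_liability, dtype=float)
            if len(self.true_liability) != n:
                raise ValueError("true_liability length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def is_case(self) -> np.ndarray:
        return self.status == "case"

    def subset(self, idx: np.ndarray) -> "Cohort":
        idx = np.asarray(idx)
        return Cohort(
            sample_ids=self.sample_ids[idx],
            status=self.status[idx],
            bmi=self.bmi[idx],
            diagnosis_codes=[self.diagnosis_codes[i] for i in idx],
            true_liability=None if self.true_liability is None else self.true_liability[idx],
        )


@dataclass
class MrInstrumentSet:
    """Per-SNP exposure and outcome summary effects for two-sample MR."""

    snp_ids: np.ndarray
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    p_exposure: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome", "p_exposure"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if len(arr) != len(self.snp_ids):
                raise ValueError(f"{name} length does not match snp_ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        if (self.se_exposure <= 0).any() or (self.se_outcome <= 0).any():
            raise ValueError("all standard errors must be positive")

    @property
    def n_instruments(self) -> int:
        return len(self.snp_ids)

    def subset(self, mask: np.ndarray) -> "MrInstrumentSet":
        return MrInstrumentSet(
            snp_ids=self.snp_ids[mask],
            beta_exposure=self.beta_exposure[mask],
            se_exposure=self.se_exposure[mask],
            beta_outcome=self.beta_outcome[mask],
            se_outcome=self.se_outcome[mask],
            p_exposure=self.p_exposure[mask],
        )


# ---------------------------------------------------------------------------
# genotype generation
# ---------------------------------------------------------------------------

def _binary_threshold_corr(rho: float, q1: float, q2: float, f1: float, f2: float) -> float:
    """Pearson correlation of threshold indicators of a bivariate normal."""
    if rho == 0.0:
        return 0.0
    cov = np.array([[1.0, rho], [rho, 1.0]])
    p11 = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([q1, q2])
    return (p11 - f1 * f2) / np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))


def _solve_latent_rho(target_r2: float, freqs: np.ndarray) -> float:
    """Latent Gaussian correlation for one block such that the mean pairwise
    squared correlation of the thresholded indicators matches ``target_r2``.

    Solved against the block's actual allele frequencies, since unequal
    frequencies cap the attainable indicator correlation below 1.
    """
    if target_r2 <= 0.0 or len(freqs) < 2:
        return 0.0
    qs = stats.norm.ppf(freqs)
    pairs = [(i, j) for i in range(len(freqs)) for j in range(i + 1, len(freqs))]
    if len(pairs) > 30:  # large block: a deterministic subsample is enough
        pairs = pairs[:: max(1, len(pairs) // 30)]

    def gap(rho: float) -> float:
        r2s = [
            _binary_threshold_corr(rho, qs[i], qs[j], freqs[i], freqs[j]) ** 2
            for i, j in pairs
        ]
        return float(np.mean(r2s)) - target_r2

    hi = 1.0 - 1e-9
    if gap(hi) < 0:  # target unattainable at these frequencies; saturate
        return hi
    return optimize.brentq(gap, 0.0, hi, xtol=1e-6)


def _block_sizes(n_snps: int, n_blocks: int) -> list[int]:
    return [len(a) for a in np.array_split(np.arange(n_snps), n_blocks)]


def _draw_dosages(
    rng: np.random.Generator,
    n: int,
    freqs: np.ndarray,
    blocks: list[int],
    latent_rhos: list[float],
) -> np.ndarray:
    """Dosages as the sum of two haplotypes, each an equicorrelated latent
    Gaussian thresholded at the per-SNP allele frequency."""
    out = np.empty((n, len(freqs)), dtype=np.int8)
    start = 0
    for size, rho in zip(blocks, latent_rhos):
        q = stats.norm.ppf(freqs[start:start + size])
        dos = np.zeros((n, size), dtype=np.int8)
        for _hap in range(2):
            common = rng.standard_normal((n, 1))
            noise = rng.standard_normal((n, size))
            latent = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * noise
            dos += (latent < q).astype(np.int8)
        out[:, start:start + size] = dos
        start += size
    return out


def _draw_true_weights(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    n_causal = int(round(cfg.causal_fraction * cfg.n_snps))
    weights = np.zeros(cfg.n_snps)
    if n_causal:
        causal = rng.choice(cfg.n_snps, size=n_causal, replace=False)
        weights[causal] = rng.normal(0.0, cfg.effect_sd, size=n_causal)
    return weights


def _assign_codes(rng: np.random.Generator, status: np.ndarray) -> list[frozenset[str]]:
    codes: list[frozenset[str]] = []
    for s in status:
        if s == "case":
            primary = _CASE_CODE_MENU[rng.integers(len(_CASE_CODE_MENU))]
            extra = {"O13"} if rng.random() < _CASE_SECONDARY_O13_PROB else set()
            codes.append(frozenset({primary} | extra))
        else:
            codes.append(frozenset({_CONTROL_CODE_MENU[rng.integers(len(_CONTROL_CODE_MENU))]}))
    return codes


def simulate_cohort(config: SimulationConfig) -> tuple[GenotypeMatrix, Cohort, np.ndarray]:
    """Generate a case-control cohort with known generative truth.

    Returns ``(genotypes, cohort, true_weights)`` where ``true_weights`` are
    the per-SNP log-odds effects of the generative logistic disease model.
    Output is a pure function of the config (including its seed).

    Raises
    ------
    RuntimeError
        If the requested case or control count cannot be assembled from the
        bounded sampling pool.
    """
    cfg = config
    geno_rng = stage_rng(cfg.seed, "genotypes")
    eff_rng = stage_rng(cfg.seed, "effects")
    bmi_rng = stage_rng(cfg.seed, "bmi")
    status_rng = stage_rng(cfg.seed, "status")
    code_rng = stage_rng(cfg.seed, "codes")
    miss_rng = stage_rng(cfg.seed, "missing")
    sample_rng = stage_rng(cfg.seed, "sample")

    need = max(cfg.n_cases / cfg.prevalence, cfg.n_controls / (1.0 - cfg.prevalence))
    pool_n = int(np.ceil(_POOL_MARGIN * need))
    if pool_n > cfg.max_pool_draws:
        raise RuntimeError(
            f"requested {cfg.n_cases} cases / {cfg.n_controls} controls at "
            f"prevalence {cfg.prevalence} needs a pool of {pool_n} draws, "
            f"exceeding the bound of {cfg.max_pool_draws} (max_pool_draws)"
        )

    freqs = geno_rng.uniform(*cfg.allele_freq_range, size=cfg.n_snps)
    blocks = _block_sizes(cfg.n_snps, cfg.n_ld_blocks)
    rhos = []
    start = 0
    for size in blocks:
        rhos.append(_solve_latent_rho(cfg.within_block_r2, freqs[start:start + size]))
        start += size
    dosages = _draw_dosages(geno_rng, pool_n, freqs, blocks, rhos)

    true_weights = _draw_true_weights(eff_rng, cfg)
    eta_g = (dosages - 2.0 * freqs) @ true_weights

    # BMI: mixture of the standardized genetic score and independent noise
    sd_g = eta_g.std()
    z_g = (eta_g - eta_g.mean()) / sd_g if sd_g > 0 else np.zeros(pool_n)
    c = cfg.bmi_genetic_corr
    z_bmi = c * z_g + np.sqrt(max(0.0, 1.0 - c * c)) * bmi_rng.standard_normal(pool_n)
    bmi = cfg.bmi_mean + cfg.bmi_sd * z_bmi
    low = bmi < 18.5
    for _ in range(20):  # re-draw the noise component for sub-threshold values
        if not low.any():
            break
        z_redraw = c * z_g[low] + np.sqrt(max(0.0, 1.0 - c * c)) * bmi_rng.standard_normal(low.sum())
        bmi[low] = cfg.bmi_mean + cfg.bmi_sd * z_redraw
        low = bmi < 18.5
    bmi = np.maximum(bmi, 18.5)

    liability = eta_g + cfg.bmi_effect * (bmi - cfg.bmi_mean) / cfg.bmi_sd
    b0 = optimize.brentq(
        lambda b: expit(b + liability).mean() - cfg.prevalence, -40.0, 40.0, xtol=1e-10
    )
    liability = b0 + liability
    is_case = status_rng.random(pool_n) < expit(liability)

    case_idx = np.flatnonzero(is_case)
    ctrl_idx = np.flatnonzero(~is_case)
    if len(case_idx) < cfg.n_cases or len(ctrl_idx) < cfg.n_controls:
        raise RuntimeError(
            f"could not assemble {cfg.n_cases} cases / {cfg.n_controls} controls "
            f"from a bounded pool of {pool_n} draws at prevalence {cfg.prevalence} "
            f"(got {len(case_idx)} cases, {len(ctrl_idx)} controls)"
        )
    chosen = np.concatenate([case_idx[: cfg.n_cases], ctrl_idx[: cfg.n_controls]])
    chosen = chosen[sample_rng.permutation(len(chosen))]

    status = np.where(is_case[chosen], "case", "control").astype(object)
    sample_ids = np.array([f"S{i:06d}" for i in range(len(chosen))], dtype=object)
    snp_ids = np.array([f"rs{j + 1:05d}" for j in range(cfg.n_snps)], dtype=object)
    sel_dos = dosages[chosen].astype(float)
    sel_bmi = bmi[chosen]

    if cfg.missing_rate > 0:
        mask = miss_rng.random(sel_dos.shape) < cfg.missing_rate
        sel_dos[mask] = np.nan
        sel_bmi = sel_bmi.copy()
        sel_bmi[miss_rng.random(len(sel_bmi)) < cfg.missing_rate] = np.nan

    genotypes = GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        dosages=sel_dos,
        effect_alleles=np.array(["A"] * cfg.n_snps, dtype=object),
    )
    cohort = Cohort(
        sample_ids=sample_ids,
        status=status,
        bmi=sel_bmi,
        diagnosis_codes=_assign_codes(code_rng, status),
        true_liability=liability[chosen],
    )
    return genotypes, cohort, true_weights


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _univariate_logistic(x: np.ndarray, y: np.ndarray, max_iter: int = 30, tol: float = 1e-8):
    """Vectorized per-column univariate logistic Newton fits.

    ``x`` is (n, p); returns (beta, se) arrays of length p for the slope.
    """
    n, p = x.shape
    b0 = np.full(p, np.log(y.mean() / (1.0 - y.mean())))
    b1 = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(b0 + x * b1, -30, 30)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        r = y[:, None] - mu
        g0 = r.sum(axis=0)
        g1 = (x * r).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * x).sum(axis=0)
        h11 = (w * x * x).sum(axis=0)
        det = h00 * h11 - h01 * h01
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        d0 = np.nan_to_num(d0)
        d1 = np.nan_to_num(d1)
        b0 += d0
        b1 += d1
        if max(np.abs(d0).max(initial=0.0), np.abs(d1).max(initial=0.0)) < tol:
            break
    eta = np.clip(b0 + x * b1, -30, 30)
    mu = expit(eta)
    w = mu * (1.0 - mu)
    h00 = w.sum(axis=0)
    h01 = (w * x).sum(axis=0)
    h11 = (w * x * x).sum(axis=0)
    det = h00 * h11 - h01 * h01
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = h00 / det
    se = np.sqrt(np.where(var_b1 > 0, var_b1, np.nan))
    return b1, se


def simulate_gwas_summary(genotypes: GenotypeMatrix, cohort: Cohort):
    """Per-SNP univariate logistic association scan of status on dosage.

    Returns a dict of arrays ``{"snp", "beta", "se", "p", "monomorphic"}``.
    Monomorphic SNPs (no dosage variation) get ``beta = 0``, a non-finite SE,
    and ``p = 1`` by convention.
    """
    y = cohort.is_case.astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 samples in each status group")
    x = genotypes.imputed()
    mono = x.std(axis=0) == 0.0

    beta = np.zeros(genotypes.n_snps)
    se = np.full(genotypes.n_snps, np.inf)
    p = np.ones(genotypes.n_snps)
    poly = ~mono
    if poly.any():
        b, s = _univariate_logistic(x[:, poly], y)
        z = np.where(np.isfinite(s) & (s > 0), b / s, 0.0)
        pv = 2.0 * stats.norm.sf(np.abs(z))
        pv = np.clip(pv, np.nextafter(0.0, 1.0), 1.0)
        beta[poly] = b
        se[poly] = np.where(np.isfinite(s), s, np.inf)
        p[poly] = pv
    return {
        "snp": genotypes.snp_ids.copy(),
        "beta": beta,
        "se": se,
        "p": p,
        "monomorphic": mono,
    }


# ---------------------------------------------------------------------------
# MR instrument simulation
# ---------------------------------------------------------------------------

def simulate_mr_instruments(
    n_instruments: int,
    causal_beta: float,
    pleiotropy_mean: float,
    seed: int,
    *,
    beta_exposure_range: tuple[float, float] = (0.1, 0.5),
    se_exposure_range: tuple[float, float] = (0.005, 0.015),
    se_outcome_range: tuple[float, float] = (0.02, 0.06),
) -> MrInstrumentSet:
    """Draw a seeded two-sample MR instrument set with known causal effect.

    Exposure effects are uniform on ``beta_exposure_range`` (positive, so no
    harmonization flips disturb a constant pleiotropy term); outcome effects
    are ``causal_beta * beta_exposure + pleiotropy_mean + N(0, se_outcome^2)``.
    """
    if n_instruments < 2:
        raise ValueError("n_instruments must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    beta_exp = rng.uniform(*beta_exposure_range, size=n_instruments)
    se_exp = rng.uniform(*se_exposure_range, size=n_instruments)
    se_out = rng.uniform(*se_outcome_range, size=n_instruments)
    beta_out = causal_beta * beta_exp + pleiotropy_mean + rng.normal(0.0, se_out)
    z = beta_exp / se_exp
    p_exp = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0.0, 1.0), 1.0)
    return MrInstrumentSet(
        snp_ids=np.array([f"iv{k + 1:04d}" for k in range(n_instruments)], dtype=object),
        beta_exposure=beta_exp,
        se_exposure=se_exp,
        beta_outcome=beta_out,
        se_outcome=se_out,
        p_exposure=p_exp,
    )
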