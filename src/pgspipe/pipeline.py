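"""End-to-end pipeline orchestration with a reproducible run manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .cohort import assign_case_control, default_rules, filter_bmi
from .mr import egger_estimate, ivw_estimate, reporting_filter, select_instruments
from .scoring import compute_pgs
from .simulate import SimulationConfig, simulate_cohort, simulate_gwas_summary, simulate_mr_instruments
from .stratify import bmi_pgs_grid, top_vs_bottom_or
from .training import ResampleScheme, stepwise_aic, train_pgs
from .variants import (
    DEFAULT_R2_THRESHOLD,
    DEFAULT_WINDOW_BP,
    SnpRecord,
    estimate_ld,
    ld_clump,
    select_by_pvalue,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline, recorded verbatim in the run manifest."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    p_cutoff: float = 1e-5
    clump_r2: float = DEFAULT_R2_THRESHOLD
    clump_window_bp: int = DEFAULT_WINDOW_BP
    n_subsets: int = 10
    control_ratio: int = 4
    cv_folds: int = 10
    cv_repeats: int = 10
    vif_threshold: float = 10.0
    min_bmi: float = 18.5
    alpha: float = 0.05
    top_fractions: tuple[float, ...] = (0.25, 0.10, 0.05, 0.02, 0.01)
    bottom_fraction: float = 0.5
    strict_preeclampsia: bool = False
    run_stepwise: bool = False
    run_mr: bool = False
    mr_n_instruments: int = 50
    mr_causal_beta: float = 0.3
    mr_pleiotropy_mean: float = 0.0
    mr_instrument_threshold: float = 5e-8
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must be in (0, 1)")
        if not 0 < self.clump_r2 <= 1:
            raise ValueError("clump_r2 must be in (0, 1]")
        if self.clump_window_bp <= 0:
            raise ValueError("clump_window_bp must be positive")
        if any(not 0 < f < 1 for f in self.top_fractions):
            raise ValueError("top_fractions must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**data.pop("simulation", {}))
        if "top_fractions" in data:
            data["top_fractions"] = tuple(data["top_fractions"])
        cfg = cls(simulation=sim, **data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["top_fractions"] = list(self.top_fractions)
        d["simulation"]["allele_freq_range"] = list(self.simulation.allele_freq_range)
        return d


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute simulate -> define-cohort -> select -> clump -> train ->
    score -> stratify (-> mr) and write every intermediate to ``out_dir``.

    Returns the manifest dict (also written as ``manifest.json``), which
    records parameter values, seeds, and row counts at every stage.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    logger.info("stage 1: simulate")
    genotypes, cohort, true_weights = simulate_cohort(config.simulation)
    io.write_dosage_tsv(genotypes, out / "dosages.tsv", out / "alleles.tsv")
    io.write_cohort_tsv(cohort, out / "cohort.tsv")
    counts["samples"] = genotypes.n_samples
    counts["snps"] = genotypes.n_snps

    logger.info("stage 2: define cohort")
    rules = default_rules(strict_preeclampsia=config.strict_preeclampsia)
    labelled, report = assign_case_control(cohort, rules)
    counts["cases"] = report.n_cases
    counts["controls"] = report.n_controls
    counts["excluded"] = report.n_excluded
    io.write_cohort_tsv(labelled, out / "cohort_labelled.tsv")

    logger.info("stage 3: association scan + selection + clumping")
    keep = labelled.status != "excluded"
    analysis_cohort = labelled.subset(np.flatnonzero(keep))
    analysis_geno = _subset_genotypes(genotypes, np.flatnonzero(keep))
    summary = simulate_gwas_summary(analysis_geno, analysis_cohort)
    records = [
        SnpRecord(
            snp_id=str(s), chrom="1", pos=int(j + 1) * 10_000,
            effect_allele="A", other_allele="N",
            p=float(summary["p"][j]), source="scan",
            beta=float(summary["beta"][j]),
            se=float(summary["se"][j]) if np.isfinite(summary["se"][j]) else None,
        )
        for j, s in enumerate(summary["snp"])
    ]
    io.write_summary_tsv(records, out / "summary_stats.tsv")
    selected = select_by_pvalue(records, config.p_cutoff)
    counts["selected_snps"] = len(selected)
    ld, ld_excluded = estimate_ld(analysis_geno)
    selected = [r for r in selected if r.snp_id in ld]
    clumped = ld_clump(selected, ld, config.clump_r2, config.clump_window_bp)
    counts["clumped_snps"] = len(clumped)
    io.write_summary_tsv(clumped, out / "clumped_snps.tsv")
    logger.info(
        "selection: %d scanned -> %d below p<%g -> %d after clumping",
        len(records), len(selected), config.p_cutoff, len(clumped),
    )
    if len(clumped) == 0:
        raise RuntimeError("stage select/clump failed: no SNPs pass the p-value cutoff")

    logger.info("stage 4: train")
    scheme = ResampleScheme(
        n_subsets=config.n_subsets, control_ratio=config.control_ratio, seed=config.seed
    )
    model = train_pgs(
        analysis_cohort,
        analysis_geno,
        scheme,
        panel_snp_ids=[r.snp_id for r in clumped],
        n_folds=config.cv_folds,
        n_repeats=config.cv_repeats,
        vif_threshold=config.vif_threshold,
    )
    io.write_scoring_file(model, out / "pgs_model.tsv")
    counts["model_snps"] = model.n_snps

    if config.run_stepwise:
        logger.info("stage 4b: stepwise AIC reduction")
        cols = [int(np.flatnonzero(analysis_geno.snp_ids == s)[0]) for s in model.snp_ids]
        reduced = stepwise_aic(
            analysis_geno.imputed()[:, cols],
            analysis_cohort.is_case.astype(int),
            [str(s) for s in model.snp_ids],
            effect_alleles=model.effect_alleles,
        )
        io.write_scoring_file(reduced, out / "pgs_model_stepwise.tsv")
        counts["stepwise_snps"] = reduced.n_snps

    logger.info("stage 5: score")
    scores = compute_pgs(model, analysis_geno)
    io.write_scores_tsv(scores, out / "scores.tsv")

    logger.info("stage 6: stratify")
    strata = [
        top_vs_bottom_or(
            scores, analysis_cohort.status, f, config.bottom_fraction, config.alpha
        )
        for f in config.top_fractions
    ]
    io.write_strata_tsv(strata, out / "top_vs_bottom_or.tsv")
    bmi_cohort = filter_bmi(analysis_cohort, config.min_bmi)
    bmi_idx = np.flatnonzero(
        ~np.isnan(analysis_cohort.bmi) & (analysis_cohort.bmi >= config.min_bmi)
    )
    counts["bmi_analysis_samples"] = bmi_cohort.n_samples
    try:
        grid_scores = compute_pgs(model, _subset_genotypes(analysis_geno, bmi_idx))
        grid = bmi_pgs_grid(bmi_cohort, grid_scores, config.alpha)
        io.write_strata_tsv(grid, out / "bmi_pgs_grid.tsv")
    except ValueError as exc:  # e.g. an empty cell at small n
        logger.warning("BMI x PGS grid skipped: %s", exc)
        counts["bmi_grid_skipped"] = 1

    if config.run_mr:
        logger.info("stage 7: mendelian randomization")
        instruments = simulate_mr_instruments(
            config.mr_n_instruments, config.mr_causal_beta, config.mr_pleiotropy_mean,
            seed=config.seed,
        )
        io.write_instruments_tsv(instruments, out / "mr_instruments.tsv")
        sel = select_instruments(instruments, config.mr_instrument_threshold)
        results = [ivw_estimate(sel), egger_estimate(sel)]
        io.write_mr_results_tsv(results, out / "mr_results.tsv")
        io.write_mr_results_tsv(reporting_filter(results), out / "mr_results_reported.tsv")
        counts["mr_instruments"] = sel.n_instruments

    manifest = {
        "package": "pgspipe",
        "version": _package_version(),
        "numpy_version": np.__version__,
        "config": config.to_dict(),
        "counts": counts,
        "training_auc": model.training_auc,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _subset_genotypes(genotypes, idx):
    from .simulate import GenotypeMatrix

    return GenotypeMatrix(
        sample_ids=genotypes.sample_ids[idx],
        snp_ids=genotypes.snp_ids.copy(),
        dosages=genotypes.dosages[idx],
        effect_alleles=genotypes.effect_alleles.copy(),
    )


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("pgspipe")
    except PackageNotFoundError:
        return "unknown"
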