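"""Polygenic score computation and within-cohort percentile ranking."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import GenotypeMatrix
from .training import PgsModel

__all__ = ["ScoreVector", "compute_pgs", "percentile_ranks"]


@dataclass
class ScoreVector:
    sample_ids: np.ndarray
    scores: np.ndarray
    percentile_rank: np.ndarray  # mid-rank fraction in [0, 1)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        self.percentile_rank = np.asarray(self.percentile_rank, dtype=float)
        n = len(self.sample_ids)
        if not (len(self.scores) == len(self.percentile_rank) == n):
            raise ValueError("score vector field lengths disagree")

    def __len__(self) -> int:
        return len(self.sample_ids)


def percentile_ranks(scores: np.ndarray) -> np.ndarray:
    """Mid-rank percentile: fraction strictly below plus half the tied fraction.

    Ties therefore share a rank, and ranks lie in (0, 1).
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    # average rank r in [1, n]  ->  (r - 0.5) / n == frac_below + tied/2
    return (stats.rankdata(scores, method="average") - 0.5) / n


def compute_pgs(
    model: PgsModel, genotypes: GenotypeMatrix, include_intercept: bool = False
) -> ScoreVector:
    """Score every sample as the weighted sum of effect-allele dosages.

    Every model SNP must be present in the genotypes; a mismatched effect
    allele is handled by the dosage flip ``g -> 2 - g``. Missing dosages are
    mean-imputed per SNP. Percentile ranks are computed against the scored
    cohort itself.
    """
    index = {s: j for j, s in enumerate(genotypes.snp_ids)}
    missing = [str(s) for s in model.snp_ids if s not in index]
    if missing:
        raise ValueError(f"model SNPs absent from genotypes: {missing}")
    cols = [index[s] for s in model.snp_ids]
    x = genotypes.imputed()[:, cols]
    flip = np.array(
        [
            genotypes.effect_alleles[index[s]] != model.effect_alleles[k]
            for k, s in enumerate(model.snp_ids)
        ]
    )
    if flip.any():
        x = np.where(flip[None, :], 2.0 - x, x)
    scores = x @ model.weights
    if include_intercept:
        scores = scores + model.intercept
    return ScoreVector(
        sample_ids=genotypes.sample_ids.copy(),
        scores=scores,
        percentile_rank=percentile_ranks(scores),
    )
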