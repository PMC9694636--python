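"""Candidate SNP selection: p-value thresholding, multi-source merging, and
greedy LD clumping."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import GenotypeMatrix

__all__ = [
    "SnpRecord",
    "LdMatrix",
    "select_by_pvalue",
    "merge_snp_sources",
    "MergeReport",
    "ld_clump",
    "estimate_ld",
]

DEFAULT_R2_THRESHOLD = 0.1
DEFAULT_WINDOW_BP = 250_000


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    p: float
    source: str = ""
    beta: float | None = None
    se: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: positions are 1-based, got {self.pos}")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"{self.snp_id}: p must be in (0, 1], got {self.p}")


@dataclass
class LdMatrix:
    """Squared dosage correlations between SNPs."""

    snp_ids: np.ndarray
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise ValueError("r2 matrix shape does not match snp_ids")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-9):
            raise ValueError("r2 diagonal must be 1")
        if (self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-9).any():
            raise ValueError("r2 entries must lie in [0, 1]")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValueError("r2 matrix must be symmetric")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def value(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index


def select_by_pvalue(records: list[SnpRecord], cutoff: float) -> list[SnpRecord]:
    """Records with p strictly below the cutoff, input order preserved."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    return [r for r in records if r.p < cutoff]


@dataclass
class MergeReport:
    per_source_counts: dict[str, int]
    n_distinct: int
    n_duplicates_dropped: int
    dropped_missing: list[str]
    sources_by_snp: dict[str, list[str]]


def merge_snp_sources(
    lists: list[list[SnpRecord]], known_missing: set[str] = frozenset()
) -> tuple[list[SnpRecord], MergeReport]:
    """Union several source lists into one record per SNP id.

    First-seen record wins; every contributing source is recorded. Ids in
    ``known_missing`` (e.g. absent from the target genotype panel) are dropped
    and reported. Conflicting effect alleles across sources are an error.
    """
    seen: dict[str, SnpRecord] = {}
    sources_by_snp: dict[str, list[str]] = {}
    per_source: dict[str, int] = {}
    dropped_missing: list[str] = []
    n_dupes = 0
    for records in lists:
        for rec in records:
            per_source[rec.source] = per_source.get(rec.source, 0) + 1
            if rec.snp_id in known_missing:
                if rec.snp_id not in dropped_missing:
                    dropped_missing.append(rec.snp_id)
                continue
            if rec.snp_id in seen:
                prior = seen[rec.snp_id]
                if prior.effect_allele != rec.effect_allele:
                    raise ValueError(
                        f"conflicting effect alleles for {rec.snp_id}: "
                        f"{prior.effect_allele!r} ({prior.source}) vs "
                        f"{rec.effect_allele!r} ({rec.source})"
                    )
                n_dupes += 1
                if rec.source not in sources_by_snp[rec.snp_id]:
                    sources_by_snp[rec.snp_id].append(rec.source)
            else:
                seen[rec.snp_id] = rec
                sources_by_snp[rec.snp_id] = [rec.source]
    merged = list(seen.values())
    report = MergeReport(
        per_source_counts=per_source,
        n_distinct=len(merged),
        n_duplicates_dropped=n_dupes,
        dropped_missing=dropped_missing,
        sources_by_snp=sources_by_snp,
    )
    return merged, report


def ld_clump(
    records: list[SnpRecord],
    ld: LdMatrix,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[SnpRecord]:
    """Greedy LD clumping.

    Repeatedly take the unclaimed record with the lowest p (ties broken by
    snp_id) as an index SNP and claim every unclaimed record on the same
    chromosome within ``window_bp`` whose r^2 with the index is at or above
    ``r2_threshold``. Index SNPs are retained, in selection order.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in (0, 1]")
    missing = [r.snp_id for r in records if r.snp_id not in ld]
    if missing:
        raise ValueError(f"records missing from the LD matrix: {missing}")

    order = sorted(range(len(records)), key=lambda i: (records[i].p, records[i].snp_id))
    claimed = np.zeros(len(records), dtype=bool)
    retained: list[SnpRecord] = []
    for i in order:
        if claimed[i]:
            continue
        idx = records[i]
        retained.append(idx)
        claimed[i] = True
        for j in order:
            if claimed[j]:
                continue
            other = records[j]
            if (
                other.chrom == idx.chrom
                and abs(other.pos - idx.pos) <= window_bp
                and ld.value(idx.snp_id, other.snp_id) >= r2_threshold
            ):
                claimed[j] = True
    return retained


def estimate_ld(genotypes: GenotypeMatrix) -> tuple[LdMatrix, list[str]]:
    """Squared Pearson correlation of (mean-imputed) dosage columns.

    Zero-variance SNPs are excluded from the matrix and returned as the second
    element.
    """
    if genotypes.n_samples < 2:
        raise ValueError("need at least 2 samples to estimate LD")
    x = genotypes.imputed()
    sd = x.std(axis=0)
    excluded = [str(s) for s in genotypes.snp_ids[sd == 0.0]]
    keep = sd > 0.0
    corr = np.corrcoef(x[:, keep].T)
    corr = np.atleast_2d(corr)
    r2 = np.clip(corr * corr, 0.0, 1.0)
    np.fill_diagonal(r2, 1.0)
    return LdMatrix(snp_ids=genotypes.snp_ids[keep], r2=r2), excluded
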