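"""File formats: TSV readers/writers for every pipeline artifact, a
PGS-Catalog-style scoring file, and a minimal PLINK .bed/.bim/.fam codec.

All tables are tab-separated with documented headers; genomic coordinates are
1-based. Each writer has a paired reader that round-trips all fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CodeRuleSet
from .mr import MrResult
from .scoring import ScoreVector
from .simulate import Cohort, GenotypeMatrix, MrInstrumentSet
from .stratify import StratumResult
from .training import PgsModel
from .variants import SnpRecord

__all__ = [
    "write_dosage_tsv", "read_dosage_tsv",
    "write_cohort_tsv", "read_cohort_tsv",
    "write_summary_tsv", "read_summary_tsv", "records_from_frame", "frame_from_records",
    "write_scoring_file", "read_scoring_file",
    "write_scores_tsv", "read_scores_tsv",
    "write_instruments_tsv", "read_instruments_tsv",
    "write_mr_results_tsv", "write_strata_tsv",
    "write_plink", "read_plink",
    "read_rules_json", "write_rules_json",
]

_MISSING = "NA"


# ---------------------------------------------------------------------------
# genotypes as TSV
# ---------------------------------------------------------------------------

def write_dosage_tsv(genotypes: GenotypeMatrix, dosage_path, alleles_path=None) -> None:
    """Samples x SNPs dosage matrix; optional effect-allele sidecar TSV."""
    df = pd.DataFrame(genotypes.dosages, columns=list(genotypes.snp_ids))
    df.insert(0, "sample_id", genotypes.sample_ids)
    df.to_csv(dosage_path, sep="\t", index=False, na_rep=_MISSING, float_format="%g")
    if alleles_path is not None:
        pd.DataFrame(
            {"snp": genotypes.snp_ids, "effect_allele": genotypes.effect_alleles}
        ).to_csv(alleles_path, sep="\t", index=False)


def read_dosage_tsv(dosage_path, alleles_path=None) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", na_values=[_MISSING])
    sample_ids = df["sample_id"].astype(str).to_numpy(dtype=object)
    snp_ids = np.array(df.columns[1:], dtype=object)
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    if alleles_path is not None:
        al = pd.read_csv(alleles_path, sep="\t").set_index("snp")["effect_allele"]
        effect_alleles = np.array([al[s] for s in snp_ids], dtype=object)
    else:
        effect_alleles = np.array(["A"] * len(snp_ids), dtype=object)
    return GenotypeMatrix(sample_ids, snp_ids, dosages, effect_alleles)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def write_cohort_tsv(cohort: Cohort, path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "status": cohort.status,
            "bmi": cohort.bmi,
            "codes": [";".join(sorted(c)) for c in cohort.diagnosis_codes],
        }
    )
    if cohort.true_liability is not None:
        df["true_liability"] = cohort.true_liability
    df.to_csv(path, sep="\t", index=False, na_rep=_MISSING)


def read_cohort_tsv(path) -> Cohort:
    df = pd.read_csv(path, sep="\t", na_values=[_MISSING], keep_default_na=False)
    codes = [
        frozenset(c.split(";")) if isinstance(c, str) and c else frozenset()
        for c in df["codes"]
    ]
    return Cohort(
        sample_ids=df["sample_id"].astype(str).to_numpy(dtype=object),
        status=df["status"].to_numpy(dtype=object),
        bmi=pd.to_numeric(df["bmi"], errors="coerce").to_numpy(dtype=float),
        diagnosis_codes=codes,
        true_liability=(
            pd.to_numeric(df["true_liability"]).to_numpy(dtype=float)
            if "true_liability" in df.columns
            else None
        ),
    )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

_SUMMARY_COLS = ["snp", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p", "source"]


def frame_from_records(records: list[SnpRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snp": r.snp_id, "chrom": r.chrom, "pos": r.pos,
                "effect_allele": r.effect_allele, "other_allele": r.other_allele,
                "beta": r.beta, "se": r.se, "p": r.p, "source": r.source,
            }
            for r in records
        ],
        columns=_SUMMARY_COLS,
    )


def records_from_frame(df: pd.DataFrame) -> list[SnpRecord]:
    return [
        SnpRecord(
            snp_id=str(row.snp), chrom=str(row.chrom), pos=int(row.pos),
            effect_allele=str(row.effect_allele), other_allele=str(row.other_allele),
            p=float(row.p),
            source=str(getattr(row, "source", "")) if pd.notna(getattr(row, "source", "")) else "",
            beta=float(row.beta) if pd.notna(row.beta) else None,
            se=float(row.se) if pd.notna(row.se) else None,
        )
        for row in df.itertuples(index=False)
    ]


def write_summary_tsv(records_or_frame, path) -> None:
    df = (
        records_or_frame
        if isinstance(records_or_frame, pd.DataFrame)
        else frame_from_records(records_or_frame)
    )
    df.to_csv(path, sep="\t", index=False, na_rep=_MISSING)


def read_summary_tsv(path) -> pd.DataFrame:
    """Summary-stat TSV; extra columns beyond the standard set are preserved."""
    return pd.read_csv(path, sep="\t", na_values=[_MISSING])


# ---------------------------------------------------------------------------
# scoring files (PGS-Catalog-style)
# ---------------------------------------------------------------------------

def write_scoring_file(model: PgsModel, path, sidecar: bool = True) -> None:
    path = Path(path)
    pd.DataFrame(
        {
            "rsID": model.snp_ids,
            "effect_allele": model.effect_alleles,
            "effect_weight": model.weights,
        }
    ).to_csv(path, sep="\t", index=False)
    if sidecar:
        meta = {
            "intercept": model.intercept,
            "training_auc": None if np.isnan(model.training_auc) else model.training_auc,
            "provenance": model.provenance,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_scoring_file(path) -> PgsModel:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta_path = path.with_suffix(path.suffix + ".json")
    intercept, auc, prov = 0.0, float("nan"), {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        intercept = meta.get("intercept", 0.0)
        auc = meta.get("training_auc")
        auc = float("nan") if auc is None else float(auc)
        prov = meta.get("provenance", {})
    return PgsModel(
        snp_ids=df["rsID"].astype(str).to_numpy(dtype=object),
        weights=df["effect_weight"].to_numpy(dtype=float),
        intercept=float(intercept),
        effect_alleles=df["effect_allele"].astype(str).to_numpy(dtype=object),
        training_auc=auc,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# per-sample scores
# ---------------------------------------------------------------------------

def write_scores_tsv(scores: ScoreVector, path) -> None:
    pd.DataFrame(
        {"sample_id": scores.sample_ids, "pgs": scores.scores, "percentile": scores.percentile_rank}
    ).to_csv(path, sep="\t", index=False)


def read_scores_tsv(path) -> ScoreVector:
    df = pd.read_csv(path, sep="\t")
    return ScoreVector(
        sample_ids=df["sample_id"].astype(str).to_numpy(dtype=object),
        scores=df["pgs"].to_numpy(dtype=float),
        percentile_rank=df["percentile"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# MR instruments and results
# ---------------------------------------------------------------------------

def write_instruments_tsv(instruments: MrInstrumentSet, path) -> None:
    pd.DataFrame(
        {
            "snp": instruments.snp_ids,
            "beta_exposure": instruments.beta_exposure,
            "se_exposure": instruments.se_exposure,
            "p_exposure": instruments.p_exposure,
            "beta_outcome": instruments.beta_outcome,
            "se_outcome": instruments.se_outcome,
        }
    ).to_csv(path, sep="\t", index=False)


def read_instruments_tsv(path) -> MrInstrumentSet:
    df = pd.read_csv(path, sep="\t")
    return MrInstrumentSet(
        snp_ids=df["snp"].astype(str).to_numpy(dtype=object),
        beta_exposure=df["beta_exposure"].to_numpy(dtype=float),
        se_exposure=df["se_exposure"].to_numpy(dtype=float),
        beta_outcome=df["beta_outcome"].to_numpy(dtype=float),
        se_outcome=df["se_outcome"].to_numpy(dtype=float),
        p_exposure=df["p_exposure"].to_numpy(dtype=float),
    )


def write_mr_results_tsv(results: list[MrResult], path) -> None:
    pd.DataFrame(
        [
            {
                "method": r.method, "exposure": r.exposure, "outcome": r.outcome,
                "beta": r.beta, "se": r.se, "or": r.odds_ratio,
                "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
                "egger_intercept": r.egger_intercept, "intercept_p": r.intercept_p,
                "n_instruments": r.n_instruments,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False, na_rep=_MISSING)


def write_strata_tsv(results: list[StratumResult], path) -> None:
    pd.DataFrame(
        [
            {
                "stratum": r.stratum_label,
                "a": r.estimate.cells.a, "b": r.estimate.cells.b,
                "c": r.estimate.cells.c, "d": r.estimate.cells.d,
                "or": r.estimate.odds_ratio,
                "ci_low": r.estimate.ci_low, "ci_high": r.estimate.ci_high,
                "corrected": r.estimate.zero_cell_corrected,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK .bed/.bim/.fam
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# 2-bit codes, indexed by effect-allele (A1) dosage; 0b01 is missing
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
_CODE_TO_DOSAGE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}


def write_plink(
    genotypes: GenotypeMatrix,
    prefix,
    cohort: Cohort | None = None,
    chroms: np.ndarray | None = None,
    positions: np.ndarray | None = None,
) -> None:
    """Write the PLINK trio. A1 in the .bim is the effect allele, so the
    2-bit code 00 means two effect-allele copies."""
    prefix = Path(prefix)
    n, p = genotypes.n_samples, genotypes.n_snps
    chroms = chroms if chroms is not None else np.array(["1"] * p)
    positions = positions if positions is not None else np.arange(1, p + 1)

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        n_bytes = (n + 3) // 4
        for j in range(p):
            packed = np.zeros(n_bytes, dtype=np.uint8)
            col = genotypes.dosages[:, j]
            for i in range(n):
                code = 0b01 if np.isnan(col[i]) else _DOSAGE_TO_CODE[col[i]]
                packed[i // 4] |= code << (2 * (i % 4))
            fh.write(packed.tobytes())

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(p):
            fh.write(
                f"{chroms[j]}\t{genotypes.snp_ids[j]}\t0\t{positions[j]}\t"
                f"{genotypes.effect_alleles[j]}\tN\n"
            )

    status = cohort.status if cohort is not None else None
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i, sid in enumerate(genotypes.sample_ids):
            pheno = -9
            if status is not None:
                pheno = 2 if status[i] == "case" else 1
            fh.write(f"{sid}\t{sid}\t0\t0\t2\t{pheno}\n")


def read_plink(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep="\t", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep="\t", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
    )
    n, p = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK .bed file")
    n_bytes = (n + 3) // 4
    body = raw[3:].reshape(p, n_bytes)
    dosages = np.empty((n, p))
    for j in range(p):
        codes = np.repeat(body[j], 4)
        shifts = np.tile([0, 2, 4, 6], n_bytes)
        two_bit = (codes >> shifts) & 0b11
        dosages[:, j] = [_CODE_TO_DOSAGE[c] for c in two_bit[:n]]
    return GenotypeMatrix(
        sample_ids=fam["iid"].astype(str).to_numpy(dtype=object),
        snp_ids=bim["snp"].astype(str).to_numpy(dtype=object),
        dosages=dosages,
        effect_alleles=bim["a1"].astype(str).to_numpy(dtype=object),
    )


# ---------------------------------------------------------------------------
# code rule sets
# ---------------------------------------------------------------------------

def write_rules_json(rules: CodeRuleSet, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "case_codes": sorted(rules.case_codes),
                "case_exclusions": sorted(rules.case_exclusions),
                "control_required_codes": sorted(rules.control_required_codes),
                "control_exclusions": sorted(rules.control_exclusions),
                "strict_preeclampsia": rules.strict_preeclampsia,
            },
            indent=2,
        )
    )


def read_rules_json(path) -> CodeRuleSet:
    data = json.loads(Path(path).read_text())
    return CodeRuleSet(
        case_codes=frozenset(data["case_codes"]),
        control_required_codes=frozenset(data["control_required_codes"]),
        case_exclusions=frozenset(data.get("case_exclusions", [])),
        control_exclusions=frozenset(data.get("control_exclusions", [])),
        strict_preeclampsia=bool(data.get("strict_preeclampsia", False)),
    )
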