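import numpy as np
import pytest

from pgspipe import Cohort, GenotypeMatrix, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded cohort with signal, shared across read-only tests."""
    cfg = SimulationConfig(
        n_cases=300, n_controls=1400, n_snps=40, n_ld_blocks=10,
        within_block_r2=0.4, causal_fraction=0.2, effect_sd=0.4,
        prevalence=0.15, seed=11,
    )
    genotypes, cohort, weights = simulate_cohort(cfg)
    return cfg, genotypes, cohort, weights


def make_genotypes(dosages, snp_ids=None, alleles=None):
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    snp_ids = snp_ids if snp_ids is not None else [f"rs{j}" for j in range(p)]
    alleles = alleles if alleles is not None else ["A"] * p
    return GenotypeMatrix(
        sample_ids=np.array([f"S{i}" for i in range(n)], dtype=object),
        snp_ids=np.array(snp_ids, dtype=object),
        dosages=dosages,
        effect_alleles=np.array(alleles, dtype=object),
    )


def make_cohort(status, bmi=None, codes=None, liability=None):
    status = np.asarray(status, dtype=object)
    n = len(status)
    return Cohort(
        sample_ids=np.array([f"S{i}" for i in range(n)], dtype=object),
        status=status,
        bmi=np.asarray(bmi, dtype=float) if bmi is not None else np.full(n, 25.0),
        diagnosis_codes=codes if codes is not None else [frozenset()] * n,
        true_liability=liability,
    )
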