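import numpy as np
import pytest

from rddaudit.pipeline import AuditParams, run_cohort_audit, simulate_cohort_reads
from rddaudit.simulate import SimConfig, simulate_cohort

RNG_SEED = 20260904


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(
        genome_length=120_000,
        n_genes=24,
        n_individuals=4,
        paralog_fraction=0.25,
        cnv_fraction=0.125,
        n_true_edits=4,
        snp_rate=0.0002,
        error_rate=0.002,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_reads(small_cohort):
    return simulate_cohort_reads(small_cohort, 11)


@pytest.fixture(scope="session")
def small_audit(small_cohort, small_reads):
    rna, dna = small_reads
    params = AuditParams(
        swap_iterations=100, permutation_replicates=200, rarefaction_replicates=50
    )
    return run_cohort_audit(small_cohort, rna, dna, params, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(RNG_SEED)
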