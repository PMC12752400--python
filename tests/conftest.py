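import numpy as np
import pytest

from gwaskd.simulate import CohortDataset, SimulationConfig, simulate_cohorts


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_dataset(
    genotypes, labels, name="toy", rsids=None, missing_mask=None
) -> CohortDataset:
    genotypes = np.asarray(genotypes, dtype=float)
    if rsids is None:
        rsids = [f"rs{j:03d}" for j in range(genotypes.shape[1])]
    if missing_mask is None:
        missing_mask = np.isnan(genotypes)
    return CohortDataset(
        name=name,
        genotypes=genotypes,
        rsids=rsids,
        labels=np.asarray(labels, dtype=int),
        missing_mask=missing_mask,
    )


@pytest.fixture
def small_cohorts():
    """Two modest cohorts with 10 strong causal SNPs among 75."""
    config = SimulationConfig(
        n_cohorts=2,
        n_samples_per_cohort=[400, 400],
        n_snps=75,
        n_causal=10,
        effect_sizes=[0.8] * 10,
        case_fraction_per_cohort=[0.55, 0.6],
        base_maf_range=(0.1, 0.5),
        cohort_maf_shift_sd=0.05,
        missing_rate=0.02,
        seed=42,
    )
    return simulate_cohorts(config)
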