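import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import oakscan as ok

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset() -> ok.SyntheticDataset:
    """A small mixed-class dataset with outgroup and hybrid."""
    cfg = ok.SimulationConfig(
        seed=7,
        n_genes=12,
        cds_length_range=(300, 900),
        include_hybrid=True,
        class_specs=(
            ok.ClassSpec("PF00001", 1.0, "neutral"),
            ok.ClassSpec("PF00002", 0.2, "neutral"),
        ),
    )
    return ok.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_snps(small_dataset):
    return ok.filtered_snps(small_dataset.records, small_dataset.samples)


@pytest.fixture(scope="session")
def dense_dataset() -> ok.SyntheticDataset:
    """A clean high-density neutral dataset (~10^4 polymorphic sites) for
    distributional checks: no missing data, failing genotypes or
    contaminated sites."""
    cfg = ok.SimulationConfig(
        seed=11,
        n_genes=60,
        cds_length_range=(3300, 3600),
        theta_site=0.05,
        outgroup_divergence=0.005,
        missing_rate=0.0,
        geno_fail_rate=0.0,
        contamination=0.0,
    )
    return ok.simulate_dataset(cfg)


def make_locus(gt_codes, ref="A", var="G", contig="ctg", pos=100):
    gt = np.asarray(gt_codes, dtype=np.int8)
    samples = tuple(f"s{i:02d}" for i in range(len(gt)))
    return ok.SnpLocus(contig, pos, ref, var, gt, samples)
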