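import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tcrcompart import benchmarks
from tcrcompart.synthetic_repertoire import (
    SimulationConfig,
    default_clusters,
    default_compartments,
    generate_dataset,
    write_dataset,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact but structurally complete dataset: 2 donors, both lineages,
    all three compartments, 5 clusters, partial clonotype sharing."""
    return SimulationConfig(
        n_donors=2,
        compartments=default_compartments(250),
        clusters=default_clusters(5),
        sharing_fraction=0.3,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def dataset_paths(small_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("synthetic")
    return write_dataset(small_dataset, outdir)


@pytest.fixture(scope="session")
def calibration_pvalues_500() -> np.ndarray:
    """500 overlap-test p-values under exchangeable labels (full sharing),
    300 cells per group, 100-clonotype geometric pools, 200 permutations.
    Shared between the calibration property test and the acceptance check."""
    return benchmarks.calibration_pvalues(
        n_tests=500, n_permutations=200, n_cells_per_group=300, seed=0
    )
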