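import numpy as np
import pytest

from apconn import (
    GroupDataset,
    RegionTimeSeries,
    planted_benchmark_spec,
    simulate_dataset,
    subject_community,
)
from apconn.simulate import PlantedEdge, SimulationSpec


@pytest.fixture
def toy_series() -> RegionTimeSeries:
    """3 regions, 4 time points, well-conditioned."""
    return RegionTimeSeries(
        subject_id="toy",
        region_labels=["a-L", "a-R", "b-L"],
        data=np.array(
            [[1.0, 2.0, 3.0, 4.0], [1.1, 2.0, 2.9, 4.2], [4.0, -1.0, 0.5, 2.0]]
        ),
    )


@pytest.fixture(scope="session")
def small_planted():
    """A small planted two-group dataset: 12 regions, 8+8 subjects.

    Two correlated blocks of five regions plus two initially unattached
    regions that each join one whole block in patients (10 planted edges).
    """
    blocks = (tuple(range(0, 5)), tuple(range(5, 10)), (10,), (11,))
    planted = tuple(
        PlantedEdge(i=min(f, m), j=max(f, m), rho_control=0.0, rho_patient=0.8)
        for f, members in zip((10, 11), blocks[:2])
        for m in members
    )
    spec = SimulationSpec(
        n_regions=12,
        n_timepoints=150,
        subjects_per_group=(8, 8),
        blocks=blocks,
        planted_edges=planted,
        seed=7,
    )
    dataset, truth = simulate_dataset(spec)
    return dataset, truth


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The standard 23-region 20+20 planted benchmark (seed 0)."""
    dataset, truth = simulate_dataset(planted_benchmark_spec(seed=0))
    return dataset, truth


@pytest.fixture(scope="session")
def benchmark_K(benchmark_dataset):
    """Community matrices for every benchmark subject (computed once)."""
    dataset, _ = benchmark_dataset
    return np.stack([subject_community(s).K for s in dataset.subjects])


def make_dataset(data_list, labels, region_labels=None) -> GroupDataset:
    subjects = []
    for k, d in enumerate(data_list):
        d = np.asarray(d, float)
        subjects.append(
            RegionTimeSeries(
                subject_id=f"s{k}",
                region_labels=region_labels or [f"r{i}" for i in range(d.shape[0])],
                data=d,
            )
        )
    return GroupDataset(subjects=subjects, labels=list(labels))
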