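import numpy as np
import pytest

from lodemap import GeneticMap, GenotypeMatrix, mask_map, simulate_population


@pytest.fixture(scope="session")
def default_sim():
    """The standard test population: 3 LGs x 100 cM x 200 markers, 8 founders,
    5 generations, 500 samples, seed 1."""
    return simulate_population()


@pytest.fixture(scope="session")
def small_sim():
    """A lighter population for fast unit tests."""
    return simulate_population(
        n_linkage_groups=2, n_markers_per_lg=40, n_samples=150, seed=11
    )


@pytest.fixture(scope="session")
def masked_default(default_sim):
    """Default simulation with 10% of markers held out (seeded)."""
    anchor, held = mask_map(default_sim.truth_map, fraction=0.1, seed=1)
    return default_sim.genotypes, anchor, held


@pytest.fixture()
def tiny_map():
    return GeneticMap(
        [
            ("a1", "LG1", 0.0),
            ("a2", "LG1", 10.0),
            ("a3", "LG1", 20.0),
            ("b1", "LG2", 5.0),
            ("b2", "LG2", 15.0),
        ]
    )


def genotypes_from_columns(columns: dict[str, list[int]]) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {marker_id: calls} (missing = -1)."""
    marker_ids = list(columns)
    calls = np.array([columns[m] for m in marker_ids], dtype=np.int8).T
    samples = [f"s{i}" for i in range(calls.shape[0])]
    return GenotypeMatrix(samples, marker_ids, calls)
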