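import numpy as np
import pandas as pd
import pytest

from rohscape.fixtures import PlantedRohSpec, generate_planted
from rohscape.markers_io import GenotypeMatrix, MarkerMap


@pytest.fixture
def small_map() -> MarkerMap:
    """Five markers on one chromosome, 1 Mb apart."""
    bp = np.array([1, 2, 3, 4, 5]) * 1_000_000
    return MarkerMap(pd.DataFrame({
        "chromosome": [1] * 5,
        "marker_id": [f"snp{i}" for i in range(5)],
        "bp_pos": bp,
        "cm_pos": bp * 1e-6,
    }))


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    calls = np.array([
        [0, 1, 2, 0, 1],
        [2, 2, 2, 2, 2],
        [0, -1, 1, 0, 2],
    ], dtype=np.int8)
    return GenotypeMatrix(calls, ["a", "b", "c"])


@pytest.fixture
def planted_dataset():
    """Ten individuals, one 3.1 Mb homozygous tract planted in the first."""
    spec = PlantedRohSpec(
        n_individuals=10,
        chromosome_lengths={1: 12_000_000},
        spacing_bp=50_000,
        tracts=[(0, 1, 2_000_000, 5_100_000)],
        background_het_rate=0.3,
        seed=20)
    genotypes, marker_map, truth = generate_planted(spec)
    return genotypes, marker_map, truth


def make_map(bp_positions, chromosomes=None, n_autosomes=33) -> MarkerMap:
    bp = np.asarray(bp_positions)
    chroms = np.ones(len(bp), int) if chromosomes is None else np.asarray(chromosomes)
    return MarkerMap(pd.DataFrame({
        "chromosome": chroms,
        "marker_id": [f"m{i}" for i in range(len(bp))],
        "bp_pos": bp,
        "cm_pos": bp * 1e-6,
    }), n_autosomes=n_autosomes)
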