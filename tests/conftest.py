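import numpy as np
import pandas as pd
import pytest

from varmap.counting import CountTable
from varmap.synthetic import (
    GroundTruthMap,
    LibraryModel,
    SelectionModel,
    SequencingModel,
    generate_ground_truth,
    simulate_clone_pool,
)
from varmap.variants import VariantKey


@pytest.fixture(scope="session")
def small_truth() -> GroundTruthMap:
    return generate_ground_truth(40, hyper_fraction=0.05, seed=11)


@pytest.fixture(scope="session")
def small_pool(small_truth):
    lib = LibraryModel(n_clones=3_000)
    return simulate_clone_pool(small_truth, lib, seed=7, region=(1, 41))


@pytest.fixture(scope="session")
def small_seqm() -> SequencingModel:
    return SequencingModel(
        depth_per_tile=5_000, tile_length=30, per_base_error=0.001
    )


def make_count_table(
    entries: dict[VariantKey, int],
    depth: int = 100_000,
    condition: str = "nonselective",
    replicate: int = 1,
    n_tiles: int = 1,
    tile_len_nt: int = 10_000,
) -> CountTable:
    """Hand-rolled count table over wide pseudo-tiles (testing helper)."""
    tile_bounds = {i: (i * tile_len_nt, (i + 1) * tile_len_nt) for i in range(n_tiles)}
    depths = {i: depth for i in range(n_tiles)}
    return CountTable(condition, replicate, dict(entries), depths, tile_bounds)
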