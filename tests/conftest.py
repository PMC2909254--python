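import numpy as np
import pytest

from ecmcomm.config import SyntheticConfig
from ecmcomm.matrix import CommunityMatrix
from ecmcomm.tree import PhyloTree


@pytest.fixture
def balanced_tree() -> PhyloTree:
    """Four-tip balanced ultrametric tree; d(A,B)=2, d(A,C)=4."""
    return PhyloTree.from_string("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def star_tree() -> PhyloTree:
    return PhyloTree.from_string("(A:1,B:1,C:1,D:1);", allow_polytomy=True)


@pytest.fixture
def small_matrix() -> CommunityMatrix:
    return CommunityMatrix(
        sample_ids=["s1", "s2", "s3"],
        species_ids=["A", "B", "C"],
        data=np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]]),
        forests=["f1", "f1", "f2"],
        habitats=["serpentine", "serpentine", "non_serpentine"],
    )


@pytest.fixture
def tiny_synth_config() -> SyntheticConfig:
    """Small but complete study configuration for integration tests."""
    return SyntheticConfig(
        seed=11,
        n_species_pool=32,
        n_samples_per_forest=8,
        seq_len_its=300,
        seq_len_lsu=400,
    )
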