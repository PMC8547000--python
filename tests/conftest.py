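import io

import numpy as np
import pandas as pd
import pytest
import skbio

from rarebiome.diversity import CopheneticMatrix, cophenetic_matrix
from rarebiome.io_config import CommunityMatrix, EnvTable, Phylogeny


def tree_from_newick(newick: str) -> Phylogeny:
    return Phylogeny(skbio.TreeNode.read(io.StringIO(newick), format="newick"))


@pytest.fixture
def balanced_tree() -> Phylogeny:
    """((A:1,B:1):1,(C:1,D:1):1); — d(A,B)=2, d(A,C)=4."""
    return tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def balanced_dmat(balanced_tree) -> CopheneticMatrix:
    return cophenetic_matrix(balanced_tree)


@pytest.fixture
def toy_community() -> CommunityMatrix:
    counts = pd.DataFrame(
        [[5, 0, 5], [0, 10, 0]],
        index=["S1", "S2"], columns=["OTU_1", "OTU_2", "OTU_3"],
    )
    return CommunityMatrix(counts)


def make_env_table(n=6, seed=0) -> EnvTable:
    from rarebiome.io_config import ENV_VARIABLES, FUNCTION_VARIABLES

    rng = np.random.default_rng(seed)
    idx = pd.Index([f"S{i+1}" for i in range(n)], name="sample_id")
    env = pd.DataFrame(rng.uniform(1, 10, (n, len(ENV_VARIABLES))),
                       index=idx, columns=ENV_VARIABLES)
    fn = pd.DataFrame(rng.uniform(1, 10, (n, len(FUNCTION_VARIABLES))),
                      index=idx, columns=FUNCTION_VARIABLES)
    return EnvTable(env=env, functions=fn)


@pytest.fixture
def env_table() -> EnvTable:
    return make_env_table()
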