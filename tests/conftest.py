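import numpy as np
import pytest

from selscape.synthetic import random_tree
from selscape.trees import Phylogeny


@pytest.fixture
def two_tip_tree() -> Phylogeny:
    return Phylogeny.from_newick("(A:0.1,B:0.3)R;")


@pytest.fixture
def quartet_tree() -> Phylogeny:
    # total branch length 1.0
    return Phylogeny.from_newick(
        "((A:0.1,B:0.2)N1:0.3,(C:0.15,D:0.15)N2:0.1)R;"
    )


@pytest.fixture
def ten_tip_tree() -> Phylogeny:
    return random_tree(10, 1.0, seed=7)


def lstsq_decomposition(matrix):
    """Normal-equations least-squares oracle for the two-way additive model,
    gauged so mean(R) = 0."""
    mask = matrix.observed_mask
    n_l, n_g = mask.shape
    obs = np.argwhere(mask)
    design = np.zeros((len(obs), n_l + n_g))
    rhs = np.empty(len(obs))
    for k, (i, j) in enumerate(obs):
        design[k, i] = 1.0
        design[k, n_l + j] = 1.0
        rhs[k] = matrix.values[i, j]
    solution, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    f, r = solution[:n_l], solution[n_l:]
    shift = r.mean()
    return f + shift, r - shift
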