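import numpy as np
import pytest

from phytoassembly.io import CommunityTable, Phylogeny, read_tree

FOUR_TIP_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);\n"


@pytest.fixture()
def four_tip_tree(tmp_path) -> Phylogeny:
    """Two cherries at depth 2: d(A,B)=d(C,D)=2, all cross distances 4."""
    p = tmp_path / "four.nwk"
    p.write_text(FOUR_TIP_NEWICK)
    return read_tree(p)


@pytest.fixture()
def four_tip_table() -> CommunityTable:
    """s1 occupies the {A,B} cherry, s2 one tip of each cherry."""
    return CommunityTable(
        ["A", "B", "C", "D"],
        ["s1", "s2"],
        np.array([[5, 7], [5, 0], [0, 3], [0, 0]]),
    )


def random_instance(seed: int, max_tips: int = 12):
    """Small random tree + community for brute-force oracle comparisons."""
    from phytoassembly.simulate import simulate_tree

    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_tips + 1))
    tree = simulate_tree(n, 1.0, 0.0, seed)
    dmat = tree.cophenetic_matrix()
    k = int(rng.integers(2, n + 1))
    occupied = rng.choice(n, size=k, replace=False)
    return tree, dmat, occupied, rng
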