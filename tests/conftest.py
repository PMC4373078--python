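import numpy as np
import pytest

from melinvade.characters import load_melanoides_scores
from melinvade.phylo import tree_from_string


@pytest.fixture(scope="session")
def melanoides():
    return load_melanoides_scores()


@pytest.fixture
def four_tip_tree():
    return tree_from_string("((A:0.5,B:1.2):0.8,(C:0.3,D:0.9):0.4);")


def random_small_tree_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random rooted topology (with occasional polytomies), exp branch lengths."""
    nodes = [f"t{i}:{rng.exponential(1.0):.6f}" for i in range(n_tips)]
    while len(nodes) > 1:
        k = int(rng.integers(2, 4)) if len(nodes) > 2 else 2
        k = min(k, len(nodes))
        picks = [nodes.pop(int(rng.integers(0, len(nodes)))) for _ in range(k)]
        nodes.append(f"({','.join(picks)}):{rng.exponential(1.0):.6f}")
    last = nodes[0]
    return last[: last.rindex(":")] + ";"
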