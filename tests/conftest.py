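import numpy as np
import pytest

from gipscape import default_basis, load_gip_signature


@pytest.fixture(scope="session")
def gip_pattern():
    return load_gip_signature()


@pytest.fixture(scope="session")
def basis():
    return default_basis()


@pytest.fixture()
def rng():
    return np.random.default_rng(20130480)


def random_binary_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary topology (trifurcating root) with positive
    branch lengths; used to build additive distance matrices."""
    from skbio import TreeNode

    nodes = [TreeNode(name=f"t{i + 1}") for i in range(n_taxa)]
    for node in nodes:
        node.length = float(rng.uniform(0.1, 1.0))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        parent.length = float(rng.uniform(0.1, 1.0))
        parent.append(nodes[i])
        parent.append(nodes[j])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for nd in nodes:
        root.append(nd)
    return root
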