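import numpy as np
import pytest

from lineagemst.edit_space import EditOperation
from lineagemst.tree import LineageTree


@pytest.fixture
def chain_tree():
    """root -> a -> b, all observed."""
    t = LineageTree("AAAA", observed=True, multiplicity=1)
    a = t.add_child(0, "CAAA", EditOperation("sub", 1, "C"), observed=True, multiplicity=1)
    t.add_child(a, "CCAA", EditOperation("sub", 2, "C"), observed=True, multiplicity=1)
    return t


@pytest.fixture
def star_tree():
    """root with three observed children."""
    t = LineageTree("AAAA")
    for base, pos in [("C", 1), ("C", 2), ("C", 3)]:
        t.add_child(0, "AAAA"[:pos - 1] + base + "AAAA"[pos:], EditOperation("sub", pos, base), observed=True, multiplicity=1)
    return t


@pytest.fixture
def detour_tree():
    """Two-branch tree where relocating one observed leaf saves two nodes."""
    t = LineageTree("AAAA")
    a = t.add_child(0, "TAAA", EditOperation("sub", 1, "T"))
    t.add_child(a, "TTAA", EditOperation("sub", 2, "T"), observed=True, multiplicity=1)
    c = t.add_child(0, "AAAT", EditOperation("sub", 4, "T"))
    d = t.add_child(c, "TAAT", EditOperation("sub", 1, "T"))
    t.add_child(d, "TTAT", EditOperation("sub", 2, "T"), observed=True, multiplicity=1)
    return t


def random_instances(n, rng=None, lengths=(6, 14), n_obs=(1, 6), p_indel=0.2):
    """Small random reconstruction inputs for property tests."""
    rng = rng or np.random.default_rng(42)
    from lineagemst.simulate import SimulationSetting, simulate_instance

    out = []
    for _ in range(n):
        length = int(rng.integers(*lengths))
        probs = (1.0 - p_indel, p_indel / 2, p_indel / 2)
        setting = SimulationSetting(
            root_length=length,
            op_probs=probs,
            tree_size_range=(8, 20),
            observed_range=(2, 8),
            seed=0,
        )
        out.append(simulate_instance(setting, rng))
    return out
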