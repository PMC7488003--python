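"""Ground-truth lineage simulation and the reconstruction benchmark.

The simulator emulates somatic hypermutation of a B-cell receptor clone as
a random growth process: starting from a uniformly random germline root, it
repeatedly picks an existing node uniformly, draws an operation kind
(substitution / insertion / deletion) from the setting's probabilities, a
uniform position and a uniform valid base, and attaches the edited sequence
as a new child whenever it is globally novel.  Mutations are uniform along
the sequence — shorter roots therefore emulate higher per-position mutation
rates, which is what makes the short-root settings hard.

The benchmark draws a ground-truth tree, reveals a uniform subsample of its
non-root sequences as the "observed" reads, reconstructs a tree from root
plus observations, and compares reconstructed size against the ground truth
*restricted to what the observations require*: the simulated tree pruned of
branches holding no observed node (the observed nodes' ancestor closure).
The unobserved remainder of the latent process is not something any
reconstruction should be charged with.  A replicate counts as a success
when the reconstruction is no larger than this pruned truth; smaller
remains possible because the true mutational history need not be the most
parsimonious explanation of the revealed subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .edit_space import DELETION, DNA_ALPHABET, INSERTION, SUBSTITUTION, EditOperation, apply_operation
from .growth import reconstruct
from .tree import LineageTree

__all__ = [
    "SimulationSetting",
    "SimulatedInstance",
    "BenchmarkRow",
    "simulate_tree",
    "subsample_observed",
    "simulate_instance",
    "run_benchmark",
]

_REDRAW_CAP = 100


class SimulationError(RuntimeError):
    """The growth process exhausted its redraw budget (degenerate setting)."""


@dataclass(frozen=True)
class SimulationSetting:
    """One benchmark condition.

    ``op_probs`` is the (substitution, insertion, deletion) probability
    triple; it must sum to one.  Defaults for the tree-size range, the
    observed-count range and the replicate count are the standard benchmark
    conditions: trees of 20-80 unique sequences with 2-24 of them observed,
    500 replicates per setting.
    """

    root_length: int
    op_probs: tuple[float, float, float] = (1.0, 0.0, 0.0)
    tree_size_range: tuple[int, int] = (20, 80)
    observed_range: tuple[int, int] = (2, 24)
    replicates: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_length < 1:
            raise ValueError("root_length must be positive")
        if any(p < 0 for p in self.op_probs):
            raise ValueError("operation probabilities must be non-negative")
        if abs(sum(self.op_probs) - 1.0) > 1e-9:
            raise ValueError("operation probabilities must sum to 1")
        lo, hi = self.tree_size_range
        if not 2 <= lo <= hi:
            raise ValueError("invalid tree_size_range")
        olo, ohi = self.observed_range
        if not 2 <= olo <= ohi or ohi > hi:
            raise ValueError("invalid observed_range")
        if self.replicates < 1:
            raise ValueError("replicates must be positive")


@dataclass
class SimulatedInstance:
    """A ground-truth tree with its revealed observation subset.

    ``ground_truth`` is the full simulated tree with the sampled nodes
    flagged observed.  ``pruned_truth`` is its restriction to the root plus
    the observed nodes and their ancestors — the part of the latent process
    a reconstruction is accountable for; benchmark size comparisons use it.
    """

    root: str
    observed: list[str]
    ground_truth: LineageTree

    @property
    def pruned_truth(self) -> LineageTree:
        from .refine import trim

        return trim(self.ground_truth)


@dataclass
class BenchmarkRow:
    """Size comparison over all replicates of one setting."""

    setting: SimulationSetting
    larger: int
    same: int
    smaller: int
    feature_errors: dict | None = None

    @property
    def replicates(self) -> int:
        return self.larger + self.same + self.smaller

    @property
    def success(self) -> int:
        """Percentage of replicates reconstructed at or below truth size."""
        return round(100.0 * (self.same + self.smaller) / self.replicates)


def _random_operation(
    seq: str, op_probs: tuple[float, float, float], rng: np.random.Generator,
    alphabet: str = DNA_ALPHABET,
) -> EditOperation | None:
    """Draw one operation; ``None`` when the drawn kind is inapplicable."""
    u = rng.random()
    p_sub, p_ins, _ = op_probs
    n = len(seq)
    k = len(alphabet)
    if u < p_sub:
        if n == 0:
            return None
        pos = int(rng.integers(1, n + 1))
        current = seq[pos - 1]
        choices = [c for c in alphabet if c != current]
        return EditOperation(SUBSTITUTION, pos, choices[int(rng.integers(k - 1))])
    if u < p_sub + p_ins:
        pos = int(rng.integers(1, n + 2))
        return EditOperation(INSERTION, pos, alphabet[int(rng.integers(k))])
    if n == 0:
        return None
    return EditOperation(DELETION, int(rng.integers(1, n + 1)))


def simulate_tree(setting: SimulationSetting, rng: np.random.Generator) -> LineageTree:
    """Draw one ground-truth lineage tree under the given setting.

    Every node starts unobserved (the simulated process is latent);
    :func:`subsample_observed` picks the subset revealed to reconstruction,
    and :func:`simulate_instance` flags it on the tree.
    """
    alphabet = DNA_ALPHABET
    root = "".join(alphabet[c] for c in rng.integers(len(alphabet), size=setting.root_length))
    lo, hi = setting.tree_size_range
    target = int(rng.integers(lo, hi + 1))
    tree = LineageTree(root, alphabet=alphabet)
    ids = [tree.root_id]
    while tree.size < target:
        for _attempt in range(_REDRAW_CAP):
            parent = ids[int(rng.integers(len(ids)))]
            parent_seq = tree.node(parent).sequence
            op = _random_operation(parent_seq, setting.op_probs, rng, alphabet)
            if op is None:
                continue
            child = apply_operation(parent_seq, op, alphabet)
            if not tree.has_sequence(child):
                ids.append(tree.add_child(parent, child, op))
                break
        else:
            raise SimulationError(
                f"could not draw a novel sequence in {_REDRAW_CAP} attempts "
                f"(root_length={setting.root_length})"
            )
    return tree


def subsample_observed(
    tree: LineageTree, k: int, rng: np.random.Generator
) -> list[str]:
    """Draw ``k`` distinct non-root node sequences uniformly without replacement.

    The root is never sampled: in real use the germline root is known
    separately and supplied to reconstruction as such.
    """
    pool = sorted(set(tree.node_ids()) - {tree.root_id})
    if not 2 <= k <= len(pool):
        raise ValueError(f"k={k} out of range [2, {len(pool)}]")
    picks = rng.choice(len(pool), size=k, replace=False)
    return [tree.node(pool[int(i)]).sequence for i in picks]


def simulate_instance(
    setting: SimulationSetting, rng: np.random.Generator
) -> SimulatedInstance:
    """One ground-truth tree plus its revealed observation subset."""
    tree = simulate_tree(setting, rng)
    olo, ohi = setting.observed_range
    k = min(int(rng.integers(olo, ohi + 1)), tree.size - 1)
    observed = subsample_observed(tree, k, rng)
    for seq in observed:
        node = tree.node(tree.id_of_sequence(seq))
        node.observed = True
        node.multiplicity = 1
    return SimulatedInstance(tree.root.sequence, observed, tree)


def run_benchmark(
    setting: SimulationSetting, collect_features: bool = False
) -> BenchmarkRow:
    """Run the full replicate loop for one setting.

    Per replicate: simulate a ground truth, subsample observations,
    reconstruct (with trimming and rewiring), and compare the reconstructed
    size against the pruned ground truth.  All randomness derives from
    ``setting.seed``.  With ``collect_features`` the row additionally
    carries the per-feature normalized mean squared error between
    pruned-truth and reconstructed tree shapes.
    """
    from .features import compare_features, compute_features  # lazy: optional path

    streams = np.random.SeedSequence(setting.seed).spawn(2 * setting.replicates)
    larger = same = smaller = 0
    truth_fvs = []
    recon_fvs = []
    for rep in range(setting.replicates):
        sim_rng = np.random.default_rng(streams[2 * rep])
        instance = simulate_instance(setting, sim_rng)
        recon = reconstruct(
            instance.root,
            instance.observed,
            rng=np.random.default_rng(streams[2 * rep + 1]),
        )
        truth = instance.pruned_truth
        if recon.size > truth.size:
            larger += 1
        elif recon.size == truth.size:
            same += 1
        else:
            smaller += 1
        if collect_features:
            truth_fvs.append(compute_features(truth))
            recon_fvs.append(compute_features(recon))
    errors = compare_features(truth_fvs, recon_fvs) if collect_features else None
    return BenchmarkRow(setting, larger, same, smaller, errors)
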