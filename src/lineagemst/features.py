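"""Lineage-tree shape statistics and ground-truth comparison.

Twelve scalar features summarize the topology of a lineage tree; several of
them are known to correlate with the selection pressure a B-cell clone
experienced.  Distances are edge counts, which for these trees equal
mutational distances (one base operation per edge).  A *branching node* is
a node of out-degree greater than one; the *first* branching node is the
shallowest.  Features that need a branching node are undefined on chains
and reported as ``None`` (serialized ``NA``).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

__all__ = ["FeatureVector", "FEATURE_NAMES", "FeatureError", "compute_features", "compare_features"]


@dataclass(frozen=True)
class FeatureVector:
    """The 12 tree-shape statistics; ``None`` marks an undefined feature."""

    tree_size: float       # total number of nodes
    od_root: float         # out-degree of the root
    od_avg: float          # mean out-degree over all nodes = (N-1)/N
    od_ratio: float        # od_root / od_avg
    t_max_depth: float     # maximum depth over leaves
    pl_min: float          # minimum depth over leaves
    pl_avg: float          # mean depth over all nodes
    drsn_min: float | None   # minimum depth of a branching node
    dlfsn_min: float | None  # pl_min - drsn_min
    dlfsn_avg: float | None  # pl_avg - drsn_min
    dasn_min: float | None   # min distance branching node -> nearest branching ancestor
    dasn_avg: float | None   # mean of those distances

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


FEATURE_NAMES = [f.name for f in fields(FeatureVector)]


def compute_features(tree) -> FeatureVector:
    n = tree.size
    depths = tree.depths()
    leaves = [nid for nid in tree.node_ids() if tree.out_degree(nid) == 0]
    branching = [nid for nid in tree.node_ids() if tree.out_degree(nid) > 1]

    od_root = float(tree.out_degree(tree.root_id))
    od_avg = (n - 1) / n
    leaf_depths = [depths[nid] for nid in leaves] or [0]
    t_max_depth = float(max(leaf_depths))
    pl_min = float(min(leaf_depths))
    pl_avg = sum(depths.values()) / n

    drsn_min = dlfsn_min = dlfsn_avg = None
    if branching:
        drsn_min = float(min(depths[nid] for nid in branching))
        dlfsn_min = pl_min - drsn_min
        dlfsn_avg = pl_avg - drsn_min

    # distance of each branching node to its nearest branching proper
    # ancestor; the shallowest branching node(s) contribute nothing
    branch_set = set(branching)
    gaps = []
    for nid in branching:
        steps = 0
        cur = tree.parent_of(nid)
        while cur is not None:
            steps += 1
            if cur in branch_set:
                gaps.append(steps)
                break
            cur = tree.parent_of(cur)
    dasn_min = float(min(gaps)) if gaps else None
    dasn_avg = sum(gaps) / len(gaps) if gaps else None

    return FeatureVector(
        tree_size=float(n),
        od_root=od_root,
        od_avg=od_avg,
        od_ratio=od_root / od_avg,
        t_max_depth=t_max_depth,
        pl_min=pl_min,
        pl_avg=pl_avg,
        drsn_min=drsn_min,
        dlfsn_min=dlfsn_min,
        dlfsn_avg=dlfsn_avg,
        dasn_min=dasn_min,
        dasn_avg=dasn_avg,
    )


@dataclass(frozen=True)
class FeatureError:
    """Aggregated reconstruction error for one feature.

    ``normalized`` is False when the feature's range in the ground truth was
    degenerate (zero), in which case the raw difference is used unscaled.
    ``n_pairs`` counts the tree pairs on which the feature was defined.
    """

    error: float | None
    normalized: bool
    n_pairs: int


def compare_features(
    truth: list[FeatureVector],
    recon: list[FeatureVector],
    squared: bool = True,
) -> dict[str, FeatureError]:
    """Per-feature error between aligned ground-truth and reconstructed trees.

    For each feature the differences (recon - truth) are divided by the
    range of that feature over the ground-truth list, then aggregated as a
    mean of squares (default) or of absolute values (``squared=False``).
    Pairs where the feature is undefined on either side are excluded.
    """
    if len(truth) != len(recon):
        raise ValueError("truth and reconstruction lists must be index-aligned")
    out: dict[str, FeatureError] = {}
    for name in FEATURE_NAMES:
        pairs = [
            (getattr(t, name), getattr(r, name))
            for t, r in zip(truth, recon)
            if getattr(t, name) is not None and getattr(r, name) is not None
        ]
        if not pairs:
            out[name] = FeatureError(None, True, 0)
            continue
        truth_vals = [
            v for fv in truth if (v := getattr(fv, name)) is not None
        ]
        rng = max(truth_vals) - min(truth_vals)
        normalized = rng > 0
        scale = rng if normalized else 1.0
        diffs = [(r - t) / scale for t, r in pairs]
        if squared:
            err = sum(d * d for d in diffs) / len(diffs)
        else:
            err = sum(abs(d) for d in diffs) / len(diffs)
        out[name] = FeatureError(err, normalized, len(pairs))
    return out
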