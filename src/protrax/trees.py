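"""Species-tree utilities: Newick I/O, branching times, cherries, cophenetic
distances, and Welch's t-test.

Trees are rooted, binary, ultrametric :class:`dendropy.Tree` objects with
branch lengths in Myr, as produced by
:func:`protrax.simulate.sample_species_tree`.

A note on "divergence time": the cophenetic distance between two tips is
the full branch-length path between them, which on an ultrametric tree is
*twice* the age of their most recent common ancestor.  Sister-species
divergence is reported here as that full path distance — the convention
of R's ``cophenetic`` — not as the node age, so the reported values are
double what a naive "age of the cherry node" reading would give.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np
from scipy import stats

__all__ = [
    "read_newick",
    "write_newick",
    "branching_times",
    "sister_pairs",
    "cophenetic_distance",
    "sister_distances",
    "welch_t",
]

#: absolute tolerance (Myr) for ultrametricity checks; simulator output is
#: exact by construction, the tolerance guards file round trips
ULTRAMETRIC_TOL = 1e-9


def read_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick string with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError("Newick tree is missing branch lengths")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise to Newick with full float precision (round-trip exact)."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    )


def _leaf_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[parent] + node.edge.length
    return depths


def _check_ultrametric(depths, leaves, tol: float) -> float:
    tip_depths = [depths[leaf] for leaf in leaves]
    height = max(tip_depths)
    if height - min(tip_depths) > tol:
        raise ValueError(
            f"tree is not ultrametric within {tol} Myr "
            f"(tip depth spread {height - min(tip_depths):.3g})"
        )
    return height


def branching_times(tree: dendropy.Tree, tol: float = ULTRAMETRIC_TOL) -> np.ndarray:
    """Internal-node ages before present, sorted descending.

    The first entry is the crown age; the length is ``n_tips - 1`` for a
    binary rooted tree.  Requires at least two tips and ultrametricity
    within ``tol``.
    """
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("branching times require at least two tips")
    depths = _leaf_depths(tree)
    height = _check_ultrametric(depths, leaves, tol)
    ages = [
        height - depths[node]
        for node in tree.preorder_node_iter()
        if not node.is_leaf()
    ]
    return np.asarray(sorted(ages, reverse=True))


def sister_pairs(tree: dendropy.Tree) -> list[tuple[str, str]]:
    """All cherries: pairs of tips forming a two-tip monophyletic group.

    Each tip appears in at most one pair.  Labels are returned in the
    tree's child order.
    """
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("sister pairs require at least two tips")
    pairs = []
    for node in tree.preorder_internal_node_iter():
        kids = node.child_nodes()
        if len(kids) == 2 and all(k.is_leaf() for k in kids):
            pairs.append((kids[0].taxon.label, kids[1].taxon.label))
    return pairs


def _leaf_by_label(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == label:
            return leaf
    raise KeyError(f"tip {label!r} not found in tree")


def cophenetic_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Sum of branch lengths on the path between tips ``a`` and ``b``.

    On an ultrametric tree this equals twice the age of the pair's most
    recent common ancestor.
    """
    na, nb = _leaf_by_label(tree, a), _leaf_by_label(tree, b)
    # path sums via ancestor walk
    dist_a: dict[int, float] = {}
    node, d = na, 0.0
    while node is not None:
        dist_a[id(node)] = d
        if node.parent_node is not None:
            d += node.edge.length
        node = node.parent_node
    node, d = nb, 0.0
    while node is not None:
        if id(node) in dist_a:
            return d + dist_a[id(node)]
        if node.parent_node is not None:
            d += node.edge.length
        node = node.parent_node
    raise ValueError("tips do not share a common ancestor")  # pragma: no cover


def sister_distances(tree: dendropy.Tree) -> np.ndarray:
    """Cophenetic distances of all cherries (sister-species pairs).

    For a cherry the tip-to-tip path is just the two pendant branches.
    """
    out = []
    for node in tree.preorder_internal_node_iter():
        kids = node.child_nodes()
        if len(kids) == 2 and all(k.is_leaf() for k in kids):
            out.append(kids[0].edge.length + kids[1].edge.length)
    return np.asarray(out)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of
    freedom and a two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two observations")
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        raise ValueError("Welch's t is undefined when both variances are zero")
    res = stats.ttest_ind(x, y, equal_var=False)
    df = res.df
    if not math.isfinite(df):  # older scipy fallback, defensive
        vx, vy = np.var(x, ddof=1) / len(x), np.var(y, ddof=1) / len(y)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return float(res.statistic), float(df), float(res.pvalue)
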