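"""Reading and decomposing ultrametric gene trees.

The adequacy test consumes a rooted, strictly bifurcating ultrametric tree
(typically a TreeAnnotator MCC tree) and needs only two derived quantities:

* the ages of the internal nodes ("divergence times"), measured from the tips
  (present = 0) and ordered oldest first, and
* the inter-coalescent interval lengths tau_k, i.e. the time spans during
  which exactly k ancestral lineages existed, for k = n_tips .. 2.

Branch lengths may be in any time-proportional unit (substitutions/site,
years, ...); every downstream quantity inherits that unit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import NewickParseError, NotUltrametricError, TreeStructureError

__all__ = [
    "UltrametricTree",
    "DivergenceTimes",
    "CoalescentIntervals",
    "parse_newick",
    "read_tree",
    "check_ultrametric",
    "divergence_times",
    "coalescent_intervals",
]

#: Default relative tolerance for ultrametricity checks, as a fraction of
#: tree height.  MCC trees written by TreeAnnotator carry floating-point
#: jitter of roughly this order.
DEFAULT_REL_TOL = 1e-6


@dataclass(frozen=True)
class UltrametricTree:
    """A rooted binary tree with time-proportional branch lengths.

    Wraps a :class:`dendropy.Tree` and caches tip labels and node depths.
    Construct via :func:`parse_newick` or :func:`read_tree`.
    """

    tree: dendropy.Tree
    tip_labels: tuple[str, ...]
    #: root-to-node distance for every internal node, in input order
    _internal_depths: np.ndarray = field(repr=False)
    #: root-to-tip distance per tip, in tip_labels order
    _tip_depths: np.ndarray = field(repr=False)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def height(self) -> float:
        """Tree height: the maximum root-to-tip path length."""
        return float(self._tip_depths.max())

    def serialize(self) -> str:
        """Newick string round-tripping topology and branch lengths."""
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, real_value_format_specifier=".10g"
        ).strip()


@dataclass(frozen=True)
class DivergenceTimes:
    """Internal-node ages (tip-to-node distances), ordered oldest first."""

    ages: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        if ages.ndim != 1 or ages.size == 0:
            raise ValueError("ages must be a non-empty 1-d array")
        if np.any(np.diff(ages) > 0):
            raise ValueError("ages must be ordered oldest first (non-increasing)")
        if np.any(ages < 0):
            raise ValueError("node ages must be nonnegative")
        object.__setattr__(self, "ages", ages)

    @property
    def n_events(self) -> int:
        return self.ages.size

    @property
    def height(self) -> float:
        return float(self.ages[0])


@dataclass(frozen=True)
class CoalescentIntervals:
    """Per-lineage-count interval lengths tau_k for k = n_tips .. 2.

    ``k[j]`` lineages existed for a span of ``tau[j]`` time units, during
    which ``pairs[j] = k(k-1)/2`` lineage pairs could coalesce.
    """

    k: np.ndarray
    tau: np.ndarray
    pairs: np.ndarray

    @property
    def n_tips(self) -> int:
        return int(self.k[0])

    @property
    def total_depth(self) -> float:
        return float(self.tau.sum())


def parse_newick(text: str) -> UltrametricTree:
    """Parse a single newick tree with branch lengths on all edges.

    Raises :class:`NewickParseError` for syntax errors or missing branch
    lengths and :class:`TreeStructureError` for polytomies or n_tips < 2.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed newick: {exc}") from exc
    return _build(tree)


def read_tree(path) -> UltrametricTree:
    """Read the single newick tree stored in ``path``."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def _build(tree: dendropy.Tree) -> UltrametricTree:
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise TreeStructureError(f"need at least 2 tips, found {len(leaves)}")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            label = node.taxon.label if node.taxon else "<internal>"
            raise NewickParseError(f"missing branch length on edge leading to {label!r}")
        nch = len(node.child_nodes())
        if nch not in (0, 2):
            raise TreeStructureError(
                f"polytomy ({nch} children) at an internal node; only strictly "
                "bifurcating trees are accepted — resolve polytomies (e.g. randomly, "
                "with zero-length branches) before running the test"
            )
    root = tree.seed_node
    root.depth = 0.0
    internal_depths, tip_depths, tip_labels = [], [], []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.depth = node.parent_node.depth + float(node.edge.length)
        if node.is_leaf():
            tip_labels.append(node.taxon.label if node.taxon else "")
            tip_depths.append(node.depth)
        else:
            internal_depths.append(node.depth)
    return UltrametricTree(
        tree=tree,
        tip_labels=tuple(tip_labels),
        _internal_depths=np.asarray(internal_depths, dtype=float),
        _tip_depths=np.asarray(tip_depths, dtype=float),
    )


def check_ultrametric(
    tree: UltrametricTree, rel_tol: float = DEFAULT_REL_TOL, coerce: bool = False
) -> UltrametricTree:
    """Validate that all root-to-tip path lengths agree.

    The maximum deviation of any tip depth from the tree height must not
    exceed ``rel_tol * height``.  With ``coerce=True`` the check is waived
    and deviating tips are treated as contemporaneous: node ages are measured
    against the tree height regardless, so coercion needs no edge rewriting.

    Returns the validated tree; raises :class:`NotUltrametricError` naming
    the worst-offending tip otherwise.
    """
    height = tree.height
    if height == 0 or coerce:
        return tree
    dev = height - tree._tip_depths
    worst = int(np.argmax(dev))
    if dev[worst] > rel_tol * height:
        raise NotUltrametricError(
            f"tree is not ultrametric: tip {tree.tip_labels[worst]!r} is "
            f"{dev[worst]:.6g} below the height {height:.6g} "
            f"(tolerance {rel_tol * height:.6g})"
        )
    return tree


def divergence_times(tree: UltrametricTree) -> DivergenceTimes:
    """Ages of all internal nodes, oldest first.

    Age = tree height minus root-to-node distance, clipped at zero to absorb
    ultrametricity jitter.
    """
    ages = tree.height - tree._internal_depths
    ages = np.clip(ages, 0.0, None)
    return DivergenceTimes(np.sort(ages)[::-1])


def coalescent_intervals(times: DivergenceTimes, n_tips: int) -> CoalescentIntervals:
    """Decompose node ages into inter-coalescent interval lengths.

    Walking from the present (age 0, k = n_tips lineages) into the past,
    each divergence event reduces the lineage count by one; tau_k is the
    span spent at lineage count k.  Tied node ages yield zero-length
    intervals.
    """
    if times.n_events != n_tips - 1:
        raise ValueError(
            f"expected {n_tips - 1} divergence events for {n_tips} tips, "
            f"got {times.n_events}"
        )
    ages_asc = times.ages[::-1]  # youngest first
    bounds = np.concatenate([[0.0], ages_asc])
    tau = np.diff(bounds)  # tau for k = n_tips, n_tips-1, ..., 2
    k = np.arange(n_tips, 1, -1)
    return CoalescentIntervals(k=k, tau=tau, pairs=k * (k - 1) // 2)
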