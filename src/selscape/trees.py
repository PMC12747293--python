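"""Rooted phylogenies and operations on them.

Provides the :class:`Phylogeny` container used throughout the package, plus
lineage-splitting utilities: phylogenetic depth, detection of the best branch
partitioning a tree into two large, deep subtrees, subtree extraction, and
heterogeneity checks between subtree-specific selective constraints.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional, Sequence

import dendropy
import numpy as np

from selscape.errors import (
    EstimationDegenerateError,
    InvalidArgumentError,
)

__all__ = [
    "Phylogeny",
    "SplitCandidate",
    "phylogenetic_depth",
    "find_split_branch",
    "extract_subtrees",
    "flag_unreliable_subtree",
    "compare_subtree_constraints",
    "bootstrap_subtree_dnds",
    "BootstrapProportion",
]


class Node:
    """A node of a rooted tree. ``length`` is the edge above the node."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        clone = Node(self.label, self.length)
        for child in self.children:
            clone.add_child(child.copy())
        return clone


class Phylogeny:
    """A rooted tree with nonnegative branch lengths and unique tip labels.

    The root carries no parent edge; its ``length`` is always 0. Internal
    nodes without labels are assigned deterministic preorder labels
    (``N0``, ``N1``, ...) so that ancestral-state tables can reference them.
    """

    def __init__(self, root: Node):
        self.root = root
        self.root.length = 0.0
        self._assign_internal_labels()
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise InvalidArgumentError(f"invalid newick: {exc}") from exc
        return cls(_from_dendropy(dtree.seed_node))

    @classmethod
    def read(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.root.copy())

    # -- validation --------------------------------------------------------

    def _assign_internal_labels(self) -> None:
        used = {n.label for n in self.preorder() if n.label is not None}
        counter = 0
        for node in self.preorder():
            if node.is_leaf:
                if node.label is None:
                    raise InvalidArgumentError("tree has an unlabeled tip")
                continue
            if node.label is None:
                while f"N{counter}" in used:
                    counter += 1
                node.label = f"N{counter}"
                used.add(node.label)

    def _validate(self) -> None:
        tips = self.tip_labels
        if len(tips) < 2:
            raise InvalidArgumentError("tree must have at least 2 tips")
        if len(set(tips)) != len(tips):
            raise InvalidArgumentError("tip labels must be unique")
        for node in self.preorder():
            if node.length < 0:
                raise InvalidArgumentError(
                    f"negative branch length at {node.label!r}"
                )

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    def node_labels(self) -> list[str]:
        return [n.label for n in self.preorder()]

    def find(self, label: str) -> Optional[Node]:
        for node in self.preorder():
            if node.label == label:
                return node
        return None

    # -- measures ----------------------------------------------------------

    def total_length(self) -> float:
        return sum(n.length for n in self.preorder() if n.parent is not None)

    def node_depths(self) -> dict[str, float]:
        """Distance from root to every node, keyed by label."""
        depths: dict[str, float] = {}
        stack: list[tuple[Node, float]] = [(self.root, 0.0)]
        while stack:
            node, d = stack.pop()
            depths[node.label] = d
            for child in node.children:
                stack.append((child, d + child.length))
        return depths

    def depth(self) -> float:
        depths = self.node_depths()
        return max(depths[t] for t in self.tip_labels)

    # -- serialization -----------------------------------------------------

    def to_newick(self, include_internal_labels: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                core = node.label
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = node.label if include_internal_labels else ""
                core = f"({inner}){label}"
            if node.parent is None:
                return core
            return f"{core}:{node.length:.10g}"

        return fmt(self.root) + ";"

    def write(self, path, **kwargs) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kwargs) + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips>"


def _from_dendropy(dnode) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    length = dnode.edge.length if dnode.edge.length is not None else 0.0
    node = Node(label, length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


# ---------------------------------------------------------------------------
# Splitting


@dataclass(frozen=True)
class SplitCandidate:
    """A branch whose removal partitions the tips into two qualifying sets."""

    branch_id: str
    tips_a: frozenset[str] = field(repr=False)
    tips_b: frozenset[str] = field(repr=False)
    depth_a: float = 0.0
    depth_b: float = 0.0
    score: int = 0


def phylogenetic_depth(tree: Phylogeny) -> float:
    """Maximum root-to-tip path length of the tree."""
    return tree.depth()


def find_split_branch(
    tree: Phylogeny, min_tips: int = 20, min_depth: float = 0.2
) -> Optional[SplitCandidate]:
    """Find the branch splitting ``tree`` into two subtrees that each hold at
    least ``min_tips`` tips and exceed ``min_depth`` in phylogenetic depth.

    Among qualifying branches the one maximizing the smaller tip count is
    chosen (so both parts are as large as possible); remaining ties are broken
    by deterministic preorder branch ordering. Returns ``None`` when no branch
    qualifies.
    """
    depths = tree.node_depths()
    all_tips = set(tree.tip_labels)
    tip_depth = {t: depths[t] for t in all_tips}

    # per-node tip sets below, via postorder accumulation
    below: dict[str, set[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[node.label] = {node.label}
        else:
            acc: set[str] = set()
            for child in node.children:
                acc |= below[child.label]
            below[node.label] = acc

    best: Optional[SplitCandidate] = None
    best_key: Optional[tuple] = None
    order = 0
    for node in tree.preorder():
        if node.parent is None:
            continue
        order += 1
        tips_a = below[node.label]
        tips_b = all_tips - tips_a
        if len(tips_a) < min_tips or len(tips_b) < min_tips:
            continue
        # depth of the clade measured from the split node itself
        base = depths[node.label]
        depth_a = max(tip_depth[t] for t in tips_a) - base
        depth_b = max(tip_depth[t] for t in tips_b)
        if depth_a <= min_depth or depth_b <= min_depth:
            continue
        key = (min(len(tips_a), len(tips_b)), len(tips_a) + len(tips_b), -order)
        if best_key is None or key > best_key:
            best_key = key
            best = SplitCandidate(
                branch_id=node.label,
                tips_a=frozenset(tips_a),
                tips_b=frozenset(tips_b),
                depth_a=depth_a,
                depth_b=depth_b,
                score=key[0],
            )
    return best


def extract_subtrees(
    tree: Phylogeny, split: SplitCandidate
) -> tuple[Phylogeny, Phylogeny]:
    """Detach the split branch and return the two resulting rooted subtrees.

    The first subtree is the clade below the split branch (the branch itself
    is dropped); the second is the remainder, with unifurcations merged so
    that branch-length totals are conserved up to the removed edge.
    """
    work = tree.copy()
    node = work.find(split.branch_id)
    if node is None or node.parent is None:
        raise InvalidArgumentError(
            f"split branch {split.branch_id!r} not present in tree"
        )
    below = {n.label for n in _subtree_tips(node)}
    if below != set(split.tips_a):
        raise InvalidArgumentError("stale split: tip set under branch changed")

    parent = node.parent
    parent.children.remove(node)
    node.parent = None
    subtree_a = Phylogeny(node)

    _suppress_unifurcations(work.root)
    subtree_b = Phylogeny(work.root)
    return subtree_a, subtree_b


def _subtree_tips(node: Node) -> list[Node]:
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


def _suppress_unifurcations(root: Node) -> None:
    """Merge internal nodes with a single child, summing edge lengths.

    A unifurcating root is kept (still a valid rooted tree) so that
    root-to-tip distances in the remainder are unchanged.
    """
    stack = [root]
    while stack:
        node = stack.pop()
        for child in list(node.children):
            while len(child.children) == 1:
                grandchild = child.children[0]
                grandchild.length += child.length
                grandchild.parent = node
                node.children[node.children.index(child)] = grandchild
                child = grandchild
            stack.append(child)


# ---------------------------------------------------------------------------
# Heterogeneity checks


def flag_unreliable_subtree(
    dnds_values: Sequence[float],
    boundary_value: float = 1.0,
    max_fraction: float = 0.3,
) -> bool:
    """True iff more than ``max_fraction`` of values sit at the boundary."""
    values = np.asarray(dnds_values, dtype=float)
    if values.size == 0:
        raise InvalidArgumentError("empty dN/dS collection")
    at_boundary = np.abs(values - boundary_value) <= 1e-6
    return bool(at_boundary.mean() > max_fraction)


def compare_subtree_constraints(
    f_a: float, f_b: float, threshold: float = 0.4
) -> tuple[float, bool]:
    """Relative difference between two log-scale constraints.

    Returns ``max(exp(f_a-f_b), exp(f_b-f_a)) - 1`` and whether it strictly
    exceeds ``threshold``.
    """
    measure = math.exp(abs(f_a - f_b)) - 1.0
    return measure, measure > threshold


# ---------------------------------------------------------------------------
# Subtree bootstrap


class BootstrapProportion(NamedTuple):
    proportion: float
    n_used: int
    n_failed: int


def bootstrap_subtree_dnds(
    alignment,
    subtree: Phylogeny,
    full_tree_estimate: float,
    n_replicates: int = 100,
    seed: int = 0,
    gene_id: str = "",
) -> BootstrapProportion:
    """Column-bootstrap the alignment and re-estimate dN/dS on a subtree.

    Resamples codon columns with replacement ``n_replicates`` times, restricts
    each resample to the subtree's taxa, re-estimates dN/dS by ML, and returns
    the fraction of replicate estimates strictly exceeding
    ``full_tree_estimate``. Replicates where estimation degenerates (e.g. an
    invariant resample) are dropped and counted.

    Replicate RNG streams are derived from ``(seed, gene_id, replicate)`` so
    the result does not depend on evaluation order.
    """
    from selscape.codon import estimate_dnds_ml, subset_alignment

    taxa = set(subtree.tip_labels)
    if not taxa.issubset(set(alignment.taxa)):
        raise InvalidArgumentError("subtree tips missing from alignment")
    sub_aln = subset_alignment(alignment, sorted(taxa))
    # canonicalize column order so results do not depend on how the
    # alignment's columns happen to be arranged
    columns = [
        "".join(seq[3 * c : 3 * c + 3] for seq in sub_aln.sequences)
        for c in range(sub_aln.length_codons)
    ]
    sub_aln = sub_aln.take_codon_columns(
        sorted(range(len(columns)), key=columns.__getitem__)
    )

    gene_key = zlib.crc32(gene_id.encode())
    n_codons = sub_aln.length_codons
    exceed = 0
    used = 0
    failed = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=[int(seed), gene_key, rep])
        )
        cols = rng.integers(0, n_codons, size=n_codons)
        resampled = sub_aln.take_codon_columns(cols)
        try:
            params, _ = estimate_dnds_ml(resampled, subtree)
        except EstimationDegenerateError:
            failed += 1
            continue
        used += 1
        if params.omega > full_tree_estimate:
            exceed += 1
    if used == 0:
        raise EstimationDegenerateError(
            f"all {n_replicates} bootstrap replicates failed estimation"
        )
    return BootstrapProportion(exceed / used, used, failed)
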