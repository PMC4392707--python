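"""Split systems and the split-diversity (SD) measure.

A split system (Sigma, lambda) is a collection of bipartitions (splits) of a
taxon set X, each carrying a non-negative weight in branch-length units.  The
split diversity of a taxon subset S is the total weight of the splits that
separate at least two taxa of S.  For the split system induced by a single
phylogenetic tree, SD coincides with Faith's phylogenetic diversity (PD): the
length of the minimal subtree spanning S.  Pooling splits across a collection
of trees (bootstrap replicates, gene trees) extends PD to distributions of
trees, which is the setting in which SD is most useful.
"""
from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonSet",
    "Split",
    "SplitSystem",
    "DegenerateSplitError",
    "canonicalize",
    "splits_from_tree",
    "aggregate_trees",
    "separates",
    "sd_score",
    "pd_score",
]


class DegenerateSplitError(ValueError):
    """Raised when a membership vector places all taxa on one side."""


class TaxonSet:
    """An ordered, immutable collection of unique taxon labels.

    The order is frozen at construction; splits and presence matrices derived
    from a TaxonSet index taxa by their position in it.
    """

    __slots__ = ("labels", "_index")

    def __init__(self, labels: Iterable[str]):
        labels = tuple(str(x) for x in labels)
        if not labels:
            raise ValueError("TaxonSet requires at least one taxon")
        if any(not x for x in labels):
            raise ValueError("taxon labels must be non-empty")
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        self.labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self._index[label]

    def indices(self, labels: Iterable[str]) -> frozenset[int]:
        """Map taxon labels to their positional indices."""
        return frozenset(self._index[x] for x in labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label) -> bool:
        return label in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonSet) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"TaxonSet({list(self.labels)!r})"


@dataclass(frozen=True)
class Split:
    """A canonical bipartition of a TaxonSet.

    ``membership[i]`` is 0 or 1 depending on which side taxon i lies;
    the canonical orientation assigns 0 to the first taxon.  ``mask1`` is the
    bitmask of taxa with membership 1 (bit i set iff membership[i] == 1) and
    ``mask0`` its complement within the taxon set; both are precomputed for
    fast separation tests.
    """

    membership: tuple[int, ...]
    mask1: int = field(compare=False)
    mask0: int = field(compare=False)

    @property
    def n(self) -> int:
        return len(self.membership)

    def side(self, value: int) -> frozenset[int]:
        """Taxon indices carrying ``value`` (0 or 1)."""
        return frozenset(i for i, m in enumerate(self.membership) if m == value)

    def is_trivial(self) -> bool:
        """True for singleton-vs-rest splits."""
        ones = bin(self.mask1).count("1")
        return ones == 1 or ones == self.n - 1

    def __repr__(self) -> str:
        return "Split(" + "".join(map(str, self.membership)) + ")"


def canonicalize(membership: Sequence[int]) -> Split:
    """Return the canonical orientation of a membership vector.

    The vector and its complement denote the same bipartition; the canonical
    form is the one in which the first taxon carries 0.  All-zero or all-one
    vectors do not bipartition the taxon set and raise DegenerateSplitError.
    """
    memb = tuple(int(bool(v)) for v in membership)
    if not memb:
        raise ValueError("empty membership vector")
    s = sum(memb)
    if s == 0 or s == len(memb):
        raise DegenerateSplitError(
            f"degenerate split: all taxa on one side ({memb})"
        )
    if memb[0] == 1:
        memb = tuple(1 - v for v in memb)
    mask1 = 0
    for i, v in enumerate(memb):
        if v:
            mask1 |= 1 << i
    full = (1 << len(memb)) - 1
    return Split(memb, mask1, full & ~mask1)


class SplitSystem:
    """A weighted split system (Sigma, lambda) over a fixed TaxonSet.

    Splits are stored in canonical form with no duplicates; adding an already
    present split accumulates its weight.
    """

    def __init__(self, taxa: TaxonSet):
        self.taxa = taxa
        self.splits: list[Split] = []
        self._weights: list[float] = []
        self._lookup: dict[tuple[int, ...], int] = {}

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(self._weights, dtype=float)

    def add(self, membership: Sequence[int], weight: float) -> None:
        if len(membership) != self.taxa.n:
            raise ValueError(
                f"membership length {len(membership)} != n taxa {self.taxa.n}"
            )
        w = float(weight)
        if w < 0:
            raise ValueError(f"negative split weight {w}")
        sp = canonicalize(membership)
        idx = self._lookup.get(sp.membership)
        if idx is None:
            self._lookup[sp.membership] = len(self.splits)
            self.splits.append(sp)
            self._weights.append(w)
        else:
            self._weights[idx] += w

    def add_split(self, split: Split, weight: float) -> None:
        self.add(split.membership, weight)

    def weight_of(self, split: Split) -> float:
        idx = self._lookup.get(split.membership)
        return 0.0 if idx is None else self._weights[idx]

    def total_weight(self) -> float:
        return float(sum(self._weights))

    def trivial_split_for(self, taxon_index: int) -> Split:
        memb = [0] * self.taxa.n
        memb[taxon_index] = 1
        return canonicalize(memb)

    def nontrivial(self) -> "SplitSystem":
        """A copy retaining only the non-trivial splits."""
        out = SplitSystem(self.taxa)
        for sp, w in zip(self.splits, self._weights):
            if not sp.is_trivial():
                out.add_split(sp, w)
        return out

    def __len__(self) -> int:
        return len(self.splits)

    def __iter__(self):
        return iter(zip(self.splits, self._weights))

    def __repr__(self) -> str:
        return (
            f"SplitSystem(n_taxa={self.taxa.n}, n_splits={len(self.splits)}, "
            f"total_weight={self.total_weight():.6g})"
        )


# ---------------------------------------------------------------------------
# Trees


def _parse_newick(source: str) -> list[dendropy.Tree]:
    tns = dendropy.TaxonNamespace()
    trees = dendropy.TreeList.get(
        data=source, schema="newick", taxon_namespace=tns,
        preserve_underscores=True,
    )
    return list(trees)


class Tree:
    """A phylogenetic tree over a TaxonSet, with non-negative branch lengths.

    Thin wrapper around a dendropy tree; rooted inputs are treated as
    unrooted for all diversity computations.
    """

    def __init__(self, dtree: dendropy.Tree, taxa: TaxonSet | None = None):
        labels = [lf.taxon.label if lf.taxon else None
                  for lf in dtree.leaf_node_iter()]
        if any(lab is None for lab in labels):
            raise ValueError("tree has unlabeled leaves")
        if len(set(labels)) != len(labels):
            raise ValueError("tree has duplicate leaf labels")
        if taxa is None:
            taxa = TaxonSet(sorted(labels))
        else:
            missing = set(labels) - set(taxa.labels)
            if missing:
                raise ValueError(f"leaf labels not in TaxonSet: {sorted(missing)}")
        for edge in dtree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")
        self._dtree = dtree
        self.taxa = taxa
        self.leaf_labels = tuple(labels)

    @classmethod
    def from_newick(cls, newick: str, taxa: TaxonSet | None = None) -> "Tree":
        try:
            trees = _parse_newick(newick)
        except dendropy.utility.error.DataParseError as exc:
            raise ValueError(f"malformed Newick (duplicate or bad labels?): {exc}") from exc
        if len(trees) != 1:
            raise ValueError(f"expected exactly one tree, got {len(trees)}")
        return cls(trees[0], taxa)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._dtree

    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def total_branch_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self._dtree.preorder_edge_iter()
            if e.head_node.parent_node is not None
        )

    def as_newick(self) -> str:
        return self._dtree.as_string(schema="newick").strip()


def splits_from_tree(tree: Tree) -> SplitSystem:
    """Extract the split system induced by the edges of a tree.

    Every edge of the unrooted tree defines the bipartition of taxa on its two
    sides, weighted by its branch length.  Parallel edges that induce the same
    bipartition -- notably the two root-incident edges of a rooted binary
    tree -- merge by weight summation.  Trivial (leaf) splits are retained.
    Missing branch lengths count as 0 with a warning.
    """
    if tree.n_leaves() < 2:
        raise ValueError("need at least 2 leaves to extract splits")
    taxa = tree.taxa
    system = SplitSystem(taxa)
    missing_lengths = 0
    dtree = tree.dendropy_tree
    # leaf-set-below per node, bottom-up
    below: dict[int, int] = {}
    present_mask = 0
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            bit = 1 << taxa.index(node.taxon.label)
            below[id(node)] = bit
            present_mask |= bit
        else:
            m = 0
            for ch in node.child_nodes():
                m |= below[id(ch)]
            below[id(node)] = m
    for node in dtree.postorder_node_iter():
        if node.parent_node is None:
            continue
        mask = below[id(node)]
        length = node.edge.length
        if length is None:
            missing_lengths += 1
            length = 0.0
        # side masks relative to the taxa present in this tree
        if mask == 0 or mask == present_mask:
            continue  # uninformative edge (e.g. root edge of a one-child root)
        memb = [(mask >> i) & 1 for i in range(taxa.n)]
        # taxa absent from this tree stay on side 0; for a shared TaxonSet the
        # caller is expected to provide trees over the full set
        try:
            system.add(memb, length)
        except DegenerateSplitError:
            continue
    if missing_lengths:
        logger.warning(
            "%d edges without branch lengths treated as length 0", missing_lengths
        )
    return system


def aggregate_trees(
    trees: Sequence[Tree], mode: str = "mean"
) -> SplitSystem:
    """Pool the split systems of a tree collection into one (Sigma, lambda).

    Parameters
    ----------
    trees
        Trees over a single shared TaxonSet.
    mode
        ``mean``: lambda(sigma) = average branch length across trees, counting
        0 where the split is absent (the default; SD is motivated as an
        expectation over a tree distribution).  ``sum``: unnormalized total.
        ``frequency``: fraction of trees containing the split.
    """
    if not trees:
        raise ValueError("need at least one tree")
    if mode not in ("mean", "sum", "frequency"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            a, b = set(taxa.labels), set(t.taxa.labels)
            diff = sorted(a.symmetric_difference(b))
            raise ValueError(f"trees have mismatched taxon sets; differ by {diff}")
    pooled = SplitSystem(taxa)
    counts: dict[tuple[int, ...], int] = {}
    for t in trees:
        sub = splits_from_tree(t)
        for sp, w in sub:
            pooled.add_split(sp, w)
            counts[sp.membership] = counts.get(sp.membership, 0) + 1
    k = len(trees)
    if mode == "mean":
        pooled._weights = [w / k for w in pooled._weights]
    elif mode == "frequency":
        pooled._weights = [
            counts[sp.membership] / k for sp in pooled.splits
        ]
    return pooled


# ---------------------------------------------------------------------------
# Diversity scores


def _subset_mask(subset: Iterable[int], n: int) -> int:
    mask = 0
    for i in subset:
        i = int(i)
        if i < 0 or i >= n:
            raise ValueError(f"taxon index {i} out of range for n={n}")
        mask |= 1 << i
    return mask


def separates(split: Split, subset: Iterable[int]) -> bool:
    """True iff the subset has at least one taxon on each side of the split."""
    mask = _subset_mask(subset, split.n)
    return bool(mask & split.mask1) and bool(mask & split.mask0)


def sd_score(system: SplitSystem, subset: Iterable[int]) -> float:
    """Split diversity of a taxon subset: total weight of separating splits.

    SD of the empty set or a singleton is 0; SD of the full taxon set is the
    total split weight.
    """
    mask = _subset_mask(subset, system.taxa.n)
    total = 0.0
    for sp, w in zip(system.splits, system._weights):
        if (mask & sp.mask1) and (mask & sp.mask0):
            total += w
    return total


def sd_score_mask(system: SplitSystem, mask: int) -> float:
    """sd_score on a precomputed taxon bitmask (hot path for oracles)."""
    total = 0.0
    for sp, w in zip(system.splits, system._weights):
        if (mask & sp.mask1) and (mask & sp.mask0):
            total += w
    return total


def pd_score(tree: Tree, subset: Iterable[int]) -> float:
    """Phylogenetic diversity: length of the minimal subtree spanning a subset.

    Computed as the total length of the union of the leaf-to-leaf paths
    between subset members on the unrooted tree -- an implementation that is
    deliberately independent of the split machinery, so the PD = SD identity
    can be verified rather than assumed.  Subsets with fewer than two taxa
    have PD 0 (with a warning).
    """
    subset = list(subset)
    if len(subset) < 2:
        warnings.warn("PD of a subset with < 2 taxa is defined as 0")
        return 0.0
    taxa = tree.taxa
    want = {taxa.labels[i] for i in subset}
    g = nx.Graph()
    leaf_node: dict[str, int] = {}
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.is_leaf() and node.taxon.label in want:
            leaf_node[node.taxon.label] = id(node)
        if node.parent_node is not None:
            g.add_edge(
                id(node.parent_node), id(node), length=node.edge.length or 0.0
            )
    terminals = [leaf_node[lab] for lab in sorted(want)]
    used: set[frozenset] = set()
    src = terminals[0]
    paths = nx.single_source_shortest_path(g, src)
    for t in terminals[1:]:
        path = paths[t]
        for u, v in zip(path, path[1:]):
            used.add(frozenset((u, v)))
    # paths from one terminal to all others cover the Steiner tree of the
    # terminals because the graph is a tree
    return float(sum(g.edges[tuple(e)]["length"] for e in used))
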