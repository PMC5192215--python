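"""Rooted-tree container, Newick I/O and the covariance algebra used by all
comparative analyses.

A :class:`Phylogeny` stores a rooted tree as flat integer arrays (tips first,
internal nodes after, root last).  Branch lengths are interpreted as absolute
time, so an ultrametric tree is expected for Ornstein-Uhlenbeck model fitting;
non-ultrametric trees are accepted for generalized least squares with a
warning.  Newick parsing and writing are delegated to :mod:`dendropy`; branch
lengths are mandatory on every non-root edge (no silent defaults).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TreeEnsemble",
    "PhyloCovariance",
    "read_newick",
    "write_newick",
    "read_newick_ensemble",
    "phylo_covariance",
    "lambda_transform",
    "simulate_yule_tree",
    "reconcile_tips",
]


class NewickError(ValueError):
    """Raised on malformed Newick input or missing branch lengths."""


@dataclass
class Phylogeny:
    """Rooted, branch-length-bearing tree.

    Nodes are integers ``0 .. n_nodes-1``: tips are ``0 .. n_tips-1`` in the
    order of ``tip_labels``; the root is ``n_nodes - 1``.  ``parent[root]``
    is ``-1`` and ``branch_lengths[root]`` is ``0``.
    """

    tip_labels: list[str]
    parent: np.ndarray          # (n_nodes,) int
    branch_lengths: np.ndarray  # (n_nodes,) float, time units

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.branch_lengths = np.asarray(self.branch_lengths, dtype=float)
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("tip labels must be unique")
        if np.any(self.branch_lengths < 0):
            raise ValueError("negative branch length")
        if self.parent[self.root] != -1:
            raise ValueError("root (last node) must have parent -1")
        self._children: list[list[int]] | None = None
        self._postorder: np.ndarray | None = None

    # -- structure ---------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def children(self) -> list[list[int]]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for v, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(v)
            self._children = ch
        return self._children

    @property
    def postorder(self) -> np.ndarray:
        """Node ids with every child before its parent."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(self.children[v])
            self._postorder = np.asarray(order[::-1], dtype=np.int64)
        return self._postorder

    @property
    def preorder(self) -> np.ndarray:
        return self.postorder[::-1]

    def node_depths(self) -> np.ndarray:
        """Time from the root to every node."""
        depth = np.zeros(self.n_nodes)
        for v in self.preorder:
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.branch_lengths[v]
        return depth

    @property
    def depth(self) -> float:
        return float(self.node_depths()[: self.n_tips].max())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.node_depths()[: self.n_tips]
        return bool(np.ptp(d) <= rtol * d.max()) if d.max() > 0 else True

    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())

    def mrca_matrix(self) -> np.ndarray:
        """(n_tips, n_tips) node id of the most recent common ancestor.

        The diagonal holds the tip itself, which is the convention the OU
        covariance accumulation relies on (a tip's "shared path with itself"
        is its entire root-to-tip path).
        """
        n = self.n_tips
        mrca = np.zeros((n, n), dtype=np.int64)
        np.fill_diagonal(mrca, np.arange(n))
        below: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * self.n_nodes
        for v in self.postorder:
            kids = self.children[v]
            if not kids:
                below[v] = np.array([v], dtype=np.int64)
                continue
            sets = [below[c] for c in kids]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    mrca[np.ix_(sets[a], sets[b])] = v
                    mrca[np.ix_(sets[b], sets[a])] = v
            below[v] = np.concatenate(sets)
        return mrca

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        dnodes = list(dtree)  # preorder
        leaves = [nd for nd in dnodes if nd.is_leaf()]
        labels = [lf.taxon.label if lf.taxon else lf.label for lf in leaves]
        if any(lb is None for lb in labels):
            raise NewickError("unlabelled tip")
        internal = [nd for nd in dnodes if not nd.is_leaf() and nd is not dtree.seed_node]
        order = leaves + internal[::-1] + [dtree.seed_node]
        index = {id(nd): i for i, nd in enumerate(order)}
        parent = np.full(len(order), -1, dtype=np.int64)
        blen = np.zeros(len(order))
        for nd in dnodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise NewickError(
                        f"missing branch length on edge above {labels[i] if i < len(labels) else 'an internal node'!r}"
                    )
                blen[i] = nd.edge.length
        return cls([str(lb) for lb in labels], parent, blen)

    def to_dendropy(self) -> dendropy.Tree:
        """Convert to dendropy with children in canonical order (sorted by the
        smallest tip label in each subtree), so writing is deterministic."""
        taxa = dendropy.TaxonNamespace(self.tip_labels)
        dtree = dendropy.Tree(taxon_namespace=taxa)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        min_label = [""] * self.n_nodes
        for v in self.postorder:
            kids = self.children[v]
            min_label[v] = self.tip_labels[v] if not kids else min(min_label[c] for c in kids)
        for i, lab in enumerate(self.tip_labels):
            nodes[i].taxon = taxa.get_taxon(lab)
        for v in self.preorder:
            for c in sorted(self.children[v], key=lambda c: min_label[c]):
                nodes[v].add_child(nodes[c])
                nodes[c].edge.length = float(self.branch_lengths[c])
        dtree.seed_node = nodes[self.root]
        return dtree

    def signature(self) -> dict:
        """Structure fingerprint: {tip set below an edge: branch length}.
        Two trees are equal as rooted weighted trees iff the key sets match
        and the lengths agree (compare with a tolerance)."""
        below: list[frozenset] = [frozenset()] * self.n_nodes
        items: dict[frozenset, float] = {}
        for v in self.postorder:
            kids = self.children[v]
            below[v] = (
                frozenset([self.tip_labels[v]]) if not kids
                else frozenset().union(*[below[c] for c in kids])
            )
            if v != self.root:
                items[below[v]] = float(self.branch_lengths[v])
        return items

    def copy(self) -> "Phylogeny":
        return Phylogeny(list(self.tip_labels), self.parent.copy(), self.branch_lengths.copy())


def read_newick(text: str) -> Phylogeny:
    """Parse one Newick string into a :class:`Phylogeny`.

    Branch lengths are required on every non-root edge; a missing length or a
    syntax problem raises :class:`NewickError` carrying dendropy's position
    report.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            terminating_semicolon_required=True,
        )
    except Exception as exc:  # dendropy reports line/column in its message
        raise NewickError(f"Newick parse error: {exc}") from exc
    return Phylogeny.from_dendropy(dtree)


def write_newick(tree: Phylogeny, precision: int = 12) -> str:
    out = tree.to_dendropy().as_string(
        schema="newick", suppress_rooting=True,
        real_value_format_specifier=f".{precision}g",
    )
    return out.strip() + ("" if out.strip().endswith(";") else ";")


def read_newick_ensemble(text: str, source: str = "") -> "TreeEnsemble":
    """Read a multi-tree Newick document into a :class:`TreeEnsemble`."""
    trees: list[Phylogeny] = []
    for chunk in text.split(";"):
        if chunk.strip():
            trees.append(read_newick(chunk.strip() + ";"))
    return TreeEnsemble(trees, source=source)


@dataclass
class TreeEnsemble:
    """A set of trees over an identical tip set (e.g. posterior samples)."""

    trees: list[Phylogeny]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("empty ensemble")
        ref = set(self.trees[0].tip_labels)
        for i, t in enumerate(self.trees[1:], 1):
            if set(t.tip_labels) != ref:
                raise ValueError(f"tree {i} has a different tip set")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    @property
    def tip_labels(self) -> list[str]:
        return self.trees[0].tip_labels


@dataclass
class PhyloCovariance:
    """Shared-path-length matrix C with its tip order and tree depth T.

    ``C[i, j]`` is the depth of the MRCA of tips i and j; the diagonal holds
    root-to-tip depths.  This is the covariance scaffold of Brownian motion
    and, after the Pagel-lambda transform, of every PGLS fit.
    """

    matrix: np.ndarray
    tip_labels: list[str]
    depth: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.tip_labels),) * 2:
            raise ValueError("covariance shape does not match tip labels")


def phylo_covariance(tree: Phylogeny) -> PhyloCovariance:
    """C_ij = depth of MRCA(i, j); C_ii = root-to-tip depth of tip i."""
    depths = tree.node_depths()
    C = depths[tree.mrca_matrix()]
    return PhyloCovariance(C, list(tree.tip_labels), tree.depth)


def lambda_transform(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda: scale off-diagonal covariances by ``lam`` in [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    M = C.matrix * lam
    np.fill_diagonal(M, np.diag(C.matrix))
    return PhyloCovariance(M, list(C.tip_labels), C.depth)


def simulate_yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    label_prefix: str = "t",
) -> Phylogeny:
    """Simulate a pure-birth (Yule) tree with ``n_tips`` extant tips.

    The process starts at the root split (two lineages) and runs until the
    ``n_tips``-th lineage appears; the present is placed one further
    exponential waiting time later, so the tree is ultrametric with strictly
    positive terminal branches.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    # grow: each active lineage remembers its birth time and future node id
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    blen = np.zeros(n_nodes)
    root = n_nodes - 1
    next_internal = root  # allocate internal ids downwards root..n_tips
    next_tip = 0

    t = 0.0
    active: list[tuple[float, int]] = []  # (birth time, parent node id)
    active.append((0.0, root))
    active.append((0.0, root))
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        birth, par = active.pop(i)
        next_internal -= 1
        v = next_internal
        parent[v] = par
        blen[v] = t - birth
        active.append((t, v))
        active.append((t, v))
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    # shuffle so tip ids are not correlated with clade age
    rng.shuffle(active)
    labels = []
    for birth, par in active:
        v = next_tip
        next_tip += 1
        parent[v] = par
        blen[v] = t_end - birth
        labels.append(f"{label_prefix}{v + 1}")
    return Phylogeny(labels, parent, blen)


def reconcile_tips(
    tree: Phylogeny, names: list[str], zero_tol: float = 0.0
) -> dict:
    """Exact-string reconciliation between a tree and a trait table.

    Returns a report with the shared names (in tree tip order), names dropped
    on either side, and any near-zero branch lengths — these are surfaced,
    never silently modified.
    """
    tree_set = set(tree.tip_labels)
    name_set = set(names)
    shared = [lb for lb in tree.tip_labels if lb in name_set]
    near_zero = int(np.sum(tree.branch_lengths[:-1] <= zero_tol))
    return {
        "shared": shared,
        "dropped_from_tree": sorted(tree_set - name_set),
        "dropped_from_table": sorted(name_set - tree_set),
        "n_shared": len(shared),
        "n_near_zero_branches": near_zero,
    }


def prune_to_tips(tree: Phylogeny, keep: list[str]) -> Phylogeny:
    """Restrict the tree to ``keep`` (suppressing unifurcations by summing
    branch lengths)."""
    keep_set = set(keep)
    missing = keep_set - set(tree.tip_labels)
    if missing:
        raise ValueError(f"tips not in tree: {sorted(missing)[:5]}")
    dtree = tree.to_dendropy()
    taxa = [tx for tx in dtree.taxon_namespace if tx.label in keep_set]
    dtree.retain_taxa(taxa)
    dtree.suppress_unifurcations()
    return Phylogeny.from_dendropy(dtree)


def check_ultrametric_for_ou(tree: Phylogeny) -> None:
    if not tree.is_ultrametric():
        raise ValueError("OU model fitting requires an ultrametric (time-calibrated) tree")


def warn_if_not_ultrametric(tree: Phylogeny) -> None:
    if not tree.is_ultrametric():
        warnings.warn("tree is not ultrametric; PGLS proceeds but OU fitting would not", stacklevel=2)
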