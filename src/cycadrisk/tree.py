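"""Rooted phylogenies with branch lengths in Myr.

The :class:`Phylogeny` container is an immutable array-backed rooted tree
(parent pointers, branch lengths, labels).  It is the common currency of the
whole package: phylogenetic diversity, evolutionary distinctiveness, pruning
scenarios, phylogenetic signal and diversification fits all consume it.

Conventions
-----------
* Branch lengths are stored as read, in Myr, and never rescaled.  Node ages
  are computed from tip depths with all tips at age 0.
* A pruned tree retains the path to the original root, so "remaining PD" is
  well defined even when one side of the root is lost and the fair-proportion
  ED values always sum exactly to total PD.
* Polytomies are allowed in storage; operations that need binary trees
  resolve them deterministically (label order) with zero-length branches.
* Newick dialect: unquoted labels, underscores preserved, no comments.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "Phylogeny",
    "parse_newick",
    "write_newick",
    "prune_to",
    "drop_tips",
    "branching_times",
    "clade_tips",
    "mrca",
    "resolve_to_binary",
]


class TreeError(ValueError):
    """Malformed tree input or invalid tree operation."""


class _MutableNode:
    """Scratch node used while building or editing trees."""

    __slots__ = ("label", "length", "children", "parent", "age")

    def __init__(self, label=None, length=0.0, parent=None):
        self.label = label
        self.length = float(length)
        self.children = []
        self.parent = parent
        self.age = None

    def add(self, child):
        child.parent = self
        self.children.append(child)
        return child


class Phylogeny:
    """Immutable rooted tree over arrays.

    Parameters
    ----------
    parents : array of int
        Parent index per node; the single root has parent -1.
    lengths : array of float
        Branch length (Myr) of the edge above each node; 0 for the root
        unless the source Newick carried an explicit root edge.
    labels : sequence of str or None
        Tip labels (required, unique); internal labels optional.
    """

    def __init__(self, parents, lengths, labels):
        parents = np.asarray(parents, dtype=np.int64).copy()
        lengths = np.asarray(lengths, dtype=float).copy()
        labels = list(labels)
        n = parents.size
        if n == 0:
            raise TreeError("empty tree")
        if lengths.size != n or len(labels) != n:
            raise TreeError("parents, lengths and labels must have equal size")
        if not np.all(np.isfinite(lengths)):
            raise TreeError("non-finite branch length")
        if np.any(lengths < 0):
            i = int(np.argmin(lengths))
            who = labels[i] if labels[i] else f"node {i}"
            raise TreeError(f"negative branch length at {who!r}: {lengths[i]}")
        roots = np.flatnonzero(parents < 0)
        if roots.size != 1:
            raise TreeError(f"tree must have exactly one root, found {roots.size}")
        if np.any(parents >= n):
            raise TreeError("parent index out of range")
        self.root = int(roots[0])
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            p = int(parents[i])
            if p >= 0:
                children[p].append(i)
        # preorder traversal; also detects cycles/disconnected parts
        order = []
        stack = [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(children[i]))
        if len(order) != n:
            raise TreeError("disconnected nodes or cycle in parent pointers")

        self._parents = parents
        self._lengths = lengths
        self._labels = labels
        self._children = children
        self._preorder = np.asarray(order, dtype=np.int64)
        # reversed preorder: every node appears after all of its descendants
        self._postorder = self._preorder[::-1].copy()

        tip_idx = [i for i in order if not children[i]]
        tip_labels = [labels[i] for i in tip_idx]
        if any(lab is None or lab == "" for lab in tip_labels):
            raise TreeError("every tip must carry a label")
        if len(set(tip_labels)) != len(tip_labels):
            seen, dup = set(), set()
            for lab in tip_labels:
                (dup if lab in seen else seen).add(lab)
            raise TreeError("duplicate tip label(s): " + ", ".join(sorted(dup)))
        self._tip_indices = np.asarray(tip_idx, dtype=np.int64)
        self._tip_labels = tip_labels
        self._tip_index_of = dict(zip(tip_labels, tip_idx))

        depths = np.zeros(n)
        for i in order[1:]:
            depths[i] = depths[parents[i]] + lengths[i]
        self._depths = depths

        ndesc = np.zeros(n, dtype=np.int64)
        ndesc[self._tip_indices] = 1
        for i in self._postorder:
            p = parents[i]
            if p >= 0:
                ndesc[p] += ndesc[i]
        self._n_desc = ndesc

    # ------------------------------------------------------------------ #
    # basic accessors

    @property
    def n_nodes(self) -> int:
        return self._parents.size

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in left-to-right (preorder) tree order."""
        return list(self._tip_labels)

    @property
    def tip_indices(self) -> np.ndarray:
        return self._tip_indices.copy()

    @property
    def parents(self) -> np.ndarray:
        return self._parents.copy()

    @property
    def lengths(self) -> np.ndarray:
        return self._lengths.copy()

    @property
    def labels(self) -> list:
        return list(self._labels)

    @property
    def preorder(self) -> np.ndarray:
        return self._preorder.copy()

    @property
    def postorder(self) -> np.ndarray:
        """Node order guaranteeing children before parents."""
        return self._postorder.copy()

    @property
    def depths(self) -> np.ndarray:
        """Root-to-node path lengths (root edge excluded)."""
        return self._depths.copy()

    @property
    def height(self) -> float:
        """Maximum root-to-tip depth (the root age for ultrametric trees)."""
        return float(self._depths[self._tip_indices].max())

    @property
    def n_descendant_tips(self) -> np.ndarray:
        return self._n_desc.copy()

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths (root edge excluded)."""
        return float(self._lengths.sum() - self._lengths[self.root])

    def children(self, i: int) -> list[int]:
        return list(self._children[i])

    def is_tip(self, i: int) -> bool:
        return not self._children[i]

    def tip_index(self, label: str) -> int:
        try:
            return self._tip_index_of[label]
        except KeyError:
            raise TreeError(f"unknown tip label {label!r}") from None

    def ages(self) -> np.ndarray:
        """Node ages (Myr before present), taking all tips at age 0."""
        return self.height - self._depths

    def ultrametric_deviation(self) -> float:
        d = self._depths[self._tip_indices]
        return float(d.max() - d.min())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        h = self.height
        if h == 0.0:
            return True
        return self.ultrametric_deviation() <= rtol * h

    # ------------------------------------------------------------------ #
    # serialization

    def to_newick(self) -> str:
        """Serialize to a Newick string (round-trips exactly)."""
        parts: list = [None] * self.n_nodes
        for i in self._postorder:
            kids = self._children[i]
            lab = self._labels[i] or ""
            length = float(self._lengths[i])
            if not kids:
                parts[i] = f"{lab}:{length!r}"
            else:
                inner = ",".join(parts[c] for c in kids)
                if i == self.root:
                    suffix = f":{length!r}" if length != 0.0 else ""
                else:
                    suffix = f":{length!r}"
                parts[i] = f"({inner}){lab}{suffix}"
        return parts[self.root] + ";"

    def __repr__(self):  # pragma: no cover - debugging nicety
        return f"<Phylogeny {self.n_tips} tips, height {self.height:.4g} Myr>"


# ---------------------------------------------------------------------- #
# mutable <-> frozen conversion helpers (used by simulators and pruning)


def _freeze(root: _MutableNode) -> Phylogeny:
    parents, lengths, labels = [], [], []
    stack = [(root, -1)]
    while stack:
        node, pidx = stack.pop()
        idx = len(parents)
        parents.append(pidx)
        lengths.append(node.length)
        labels.append(node.label)
        for child in reversed(node.children):
            stack.append((child, idx))
    return Phylogeny(parents, lengths, labels)


def _thaw(tree: Phylogeny) -> _MutableNode:
    nodes = [
        _MutableNode(tree._labels[i], tree._lengths[i]) for i in range(tree.n_nodes)
    ]
    ages = tree.ages()
    for i in tree._preorder:
        nodes[i].age = float(ages[i])
        for c in tree._children[i]:
            nodes[i].add(nodes[c])
    return nodes[tree.root]


# ---------------------------------------------------------------------- #
# Newick I/O


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick statement into a :class:`Phylogeny`.

    Raises :class:`TreeError` for unbalanced parentheses, duplicate tip
    labels or negative branch lengths, naming the offending token.
    """
    if not isinstance(text, str) or not text.strip():
        raise TreeError("empty newick input")
    s = text.strip()
    n_open, n_close = s.count("("), s.count(")")
    if n_open != n_close:
        raise TreeError(
            f"unbalanced parentheses in newick: {n_open} '(' vs {n_close} ')'"
        )
    if not s.endswith(";"):
        raise TreeError("newick statement must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=s,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy's parse errors carry the bad token
        msg = str(exc)
        if "Duplicate taxon labels" in msg:
            dup = msg.rsplit(":", 1)[-1].strip()
            raise TreeError(f"duplicate tip label(s): {dup}") from None
        raise TreeError(f"newick parse error: {exc}") from None

    parents, lengths, labels = [], [], []
    index_of = {}
    for node in dtree.preorder_node_iter():
        idx = len(parents)
        index_of[id(node)] = idx
        parents.append(index_of[id(node.parent_node)] if node.parent_node else -1)
        length = node.edge.length
        lengths.append(0.0 if length is None else float(length))
        if node.is_leaf():
            labels.append(node.taxon.label if node.taxon else node.label)
        else:
            labels.append(node.label)
    return Phylogeny(parents, lengths, labels)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()


# ---------------------------------------------------------------------- #
# operations


def _check_tipset(tree: Phylogeny, tips: Iterable[str]) -> set[str]:
    tipset = set(tips)
    unknown = tipset.difference(tree._tip_index_of)
    if unknown:
        raise TreeError("unknown tip label(s): " + ", ".join(sorted(unknown)))
    return tipset


def prune_to(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Restrict the tree to ``keep`` tips, retaining the root path.

    Unbranched internal nodes created by the pruning are suppressed with
    their branch lengths summed; the original root is always kept, so the
    total length of the pruned tree equals the Faith PD of ``keep``.
    """
    keep_set = _check_tipset(tree, keep)
    if not keep_set:
        raise TreeError("keep set must be nonempty")
    n = tree.n_nodes
    flag = np.zeros(n, dtype=bool)
    for lab in keep_set:
        flag[tree._tip_index_of[lab]] = True
    for i in tree._postorder:
        p = tree._parents[i]
        if p >= 0 and flag[i]:
            flag[p] = True

    def build(i: int) -> _MutableNode:
        kids = [c for c in tree._children[i] if flag[c]]
        node = _MutableNode(tree._labels[i], tree._lengths[i])
        if not kids:
            return node
        built = [build(c) for c in kids]
        if len(built) == 1 and i != tree.root:
            # suppress unbranched internal: fold this edge into the child
            child = built[0]
            child.length += node.length
            return child
        for b in built:
            node.add(b)
        return node

    return _freeze(build(tree.root))


def drop_tips(tree: Phylogeny, drop: Iterable[str]) -> Phylogeny:
    """Remove the given tips (e.g. outgroups), keeping everything else."""
    drop_set = _check_tipset(tree, drop)
    remaining = [lab for lab in tree._tip_labels if lab not in drop_set]
    if not remaining:
        raise TreeError("cannot drop all tips")
    return prune_to(tree, remaining)


def branching_times(tree: Phylogeny, rtol: float = 1e-6) -> np.ndarray:
    """Descending ages (Myr) of the tree's branching nodes.

    Requires an ultrametric tree with >= 3 tips.  Nodes with a single child
    (a retained root path after pruning) are not branching events and are
    skipped, so the first element is the age of the oldest bifurcation.
    """
    if tree.n_tips < 3:
        raise TreeError("branching times require >= 3 tips")
    dev = tree.ultrametric_deviation()
    if dev > rtol * max(tree.height, 1e-300):
        raise TreeError(
            f"tree is not ultrametric: max root-to-tip deviation {dev:.6g} Myr"
        )
    ages = tree.ages()
    internal = [i for i in range(tree.n_nodes) if len(tree._children[i]) >= 2]
    bt = np.sort(ages[internal])[::-1]
    return bt


def clade_tips(tree: Phylogeny, node_id: int) -> set[str]:
    """Tip labels descending from ``node_id`` (a tip returns itself)."""
    if not (0 <= node_id < tree.n_nodes):
        raise TreeError(f"unknown node id {node_id}")
    out, stack = [], [node_id]
    while stack:
        i = stack.pop()
        kids = tree._children[i]
        if not kids:
            out.append(tree._labels[i])
        else:
            stack.extend(kids)
    return set(out)


def mrca(tree: Phylogeny, labels: Iterable[str]) -> int:
    """Node id of the most recent common ancestor of the given tips."""
    labs = _check_tipset(tree, labels)
    if not labs:
        raise TreeError("mrca of an empty tip set is undefined")
    idx = [tree._tip_index_of[lab] for lab in labs]
    paths = []
    for i in idx:
        path = []
        while i >= 0:
            path.append(i)
            i = int(tree._parents[i])
        paths.append(path[::-1])  # root ... tip
    k = 0
    limit = min(len(p) for p in paths)
    while k < limit and all(p[k] == paths[0][k] for p in paths):
        k += 1
    return paths[0][k - 1]


def resolve_to_binary(tree: Phylogeny) -> Phylogeny:
    """Resolve polytomies with zero-length branches, by label order.

    At every multifurcation the children are sorted by their smallest
    descendant tip label and folded pairwise into zero-length nodes (a
    left-ladder), which is the deterministic convention used before the
    D statistic and any operation that requires a binary tree.
    """
    minlab = [None] * tree.n_nodes
    for i in tree._postorder:
        kids = tree._children[i]
        if not kids:
            minlab[i] = tree._labels[i]
        else:
            minlab[i] = min(minlab[c] for c in kids)

    def build(i: int) -> _MutableNode:
        node = _MutableNode(tree._labels[i], tree._lengths[i])
        kids = sorted(tree._children[i], key=lambda c: minlab[c])
        built = [build(c) for c in kids]
        while len(built) > 2:
            joint = _MutableNode(None, 0.0)
            joint.add(built[0])
            joint.add(built[1])
            built = [joint] + built[2:]
        for b in built:
            node.add(b)
        return node

    return _freeze(build(tree.root))
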