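"""Dated phylogeny container, I/O and tree-derived statistics.

Trees are rooted, strictly binary and time-calibrated.  Node ages are in
million years (My) before present: extant tips sit at age 0 and ages
increase toward the root.  All downstream likelihoods (birth-death
diversification models, phylogenetic trait models) consume this
representation, so ultrametricity and binarity are enforced at read time
rather than silently repaired.

Recently extinct species (e.g. subfossil taxa that disappeared within the
last couple of millennia) are treated as extant: any tip whose age deviates
from 0 by less than ``ULTRAMETRIC_RTOL`` times the crown age is snapped to
age 0.  Larger deviations raise :class:`TreeError`.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import dendropy

__all__ = [
    "TreeError",
    "Node",
    "DatedTree",
    "read_tree",
    "tree_from_newick",
    "read_richness",
    "sampling_fraction",
    "branching_times",
    "ltt_curve",
    "gamma_statistic",
    "colless_index",
    "patristic_matrix",
    "extract_clade",
]

#: relative (to crown age) tolerance under which tip ages are snapped to 0
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed trees (polytomies, negative or missing branch
    lengths, non-ultrametric tips beyond tolerance, unknown tip labels)."""


class Node:
    """A tree node.  ``age`` is in My before present; ``length`` is the
    branch length to the parent (``None`` for the root)."""

    __slots__ = ("name", "age", "parent", "children", "index")

    def __init__(self, name: str | None = None, age: float = 0.0):
        self.name = name
        self.age = float(age)
        self.parent: "Node | None" = None
        self.children: list["Node"] = []
        self.index: int = -1

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def length(self) -> float | None:
        if self.parent is None:
            return None
        return self.parent.age - self.age

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, age={self.age:.4g})"


class DatedTree:
    """Rooted binary ultrametric tree with node ages in My.

    Construct from a root :class:`Node` whose ages are already set, or use
    :func:`read_tree` / :func:`tree_from_newick`.  Node indices are
    assigned in postorder with tips first (tips ``0..n-1`` in a stable
    left-to-right order, internals after).
    """

    def __init__(self, root: Node, require_ultrametric: bool = True):
        self.root = root
        self._index(require_ultrametric=require_ultrametric)

    # -- construction / validation ------------------------------------

    def _index(self, require_ultrametric: bool = True) -> None:
        post: list[Node] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                post.append(node)
                continue
            stack.append((node, True))
            for c in reversed(node.children):
                stack.append((c, False))
        tips = [n for n in post if n.is_tip]
        internals = [n for n in post if not n.is_tip]
        for node in internals:
            if len(node.children) != 2:
                raise TreeError(
                    f"internal node {node.name or node!r} has "
                    f"{len(node.children)} children; resolve polytomies "
                    "upstream (binary trees required)"
                )
        for node in post:
            if node.parent is not None:
                bl = node.parent.age - node.age
                if bl < 0:
                    raise TreeError(
                        f"negative branch length ({bl:.6g}) above node "
                        f"{node.name or node!r}"
                    )
        crown = self.root.age
        if crown <= 0:
            raise TreeError("crown age must be positive")
        tol = ULTRAMETRIC_RTOL * crown
        for t in tips:
            if abs(t.age) <= tol:
                t.age = 0.0
            elif require_ultrametric and t.age > tol:
                raise TreeError(
                    f"tip {t.name!r} ends at age {t.age:.6g} My "
                    f"(> tolerance {tol:.3g}); tree is not ultrametric"
                )
        seen: set[str] = set()
        for t in tips:
            if t.name is None:
                raise TreeError("unlabelled tip")
            if t.name in seen:
                raise TreeError(f"duplicate tip label {t.name!r}")
            seen.add(t.name)
        for i, n in enumerate(tips):
            n.index = i
        for j, n in enumerate(internals):
            n.index = len(tips) + j
        self.tips: list[Node] = tips
        self.internals: list[Node] = internals
        self.postorder: list[Node] = tips_and_internals_postorder(post)

    # -- basic properties ----------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def tip_labels(self) -> list[str]:
        return [t.name for t in self.tips]

    @property
    def crown_age(self) -> float:
        return self.root.age

    def preorder(self) -> list[Node]:
        out = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    # -- derived quantities --------------------------------------------

    def branching_times(self) -> np.ndarray:
        """Internal-node ages, sorted old -> young (first = crown age)."""
        for t in self.tips:
            if t.age != 0.0:
                raise TreeError("branching times require an ultrametric tree")
        ages = np.array([n.age for n in self.internals], dtype=float)
        return np.sort(ages)[::-1]

    def node_heights(self) -> np.ndarray:
        """Root-to-node times (crown_age - age), indexed by node.index."""
        h = np.empty(len(self.postorder))
        for n in self.postorder:
            h[n.index] = self.crown_age - n.age
        return h

    def total_branch_length(self) -> float:
        return float(
            sum(n.length for n in self.postorder if n.parent is not None)
        )

    def mrca(self, labels: Iterable[str]) -> Node:
        labels = set(labels)
        if not labels:
            raise TreeError("empty tip set")
        unknown = labels - set(self.tip_labels)
        if unknown:
            raise TreeError(f"unknown tip labels: {sorted(unknown)}")
        # walk up from one tip, collecting ancestors; then ascend from others
        by_name = {t.name: t for t in self.tips}
        paths = []
        for lab in labels:
            node = by_name[lab]
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(set(id(x) for x in path))
        first = by_name[next(iter(labels))]
        node = first
        common = set.intersection(*paths)
        while id(node) not in common:
            node = node.parent
        return node

    def mrca_matrix(self) -> np.ndarray:
        """(n_tips x n_tips) matrix of MRCA node indices (diag = tip index)."""
        n = self.n_tips
        M = np.empty((n, n), dtype=np.int64)
        tipsets: dict[int, list[int]] = {}
        for node in self.postorder:
            if node.is_tip:
                tipsets[id(node)] = [node.index]
                M[node.index, node.index] = node.index
            else:
                sets = [tipsets.pop(id(c)) for c in node.children]
                for a_i in range(len(sets)):
                    for b_i in range(a_i + 1, len(sets)):
                        ia = np.asarray(sets[a_i])
                        ib = np.asarray(sets[b_i])
                        M[np.ix_(ia, ib)] = node.index
                        M[np.ix_(ib, ia)] = node.index
                merged = [i for s in sets for i in s]
                tipsets[id(node)] = merged
        return M

    def shared_time_matrix(self) -> np.ndarray:
        """(n x n) root-to-MRCA times (BM covariance up to sigma^2)."""
        heights = self.node_heights()
        M = self.mrca_matrix()
        return heights[M]

    def copy(self) -> "DatedTree":
        return DatedTree(_copy_node(self.root), require_ultrametric=False)

    # -- I/O -------------------------------------------------------------

    def newick(self, digits: int = 10) -> str:
        buf = io.StringIO()

        def rec(node: Node):
            if node.is_tip:
                buf.write(_quote(node.name))
            else:
                buf.write("(")
                for i, c in enumerate(node.children):
                    if i:
                        buf.write(",")
                    rec(c)
                buf.write(")")
                if node.name:
                    buf.write(_quote(node.name))
            if node.parent is not None:
                buf.write(f":{node.length:.{digits}g}")

        rec(self.root)
        buf.write(";")
        return buf.getvalue()

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")

    def __repr__(self):  # pragma: no cover
        return f"DatedTree(n_tips={self.n_tips}, crown_age={self.crown_age:.4g})"


def tips_and_internals_postorder(post: list[Node]) -> list[Node]:
    return post


def _copy_node(node: Node) -> Node:
    new = Node(node.name, node.age)
    for c in node.children:
        new.add_child(_copy_node(c))
    return new


def _quote(name: str) -> str:
    if any(ch in name for ch in " ()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


# ----------------------------------------------------------------------
# I/O


def _from_dendropy(dtree: "dendropy.Tree") -> DatedTree:
    """Convert a dendropy tree (branch lengths in My) to a DatedTree."""
    for edge in dtree.preorder_edge_iter():
        if edge.head_node is dtree.seed_node:
            continue
        if edge.length is None:
            raise TreeError("missing branch length")
        if edge.length < 0:
            raise TreeError(f"negative branch length {edge.length}")
    # depths from root
    depth: dict[int, float] = {id(dtree.seed_node): 0.0}
    maxdepth = 0.0
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            continue
        d = depth[id(nd.parent_node)] + nd.edge.length
        depth[id(nd)] = d
        if nd.is_leaf():
            maxdepth = max(maxdepth, d)

    def convert(nd) -> Node:
        if nd.is_leaf():
            name = nd.taxon.label if nd.taxon is not None else nd.label
        else:
            name = nd.label
        out = Node(name, age=maxdepth - depth.get(id(nd), 0.0))
        for c in nd.child_nodes():
            out.add_child(convert(c))
        return out

    root = convert(dtree.seed_node)
    return DatedTree(root)


def read_tree(path_or_handle, format: str = "newick") -> DatedTree:
    """Read a single rooted, dated tree from a Newick or NEXUS file.

    Branch lengths are interpreted as My.  Polytomies, negative and
    missing branch lengths are rejected; tips within tolerance of age 0
    are snapped to 0 (recently extinct taxa treated as extant).
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format {format!r}")
    if hasattr(path_or_handle, "read"):
        data = path_or_handle.read()
    else:
        with open(path_or_handle) as fh:
            data = fh.read()
    dtree = dendropy.Tree.get(
        data=data, schema=format, preserve_underscores=True
    )
    return _from_dendropy(dtree)


def tree_from_newick(newick: str) -> DatedTree:
    """Parse a Newick string with branch lengths in My."""
    dtree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    return _from_dendropy(dtree)


def read_richness(path_or_handle) -> pd.Series:
    """Read a 2-column CSV (tip_label, n_species) into a Series.

    Counts must be positive integers: the total number of described
    species represented by each tip (1 = fully sampled tip).
    """
    df = pd.read_csv(path_or_handle)
    if df.shape[1] < 2:
        raise ValueError("richness table needs columns (tip_label, n_species)")
    s = pd.Series(
        df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str), name="n_species"
    )
    if not np.all(s.to_numpy() == s.to_numpy().astype(int)) or (s <= 0).any():
        raise ValueError("species counts must be positive integers")
    return s.astype(int)


def sampling_fraction(tree: DatedTree, richness: pd.Series) -> float:
    """Clade sampling fraction rho = (tips in tree) / (assigned richness)."""
    missing = set(tree.tip_labels) - set(richness.index)
    if missing:
        raise ValueError(f"tips missing from richness table: {sorted(missing)[:5]}")
    total = int(richness.loc[tree.tip_labels].sum())
    rho = tree.n_tips / total
    if not 0 < rho <= 1:
        raise ValueError(f"sampling fraction {rho} outside (0, 1]")
    return rho


# ----------------------------------------------------------------------
# Tree statistics


def branching_times(tree: DatedTree) -> np.ndarray:
    return tree.branching_times()


def ltt_curve(tree: DatedTree) -> tuple[np.ndarray, np.ndarray]:
    """Lineage-through-time step function.

    Returns ``(ages, counts)``: at any age ``a`` the number of
    reconstructed lineages equals ``counts[k]`` for the largest ``k``
    with ``ages[k] >= a``; ``ages`` descend from the crown age and
    ``counts`` rises from 2 to n_tips.
    """
    bt = tree.branching_times()
    ages = bt
    counts = np.arange(2, tree.n_tips + 1)
    return ages, counts


def lineages_at(tree: DatedTree, age: float) -> int:
    """Number of reconstructed lineages alive at a given age."""
    bt = tree.branching_times()
    if age > bt[0]:
        return 1
    return int(np.sum(bt > age) + 1)


def gamma_statistic(tree: DatedTree) -> float:
    """Pybus–Harvey gamma: standard-normal under constant-rate pure birth.

    Positive values indicate nodes concentrated toward the tips
    (apparent acceleration), negative toward the root.
    """
    n = tree.n_tips
    if n < 3:
        raise TreeError("gamma statistic requires >= 3 tips")
    x = tree.branching_times()  # descending, length n-1
    # internode intervals g_k during which k lineages exist, k = 2..n
    bounds = np.concatenate([x, [0.0]])
    g = bounds[:-1] - bounds[1:]  # g[k-2] = interval with k lineages
    k = np.arange(2, n + 1)
    T = float(np.sum(k * g))
    cum = np.cumsum(k * g)  # cum[i-2] = sum_{k=2}^{i} k g_k
    mean_part = np.sum(cum[: n - 2]) / (n - 2)
    return float((mean_part - T / 2.0) / (T * np.sqrt(1.0 / (12.0 * (n - 2)))))


def colless_index(tree: DatedTree, normalize: bool = True) -> float:
    """Colless imbalance: sum over internal nodes of |nL - nR|.

    Normalized by (n-1)(n-2)/2 when ``normalize`` is set.
    """
    sizes: dict[int, int] = {}
    total = 0
    for node in tree.postorder:
        if node.is_tip:
            sizes[id(node)] = 1
        else:
            a, b = (sizes.pop(id(c)) for c in node.children)
            total += abs(a - b)
            sizes[id(node)] = a + b
    n = tree.n_tips
    if normalize:
        denom = (n - 1) * (n - 2) / 2.0
        return total / denom if denom > 0 else 0.0
    return float(total)


def median_internal_branch(tree: DatedTree) -> float:
    lens = [
        n.length
        for n in tree.postorder
        if n.parent is not None and not n.is_tip
    ]
    if not lens:
        return 0.0
    return float(np.median(lens))


def patristic_matrix(tree: DatedTree) -> pd.DataFrame:
    """Symmetric tip-to-tip path-length matrix (My)."""
    heights = tree.node_heights()
    M = tree.mrca_matrix()
    n = tree.n_tips
    hi = heights[:n]
    D = hi[:, None] + hi[None, :] - 2.0 * heights[M]
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=tree.tip_labels, columns=tree.tip_labels)


def extract_clade(tree: DatedTree, labels: Iterable[str]) -> DatedTree:
    """Crown subtree spanned by the MRCA of the named tips."""
    node = tree.mrca(labels)
    return DatedTree(_copy_node(node), require_ultrametric=False)
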