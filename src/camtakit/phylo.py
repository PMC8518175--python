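"""Distance-based phylogeny: pairwise distances, neighbor joining, bootstrap.

Deliberately a descriptive stand-in for likelihood tree inference: distances
(p or Poisson-corrected) under pairwise gap deletion, Saitou-Nei neighbor
joining with deterministic tie-breaking, and nonparametric bootstrap support
from column resampling.  Output is newick; headers written by the pipeline
mark these trees as distance-based.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("nonzero diagonal")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> set[str]:
        return {leaf.name for leaf in self.leaves()}


def pairwise_distance(alignment: dict[str, str], model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances under pairwise gap deletion.

    For each pair, columns where either row has a gap are dropped; p is the
    mismatch fraction among the rest; the poisson model applies -ln(1 - p).
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    taxa = list(alignment)
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = alignment[taxa[i]], alignment[taxa[j]]
            pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not pairs:
                raise ValueError(
                    f"no comparable columns between {taxa[i]} and {taxa[j]}"
                )
            p = sum(1 for x, y in pairs if x != y) / len(pairs)
            if model == "p":
                dist = p
            else:
                if p >= 1.0:
                    raise ValueError(
                        f"saturated pair {taxa[i]}/{taxa[j]}: p = 1"
                    )
                dist = -math.log(1.0 - p)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa, d)


def _clamp(length: float, context: str) -> float:
    if length < 0:
        warnings.warn(f"negative branch length clamped to 0 ({context})", stacklevel=3)
        return 0.0
    return length


def neighbor_joining(m: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Ties in Q are broken toward the lowest taxon-index pair in the current
    working order, so the result is deterministic.  Negative branch lengths
    are clamped to zero with a warning.  The returned root is the final
    unresolved node (3 children for >= 3 taxa, matching the unrooted tree).
    """
    n = len(m.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=t) for t in m.taxa]
    d = m.d.copy()
    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        node = TreeNode()
        ni, nj = nodes[i], nodes[j]
        ni.length = _clamp(li, f"join {len(nodes)}")
        nj.length = _clamp(lj, f"join {len(nodes)}")
        node.children = [ni, nj]
        new_index = d.shape[0]
        newrow = np.zeros(new_index + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[new_index, k] = d[k, new_index] = dk
        nodes.append(node)
        active = [k for k in active if k not in (i, j)] + [new_index]
    # final star join of the last three nodes
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = TreeNode()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = _clamp(ln, "final join")
        root.children.append(nodes[idx])
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Internal-edge bipartitions as leaf-name sets (smaller/canonical side);
    trivial single-leaf and all-taxa splits are excluded."""
    all_leaves = frozenset(tree.leaf_names())
    splits = set()

    def walk(node: TreeNode):
        for child in node.children:
            names = frozenset(child.leaf_names())
            if 1 < len(names) < len(all_leaves) - 1:
                other = all_leaves - names
                splits.add(min(names, other, key=lambda s: (len(s), sorted(s))))
            walk(child)

    walk(tree)
    return splits


def bootstrap_support(
    alignment: dict[str, str],
    n_reps: int = 1000,
    seed: int | None = None,
    model: str = "poisson",
) -> TreeNode:
    """NJ tree with bootstrap supports from column resampling.

    Support of an internal bipartition is the percentage of replicate NJ
    trees (columns resampled with replacement, same distance model) that
    contain it.  ``n_reps = 0`` returns the tree with absent supports.
    """
    tree = neighbor_joining(pairwise_distance(alignment, model))
    if n_reps == 0:
        return tree
    if seed is None:
        raise ValueError("bootstrap requires a seed")
    rng = np.random.default_rng(seed)
    taxa = list(alignment)
    cols = np.array([list(alignment[t]) for t in taxa])
    ncol = cols.shape[1]
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        rep = {t: "".join(cols[i, idx]) for i, t in enumerate(taxa)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep_tree = neighbor_joining(pairwise_distance(rep, model))
        for split in bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    all_leaves = frozenset(tree.leaf_names())

    def annotate(node: TreeNode):
        for child in node.children:
            if not child.is_leaf:
                names = frozenset(child.leaf_names())
                if 1 < len(names) < len(all_leaves) - 1:
                    key = min(names, all_leaves - names, key=lambda s: (len(s), sorted(s)))
                    child.support = 100.0 * counts.get(key, 0) / n_reps
            annotate(child)

    annotate(tree)
    return tree


def _format_label(name: str) -> str:
    if any(c in name for c in " ();:,'\""):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: TreeNode) -> str:
    """Standard newick with branch lengths; bootstrap supports appear as
    internal node labels.  Labels containing spaces or punctuation are
    single-quoted."""

    def fmt(node: TreeNode, is_root: bool = False) -> str:
        if node.is_leaf:
            body = _format_label(node.name)
        else:
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if node.support is not None:
                label = f"{node.support:g}"
            elif node.name:
                label = _format_label(node.name)
            body = f"({inner}){label}"
        if is_root:
            return body
        return f"{body}:{node.length:.10g}"

    return fmt(tree, is_root=True) + ";"
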