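"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap support.

Distances are uncorrected p-distances (1 - identity over columns where
neither row is gapped). Neighbor joining is the Saitou-Nei algorithm with
the standard Q criterion; on additive distance matrices it recovers the
generating topology and branch lengths exactly. Ties in Q are broken by the
lexicographically lowest label pair and negative branch lengths are clamped
to zero (the raw value is kept on the edge record), so output is fully
deterministic. Bootstrap support resamples alignment columns with
replacement and counts bipartition recurrence over replicate NJ trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import GAP, Msa


class PhyloError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise PhyloError("matrix shape does not match labels")
        if not np.allclose(d, d.T) or not np.all(np.isfinite(d)):
            raise PhyloError("distance matrix must be symmetric and finite")
        if not np.allclose(np.diag(d), 0):
            raise PhyloError("diagonal must be zero")
        object.__setattr__(self, "d", d)

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lbl, row in zip(self.labels, self.d):
                fh.write(lbl + "  " + " ".join(f"{v:.6f}" for v in row) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lbl, row in zip(self.labels, self.d):
                fh.write(lbl + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label] if self.label else []
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree represented with an arbitrary internal node as root."""

    root: TreeNode
    labels: tuple[str, ...]
    clamped_deficit: float = 0.0  # total negative branch length clamped to 0

    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-or-lexmin leaf set."""
        all_leaves = frozenset(self.leaf_names())
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if not node.children:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        for child, _ in self.root.children:
            walk(child)
        return out


def distances_from_msa(msa: Msa) -> DistanceMatrix:
    """p-distance matrix: 1 - identity over mutually ungapped columns."""
    if len(msa.rows) < 3:
        raise PhyloError("need at least 3 rows")
    labels = tuple(msa.ids)
    n = len(labels)
    arr = np.array([list(s) for _, s in msa.rows])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (arr[i] != GAP) & (arr[j] != GAP)
            ncols = int(both.sum())
            if ncols == 0:
                raise PhyloError(
                    f"rows {labels[i]!r} and {labels[j]!r} share no comparable columns"
                )
            ident = float((arr[i][both] == arr[j][both]).sum()) / ncols
            d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(labels=labels, d=d)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking."""
    n = len(dm.labels)
    if n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in dm.labels]
    # representative label per active node, for lexicographic tie-breaks
    reps: list[str] = list(dm.labels)
    D = dm.d.copy()
    active = list(range(n))
    deficit = 0.0

    def clamp(v: float) -> float:
        nonlocal deficit
        if v < 0:
            deficit += -v
            return 0.0
        return v

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                key = tuple(sorted((reps[i], reps[j])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12
                    and best is not None
                    and key < best[2]
                ):
                    best_q = q
                    best = (i, j, key)
        i, j, _ = best
        vi = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        vj = D[i, j] - vi
        parent = TreeNode(
            children=[(nodes[i], clamp(vi)), (nodes[j], clamp(vj))]
        )
        new_idx = len(nodes)
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        Dn = np.zeros((new_idx + 1, new_idx + 1))
        Dn[: D.shape[0], : D.shape[1]] = D
        for k in active:
            if k in (i, j):
                continue
            Dn[new_idx, k] = Dn[k, new_idx] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = Dn
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j, k = active
    # three-point formulas
    vi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    vj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    vk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    order = sorted(((reps[x], x, v) for x, v in ((i, vi), (j, vj), (k, vk))))
    root = TreeNode(children=[(nodes[x], clamp(v)) for _, x, v in order])
    return PhyloTree(root=root, labels=dm.labels, clamped_deficit=deficit)


def bootstrap_support(
    msa: Msa, replicates: int = 1000, seed: int = 0
) -> PhyloTree:
    """NJ tree on the full MSA with per-bipartition bootstrap support fractions."""
    if replicates < 1:
        raise PhyloError("replicates must be >= 1")
    base = nj_tree(distances_from_msa(msa))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in base.bipartitions()}
    rng = np.random.default_rng(seed)
    ncols = msa.column_count
    for _ in range(replicates):
        cols = rng.integers(0, ncols, size=ncols)
        rows = tuple(
            (rid, "".join(s[c] for c in cols)) for rid, s in msa.rows
        )
        try:
            rep_tree = nj_tree(distances_from_msa(Msa(rows=rows)))
        except PhyloError:
            continue  # a replicate can lose all comparable columns for a pair
        reps_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in reps_bps:
                counts[bp] += 1

    def annotate(node: TreeNode, all_leaves: frozenset[str]) -> frozenset[str]:
        if not node.children:
            return frozenset([node.label])
        below = frozenset().union(*(annotate(c, all_leaves) for c, _ in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            other = all_leaves - below
            key = min(below, other, key=lambda s: (len(s), sorted(s)))
            node.support = counts.get(key, 0) / replicates
        return below

    all_leaves = frozenset(base.leaf_names())
    for child, _ in base.root.children:
        annotate(child, all_leaves)
    return base


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]:;,'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick(node: TreeNode, with_support: bool) -> str:
    if not node.children:
        return _quote(node.label or "")
    inner = ",".join(
        f"{_newick(c, with_support)}:{bl:.6f}" for c, bl in node.children
    )
    sup = ""
    if with_support and node.support is not None:
        sup = f"{node.support:.3f}"
    return f"({inner}){sup}"


def write_newick(tree: PhyloTree, path: str | Path, with_support: bool = True) -> None:
    Path(path).write_text(_newick(tree.root, with_support) + ";\n")


def newick_string(tree: PhyloTree, with_support: bool = True) -> str:
    return _newick(tree.root, with_support) + ";"
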