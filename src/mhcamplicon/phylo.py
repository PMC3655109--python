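"""Distance-based phylogenetics: Jukes–Cantor distances, neighbor joining,
nonparametric bootstrap support, newick output.

The tree is the Saitou–Nei neighbor-joining topology (Q-criterion), rooted
arbitrarily at the final three-way join; supports are percentages of
bootstrap replicate trees (alignment columns resampled with replacement)
containing the same unrooted bipartition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("nonzero diagonal")
        if not np.isfinite(m).all():
            raise ValueError("non-finite distances")
        if (m < 0).any():
            raise ValueError("negative distances")
        self.matrix = m


class SaturationError(ValueError):
    """Raised when a pairwise mismatch proportion reaches the JC domain edge."""


def p_distance_matrix(align: Alignment) -> np.ndarray:
    arr = np.array([list(s) for s in align.seqs])
    n = len(align)
    p = np.zeros((n, n))
    for i in range(n):
        d = (arr[i + 1 :] != arr[i]).mean(axis=1)
        p[i, i + 1 :] = d
        p[i + 1 :, i] = d
    return p


def jc_distance(align: Alignment, model: str = "jc") -> DistanceMatrix:
    """Pairwise distances under Jukes–Cantor (default) or raw p-distance.

    JC: d = -(3/4) ln(1 - 4p/3). A mismatch proportion p >= 3/4 has no
    finite JC distance; the offending pair is named in the error.
    """
    if len(align) < 2:
        raise ValueError("need at least 2 sequences")
    p = p_distance_matrix(align)
    if model == "p":
        return DistanceMatrix(list(align.ids), p)
    if model != "jc":
        raise ValueError(f"unknown model {model!r}")
    sat = np.argwhere(np.triu(p, k=1) >= 0.75)
    if len(sat):
        i, j = sat[0]
        raise SaturationError(
            f"saturated pair ({align.ids[i]}, {align.ids[j]}): p = {p[i, j]:.3f}"
        )
    d = -0.75 * np.log1p(-4.0 * p / 3.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(align.ids), d)


def _saturation_tolerant_jc(p: np.ndarray) -> np.ndarray:
    """JC distances where saturated pairs get placeholder values above the
    largest finite distance, ordered by their p-distances.

    Used inside bootstrap replicates: dropping a replicate whose resampled
    columns saturate one pair would bias support, so the pair is kept with a
    large distance that preserves the ranking among saturated pairs.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
    np.fill_diagonal(d, 0.0)
    bad = ~np.isfinite(d)
    if bad.any():
        finite_max = np.nanmax(np.where(bad, np.nan, d))
        if not np.isfinite(finite_max):
            finite_max = 1.0
        iu, ju = np.nonzero(np.triu(bad, k=1))
        order = np.argsort(p[iu, ju], kind="stable")
        step = max(finite_max, 1.0) * 0.05
        for rank, k in enumerate(order):
            i, j = iu[k], ju[k]
            d[i, j] = d[j, i] = finite_max + (rank + 1) * step
    return d


@dataclass
class Node:
    name: str | None = None
    children: list[tuple["Node", float]] = field(default_factory=list)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, precision: int = 6) -> str:
        return self._newick(precision) + ";"

    def _newick(self, precision: int) -> str:
        if self.is_leaf():
            return self.name
        inner = ",".join(
            f"{child._newick(precision)}:{length:.{precision}f}"
            for child, length in self.children
        )
        label = "" if self.support is None else str(int(round(self.support)))
        return f"({inner}){label}"


@dataclass
class Tree:
    root: Node
    labels: list[str]
    clamped_deficit: float = 0.0  # total negative branch length clamped to 0

    def newick(self, precision: int = 6) -> str:
        return self.root.newick(precision)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted bipartitions, canonicalised as the side not
        containing the first taxon."""
        all_taxa = frozenset(self.labels)
        ref = self.labels[0]
        out: set[frozenset[str]] = set()
        stack = [(child, self.root) for child, _ in self.root.children]
        nodes = []
        self._collect_internal(self.root, nodes)
        for node in nodes:
            side = frozenset(node.leaves())
            if ref in side:
                side = all_taxa - side
            if 1 < len(side) < len(all_taxa) - 1:
                out.add(side)
        return out

    def _collect_internal(self, node: Node, acc: list[Node]) -> None:
        for child, _ in node.children:
            if not child.is_leaf():
                acc.append(child)
                self._collect_internal(child, acc)

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (for additivity checks)."""
        dists: dict[str, dict[str, float]] = {}

        def walk(node: Node) -> dict[str, float]:
            if node.is_leaf():
                return {node.name: 0.0}
            sub = []
            for child, length in node.children:
                d = walk(child)
                sub.append({k: v + length for k, v in d.items()})
            for a, b in itertools.combinations(range(len(sub)), 2):
                for la, da in sub[a].items():
                    for lb, db in sub[b].items():
                        dists.setdefault(la, {})[lb] = da + db
                        dists.setdefault(lb, {})[la] = da + db
            merged = {}
            for d in sub:
                merged.update(d)
            return merged

        walk(self.root)
        n = len(self.labels)
        m = np.zeros((n, n))
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                if i != j:
                    m[i, j] = dists[a][b]
        return DistanceMatrix(list(self.labels), m)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining.

    Ties in the Q-criterion are broken deterministically by the smallest
    (row, column) index pair in the current matrix ordering; negative branch
    lengths are clamped to zero and the clamped total is recorded on the
    returned tree.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    D = dm.matrix.astype(float).copy()
    nodes: list[Node] = [Node(name=lbl) for lbl in dm.labels]
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)  # row-major: smallest (i, j)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        new = Node(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = clamp(0.5 * (d01 + d02 - d12))
    l1 = clamp(0.5 * (d01 + d12 - d02))
    l2 = clamp(0.5 * (d02 + d12 - d01))
    root = Node(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])
    return Tree(root, list(dm.labels), clamped_deficit=deficit)


def bootstrap_support(
    align: Alignment,
    n_replicates: int = 1000,
    seed: int = 0,
    model: str = "jc",
) -> Tree:
    """Point-estimate NJ tree with bootstrap bipartition support.

    Columns are resampled with replacement ``n_replicates`` times; the
    support of each internal edge of the point tree is the percentage of
    replicate trees containing the same bipartition. ``n_replicates=0``
    returns the point tree with supports absent. Replicates whose resampled
    pairs saturate under JC keep those pairs at placeholder distances above
    the replicate's largest finite distance (dropping replicates would bias
    support downward).
    """
    if n_replicates < 0:
        raise ValueError("n_replicates must be >= 0")
    point = nj_tree(jc_distance(align, model=model))
    if n_replicates == 0:
        return point
    rng = np.random.default_rng(seed)
    arr = np.array([list(s) for s in align.seqs])
    n, L = arr.shape
    counts: dict[frozenset[str], int] = {bp: 0 for bp in point.bipartitions()}
    for _ in range(n_replicates):
        cols = rng.integers(L, size=L)
        sub = arr[:, cols]
        p = np.zeros((n, n))
        for i in range(n):
            d = (sub[i + 1 :] != sub[i]).mean(axis=1)
            p[i, i + 1 :] = d
            p[i + 1 :, i] = d
        if model == "jc":
            dmat = _saturation_tolerant_jc(p)
        else:
            dmat = p
        rep = nj_tree(DistanceMatrix(list(align.ids), dmat))
        rep_bps = rep.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
    _attach_support(point, supports)
    return point


def _attach_support(tree: Tree, supports: dict[frozenset[str], float]) -> None:
    all_taxa = frozenset(tree.labels)
    ref = tree.labels[0]
    nodes: list[Node] = []
    tree._collect_internal(tree.root, nodes)
    for node in nodes:
        side = frozenset(node.leaves())
        if ref in side:
            side = all_taxa - side
        if 1 < len(side) < len(all_taxa) - 1:
            node.support = supports.get(side)
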