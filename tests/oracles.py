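"""Independent brute-force oracles shared by the unit and acceptance tests.

Each oracle re-derives an expected value by exhaustive enumeration or direct
construction, without touching the implementation path it checks.
"""

import itertools

import numpy as np
from Bio.Seq import Seq

from mhcamplicon.alignment import Alignment, STOP_CODONS
from mhcamplicon.iupac import IUPAC
from mhcamplicon.recomb import segregating_sites

BASES = "ACGT"


# --- IUPAC-aware infix edit distance -------------------------------------


def oracle_infix_distance(pattern: str, sequence: str) -> int:
    """Dynamic-programming edit distance with free gaps at sequence ends."""
    m, n = len(pattern), len(sequence)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            match = 0 if sequence[j - 1] in IUPAC[pattern[i - 1]] else 1
            cur[j] = min(prev[j - 1] + match, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)


# --- Nei-Gojobori pathway counting ---------------------------------------


def _aa(codon):
    return str(Seq(codon).translate())


def oracle_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Exhaustive pathway enumeration (pathways through stops excluded)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    kept, all_paths = [], []
    for order in itertools.permutations(diff):
        cur, steps, bad = c1, [], False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != c2:
                bad = True
            steps.append((cur, nxt))
            cur = nxt
        all_paths.append(steps)
        if not bad:
            kept.append(steps)
    use = kept or all_paths
    sd = sum(1 for steps in use for a, b in steps if _aa(a) == _aa(b)) / len(use)
    nd = sum(1 for steps in use for a, b in steps if _aa(a) != _aa(b)) / len(use)
    return sd, nd


def oracle_codon_sites(codon: str) -> tuple[float, float]:
    """Neighbor enumeration of synonymous/nonsynonymous potential sites,
    normalised to 3 per codon (stop neighbors count as nonsynonymous)."""
    s = n = 0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            neighbor = codon[:pos] + b + codon[pos + 1:]
            if neighbor in STOP_CODONS:
                n += 1
            elif _aa(neighbor) == _aa(codon):
                s += 1
            else:
                n += 1
    norm = (s + n) / 3.0
    return s / norm, n / norm


def random_sense_codon(rng) -> str:
    while True:
        c = "".join(BASES[i] for i in rng.integers(4, size=3))
        if c not in STOP_CODONS:
            return c


# --- Hudson-Kaplan minimum breakpoints -----------------------------------


def random_alignment(rng, n_seqs: int, n_sites: int) -> Alignment:
    arr = rng.integers(0, 2, size=(n_seqs, n_sites))
    seqs = ["".join("AT"[v] for v in row) for row in arr]
    return Alignment([f"s{i}" for i in range(n_seqs)], seqs)


def oracle_min_breakpoints(align: Alignment) -> int:
    """Minimum number of points piercing every incompatible open interval."""
    seg = segregating_sites(align)
    pos = [p for p, b in zip(seg.positions, seg.biallelic) if b]
    arr = np.array([list(s) for s in align.seqs])
    intervals = []
    for a, b in itertools.combinations(pos, 2):
        if len(set(zip(arr[:, a], arr[:, b]))) == 4:
            intervals.append((a, b))
    if not intervals:
        return 0
    candidates = sorted({a + 0.5 for a, _ in intervals} |
                        {b - 0.5 for _, b in intervals} |
                        {(a + b) / 2 for a, b in intervals})
    for k in range(1, len(intervals) + 1):
        for combo in itertools.combinations(candidates, k):
            if all(any(a < c < b for c in combo) for a, b in intervals):
                return k
    return len(intervals)


# --- random additive distance matrices -----------------------------------


def random_additive_matrix(rng, n_taxa: int):
    """Random unrooted binary tree; returns (labels, matrix, bipartitions)."""
    next_id = [n_taxa]
    edges: dict[int, list[tuple[int, float]]] = {}

    def connect(a, b, w):
        edges.setdefault(a, []).append((b, w))
        edges.setdefault(b, []).append((a, w))

    active = list(range(n_taxa))
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        new = next_id[0]
        next_id[0] += 1
        connect(a, new, float(rng.uniform(0.5, 3.0)))
        connect(b, new, float(rng.uniform(0.5, 3.0)))
        active = [x for x in active if x not in (a, b)] + [new]
    center = next_id[0]
    next_id[0] += 1
    for x in active:
        connect(x, center, float(rng.uniform(0.5, 3.0)))

    labels = [f"t{i}" for i in range(n_taxa)]
    n_all = next_id[0]
    dist = np.full((n_all, n_all), np.inf)
    for a in range(n_all):
        dist[a, a] = 0.0
        stack = [a]
        seen = {a}
        while stack:
            u = stack.pop()
            for v, w in edges.get(u, []):
                if v not in seen:
                    seen.add(v)
                    dist[a, v] = dist[a, u] + w
                    stack.append(v)
    m = dist[:n_taxa, :n_taxa]

    bips = set()
    for u in edges:
        for v, _ in edges[u]:
            if u < v and u >= n_taxa and v >= n_taxa:
                side = frozenset(f"t{i}" for i in _leaves_on_side(edges, u, v, n_taxa))
                comp = frozenset(labels) - side
                canon = comp if "t0" in side else side
                if 1 < len(canon) < n_taxa - 1:
                    bips.add(canon)
    return labels, m, bips


def _leaves_on_side(edges, start, blocked, n_taxa):
    seen = {start, blocked}
    stack = [start]
    leaves = []
    while stack:
        u = stack.pop()
        if u < n_taxa:
            leaves.append(u)
        for v, _ in edges.get(u, []):
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return leaves
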