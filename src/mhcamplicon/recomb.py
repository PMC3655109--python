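"""Recombination, gene-conversion and multilocus linkage statistics.

Three complementary views of sequence exchange among alleles:

* :func:`four_gamete_rm` — the Hudson–Kaplan lower bound RM on the number of
  recombination events, from pairs of biallelic sites exhibiting all four
  gametes;
* :func:`geneconv_scan` — a Sawyer-style scan for unusually long runs of
  agreement between sequence pairs across polymorphic columns, with
  permutation p-values (gene conversion leaves long shared tracts);
* :func:`ld_randomization` — the standardized index of association (r̄d) on
  an individuals × alleles presence/absence matrix, tested by independently
  permuting each allele column.

All permutation p-values use the add-one convention
``p = (1 + #{null >= observed}) / (n_permutations + 1)`` and are therefore
never zero and bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import Alignment


@dataclass
class SegregatingSites:
    """Polymorphic columns of an alignment (0-based positions)."""

    positions: list[int]
    states: list[str]  # observed states per site, joined alphabetically
    biallelic: list[bool]


def segregating_sites(align: Alignment) -> SegregatingSites:
    arr = np.array([list(s) for s in align.seqs])
    positions, states, biallelic = [], [], []
    for col in range(arr.shape[1]):
        uniq = sorted(set(arr[:, col]))
        if len(uniq) > 1:
            positions.append(col)
            states.append("".join(uniq))
            biallelic.append(len(uniq) == 2)
    return SegregatingSites(positions, states, biallelic)


def four_gamete_rm(align: Alignment) -> tuple[int, list[tuple[int, int]]]:
    """Hudson–Kaplan minimum number of recombination events (RM).

    A pair of biallelic segregating sites showing all four gametes requires
    at least one recombination event strictly between them; incompatible
    pairs bound OPEN intervals, and RM is the size of a maximal set of
    pairwise-disjoint such intervals (equivalently the minimum number of
    breakpoints piercing every interval). Sites with more than two states
    are excluded, following common practice. Returns (RM, the selected
    disjoint intervals as 0-based site-position pairs).
    """
    if len(align) < 2:
        raise ValueError("need at least 2 sequences")
    seg = segregating_sites(align)
    pos = [p for p, b in zip(seg.positions, seg.biallelic) if b]
    if len(pos) < 2:
        return 0, []
    arr = np.array([list(s) for s in align.seqs])
    cols = {p: arr[:, p] for p in pos}
    intervals = []
    for a, b in itertools.combinations(pos, 2):
        gametes = set(zip(cols[a], cols[b]))
        if len(gametes) == 4:
            intervals.append((a, b))
    # maximal disjoint set: greedy by right endpoint; open intervals (a, b)
    # and (c, d) are disjoint iff c >= b
    intervals.sort(key=lambda iv: iv[1])
    chosen: list[tuple[int, int]] = []
    last_right = -1
    for a, b in intervals:
        if a >= last_right:
            chosen.append((a, b))
            last_right = b
    return len(chosen), chosen


# ---------------------------------------------------------------------------
# gene-conversion fragment scan


@dataclass
class GeneConvResult:
    fragments: pd.DataFrame  # per-pair best inner fragment
    global_p: float
    frac_significant: float
    n_polymorphic: int
    n_permutations: int
    tested: bool


def _max_runs(agree: np.ndarray) -> np.ndarray:
    """Longest run of True per row of a boolean matrix."""
    best = np.zeros(agree.shape[0], dtype=int)
    run = np.zeros(agree.shape[0], dtype=int)
    for k in range(agree.shape[1]):
        col = agree[:, k]
        run = (run + 1) * col
        np.maximum(best, run, out=best)
    return best


def geneconv_scan(
    align: Alignment,
    n_permutations: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> GeneConvResult:
    """Scan sequence pairs for unusually long shared tracts.

    Restricted to polymorphic columns, each unordered pair's inner fragments
    are maximal runs of agreement, scored by their length in polymorphic
    sites (exact-match runs; no mismatch-penalised extension). Significance
    comes from randomly permuting the order of polymorphic columns — the
    same permutation applied to every sequence — which preserves each pair's
    overall similarity while destroying tract structure. The pairwise p-value
    compares the pair's best fragment to its permutation null; the global
    p-value compares the alignment-wide best fragment. Also reported: the
    fraction of pairs with pairwise p < ``alpha`` (under the null ~= alpha,
    excess suggests gene conversion).

    Fewer than 3 polymorphic sites yields a no-test sentinel
    (``tested=False``).
    """
    if n_permutations <= 0:
        raise ValueError("n_permutations must be positive")
    seg = segregating_sites(align)
    S = len(seg.positions)
    empty = pd.DataFrame(
        columns=["seq_i", "seq_j", "start_poly", "end_poly", "start", "end",
                 "length", "score", "pairwise_p"]
    )
    if S < 3:
        return GeneConvResult(empty, float("nan"), float("nan"), S,
                              n_permutations, tested=False)
    arr = np.array([list(s) for s in align.seqs])[:, seg.positions]
    n = len(align)
    pair_idx = list(itertools.combinations(range(n), 2))
    agree = np.array([(arr[i] == arr[j]) for i, j in pair_idx])
    observed = _max_runs(agree)
    rng = np.random.default_rng(seed)
    ge_pair = np.zeros(len(pair_idx), dtype=int)
    ge_global = 0
    obs_global = observed.max()
    for _ in range(n_permutations):
        perm = rng.permutation(S)
        null = _max_runs(agree[:, perm])
        ge_pair += null >= observed
        ge_global += null.max() >= obs_global
    pairwise_p = (1.0 + ge_pair) / (n_permutations + 1.0)
    global_p = (1.0 + ge_global) / (n_permutations + 1.0)
    records = []
    for k, (i, j) in enumerate(pair_idx):
        start_poly, end_poly = _best_run_span(agree[k])
        records.append(
            dict(
                seq_i=align.ids[i],
                seq_j=align.ids[j],
                start_poly=start_poly,
                end_poly=end_poly,
                start=seg.positions[start_poly],
                end=seg.positions[end_poly],
                length=end_poly - start_poly + 1,
                score=int(observed[k]),
                pairwise_p=pairwise_p[k],
            )
        )
    fragments = pd.DataFrame(records)
    frac = float((pairwise_p < alpha).mean())
    return GeneConvResult(fragments, float(global_p), frac, S, n_permutations,
                          tested=True)


def _best_run_span(row: np.ndarray) -> tuple[int, int]:
    """(start, end) polymorphic-site indices of the longest True run."""
    best = run = 0
    best_end = 0
    for k, v in enumerate(row):
        run = run + 1 if v else 0
        if run > best:
            best, best_end = run, k
    if best == 0:
        return 0, 0
    return best_end - best + 1, best_end


# ---------------------------------------------------------------------------
# multilocus linkage disequilibrium


def presence_matrix(genotype_df: pd.DataFrame) -> pd.DataFrame:
    """Individuals × alleles binary matrix from a long genotypes table.

    Expects columns ``individual`` and ``allele_id`` (as written by the
    genotype module).
    """
    mat = pd.crosstab(genotype_df["individual"], genotype_df["allele_id"])
    mat = (mat > 0).astype(int)
    if (mat.sum(axis=1) == 0).any():
        raise ValueError("all-zero individual rows")
    return mat


def ld_randomization(
    matrix: pd.DataFrame | np.ndarray,
    n_randomizations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Standardized index of association r̄d with a column-permutation test.

    Each allele column is a binary "locus"; for every pair of individuals the
    per-locus distance is a 0/1 mismatch. With V_O the variance over
    individual pairs of the summed distance and V_E the sum of per-locus
    distance variances,

        IA  = V_O / V_E - 1
        r̄d = (V_O - V_E) / (2 * sum_{j<k} sqrt(var_j var_k))

    r̄d is 0 in expectation under free assortment and 1 for perfectly
    co-occurring loci, independent of the number of loci. The null permutes
    each column independently across individuals (which fixes every var_j, so
    only V_O varies); the one-tailed p-value uses the add-one convention.
    Monomorphic columns are dropped; fewer than 2 polymorphic columns yields
    the no-test sentinel (``tested=False``).
    """
    if n_randomizations <= 0:
        raise ValueError("n_randomizations must be positive")
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if not np.isin(M, (0, 1)).all():
        raise ValueError("matrix entries must be 0/1")
    freq = M.mean(axis=0)
    poly = (freq > 0) & (freq < 1)
    M = M[:, poly]
    n, L = M.shape
    if L < 2:
        return dict(rbarD=float("nan"), IA=float("nan"), p=float("nan"),
                    n_loci=int(L), tested=False)

    iu, ju = np.triu_indices(n, k=1)

    def pair_stats(mat: np.ndarray) -> float:
        # summed mismatch distance over loci for each individual pair
        mism = mat @ (1 - mat).T
        D = (mism + mism.T)[iu, ju]
        return float(D.var())

    # per-locus pair-distance variances depend only on column sums
    ones = M.sum(axis=0)
    mu = ones * (n - ones) / (n * (n - 1) / 2.0)
    var_j = mu * (1.0 - mu)
    V_E = float(var_j.sum())
    denom = float((np.sqrt(var_j).sum()) ** 2 - var_j.sum())  # 2*sum_{j<k} sqrt
    V_O = pair_stats(M)
    rbar_d = (V_O - V_E) / denom if denom > 0 else float("nan")
    ia = V_O / V_E - 1.0 if V_E > 0 else float("nan")
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_randomizations):
        perm = rng.permuted(M, axis=0)  # each column shuffled independently
        V_O_null = pair_stats(perm)
        null_stat = (V_O_null - V_E) / denom if denom > 0 else float("nan")
        if null_stat >= rbar_d:
            ge += 1
    p = (1.0 + ge) / (n_randomizations + 1.0)
    return dict(rbarD=float(rbar_d), IA=float(ia), p=float(p), n_loci=int(L),
                tested=True)
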