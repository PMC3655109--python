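"""Divergence and selection statistics on allele alignments.

Implements the classical Nei–Gojobori (1986) codon-counting estimate of
synonymous (dS) and nonsynonymous (dN) substitution rates with the
Jukes–Cantor multiple-hit correction, the one-tailed codon Z-test for
positive selection (dN > dS), pairwise nucleotide/amino-acid difference
summaries, and a weighted sum-of-pairs residue variability (1 - conservation,
Valdar-2001 style).

Conventions
-----------
Potential-site counting normalises each codon to 3 sites (mutations to stop
codons count as nonsynonymous), so S + N equals the alignment length for
every pair. Observed differences are averaged over all minimal mutational
pathways between two codons; pathways passing through a stop codon are
excluded (when every pathway would be excluded, all are kept).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

from .alignment import Alignment, STOP_CODONS

_BASES = "ACGT"
_AA = dict(standard_dna_table.forward_table)  # codon -> amino acid, stops absent


def _translate_codon(codon: str) -> str | None:
    return _AA.get(codon)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous potential sites of one codon (sum = 3)."""
    aa = _translate_codon(codon)
    if aa is None:
        raise ValueError(f"stop codon {codon}")
    s_raw = n_raw = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            neighbor = codon[:pos] + b + codon[pos + 1 :]
            if neighbor in STOP_CODONS:
                n_raw += 1
            elif _AA[neighbor] == aa:
                s_raw += 1
            else:
                n_raw += 1
    norm = (s_raw + n_raw) / 3.0
    return s_raw / norm, n_raw / norm


@lru_cache(maxsize=None)
def codon_path_counts(codon1: str, codon2: str) -> tuple[float, float]:
    """Observed (sd, nd) between two codons, averaged over mutational pathways.

    Pathways are the orderings of the differing positions; each step is
    classified synonymous or nonsynonymous. Pathways whose intermediate
    codons are stops are excluded; if that excludes all pathways the full set
    is used instead.
    """
    for c in (codon1, codon2):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c}")
    diff = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = codon1
        steps = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon2:
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((through_stop, steps))
    usable = [steps for through_stop, steps in paths if not through_stop]
    if not usable:
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if _translate_codon(a) == _translate_codon(b):
                sd += 1
            else:
                nd += 1
    return sd / len(usable), nd / len(usable)


def jukes_cantor(p: float) -> float | None:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); None when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return None
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def pairwise_differences(
    align: Alignment, level: str = "nucleotide"
) -> tuple[np.ndarray, dict[str, float]]:
    """Hamming difference counts over all unordered pairs, with a summary.

    ``level="amino_acid"`` translates frame 0 first. The summary (min, max,
    median, mean, sd) is over the strictly-lower-triangle values; sd is the
    sample standard deviation (ddof=1).
    """
    if len(align) < 2:
        raise ValueError("need at least 2 sequences")
    if level == "nucleotide":
        seqs = align.seqs
    elif level == "amino_acid":
        seqs = align.translate()
    else:
        raise ValueError(f"unknown level {level!r}")
    arr = np.array([list(s) for s in seqs])
    n = len(seqs)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        diffs = (arr[i + 1 :] != arr[i]).sum(axis=1)
        mat[i, i + 1 :] = diffs
        mat[i + 1 :, i] = diffs
    vals = mat[np.tril_indices(n, k=-1)]
    summary = {
        "min": int(vals.min()),
        "max": int(vals.max()),
        "median": float(np.median(vals)),
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
    }
    return mat, summary


@dataclass
class DnDsResult:
    dN: float
    dS: float
    var_dN: float
    var_dS: float
    Z: float | None
    p: float | None
    pairs: pd.DataFrame
    n_excluded: int
    variance_method: str

    def to_json_dict(self) -> dict:
        return {
            "dN": self.dN, "dS": self.dS,
            "var_dN": self.var_dN, "var_dS": self.var_dS,
            "Z": self.Z, "p": self.p,
            "n_pairs": int(len(self.pairs)),
            "n_excluded_saturated": self.n_excluded,
            "variance_method": self.variance_method,
        }


def _pair_counts(codons1: list[str], codons2: list[str]) -> tuple[float, ...]:
    S = N = sd = nd = 0.0
    for c1, c2 in zip(codons1, codons2):
        s1, n1 = codon_sites(c1)
        s2, n2 = codon_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        d_s, d_n = codon_path_counts(c1, c2)
        sd += d_s
        nd += d_n
    return S, N, sd, nd


def _proportion_variance(p: float, sites: float) -> float:
    return p * (1.0 - p) / sites if sites > 0 else float("nan")


def _jc_variance(p: float, sites: float) -> float:
    # delta method: var(d) = var(p) / (1 - 4p/3)^2
    return _proportion_variance(p, sites) / (1.0 - 4.0 * p / 3.0) ** 2


def nei_gojobori(
    align: Alignment,
    correction: str = "jukes_cantor",
    variance: str = "analytic",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> DnDsResult:
    """Overall-average Nei–Gojobori dN and dS with a Z-test for dN > dS.

    Per pair, potential sites are the average of the two sequences' site
    counts and observed differences are pathway-averaged; pS = sd/S and
    pN = nd/N are corrected with Jukes–Cantor (``correction="none"`` reports
    the raw proportions). Pairs with a saturated proportion (p >= 3/4) have
    no defined corrected rate and are excluded from the overall means with a
    warning.

    ``variance="analytic"`` uses the delta-method variance of each pairwise
    estimate and treats pairs as independent when averaging — the classical
    overall-average codon Z-test. ``variance="bootstrap"`` resamples codon
    columns and estimates the variance of the mean difference directly,
    which also captures the between-pair covariance induced by shared
    ancestry.
    """
    align.require_codons()
    if len(align) < 2:
        raise ValueError("need at least 2 sequences")
    if correction not in ("jukes_cantor", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    if variance not in ("analytic", "bootstrap"):
        raise ValueError(f"unknown variance {variance!r}")
    codons = align.codons()
    n = len(align)
    rows = []
    for i, j in itertools.combinations(range(n), 2):
        S, N, sd, nd = _pair_counts(codons[i], codons[j])
        pS = sd / S if S else 0.0
        pN = nd / N if N else 0.0
        if correction == "jukes_cantor":
            dS_ij, dN_ij = jukes_cantor(pS), jukes_cantor(pN)
        else:
            dS_ij, dN_ij = pS, pN
        valid = dS_ij is not None and dN_ij is not None
        rows.append(
            dict(seq_i=align.ids[i], seq_j=align.ids[j], S=S, N=N, sd=sd, nd=nd,
                 pS=pS, pN=pN, dS=dS_ij, dN=dN_ij, valid=valid)
        )
    pairs = pd.DataFrame(rows)
    n_excluded = int((~pairs["valid"]).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} saturated pair(s) (p >= 3/4) excluded from means"
        )
    ok = pairs[pairs["valid"]]
    if ok.empty:
        return DnDsResult(float("nan"), float("nan"), float("nan"), float("nan"),
                          None, None, pairs, n_excluded, variance)
    dN = float(ok["dN"].mean())
    dS = float(ok["dS"].mean())
    if variance == "analytic":
        if correction == "jukes_cantor":
            vN = np.array([_jc_variance(r.pN, r.N) for r in ok.itertuples()])
            vS = np.array([_jc_variance(r.pS, r.S) for r in ok.itertuples()])
        else:
            vN = np.array([_proportion_variance(r.pN, r.N) for r in ok.itertuples()])
            vS = np.array([_proportion_variance(r.pS, r.S) for r in ok.itertuples()])
        var_dN = float(vN.sum()) / len(ok) ** 2
        var_dS = float(vS.sum()) / len(ok) ** 2
        denom = var_dN + var_dS
    else:
        var_dN, var_dS, denom = _bootstrap_variance(
            align, correction, n_bootstrap, seed
        )
    if denom > 0:
        Z = (dN - dS) / float(np.sqrt(denom))
        p = float(stats.norm.sf(Z))
    else:
        Z = p = None  # no-test: degenerate variance (e.g. identical sequences)
    return DnDsResult(dN, dS, var_dN, var_dS, Z, p, pairs, n_excluded, variance)


def _bootstrap_variance(
    align: Alignment, correction: str, n_bootstrap: int, seed: int
) -> tuple[float, float, float]:
    """Codon-column bootstrap of (mean dN, mean dS); returns variances and
    the variance of the mean difference."""
    rng = np.random.default_rng(seed)
    codons = align.codons()
    n = len(align)
    L = len(codons[0])
    pair_idx = list(itertools.combinations(range(n), 2))
    P = len(pair_idx)
    sd_arr = np.zeros((P, L))
    nd_arr = np.zeros((P, L))
    S_arr = np.zeros((P, L))
    N_arr = np.zeros((P, L))
    for p_i, (i, j) in enumerate(pair_idx):
        for k in range(L):
            s1, n1 = codon_sites(codons[i][k])
            s2, n2 = codon_sites(codons[j][k])
            S_arr[p_i, k] = (s1 + s2) / 2
            N_arr[p_i, k] = (n1 + n2) / 2
            sd_arr[p_i, k], nd_arr[p_i, k] = codon_path_counts(
                codons[i][k], codons[j][k]
            )
    means_N = np.empty(n_bootstrap)
    means_S = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        cols = rng.integers(L, size=L)
        S = S_arr[:, cols].sum(axis=1)
        N = N_arr[:, cols].sum(axis=1)
        pS = np.divide(sd_arr[:, cols].sum(axis=1), S, out=np.zeros(P), where=S > 0)
        pN = np.divide(nd_arr[:, cols].sum(axis=1), N, out=np.zeros(P), where=N > 0)
        if correction == "jukes_cantor":
            with np.errstate(invalid="ignore"):
                dS = np.where(pS < 0.75, -0.75 * np.log1p(-4 * pS / 3), np.nan)
                dN = np.where(pN < 0.75, -0.75 * np.log1p(-4 * pN / 3), np.nan)
        else:
            dS, dN = pS, pN
        means_S[b] = np.nanmean(dS)
        means_N[b] = np.nanmean(dN)
    diff = means_N - means_S
    return (float(np.nanvar(means_N, ddof=1)), float(np.nanvar(means_S, ddof=1)),
            float(np.nanvar(diff, ddof=1)))


def ztest_positive_selection(result: DnDsResult) -> tuple[float | None, float | None]:
    """One-tailed test of dN > dS from a computed :class:`DnDsResult`.

    Returns (Z, p); (None, None) is the no-test sentinel when the variance is
    degenerate (identical sequences or no valid pairs).
    """
    return result.Z, result.p


# ---------------------------------------------------------------------------
# residue variability (1 - conservation)


def residue_variability(
    align: Alignment,
    similarity: dict[tuple[str, str], float] | None = None,
    weighting: str = "distance",
) -> pd.DataFrame:
    """Per-codon-column variability y = 1 - conservation.

    Conservation of a column is the weighted sum of pairs
    ``sum_{i<j} w_i w_j m(a_i, a_j) / sum_{i<j} w_i w_j`` with residue
    similarity ``m`` in [0, 1] (identity by default) and sequence weights
    proportional to each sequence's mean amino-acid distance from the others
    (so near-duplicate sequences are down-weighted); ``weighting="equal"``
    uses uniform weights. Invariant columns get y = 0; a column of all
    distinct residues under identity similarity and equal weights gets y = 1.

    The output table reports 1-based codon columns plus ``external_site``
    (column + alignment offset) for quoting positions in a reference frame.
    """
    proteins = align.translate()
    n = len(proteins)
    L = len(proteins[0])
    aa = np.array([list(s) for s in proteins])
    if weighting == "distance":
        dist = np.zeros((n, n))
        for i in range(n):
            dist[i] = (aa != aa[i]).mean(axis=1)
        w = dist.sum(axis=1) / max(n - 1, 1)
        if w.sum() == 0:  # all sequences identical
            w = np.ones(n)
    elif weighting == "equal":
        w = np.ones(n)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = w / w.sum()
    iu, ju = np.triu_indices(n, k=1)
    pair_w = w[iu] * w[ju]
    denom = pair_w.sum()
    rows = []
    for col in range(L):
        a = aa[:, col]
        if similarity is None:
            m = (a[iu] == a[ju]).astype(float)
        else:
            m = np.array([similarity.get((x, y), similarity.get((y, x), 0.0))
                          for x, y in zip(a[iu], a[ju])])
        score = float((pair_w * m).sum() / denom)
        rows.append(
            dict(column=col + 1, external_site=col + 1 + align.offset,
                 score=score, y=1.0 - score)
        )
    return pd.DataFrame(rows)
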