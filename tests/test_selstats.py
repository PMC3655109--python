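"""Divergence summaries, Nei-Gojobori dN/dS, Z-test and residue variability.

The dN/dS path is checked two ways: against a test-local brute-force pathway
enumerator (stop-excluding convention) and against Biopython's independent
NG86 implementation on codon pairs where no mutational pathway touches a
stop codon (the two conventions agree exactly there).
"""

import itertools
import warnings

import numpy as np
import pytest
from mhcamplicon import simulate as sim
from mhcamplicon.alignment import Alignment, STOP_CODONS
from mhcamplicon.selstats import (
    codon_path_counts,
    codon_sites,
    jukes_cantor,
    nei_gojobori,
    pairwise_differences,
    residue_variability,
    ztest_positive_selection,
)

from oracles import oracle_path_counts, random_sense_codon  # noqa: E402


class TestPairwiseDifferences:
    def test_identical_pair_is_zero(self):
        aln = Alignment(["a", "b"], ["AAATTT", "AAATTT"])
        mat, summ = pairwise_differences(aln)
        assert mat[0, 1] == 0 and summ["max"] == 0

    def test_synonymous_vs_nonsynonymous_counting(self):
        aln = Alignment(["a", "b"], ["AAATTT", "AAATTA"])
        nt, _ = pairwise_differences(aln, "nucleotide")
        aa, _ = pairwise_differences(aln, "amino_acid")
        assert nt[0, 1] == 1
        assert aa[0, 1] == 1  # Phe -> Leu

    def test_summary_statistics(self):
        # pairwise diffs: (a,b)=1, (b,c)=2, (a,c)=3
        aln = Alignment(["a", "b", "c"], ["AAATTT", "AAATTA", "ACGTTA"])
        _, summ = pairwise_differences(aln)
        assert summ["median"] == 2.0 and summ["mean"] == 2.0
        assert summ["min"] == 1 and summ["max"] == 3

    def test_symmetry_and_zero_diagonal(self):
        aln = sim.evolve_codon_alignment(6, 20, seed=3)
        mat, _ = pairwise_differences(aln)
        assert (mat == mat.T).all() and (np.diag(mat) == 0).all()


class TestNeiGojobori:
    def test_worked_example(self):
        # ATG GCT vs ATG GAT: S = 2/3, N = 16/3, one nonsynonymous difference
        aln = Alignment(["a", "b"], ["ATGGCT", "ATGGAT"])
        res = nei_gojobori(aln)
        pair = res.pairs.iloc[0]
        assert pair.S == pytest.approx(2 / 3)
        assert pair.N == pytest.approx(16 / 3)
        assert (pair.sd, pair.nd) == (0.0, 1.0)
        assert pair.pN == pytest.approx(0.1875)
        assert res.dN == pytest.approx(0.21576155433883568)
        assert res.dS == 0.0

    def test_identical_sequences_yield_no_test(self):
        aln = Alignment(["a", "b"], ["ATGGCT", "ATGGCT"])
        res = nei_gojobori(aln)
        assert res.dN == res.dS == 0.0
        assert ztest_positive_selection(res) == (None, None)

    def test_saturated_pair_excluded_with_warning(self):
        # every codon is four-fold synonymous at position 3 and differs there:
        # pS = 1 >= 3/4, JC undefined
        a = "GGA" * 4
        b = "GGT" + "GGC" + "GGG" + "GGC"
        aln = Alignment(["a", "b"], [a, b])
        with pytest.warns(UserWarning, match="saturated"):
            res = nei_gojobori(aln)
        assert res.n_excluded == 1
        assert np.isnan(res.dN)

    def test_site_counts_sum_to_sequence_length(self):
        rng = np.random.default_rng(8)
        aln = sim.evolve_codon_alignment(5, 25, seed=9)
        res = nei_gojobori(aln)
        for row in res.pairs.itertuples():
            assert row.S + row.N == pytest.approx(aln.length, abs=1e-9)

    def test_pathway_counts_match_bruteforce_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(500):
            c1, c2 = random_sense_codon(rng), random_sense_codon(rng)
            assert codon_path_counts(c1, c2) == pytest.approx(
                oracle_path_counts(c1, c2)
            )

    def test_matches_biopython_on_stop_free_pathways(self):
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        rng = np.random.default_rng(42)
        checked = 0
        while checked < 40:
            codons1 = [random_sense_codon(rng) for _ in range(12)]
            codons2 = [random_sense_codon(rng) for _ in range(12)]
            clean = True
            for c1, c2 in zip(codons1, codons2):
                diff = [i for i in range(3) if c1[i] != c2[i]]
                for order in itertools.permutations(diff):
                    cur = c1
                    for pos in order:
                        cur = cur[:pos] + c2[pos] + cur[pos + 1:]
                        if cur in STOP_CODONS:
                            clean = False
            if not clean:
                continue
            s1, s2 = "".join(codons1), "".join(codons2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dn_bp, ds_bp = cal_dn_ds(CodonSeq(s1), CodonSeq(s2), method="NG86")
            res = nei_gojobori(Alignment(["a", "b"], [s1, s2]))
            if np.isnan(res.dN) or np.isnan(res.dS):
                continue  # saturation conventions differ; not compared
            assert res.dN == pytest.approx(dn_bp, abs=1e-9)
            assert res.dS == pytest.approx(ds_bp, abs=1e-9)
            checked += 1

    def test_positive_selection_power(self):
        hits = 0
        n_reps = 40
        for s in range(n_reps):
            aln = sim.evolve_codon_alignment(
                30, 72, omega=5.0, mutations_per_branch=25, seed=10_000 + s
            )
            res = nei_gojobori(aln)
            if res.p is not None and res.p < 0.05:
                hits += 1
        assert hits >= 0.9 * n_reps

    def test_bootstrap_variance_runs(self):
        aln = sim.evolve_codon_alignment(6, 40, omega=3.0, seed=5)
        res = nei_gojobori(aln, variance="bootstrap", n_bootstrap=200, seed=1)
        assert res.Z is not None and np.isfinite(res.Z)


class TestResidueVariability:
    def test_invariant_column_is_zero(self):
        aln = Alignment(["a", "b", "c"], ["AAATTT"] * 3)
        df = residue_variability(aln)
        assert (df["y"] == 0.0).all()

    def test_all_distinct_residues_equal_weights_is_one(self):
        # column 1: K, N, I, R all distinct
        aln = Alignment(list("abcd"), ["AAA", "AAC", "ATA", "AGA"])
        df = residue_variability(aln, weighting="equal")
        assert df["y"].iloc[0] == pytest.approx(1.0)

    def test_three_one_split_equal_weights(self):
        # column A,A,A,T at the protein level: conservation 3/6
        aln = Alignment(list("abcd"), ["GCT", "GCT", "GCT", "ACT"])
        df = residue_variability(aln, weighting="equal")
        assert df["y"].iloc[0] == pytest.approx(0.5)

    def test_order_invariance(self):
        aln = sim.evolve_codon_alignment(6, 15, seed=2)
        perm = [3, 1, 5, 0, 4, 2]
        shuffled = Alignment([aln.ids[i] for i in perm], [aln.seqs[i] for i in perm])
        a = residue_variability(aln)["y"].to_numpy()
        b = residue_variability(shuffled)["y"].to_numpy()
        assert a == pytest.approx(b)

    def test_distance_weighting_dampens_duplicate_inflation(self):
        # a duplicated sequence can raise y at columns where it carries a
        # minority residue; distance-based weights down-weight the duplicate,
        # so the inflation is never worse than under equal weights
        for s in range(10):
            aln = sim.evolve_codon_alignment(5, 12, seed=100 + s)
            dup = Alignment(aln.ids + ["dup"], aln.seqs + [aln.seqs[0]])
            inflation = {}
            for w in ("distance", "equal"):
                y0 = residue_variability(aln, weighting=w)["y"].to_numpy()
                y1 = residue_variability(dup, weighting=w)["y"].to_numpy()
                inflation[w] = np.maximum(y1 - y0, 0).sum()
            assert inflation["distance"] <= inflation["equal"] + 1e-12

    def test_external_numbering_offset(self):
        aln = Alignment(["a", "b"], ["AAATTT", "AAATTA"], offset=120)
        df = residue_variability(aln)
        assert list(df["external_site"]) == [121, 122]


def test_jukes_cantor_domain():
    assert jukes_cantor(0.0) == 0.0
    assert jukes_cantor(0.25) == pytest.approx(0.30409883108112323)
    assert jukes_cantor(0.75) is None
    with pytest.raises(ValueError):
        jukes_cantor(-0.1)


def test_codon_sites_cached_table_spotchecks():
    assert codon_sites("ATG") == pytest.approx((0.0, 3.0))
    assert codon_sites("GCT") == pytest.approx((1.0, 2.0))
    s, n = codon_sites("GAT")
    assert s == pytest.approx(1 / 3) and n == pytest.approx(8 / 3)
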