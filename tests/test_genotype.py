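"""Demultiplexing, MID-set validation and replicate-validated allele calling."""

import numpy as np
import pytest

from mhcamplicon import genotype as gt
from mhcamplicon.iupac import revcomp


def _mk_reads(variants_rep1: dict, variants_rep2: dict, individual="ind_A"):
    reads = []
    i = 0
    for rep, variants in ((1, variants_rep1), (2, variants_rep2)):
        for seq, count in variants.items():
            for _ in range(count):
                i += 1
                reads.append(gt.DemuxedRead(f"r{i}", individual, rep, seq, "+"))
    return reads


class TestValidateMidSet:
    def test_distant_pair_passes(self):
        ok, bad = gt.validate_mid_set(["AAAAAAAAAA", "TTTTTTTTTT"])
        assert ok and not bad

    def test_distance_six_passes(self):
        ok, bad = gt.validate_mid_set(["AAAAAAAAAA", "AAAATTTTTT"])
        assert ok and not bad

    def test_distance_four_fails_with_pair_reported(self):
        ok, bad = gt.validate_mid_set(["AAAAAAAAAA", "AAAAAATTTT"])
        assert not ok
        assert bad == [("AAAAAAAAAA", "AAAAAATTTT", 4)]

    def test_single_mid_trivially_passes_with_warning(self):
        with pytest.warns(UserWarning):
            ok, _ = gt.validate_mid_set(["AAAAAAAAAA"])
        assert ok


class TestCallAlleles:
    def test_replicate_concordance_and_threshold(self):
        reads = _mk_reads({"A" * 30: 50, "C" * 30: 30, "G" * 30: 4},
                          {"A" * 30: 60, "C" * 30: 25})
        g = gt.call_alleles(reads, expected_length=30)
        assert g.sequences() == {"A" * 30, "C" * 30}
        assert ("G" * 30, "single_replicate") in g.rejected

    def test_threshold_is_strictly_above_ten_percent(self):
        # B pooled 17 vs A pooled 195: 8.7% <= 10% -> rejected
        reads = _mk_reads({"A" * 30: 100, "C" * 30: 9},
                          {"A" * 30: 95, "C" * 30: 8})
        g = gt.call_alleles(reads, expected_length=30)
        assert g.sequences() == {"A" * 30}
        assert ("C" * 30, "below_threshold") in g.rejected

    def test_single_shared_variant_retained(self):
        reads = _mk_reads({"A" * 30: 5}, {"A" * 30: 7})
        g = gt.call_alleles(reads, expected_length=30)
        assert g.sequences() == {"A" * 30}
        calls = g.alleles[0]
        assert (calls.count_rep1, calls.count_rep2) == (5, 7)
        assert calls.pooled_frequency == 1.0

    def test_single_replicate_individual_flagged_ungenotypable(self):
        reads = _mk_reads({"A" * 30: 50}, {})
        g = gt.call_alleles(reads, expected_length=30)
        assert g.ungenotypable and not g.alleles

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        variants = {f"{'A' * 10}{i:02d}".replace("0", "C").replace("1", "G"): 0
                    for i in range(12)}
        keys = list(variants)
        r1 = {k: int(rng.integers(1, 40)) for k in keys}
        r2 = {k: int(rng.integers(1, 40)) for k in keys}
        previous = None
        for thr in (0.0, 0.05, 0.1, 0.2, 0.5, 0.9):
            n = len(gt.call_alleles(_mk_reads(r1, r2), rel_threshold=thr,
                                    expected_length=None).alleles)
            if previous is not None:
                assert n <= previous
            previous = n

    def test_single_replicate_error_never_retained_regardless_of_abundance(self):
        reads = _mk_reads({"A" * 30: 5, "C" * 30: 500}, {"A" * 30: 5})
        g = gt.call_alleles(reads, expected_length=30)
        assert "C" * 30 not in g.sequences()

    def test_mixed_individuals_rejected(self):
        reads = [gt.DemuxedRead("r1", "a", 1, "AAA", "+"),
                 gt.DemuxedRead("r2", "b", 1, "AAA", "+")]
        with pytest.raises(ValueError):
            gt.call_alleles(reads)


class TestScreenAndDemux:
    def test_error_free_roundtrip(self, tiny_dataset):
        pool, genotypes, sheet, truth = tiny_dataset
        reads = [(r.read_id, r.seq) for r in truth.reads]
        demuxed, discards = gt.screen_and_demux(reads, sheet)
        assert len(discards) == 0
        byid = {r.read_id: r for r in truth.reads}
        for d in demuxed:
            assert (d.individual, d.replicate) == (
                byid[d.read_id].individual, byid[d.read_id].replicate
            )

    def test_one_substitution_in_mid_still_assigned(self, tiny_dataset):
        pool, genotypes, sheet, truth = tiny_dataset
        r = truth.reads[0]
        mid = sheet.rows[0].fwd_mid  # not necessarily r's, so look it up
        row = next(x for x in sheet.rows if x.individual == r.individual)
        corrupted = ("T" if row.fwd_mid[0] != "T" else "G") + r.seq[1:]
        demuxed, discards = gt.screen_and_demux([(r.read_id, corrupted)], sheet)
        assert len(demuxed) == 1
        assert demuxed[0].individual == r.individual

    def test_two_primer_errors_discarded_as_no_primer(self, tiny_dataset):
        pool, genotypes, sheet, truth = tiny_dataset
        r = truth.reads[0]
        mlen = sheet.mid_length
        # corrupt two bases inside the forward primer region
        s = list(r.seq)
        s[mlen + 2] = "A" if s[mlen + 2] != "A" else "C"
        s[mlen + 5] = "A" if s[mlen + 5] != "A" else "C"
        demuxed, discards = gt.screen_and_demux([(r.read_id, "".join(s))], sheet)
        assert len(demuxed) == 0
        assert list(discards["reason"]) == ["no_primer"]

    def test_assignment_invariant_to_order_and_orientation(self, tiny_dataset):
        pool, genotypes, sheet, truth = tiny_dataset
        reads = [(r.read_id, r.seq) for r in truth.reads[:30]]
        fwd, _ = gt.screen_and_demux(reads, sheet)
        flipped, _ = gt.screen_and_demux(
            [(rid, revcomp(s)) for rid, s in reversed(reads)], sheet
        )
        key = lambda d: d.read_id
        a = [(d.read_id, d.individual, d.replicate, d.insert) for d in sorted(fwd, key=key)]
        b = [(d.read_id, d.individual, d.replicate, d.insert) for d in sorted(flipped, key=key)]
        assert a == b

    def test_unknown_mid_logged(self, tiny_dataset):
        pool, genotypes, sheet, truth = tiny_dataset
        r = truth.reads[0]
        # replace the forward MID entirely with a foreign barcode
        foreign = "ACGT" * 2 + "CA"
        read = foreign + r.seq[sheet.mid_length:]
        demuxed, discards = gt.screen_and_demux([(r.read_id, read)], sheet)
        reasons = set(discards["reason"])
        assert not demuxed and reasons <= {"unknown_mid", "ambiguous_mid"}


class TestPopulationTable:
    def test_carrier_proportions(self):
        genos = {}
        for i in range(40):
            alleles = [gt.AlleleCall("A" * 9, 5, 5, 0.5)]
            if i == 0:
                alleles.append(gt.AlleleCall("C" * 9, 3, 3, 0.3))
            g = gt.IndividualGenotype(f"ind_{i}", alleles=alleles)
            genos[f"ind_{i}"] = g
        table, id_map = gt.build_population_table(genos)
        by_seq = table.set_index("sequence")
        assert by_seq.loc["C" * 9, "proportion"] == pytest.approx(0.025)
        assert by_seq.loc["A" * 9, "proportion"] == pytest.approx(1.0)
        assert bool(by_seq.loc["C" * 9, "singleton"])

    def test_empty_individuals_excluded_from_denominator(self):
        genos = {
            "a": gt.IndividualGenotype("a", alleles=[gt.AlleleCall("A" * 9, 2, 2, 1.0)]),
            "b": gt.IndividualGenotype("b", alleles=[]),
        }
        with pytest.warns(UserWarning, match="excluded"):
            table, _ = gt.build_population_table(genos)
        assert table["proportion"].iloc[0] == pytest.approx(1.0)

    def test_stable_ids_across_runs(self):
        genos = {
            "a": gt.IndividualGenotype("a", alleles=[gt.AlleleCall("AAATTT", 2, 2, 0.6),
                                                     gt.AlleleCall("CCCTTT", 1, 1, 0.4)]),
            "b": gt.IndividualGenotype("b", alleles=[gt.AlleleCall("AAATTT", 3, 3, 1.0)]),
        }
        t1, m1 = gt.build_population_table(genos)
        t2, m2 = gt.build_population_table(genos)
        assert m1 == m2 and t1.equals(t2)
        assert m1["AAATTT"] == "allele_001"  # most carried gets the first id


def test_sample_sheet_validation():
    rows = [gt.SampleRow("a", "A" * 10, "C" * 10, "G" * 10),
            gt.SampleRow("b", "A" * 10, "T" * 10, "CT" * 5)]
    with pytest.raises(ValueError, match="forward MIDs"):
        gt.SampleSheet(rows)
    with pytest.raises(ValueError, match="length"):
        gt.SampleSheet([gt.SampleRow("a", "A" * 10, "C" * 10, "G" * 9)])


def test_sample_sheet_tsv_roundtrip(tmp_path, tiny_dataset):
    _, _, sheet, _ = tiny_dataset
    p = tmp_path / "sheet.tsv"
    sheet.to_tsv(p)
    again = gt.SampleSheet.from_tsv(p)
    assert again.rows == sheet.rows
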