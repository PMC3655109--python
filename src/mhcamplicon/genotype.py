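"""Demultiplexing and replicate-validated allele calling.

Barcoded amplicon reads are screened for both PCR primers (IUPAC-aware,
allowing one mismatch or indel each), assigned to an (individual, replicate)
by their forward and reverse MID barcodes (again within one edit), and
trimmed to the insert. Per individual, a sequence variant is retained as an
allele only if

1. it appears in BOTH independent PCR replicates, and
2. its pooled read count is above ``rel_threshold`` (default 10%) of the
   individual's most frequent variant.

Criterion 1 suppresses polymerase/sequencing artifacts that arise in a single
reaction; criterion 2 removes recurrent low-frequency errors such as
homopolymer slips. Variant identity is exact string equality after trimming —
the filters, not clustering, remove errors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from .iupac import (
    edit_distance,
    match_iupac,
    prefix_distance,
    revcomp,
    suffix_distance,
)


@dataclass(frozen=True)
class SampleRow:
    individual: str
    fwd_mid: str
    rev_mid_rep1: str
    rev_mid_rep2: str


@dataclass
class SampleSheet:
    """individual ↔ (forward MID, replicate-specific reverse MIDs) mapping."""

    rows: list[SampleRow]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty sample sheet")
        fwd = [r.fwd_mid for r in self.rows]
        if len(set(fwd)) != len(fwd):
            raise ValueError("forward MIDs not unique across individuals")
        pairs = [
            (r.fwd_mid, m) for r in self.rows
            for m in (r.rev_mid_rep1, r.rev_mid_rep2)
        ]
        if len(set(pairs)) != len(pairs):
            raise ValueError("(forward, reverse) MID pairs not unique")
        lengths = {
            len(m) for r in self.rows
            for m in (r.fwd_mid, r.rev_mid_rep1, r.rev_mid_rep2)
        }
        if len(lengths) != 1:
            raise ValueError("MIDs differ in length")

    @property
    def mid_length(self) -> int:
        return len(self.rows[0].fwd_mid)

    def fwd_map(self) -> dict[str, str]:
        return {r.fwd_mid: r.individual for r in self.rows}

    def rev_map(self) -> dict[str, list[tuple[str, int]]]:
        out: dict[str, list[tuple[str, int]]] = {}
        for r in self.rows:
            out.setdefault(r.rev_mid_rep1, []).append((r.individual, 1))
            out.setdefault(r.rev_mid_rep2, []).append((r.individual, 2))
        return out

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = ["individual", "fwd_mid", "rev_mid_rep1", "rev_mid_rep2"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns {missing}")
        return cls([SampleRow(*row) for row in df[required].itertuples(index=False)])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("individual\tfwd_mid\trev_mid_rep1\trev_mid_rep2\n")
            for r in self.rows:
                fh.write(
                    f"{r.individual}\t{r.fwd_mid}\t{r.rev_mid_rep1}\t{r.rev_mid_rep2}\n"
                )


def validate_mid_set(
    mids: list[str], error_budget: int = 2
) -> tuple[bool, list[tuple[str, str, int]]]:
    """Check that a MID set supports unique decoding under ``error_budget`` errors.

    Passes iff the minimum pairwise edit distance is >= ``2*error_budget + 1``
    (default 5), the condition for unique nearest-neighbour decoding when up
    to ``error_budget`` polymerase/sequencing errors hit the barcode. Returns
    (passed, offending pairs with their distances).
    """
    if len({len(m) for m in mids}) > 1:
        raise ValueError("MIDs differ in length")
    if len(mids) < 2:
        warnings.warn("fewer than 2 MIDs: decoding trivially unambiguous")
        return True, []
    need = 2 * error_budget + 1
    offending = [
        (a, b, d)
        for a, b in itertools.combinations(sorted(set(mids)), 2)
        if (d := edit_distance(a, b)) < need
    ]
    return not offending, offending


@dataclass(frozen=True)
class DemuxedRead:
    read_id: str
    individual: str
    replicate: int
    insert: str
    orientation: str  # "+" as emitted, "-" reverse-complemented before parsing


def read_sequences(path, fmt: str | None = None) -> list[tuple[str, str]]:
    """Load reads as (id, sequence) pairs from FASTA or FASTQ."""
    path = str(path)
    if fmt is None:
        fmt = "fastq" if path.endswith(("fastq", "fq")) else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, fmt)]


def _decode_mid(
    window: str,
    candidates: dict[str, object],
    max_edits: int,
    anchored: str,
) -> tuple[str | None, str | None]:
    """Decode one barcode from a read window.

    Returns (mid, None) on success or (None, reason). ``anchored`` is "end"
    for the forward MID (flush against the forward primer's start) and
    "start" for the reverse MID (flush after the reverse primer's end);
    anchoring on the primer-proximal side keeps the decoder robust to indels
    elsewhere in the window.
    """
    dist_fn = suffix_distance if anchored == "end" else prefix_distance
    best: list[str] = []
    best_d = max_edits + 1
    for mid in candidates:
        d = dist_fn(mid, window)
        if d < best_d:
            best, best_d = [mid], d
        elif d == best_d:
            best.append(mid)
    if best_d > max_edits:
        return None, "unknown_mid"
    if len(best) > 1:
        return None, "ambiguous_mid"
    return best[0], None


def screen_and_demux(
    reads: list[tuple[str, str]],
    sheet: SampleSheet,
    primer_fwd: str | None = None,
    primer_rev: str | None = None,
    max_edits: int = 1,
) -> tuple[list[DemuxedRead], pd.DataFrame]:
    """Primer-screen, orient, barcode-assign and trim a batch of reads.

    A read is retained iff both primers are found (each within ``max_edits``,
    IUPAC-aware) in one orientation and both MIDs decode uniquely to a sheet
    entry naming a single (individual, replicate). All failures are logged,
    not raised; the discard log carries one of the reason codes ``no_primer``,
    ``unknown_mid``, ``ambiguous_mid``, ``conflicting_pair``.
    """
    from .simulate import PRIMER_FWD, PRIMER_REV  # default study primers

    primer_fwd = primer_fwd or PRIMER_FWD
    primer_rev = primer_rev or PRIMER_REV
    rev_pattern = revcomp(primer_rev)
    mlen = sheet.mid_length
    fwd_map = sheet.fwd_map()
    rev_map = sheet.rev_map()
    rc_rev_map = {revcomp(m): v for m, v in rev_map.items()}
    demuxed: list[DemuxedRead] = []
    discards: list[tuple[str, str]] = []
    for read_id, seq in reads:
        hit = None
        for orientation in ("+", "-"):
            oriented = seq if orientation == "+" else revcomp(seq)
            f = match_iupac(primer_fwd, oriented, max_edits)
            r = match_iupac(rev_pattern, oriented, max_edits)
            if f and r and f[1][1] <= r[1][0]:
                hit = (orientation, oriented, f[1], r[1])
                break
        if hit is None:
            discards.append((read_id, "no_primer"))
            continue
        orientation, oriented, (f0, f1), (r0, r1) = hit
        fwd_window = oriented[max(0, f0 - mlen - max_edits) : f0]
        fwd_mid, reason = _decode_mid(fwd_window, fwd_map, max_edits, "end")
        if fwd_mid is None:
            discards.append((read_id, reason))
            continue
        rev_window = oriented[r1 : r1 + mlen + max_edits]
        rev_mid_rc, reason = _decode_mid(rev_window, rc_rev_map, max_edits, "start")
        if rev_mid_rc is None:
            discards.append((read_id, reason))
            continue
        individual = fwd_map[fwd_mid]
        matches = [
            rep for ind, rep in rc_rev_map[rev_mid_rc] if ind == individual
        ]
        if len(matches) != 1:
            discards.append((read_id, "conflicting_pair"))
            continue
        demuxed.append(
            DemuxedRead(read_id, individual, matches[0], oriented[f1:r0], orientation)
        )
    log = pd.DataFrame(discards, columns=["read_id", "reason"])
    return demuxed, log


@dataclass
class AlleleCall:
    sequence: str
    count_rep1: int
    count_rep2: int
    pooled_frequency: float


@dataclass
class IndividualGenotype:
    individual: str
    alleles: list[AlleleCall] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)
    ungenotypable: bool = False

    def sequences(self) -> frozenset[str]:
        return frozenset(a.sequence for a in self.alleles)


def call_alleles(
    reads: list[DemuxedRead],
    rel_threshold: float = 0.10,
    reference: str = "prefilter",
    expected_length: int | None = 216,
) -> IndividualGenotype:
    """Apply the two retention criteria to one individual's demuxed reads.

    The frequency criterion compares POOLED counts across both replicates
    against the individual's most frequent variant; with the default
    ``reference="prefilter"`` that reference is the top variant before any
    filtering, with ``"postfilter"`` it is the top variant among those passing
    the replicate-concordance criterion. "Above" is strict (>). No cap is
    placed on the number of alleles and no length/stop filter is applied;
    inserts deviating from ``expected_length`` only trigger a warning.
    """
    individuals = {r.individual for r in reads}
    if len(individuals) != 1:
        raise ValueError(f"reads from {len(individuals)} individuals, expected 1")
    (individual,) = individuals
    if reference not in ("prefilter", "postfilter"):
        raise ValueError("reference must be 'prefilter' or 'postfilter'")
    counts: dict[str, list[int]] = {}
    for r in reads:
        c = counts.setdefault(r.insert, [0, 0])
        c[r.replicate - 1] += 1
    reps_seen = {r.replicate for r in reads}
    if reps_seen != {1, 2}:
        return IndividualGenotype(
            individual,
            rejected=[(v, "ungenotypable") for v in sorted(counts)],
            ungenotypable=True,
        )
    total = len(reads)
    pooled = {v: c[0] + c[1] for v, c in counts.items()}
    if reference == "prefilter":
        top = max(pooled.values())
    else:
        concordant = [p for v, p in pooled.items() if min(counts[v]) >= 1]
        top = max(concordant) if concordant else max(pooled.values())
    result = IndividualGenotype(individual)
    for v in sorted(counts, key=lambda v: (-pooled[v], v)):
        c1, c2 = counts[v]
        if min(c1, c2) < 1:
            result.rejected.append((v, "single_replicate"))
        elif not pooled[v] > rel_threshold * top:
            result.rejected.append((v, "below_threshold"))
        else:
            if expected_length is not None and len(v) != expected_length:
                warnings.warn(
                    f"{individual}: retained allele of length {len(v)} "
                    f"(expected {expected_length})"
                )
            result.alleles.append(AlleleCall(v, c1, c2, pooled[v] / total))
    return result


def genotype_all(
    demuxed: list[DemuxedRead], rel_threshold: float = 0.10, **kwargs
) -> dict[str, IndividualGenotype]:
    by_ind: dict[str, list[DemuxedRead]] = {}
    for r in demuxed:
        by_ind.setdefault(r.individual, []).append(r)
    return {
        ind: call_alleles(by_ind[ind], rel_threshold=rel_threshold, **kwargs)
        for ind in sorted(by_ind)
    }


def build_population_table(
    genotypes: dict[str, IndividualGenotype],
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Summarise the allele pool across genotyped individuals.

    Carrier proportion = carriers / individuals genotyped; individuals with
    zero retained alleles are excluded from the denominator (assay failure
    cannot be distinguished from true absence) with a warning. Returns the
    table and a stable sequence → allele-id mapping (ids ordered by
    descending carrier count, then sequence, so identical input yields
    identical ids).
    """
    genotyped = {
        ind: g for ind, g in genotypes.items() if g.alleles and not g.ungenotypable
    }
    dropped = sorted(set(genotypes) - set(genotyped))
    if dropped:
        warnings.warn(f"excluded from population denominator: {dropped}")
    if not genotyped:
        raise ValueError("no genotyped individuals")
    carriers: dict[str, int] = {}
    for g in genotyped.values():
        for seq in g.sequences():
            carriers[seq] = carriers.get(seq, 0) + 1
    order = sorted(carriers, key=lambda s: (-carriers[s], s))
    id_map = {seq: f"allele_{i + 1:03d}" for i, seq in enumerate(order)}
    n = len(genotyped)
    df = pd.DataFrame(
        {
            "allele_id": [id_map[s] for s in order],
            "sequence": order,
            "carriers": [carriers[s] for s in order],
            "proportion": [carriers[s] / n for s in order],
            "singleton": [carriers[s] == 1 for s in order],
        }
    )
    return df, id_map


def write_genotype_tables(
    genotypes: dict[str, IndividualGenotype],
    outdir,
    discards: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Write genotypes.tsv, alleles.fasta, population.tsv (+ discards.tsv)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pop, id_map = build_population_table(genotypes)
    rows = []
    for ind in sorted(genotypes):
        for a in genotypes[ind].alleles:
            rows.append(
                (ind, id_map[a.sequence], a.count_rep1, a.count_rep2,
                 round(a.pooled_frequency, 6))
            )
    gdf = pd.DataFrame(
        rows,
        columns=["individual", "allele_id", "count_rep1", "count_rep2",
                 "pooled_frequency"],
    )
    gdf.to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
    pop.to_csv(outdir / "population.tsv", sep="\t", index=False)
    with open(outdir / "alleles.fasta", "w") as fh:
        for _, row in pop.iterrows():
            fh.write(f">{row.allele_id}\n{row.sequence}\n")
    if discards is not None:
        discards.to_csv(outdir / "discards.tsv", sep="\t", index=False)
    return gdf


def genotype_accuracy(
    called: dict[str, IndividualGenotype],
    truth_genotypes: dict[str, frozenset[str]],
    pool_sequences: dict[str, str],
) -> dict[str, float]:
    """Accuracy of called allele sequences against the simulator truth.

    Reports both micro-averaged precision/recall (pooled allele counts across
    the population) and the per-individual medians (precision and recall
    computed within each individual, then the median over individuals).
    """
    tp = fp = fn = 0
    per_prec, per_rec = [], []
    for ind, true_ids in truth_genotypes.items():
        true_seqs = {pool_sequences[a] for a in true_ids}
        called_seqs = called[ind].sequences() if ind in called else frozenset()
        tp_i = len(called_seqs & true_seqs)
        fp_i = len(called_seqs - true_seqs)
        fn_i = len(true_seqs - called_seqs)
        tp, fp, fn = tp + tp_i, fp + fp_i, fn + fn_i
        if called_seqs:
            per_prec.append(tp_i / (tp_i + fp_i))
        per_rec.append(tp_i / (tp_i + fn_i))
    import numpy as np

    return {
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "median_individual_precision": float(np.median(per_prec)) if per_prec
        else float("nan"),
        "median_individual_recall": float(np.median(per_rec)) if per_rec
        else float("nan"),
        "tp": tp, "fp": fp, "fn": fn,
    }
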