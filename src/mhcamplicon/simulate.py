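"""Synthetic barcoded amplicon data with a known truth set.

Emulates the study design this package analyses: a pool of ~34 distinct,
stop-free 216-bp MHC alleles; ~40 individuals each carrying 1-4 alleles; two
independent PCR replicates per individual that share a forward barcode (MID)
but differ in reverse MID; and 454-style read errors — per-base substitutions,
+/-1 bp slips in homopolymer tracts, and two-parent PCR chimeras with a
uniform breakpoint. Every emitted read is recorded in a machine-readable
truth set so genotype calls can be scored exactly.

Reads are laid out as::

    [adaptor] fwd_MID  fwd_primer  insert  revcomp(rev_primer)  revcomp(rev_MID) [adaptor]

with degenerate primer positions realised per read (PCR with degenerate
primers yields mixed products). Sequencing adaptors are omitted by default;
an option prepends them for robustness testing. Errors are applied after
assembly, so barcodes and primers are error-prone too.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .alignment import Alignment, has_inframe_stop
from .genotype import SampleSheet, SampleRow
from .iupac import edit_distance, realize, revcomp

# 454 Titanium adaptors and the MHC class I exon-2 primer pair used by the
# study design this simulator emulates.
ADAPTOR_FWD = "CCATCTCATCCCTGCGTGTCTCCGACTCAG"
ADAPTOR_REV = "CCTATCCCCTGTGTGCCTTGGCAGTCTCAG"
PRIMER_FWD = "GATGTATGGGTGTGATCTCCGGG"
PRIMER_REV = "TTCACTCGATGCAGGTCDNCTCCAGGT"

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ReadLayout:
    adaptor_fwd: str = ADAPTOR_FWD
    adaptor_rev: str = ADAPTOR_REV
    mid_length: int = 10
    primer_fwd: str = PRIMER_FWD
    primer_rev: str = PRIMER_REV


@dataclass
class AllelePool:
    """Distinct, equal-length, stop-free allele sequences with stable ids."""

    ids: list[str]
    alleles: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.alleles):
            raise ValueError("ids and alleles differ in length")
        lengths = {len(a) for a in self.alleles}
        if len(lengths) != 1:
            raise ValueError("alleles differ in length")
        (L,) = lengths
        if L % 3 != 0:
            raise ValueError("allele length not divisible by 3")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError("duplicate allele sequences")
        for a in self.alleles:
            if has_inframe_stop(a):
                raise ValueError("in-frame stop codon in allele")

    @property
    def length(self) -> int:
        return len(self.alleles[0])

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.ids, self.alleles))

    def to_alignment(self) -> Alignment:
        return Alignment(list(self.ids), list(self.alleles))


@dataclass
class PopulationDesign:
    n_individuals: int = 40
    # allele-count distribution chosen so the median is 2, matching a
    # population where individuals carry 1-4 copies across up to 4 loci
    copies_per_individual: dict[int, float] = field(
        default_factory=lambda: {1: 0.25, 2: 0.35, 3: 0.25, 4: 0.15}
    )
    # pool sampling weights: "zipf" gives the skewed abundance spectrum seen
    # in real MHC pools (a few common alleles, many singletons)
    allele_frequency_spectrum: str | list[float] = "zipf"
    max_loci: int = 4

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not self.copies_per_individual:
            raise ValueError("empty copies_per_individual")
        for k, p in self.copies_per_individual.items():
            if not 1 <= k <= self.max_loci:
                raise ValueError(f"copy number {k} outside [1, {self.max_loci}]")
            if p < 0:
                raise ValueError("negative probability")
        if sum(self.copies_per_individual.values()) <= 0:
            raise ValueError("copies_per_individual weights sum to 0")

    def weights(self, n_alleles: int) -> np.ndarray:
        if isinstance(self.allele_frequency_spectrum, str):
            if self.allele_frequency_spectrum == "uniform":
                w = np.ones(n_alleles)
            elif self.allele_frequency_spectrum == "zipf":
                w = 1.0 / np.arange(1, n_alleles + 1)
            else:
                raise ValueError(
                    f"unknown spectrum {self.allele_frequency_spectrum!r}"
                )
        else:
            w = np.asarray(self.allele_frequency_spectrum, dtype=float)
            if len(w) != n_alleles:
                raise ValueError("weight vector length != pool size")
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("weights must be nonnegative with positive sum")
        return w / w.sum()


@dataclass
class ErrorModel:
    substitution_rate: float = 0.005
    homopolymer_indel_rate: float = 0.01  # per run of length >= 2, per read
    chimera_rate: float = 0.03
    reads_per_replicate: float = 60.0
    revcomp_fraction: float = 0.0
    include_adaptors: bool = False

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "homopolymer_indel_rate",
                     "chimera_rate", "revcomp_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.reads_per_replicate < 1:
            raise ValueError("reads_per_replicate must be >= 1")


@dataclass
class ReadRecord:
    read_id: str
    individual: str
    replicate: int
    template: str  # allele id, or "chimera:<p1>:<p2>:<breakpoint>"
    n_subs: int
    n_slips: int
    revcomped: bool
    seq: str


@dataclass
class TruthSet:
    genotypes: dict[str, frozenset[str]]
    reads: list[ReadRecord] = field(default_factory=list)

    def write_genotypes(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("individual\tallele_id\n")
            for ind in sorted(self.genotypes):
                for aid in sorted(self.genotypes[ind]):
                    fh.write(f"{ind}\t{aid}\n")

    def write_provenance(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tindividual\treplicate\ttemplate\tevents\n")
            for r in self.reads:
                events = f"sub={r.n_subs};slip={r.n_slips};rc={int(r.revcomped)}"
                fh.write(
                    f"{r.read_id}\t{r.individual}\t{r.replicate}\t{r.template}\t{events}\n"
                )


def _random_stopfree(length: int, rng: np.random.Generator) -> str:
    codons = []
    while len(codons) * 3 < length:
        c = "".join(_BASES[i] for i in rng.integers(4, size=3))
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        alt = [b for b in _BASES if b != out[i]]
        out[i] = alt[rng.integers(3)]
    return "".join(out)


def generate_allele_pool(
    n_alleles: int = 34,
    length: int = 216,
    divergence: float = 0.10,
    seed: int | np.random.Generator = 0,
) -> AllelePool:
    """Simulate a pool of distinct, stop-free alleles.

    Each allele is an independently mutated copy of one random stop-free
    ancestor; ``divergence`` is the per-site mutation probability from that
    ancestor, so two alleles differ at ~``2*divergence*(1-divergence)`` of
    sites. Candidates containing an in-frame stop or duplicating an accepted
    allele are resampled.
    """
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    if length < 3 or length % 3 != 0:
        raise ValueError("length must be a positive multiple of 3")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    if n_alleles > 4 ** min(length, 30):
        raise ValueError("more alleles requested than sequences of this length")
    if divergence == 0.0 and n_alleles > 1:
        raise ValueError("divergence=0 cannot yield distinct alleles")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    ancestor = _random_stopfree(length, rng)
    alleles: list[str] = []
    attempts = 0
    while len(alleles) < n_alleles:
        attempts += 1
        if attempts > 10_000 * n_alleles:
            raise RuntimeError("could not sample a distinct stop-free pool")
        cand = ancestor if n_alleles == 1 and divergence == 0 else _mutate(
            ancestor, divergence, rng
        )
        if has_inframe_stop(cand) or cand in alleles:
            continue
        alleles.append(cand)
    ids = [f"allele_{i + 1:03d}" for i in range(n_alleles)]
    return AllelePool(ids, alleles)


def generate_mid_set(
    n: int,
    length: int = 10,
    min_distance: int = 5,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Greedy random search for barcodes with pairwise edit distance >= 5.

    Minimum pairwise edit distance ``2e+1`` guarantees unique nearest-barcode
    decoding under up to ``e`` errors; the default (5) tolerates two.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    mids: list[str] = []
    attempts = 0
    while len(mids) < n:
        attempts += 1
        if attempts > 20_000 * max(n, 1):
            raise RuntimeError("MID search did not converge; lower min_distance")
        cand = "".join(_BASES[i] for i in rng.integers(4, size=length))
        if all(edit_distance(cand, m) >= min_distance for m in mids):
            mids.append(cand)
    return mids


def make_sample_sheet(
    individuals: list[str], seed: int | np.random.Generator = 0,
    mid_length: int = 10, min_distance: int = 5,
) -> SampleSheet:
    """One forward MID per individual plus two replicate-specific reverse MIDs.

    All MIDs are drawn from a single pool with pairwise edit distance >=
    ``min_distance`` so both the forward and reverse decoders tolerate two
    errors.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    n = len(individuals)
    mids = generate_mid_set(3 * n, length=mid_length, min_distance=min_distance,
                            seed=rng)
    rows = [
        SampleRow(ind, mids[i], mids[n + 2 * i], mids[n + 2 * i + 1])
        for i, ind in enumerate(individuals)
    ]
    return SampleSheet(rows)


def assign_genotypes(
    pool: AllelePool,
    design: PopulationDesign,
    seed: int | np.random.Generator = 0,
) -> dict[str, frozenset[str]]:
    """Draw each individual's allele set (1-4 distinct alleles) from the pool."""
    if not pool.ids:
        raise ValueError("empty pool")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    counts = sorted(design.copies_per_individual)
    probs = np.array([design.copies_per_individual[k] for k in counts], float)
    probs /= probs.sum()
    if max(counts) > len(pool.ids):
        raise ValueError("design requests more copies than pool size")
    weights = design.weights(len(pool.ids))
    genotypes: dict[str, frozenset[str]] = {}
    for i in range(design.n_individuals):
        k = counts[rng.choice(len(counts), p=probs)]
        chosen = rng.choice(len(pool.ids), size=k, replace=False, p=weights)
        genotypes[f"ind_{i + 1:03d}"] = frozenset(pool.ids[j] for j in chosen)
    return genotypes


def _homopolymer_runs(seq: str) -> list[tuple[int, int]]:
    """(start, length) of maximal single-base runs of length >= 2."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= 2:
            runs.append((i, j - i))
        i = j
    return runs


def _apply_slips(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate == 0.0:
        return seq, 0
    runs = _homopolymer_runs(seq)
    n_slips = 0
    # apply right-to-left so earlier run coordinates stay valid
    for start, length in reversed(runs):
        if rng.random() < rate:
            n_slips += 1
            if rng.random() < 0.5:
                seq = seq[:start] + seq[start] + seq[start:]  # +1 duplication
            else:
                seq = seq[:start] + seq[start + 1 :]  # -1 deletion
    return seq, n_slips


def simulate_reads(
    genotypes: dict[str, frozenset[str]],
    pool: AllelePool,
    sheet: SampleSheet,
    errmodel: ErrorModel | None = None,
    layout: ReadLayout | None = None,
    seed: int | np.random.Generator = 0,
) -> TruthSet:
    """Emit barcoded amplicon reads for every individual and replicate.

    Read counts per (individual, replicate) are Poisson around
    ``reads_per_replicate``. A read's template is one of the individual's
    alleles, or — with probability ``chimera_rate`` when the individual
    carries at least two alleles — a two-parent recombinant joined at a
    uniform breakpoint. Substitutions and homopolymer slips are applied to
    the fully assembled read (barcodes and primers included).
    """
    errmodel = errmodel or ErrorModel()
    layout = layout or ReadLayout()
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    by_ind = {r.individual: r for r in sheet.rows}
    missing = sorted(set(genotypes) - set(by_ind))
    if missing:
        raise ValueError(f"individuals missing from sample sheet: {missing}")
    seqs = pool.as_dict()
    truth = TruthSet(genotypes=dict(genotypes))
    counter = 0
    for ind in sorted(genotypes):
        alleles = sorted(genotypes[ind])
        row = by_ind[ind]
        for rep, rev_mid in ((1, row.rev_mid_rep1), (2, row.rev_mid_rep2)):
            n_reads = rng.poisson(errmodel.reads_per_replicate)
            for _ in range(n_reads):
                if len(alleles) >= 2 and rng.random() < errmodel.chimera_rate:
                    i, j = rng.choice(len(alleles), size=2, replace=False)
                    p1, p2 = alleles[i], alleles[j]
                    bp = int(rng.integers(1, pool.length))
                    template = seqs[p1][:bp] + seqs[p2][bp:]
                    desc = f"chimera:{p1}:{p2}:{bp}"
                else:
                    aid = alleles[rng.integers(len(alleles))]
                    template = seqs[aid]
                    desc = aid
                read = (
                    row.fwd_mid
                    + realize(layout.primer_fwd, rng)
                    + template
                    + revcomp(realize(layout.primer_rev, rng))
                    + revcomp(rev_mid)
                )
                if errmodel.include_adaptors:
                    read = layout.adaptor_fwd + read + revcomp(layout.adaptor_rev)
                n_subs = 0
                if errmodel.substitution_rate > 0:
                    before = read
                    read = _mutate(read, errmodel.substitution_rate, rng)
                    n_subs = sum(a != b for a, b in zip(before, read))
                read, n_slips = _apply_slips(
                    read, errmodel.homopolymer_indel_rate, rng
                )
                rc = rng.random() < errmodel.revcomp_fraction
                if rc:
                    read = revcomp(read)
                counter += 1
                truth.reads.append(
                    ReadRecord(
                        read_id=f"read_{counter:06d}",
                        individual=ind,
                        replicate=rep,
                        template=desc,
                        n_subs=n_subs,
                        n_slips=n_slips,
                        revcomped=rc,
                        seq=read,
                    )
                )
    return truth


def write_reads(truth: TruthSet, path, fmt: str = "fasta") -> None:
    """Write simulated reads as FASTA or FASTQ (constant placeholder qualities)."""
    with open(path, "w") as fh:
        for r in truth.reads:
            if fmt == "fasta":
                fh.write(f">{r.read_id}\n{r.seq}\n")
            elif fmt == "fastq":
                fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")
            else:
                raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# codon-level sequence evolution, for selection-statistic calibration


def evolve_codon_alignment(
    n_seqs: int,
    n_codons: int,
    omega: float = 1.0,
    mutations_per_branch: int = 20,
    seed: int | np.random.Generator = 0,
) -> Alignment:
    """Evolve sequences from one ancestor on a star tree with dN/dS ratio ``omega``.

    Point-mutation proposals are accepted with probability min(1, 1/omega) if
    synonymous and min(1, omega) if nonsynonymous, so the realised
    nonsynonymous/synonymous acceptance ratio is omega; proposals creating a
    stop codon are rejected. ``omega=1`` is the neutral null.
    """
    from Bio.Seq import Seq

    if omega <= 0:
        raise ValueError("omega must be > 0")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    anc = _random_stopfree(3 * n_codons, rng)
    p_syn = min(1.0, 1.0 / omega)
    p_non = min(1.0, omega)
    seqs = []
    for s in range(n_seqs):
        cur = list(anc)
        done = 0
        while done < mutations_per_branch:
            pos = int(rng.integers(len(cur)))
            alt = [b for b in _BASES if b != cur[pos]]
            new = alt[rng.integers(3)]
            c0 = pos - pos % 3
            old_codon = "".join(cur[c0 : c0 + 3])
            new_codon = old_codon[: pos - c0] + new + old_codon[pos - c0 + 1 :]
            if new_codon in _STOPS:
                continue
            syn = str(Seq(old_codon).translate()) == str(Seq(new_codon).translate())
            if rng.random() < (p_syn if syn else p_non):
                cur[pos] = new
            done += 1
        seqs.append("".join(cur))
    return Alignment([f"seq_{i + 1}" for i in range(n_seqs)], seqs)


# ---------------------------------------------------------------------------
# configuration


def load_config(path) -> dict:
    """Read a flat key: value configuration file (YAML syntax)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of keys to values")
    return cfg


def dataset_from_config(cfg: dict, seed: int):
    """Build (pool, genotypes, sheet, truth) from a flat config dict."""
    rng = np.random.default_rng(seed)
    pool = generate_allele_pool(
        n_alleles=cfg.get("n_alleles", 34),
        length=cfg.get("length", 216),
        divergence=cfg.get("divergence", 0.10),
        seed=rng,
    )
    design_fields = {f.name for f in dataclasses.fields(PopulationDesign)}
    design = PopulationDesign(
        **{k: v for k, v in cfg.items() if k in design_fields}
    )
    err_fields = {f.name for f in dataclasses.fields(ErrorModel)}
    errmodel = ErrorModel(**{k: v for k, v in cfg.items() if k in err_fields})
    layout_fields = {f.name for f in dataclasses.fields(ReadLayout)}
    layout = ReadLayout(**{k: v for k, v in cfg.items() if k in layout_fields})
    genotypes = assign_genotypes(pool, design, seed=rng)
    sheet = make_sample_sheet(sorted(genotypes), seed=rng,
                              mid_length=layout.mid_length)
    truth = simulate_reads(genotypes, pool, sheet, errmodel, layout, seed=rng)
    return pool, genotypes, sheet, truth
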