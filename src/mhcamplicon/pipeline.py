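"""Study-scale workflows: simulate → genotype → population statistics.

Convenience compositions of the module-level operations, used by the
acceptance machinery and useful interactively: one call simulates a
population at the study design's scale (34 alleles × 216 bp, 40 individuals,
two replicates of ~60 reads), genotypes it blind to the truth, and scores
the recovery.
"""

from __future__ import annotations

import numpy as np

from . import genotype as gt
from . import simulate as sim
from .alignment import Alignment


def study_conditions() -> sim.ErrorModel:
    """The realistic 454-style error model used for recovery benchmarks."""
    return sim.ErrorModel(
        substitution_rate=0.005,
        homopolymer_indel_rate=0.01,
        chimera_rate=0.03,
        reads_per_replicate=60,
    )


def simulate_and_genotype(
    seed: int,
    errmodel: sim.ErrorModel | None = None,
    n_alleles: int = 34,
    length: int = 216,
    n_individuals: int = 40,
):
    """One full simulate → demultiplex → call round trip.

    Returns (pool, truth, calls, accuracy) where accuracy holds
    micro-averaged and per-individual-median precision/recall against the
    simulator's truth set.
    """
    rng = np.random.default_rng(seed)
    pool = sim.generate_allele_pool(n_alleles, length, 0.10, seed=rng)
    design = sim.PopulationDesign(n_individuals=n_individuals)
    genotypes = sim.assign_genotypes(pool, design, seed=rng)
    sheet = sim.make_sample_sheet(sorted(genotypes), seed=rng)
    truth = sim.simulate_reads(
        genotypes, pool, sheet, errmodel or study_conditions(), seed=rng
    )
    reads = [(r.read_id, r.seq) for r in truth.reads]
    demuxed, _ = gt.screen_and_demux(reads, sheet)
    calls = gt.genotype_all(demuxed)
    accuracy = gt.genotype_accuracy(calls, truth.genotypes, pool.as_dict())
    return pool, truth, calls, accuracy


def detected_allele_alignment(calls: dict[str, gt.IndividualGenotype]) -> Alignment:
    """Alignment of detected alleles of the modal length (population table order).

    Alleles whose length differs from the modal length (uncorrected
    homopolymer artifacts) cannot enter a gap-free alignment and are
    dropped.
    """
    import collections
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, _ = gt.build_population_table(calls)
    lengths = collections.Counter(len(s) for s in table["sequence"])
    modal = lengths.most_common(1)[0][0]
    keep = table[table["sequence"].str.len() == modal]
    return Alignment(list(keep["allele_id"]), list(keep["sequence"]))


def deduplicated_alignment_from_fasta(path) -> Alignment:
    """Load an allele FASTA and collapse identical sequences.

    Database deposits may contain one entry per carrier; population-level
    statistics operate on unique allele sequences (first id kept, input
    order preserved).
    """
    aln = Alignment.from_fasta(path)
    seen: dict[str, str] = {}
    for sid, seq in zip(aln.ids, aln.seqs):
        if seq not in seen:
            seen[seq] = sid
    return Alignment([seen[s] for s in seen], list(seen))
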