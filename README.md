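# mhcamplicon

Replicate-validated MHC amplicon genotyping and molecular-evolution
statistics for barcoded 454-style reads.

Genes of the major histocompatibility complex (MHC) are among the most
polymorphic loci in vertebrate genomes: one individual may carry several
divergent alleles across duplicated loci, and population screens must
separate true alleles from PCR and pyrosequencing artifacts (substitutions,
homopolymer slips, chimeras). This package implements the full analysis
chain used for such screens — here modelled on an MHC class I exon-2 survey
of nesting loggerhead sea turtles (*Caretta caretta*) — for researchers in
molecular ecology and conservation genetics:

* **simulate** — barcoded amplicon reads with a known truth set: an allele
  pool (default 34 distinct stop-free 216-bp alleles), individuals carrying
  1–4 alleles, two independent PCR replicates per individual sharing a
  forward MID barcode but differing in reverse MID, and a 454-style error
  model (per-base substitutions, ±1 bp slips in homopolymer runs, two-parent
  chimeras with a uniform breakpoint).
* **genotype** — IUPAC-aware primer screening (one mismatch or indel
  allowed), MID demultiplexing within one edit, trimming, and allele calling
  by the two replicate-validation filters: a variant is an allele only if it
  (1) appears in both PCR replicates and (2) exceeds 10% of the individual's
  most frequent variant (pooled read counts).
* **selstats** — pairwise nucleotide/amino-acid divergence; Nei–Gojobori
  dN/dS with Jukes–Cantor correction and the one-tailed codon Z-test
  `Z = (d̄N − d̄S)/√(Var d̄N + Var d̄S)` for positive selection (dN > dS);
  per-residue variability `y = 1 − conservation` with Valdar-style
  sequence weighting.
* **recomb** — Hudson–Kaplan minimum recombination events (RM) from the
  four-gamete test; a GENECONV-style scan for unusually long shared tracts
  between allele pairs with column-permutation p-values; the standardized
  index of association r̄d on the individuals × alleles presence matrix
  with a column-randomization test.
* **phylo** — Jukes–Cantor distances, Saitou–Nei neighbor joining, and
  nonparametric bootstrap support on unrooted bipartitions, written as
  newick.
* **fitness** — body condition as the residual of curved carapace length
  (CCL) regressed on curved carapace width (CCW), and its quadratic
  association with individual allele count (a negative quadratic term means
  intermediate MHC diversity goes with the best condition).

## Worked example

```python
from mhcamplicon import pipeline
from mhcamplicon.selstats import nei_gojobori, pairwise_differences
from mhcamplicon.recomb import four_gamete_rm

pool, truth, calls, acc = pipeline.simulate_and_genotype(seed=1)
print(f"alleles simulated: {len(pool.ids)}; reads: {len(truth.reads)}")
print(f"micro precision {acc['precision']:.3f}  recall {acc['recall']:.3f}")

aln = pipeline.detected_allele_alignment(calls)
_, nt = pairwise_differences(aln, "nucleotide")
res = nei_gojobori(aln)
rm, _ = four_gamete_rm(aln)
print(f"detected pool: {len(aln)} alleles; nt diffs median {nt['median']:.0f}")
print(f"dN = {res.dN:.4f}, dS = {res.dS:.4f}, Z = {res.Z:.3f}, RM = {rm}")
```

prints

```
alleles simulated: 34; reads: 4743
micro precision 0.947  recall 0.968
detected pool: 29 alleles; nt diffs median 37
dN = 0.1859, dS = 0.2418, Z = -12.843, RM = 7
```

Reading the output: of 4743 simulated reads, demultiplexing and the two
validation filters recover the allele sets with 94.7% precision and 96.8%
recall (the residual false positives are recurrent error variants that pass
both filters by chance; most individuals are called perfectly — the median
per-individual precision and recall are 1.0). The detected pool's neutral
simulated alleles show dN < dS (negative Z: no positive selection was
simulated, none is found) and RM = 7 apparent recombination events arising
from the independent resampling of ancestral polymorphism.

The same workflow is exposed as a CLI:

```
mhcamplicon simulate --n-individuals 40 --seed 1 --outdir sim/
mhcamplicon genotype --reads sim/reads.fasta --sheet sim/sample_sheet.tsv --outdir geno/
mhcamplicon selstats --alignment geno/alleles.fasta --outdir sel/
mhcamplicon recomb   --alignment geno/alleles.fasta --genotypes geno/genotypes.tsv \
                     --permutations 10000 --seed 1 --outdir rec/
mhcamplicon phylo    --alignment geno/alleles.fasta --bootstrap 1000 --seed 1 --out tree.nwk
mhcamplicon fitness  --morphometrics morph.tsv --genotypes geno/genotypes.tsv --out fit.json
```

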