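# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `mhcamplicon`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## The experimental design being modelled

The package targets barcoded deep-amplicon genotyping of a multi-locus,
highly polymorphic gene family (MHC class I exon 2, 216 bp, in a nesting
population of loggerhead sea turtles). Each individual is amplified in two
independent PCR reactions; both share the individual's forward MID barcode
(10 nt) but carry different reverse MIDs, so every read can be traced to one
(individual, replicate). Reads are laid out
`fwd_MID · fwd_primer · insert · revcomp(rev_primer) · revcomp(rev_MID)`;
sequencing adaptors are not part of the parsed read (an option prepends
them for robustness testing). The forward primer is
`GATGTATGGGTGTGATCTCCGGG` and the reverse primer
`TTCACTCGATGCAGGTCDNCTCCAGGT` (IUPAC codes D, N mark degenerate positions,
realised uniformly per simulated read, as degenerate-primer PCR produces
mixed products).

## Simulator

**Allele pool.** A random stop-free ancestor is mutated independently per
allele at per-site probability `divergence` (default 0.10); candidates with
in-frame stops or duplicating an earlier allele are resampled. Defaults —
34 alleles × 216 bp — mirror the study design; at `divergence = 0.10` two
alleles differ at ~18% of sites (≈ 38 bp), the same order as the real
pool's mean of 34 bp.

**Population.** 40 individuals; allele-count distribution
{1: 0.25, 2: 0.35, 3: 0.25, 4: 0.15} (median 2, range 1–4, matching the
observed per-individual diversity over up to four loci); pool sampling
weights default to a Zipf (1/k) spectrum so a few alleles are common and
many are singletons, as in real MHC pools.

**Errors.** Applied to the fully assembled read, so barcodes and primers
are error-prone too: per-base substitutions (default 0.005); homopolymer
slips — each maximal single-base run of length ≥ 2 gains or loses one copy
of the run base with probability 0.01 per read (the dominant 454 error
mode); and PCR chimeras — with probability 0.03 a read's template is a
two-parent recombinant of the individual's own alleles joined at a uniform
breakpoint (individuals carrying a single allele cannot form chimeras).
Read counts per (individual, replicate) are Poisson with mean
`reads_per_replicate` (default 60, giving ≈ 120 usable reads per individual
after filtering, the depth regime of the real study, whose raw pre-filter
depth is unpublished). FASTQ qualities are constant placeholders: the
pipeline never uses them.

**What the simulator omits.** No flowgram-level signal model, no
quality-score realism, no PCR-efficiency bias between alleles, no
run-length dependence of the slip rate. Consequently, recovery results
transfer to real 454 data only to the extent that real error rates resemble
the configured ones; the simulator's i.i.d. substitution model is, if
anything, harsher than real data at equal nominal rate because it
distributes errors uniformly across a 216-bp insert.

## Genotyper

Primers are located by IUPAC-aware edit-distance alignment (edlib),
allowing one mismatch or indel each; reads failing either primer in both
orientations are discarded (`no_primer`). MIDs are decoded from the windows
flanking the primer matches, anchored on the primer-proximal side, again
within one edit; decoding must be unique (`ambiguous_mid`, `unknown_mid`)
and the (forward, reverse) pair must name a single (individual, replicate)
(`conflicting_pair`). The MID decoding radius (1) is deliberately smaller
than what the barcode design supports (2): `validate_mid_set` checks the
pairwise edit distance is ≥ 2·e + 1 = 5, the condition for unique
nearest-neighbour decoding under e = 2 errors.

Variants are exact trimmed insert strings — no clustering, no length or
stop-codon filters. A variant is retained iff (1) it occurs in both
replicates and (2) its pooled count is strictly above `rel_threshold`
(default 0.10) times the individual's most frequent variant (pre-filter
reference; a post-filter reference is available via `reference=
"postfilter"`). Individuals with reads in only one replicate are flagged
ungenotypable; individuals with zero retained alleles are excluded from
population carrier-proportion denominators (assay failure is
indistinguishable from true absence). No cap is placed on alleles per
individual — the observed 1–4 range is a result, not a rule.

**Expected accuracy at the default error model.** Because only ~23% of
216-bp inserts are error-free at these rates, a specific single-error
variant recurs in both replicates by chance a handful of times per
40-individual population, and with top-variant pooled counts of ~15 the
relative threshold cannot exclude pooled-count-2 artifacts. Micro-averaged
precision is therefore ~0.91–0.95 (recall ~0.97), while the median
per-individual precision and recall are 1.0 (three quarters of individuals
are called perfectly). At lower, more typical per-base substitution rates
the same filters are essentially exact.

## Selection statistics

**Nei–Gojobori (1986) with Jukes–Cantor correction.** Per codon, potential
synonymous sites are the fraction of the nine single-base neighbours that
preserve the amino acid, normalised so S + N = 3 per codon (mutations to
stop codons count as nonsynonymous), hence S + N equals the alignment
length for every pair. Observed synonymous/nonsynonymous differences are
averaged over all orderings of the differing positions; orderings passing
through a stop codon are excluded (if all would be, all are kept). With
pS = sd/S and pN = nd/N, the corrected rates are d = −(3/4)·ln(1 − 4p/3);
p ≥ 3/4 is saturation — the pair has no defined rate and is excluded from
the overall means with a warning. Overall dN and dS are means over pairs.

**Z-test.** One-tailed, Z = (d̄N − d̄S)/√(Var d̄N + Var d̄S) against N(0,1).
The default variance is analytic: the delta-method variance of each
pairwise estimate, Var(d) = p(1−p)/(sites·(1−4p/3)²), averaged treating
pairs as independent — the classical overall-average codon Z-test. For
multi-sequence alignments pairs share ancestry and this underestimates the
variance, which inflates |Z|; a codon-column bootstrap
(`variance="bootstrap"`) estimates Var(d̄N − d̄S) directly and accounts for
the covariance. Calibration is therefore demonstrated where the analytic
form's assumptions hold — two-sequence neutral alignments, where the
empirical type-I error is 0.05 — and the power check (ω = 5, 30 sequences,
rejection in ≥ 90% of replicates) uses the default analytic form.

**Residue variability.** Per amino-acid column,
conservation = Σ_{i<j} w_i w_j m(a_i, a_j) / Σ_{i<j} w_i w_j with identity
similarity by default (a similarity-matrix hook is provided) and sequence
weights proportional to each sequence's mean amino-acid distance from the
others, so near-duplicate sequences are down-weighted (Valdar-2001 style);
y = 1 − conservation. Note that down-weighting dampens but does not
eliminate the effect of adding a duplicated sequence on individual columns.
Reported positions add a configurable offset for quoting sites in an
external residue-numbering frame.

## Recombination and linkage

**Hudson–Kaplan RM.** For every ordered pair of biallelic segregating sites
(sites with more than two states are excluded, following DnaSP), the pair
is incompatible iff all four gametes occur, requiring ≥ 1 recombination
event strictly between the sites. Incompatible pairs bound open intervals;
RM is the size of a maximal set of pairwise-disjoint intervals (greedy by
right endpoint), which by interval duality equals the minimum number of
breakpoints piercing every interval. Adjacent incompatible pairs (i, j) and
(j, k) are disjoint as open intervals and both count.

**Gene-conversion scan.** Restricted to polymorphic columns, each unordered
pair's score is its longest run of agreement (exact-match runs, the
behaviour of the reference binary at zero mismatch penalty; no penalised
extension is implemented). The null permutes the order of polymorphic
columns — one permutation per replicate applied to all sequences — which
preserves pairwise similarity while destroying tract structure. P-values
use the add-one convention (never zero, bit-reproducible under a seed);
fewer than 3 polymorphic sites is a no-test sentinel. Two caveats are
inherent to the design: a globally identical pair agrees under every
permutation and necessarily gets p = 1 (the scan has no power there), and
the integer run-length statistic makes p-values conservative at finite
permutation resolution — the null rejection rate at α = 0.05 is ~0.03, not
0.05 (validity, not exactness, is the guarantee).

**Multilocus linkage.** Each detected allele is a binary presence column.
With per-locus pair distances d_j (0/1 mismatch over individual pairs),
V_O the variance of Σ_j d_j over pairs and V_E = Σ_j Var(d_j):
IA = V_O/V_E − 1 and r̄d = (V_O − V_E)/(2 Σ_{j<k} √(Var d_j · Var d_k)).
r̄d is reported as the primary statistic because it does not scale with the
number of loci (it reaches 1 for perfectly co-occurring columns); IA is
reported alongside. The null permutes each column independently; since
column sums are preserved, only V_O varies under permutation. Monomorphic
columns are dropped; fewer than two polymorphic columns is a no-test
sentinel.

## Phylogenetics

Distances are Jukes–Cantor by default (consistent with the substitution
correction used elsewhere in the pipeline) with raw p-distance as an
option. Neighbor joining is the standard Saitou–Nei Q-criterion algorithm;
ties are broken deterministically by the smallest (row, column) pair in the
current matrix order, and negative branch lengths are clamped to zero with
the total deficit recorded on the tree. Bootstrap support resamples
alignment columns with replacement and scores each internal edge of the
point-estimate tree by the percentage of replicate trees containing the
same unrooted bipartition (support attaches to the point tree, not a
consensus). If a bootstrap replicate saturates a pair (p ≥ 3/4), that pair
receives a placeholder distance above the replicate's largest finite
distance, ranked by p-distance among saturated pairs — dropping such
replicates would bias support downward. Newick output carries branch
lengths at six decimals and integer-percent supports in the internal-label
position.

## Fitness proxy

Body condition is the residual of OLS CCL ~ CCW (both in cm, positive);
condition is then regressed on allele count with linear and quadratic terms
(raw counts by default, matching the printed-equation parameterisation;
centering before squaring is an option). Coefficient p-values are
two-sided. The synthetic recovery experiment plants a quadratic coefficient
of −0.194 (the scale reported for the real population) on counts drawn
from the study's 1–4 distribution with unit Gaussian noise and verifies
unbiased recovery over replicates.

## Problem sizes and reproducibility

The default test suite and `scripts/acceptance.py` use study-scale
simulations (40 individuals, ~4 700 reads) for recovery checks; 500
replicates for the Z-test type-I and quadratic-recovery experiments;
200 presence matrices × 199 randomizations for r̄d calibration; 50
alignments × 999 permutations for the gene-conversion null; 200 random
instances for the Hudson–Kaplan oracle comparison and 100 random additive
matrices for neighbor joining. Permutation defaults in the public API are
10 000, as a practitioner would run them. All stochastic components accept
a seed (numpy `default_rng`); identical inputs and seeds reproduce outputs
bit for bit.

## Known limitations

* No chimera-specific detector: chimera suppression relies entirely on the
  two replicate-validation filters.
* No locus assignment or phasing of alleles to the up-to-four loci.
* The gene-conversion scan implements inner (alignment-internal) fragments
  only, without the reference binary's mismatch-penalty machinery or
  BLAST-like global scoring constants.
* Codon-model likelihood machinery (site-model mixtures, empirical-Bayes
  site identification) is out of scope; positive selection is addressed by
  the Nei–Gojobori Z-test and per-residue variability.
* The analytic Z-test variance treats pairwise comparisons as independent;
  use the bootstrap variance for multi-sequence alignments when calibrated
  p-values matter.
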