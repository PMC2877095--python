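# Methods

## Coordinate and unit conventions

All genomic intervals are 0-based half-open; GFF3 input (1-based closed) is
converted at the read boundary. Probe signals are stored and summarized as
log2 intensities per probe, the scale on which tiling-array region means are
conventionally reported. Small-RNA abundances are TPQ (transcripts per
quarter-million reads): count × 250 000 / library size. TPQ is linear in the
count and inverse-linear in library size, so summing per-library TPQ equals
the TPQ of pooled counts only when library sizes are equal — the small-RNA
features therefore keep the libraries separate and sum TPQ, not reads.

## Probe handling

Probes whose cytosine fraction exceeds 0.40 are removed before any signal
statistic (C-rich probes are prone to a sample-amplification artifact). The
0.40 default is a configurable choice; no published cutoff exists for the
artifact, so the threshold errs toward keeping probes (a random 25-mer
exceeds it ~3% of the time). A probe maps "uniquely" when it overlaps
exactly one annotated gene; multi-gene probes are flagged and excluded from
per-gene statistics. Exon vs intron is decided by majority overlap with the
exon/intron unions, ties to exon, since exonic signal is the quantity of
interest.

## Hairpin topology

Signature-to-hairpin matching is exact substring search, forward for sense
reads and of the reverse complement for antisense reads (equivalent to
ungapped perfect BLAST hits; a mismatch-tolerant mode is out of scope).
Antisense matches are reported by the start of the matched region in
sense-hairpin coordinates. Positions are normalized affinely so the miRNA
start is 0 and the miRNA* start is 1.

Hairpin-overlapping probes partition into four regions: miRNA and miRNA*
require ≥11 contiguous nt of overlap with the 21-nt arm site, "other
smRNAs" requires ≥7 nt with a 17-nt MPSS signature site, and everything
else is "no smRNA". When both arm rules fire the larger overlap wins, ties
to miRNA. Region signal cells are compared to the pooled no-smRNA probes
(both orientations) with Student's equal-variance two-tailed t-test; cells
with fewer than two probes report a mean but are flagged not computable.

Averaged strand profiles around an anchor (the miRNA* start for hairpin
loci, the binding site for targets) normalize each locus × sample window to
sum 1 over both strands and then add position-wise across loci and samples.
Window values are the log2 signals clipped below at zero — clipping makes
the weights non-negative and makes "no signal anywhere" a well-defined
skip condition for that locus × sample. Minus-strand loci are flipped so
upstream/downstream are transcript-relative.

## Strand ratio and enrichment

Per gene, the four (orientation × region) cell means are arithmetic means
of per-probe average log2 signal (probes first averaged across samples).
The ratio is (sense_exon/antisense_exon)/(sense_intron/antisense_intron);
when either intron mean is missing or non-positive the exon-only quotient
is used and the formula recorded per gene. The intron-normalized form is
primary because it damps gene-level hybridization offsets that affect both
strands; both forms are invariant to multiplying all stored signals by a
positive constant. Genes without both a sense-exon and an antisense-exon
probe, or with a non-positive antisense exon mean, are excluded with a
recorded reason — downstream statistics never divide by zero.

Ranking is ascending by ratio with ties broken lexicographically by gene
id, so reruns are identical. The low/high halves take ⌊n/2⌋ genes each;
with odd n the median gene is excluded. Class enrichment counts members per
half and tests the minority count with a one-tailed binomial test,
P(X ≤ k) under Binomial(n, ½). Exact summation is the default — the extreme
published tail values are reproduced by exact summation, not the normal
model — and a continuity-corrected normal approximation is provided.
The two agree within a factor of 3 for |z| ≤ 4 once n ≥ 50, and out to
|z| ≤ 6 for n ≥ 500; in the far tail at small n the normal model
underestimates by an order of magnitude or more, which is why exact is the
default. No multiple-testing correction is applied across class rows.

## Feature encoding

Expression topology: 65 bins per strand at 25 bp over transcript-relative
offsets −800…+800 from the site anchor (the site midpoint); bin i covers
[−800+25i, −800+25(i+1)) with the final bin closed at +800 — the only
binning consistent with 130 total features. Per sample, linear-scale
signals (2^log2) are summed per bin, the 130-vector is normalized to sum 1
(window-level, not gene-level), and per-sample vectors are averaged. Pairs
with no probes in the window carry the all-zero vector as a sentinel.

Small-RNA features: per MPSS library (FLR, RDR, SD1, SD2), summed TPQ of
genome-unique signatures overlapping the site ± 800 bp window, both strands
counted (configurable); the fifth feature pools the pyrosequencing
libraries. Absent data is zero.

Duplex energy: the external folding engine is replaced by an in-package
nearest-neighbor dynamic program over the miRNA:target duplex. The model
scores consecutive pairs with the ten canonical Watson-Crick stack free
energies (kcal/mol, 37 °C), a flat −1.0 for any wobble-containing stack,
and an affine penalty (3.0 + 0.5/nt) for internal loops and bulges;
dangling ends are ignored and positive totals clip to zero. The DP is
O(nm) via a prefix-minimum over affine-shifted cell energies. Because the
reported feature is the ratio of the observed duplex energy to the energy
of the same miRNA on its exact reverse complement (percent minimum free
energy), systematic level differences of the parameter table largely
cancel: the ratio is exactly invariant to scaling every parameter by a
positive constant (tested), equals 1 for a perfect complement and 0 when
no stabilizing duplex exists. The 7-uridine pseudo-hairpin linker used for
batch folding is constructed but excluded from the energy sum; its
hairpin-loop contribution is common to numerator and denominator.

Assembly order is fixed and named in the TSV header: 65 sense bins, 65
antisense bins, four MPSS sums, the pooled pyrosequencing sum, energy —
136 columns. No feature standardization is applied before classification.

## Classification

A soft-margin linear-kernel SVM with C = 1 ("default parameters"),
evaluated by stratified ten-fold cross-validation from a seeded shuffling
splitter. Metrics come from the confusion counts pooled over all held-out
predictions (not per-fold averages): accuracy, sensitivity, specificity,
precision; precision is NaN when no positive prediction is made and the
NaN propagates as such. External *MIRNA*-gene sets (all labeled +1, since
hairpin loci are expected to behave like targets at the miRNA\* position)
are scored per group — ancient, new — and in total by a model trained on
the full target/paralog set.

## The synthetic study

The generator emulates the data shapes the analysis assumes, with defaults
chosen once for testability rather than biological realism (the source
observations are qualitative about effect sizes):

* 200 genes over five chromosomes, 1–8 exons (150–400 nt) with 80–300 nt
  introns, intergenic gaps wide enough that no probe can touch two genes;
  class mix: 10% ribosomal, 15% targets, 15% paralogs, 4 × 10% unknown
  star-rating classes, 20% plain protein-coding.
* Five samples (flower, leaf, root, two callus lines) tiled at 25 nt on
  both strands over gene ± 800 bp. Log2 means: sense exon 4.0; antisense
  exon 1.0 by default, 0.4 for ribosomal, 2.5 for targets, 2.0/1.8 for
  low-confidence unknowns, 0.8 for high-confidence unknowns; introns 1.0;
  flanking background 0.2; Gaussian noise σ = 0.25. Target genes and
  ancient hairpins add a ping-pong term of +1.5 log2 units (sense
  downstream, antisense upstream, within ±800 bp of the site — matching
  the feature window so feature recovery is testable); new hairpins get
  only a sense peak at the miRNA* anchor.
* Targets embed a 21-nt site perfectly complementary to a generated miRNA;
  paralogs copy a target layout with the site nucleotides shuffled until
  Hamming distance ≥ 8 from the cognate complement. Hairpin miRNA* arms
  are reverse complements with 1 (ancient) or 4 (new) substitutions.
* Small-RNA counts are negative binomial (size 5, mean 20 per library) in
  libraries FLR, RDR, SD1, SD2 and one pooled pyrosequencing set (P454),
  all sized 250 000 reads; signature lengths ∈ {17, 21, 24}; 8 signatures
  per target, 20 per ancient hairpin, 3 per new hairpin; antisense hairpin
  signature starts 5′ of the miRNA* are weighted 3× (the transitivity
  bias). Only target and hairpin loci produce signatures.
* All randomness flows from one integer seed through numpy seed-sequence
  spawning with fixed stage keys, so identical configs give byte-identical
  outputs on any platform.

What passing tests on this generator do **not** show: robustness to
cross-hybridization, sequence-composition biases (GC, repeats), multi-locus
signatures, overlapping gene models, or effect sizes of real tissue —
the generator has none of these by design.

## Numerical and degenerate-input choices

Binomial tails are computed through scipy's log-space routines to keep
precision in extreme tails. t-tests require ≥2 probes per compared group,
otherwise flagged not computable rather than erroring. Empty enrichment
classes return an empty-result flag. Class-ordinal correlations return NaN
on zero-variance input. Cross-validation refuses single-class inputs and
refolds with an incremented seed (logged) in the rare case a fold is
single-class.

## Problem sizes

The default demo study — 200 genes, 24 hairpins, ~84 gold pairs, ~60 000
probes × 5 samples, ~520 signatures — runs the full pipeline in well under
a minute on one CPU; the statistical calibration suites use 10⁴
permutations. These sizes were chosen as the smallest at which every
directional property is comfortably detectable.
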