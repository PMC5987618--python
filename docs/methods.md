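# Methods

`utr3evo` implements a comparative analysis of 3'UTR length evolution
across nine teleost fishes — five cichlids as a focal clade and four
model teleosts as background — together with a synthetic-data layer
that makes every stage testable against planted ground truth. This note
records the models, the numerical choices, and the places where the
design was genuinely open.

## Feature extraction

Gene models come from GFF3 plus genome FASTA. Coordinates are 1-based
inclusive in all public types (as in the format); interval arithmetic
converts to 0-based half-open internally. A transcript is rejected,
with a logged reason, if its CDS endpoints fall outside its exons, its
spliced CDS length is not a positive multiple of 3, or its chromosome
is absent from the FASTA. The annotated CDS is assumed to include the
stop codon; a transcript whose spliced CDS does not end in TAA/TAG/TGA
is kept but flagged and never chosen as canonical — such models are
treated as degraded or partial. The canonical transcript of a gene is
the stop-codon-bearing isoform with the longest spliced CDS, ties
broken by lexicographically smallest transcript id so selection is
deterministic and order-independent. The 3'UTR is everything in the
spliced mRNA strictly downstream of the stop codon; zero-length UTRs
are retained in summaries (there is no biological reason to discard
them, and dropping them would bias the length distributions). Length
histograms use half-open, lower-inclusive 50-nt bins; quantiles use
linear interpolation (numpy's default).

## Orthology

Input is all-against-all protein similarity in BLAST tabular form.
HSPs with E-value above 1e-10 and self hits are dropped. Per directed
gene pair, HSPs are conjoined by maximum-weight chaining: dynamic
programming over HSPs sorted by query start, where a chain may extend
an HSP only by one starting strictly after it in both query and subject
(overlapping HSPs simply cannot co-occur in a chain; no trimming or
partial credit), and the chain weight is the summed bit scores.
Directions are merged by taking the maximum conjoined score per
unordered pair.

Families are built by average-linkage agglomeration with a merge
quality test, parameterized as weight floor 5 bits, merge ratio 0.33,
size cap 100000. Edges below the floor are removed; absent edges count
as similarity 0 in averages. Repeatedly, the cluster pair with the
highest between-cluster average similarity is merged, provided that
average is at least 0.33 times the internal average similarity of the
smaller cluster (size ties resolved to the cluster holding the
lexicographically smallest member; singletons always merge) and the
union respects the size cap; ties in the average break on the
lexicographically smallest representative pair. The published
clustering tool's exact semantics are not documented anywhere we could
rely on, so this rule is our own, fully specified and tested against a
brute-force re-derivation on small graphs. 1:1 orthologs are families
with exactly one member in every species.

## Repeat content

Repeat annotations (RepeatMasker `.out`, parsed by hand since no
installed library reads that format, or BED) are normalized to 0-based
half-open intervals and merged class-agnostically per chromosome. The
repeat fraction of a feature class is overlap bases divided by feature
bases; the genome-wide fraction uses full chromosome lengths. Feature
intervals come from canonical transcripts only, matching the length
analyses. The per-species genome-vs-3'UTR comparison uses the exact
two-sided Wilcoxon signed-rank test: zero differences dropped (the
classic convention; with nine species and continuous fractions zeros do
not arise), average ranks under ties, and the full sign-assignment null
distribution computed by convolution for n <= 25 (equivalent to 2^n
enumeration, verified against it), with a tie-corrected,
continuity-corrected normal approximation beyond. Two-sided p is
min(1, 2*min(lower tail, upper tail)). With nine species all in the
same direction this gives exactly 2/2^9 = 0.00390625.

## miRNA target scanning

A candidate site requires perfect Watson-Crick complementarity — no
G:U wobble, no gaps — between miRNA positions 2–8 (the 7-nt seed) and
the UTR. Around a confirmed seed match the pairing is extended in both
directions along an ungapped duplex until the first mismatch, and the
site is scored by summing nearest-neighbor Watson-Crick stacking free
energies (Turner 2004 ΔG°37 values, shipped as a package TSV; a
missing stack entry is a fatal configuration error) over adjacent base
pairs of that maximal contiguous helix. Initiation and end terms are
omitted, so a degenerate duplex scores 0.0 and adding pairs can only
lower the energy — the monotonicity the cutoff semantics rely on.
Sites above −20 kcal/mol are discarded. Overlapping sites of the same
miRNA on one UTR are collapsed greedily left to right. This scanner is
a documented, reproducible scheme for strict-seed plus energy
filtering; it shares the cutoff and seed semantics commonly used by
hybrid-alignment tools but is not bit-compatible with any of them. A
seed-only perfect match contributes six stacks (at most about −20 only
for an all-GC seed), so chance seed matches in random sequence
essentially never pass the cutoff without genuine flanking
complementarity — the plant-and-recover tests verify 100% recall of
planted sites and zero background calls on >1e5 nt of seed-scrubbed
sequence.

## Rate estimation on the painted tree

The trait is the raw 3'UTR length in nt (no transform). The
time-calibrated tree must be ultrametric to a relative tolerance of
1e-6 and is painted into two regimes: the focal clade's crown branches
plus its stem branch are "focal", everything else "background".
Assigning the stem to the focal regime keeps one rooted likelihood and
avoids re-rooting the paraphyletic background.

Under two-regime Brownian motion the tip covariance is
V = σ²_f·T_f + σ²_b·T_b, where T_r[i,j] is the branch length in regime
r on the root-to-MRCA(i,j) path. The root state is profiled by
generalized least squares. Writing r = σ²_f/σ²_b, the scale σ²_b also
profiles out analytically, so the fit is a one-dimensional search over
log r: a deterministic 25-point coarse grid on log r ∈ [−13.8, 13.8]
followed by bounded Brent refinement (xatol 1e-8). Estimates at the
ratio bounds, and rates below 1e-9 relative to the trait's scale, are
flagged and excluded from downstream ratio tests (a constant trait
vector is flagged as degenerate outright). A fit takes ~2.5 ms, so the
2041-gene analyses run in seconds.

REML (quadratic form divided by n−1, with the log|1'W⁻¹1| term) is the
default criterion. With nine tips this matters: in 1000-gene
simulations at (σ²_f, σ²_b) = (2, 1), ML recovers the background rate
~23% low (the familiar downward bias from the profiled mean
concentrated in the 4-tip background regime), while REML recovers both
mean rates within ~5%. ML remains available via `reml=False`.

The per-gene statistic is log10(σ̂²_f/σ̂²_b). Users should know its
small-sample behavior, which we measured rather than assumed: with 5
focal tips (plus stem) against 4 background tips, the estimator's
regime degrees of freedom differ, and under equal rates the mean
log10 ratio is not 0 but ≈ +0.04 (SD ≈ 0.57). Consequently the
one-sample t-test of mean log10 ratio = 0 is approximately calibrated
only for modest gene counts — at 10 genes per replicate we measure a
5.5% rejection rate at α = 0.05 over 1000 replicates — and with
thousands of genes it will reject even under the null (t ≈ 7 at
n = 2041). A twofold planted rate difference (mean log10 ratio ≈ 0.33)
dwarfs this bias, and the headline tests pass with p far below 0.001;
but a *marginal* positive result from this statistic on real data
should be interpreted against that +0.04 null offset. The raw ratio
σ̂²_f/σ̂²_b is heavy-tailed (its mean is dominated by the small
background degrees of freedom; ≈2.9 under the null) and is reported
but never averaged in our tests.

The clade length comparison uses log10(mean focal length / mean
background length) per gene, with a one-sample t-test against 0; genes
with a non-positive clade mean are excluded.

An alternative prune-and-fit analysis (fitting each regime's induced
subtree separately) was considered and rejected as the default: it
discards the shared root information and showed no bias advantage.

## Enrichment

The outlier sets are the floor(0.05·n) genes with the highest scores,
boundary ties broken by gene id. (For n = 2041 this gives 102 genes;
no standard rounding rule yields the 101 sometimes quoted for a "top
5%" of 2041, and we use the floor rule rather than reverse-engineer
one.) Over-representation of a term annotated in K of N baseline genes
with k hits in the n-gene test set is the hypergeometric upper tail
P[X ≥ k] — the one-sided Fisher's exact test; depletion is out of
scope. Benjamini-Hochberg at 0.05 is the default correction, chosen as
a standard reproducible procedure. Note that enlarging the baseline
with unannotated genes makes any fixed observed overlap less likely by
chance, so raw p-values can only shrink — baselines should therefore
be restricted to genes that could in principle carry annotations.

## Synthetic data

The generators are pure functions of (config, seed) and write the same
formats the pipeline consumes; every dataset ships its truth table so
tests never re-derive planted values from generator internals.

* **Tree.** The default 9-taxon topology places the five cichlids as a
  clade sister to the two atherinomorphs, with the two otophysans as
  outgroup. Node ages (root 230 Myr, cichlid crown 25 Myr, etc.) are
  configurable round defaults chosen to be order-of-magnitude
  realistic; they are simulation parameters, not estimates.
* **Traits.** Per-gene tip values arise from root value plus
  independent normal branch increments with variance rate × branch
  length. Raw values (possibly negative) feed the rate-fitting tests
  so the model is exact; genome building floors them at 50 nt, since a
  physical UTR cannot be negative and annotation pipelines rarely call
  UTRs shorter than that. An optional multiplicative inflation of
  focal tip values plants a mean-length difference.
* **Genomes.** One chromosome per species; genes alternate strands;
  every third gene carries an intron inside its 3'UTR; decoy isoforms
  (shorter CDS, and stopless) are added at configured rates and must
  never be selected as canonical. The canonical 3'UTR length equals
  the planted value by construction, giving an exact round-trip test.
* **Repeats.** Fixed 50-nt blocks within feature intervals are
  overwritten with copies from a small shipped repeat library at the
  configured per-class density (3'UTR 10%, 5'UTR 8%, CDS 2%,
  intergenic 35% by default, emulating the observed ordering
  CDS < UTR < genome), so coordinates never shift; the 3 nt at each
  end of a CDS are never overwritten, keeping stop codons intact.
  Densities are recovered within ±0.02.
* **miRNA sites.** Backgrounds are first scrubbed of chance seed
  complements, then perfect-complement windows of the miRNA's first 18
  bases are written in; each placement is re-checked for exactness and
  for energy ≤ −20 under the shipped table. miRNAs are generated with
  40–70% GC so a full-length perfect duplex always clears the cutoff.
* **Similarity tables.** Within-family cross-species hits are strong
  and split into two colinear HSPs (exercising the chaining);
  between-family noise is either below the weight floor or above the
  E-value cutoff; optional planted duplications/absences must drop a
  family from the 1:1 set.
* **Term maps.** Terms are assigned independently at a background
  frequency (5%); one term can be planted at 40% within a designated
  top set.

What the synthetic layer does **not** emulate: realistic base
composition or codon usage, repeat family structure beyond coverage
fractions, alignment noise in similarity scores, annotation errors
other than the planted decoys, or any correlation between 3'UTR length
and miRNA site count. Passing tests therefore demonstrate correctness
of the computations and calibration of the statistics under the stated
models — not robustness to the messiness of real genome annotations.

## Problem sizes

The test suite and the acceptance script run everything at sizes a
single CPU handles in seconds to a few minutes: 2041 genes for the
rate and length analyses (matching the ortholog count the statistics
are quoted for), 1000–1200 genes for recovery checks, 1000 replicates
of 10 genes for the type-I calibration, 120 planted families for
orthology, 150 UTRs × 5 sites for target scanning, and a 2000-gene
universe for enrichment.
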