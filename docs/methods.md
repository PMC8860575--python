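# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic generator does and does not emulate, and the
known limitations. All quantities reported in the README are computed by
the code; nothing here states a result the tests or the pipeline do not
themselves produce.

## Labeled-read counting and normalization

A gene's nascent signal is the number of reads overlapping its 3′UTR that
carry at least one T>C conversion on the transcript strand: reference
T→read C inside the UTR for + strand genes, reference A→read G for −
strand genes. Mismatches are resolved from the SAM MD tag; positions in an
optional SNP mask (plain-text VCF, CHROM/POS) and bases below a minimum
base quality (default 27, the common aligner-filter default for this assay
class) are excluded. A read is assigned to the UTR it overlaps by the most
aligned bases; ties break to the lexicographically smaller gene id, so
assignment is deterministic.

Library depth is corrected with median-of-ratios size factors: for sample
s, the median over genes (positive in every sample) of the gene's count
divided by its geometric mean across samples. Two properties matter and
are asserted in tests: (i) factors are defined only up to a common scale —
multiplying one sample's counts by c multiplies its factor *relative to
every other sample* by exactly c, while the absolute factor changes by
c^((m−1)/m) because the per-gene geometric mean absorbs c^(1/m); (ii) the
estimator assumes a majority of genes are non-differential. On matrices
where *every* gene carries planted stage structure the per-time-point
median is biased by module composition (≈10% at the default design), which
is expected behaviour, not an implementation error; planted-factor
recovery is therefore checked on flat-profile matrices. Factors learned on
total-RNA counts are applied unchanged to labeled counts
(cross-normalization), never re-estimated, so the nascent and steady-state
assays stay on one scale.

Because only a minority of labeled reads show a conversion at realistic
per-T conversion efficiency (at 2% efficiency a 50-nt read over a ~30% T
UTR is flagged with probability ≈ 0.4), the observed labeled-read rate
understates the labeled fraction. `estimate_labeled_fraction` inverts

    observed_rate = f · p_labeled + (1 − f) · p_unlabeled

where the flagging probabilities are computed from the reference T content
of each UTR averaged over read start positions, with sequencing errors
(rate/3 toward the conversion base) contributing to both. The standard
error is the binomial SE of the observed rate propagated through the
inversion. The per-T conversion efficiency of this system is not a
published constant; it is a configurable parameter (default 0.02) and the
estimator takes it as an input rather than asserting it.

## SUMO peptide evidence filters

The remnant mass function sums residue (in-chain) monoisotopic masses with
no terminal water, since the remnant is an isopeptide-linked modification;
for DVFQQQTGG this gives 960.4301 Da, C41H60N12O15. An independent mass
library is used as a cross-check in tests, never as the implementation.

Filtering applies four rules in a fixed order, and a rejected record
reports the first rule it fails:

1. **localization** — every SUMO localization probability must exceed 0.75
   (applied to *each* site of a multiply-modified peptide; the strict
   reading, since a single poorly-localized site invalidates the site-level
   claim even when a sibling site is solid);
2. **diagnostic_ions** — at least one remnant diagnostic ion (b2-DV …
   b9-DVFQQQTGG, QQ, FQ, FQQ) observed; the count threshold is
   configurable;
3. **decoy** — decoy-database hits are removed;
4. **delta** — when a SUMO modification sits on the peptide's C-terminal
   lysine and the next residue in the protein is not Asp/Glu, the cleavage
   specificity of Asp-N/Glu-N cannot vouch for the peptide boundary, so a
   delta score > 40 is required. Protein sequences (FASTA) are a required
   input for this rule; a modified K at the protein's C-terminus has no
   following residue, hence does not precede D/E, hence the rule applies.

Multiply-SUMOylated peptides survive only when every one of their sites is
independently evidenced by an accepted singly-modified peptide. Sites are
then mapped as peptide_start + position-in-peptide − 1 (1-based), site
intensity is the sum over supporting peptides per sample, and any protein
with ≥ 1 site is a SUMO target.

**Density** divides the summed site intensity (arbitrary ion-current
units) by the input protein mass per replicate and reports mean ± SD; no
cross-run intensity calibration is attempted. **Equilibrium** classifies
each record into exactly one pool — chains (SUMO-modified peptide on a
SUMO-family protein), target conjugation (SUMO-modified otherwise), free
mature SUMO (SUMO-derived peptide ending QQTGG), immature SUMO-2 /
SUMO-3 (internal QQTGG followed by the respective propeptide tail, VY… or
SASRGSVPTPNRCP…), or internal (anything else SUMO-derived; an
unrecognized post-QQTGG tail falls here with a logged warning) — and
reports intensity fractions per time point, which sum to 1 within 1e-9.
The equilibrium consumes modification-specific peptide evidence before
site collapsing, because free/immature/internal pools are by definition
not site-mapped; the pipeline feeds it the filtered, decoy-free record
set (decoys are search artifacts, not cellular SUMO).

**LFQ summarization** treats zero intensities as missing (the exporter
writes 0 for not-quantified), averages replicates over observed values,
log2-transforms, imputes remaining gaps from a downshifted Gaussian
(downshift 1.8 × SD, width 0.3 × SD — the conventional
low-abundance-imputation defaults) computed from the row's observed
values, falling back to the matrix-wide SD when a row has fewer than two
observations, and finally row Z-scores with the sample SD. Imputation is
seeded; identical seeds give identical matrices.

## Union peaks, differential regions, annotation, profiles

Union peaks follow merge semantics with distance 0: overlapping *and*
bookended intervals coalesce, the result is sorted, disjoint, independent
of input order and idempotent. Coordinates are 0-based half-open
throughout; BED round-trips without shifting.

A read counts for the union region containing its 5′-most aligned base
(reference_start for forward reads, reference_end − 1 for reverse), so a
read spanning two regions is counted once. Counts are normalized with the
same median-of-ratios estimator as the RNA assays.

Time-varying regions are tested with a **negative-binomial LRT stand-in**:
group means per time point versus a grand mean, a single dispersion per
region estimated by method of moments from the full-model residuals, and
2ΔlogL referred to χ² with (time points − 1) degrees of freedom
(Poisson likelihood when the moment estimate collapses to zero;
all-zero regions get p = 1 by convention). This is a transparent
approximation of a GLM-based count LRT, documented as such, with no claim
of numerical equality to any specific GLM implementation. At three
replicates per group its null p-values are conservative in distribution
but the realized false-flag rate at BH ≤ 0.05 plus the fold-change gate
stays at or below nominal (asserted on 500 null regions); with many
replicates (25/group) the null distribution is uniform by KS. The
fold-change contrast for the |FC| > 1.5 gate is max over time points of
the normalized mean divided by the min, with pseudocount 1 — a documented
package convention, since different baselines are defensible.

Annotation classifies each summit with precedence promoter-TSS > exon >
intron > distant promoter > intergenic. The promoter window is −1000..+100
around the TSS (strand-aware) and the distant-promoter window
−10000..−1000, both configurable; the nearest gene is the one minimizing
|summit − TSS| with ties to the smaller gene id. Coverage profiles scale
each library to counts per million mapped reads, sample every `step` nt
(default 10) in a window around each anchor, average over anchors, and
skip anchors within window/2 of a contig edge (logged).

## Modules, correlation, overlap statistics

Row Z-scoring uses the sample SD; constant rows become all-zero and are
flagged rather than propagating NaN. Clustering is k-means (Euclidean,
k-means++ initialization, ≥ 10 restarts keeping the best inertia, fixed
seed); the module count k is a config parameter, with a silhouette scan
over k ∈ [4, 15] as the default when unset. Row ordering for display may
use hierarchical linkage of centroids, but assignment never depends on the
dendrogram. A module's stage is the argmax over stages of the mean
centroid value at that stage's time points (default map d−2→PA, d1/d3→CE,
d7→MA; supplied per assay when time grids differ); exact ties break
PA > CE > MA with a logged warning.

Per-feature Pearson correlation requires ≥ 3 matched time points;
zero-variance profiles yield undefined r, which is excluded from the
10-bin histogram but counted — assigning r = 0 would invent signal for
flat profiles. Bins are equal-width over [−1, 1], right-closed, with
r = −1 in the lowest bin. Hypergeometric over-representation is the exact
upper tail P(X ≥ k); Benjamini–Hochberg is the standard step-up with
enforced monotonicity, stable under input permutation. Both are checked
against brute-force oracles to 1e-12.

## The synthetic study and what passing it shows

The generator's defaults *are* the study conditions: four time points
(d−2, d1, d3, d7) spanning PA→CE→MA, three RNA replicates, mean depth 100
reads/gene, labeled fraction 0.3, conversion efficiency 0.02, sequencing
error 1e-3, negative-binomial dispersion 0.05 with three planted stage
modules at 8× elevation, four-replicate-style peptide intensities
(log-normal, CV ≈ 50%), and peak sets with 4× stage-specific occupancy
over a base of 60 reads/library. Problem sizes (60 genes, ~2000 reads per
fixture, ~200 peptide records, ~60 peak regions) are chosen so the full
suite and pipeline run in seconds to a couple of minutes while leaving
every statistical check well-powered.

Random streams are split per fixture family from the master seed, so
adding a generator does not perturb the others; fixed seeds give
byte-identical FASTA/BED/SAM/TSV outputs. Ground truth lives only in
`truth_`-prefixed sidecar tables. The toy genome uses contigs ≤ 100 kb
and UTRs of 300–1500 bp with ≥ 20% transcript-strand T content (both
strands always represented).

What the simulation does **not** emulate: alignment artifacts
(multi-mappers, soft-clipping, indels — simulated reads are ungapped),
sequencing-quality models, PCR duplicates, isotope envelopes or retention
times, peptide co-modification, chromatin copy-number or GC biases, and
real biological covariance between assays (cross-assay correlations in
the demo reflect shared planted structure only). Passing the suite
demonstrates that the rules engines, estimators and statistics are
implemented correctly and deterministically — not that the defaults match
any particular real dataset's noise regime.

## Degenerate inputs and tie-breaks (summary)

- No gene positive in all samples → size factors raise an estimation error.
- Empty read set → all-zero count table over the declared genes × samples.
- Missing MD tag → evidence error (mismatches unresolvable).
- Multi-UTR overlap → largest overlap, then smaller gene id.
- All-missing LFQ row → dropped with a log entry.
- Zero-intensity time point → excluded from equilibrium with a warning.
- k > rows, step ∤ window, mg ≤ 0, dispersion ≤ 0 → parameter errors.
- Unknown config keys or missing threshold keys → configuration errors
  naming the offending key.
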