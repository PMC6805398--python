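# Methods

## Overview

`equicnv` implements a population-level copy-number-variation (CNV)
analysis for multi-breed SNP-array cohorts, of the kind used to compare
European horse breeds. The pipeline has six computational stages:

1. **reference-relative calling** — per-marker gain/loss calls from the
   log2 ratio of each sample's total signal intensity against the mean
   intensity of a designated reference breed;
2. **segmentation** — per-individual runs of consecutive called markers
   become segment CNVs labelled gain, loss or mixed;
3. **CNVR construction** — segments from the whole cohort that share at
   least 1 bp merge transitively into CNV regions (gain / loss / both);
4. **sharing analysis** — within-breed and within-cluster position
   frequencies, a ≥1%-of-group reporting filter, and unique private
   (position, state) pairs carried by exactly one group;
5. **population structure** — PCA of the B-allele-frequency matrix and
   of a per-CNVR segment-signal matrix;
6. **annotation and validation** — interval intersection with gene/QTL
   tracks, novelty against a published-CNVR catalogue, hypergeometric
   gene-set over/under-representation, and 2^-ΔΔCt qPCR concordance.

Because real multi-breed array intensities of this kind are
owner-restricted, the package ships a synthetic cohort generator whose
planted variants provide ground truth for every stage.

## Calling model

Commercial array-CNV callers do not document their internals, so calling
here is an explicit, testable rule. For sample *i* and marker *m*,

    L(i, m) = log2( x(i, m) / mean_ref(m) )

where `mean_ref(m)` averages the reference breed's intensities at *m*. A
marker is a **gain** when `L ≥ gain_threshold` and a **loss** when
`L ≤ −loss_threshold` (defaults ±0.3, i.e. about 2.46 and 1.62 copies;
ties at the threshold count as calls so the boundary is deterministic).
Reference-breed individuals are compared against their own breed mean
like everyone else — the reference breed can and does carry CNVs.

Two consequences of a reference-relative design are worth noting. Calls
are invariant to any global rescaling of intensities (sample and
reference scale together). And when a deletion is common *within the
reference breed*, the reference mean at those markers drops, which
pushes diploid non-carriers toward apparent gains; with the default
noise level this produces genuine gain calls around shared deletions and
turns the corresponding regions' state to "both". This mirrors the bias
that reference-relative studies report, and the synthetic-recovery tests
score carrier frequencies per state so the effect is visible rather than
hidden.

Thresholding is strictly per marker: no smoothing, no HMM. Multi-marker
evidence is enforced by the segmentation stage, keeping the two stages
orthogonal. Sample-level QC (dish QC, call rate) is represented as an
exclusion list input; raw probe data needed to recompute it never reach
this pipeline.

## Segmentation

Per individual and chromosome, maximal runs of called markers form
segments. Two parameters matter:

* `min_markers` (default 3) — runs with fewer called markers are
  discarded; three probes is the common floor for array CNV calls.
* `max_gap_markers` (default 0) — how many consecutive *uncalled*
  markers may sit inside a run. The default demands strict adjacency;
  the parameter exists because published segmentations differ on whether
  interior uncalled probes are tolerated.

Segment state is gain/loss when all contributing calls agree and
**mixed** otherwise. Segment boundaries are the first and last
contributing marker positions (1-based inclusive) — conservative, and
independent of inter-marker spacing. At `max_gap_markers = 0` the
bookkeeping is exact: every call is either inside exactly one segment or
was discarded with a short run, so marker counts reconcile.

Breed-level summaries report, per individual, the percentage of the
total autosomal genome covered by the union of that individual's
segments (total change, gains, losses; mixed segments count toward both
directions and the total), then mean and sample sd per breed.

## CNV regions

Segments from all individuals and states merge transitively when they
share ≥1 bp. Bookended segments (adjacent, zero shared bases) do not
merge. Region state is gain/loss when all contributing segments agree;
any disagreement — or a single mixed segment — yields **both**. Merging
conserves covered bases (the union length of regions equals the union
length of segments), assigns every segment to exactly one region, and is
order-independent. Carrier counts per breed use the same ≥1 bp rule: an
individual carries a region when any of its segments overlaps it.

Two chromosome-level summaries complement the region table: the average
percentage of each chromosome covered by segments (averaged over *all*
cohort individuals, segment-free ones included) and each chromosome's
share of the segment count per state (sums to 100% per state),
which exposes hot spots irrespective of chromosome size.

## Sharing and private CNVs

For each group (breed, or ancestry cluster) and state, every genome
position is tabulated by carrier count; the group size comes from the
label table, not from the carriers. Positions below `min_fraction`
(default 1%) of the group are dropped from that group's report — the
boundary is inclusive, so 1 carrier in a group of exactly 100 is
retained.

A retained (position, state) is **unique private** to its group iff no
individual of any other group carries that state at that position.
Privacy is decided on *raw carrier presence*, not on the filtered
tables: a single foreign carrier destroys privacy even if it falls below
the other group's 1% filter. Gains and losses are independent — a gain
private to one group and a loss private to another may share a position.

The per-individual average reported next to each group's position total
is `n_positions / group_size`. The alternative reading — the mean of
per-individual call counts — is available as a diagnostic
(`per_individual_call_counts`) and differs whenever carriers stack on
the same positions.

High-frequency private positions (within-group carrier percentage
strictly above `highlight_pct`, default 20%) form the highlight list
used for chromosomal plots.

## Population structure

PCA is computed by singular value decomposition of the centered
(optionally standardised) matrix. The decomposition is made fully
deterministic by orienting each component so that its largest-magnitude
loading is positive. Variance-explained fractions cover all components
and sum to one. Defaults are center=true, scale=false; scaling refuses
zero-variance columns by name rather than silently producing NaNs.

Two feature matrices are supported: the raw BAF matrix (individuals ×
markers), and a segment-signal matrix (individuals × CNVRs) encoding +1
when an individual's overlapping segments in a region are all gains, −1
all losses, 0 otherwise, with the per-segment mean log2 ratio available
as an alternative magnitude-preserving encoding. Segment-PCA separation
of ancestry clusters is only expected when cluster-private variants are
common within their cluster; at low carrier frequency each cluster is a
carrier/non-carrier mixture and no tight per-cluster clouds exist. The
structure-recovery test therefore uses near-fixed (90%) cluster-private
variants, while the frequency-recovery tests use the study-scale cohort
at 30%.

## Annotation and enrichment

Annotation tracks are BED-style, 0-based half-open; CNVR coordinates
(1-based inclusive) are converted at this boundary and nowhere else.
Intersection uses an interval tree and returns all pairs with ≥1 shared
base and their overlap lengths. Novelty against a published-CNVR
catalogue uses the same ≥1 bp rule: a region with zero catalogue
overlaps is novel.

The overrepresentation test is an explicit hypergeometric tail test per
annotation term, in both directions (over: P(X ≥ k); under: P(X ≤ k)),
equivalent to one-sided Fisher exact tests on the 2×2 table (asserted in
the test suite). Bonferroni correction multiplies by the number of
tested terms; Benjamini–Hochberg FDR is reported alongside within each
direction. The term map is a user-supplied two-column gene→term table —
no ontology database is bundled; the analysis scripts generate a
labelled-synthetic one.

## qPCR validation

Relative quantification follows 2^-ΔΔCt: replicate Ct values average per
(sample, region, gene role); ΔCt = mean Ct(target) − mean Ct(reference
gene); ΔΔCt subtracts the ΔCt of a calibrator individual known diploid
at every assayed region, whose own fold change is exactly 1. Assay
efficiency is assumed 100% (exact doubling per cycle), as the method
requires; efficiency-corrected quantification is out of scope.

Fold changes map to copy states through lower-inclusive bins with
default cutpoints 0.25 / 0.75 / 1.25 — centred between the expected
folds 0 (homozygous deletion), 0.5 (one-copy deletion), 1.0 (diploid)
and 1.5 (three copies). Concordance is the fraction of (sample, region)
pairs whose array and qPCR states agree, reported per region and
overall; the overall rate weights regions by their comparison counts.

## Synthetic cohort generator

The generator emulates the design of a large multi-breed array study and
is the source of ground truth for every recovery test.

* **Cohort layout.** Default (`study_config`): 8 breeds in 3 ancestry
  clusters, 602 individuals with breed sizes mirroring a real European
  cohort scaled down ~3×, the largest draught breed (n=103) serving as
  the low-variance reference.
* **Markers.** 5 autosomes × 1,000 uniformly spaced markers over 100 Mb
  (uniform spacing makes coverage expectations analytic; random spacing
  is available). Sex chromosomes are never simulated — the analysis is
  autosome-only and total genome size excludes them.
* **Signal model.** intensity = baseline × (copy/2) ×
  exp(N(0, noise_sd·ln 2)), so log2 ratios are Normal with mean
  log2(copy/2) and sd `noise_sd` (default 0.05; the reference breed gets
  0.03, reflecting its role as the least-variable breed — the true value
  being unknown, it is a parameter, not an assertion). Copy number 0
  would give zero intensity; it is modelled as a residual background of
  0.1 copies (5% of diploid signal) so intensities stay positive.
* **Planted variants.** Each planted CNVR names carrier groups (breeds
  or clusters) and a carrier frequency; group members carry it
  independently with that probability, so realized counts are binomial
  around the design value. Overlapping plants with conflicting copy
  numbers are rejected. The default plants seven regions at frequency
  0.30: two cohort-wide shared (one gain, one loss), three
  breed-private, two cluster-private — the three sharing classes the
  analysis must distinguish.
* **BAF.** Genotypes are drawn from per-breed allele frequencies built
  as a shared base frequency plus cluster-level (sd 0.12) and
  breed-level (sd 0.04) perturbations, giving the BAF-PCA genuine
  nested population structure; BAF = genotype/2 + truncated noise, and
  within deletions BAF collapses to {0, 1} (the heterozygous band
  disappears).
* **Determinism.** One `numpy` Generator seeded once drives all
  randomness; identical configs reproduce bit-identical cohorts.

What the generator does **not** emulate: raw probe-level (CEL) data,
genotype-clustering artefacts, wave/GC bias along the genome, batch
effects, or call-rate-based sample QC (an exclusion list stands in for
the latter). Passing recovery tests therefore demonstrates correctness
of the analysis logic under a clean, well-specified signal model — not
robustness to every artefact of real array data.

## Problem sizes and numerical choices

The study-scale cohort used by the tests and the acceptance script is
602 individuals × 5,000 markers, which exercises every stage in seconds
while leaving the binomial sampling of carriers realistic (sd ≈ 0.05 of
the carrier fraction for a 90-individual breed at frequency 0.3 — the
dominant term in frequency-recovery error; the calling itself is exact
at this noise level, which the truth-table comparison isolates).

Degenerate inputs are handled explicitly rather than by convention:
empty call/segment sets produce empty typed tables (but
chromosome-share and novelty refuse entirely empty inputs, where a
percentage is undefined); single-individual breeds report sd 0; a
zero-variance column under PCA scaling and a non-positive intensity are
errors naming the offending column/individual. All percentage outputs
recompute exactly from their numerator and denominator columns.

## Known limitations

* The log2-threshold caller is deliberately simple; it makes no claim to
  reproduce any commercial caller's segmentation, and headline counts
  from real studies (which depend on restricted raw data and proprietary
  callers) are out of reach by design.
* CNVR construction implements only the ≥1 bp merge rule — no
  reciprocal-overlap definitions.
* No CNV allelic-state genotyping from BAF, no LOH detection, no
  formal population-differentiation statistics (V_ST/F_ST).
* The enrichment stage tests a user-supplied term map; it does not ship
  or reimplement an ontology database.
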