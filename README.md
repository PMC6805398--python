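# equicnv

Copy-number-variation (CNV) diversity analysis for multi-breed SNP-array
cohorts.

Large genotyping-array studies of livestock compare breeds not only by
SNPs but by structural variation: which genomic regions show copy-number
gains or losses, how those regions distribute over chromosomes, and
which variants are *private* to one breed or ancestry cluster — candidate
drivers of breed-specific phenotypes. `equicnv` implements that analysis
as a tested pipeline for cohorts of the kind used in European horse
breed studies, together with a synthetic cohort generator that provides
ground truth where the real genotype data are owner-restricted.

## What it computes

Starting from per-marker total signal intensities and B-allele
frequencies (BAF) of every individual, plus a marker map and breed /
cluster labels:

1. **SNP CNV calls** — per marker and individual,
   `L = log2(intensity / reference_mean)`, where the reference mean is
   the per-marker average over a designated low-variance reference
   breed; gain if `L ≥ 0.3`, loss if `L ≤ −0.3` (configurable).
2. **Segment CNVs** — maximal runs of ≥3 consecutive called markers per
   individual, labelled gain / loss / mixed.
3. **CNV regions (CNVRs)** — cohort-wide transitive merge of segments
   overlapping by ≥1 bp, state gain / loss / both, with per-breed
   carrier counts; plus per-chromosome coverage and segment-share
   summaries.
4. **Private CNVs** — within-group position frequencies with a
   ≥1%-of-group filter; a (position, state) is *unique private* when no
   other group has a single carrier; positions above 20% of their group
   form a highlight list.
5. **Population structure** — PCA (deterministic SVD) of the BAF matrix
   and of an individuals × CNVR segment-signal matrix.
6. **Annotation** — ≥1 bp interval intersection against gene and QTL
   tracks, novelty against a published-CNVR catalogue, and a
   hypergeometric over/under-representation test with Bonferroni and
   Benjamini–Hochberg control.
7. **qPCR validation** — 2^-ΔΔCt fold changes from duplicate Ct values,
   copy-state assignment (cutpoints 0.25 / 0.75 / 1.25), and
   array-vs-qPCR concordance per region and overall.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
built-in synthetic cohort (8 breeds, 3 ancestry clusters, 602
individuals, 5,000 markers, seven planted CNVRs at carrier frequency
0.30, seed 42) and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_call_and_segment.py
python analysis/03_cnv_regions.py
python analysis/04_private_cnvs.py
python analysis/05_population_structure.py
python analysis/06_annotation_enrichment.py
python analysis/07_qpcr_validation.py
```

Step 02 prints the calling and segmentation outcome:

```
6634 SNP CNV calls (3714 gains, 2920 losses)
638 segment CNVs: 365 gain, 273 loss, 0 mixed
```

Step 03 merges those segments into regions — each planted CNVR comes
back as one region at exactly its planted span, e.g.

```
7 CNVRs from 638 segments (4 gain, 2 both, 1 loss)
```

(the two "both" regions are the planted deletions that are common in
the reference breed itself: reference-breed carriers depress the
reference mean there, so diploid non-carriers show apparent gains — a
known bias of reference-relative calling which the pipeline makes
visible rather than hiding).

Step 04 recovers the sharing classes: the Friesian-private gain on
chr1, the Exmoor-private loss on chr3 and the Swedish-Warmblood-private
gain on chr4 appear as unique private to exactly those breeds, each
with all of its marker positions above the 20% highlight threshold, and
the cluster-level run adds the Warmblood-private gain (chr5) and
Draught-private loss (chr2):

```
private positions above 20% of the group:
                                 first      last  n
Exmoor           loss  chr3   20000000  20800000  9
Friesian         gain  chr1   30000000  30800000  9
SwedishWarmblood gain  chr4   40000000  40600000  7
```

Step 07 validates four regions in silico over 80 sample-locus
combinations and reports per-region and overall concordance between
array states and 2^-ΔΔCt states.

The same pipeline runs from the shell on any directory with the same
input layout:

```bash
equicnv simulate --seed 42 --outdir cohort/
equicnv run-all --indir cohort/ --outdir out/ --reference-breed BelgianDraught
```

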