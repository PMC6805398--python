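"""Merge cohort segments into CNV regions and summarize their
chromosomal distribution.

Produces the population-level CNVR table (>=1 bp transitive merge, state
gain/loss/both, per-breed carrier counts), the average percent of each
chromosome covered by segments, and each chromosome's share of the
segment count per state.
"""

from pathlib import Path

from equicnv import io, regions

BASE = Path(__file__).resolve().parent.parent / "results"
COHORT, PIPE = BASE / "cohort", BASE / "pipeline"


def main() -> None:
    labels = io.read_labels(COHORT / "labels.tsv")
    sizes = io.read_chrom_sizes(COHORT / "autosomes.chrom.sizes")
    segs = io.read_segments(PIPE / "segments.tsv")

    res = regions.merge_to_cnvrs(segs, labels)
    coverage = regions.chromosome_coverage(segs, sizes, labels.individuals)
    share = regions.chromosome_segment_share(segs)

    io.write_cnvrs(res.regions, PIPE / "cnvrs.tsv")
    coverage.round(5).to_csv(PIPE / "chromosome_coverage.tsv", sep="\t")
    share.round(3).to_csv(PIPE / "chromosome_segment_share.tsv", sep="\t")

    state_counts = res.regions["state"].value_counts()
    pretty = ", ".join(f"{int(n)} {s}" for s, n in state_counts.items())
    print(f"{len(res.regions)} CNVRs from {len(segs)} segments ({pretty})")
    print(f"lengths {res.regions['length'].min():,} - "
          f"{res.regions['length'].max():,} bp")
    top = coverage["pct_total"].idxmax()
    print(f"\nchromosome with the largest average segment coverage: {top} "
          f"({coverage.loc[top, 'pct_total']:.3f}%)")
    print("\nper-chromosome segment-count share (%):")
    print(share.round(2).to_string())
    print(f"\nwrote CNVRs and chromosome summaries -> {PIPE}")


if __name__ == "__main__":
    main()
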