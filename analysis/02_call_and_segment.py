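"""Call per-marker SNP CNVs against the reference breed and collapse
them into per-individual segment CNVs.

Reports the breed-level descriptive table: mean and sd of the percent of
the autosomal genome changed / gained / lost per individual, the analogue
of the study's first summary table.
"""

from pathlib import Path

from equicnv import calling, io, segments

BASE = Path(__file__).resolve().parent.parent / "results"
COHORT, OUT = BASE / "cohort", BASE / "pipeline"
REFERENCE_BREED = "BelgianDraught"


def main() -> None:
    marker_map = io.read_marker_map(COHORT / "marker_map.tsv")
    matrix = io.read_matrix(COHORT / "cohort")
    labels = io.read_labels(COHORT / "labels.tsv")
    sizes = io.read_chrom_sizes(COHORT / "autosomes.chrom.sizes")

    profile = calling.build_reference_profile(matrix, labels, REFERENCE_BREED)
    calls = calling.call_snp_cnvs(matrix, profile, marker_map)
    segs = segments.build_segments(calls, marker_map)
    part = segments.state_partition(segs)
    table = segments.segment_summary(segs, labels, sizes)

    OUT.mkdir(parents=True, exist_ok=True)
    io.write_calls(calls, OUT / "snp_cnv_calls.tsv")
    io.write_segments(segs, OUT / "segments.tsv")
    io.write_segments_bed(segs, OUT / "segments.bed")
    table.round(4).to_csv(OUT / "segment_summary_by_breed.tsv", sep="\t")

    print(f"reference profile from {profile.n_reference} "
          f"{REFERENCE_BREED} individuals")
    print(f"{len(calls)} SNP CNV calls "
          f"({(calls['state'] == 'gain').sum()} gains, "
          f"{(calls['state'] == 'loss').sum()} losses)")
    print(f"{part['total']} segment CNVs: {part['gain']} gain, "
          f"{part['loss']} loss, {part['mixed']} mixed")
    print("\n% genome changed per individual, by breed "
          "(mean / sd, gain and loss include mixed segments):")
    print(table.round(3).to_string())
    print(f"\nwrote calls, segments and the breed table -> {OUT}")


if __name__ == "__main__":
    main()
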