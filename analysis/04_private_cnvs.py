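"""Within-group SNP CNV position frequencies and unique private CNVs.

Applies the >=1%-of-samples filter per breed and per ancestry cluster,
identifies (position, state) pairs carried by exactly one group, and
lists the high-frequency private positions (>20% of the group) — the
analogues of the study's breed and cluster private-CNV tables and the
chromosomal highlight plots.
"""

from pathlib import Path

from equicnv import io, sharing

BASE = Path(__file__).resolve().parent.parent / "results"
COHORT, PIPE = BASE / "cohort", BASE / "pipeline"
OUT = BASE / "private"
MIN_FRACTION = 0.01
HIGHLIGHT_PCT = 20.0


def main() -> None:
    labels = io.read_labels(COHORT / "labels.tsv")
    calls = io.read_calls(PIPE / "snp_cnv_calls.tsv")
    OUT.mkdir(parents=True, exist_ok=True)

    for level in ("breed", "cluster"):
        rep = sharing.unique_private(calls, labels, level, MIN_FRACTION)
        track, high = sharing.private_chromosome_profile(rep, HIGHLIGHT_PCT)
        rep.summary.round(4).to_csv(
            OUT / f"{level}_private_summary.tsv", sep="\t", index=False
        )
        track.round(3).to_csv(
            OUT / f"{level}_private_track.tsv", sep="\t", index=False
        )
        high.round(3).to_csv(
            OUT / f"{level}_private_highlights.tsv", sep="\t", index=False
        )
        print(f"== {level} level (filter {100 * MIN_FRACTION:.0f}% of group) ==")
        nonzero = rep.summary[rep.summary["n_positions"] > 0]
        print(nonzero.round(3).to_string(index=False))
        if len(high):
            spans = high.groupby(["group", "state", "chrom"]).agg(
                first=("pos", "min"), last=("pos", "max"), n=("pos", "size")
            )
            print(f"\nprivate positions above {HIGHLIGHT_PCT:.0f}% of the group:")
            print(spans.to_string())
        print()
    print(f"wrote frequency tables and highlight lists -> {OUT}")


if __name__ == "__main__":
    main()
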