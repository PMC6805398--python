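"""Population structure: PCA of B-allele frequencies and of the
per-CNVR segment-signal matrix.

The BAF PCA reflects breed allele-frequency divergence (clusters of
related breeds group together); the segment PCA reflects shared copy
number variation. Scatter plots of PC1 vs PC2 colored by breed are
written alongside the score tables.
"""

from pathlib import Path

from equicnv import io, pca, regions

BASE = Path(__file__).resolve().parent.parent / "results"
COHORT, PIPE = BASE / "cohort", BASE / "pipeline"
OUT = BASE / "structure"


def main() -> None:
    matrix = io.read_matrix(COHORT / "cohort")
    labels = io.read_labels(COHORT / "labels.tsv")
    segs = io.read_segments(PIPE / "segments.tsv")
    OUT.mkdir(parents=True, exist_ok=True)

    baf = pca.run_pca(matrix.baf, n_components=10)
    baf.scores.round(5).to_csv(OUT / "baf_pca_scores.tsv", sep="\t")
    pca.plot_pca(baf, labels.group_of("breed"), OUT / "baf_pca.png")
    ve = baf.variance_explained
    print(f"BAF PCA: PC1 {100 * ve[0]:.1f}%, PC2 {100 * ve[1]:.1f}% "
          "of total variance")

    cnvrs = regions.merge_to_cnvrs(segs, labels).regions
    sig = pca.segment_signal_matrix(segs, cnvrs, labels.individuals)
    seg = pca.run_pca(sig, n_components=min(10, sig.shape[1]))
    seg.scores.round(5).to_csv(OUT / "segment_pca_scores.tsv", sep="\t")
    pca.plot_pca(seg, labels.group_of("breed"), OUT / "segment_pca.png")
    sve = seg.variance_explained
    print(f"segment PCA over {sig.shape[1]} CNVRs: PC1 {100 * sve[0]:.1f}%, "
          f"PC2 {100 * sve[1]:.1f}%")

    cluster_of = labels.group_of("cluster")
    means = baf.scores[["PC1", "PC2"]].groupby(
        cluster_of.reindex(baf.scores.index)
    ).mean()
    print("\nBAF PC1-2 cluster centroids:")
    print(means.round(2).to_string())
    print(f"\nwrote scores and plots -> {OUT}")


if __name__ == "__main__":
    main()
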