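"""Annotate CNVRs against synthetic gene / QTL / catalogue tracks and
run the gene-set overrepresentation test.

The three tracks are synthetic stand-ins generated here (real gene
models, QTL databases and published CNVR catalogues are user inputs in
production use): a genome-wide gene track, a QTL track of a few broad
intervals, and a known-CNVR catalogue built to cover part of the
detected regions so that novelty is non-trivial. The gene->term map
plants one term enriched among CNVR genes and one depleted.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from equicnv import annotate, io

BASE = Path(__file__).resolve().parent.parent / "results"
COHORT, PIPE = BASE / "cohort", BASE / "pipeline"
OUT = BASE / "annotation"
SEED = 42


def synthetic_tracks(cnvr_track, sizes, rng):
    genes = []
    gid = 0
    for chrom, size in sizes.items():
        starts = np.sort(rng.choice(size - 50_000, size=400, replace=False))
        for s in starts:
            genes.append((chrom, int(s), int(s + rng.integers(5_000, 50_000)),
                          f"GENE{gid:05d}"))
            gid += 1
    gene_track = pd.DataFrame(genes, columns=["chrom", "start", "end", "name"])

    qtls = []
    for q, chrom in enumerate(sizes.index):
        s = int(rng.integers(0, sizes[chrom] // 2))
        qtls.append((chrom, s, s + int(rng.integers(2_000_000, 10_000_000)),
                     f"QTL{q}"))
    qtl_track = pd.DataFrame(qtls, columns=["chrom", "start", "end", "name"])

    # catalogue covering ~70% of detected regions (jittered), so some
    # regions come out novel
    keep = rng.random(len(cnvr_track)) < 0.7
    catalog = cnvr_track[keep].copy()
    catalog["start"] = np.maximum(
        0, catalog["start"] + rng.integers(-20_000, 20_000, size=len(catalog))
    )
    catalog["end"] = catalog["end"] + rng.integers(
        -20_000, 20_000, size=len(catalog)
    )
    catalog = catalog[catalog["start"] < catalog["end"]]
    catalog["name"] = [f"known_{i}" for i in range(len(catalog))]
    return gene_track, qtl_track, catalog


def synthetic_term_map(cnvr_genes, universe, rng):
    """One term concentrated in CNVR genes, one avoiding them, plus
    background terms annotating random genes."""
    inside = list(cnvr_genes)
    outside = [g for g in universe if g not in cnvr_genes]
    rows = [("TERM_ENRICHED", g) for g in inside[: max(5, len(inside) // 2)]]
    rows += [("TERM_DEPLETED", g)
             for g in rng.choice(outside, size=min(200, len(outside)),
                                 replace=False)]
    for k in range(8):
        rows += [(f"TERM_BG{k}", g)
                 for g in rng.choice(universe, size=60, replace=False)]
    return pd.DataFrame(rows, columns=["term", "gene"])


def main() -> None:
    rng = np.random.default_rng(SEED)
    sizes = io.read_chrom_sizes(COHORT / "autosomes.chrom.sizes")
    cnvrs = pd.read_csv(PIPE / "cnvrs.tsv", sep="\t",
                        dtype={"chrom": str}).set_index("region_id")
    track = annotate.cnvrs_to_track(cnvrs)
    gene_track, qtl_track, catalog = synthetic_tracks(track, sizes, rng)

    OUT.mkdir(parents=True, exist_ok=True)
    io.write_bed(gene_track, OUT / "genes.synthetic.bed")
    io.write_bed(qtl_track, OUT / "qtls.synthetic.bed")
    io.write_bed(catalog, OUT / "known_cnvrs.synthetic.bed")

    frac, per_region, union = annotate.gene_content_summary(track, gene_track)
    print(f"{100 * frac:.1f}% of CNVRs contain >=1 gene "
          f"({len(union)} distinct genes)")

    qtl_hits = annotate.intersect(track, qtl_track)
    print(f"{qtl_hits['name_a'].nunique()} CNVRs overlap a QTL interval")
    qtl_hits.to_csv(OUT / "qtl_overlaps.tsv", sep="\t", index=False)

    flagged, summary = annotate.flag_novel(track, catalog)
    flagged.to_csv(OUT / "novelty_flags.tsv", sep="\t", index=False)
    print(f"{summary['n_novel']} of {summary['n_regions']} CNVRs novel "
          f"({summary['pct_novel']:.1f}%) against the synthetic catalogue")

    universe = list(gene_track["name"])
    term_map = synthetic_term_map(set(union), universe, rng)
    enr = annotate.overrepresentation(union, universe, term_map)
    enr.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
    sig = enr[enr["bonferroni_p"] < 0.05]
    print("\nterms with Bonferroni p < 0.05:")
    print(sig[["term", "direction", "p_value", "bonferroni_p",
               "bh_fdr_q"]].to_string(index=False))
    print(f"\nwrote tracks and annotation tables -> {OUT}")


if __name__ == "__main__":
    main()
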