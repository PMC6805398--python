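"""Interval-track intersection, CNVR novelty and gene-set enrichment.

Annotation tracks (genes, QTLs, published CNVR catalogues) are BED-style:
0-based half-open, so two intervals overlap iff ``a.start < b.end and
b.start < a.end`` and bookended intervals share nothing. CNV regions are
produced 1-based inclusive by the merger and are converted here.

The overrepresentation test is an explicit hypergeometric tail test per
annotation term, in both directions, with Bonferroni control over the
tested terms and Benjamini-Hochberg FDR reported alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cnvrs_to_track",
    "intersect",
    "flag_novel",
    "gene_content_summary",
    "overrepresentation",
]

TRACK_COLUMNS = ["chrom", "start", "end", "name"]


def make_track(df: pd.DataFrame, name_prefix: str = "iv") -> pd.DataFrame:
    """Validate/normalise a BED-style interval table (0-based half-open)."""
    out = df.copy()
    if "name" not in out.columns:
        out["name"] = [f"{name_prefix}_{i}" for i in range(len(out))]
    if len(out) and (out["start"] >= out["end"]).any():
        bad = out.index[(out["start"] >= out["end"])][0]
        raise ValueError(f"interval with start >= end at row {bad}")
    if len(out) and ((out["start"] < 0)).any():
        raise ValueError("negative interval start")
    return out.reset_index(drop=True)


def cnvrs_to_track(regions: pd.DataFrame) -> pd.DataFrame:
    """CNVR table (1-based inclusive) -> BED-style track (0-based half-open)."""
    return pd.DataFrame(
        {
            "chrom": regions["chrom"].to_numpy(),
            "start": regions["start"].to_numpy() - 1,
            "end": regions["end"].to_numpy(),
            "name": regions.index.to_numpy(),
        }
    )


def intersect(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """All (a, b) interval pairs sharing >=1 base, with overlap lengths.

    Both inputs are BED-style tracks; the result is symmetric in content
    (swapping inputs swaps the name columns). Implemented with an interval
    tree over the smaller track.
    """
    a = make_track(a, "a")
    b = make_track(b, "b")
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in b.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), n)
            for s, e, n in zip(grp["start"], grp["end"], grp["name"])
        )
    rows = []
    for row in a.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(int(row.start), int(row.end)):
            rows.append(
                (
                    row.name,
                    hit.data,
                    row.chrom,
                    min(row.end, hit.end) - max(row.start, hit.begin),
                )
            )
    return pd.DataFrame(
        rows, columns=["name_a", "name_b", "chrom", "overlap_bp"]
    ).sort_values(["name_a", "name_b"], kind="stable").reset_index(drop=True)


def flag_novel(
    cnvr_track: pd.DataFrame, known_catalog: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Flag CNVRs with no >=1 bp overlap against a published catalogue.

    Returns the track with a ``novel`` column and a summary dict with
    ``n_regions``, ``n_novel`` and ``pct_novel`` (= 100 * n_novel / n).
    """
    track = make_track(cnvr_track, "cnvr")
    if len(track) == 0:
        raise ValueError("empty CNVR set")
    catalog = make_track(known_catalog, "known")
    hits = intersect(track, catalog)
    known = set(hits["name_a"])
    out = track.assign(novel=~track["name"].isin(known))
    n_novel = int(out["novel"].sum())
    summary = {
        "n_regions": len(out),
        "n_novel": n_novel,
        "pct_novel": 100.0 * n_novel / len(out),
    }
    return out, summary


def gene_content_summary(
    cnvr_track: pd.DataFrame, gene_track: pd.DataFrame
) -> tuple[float, pd.Series, list[str]]:
    """Fraction of CNVRs containing >=1 gene, per-region gene lists and
    the deduplicated union gene list.

    A gene spanning several regions appears in each region's list but
    once in the union.
    """
    track = make_track(cnvr_track, "cnvr")
    hits = intersect(track, make_track(gene_track, "gene"))
    per_region = (
        hits.groupby("name_a")["name_b"]
        .apply(lambda s: sorted(set(s)))
        .reindex(track["name"], fill_value=None)
    )
    per_region = per_region.apply(lambda v: v if isinstance(v, list) else [])
    genic = sum(bool(v) for v in per_region)
    fraction = genic / len(track) if len(track) else 0.0
    union = sorted(set(hits["name_b"]))
    return fraction, per_region, union


def overrepresentation(
    gene_list: list[str],
    universe: list[str],
    term_map: pd.DataFrame,
) -> pd.DataFrame:
    """Hypergeometric over/under-representation of annotation terms.

    Parameters
    ----------
    gene_list
        Genes of interest, a subset of ``universe``.
    universe
        All genes the annotation could have drawn from.
    term_map
        Two columns ``gene``, ``term``; only universe genes count.

    Returns one row per (term, direction) with the hypergeometric tail
    p-value, Bonferroni-adjusted p (over the number of tested terms) and
    Benjamini-Hochberg q within the direction, sorted by p.
    """
    universe_set = set(universe)
    listed = set(gene_list)
    stray = listed - universe_set
    if stray:
        raise ValueError(f"genes not in universe: {sorted(stray)[:5]}")
    tm = term_map[term_map["gene"].isin(universe_set)]
    by_term = tm.groupby("term")["gene"].apply(set)
    N, n = len(universe_set), len(listed)
    rows = []
    for term, genes in by_term.items():
        K = len(genes)
        k = len(genes & listed)
        # over: P(X >= k); under: P(X <= k)
        rows.append((term, K, k, "over", float(hypergeom.sf(k - 1, N, K, n))))
        rows.append((term, K, k, "under", float(hypergeom.cdf(k, N, K, n))))
    out = pd.DataFrame(
        rows,
        columns=["term", "n_universe_with_term", "n_list_with_term",
                 "direction", "p_value"],
    )
    n_terms = len(by_term)
    out["bonferroni_p"] = np.minimum(1.0, out["p_value"] * n_terms)
    out["bh_fdr_q"] = np.nan
    for direction in ("over", "under"):
        mask = out["direction"] == direction
        if mask.any():
            out.loc[mask, "bh_fdr_q"] = multipletests(
                out.loc[mask, "p_value"], method="fdr_bh"
            )[1]
    out["list_size"] = n
    out["universe_size"] = N
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
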