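"""Merge cohort-wide segment CNVs into CNV regions (CNVRs).

Segments from any individual or state that share at least 1 bp are merged
transitively into a single region; bookended segments (zero shared bases)
stay separate. A region is labelled *gain* when every contributing segment
is a gain, *loss* when every one is a loss, and *both* otherwise — a mixed
segment forces *both* on its own.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import CohortLabels
from .segments import _union_length

__all__ = [
    "CnvrResult",
    "merge_to_cnvrs",
    "chromosome_coverage",
    "chromosome_segment_share",
]

REGION_COLUMNS = [
    "region_id",
    "chrom",
    "start",
    "end",
    "state",
    "n_segments",
    "n_individuals",
    "length",
]


class CnvrResult(NamedTuple):
    """Merged regions plus the segment -> region assignment.

    ``regions`` is indexed by ``region_id``; ``segment_region`` maps each
    row index of the input segment table to the region it merged into.
    """

    regions: pd.DataFrame
    segment_region: pd.Series


def _region_state(states: set[str]) -> str:
    if states == {"gain"}:
        return "gain"
    if states == {"loss"}:
        return "loss"
    return "both"


def merge_to_cnvrs(
    segments: pd.DataFrame, labels: CohortLabels | None = None
) -> CnvrResult:
    """Transitive >=1 bp merge of all segments into disjoint CNVRs.

    When ``labels`` is given, the region table gains one carrier-count
    column per breed (``n_<breed>``: individuals with >=1 contributing
    segment) — consistent with the merge rule, a carrier is any individual
    whose segment shares >=1 bp with the region.
    """
    if (segments["start"] > segments["end"]).any():
        raise ValueError("segment with start > end")
    if len(segments) == 0:
        empty = pd.DataFrame(columns=REGION_COLUMNS).set_index("region_id")
        return CnvrResult(empty, pd.Series(dtype=object))

    order = segments.sort_values(
        ["chrom", "start", "end"], kind="stable"
    ).index
    region_of = pd.Series(index=segments.index, dtype=object)
    records = []
    cur = None  # [chrom, start, end, states, seg_rows]
    for idx in order:
        row = segments.loc[idx]
        s, e = int(row["start"]), int(row["end"])
        if cur is not None and row["chrom"] == cur[0] and s <= cur[2]:
            cur[2] = max(cur[2], e)
            cur[3].add(row["state"])
            cur[4].append(idx)
        else:
            if cur is not None:
                records.append(cur)
            cur = [row["chrom"], s, e, {row["state"]}, [idx]]
    records.append(cur)

    rows = []
    for i, (chrom, start, end, states, seg_rows) in enumerate(records):
        rid = f"cnvr_{i + 1:04d}"
        sub = segments.loc[seg_rows]
        rows.append(
            {
                "region_id": rid,
                "chrom": chrom,
                "start": start,
                "end": end,
                "state": _region_state(states),
                "n_segments": len(seg_rows),
                "n_individuals": sub["individual"].nunique(),
                "length": end - start + 1,
            }
        )
        region_of.loc[seg_rows] = rid
    regions = pd.DataFrame(rows).set_index("region_id")

    if labels is not None:
        breed_of = labels.group_of("breed")
        carriers = (
            pd.DataFrame(
                {
                    "region_id": region_of,
                    "breed": segments["individual"].map(breed_of),
                    "individual": segments["individual"],
                }
            )
            .drop_duplicates(["region_id", "breed", "individual"])
            .groupby(["region_id", "breed"])
            .size()
            .unstack(fill_value=0)
        )
        for breed in sorted(breed_of.unique()):
            col = carriers[breed] if breed in carriers else 0
            regions[f"n_{breed}"] = (
                col.reindex(regions.index, fill_value=0)
                if isinstance(col, pd.Series)
                else 0
            )
    return CnvrResult(regions, region_of)


def chromosome_coverage(
    segments: pd.DataFrame,
    chrom_sizes: pd.Series,
    individuals: pd.Index,
) -> pd.DataFrame:
    """Average % of each chromosome covered by segments, per state class.

    For each chromosome and class (total / gain / loss, mixed counting
    toward both directions), the per-individual union coverage is averaged
    over *all* cohort individuals, segment-free ones included.
    """
    unknown = set(segments["chrom"]) - set(chrom_sizes.index)
    if unknown:
        raise ValueError(f"segments on unknown chromosomes: {sorted(unknown)}")
    out = pd.DataFrame(
        0.0,
        index=pd.Index(chrom_sizes.index, name="chrom"),
        columns=["pct_total", "pct_gain", "pct_loss"],
    )
    n = len(individuals)
    if n == 0:
        raise ValueError("empty cohort")
    classes = {
        "pct_total": None,
        "pct_gain": ("gain", "mixed"),
        "pct_loss": ("loss", "mixed"),
    }
    for col, states in classes.items():
        sub = segments if states is None else segments[
            segments["state"].isin(states)
        ]
        for (chrom, _ind), grp in sub.groupby(["chrom", "individual"]):
            cov = _union_length(grp["start"].to_numpy(), grp["end"].to_numpy())
            out.loc[chrom, col] += 100.0 * cov / chrom_sizes[chrom] / n
    return out


def chromosome_segment_share(segments: pd.DataFrame) -> pd.DataFrame:
    """% of segment count per chromosome, separately per state.

    Shares sum to 100 within each state that has any segments, making
    chromosome hot spots visible regardless of chromosome size.
    """
    if len(segments) == 0:
        raise ValueError("no segments to summarize")
    counts = (
        segments.groupby(["chrom", "state"]).size().unstack(fill_value=0)
    )
    share = 100.0 * counts / counts.sum(axis=0)
    return share.fillna(0.0)
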