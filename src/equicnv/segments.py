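"""Collapse per-marker CNV calls into per-individual segment CNVs.

A segment is a maximal run of CNV-called markers that are consecutive on
the marker map (allowing up to ``max_gap_markers`` uncalled markers
inside the run), for one individual on one chromosome. Runs with fewer
than ``min_markers`` called markers are discarded. A segment is a *gain*
if every contributing call is a gain, a *loss* if every call is a loss,
and *mixed* when both states occur in the run.

Segment boundaries are the positions of the first and last contributing
marker (1-based inclusive), a conservative choice that does not depend on
inter-marker distances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CohortLabels, MarkerMap

__all__ = [
    "build_segments",
    "segment_summary",
    "state_partition",
    "SEGMENT_COLUMNS",
]

SEGMENT_COLUMNS = [
    "individual",
    "chrom",
    "start",
    "end",
    "state",
    "n_markers",
    "length",
    "mean_log2",
]


def _empty_segments() -> pd.DataFrame:
    return pd.DataFrame(columns=SEGMENT_COLUMNS).astype(
        {"start": np.int64, "end": np.int64, "n_markers": np.int64,
         "length": np.int64, "mean_log2": float}
    )


def build_segments(
    calls: pd.DataFrame,
    marker_map: MarkerMap,
    min_markers: int = 3,
    max_gap_markers: int = 0,
) -> pd.DataFrame:
    """Group each individual's calls into segment CNVs.

    Parameters
    ----------
    calls
        Long call table from :func:`equicnv.calling.call_snp_cnvs`.
    min_markers
        Minimum called markers per segment (3 is a common array floor).
    max_gap_markers
        How many consecutive uncalled markers may sit inside a segment
        before the run is broken.
    """
    if min_markers < 1 or max_gap_markers < 0:
        raise ValueError("min_markers >= 1 and max_gap_markers >= 0 required")
    if len(calls) == 0:
        return _empty_segments()

    unknown = set(calls["marker"]) - set(marker_map.markers)
    if unknown:
        raise ValueError(
            f"calls reference markers absent from the map: {sorted(unknown)[:5]}"
        )
    ordinal = marker_map.ordinal_within_chrom()

    work = calls.copy()
    work["_ord"] = work["marker"].map(ordinal).to_numpy()
    work = work.sort_values(["individual", "chrom", "_ord"], kind="stable")

    records = []
    for (ind, chrom), grp in work.groupby(["individual", "chrom"], sort=True):
        ords = grp["_ord"].to_numpy()
        # break the run when more than max_gap_markers uncalled markers
        # separate consecutive calls
        breaks = np.flatnonzero(np.diff(ords) > max_gap_markers + 1) + 1
        for chunk in np.split(np.arange(len(ords)), breaks):
            if len(chunk) < min_markers:
                continue
            sub = grp.iloc[chunk]
            states = set(sub["state"])
            state = states.pop() if len(states) == 1 else "mixed"
            start = int(sub["pos"].iloc[0])
            end = int(sub["pos"].iloc[-1])
            records.append(
                (
                    ind,
                    chrom,
                    start,
                    end,
                    state,
                    len(chunk),
                    end - start + 1,
                    float(sub["log2_ratio"].mean()),
                )
            )
    if not records:
        return _empty_segments()
    return pd.DataFrame(records, columns=SEGMENT_COLUMNS)


def state_partition(segments: pd.DataFrame) -> pd.Series:
    """Segment counts by state plus the total (states partition the set)."""
    counts = segments["state"].value_counts().reindex(
        ["gain", "loss", "mixed"], fill_value=0
    )
    counts.loc["total"] = int(counts.sum())
    return counts.astype(int)


def _union_length(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total bases covered by 1-based inclusive intervals."""
    if len(starts) == 0:
        return 0
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    total = 0
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e:  # >=1 bp shared
            cur_e = max(cur_e, int(e))
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = int(s), int(e)
    return total + cur_e - cur_s + 1


def per_individual_coverage(
    segments: pd.DataFrame,
    individuals: pd.Index,
    genome_length: int,
) -> pd.DataFrame:
    """Per-individual % of the autosomal genome in segments, by state class.

    ``total`` counts every segment; ``gain`` counts gain + mixed segments,
    ``loss`` counts loss + mixed, so a mixed segment contributes to both
    directional classes as well as the total.
    """
    out = pd.DataFrame(
        0.0, index=pd.Index(individuals, name="individual"),
        columns=["pct_total", "pct_gain", "pct_loss"],
    )
    masks = {
        "pct_total": slice(None),
        "pct_gain": ["gain", "mixed"],
        "pct_loss": ["loss", "mixed"],
    }
    for col, sel in masks.items():
        sub = segments if sel == slice(None) else segments[
            segments["state"].isin(sel)
        ]
        for ind, grp in sub.groupby("individual"):
            cov = sum(
                _union_length(g["start"].to_numpy(), g["end"].to_numpy())
                for _, g in grp.groupby("chrom")
            )
            if ind in out.index:
                out.loc[ind, col] = 100.0 * cov / genome_length
    return out


def segment_summary(
    segments: pd.DataFrame,
    labels: CohortLabels,
    chrom_sizes: pd.Series,
) -> pd.DataFrame:
    """Per-breed mean and sd of the % genome changed / gained / lost.

    The denominator is the total autosomal genome length (sex chromosomes
    never enter the map). Individuals without segments contribute zeros.
    sd is the sample standard deviation; a single-individual breed reports
    sd 0.
    """
    if len(segments):
        bad = segments.merge(
            chrom_sizes.rename("size"), left_on="chrom", right_index=True,
            how="left",
        )
        if bad["size"].isna().any():
            raise ValueError("segment on chromosome missing from chrom_sizes")
        if (bad["end"] > bad["size"]).any():
            raise ValueError("segment extends beyond chromosome end")
    genome = int(chrom_sizes.sum())
    cov = per_individual_coverage(segments, labels.individuals, genome)
    cov["breed"] = labels.group_of("breed").reindex(cov.index).to_numpy()
    agg = cov.groupby("breed").agg(
        n_individuals=("pct_total", "size"),
        pct_total_mean=("pct_total", "mean"),
        pct_total_sd=("pct_total", lambda s: s.std(ddof=1)),
        pct_gain_mean=("pct_gain", "mean"),
        pct_gain_sd=("pct_gain", lambda s: s.std(ddof=1)),
        pct_loss_mean=("pct_loss", "mean"),
        pct_loss_sd=("pct_loss", lambda s: s.std(ddof=1)),
    )
    return agg.fillna(0.0)
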