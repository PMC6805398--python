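"""Within-group SNP CNV position frequencies and unique private CNVs.

For each breed (or breed cluster), every genome position is tabulated for
gain and loss carriers separately; positions carried by fewer than
``min_fraction`` of the group's members (default 1%) are dropped from the
group's report. A retained (position, state) is *unique private* to a
group when no individual of any other group carries that same state at
that position — sharing is decided on raw carrier presence, not on the
frequency filter, so a single carrier elsewhere removes privacy.
"""

from __future__ import annotations

from typing import NamedTuple

import pandas as pd

from .core import CohortLabels

__all__ = [
    "position_frequency",
    "unique_private",
    "breed_summary",
    "private_chromosome_profile",
    "PrivateCnvReport",
]

FREQ_COLUMNS = [
    "group",
    "chrom",
    "pos",
    "state",
    "n_carriers",
    "group_size",
    "fraction",
]


def _carrier_counts(
    calls: pd.DataFrame, labels: CohortLabels, group_by: str
) -> pd.DataFrame:
    """Raw carrier counts per (group, chrom, pos, state), no filtering."""
    group_of = labels.group_of(group_by)
    grp = calls["individual"].map(group_of)
    if grp.isna().any():
        missing = sorted(calls.loc[grp.isna(), "individual"].unique()[:5])
        raise ValueError(f"unlabelled individuals in calls: {missing}")
    work = calls.assign(group=grp.to_numpy())
    counts = (
        work.drop_duplicates(["group", "chrom", "pos", "state", "individual"])
        .groupby(["group", "chrom", "pos", "state"])
        .size()
        .rename("n_carriers")
        .reset_index()
    )
    sizes = labels.group_sizes(group_by)
    counts["group_size"] = counts["group"].map(sizes).astype(int)
    counts["fraction"] = counts["n_carriers"] / counts["group_size"]
    return counts


def position_frequency(
    calls: pd.DataFrame,
    labels: CohortLabels,
    group_by: str = "breed",
    min_fraction: float = 0.01,
) -> pd.DataFrame:
    """Frequency table of SNP CNV positions per group and state.

    Group sizes come from the label table (all genotyped members), not
    from the carriers; rows with carrier fraction below ``min_fraction``
    are dropped. The >=-comparison keeps the boundary case (1 carrier in a
    group of 100 at the 1% default).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    counts = _carrier_counts(calls, labels, group_by)
    kept = counts[counts["fraction"] >= min_fraction]
    return kept.reset_index(drop=True)[FREQ_COLUMNS]


class PrivateCnvReport(NamedTuple):
    """Unique-private summary plus the private positions themselves."""

    summary: pd.DataFrame  # per (group, state) counts and percentages
    private_positions: pd.DataFrame  # one row per private (position, state)


def unique_private(
    calls: pd.DataFrame,
    labels: CohortLabels,
    group_by: str = "breed",
    min_fraction: float = 0.01,
) -> PrivateCnvReport:
    """Identify unique private SNP CNVs per group and state.

    A group's candidate positions are its frequency-filtered table; each
    candidate is checked against the *unfiltered* carrier counts of every
    other group, so privacy means literally no other carrier anywhere in
    the cohort. Gains and losses are independent: a gain private to one
    group and a loss private to another may share a position.
    """
    counts = _carrier_counts(calls, labels, group_by)
    retained = counts[counts["fraction"] >= min_fraction].copy()

    # positions carried (at any frequency) by >=2 groups are shared
    n_groups = counts.groupby(["chrom", "pos", "state"])["group"].nunique()
    retained["n_groups_with_carrier"] = n_groups.reindex(
        pd.MultiIndex.from_frame(retained[["chrom", "pos", "state"]])
    ).to_numpy()
    private = retained[retained["n_groups_with_carrier"] == 1].drop(
        columns="n_groups_with_carrier"
    )
    private = private.assign(
        pct_carriers=100.0 * private["fraction"]
    ).reset_index(drop=True)

    sizes = labels.group_sizes(group_by)
    idx = pd.MultiIndex.from_product(
        [sorted(sizes.index), ["gain", "loss"]], names=["group", "state"]
    )
    n_pos = retained.groupby(["group", "state"]).size().reindex(idx, fill_value=0)
    n_priv = private.groupby(["group", "state"]).size().reindex(idx, fill_value=0)
    summary = pd.DataFrame(
        {"n_positions": n_pos.astype(int), "n_unique_private": n_priv.astype(int)}
    ).reset_index()
    summary["group_size"] = summary["group"].map(sizes).astype(int)
    summary["avg_per_individual"] = (
        summary["n_positions"] / summary["group_size"]
    )
    summary["pct_unique_private"] = (
        100.0 * summary["n_unique_private"] / summary["n_positions"]
    ).fillna(0.0)
    return PrivateCnvReport(summary=summary, private_positions=private)


def breed_summary(
    freq_table: pd.DataFrame, labels: CohortLabels, group_by: str = "breed"
) -> pd.DataFrame:
    """Per-group position totals and the per-individual average.

    The average is total retained positions divided by the number of
    genotyped individuals in the group (the reading that reproduces the
    bracketed per-individual figures of a positions-by-breed table).
    """
    sizes = labels.group_sizes(group_by)
    out = (
        freq_table.groupby(["group", "state"])
        .size()
        .rename("n_positions")
        .reset_index()
    )
    out["group_size"] = out["group"].map(sizes).astype(int)
    out["avg_per_individual"] = out["n_positions"] / out["group_size"]
    return out


def per_individual_call_counts(
    calls: pd.DataFrame, labels: CohortLabels, group_by: str = "breed"
) -> pd.DataFrame:
    """Diagnostic alternative average: mean per-individual call count.

    Differs from :func:`breed_summary`'s positions-over-N arithmetic
    whenever carriers stack on the same positions.
    """
    group_of = labels.group_of(group_by)
    per_ind = (
        calls.groupby(["individual", "state"]).size().rename("n_calls")
        .reset_index()
    )
    per_ind["group"] = per_ind["individual"].map(group_of)
    return (
        per_ind.groupby(["group", "state"])["n_calls"].mean()
        .rename("mean_calls_per_individual").reset_index()
    )


def private_chromosome_profile(
    report: PrivateCnvReport,
    highlight_threshold: float = 20.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chromosome carrier-percentage track of private positions.

    Returns the full plottable track (group, state, chrom, pos,
    pct_carriers) and the highlight subset whose within-group carrier
    percentage strictly exceeds ``highlight_threshold``.
    """
    track = report.private_positions[
        ["group", "state", "chrom", "pos", "pct_carriers"]
    ].sort_values(["group", "state", "chrom", "pos"]).reset_index(drop=True)
    highlights = track[track["pct_carriers"] > highlight_threshold]
    return track, highlights.reset_index(drop=True)
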