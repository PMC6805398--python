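"""Independent brute-force oracles used to cross-check the pipeline.

Each oracle re-derives a result by direct enumeration (all pairs,
per-position counters, explicit covariance eigendecomposition) and stays
deliberately independent of the implementation it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def oracle_segments(
    calls: pd.DataFrame,
    marker_map_df: pd.DataFrame,
    min_markers: int,
    max_gap_markers: int,
) -> list[tuple]:
    """Run-scanner over explicit marker indices.

    Returns sorted tuples (individual, chrom, start, end, state, n_markers).
    """
    out = []
    for (ind, chrom), grp in calls.groupby(["individual", "chrom"]):
        chrom_markers = marker_map_df[marker_map_df["chrom"] == chrom]
        pos_to_idx = {p: i for i, p in enumerate(chrom_markers["pos"])}
        items = sorted(
            (pos_to_idx[p], p, s) for p, s in zip(grp["pos"], grp["state"])
        )
        run: list[tuple] = []
        for item in items:
            if run and item[0] - run[-1][0] > max_gap_markers + 1:
                out.extend(_close_run(run, ind, chrom, min_markers))
                run = []
            run.append(item)
        out.extend(_close_run(run, ind, chrom, min_markers))
    return sorted(out)


def _close_run(run, ind, chrom, min_markers):
    if len(run) < min_markers:
        return []
    states = {s for _, _, s in run}
    state = states.pop() if len(states) == 1 else "mixed"
    return [(ind, chrom, run[0][1], run[-1][1], state, len(run))]


def oracle_merge(segments: pd.DataFrame) -> list[tuple]:
    """Union-find over all segment pairs with >=1 bp overlap.

    Returns sorted tuples (chrom, start, end, state, n_segments).
    """
    n = len(segments)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    rows = segments.reset_index(drop=True)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows.iloc[i], rows.iloc[j]
            if (
                a["chrom"] == b["chrom"]
                and a["start"] <= b["end"]
                and b["start"] <= a["end"]
            ):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        sub = rows.iloc[members]
        states = set(sub["state"])
        if states == {"gain"}:
            state = "gain"
        elif states == {"loss"}:
            state = "loss"
        else:
            state = "both"
        out.append(
            (
                sub["chrom"].iloc[0],
                int(sub["start"].min()),
                int(sub["end"].max()),
                state,
                len(members),
            )
        )
    return sorted(out)


def oracle_intersect(a: pd.DataFrame, b: pd.DataFrame) -> set[tuple]:
    """All-pairs overlap test on half-open intervals."""
    out = set()
    for ra in a.itertuples(index=False):
        for rb in b.itertuples(index=False):
            if ra.chrom == rb.chrom and ra.start < rb.end and rb.start < ra.end:
                ov = min(ra.end, rb.end) - max(ra.start, rb.start)
                out.add((ra.name, rb.name, ov))
    return out


def oracle_position_frequency(
    calls: pd.DataFrame,
    labels_df: pd.DataFrame,
    group_by: str,
    min_fraction: float,
) -> set[tuple]:
    """Per-position carrier counter; returns retained rows as tuples."""
    group_of = dict(zip(labels_df["individual"], labels_df[group_by]))
    sizes: dict[str, int] = {}
    for g in labels_df[group_by]:
        sizes[g] = sizes.get(g, 0) + 1
    carriers: dict[tuple, set] = {}
    for row in calls.itertuples(index=False):
        key = (group_of[row.individual], row.chrom, row.pos, row.state)
        carriers.setdefault(key, set()).add(row.individual)
    out = set()
    for (g, chrom, pos, state), inds in carriers.items():
        frac = len(inds) / sizes[g]
        if frac >= min_fraction:
            out.add((g, chrom, pos, state, len(inds)))
    return out


def oracle_unique_private(
    calls: pd.DataFrame,
    labels_df: pd.DataFrame,
    group_by: str,
    min_fraction: float,
) -> set[tuple]:
    """Exhaustive set-difference privacy check; returns private
    (group, chrom, pos, state) tuples."""
    group_of = dict(zip(labels_df["individual"], labels_df[group_by]))
    positions_by_group: dict[str, set] = {}
    for row in calls.itertuples(index=False):
        g = group_of[row.individual]
        positions_by_group.setdefault(g, set()).add(
            (row.chrom, row.pos, row.state)
        )
    retained = oracle_position_frequency(calls, labels_df, group_by, min_fraction)
    out = set()
    for g, chrom, pos, state, _n in retained:
        shared = any(
            (chrom, pos, state) in positions
            for other, positions in positions_by_group.items()
            if other != g
        )
        if not shared:
            out.add((g, chrom, pos, state))
    return out


def oracle_pca_scores(matrix: np.ndarray, k: int) -> np.ndarray:
    """Scores from an explicit covariance eigendecomposition (centered,
    unscaled), sign-fixed to match the largest-|loading|-positive rule."""
    X = matrix - matrix.mean(axis=0)
    cov = X.T @ X / (X.shape[0] - 1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    V = V[:, order[:k]]
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] *= -1
    return X @ V
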