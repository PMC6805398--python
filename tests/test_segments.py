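"""Segmentation of per-marker calls into per-individual segment CNVs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equicnv import segments
from equicnv.core import CohortLabels, MarkerMap
from oracles import oracle_segments

from conftest import random_calls, random_marker_map


def _map_from_positions(positions, chrom="chr1"):
    return MarkerMap(
        pd.DataFrame(
            {
                "marker": [f"m{p}" for p in positions],
                "chrom": chrom,
                "pos": positions,
            }
        )
    )


def _calls(rows):
    return pd.DataFrame(
        rows,
        columns=["individual", "marker", "chrom", "pos", "state", "log2_ratio"],
    )


class TestBuildSegments:
    def test_single_run(self):
        mm = _map_from_positions([100, 200, 300, 400])
        calls = _calls(
            [("a", f"m{p}", "chr1", p, "gain", 0.6) for p in (100, 200, 300)]
        )
        segs = segments.build_segments(calls, mm, min_markers=2)
        assert len(segs) == 1
        row = segs.iloc[0]
        assert (row["start"], row["end"], row["state"], row["n_markers"]) == (
            100, 300, "gain", 3,
        )
        assert row["length"] == 201

    def test_adjacent_gain_loss_is_mixed(self):
        mm = _map_from_positions([100, 200])
        calls = _calls(
            [("a", "m100", "chr1", 100, "gain", 0.6),
             ("a", "m200", "chr1", 200, "loss", -0.6)]
        )
        segs = segments.build_segments(calls, mm, min_markers=2)
        assert len(segs) == 1
        assert segs.iloc[0]["state"] == "mixed"
        assert (segs.iloc[0]["start"], segs.iloc[0]["end"]) == (100, 200)

    def test_uncalled_marker_breaks_run_at_zero_gap(self):
        mm = _map_from_positions([100, 200, 300, 400, 500])
        pos = [100, 200, 400, 500]  # 300 uncalled
        calls = _calls([("a", f"m{p}", "chr1", p, "gain", 0.6) for p in pos])
        segs = segments.build_segments(calls, mm, min_markers=2, max_gap_markers=0)
        assert sorted(zip(segs["start"], segs["end"])) == [(100, 200), (400, 500)]
        bridged = segments.build_segments(
            calls, mm, min_markers=2, max_gap_markers=1
        )
        assert sorted(zip(bridged["start"], bridged["end"])) == [(100, 500)]
        assert bridged.iloc[0]["n_markers"] == 4  # uncalled markers don't count

    def test_min_markers_discards_short_runs(self):
        mm = _map_from_positions([100, 200, 300, 500])
        calls = _calls(
            [("a", "m100", "chr1", 100, "gain", 0.6),
             ("a", "m500", "chr1", 500, "gain", 0.6)]
        )
        assert len(segments.build_segments(calls, mm, min_markers=2)) == 0
        assert len(segments.build_segments(calls, mm, min_markers=1)) == 2

    def test_unknown_marker_errors(self):
        mm = _map_from_positions([100])
        calls = _calls([("a", "mX", "chr1", 999, "gain", 0.6)])
        with pytest.raises(ValueError, match="absent"):
            segments.build_segments(calls, mm)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_run_scanner_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mm = random_marker_map(rng)
        calls = random_calls(rng, mm, [f"i{k}" for k in range(4)])
        min_markers = int(rng.integers(1, 4))
        max_gap = int(rng.integers(0, 3))
        segs = segments.build_segments(calls, mm, min_markers, max_gap)
        got = sorted(
            zip(segs["individual"], segs["chrom"], segs["start"],
                segs["end"], segs["state"], segs["n_markers"])
        )
        assert got == oracle_segments(calls, mm.df, min_markers, max_gap)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_call_count_reconciliation(self, seed):
        """At max_gap=0 every call lands in exactly one segment or a
        discarded short run: marker counts reconcile exactly."""
        rng = np.random.default_rng(seed)
        mm = random_marker_map(rng, n_chrom=1, n_markers=25)
        calls = random_calls(rng, mm, ["a", "b"], p_call=0.4)
        min_markers = int(rng.integers(1, 4))
        segs = segments.build_segments(calls, mm, min_markers, 0)
        oracle = oracle_segments(calls, mm.df, 1, 0)  # all runs
        discarded = sum(n for *_, n in oracle if n < min_markers)
        assert segs["n_markers"].sum() + discarded == len(calls)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_segments_never_overlap_within_individual(self, seed):
        rng = np.random.default_rng(seed)
        mm = random_marker_map(rng)
        calls = random_calls(rng, mm, ["a", "b", "c"], p_call=0.5)
        segs = segments.build_segments(
            calls, mm, int(rng.integers(1, 3)), int(rng.integers(0, 2))
        )
        for (_, _), grp in segs.groupby(["individual", "chrom"]):
            grp = grp.sort_values("start")
            assert (grp["start"].to_numpy()[1:] > grp["end"].to_numpy()[:-1]).all()


class TestSegmentSummary:
    @staticmethod
    def _labels(inds, breeds):
        return CohortLabels(
            pd.DataFrame(
                {"individual": inds, "breed": breeds, "cluster": breeds}
            )
        )

    def test_direct_proportion(self):
        segs = pd.DataFrame(
            [("a", "chr1", 1001, 11_000, "gain", 3, 10_000, 0.6)],
            columns=segments.SEGMENT_COLUMNS,
        )
        labels = self._labels(["a"], ["X"])
        sizes = pd.Series({"chr1": 1_000_000})
        out = segments.segment_summary(segs, labels, sizes)
        assert out.loc["X", "pct_gain_mean"] == pytest.approx(1.0)
        assert out.loc["X", "pct_loss_mean"] == 0.0
        assert out.loc["X", "pct_total_mean"] == pytest.approx(1.0)

    def test_identical_individuals_zero_sd(self):
        segs = pd.DataFrame(
            [(i, "chr1", 1, 10_000, "gain", 3, 10_000, 0.6) for i in "abc"],
            columns=segments.SEGMENT_COLUMNS,
        )
        labels = self._labels(list("abc"), ["X"] * 3)
        out = segments.segment_summary(segs, labels, pd.Series({"chr1": 10**6}))
        assert out.loc["X", "pct_gain_sd"] == 0.0

    def test_mixed_counts_toward_both_directions(self):
        segs = pd.DataFrame(
            [("a", "chr1", 1, 10_000, "mixed", 3, 10_000, 0.0)],
            columns=segments.SEGMENT_COLUMNS,
        )
        labels = self._labels(["a"], ["X"])
        out = segments.segment_summary(segs, labels, pd.Series({"chr1": 10**6}))
        assert out.loc["X", "pct_gain_mean"] == out.loc["X", "pct_loss_mean"] == (
            pytest.approx(1.0)
        )

    def test_matches_interval_union_oracle(self):
        """Overlapping segments of one individual never double count."""
        rng = np.random.default_rng(21)
        rows = []
        for ind in "abcd":
            for _ in range(15):
                s = int(rng.integers(1, 90_000))
                e = s + int(rng.integers(1, 20_000))
                rows.append(
                    (ind, f"chr{rng.integers(1, 3)}", s, e,
                     str(rng.choice(["gain", "loss", "mixed"])), 3, e - s + 1, 0.0)
                )
        segs = pd.DataFrame(rows, columns=segments.SEGMENT_COLUMNS)
        labels = self._labels(list("abcd"), ["X", "X", "Y", "Y"])
        sizes = pd.Series({"chr1": 200_000, "chr2": 200_000})
        out = segments.segment_summary(segs, labels, sizes)

        def union_len(intervals):
            covered = set()
            for s, e in intervals:
                covered.update(range(s, e + 1))
            return len(covered)

        genome = int(sizes.sum())
        per_ind = {}
        for ind in "abcd":
            sub = segs[segs["individual"] == ind]
            total = sum(
                union_len(list(zip(g["start"], g["end"])))
                for _, g in sub.groupby("chrom")
            )
            per_ind[ind] = 100.0 * total / genome
        for breed, members in (("X", "ab"), ("Y", "cd")):
            vals = [per_ind[m] for m in members]
            assert out.loc[breed, "pct_total_mean"] == pytest.approx(
                np.mean(vals), abs=1e-9
            )
            assert out.loc[breed, "pct_total_sd"] == pytest.approx(
                np.std(vals, ddof=1), abs=1e-9
            )

    def test_segment_beyond_chromosome_errors(self):
        segs = pd.DataFrame(
            [("a", "chr1", 1, 2_000_000, "gain", 3, 2_000_000, 0.6)],
            columns=segments.SEGMENT_COLUMNS,
        )
        labels = self._labels(["a"], ["X"])
        with pytest.raises(ValueError, match="beyond"):
            segments.segment_summary(segs, labels, pd.Series({"chr1": 10**6}))


def test_state_partition_totals():
    segs = pd.DataFrame(
        [("a", "chr1", 1, 10, "gain", 3, 10, 0.6),
         ("a", "chr1", 20, 30, "loss", 3, 11, -0.6),
         ("b", "chr1", 1, 10, "mixed", 3, 10, 0.0),
         ("b", "chr2", 1, 10, "gain", 3, 10, 0.6)],
        columns=segments.SEGMENT_COLUMNS,
    )
    part = segments.state_partition(segs)
    assert part["gain"] + part["loss"] + part["mixed"] == part["total"] == 4
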