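"""Position frequencies, the 1% filter and unique private SNP CNVs."""

import numpy as np
import pandas as pd
import pytest

from equicnv import sharing
from equicnv.core import CohortLabels
from oracles import oracle_position_frequency, oracle_unique_private

from conftest import random_calls, random_labels, random_marker_map


def _labels(spec):
    """spec: {breed: (n, cluster)}"""
    rows = []
    for breed, (n, cluster) in spec.items():
        rows += [(f"{breed}{i}", breed, cluster) for i in range(n)]
    return CohortLabels(
        pd.DataFrame(rows, columns=["individual", "breed", "cluster"])
    )


def _call(ind, pos, state, chrom="chr1"):
    return (ind, f"m{pos}", chrom, pos, state, 0.6 if state == "gain" else -0.6)


def _calls(rows):
    return pd.DataFrame(
        rows,
        columns=["individual", "marker", "chrom", "pos", "state", "log2_ratio"],
    )


class TestPositionFrequency:
    def test_boundary_fraction_retained(self):
        """1 carrier in a group of 100 sits exactly on the 1% filter."""
        labels = _labels({"A": (100, "K")})
        calls = _calls([_call("A0", 500, "gain")])
        out = sharing.position_frequency(calls, labels, "breed", 0.01)
        assert len(out) == 1
        assert out.iloc[0]["fraction"] == pytest.approx(0.01)

    def test_small_group_fraction(self):
        labels = _labels({"A": (24, "K")})
        calls = _calls([_call("A3", 500, "loss")])
        out = sharing.position_frequency(calls, labels, "breed", 0.01)
        assert out.iloc[0]["fraction"] == pytest.approx(1 / 24)
        assert out.iloc[0]["group_size"] == 24

    def test_below_threshold_dropped(self):
        labels = _labels({"A": (300, "K")})
        calls = _calls([_call("A0", 500, "gain"), _call("A1", 900, "gain"),
                        _call("A2", 900, "gain"), _call("A3", 900, "gain")])
        out = sharing.position_frequency(calls, labels, "breed", 0.01)
        assert set(out["pos"]) == {900}  # 1/300 < 1% < 3/300

    def test_unlabelled_individual_errors(self):
        labels = _labels({"A": (5, "K")})
        calls = _calls([_call("ghost", 500, "gain")])
        with pytest.raises(ValueError, match="unlabelled"):
            sharing.position_frequency(calls, labels)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_counter_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mm = random_marker_map(rng)
        inds = [f"i{k}" for k in range(12)]
        labels = random_labels(rng, inds)
        calls = random_calls(rng, mm, inds, p_call=0.3)
        min_fraction = float(rng.choice([0.01, 0.1, 0.25]))
        out = sharing.position_frequency(calls, labels, "breed", min_fraction)
        got = set(
            zip(out["group"], out["chrom"], out["pos"], out["state"],
                out["n_carriers"])
        )
        assert got == oracle_position_frequency(
            calls, labels.df, "breed", min_fraction
        )


class TestUniquePrivate:
    def test_single_foreign_carrier_breaks_privacy(self):
        """Retained at 5% in A but one carrier in B: not private."""
        labels = _labels({"A": (100, "K1"), "B": (100, "K2")})
        calls = _calls(
            [_call(f"A{i}", 500, "gain") for i in range(5)]
            + [_call("B0", 500, "gain")]
        )
        rep = sharing.unique_private(calls, labels, "breed", 0.01)
        assert rep.summary["n_unique_private"].sum() == 0
        # B's single carrier is retained (1%) but not private either
        assert len(rep.private_positions) == 0

    def test_states_independent_at_same_position(self):
        labels = _labels({"A": (10, "K1"), "B": (10, "K2")})
        calls = _calls(
            [_call("A0", 500, "gain"), _call("B0", 500, "loss")]
        )
        rep = sharing.unique_private(calls, labels, "breed", 0.01)
        priv = set(zip(rep.private_positions["group"],
                       rep.private_positions["state"]))
        assert priv == {("A", "gain"), ("B", "loss")}

    def test_privacy_unique_to_one_group(self):
        rng = np.random.default_rng(2)
        mm = random_marker_map(rng)
        inds = [f"i{k}" for k in range(15)]
        labels = random_labels(rng, inds)
        calls = random_calls(rng, mm, inds, p_call=0.3)
        rep = sharing.unique_private(calls, labels, "breed", 0.01)
        keys = list(zip(rep.private_positions["chrom"],
                        rep.private_positions["pos"],
                        rep.private_positions["state"]))
        assert len(keys) == len(set(keys))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_set_difference_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        mm = random_marker_map(rng)
        inds = [f"i{k}" for k in range(12)]
        labels = random_labels(rng, inds)
        calls = random_calls(rng, mm, inds, p_call=0.35)
        rep = sharing.unique_private(calls, labels, "breed", 0.05)
        got = set(zip(rep.private_positions["group"],
                      rep.private_positions["chrom"],
                      rep.private_positions["pos"],
                      rep.private_positions["state"]))
        assert got == oracle_unique_private(calls, labels.df, "breed", 0.05)

    def test_cluster_collapse_never_creates_privacy(self):
        """A position shared between two breeds of one cluster stays
        non-private at breed level and becomes cluster-internal."""
        rng = np.random.default_rng(31)
        mm = random_marker_map(rng)
        inds = [f"i{k}" for k in range(20)]
        labels = random_labels(rng, inds, n_groups=4)
        calls = random_calls(rng, mm, inds, p_call=0.3)
        breed_rep = sharing.unique_private(calls, labels, "breed", 0.01)
        cluster_rep = sharing.unique_private(calls, labels, "cluster", 0.01)
        breed_priv = set(zip(breed_rep.private_positions["chrom"],
                             breed_rep.private_positions["pos"],
                             breed_rep.private_positions["state"]))
        cluster_priv = set(zip(cluster_rep.private_positions["chrom"],
                               cluster_rep.private_positions["pos"],
                               cluster_rep.private_positions["state"]))
        # a breed-private position is carried by one breed only, hence by
        # one cluster only: it must remain private at cluster level
        assert breed_priv <= cluster_priv

    def test_report_percentages_recompute(self):
        rng = np.random.default_rng(8)
        mm = random_marker_map(rng)
        inds = [f"i{k}" for k in range(15)]
        labels = random_labels(rng, inds)
        calls = random_calls(rng, mm, inds, p_call=0.4)
        rep = sharing.unique_private(calls, labels, "breed", 0.01)
        s = rep.summary
        nonzero = s[s["n_positions"] > 0]
        assert np.allclose(
            nonzero["pct_unique_private"],
            100.0 * nonzero["n_unique_private"] / nonzero["n_positions"],
        )
        assert np.allclose(
            s["avg_per_individual"], s["n_positions"] / s["group_size"]
        )
        assert (s["n_unique_private"] <= s["n_positions"]).all()


class TestBreedSummary:
    def test_positions_over_group_size(self):
        labels = _labels({"A": (8, "K")})
        calls = _calls(
            [_call(f"A{i}", p, "gain") for i in range(2) for p in (100, 200)]
        )
        table = sharing.position_frequency(calls, labels, "breed", 0.01)
        out = sharing.breed_summary(table, labels, "breed")
        row = out[(out["group"] == "A") & (out["state"] == "gain")].iloc[0]
        assert row["n_positions"] == 2
        assert row["avg_per_individual"] == pytest.approx(2 / 8)

    def test_empty_group_absent(self):
        labels = _labels({"A": (5, "K")})
        table = sharing.position_frequency(
            _calls([_call("A0", 100, "gain")]), labels, "breed", 0.01
        )
        out = sharing.breed_summary(table, labels)
        assert not ((out["group"] == "A") & (out["state"] == "loss")).any()


class TestPrivateChromosomeProfile:
    def test_highlight_threshold_strict(self):
        """52/256 carriers = 20.3% clears a 20% highlight threshold."""
        labels = _labels({"A": (256, "K1"), "B": (10, "K2")})
        calls = _calls([_call(f"A{i}", 700, "loss") for i in range(52)])
        rep = sharing.unique_private(calls, labels, "breed", 0.01)
        track, high = sharing.private_chromosome_profile(rep, 20.0)
        assert track.iloc[0]["pct_carriers"] == pytest.approx(100 * 52 / 256)
        assert len(high) == 1
        # exactly at the threshold is not highlighted
        _, high_at = sharing.private_chromosome_profile(
            rep, 100 * 52 / 256
        )
        assert len(high_at) == 0

    def test_empty_track(self):
        labels = _labels({"A": (5, "K1"), "B": (5, "K2")})
        calls = _calls([_call("A0", 100, "gain"), _call("B0", 100, "gain")])
        rep = sharing.unique_private(calls, labels, "breed", 0.01)
        track, high = sharing.private_chromosome_profile(rep)
        assert len(track) == 0 and len(high) == 0
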