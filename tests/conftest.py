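"""Shared fixtures: small synthetic cohorts and random-instance builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from equicnv import pipeline
from equicnv import simulate as sim
from equicnv.core import CohortLabels, MarkerMap


@pytest.fixture(scope="session")
def tiny_config() -> sim.SimConfig:
    """Three small breeds, two chromosomes, one planted gain and loss."""
    return sim.SimConfig(
        seed=7,
        breeds=(
            sim.BreedSpec("RefBreed", 20, "C1"),
            sim.BreedSpec("BreedB", 15, "C1"),
            sim.BreedSpec("BreedC", 15, "C2"),
        ),
        reference_breed="RefBreed",
        n_autosomes=2,
        chrom_length_bp=10_000_000,
        n_markers_per_chrom=100,
        planted_cnvrs=(
            sim.PlantedCnvr("chr1", 2_000_000, 2_500_000, 3, ("BreedB",), 0.5),
            sim.PlantedCnvr("chr2", 5_000_000, 5_500_000, 1, ("C2",), 0.5),
        ),
        noise_sd=0.03,
        baf_noise_sd=0.02,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return sim.generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def study_run():
    """Full study-scale cohort and pipeline run (shared across tests)."""
    cfg = sim.study_config(seed=42)
    marker_map, matrix, labels, truth = sim.generate_cohort(cfg)
    res = pipeline.run_pipeline(
        marker_map,
        matrix,
        labels,
        cfg.chrom_sizes,
        pipeline.PipelineConfig(reference_breed=cfg.reference_breed),
    )
    return cfg, marker_map, matrix, labels, truth, res


def random_marker_map(rng: np.random.Generator, n_chrom=2, n_markers=30):
    rows = []
    for c in range(1, n_chrom + 1):
        pos = np.sort(
            rng.choice(np.arange(1, 10_001), size=n_markers, replace=False)
        )
        for i, p in enumerate(pos):
            rows.append((f"chr{c}_m{i}", f"chr{c}", int(p)))
    return MarkerMap(pd.DataFrame(rows, columns=["marker", "chrom", "pos"]))


def random_calls(
    rng: np.random.Generator,
    marker_map: MarkerMap,
    individuals: list[str],
    p_call=0.25,
):
    rows = []
    for ind in individuals:
        mask = rng.random(marker_map.n_markers) < p_call
        sub = marker_map.df[mask]
        states = rng.choice(["gain", "loss"], size=len(sub))
        for (m, c, p), s in zip(sub.itertuples(index=False), states):
            lr = rng.normal(0.6 if s == "gain" else -0.6, 0.1)
            rows.append((ind, m, c, p, s, lr))
    return pd.DataFrame(
        rows,
        columns=["individual", "marker", "chrom", "pos", "state", "log2_ratio"],
    )


def random_segments(rng: np.random.Generator, n=40, individuals=("a", "b", "c")):
    rows = []
    for i in range(n):
        chrom = f"chr{rng.integers(1, 3)}"
        start = int(rng.integers(1, 5_000))
        length = int(rng.integers(1, 1_500))
        rows.append(
            (
                str(rng.choice(list(individuals))),
                chrom,
                start,
                start + length,
                str(rng.choice(["gain", "loss", "mixed"])),
                int(rng.integers(3, 10)),
                length + 1,
                float(rng.normal(0, 0.5)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "individual", "chrom", "start", "end",
            "state", "n_markers", "length", "mean_log2",
        ],
    )


def random_track(rng: np.random.Generator, n=25, prefix="iv"):
    rows = []
    for i in range(n):
        chrom = f"chr{rng.integers(1, 3)}"
        start = int(rng.integers(0, 5_000))
        end = start + int(rng.integers(1, 1_200))
        rows.append((chrom, start, end, f"{prefix}_{i}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def random_labels(rng: np.random.Generator, individuals, n_groups=3):
    groups = [f"G{i}" for i in range(1, n_groups + 1)]
    breed = rng.choice(groups, size=len(individuals))
    cluster = np.where(np.isin(breed, groups[: max(1, n_groups // 2)]),
                       "K1", "K2")
    return CohortLabels(
        pd.DataFrame(
            {"individual": individuals, "breed": breed, "cluster": cluster}
        )
    )
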