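"""Synthetic multi-breed SNP-array cohort with planted copy-number variants.

The generator emulates the design of a large multi-breed array study: a
cohort of several hundred horses from ~8 breeds falling into 3 ancestry
clusters, one large low-variance breed that serves as the signal-intensity
reference, and a set of planted CNV regions that are shared, breed-private
or cluster-private. Every planted variant is recorded in a truth table so
downstream stages can be scored against known carrier status.

Signal model
------------
A marker's total intensity for an individual carrying ``c`` copies is

    intensity = baseline * (c_eff / 2) * exp(N(0, noise_sd * ln 2))

with ``c_eff = max(c, background)`` so homozygous deletions retain a small
residual background signal (intensities must stay positive). The log2
ratio against a noise-free diploid reference is then Normal with mean
``log2(c_eff / 2)`` and standard deviation ``noise_sd`` — exactly the
quantity the ratio-based caller thresholds.

B-allele frequencies are drawn from per-breed allele frequencies that are
correlated within clusters, giving the BAF-PCA stage genuine population
structure to find; within deletions BAF collapses toward {0, 1}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CohortLabels, IntensityMatrix, MarkerMap

__all__ = [
    "BreedSpec",
    "PlantedCnvr",
    "SimConfig",
    "generate_cohort",
    "write_truth_bed",
    "study_config",
]

#: residual signal fraction for copy number 0 (fraction of diploid baseline)
BACKGROUND_COPY = 0.1

_BASELINE = 2.0  # diploid total intensity, arbitrary units


@dataclass(frozen=True)
class BreedSpec:
    name: str
    n_individuals: int
    cluster: str

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError(f"breed {self.name!r} needs >= 1 individual")


@dataclass(frozen=True)
class PlantedCnvr:
    """A CNV region planted into the cohort with known carriers.

    ``carrier_groups`` may name breeds or clusters; each member of a
    carrier group independently carries the variant with probability
    ``carrier_frequency`` (Bernoulli), so realized carrier counts are
    binomial around the design frequency.
    """

    chrom: str
    start: int  # 1-based inclusive bp
    end: int
    copy_number: int
    carrier_groups: tuple[str, ...]
    carrier_frequency: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("planted CNVR start > end")
        if self.copy_number == 2 or self.copy_number < 0:
            raise ValueError("copy_number must be a non-negative integer != 2")
        if not 0 < self.carrier_frequency <= 1:
            raise ValueError("carrier_frequency must be in (0, 1]")
        if not self.carrier_groups:
            raise ValueError("planted CNVR needs >= 1 carrier group")
        object.__setattr__(self, "carrier_groups", tuple(self.carrier_groups))

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class SimConfig:
    seed: int
    breeds: tuple[BreedSpec, ...]
    reference_breed: str
    n_autosomes: int = 5
    chrom_length_bp: int = 100_000_000
    n_markers_per_chrom: int = 1_000
    planted_cnvrs: tuple[PlantedCnvr, ...] = ()
    noise_sd: float = 0.05
    reference_noise_sd: float | None = None  # defaults to noise_sd
    baf_noise_sd: float = 0.02
    random_marker_spacing: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "breeds", tuple(self.breeds))
        object.__setattr__(self, "planted_cnvrs", tuple(self.planted_cnvrs))
        names = [b.name for b in self.breeds]
        if len(set(names)) != len(names):
            raise ValueError("duplicate breed names")
        if self.reference_breed not in names:
            raise ValueError(
                f"reference breed {self.reference_breed!r} not in breeds"
            )
        if self.n_markers_per_chrom < 1 or self.n_autosomes < 1:
            raise ValueError("need >= 1 chromosome and >= 1 marker")
        if self.n_markers_per_chrom > self.chrom_length_bp:
            raise ValueError("more markers than base pairs on a chromosome")
        known = set(names) | {b.cluster for b in self.breeds}
        for p in self.planted_cnvrs:
            if p.chrom not in self.chrom_names:
                raise ValueError(f"planted CNVR on unknown chromosome {p.chrom}")
            if p.end > self.chrom_length_bp:
                raise ValueError(f"planted CNVR {p.region_id} beyond chromosome end")
            unknown = set(p.carrier_groups) - known
            if unknown:
                raise ValueError(f"unknown carrier groups: {sorted(unknown)}")
        _reject_conflicting_overlaps(self.planted_cnvrs)

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_autosomes + 1)]

    @property
    def chrom_sizes(self) -> pd.Series:
        return pd.Series(
            self.chrom_length_bp, index=pd.Index(self.chrom_names, name="chrom")
        )

    @property
    def n_individuals(self) -> int:
        return sum(b.n_individuals for b in self.breeds)


def _reject_conflicting_overlaps(planted: Sequence[PlantedCnvr]) -> None:
    """Overlapping plants with different copy numbers are ambiguous."""
    by_chrom: dict[str, list[PlantedCnvr]] = {}
    for p in planted:
        by_chrom.setdefault(p.chrom, []).append(p)
    for plist in by_chrom.values():
        plist.sort(key=lambda p: p.start)
        for a, b in zip(plist, plist[1:]):
            if b.start <= a.end and a.copy_number != b.copy_number:
                raise ValueError(
                    "overlapping planted CNVRs with conflicting copy numbers: "
                    f"{a.region_id} (cn={a.copy_number}) vs "
                    f"{b.region_id} (cn={b.copy_number})"
                )


def _marker_map(config: SimConfig, rng: np.random.Generator) -> MarkerMap:
    rows = []
    n = config.n_markers_per_chrom
    for chrom in config.chrom_names:
        if config.random_marker_spacing:
            pos = np.sort(
                rng.choice(config.chrom_length_bp, size=n, replace=False) + 1
            )
        else:
            # uniform spacing; last marker lands on the chromosome end
            step = config.chrom_length_bp // n
            pos = step * np.arange(1, n + 1)
        rows.append(
            pd.DataFrame(
                {
                    "marker": [f"{chrom}_m{i}" for i in range(1, n + 1)],
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                }
            )
        )
    return MarkerMap(pd.concat(rows, ignore_index=True))


def _labels(config: SimConfig) -> CohortLabels:
    rows = []
    for breed in config.breeds:
        for i in range(1, breed.n_individuals + 1):
            rows.append((f"{breed.name}_{i:04d}", breed.name, breed.cluster))
    return CohortLabels(
        pd.DataFrame(rows, columns=["individual", "breed", "cluster"])
    )


def _draw_carriers(
    config: SimConfig, labels: CohortLabels, rng: np.random.Generator
) -> pd.DataFrame:
    """Bernoulli carrier draw for every (planted CNVR, carrier-group member)."""
    breed_of = labels.group_of("breed")
    cluster_of = labels.group_of("cluster")
    breeds = set(breed_of.unique())
    records = []
    for p in config.planted_cnvrs:
        for group in p.carrier_groups:
            sel = breed_of if group in breeds else cluster_of
            members = sel.index[sel == group]
            if p.carrier_frequency * len(members) < 1:
                warnings.warn(
                    f"planted CNVR {p.region_id}: expected carriers in group "
                    f"{group!r} < 1; region may have no carriers",
                    stacklevel=3,
                )
            carried = rng.random(len(members)) < p.carrier_frequency
            for ind, flag in zip(members, carried):
                records.append(
                    (
                        p.region_id,
                        p.chrom,
                        p.start,
                        p.end,
                        p.copy_number,
                        group,
                        ind,
                        bool(flag),
                    )
                )
    return pd.DataFrame(
        records,
        columns=[
            "region_id",
            "chrom",
            "start",
            "end",
            "copy_number",
            "group",
            "individual",
            "carrier",
        ],
    )


def _breed_allele_freqs(
    config: SimConfig, rng: np.random.Generator, n_markers: int
) -> dict[str, np.ndarray]:
    """Per-breed B-allele population frequencies, correlated within clusters."""
    base = rng.uniform(0.05, 0.95, size=n_markers)
    clusters = sorted({b.cluster for b in config.breeds})
    cluster_shift = {
        c: rng.normal(0.0, 0.12, size=n_markers) for c in clusters
    }
    freqs = {}
    for breed in config.breeds:
        shift = rng.normal(0.0, 0.04, size=n_markers)
        freqs[breed.name] = np.clip(
            base + cluster_shift[breed.cluster] + shift, 0.01, 0.99
        )
    return freqs


def generate_cohort(
    config: SimConfig,
) -> tuple[MarkerMap, IntensityMatrix, CohortLabels, pd.DataFrame]:
    """Generate marker map, intensities/BAF, labels and the truth table.

    Returns
    -------
    marker_map, matrix, labels, truth
        ``truth`` has one row per (planted CNVR, carrier group, group
        member) with a boolean ``carrier`` flag; the same seed always
        reproduces identical output bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    marker_map = _marker_map(config, rng)
    labels = _labels(config)
    truth = _draw_carriers(config, labels, rng)

    individuals = labels.individuals
    n_ind, n_mark = len(individuals), marker_map.n_markers
    ind_pos = pd.Series(np.arange(n_ind), index=individuals)

    # per-individual copy number grid, diploid baseline
    copy = np.full((n_ind, n_mark), 2.0)
    chrom_arr = marker_map.df["chrom"].to_numpy()
    pos_arr = marker_map.df["pos"].to_numpy()
    for p in config.planted_cnvrs:
        cols = (chrom_arr == p.chrom) & (pos_arr >= p.start) & (pos_arr <= p.end)
        hits = truth[(truth["region_id"] == p.region_id) & truth["carrier"]]
        rows = ind_pos[hits["individual"].unique()].to_numpy()
        if rows.size:
            copy[np.ix_(rows, np.flatnonzero(cols))] = max(
                p.copy_number, BACKGROUND_COPY
            )

    ref_sd = (
        config.noise_sd
        if config.reference_noise_sd is None
        else config.reference_noise_sd
    )
    sd = np.where(
        labels.df["breed"].to_numpy() == config.reference_breed,
        ref_sd,
        config.noise_sd,
    )[:, None]
    log2_noise = rng.normal(0.0, 1.0, size=(n_ind, n_mark)) * sd
    intensity = _BASELINE * (copy / 2.0) * np.exp2(log2_noise)

    baf = _simulate_baf(config, labels, rng, n_mark, copy)

    matrix = IntensityMatrix(
        intensity=pd.DataFrame(
            intensity, index=individuals, columns=marker_map.markers
        ),
        baf=pd.DataFrame(baf, index=individuals, columns=marker_map.markers),
    )
    return marker_map, matrix, labels, truth


def _simulate_baf(
    config: SimConfig,
    labels: CohortLabels,
    rng: np.random.Generator,
    n_mark: int,
    copy: np.ndarray,
) -> np.ndarray:
    freqs = _breed_allele_freqs(config, rng, n_mark)
    breed_arr = labels.df["breed"].to_numpy()
    baf = np.empty((len(breed_arr), n_mark))
    for breed, p in freqs.items():
        rows = np.flatnonzero(breed_arr == breed)
        geno = rng.binomial(2, p[None, :].repeat(len(rows), axis=0))
        baf[rows] = geno / 2.0
    if config.baf_noise_sd > 0:
        baf += rng.normal(0.0, config.baf_noise_sd, size=baf.shape)
    # hemizygous/homozygous deletions lose the heterozygous band
    deleted = copy < 2
    baf[deleted] = np.round(baf[deleted])
    return np.clip(baf, 0.0, 1.0)


def write_truth_bed(truth: pd.DataFrame, path) -> None:
    """Write planted CNVRs as BED6, one record per (region, carrier group).

    Coordinates convert from the generator's 1-based inclusive spans to
    BED's 0-based half-open; the name field encodes copy number and group,
    the score column carries the realized carrier count.
    """
    rows = []
    if len(truth):
        grouped = truth.groupby(
            ["region_id", "chrom", "start", "end", "copy_number", "group"],
            sort=True,
        )["carrier"].sum()
        for (rid, chrom, start, end, cn, group), n_carriers in grouped.items():
            rows.append(
                (chrom, start - 1, end, f"cn{cn}|{group}", int(n_carriers), ".")
            )
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    ).to_csv(path, sep="\t", header=False, index=False)


def study_config(seed: int = 42) -> SimConfig:
    """Default study-scale cohort: 8 breeds, 3 clusters, ~600 individuals.

    Breed sizes mirror a large European horse cohort scaled down ~3x, with
    the biggest draught breed as the low-variance reference. Planted
    variants cover the three sharing classes the analysis distinguishes:
    cohort-wide shared, breed-private and cluster-private, at design
    carrier frequency 0.30 with 0.05 log2-intensity noise.
    """
    breeds = (
        BreedSpec("Ardenner", 8, "Draught"),
        BreedSpec("BelgianDraught", 103, "Draught"),
        BreedSpec("GermanDraught", 8, "Draught"),
        BreedSpec("Exmoor", 88, "Draught"),
        BreedSpec("VlaamsPaard", 8, "Draught"),
        BreedSpec("BelgianWarmblood", 165, "Warmblood"),
        BreedSpec("SwedishWarmblood", 131, "Warmblood"),
        BreedSpec("Friesian", 91, "Friesian"),
    )
    planted = (
        # shared across all three clusters
        PlantedCnvr("chr1", 10_000_000, 11_000_000, 3,
                    ("Draught", "Warmblood", "Friesian"), 0.30),
        PlantedCnvr("chr2", 50_000_000, 51_000_000, 1,
                    ("Draught", "Warmblood", "Friesian"), 0.30),
        # breed-private
        PlantedCnvr("chr1", 30_000_000, 30_800_000, 3, ("Friesian",), 0.30),
        PlantedCnvr("chr3", 20_000_000, 20_800_000, 1, ("Exmoor",), 0.30),
        PlantedCnvr("chr4", 40_000_000, 40_600_000, 3,
                    ("SwedishWarmblood",), 0.30),
        # cluster-private
        PlantedCnvr("chr5", 10_000_000, 10_800_000, 3, ("Warmblood",), 0.30),
        PlantedCnvr("chr2", 80_000_000, 80_800_000, 1, ("Draught",), 0.30),
    )
    return SimConfig(
        seed=seed,
        breeds=breeds,
        reference_breed="BelgianDraught",
        n_autosomes=5,
        chrom_length_bp=100_000_000,
        n_markers_per_chrom=1_000,
        planted_cnvrs=planted,
        noise_sd=0.05,
        reference_noise_sd=0.03,
        baf_noise_sd=0.02,
    )
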