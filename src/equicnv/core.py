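"""Shared in-memory containers for the CNV pipeline.

Coordinates on the marker map, segments and CNV regions are 1-based
inclusive base pairs, the convention genome browsers report; BED-style
annotation tracks are 0-based half-open and are converted at the I/O
boundary (see :mod:`equicnv.annotate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MarkerMap", "IntensityMatrix", "CohortLabels"]


@dataclass(frozen=True)
class MarkerMap:
    """Ordered autosomal marker coordinates shared by every sample.

    Parameters
    ----------
    df
        Columns ``marker`` (unique id), ``chrom``, ``pos`` (1-based bp).
        Rows must be sorted by chromosome then position, with positions
        strictly increasing within each chromosome.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"marker", "chrom", "pos"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        if self.df["marker"].duplicated().any():
            raise ValueError("duplicate marker ids in marker map")
        for chrom, grp in self.df.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(
                    f"marker positions not strictly increasing on {chrom}"
                )
        object.__setattr__(self, "df", self.df.reset_index(drop=True))

    @property
    def markers(self) -> pd.Index:
        return pd.Index(self.df["marker"])

    @property
    def n_markers(self) -> int:
        return len(self.df)

    def chrom_of(self) -> pd.Series:
        """marker id -> chromosome."""
        return self.df.set_index("marker")["chrom"]

    def pos_of(self) -> pd.Series:
        """marker id -> 1-based position."""
        return self.df.set_index("marker")["pos"]

    def ordinal_within_chrom(self) -> pd.Series:
        """marker id -> 0-based rank of the marker within its chromosome.

        Consecutive ranks identify physically adjacent markers, which is
        what segmentation needs to detect gaps of uncalled markers.
        """
        return self.df.groupby("chrom", sort=False).cumcount().set_axis(
            self.df["marker"]
        )


@dataclass(frozen=True)
class IntensityMatrix:
    """Total signal intensity and B-allele frequency per sample x marker.

    ``intensity`` and ``baf`` are individuals x markers DataFrames with
    identical labels; intensities are strictly positive (arbitrary units)
    and BAF lies in [0, 1].
    """

    intensity: pd.DataFrame = field(repr=False)
    baf: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.intensity.index.equals(self.baf.index) or not (
            self.intensity.columns.equals(self.baf.columns)
        ):
            raise ValueError("intensity and BAF matrices must share labels")
        inten = self.intensity.to_numpy()
        if not np.all(inten > 0):
            bad = np.argwhere(inten <= 0)[0]
            raise ValueError(
                "non-positive intensity for individual "
                f"{self.intensity.index[bad[0]]!r} at marker "
                f"{self.intensity.columns[bad[1]]!r}"
            )
        b = self.baf.to_numpy()
        if np.any((b < 0) | (b > 1)):
            raise ValueError("BAF values must lie in [0, 1]")

    @property
    def individuals(self) -> pd.Index:
        return self.intensity.index

    @property
    def markers(self) -> pd.Index:
        return self.intensity.columns

    def check_against(self, marker_map: MarkerMap) -> None:
        if not self.markers.equals(marker_map.markers):
            raise ValueError("matrix columns do not match the marker map")


@dataclass(frozen=True)
class CohortLabels:
    """Breed and breed-cluster assignment of every individual."""

    df: pd.DataFrame = field(repr=False)  # individual, breed, cluster

    def __post_init__(self) -> None:
        required = {"individual", "breed", "cluster"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"labels missing columns: {sorted(missing)}")
        if self.df["individual"].duplicated().any():
            raise ValueError("duplicate individuals in labels")
        object.__setattr__(self, "df", self.df.reset_index(drop=True))

    @property
    def individuals(self) -> pd.Index:
        return pd.Index(self.df["individual"])

    def group_of(self, group_by: str) -> pd.Series:
        """individual -> breed or cluster name."""
        if group_by not in ("breed", "cluster"):
            raise ValueError("group_by must be 'breed' or 'cluster'")
        return self.df.set_index("individual")[group_by]

    def group_sizes(self, group_by: str) -> pd.Series:
        return self.group_of(group_by).value_counts()

    def members(self, group_by: str, group: str) -> pd.Index:
        gr = self.group_of(group_by)
        return pd.Index(gr.index[gr == group])
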