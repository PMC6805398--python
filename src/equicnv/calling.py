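"""Reference-relative per-marker CNV calling.

The reference profile is the per-marker mean intensity over the designated
reference breed (the breed with the largest sample and the lowest signal
variance). Every individual — including members of the reference breed —
is compared against that profile: a marker is called a gain when

    log2(intensity / reference_mean) >= gain_threshold

and a loss when the log2 ratio <= -loss_threshold. Ties at a threshold
count as calls, so the decision boundary is deterministic. Thresholding is
strictly per marker; multi-marker evidence is enforced downstream by the
segmentation minimum-marker rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .core import CohortLabels, IntensityMatrix, MarkerMap

__all__ = ["ReferenceProfile", "build_reference_profile", "call_snp_cnvs"]

#: default symmetric log2-ratio threshold (~2.46 copies up, ~1.62 down)
DEFAULT_THRESHOLD = 0.3

CALL_COLUMNS = ["individual", "marker", "chrom", "pos", "state", "log2_ratio"]


@dataclass(frozen=True)
class ReferenceProfile:
    """Per-marker mean/sd intensity of the reference-breed individuals."""

    mean: pd.Series = field(repr=False)
    sd: pd.Series = field(repr=False)
    n_reference: int

    def __post_init__(self) -> None:
        if self.n_reference < 2:
            raise ValueError("reference profile needs >= 2 individuals")
        if not (self.mean > 0).all():
            bad = self.mean.index[self.mean <= 0][0]
            raise ValueError(f"zero/negative reference mean at marker {bad!r}")


def build_reference_profile(
    matrix: IntensityMatrix,
    labels: CohortLabels,
    reference_breed: str,
    exclude: Iterable[str] = (),
) -> ReferenceProfile:
    """Mean and sd of signal intensity per marker over the reference breed.

    ``exclude`` lists individuals dropped by upstream sample QC (the
    array-level quality metrics are inputs here, not recomputed).
    """
    breed_of = labels.group_of("breed")
    members = breed_of.index[breed_of == reference_breed].difference(exclude)
    members = matrix.individuals.intersection(members)
    if len(members) == 0:
        raise ValueError(f"reference breed {reference_breed!r} absent from labels")
    sub = matrix.intensity.loc[members]
    return ReferenceProfile(
        mean=sub.mean(axis=0),
        sd=sub.std(axis=0, ddof=1),
        n_reference=len(members),
    )


def call_snp_cnvs(
    matrix: IntensityMatrix,
    profile: ReferenceProfile,
    marker_map: MarkerMap,
    gain_threshold: float = DEFAULT_THRESHOLD,
    loss_threshold: float = DEFAULT_THRESHOLD,
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Call per-marker gains and losses against the reference profile.

    Returns a long DataFrame with one row per (individual, marker) call:
    columns ``individual, marker, chrom, pos, state, log2_ratio``, sorted
    by individual then genome position. Only threshold-crossing markers
    appear; a marker can never be both gain and loss for one individual.
    """
    if gain_threshold <= 0 or loss_threshold <= 0:
        raise ValueError("thresholds must be positive")
    matrix.check_against(marker_map)
    if not profile.mean.index.equals(matrix.markers):
        raise ValueError("reference profile does not match the marker map")

    keep = matrix.individuals.difference(exclude)
    inten = matrix.intensity.loc[keep]
    log2r = np.log2(inten.to_numpy() / profile.mean.to_numpy()[None, :])

    gain = log2r >= gain_threshold
    loss = log2r <= -loss_threshold
    rows_g, cols_g = np.nonzero(gain)
    rows_l, cols_l = np.nonzero(loss)

    chrom = marker_map.df["chrom"].to_numpy()
    pos = marker_map.df["pos"].to_numpy()
    marker = marker_map.df["marker"].to_numpy()
    ind = inten.index.to_numpy()

    calls = pd.DataFrame(
        {
            "individual": np.concatenate([ind[rows_g], ind[rows_l]]),
            "marker": np.concatenate([marker[cols_g], marker[cols_l]]),
            "chrom": np.concatenate([chrom[cols_g], chrom[cols_l]]),
            "pos": np.concatenate([pos[cols_g], pos[cols_l]]),
            "state": np.repeat(["gain", "loss"], [len(rows_g), len(rows_l)]),
            "log2_ratio": np.concatenate(
                [log2r[rows_g, cols_g], log2r[rows_l, cols_l]]
            ),
        }
    )
    return calls.sort_values(
        ["individual", "chrom", "pos"], kind="stable"
    ).reset_index(drop=True)
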