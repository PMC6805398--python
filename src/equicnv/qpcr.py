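"""Relative-quantification qPCR validation of CNV calls.

Copy number is quantified with the 2^-ddCt method: per sample and target
region, replicate Ct values are averaged, the target Ct is normalised
against a reference gene (dCt = Ct_target - Ct_reference), and the dCt is
compared with the dCt of a calibrator individual known to be diploid at
every assayed region (ddCt = dCt_sample - dCt_calibrator). The fold
change 2^-ddCt is ~1 for two copies, ~0.5 for one, ~1.5 for three and ~0
for a homozygous deletion, assuming 100% assay efficiency (exact doubling
per cycle).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "delta_ct",
    "fold_change",
    "copy_state",
    "concordance",
    "DEFAULT_CUTPOINTS",
]

#: fold-change bin edges between hom-deletion / one-copy loss / normal / dup
DEFAULT_CUTPOINTS = (0.25, 0.75, 1.25)

STATES = ["homozygous deletion", "one-copy deletion", "normal", "duplication"]


def delta_ct(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, region) dCt from a long replicate table.

    ``measurements`` columns: sample, region, gene ('target' or
    'reference'), ct. Replicates average before differencing, matching
    duplicate-well practice.
    """
    required = {"sample", "region", "gene", "ct"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing columns: {sorted(missing)}")
    ct = measurements["ct"]
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise ValueError("Ct values must be positive and finite")
    means = (
        measurements.groupby(["sample", "region", "gene"])["ct"]
        .mean()
        .unstack("gene")
    )
    for role in ("target", "reference"):
        if role not in means.columns or means[role].isna().any():
            raise ValueError(f"missing {role}-gene Ct for some sample/region")
    out = (means["target"] - means["reference"]).rename("dct").reset_index()
    return out


def fold_change(
    dct: pd.DataFrame, calibrator_sample: str
) -> pd.DataFrame:
    """2^-ddCt per (sample, region), against the diploid calibrator.

    The calibrator must have a dCt for every region in the table; its own
    fold change is exactly 1.
    """
    cal = dct[dct["sample"] == calibrator_sample].set_index("region")["dct"]
    if len(cal) == 0:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not found")
    missing = set(dct["region"]) - set(cal.index)
    if missing:
        raise ValueError(
            f"calibrator lacks regions: {sorted(missing)}"
        )
    out = dct.copy()
    out["ddct"] = out["dct"] - out["region"].map(cal)
    out["fold_change"] = np.exp2(-out["ddct"])
    return out


def copy_state(
    fold: float, cutpoints: tuple[float, float, float] = DEFAULT_CUTPOINTS
) -> str:
    """Assign a copy-number state from a 2^-ddCt fold change.

    Bins are lower-inclusive: a fold change exactly on a cutpoint falls
    into the bin whose lower edge it is (0.5 -> one-copy deletion,
    1.25 -> duplication).
    """
    if not np.isfinite(fold) or fold <= 0:
        raise ValueError(f"fold change must be positive, got {fold}")
    lo, mid, hi = cutpoints
    if not lo < mid < hi:
        raise ValueError("cutpoints must be strictly increasing")
    if fold < lo:
        return STATES[0]
    if fold < mid:
        return STATES[1]
    if fold < hi:
        return STATES[2]
    return STATES[3]


def concordance(
    array_states: pd.DataFrame, qpcr_states: pd.DataFrame
) -> pd.DataFrame:
    """Array-vs-qPCR agreement per region and overall.

    Both inputs carry columns sample, region, state, keyed identically;
    the overall row weights each region by its number of comparisons.
    """
    for df, src in ((array_states, "array"), (qpcr_states, "qpcr")):
        missing = {"sample", "region", "state"} - set(df.columns)
        if missing:
            raise ValueError(f"{src} states missing columns: {sorted(missing)}")
    merged = array_states.merge(
        qpcr_states, on=["sample", "region"], how="outer",
        suffixes=("_array", "_qpcr"), indicator=True,
    )
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        keys = list(bad[["sample", "region"]].itertuples(index=False, name=None))
        raise ValueError(f"unmatched (sample, region) keys: {keys[:5]}")
    merged["concordant"] = merged["state_array"] == merged["state_qpcr"]
    per_region = merged.groupby("region").agg(
        n_compared=("concordant", "size"),
        n_concordant=("concordant", "sum"),
    )
    per_region["rate_pct"] = (
        100.0 * per_region["n_concordant"] / per_region["n_compared"]
    )
    overall = pd.DataFrame(
        {
            "n_compared": [int(per_region["n_compared"].sum())],
            "n_concordant": [int(per_region["n_concordant"].sum())],
        },
        index=pd.Index(["overall"], name="region"),
    )
    overall["rate_pct"] = (
        100.0 * overall["n_concordant"] / overall["n_compared"]
    )
    return pd.concat([per_region, overall])
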