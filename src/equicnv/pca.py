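"""Principal component analysis of BAF and segment-signal matrices.

Implemented directly as an SVD of the (centered, optionally standardised)
data matrix so the centering/scaling switches and the sign convention are
explicit: each component's sign is fixed by making its largest-magnitude
loading positive, which renders the decomposition fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PcaResult", "run_pca", "segment_signal_matrix", "plot_pca"]


@dataclass(frozen=True)
class PcaResult:
    """Scores, loadings and per-component variance fractions.

    ``variance_explained`` covers *all* components of the decomposition
    (it sums to 1); ``scores`` and ``loadings`` may be truncated to the
    requested number of leading components.
    """

    scores: pd.DataFrame = field(repr=False)
    loadings: pd.DataFrame = field(repr=False)
    variance_explained: np.ndarray = field(repr=False)


def run_pca(
    matrix: pd.DataFrame,
    center: bool = True,
    scale: bool = False,
    n_components: int | None = None,
) -> PcaResult:
    """PCA via singular value decomposition.

    Parameters
    ----------
    matrix
        individuals x features, no missing values.
    center, scale
        Subtract column means / divide by column standard deviations.
        Scaling a zero-variance column is an error naming the column.
    n_components
        Leading components to keep in scores/loadings (default: all).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("PCA needs at least a 2 x 2 matrix")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    X = matrix.to_numpy(dtype=float)
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(
                f"zero-variance column with scale=True: {matrix.columns[zero[0]]!r}"
            )
        X = X / sd

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic orientation: largest-|loading| positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0

    var = s**2
    total = var.sum()
    var_explained = var / total if total > 0 else np.zeros_like(var)

    k = len(s) if n_components is None else min(n_components, len(s))
    comp = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(
            U[:, :k] * s[:k], index=matrix.index, columns=comp
        ),
        loadings=pd.DataFrame(Vt[:k].T, index=matrix.columns, columns=comp),
        variance_explained=var_explained,
    )


def segment_signal_matrix(
    segments: pd.DataFrame,
    regions: pd.DataFrame,
    individuals: pd.Index,
    encoding: str = "indicator",
    mixed_value: float = 0.0,
) -> pd.DataFrame:
    """individuals x CNVR matrix summarizing each individual's segment state.

    ``indicator`` encodes +1 when the individual's overlapping segments
    are all gains, -1 all losses, ``mixed_value`` (default 0) when states
    conflict or a mixed segment overlaps, and 0 with no overlap.
    ``mean_log2`` instead averages the overlapping segments' mean log2
    ratios, putting signal magnitude into the components.
    """
    if encoding not in ("indicator", "mean_log2"):
        raise ValueError("encoding must be 'indicator' or 'mean_log2'")
    out = pd.DataFrame(
        0.0, index=pd.Index(individuals, name="individual"),
        columns=regions.index,
    )
    if len(segments) == 0 or len(regions) == 0:
        return out
    cell: dict[tuple, list] = {}
    for chrom, reg in regions.groupby("chrom"):
        sub = segments[segments["chrom"] == chrom]
        if not len(sub):
            continue
        rs = reg["start"].to_numpy()
        re_ = reg["end"].to_numpy()
        for row in sub.itertuples(index=False):
            hit = np.flatnonzero((row.start <= re_) & (row.end >= rs))
            for h in hit:
                cell.setdefault((row.individual, reg.index[h]), []).append(row)
    for (ind, rid), rows in cell.items():
        if ind not in out.index:
            continue
        if encoding == "mean_log2":
            out.loc[ind, rid] = float(np.mean([r.mean_log2 for r in rows]))
        else:
            states = {r.state for r in rows}
            if states == {"gain"}:
                out.loc[ind, rid] = 1.0
            elif states == {"loss"}:
                out.loc[ind, rid] = -1.0
            else:
                out.loc[ind, rid] = mixed_value
    return out


def plot_pca(result: PcaResult, groups: pd.Series, path) -> None:
    """PC1-vs-PC2 scatter colored by group label, written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for name, idx in result.scores.groupby(
        groups.reindex(result.scores.index)
    ).groups.items():
        sub = result.scores.loc[idx]
        ax.scatter(sub["PC1"], sub["PC2"], s=8, label=str(name), alpha=0.7)
    ve = result.variance_explained
    ax.set_xlabel(f"PC1 ({100 * ve[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * ve[1]:.1f}%)")
    ax.legend(fontsize=7, markerscale=1.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
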