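"""Readers and writers for the pipeline's on-disk formats.

All tabular interchange is TSV; interval tracks are BED (0-based
half-open); marker/segment/region report tables carry 1-based inclusive
coordinates. Conversions between the two conventions live here and in
:mod:`equicnv.annotate` only.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import CohortLabels, IntensityMatrix, MarkerMap

__all__ = [
    "read_bed",
    "write_bed",
    "read_marker_map",
    "write_marker_map",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_calls",
    "write_calls",
    "read_segments",
    "write_segments",
    "write_segments_bed",
    "write_cnvrs",
]

BED6 = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 into a 0-based half-open interval track.

    Track lines and browser lines are skipped; the optional name column
    is synthesised from the filename when absent. Malformed coordinates
    raise with the 1-based line number.
    """
    path = Path(path)
    rows = []
    stem = path.stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 else f"{stem}_{lineno}"
            score = fields[4] if len(fields) > 4 else "."
            rows.append((chrom, start, end, name, score))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])


def write_bed(track: pd.DataFrame, path) -> None:
    out = track.copy()
    if "name" not in out.columns:
        out["name"] = [f"iv_{i}" for i in range(len(out))]
    if "score" not in out.columns:
        out["score"] = "."
    out["strand"] = out.get("strand", ".")
    out[BED6].to_csv(path, sep="\t", header=False, index=False)


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return MarkerMap(df[["marker", "chrom", "pos"]])


def write_marker_map(marker_map: MarkerMap, path) -> None:
    marker_map.df.to_csv(path, sep="\t", index=False)


def write_matrix(matrix: IntensityMatrix, prefix) -> tuple[Path, Path]:
    """Write intensity and BAF as gzip TSV (individual rows, marker cols)."""
    prefix = Path(prefix)
    ipath = prefix.parent / f"{prefix.name}.intensity.tsv.gz"
    bpath = prefix.parent / f"{prefix.name}.baf.tsv.gz"
    matrix.intensity.rename_axis("individual").to_csv(ipath, sep="\t")
    matrix.baf.rename_axis("individual").to_csv(bpath, sep="\t")
    return ipath, bpath


def read_matrix(prefix) -> IntensityMatrix:
    prefix = Path(prefix)
    inten = pd.read_csv(
        prefix.parent / f"{prefix.name}.intensity.tsv.gz",
        sep="\t", index_col="individual",
    )
    baf = pd.read_csv(
        prefix.parent / f"{prefix.name}.baf.tsv.gz",
        sep="\t", index_col="individual",
    )
    inten.columns.name = "marker"
    baf.columns.name = "marker"
    return IntensityMatrix(intensity=inten, baf=baf)


def read_labels(path) -> CohortLabels:
    return CohortLabels(pd.read_csv(path, sep="\t"))


def write_labels(labels: CohortLabels, path) -> None:
    labels.df.to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path) -> pd.Series:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "size"], dtype={"chrom": str}
    )
    return df.set_index("chrom")["size"]


def write_chrom_sizes(sizes: pd.Series, path) -> None:
    sizes.rename("size").rename_axis("chrom").reset_index().to_csv(
        path, sep="\t", header=False, index=False
    )


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_segments(segments: pd.DataFrame, path) -> None:
    """Report-style segment table, 1-based inclusive coordinates."""
    segments.to_csv(path, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_segments_bed(segments: pd.DataFrame, path) -> None:
    """Segments as BED6 (0-based half-open), score = marker count."""
    bed = pd.DataFrame(
        {
            "chrom": segments["chrom"],
            "start": segments["start"] - 1,
            "end": segments["end"],
            "name": segments["individual"].astype(str)
            + "|" + segments["state"].astype(str),
            "score": segments["n_markers"],
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_cnvrs(regions: pd.DataFrame, path) -> None:
    """CNVR report table (1-based inclusive) with per-breed carrier counts."""
    regions.reset_index().to_csv(path, sep="\t", index=False)
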