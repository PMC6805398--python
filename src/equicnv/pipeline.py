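"""End-to-end orchestration: calling -> segmentation -> CNVRs -> sharing
-> PCA -> annotation, with every stage output written to an output
directory and a JSON run log recording version, config hash and seed."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, annotate, calling, io, pca, regions, segments, sharing
from .core import CohortLabels, IntensityMatrix, MarkerMap

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and knobs for a full pipeline run."""

    reference_breed: str
    gain_threshold: float = 0.3
    loss_threshold: float = 0.3
    min_markers: int = 3
    max_gap_markers: int = 0
    min_fraction: float = 0.01
    highlight_pct: float = 20.0
    seed: int = 0
    exclude: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.gain_threshold <= 0 or self.loss_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    calls: pd.DataFrame
    segments: pd.DataFrame
    cnvrs: pd.DataFrame
    segment_region: pd.Series
    segment_table: pd.DataFrame
    coverage: pd.DataFrame
    segment_share: pd.DataFrame
    breed_freq: pd.DataFrame
    breed_private: sharing.PrivateCnvReport
    cluster_private: sharing.PrivateCnvReport
    breed_highlights: pd.DataFrame
    cluster_highlights: pd.DataFrame
    baf_pca: pca.PcaResult
    segment_pca: pca.PcaResult | None
    annotation: dict = field(default_factory=dict)


def run_pipeline(
    marker_map: MarkerMap,
    matrix: IntensityMatrix,
    labels: CohortLabels,
    chrom_sizes: pd.Series,
    config: PipelineConfig,
    outdir: str | Path | None = None,
    gene_track: pd.DataFrame | None = None,
    qtl_track: pd.DataFrame | None = None,
    known_catalog: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run every analysis stage in dependency order.

    Deterministic given identical inputs and config; stage failures
    propagate with the stage name prefixed to the error.
    """
    try:
        profile = calling.build_reference_profile(
            matrix, labels, config.reference_breed, exclude=config.exclude
        )
        calls = calling.call_snp_cnvs(
            matrix, profile, marker_map,
            gain_threshold=config.gain_threshold,
            loss_threshold=config.loss_threshold,
            exclude=config.exclude,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'calling' failed: {exc}") from exc

    try:
        segs = segments.build_segments(
            calls, marker_map,
            min_markers=config.min_markers,
            max_gap_markers=config.max_gap_markers,
        )
        seg_table = segments.segment_summary(segs, labels, chrom_sizes)
    except Exception as exc:
        raise RuntimeError(f"stage 'segmentation' failed: {exc}") from exc

    try:
        cnvrs, seg_region = regions.merge_to_cnvrs(segs, labels)
        coverage = regions.chromosome_coverage(
            segs, chrom_sizes, labels.individuals
        )
        share = (
            regions.chromosome_segment_share(segs)
            if len(segs)
            else pd.DataFrame()
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'cnvr' failed: {exc}") from exc

    try:
        breed_freq = sharing.position_frequency(
            calls, labels, "breed", config.min_fraction
        )
        breed_priv = sharing.unique_private(
            calls, labels, "breed", config.min_fraction
        )
        cluster_priv = sharing.unique_private(
            calls, labels, "cluster", config.min_fraction
        )
        _, breed_high = sharing.private_chromosome_profile(
            breed_priv, config.highlight_pct
        )
        _, cluster_high = sharing.private_chromosome_profile(
            cluster_priv, config.highlight_pct
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'sharing' failed: {exc}") from exc

    try:
        baf_pca = pca.run_pca(matrix.baf, n_components=10)
        seg_pca = None
        if len(cnvrs) >= 2:
            sig = pca.segment_signal_matrix(segs, cnvrs, labels.individuals)
            if sig.shape[1] >= 2:
                seg_pca = pca.run_pca(sig, n_components=min(10, sig.shape[1]))
    except Exception as exc:
        raise RuntimeError(f"stage 'pca' failed: {exc}") from exc

    annotation: dict = {}
    try:
        if len(cnvrs):
            track = annotate.cnvrs_to_track(cnvrs)
            if gene_track is not None:
                frac, per_region, union = annotate.gene_content_summary(
                    track, gene_track
                )
                annotation["genic_fraction"] = frac
                annotation["genes_per_region"] = per_region
                annotation["gene_union"] = union
            if qtl_track is not None:
                annotation["qtl_overlaps"] = annotate.intersect(track, qtl_track)
            if known_catalog is not None:
                flagged, novelty = annotate.flag_novel(track, known_catalog)
                annotation["novelty"] = novelty
                annotation["novel_flags"] = flagged
    except Exception as exc:
        raise RuntimeError(f"stage 'annotation' failed: {exc}") from exc

    res = PipelineResult(
        calls=calls,
        segments=segs,
        cnvrs=cnvrs,
        segment_region=seg_region,
        segment_table=seg_table,
        coverage=coverage,
        segment_share=share,
        breed_freq=breed_freq,
        breed_private=breed_priv,
        cluster_private=cluster_priv,
        breed_highlights=breed_high,
        cluster_highlights=cluster_high,
        baf_pca=baf_pca,
        segment_pca=seg_pca,
        annotation=annotation,
    )
    if outdir is not None:
        _write_outputs(res, labels, config, Path(outdir))
    return res


def _write_outputs(
    res: PipelineResult,
    labels: CohortLabels,
    config: PipelineConfig,
    outdir: Path,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_calls(res.calls, outdir / "snp_cnv_calls.tsv")
    io.write_segments(res.segments, outdir / "segments.tsv")
    if len(res.segments):
        io.write_segments_bed(res.segments, outdir / "segments.bed")
    io.write_cnvrs(res.cnvrs, outdir / "cnvrs.tsv")
    res.segment_table.to_csv(outdir / "segment_summary_by_breed.tsv", sep="\t")
    res.coverage.to_csv(outdir / "chromosome_coverage.tsv", sep="\t")
    if len(res.segment_share):
        res.segment_share.to_csv(outdir / "chromosome_segment_share.tsv", sep="\t")
    res.breed_freq.to_csv(outdir / "breed_position_frequency.tsv",
                          sep="\t", index=False)
    res.breed_private.summary.to_csv(outdir / "breed_private_summary.tsv",
                                     sep="\t", index=False)
    res.cluster_private.summary.to_csv(outdir / "cluster_private_summary.tsv",
                                       sep="\t", index=False)
    for name, high in (
        ("breed", res.breed_highlights),
        ("cluster", res.cluster_highlights),
    ):
        bed = pd.DataFrame(
            {
                "chrom": high["chrom"],
                "start": high["pos"] - 1,
                "end": high["pos"],
                "name": high["group"].astype(str) + "|" + high["state"],
                "score": high["pct_carriers"].round(2),
                "strand": ".",
            }
        )
        io.write_bed(bed, outdir / f"{name}_private_highlights.bed")
    res.baf_pca.scores.to_csv(outdir / "baf_pca_scores.tsv", sep="\t")
    pd.Series(
        res.baf_pca.variance_explained, name="variance_explained"
    ).rename_axis("component").to_csv(outdir / "baf_pca_variance.tsv", sep="\t")
    if res.segment_pca is not None:
        res.segment_pca.scores.to_csv(outdir / "segment_pca_scores.tsv", sep="\t")
    if "novelty" in res.annotation:
        with open(outdir / "novelty_summary.json", "w") as fh:
            json.dump(res.annotation["novelty"], fh, indent=2)
    log = {
        "tool": "equicnv",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_individuals": int(len(labels.individuals)),
        "n_calls": int(len(res.calls)),
        "n_segments": int(len(res.segments)),
        "n_cnvrs": int(len(res.cnvrs)),
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
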