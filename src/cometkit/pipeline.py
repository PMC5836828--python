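"""End-to-end orchestration of the four-stage analysis.

Stage order: smoothing -> histogram thresholding (first valley, Otsu
fallback) -> 8-connectivity labeling -> border/fragment filtering ->
overlap correction -> per-comet characterization (optional
classification).  Per-comet failures are flagged, never fatal; the whole
run is deterministic for a fixed config.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import binarize, refine
from .characterize import DegenerateCometError, characterize_comet
from .config import PipelineConfig
from .io import crop_comet, load_image, save_image, save_label_mask
from .preprocess import smooth
from .records import CometRecord, write_records

log = logging.getLogger("cometkit")


@dataclass
class PipelineResult:
    records: list[CometRecord]
    labels: np.ndarray
    threshold: float
    threshold_method: str
    stage_counts: dict = field(default_factory=dict)


def analyze_image(img: np.ndarray, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full pipeline on an in-memory grayscale image."""
    if config is None:
        config = PipelineConfig()
    img = np.asarray(img, dtype=np.float64)

    smoothed = smooth(img, config.smoothing_method, config.smoothing_window)
    binary, threshold, used = binarize.threshold_image(
        smoothed, config.threshold_method, config.histogram_bins,
        config.histogram_smooth_window)
    # ambient background pedestal is not DNA: subtract the background level
    # (median of sub-threshold pixels) before any intensity measurement
    background = float(np.median(smoothed[binary == 0])) if (binary == 0).any() else 0.0
    measured = np.clip(smoothed - background, 0.0, None)
    labels = binarize.label_components(binary, connectivity=8)
    counts = {"candidates": int(labels.max())}

    labels = refine.remove_border_objects(labels)
    counts["after_border_filter"] = int(labels.max())
    labels = refine.merge_small_fragments(labels, config.small_fragment_fraction)
    counts["after_fragment_merge"] = int(labels.max())
    if config.overlap_correction:
        labels = refine.correct_overlaps(labels, config)
    counts["after_overlap_correction"] = int(labels.max())
    log.info("stage counts: %s", counts)

    records: list[CometRecord] = []
    for comet_id in range(1, int(labels.max()) + 1):
        try:
            records.append(characterize_comet(measured, labels, comet_id, config))
        except DegenerateCometError as exc:
            warnings.warn(f"comet {comet_id}: {exc}")
            member = labels == comet_id
            rows, cols = np.nonzero(member)
            records.append(CometRecord(
                id=int(comet_id),
                bbox=(int(rows.min()), int(cols.min()),
                      int(rows.max()) + 1, int(cols.max()) + 1),
                centroid=(float(rows.mean()), float(cols.mean())),
                cph=int(cols.min()), head_radius_r=0.0, tail_length=0.0,
                tail_distance=0.0, dna=0.0, tdna=0.0, extent_moment=0.0,
                olive_moment=0.0, inertia_moment=0.0, flags="degenerate"))
    return PipelineResult(records, labels, threshold, used, counts)


def run_pipeline(image_path: str | Path, config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Analyze one image file; optionally write records CSV, the 16-bit
    label mask, and per-comet crops under ``out_dir``."""
    if config is None:
        config = PipelineConfig()
    img = load_image(image_path, config.channel)
    result = analyze_image(img, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = Path(image_path).stem
        write_records(result.records, out_dir / f"{stem}_comets.csv")
        save_label_mask(result.labels, out_dir / f"{stem}_mask.png")
        for rec in result.records:
            crop = crop_comet(img, result.labels, rec.id)
            save_image(crop, out_dir / f"{stem}_comet{rec.id:03d}.png")
    return result


def run_batch(directory: str | Path, config: PipelineConfig | None = None,
              out_dir: str | Path | None = None,
              patterns: tuple[str, ...] = ("*.png", "*.tif", "*.tiff")) -> dict:
    """Process every raster in a directory independently.

    Returns ``{"images": {name: PipelineResult}, "failures": {name: msg}}``.
    """
    directory = Path(directory)
    results: dict = {"images": {}, "failures": {}}
    files: list[Path] = []
    for pat in patterns:
        files.extend(sorted(directory.glob(pat)))
    for path in sorted(set(files)):
        try:
            results["images"][path.name] = run_pipeline(path, config, out_dir)
        except Exception as exc:  # noqa: BLE001 - batch resilience
            log.error("failed on %s: %s", path.name, exc)
            results["failures"][path.name] = str(exc)
    return results
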