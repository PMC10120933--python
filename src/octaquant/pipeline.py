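"""Batch orchestration of the two-branch pipeline.

Each delineated image goes through: preprocessing (grayscale 8-bit,
contrast stretch inside the ROI, background cleared) -> branch 1
(Gaussian 1A -> Frangi 1B -> local median threshold 1C -> area biomarkers)
and branch 2 (Mexican hat 2A -> local median threshold -> skeletonize /
tag / prune 2B -> skeletal biomarkers).  Both branches consume the same
preprocessed input.  Processing order is lexicographic by filename and the
whole pipeline is deterministic, so reruns produce byte-identical CSVs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import raster_io
from .biomarkers import CSV_COLUMNS, CSV_UNITS_COMMENT, BiomarkerRecord, assemble_record
from .raster_io import RasterImage, ValidationError
from .skeleton_analysis import PruneConfig, prune, skeletonize, tag_skeleton
from .vessel_filters import (
    FilterConfig,
    frangi_vesselness,
    gaussian_blur,
    local_median_threshold,
    mexican_hat,
)

#: the five intermediate stages saved per input when stage-saving is on
STAGE_NAMES = ("stage1A", "stage1B", "stage1C", "stage2A", "stage2B")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the batch runner needs; mirrors the interactive dialog
    of the original macro as flags/fields."""

    input_dir: Path | str = "."
    output_dir: Path | str = "."
    image_format: str = "tiff"  # "tiff" | "png"
    scale: float = 170.0
    save_stages: bool = False
    filter: FilterConfig = field(default_factory=FilterConfig)
    prune: PruneConfig = field(default_factory=PruneConfig)
    contrast_saturation: float = 0.0035
    box_sizes: tuple[int, ...] | None = None
    random_seed: int = 0  # used only by phantom generation

    def __post_init__(self) -> None:
        if self.image_format not in ("tiff", "png"):
            raise ValidationError(f"unsupported image format {self.image_format!r}")
        if not (self.scale > 0):
            raise ValidationError("scale must be positive")


@dataclass
class RunLog:
    """Per-image status and timings plus the config snapshot of a run."""

    config: PipelineConfig
    entries: list[dict] = field(default_factory=list)

    def add(self, image: str, status: str, seconds: float) -> None:
        self.entries.append({"image": image, "status": status, "seconds": round(seconds, 3)})

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("# octaquant run log\n")
            for key, value in asdict(self.config).items():
                fh.write(f"config.{key}={value}\n")
            for e in self.entries:
                fh.write(f"image={e['image']}\tstatus={e['status']}\tseconds={e['seconds']}\n")


def run_single(
    image_path: str | Path,
    config: PipelineConfig,
    mask_path: str | Path | None = None,
) -> tuple[BiomarkerRecord, dict[str, RasterImage]]:
    """Process one delineated image; returns the record and the 5 stage images."""
    img = raster_io.load_image(image_path, config.scale)
    roi = raster_io.derive_roi(img, mask_path)
    pre = raster_io.to_8bit(img)
    pre = raster_io.adjust_contrast(pre, config.contrast_saturation, roi)
    pre = raster_io.clear_outside(pre, roi)
    fc = config.filter

    # branch 1: area biomarkers
    s1a = gaussian_blur(pre, fc.gaussian_sigma)
    s1b = frangi_vesselness(s1a, fc.frangi_scales, fc.frangi_beta, fc.frangi_c)
    vessels = local_median_threshold(s1b, fc.threshold_radius, fc.threshold_offset, roi)

    # branch 2: skeletal biomarkers
    s2a = mexican_hat(pre, fc.mexican_hat_radius, fc.mexican_hat_sigma)
    binary2 = local_median_threshold(s2a, fc.threshold_radius, fc.threshold_offset, roi)
    skeleton = skeletonize(binary2)
    graph = prune(tag_skeleton(skeleton), config.prune)

    record = assemble_record(roi, vessels, graph, config.box_sizes)
    stages = {
        "stage1A": s1a,
        "stage1B": s1b,
        "stage1C": RasterImage(vessels.mask.astype("uint8") * 255, config.scale),
        "stage2A": s2a,
        "stage2B": RasterImage(graph.skeleton.astype("uint8") * 255, config.scale),
    }
    return record, stages


def _discover_inputs(config: PipelineConfig) -> list[Path]:
    exts = (".tif", ".tiff") if config.image_format == "tiff" else (".png",)
    indir = Path(config.input_dir)
    files = sorted(
        p
        for p in indir.iterdir()
        if p.suffix.lower() in exts and not p.stem.endswith("_mask")
    )
    return files


def _sibling_mask(path: Path) -> Path | None:
    for suffix in (path.suffix, ".tif", ".tiff", ".png"):
        cand = path.with_name(f"{path.stem}_mask{suffix}")
        if cand.exists():
            return cand
    return None


def run_batch(config: PipelineConfig) -> tuple[Path, RunLog]:
    """Run the pipeline over every matching file in the input directory.

    Writes ``biomarkers.csv`` (one row per successful image, a units
    comment line, columns in the published table order), a mean/SD/min/max
    summary CSV, and ``run_log.txt`` to the output directory.  A failure on
    one image is logged and never stops the batch.
    """
    files = _discover_inputs(config)
    if not files:
        raise ValidationError(
            f"no {config.image_format} images found in {config.input_dir}"
        )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = RunLog(config=config)
    rows = []
    for path in files:
        t0 = time.perf_counter()
        try:
            record, stages = run_single(path, config, _sibling_mask(path))
            rows.append(record.as_row(path.stem))
            if config.save_stages:
                for stage_name in STAGE_NAMES:
                    raster_io.save_image(
                        stages[stage_name], outdir / f"{path.stem}_{stage_name}.tif"
                    )
            log.add(path.name, "ok", time.perf_counter() - t0)
        except Exception as exc:  # noqa: BLE001 - isolation: one bad file never stops the batch
            log.add(path.name, f"failed:{exc}", time.perf_counter() - t0)
    csv_path = outdir / "biomarkers.csv"
    table = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    with open(csv_path, "w", newline="") as fh:
        fh.write(CSV_UNITS_COMMENT + "\n")
        table.to_csv(fh, index=False)
    numeric = table.drop(columns=["image"]).apply(pd.to_numeric, errors="coerce")
    if len(numeric):
        summary = numeric.agg(["mean", "std", "min", "max"]).T
        summary.index.name = "biomarker"
        summary.to_csv(outdir / "biomarkers_summary.csv")
    log.write(outdir / "run_log.txt")
    return csv_path, log
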