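"""Synthetic OCTA-like vascular phantoms with analytic ground truth.

Phantoms emulate the imaging character of en-face OCTA exports: bright
vessels (~200) on a dark background (~20), 8-bit depth, multiplicative
speckle-like noise, and a lesion ROI outside which the image is cleared to
0.  Ground truth (centerline length, junction count, width, per-branch
arc-chord ratios) is computed from the continuous geometry of the
primitives, not from rasterized pixels, so recovery tolerances honestly
absorb discretization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .raster_io import RasterImage, RoiMask, ValidationError, save_image


@dataclass(frozen=True)
class Segment:
    """Straight vessel: centerline from p0 to p1 (row, col), round caps."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    width: float = 5.0

    @property
    def length_px(self) -> float:
        return math.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])

    @property
    def arc_chord(self) -> float:
        return 1.0


@dataclass(frozen=True)
class Arc:
    """Circular-arc vessel around ``center`` from theta0 to theta1 (radians).

    Angles follow atan2(row - cy, col - cx); theta1 > theta0, swept
    counter-clockwise in array coordinates.
    """

    center: tuple[float, float]
    radius: float
    theta0: float
    theta1: float
    width: float = 5.0

    @property
    def length_px(self) -> float:
        return (self.theta1 - self.theta0) * self.radius

    @property
    def arc_chord(self) -> float:
        half = (self.theta1 - self.theta0) / 2.0
        chord = 2.0 * self.radius * math.sin(half)
        return self.length_px / chord if chord > 0 else math.inf


@dataclass(frozen=True)
class Disc:
    """Filled disc (used as a space-filling pattern, not a vessel)."""

    center: tuple[float, float]
    radius: float

    @property
    def length_px(self) -> float:
        return math.nan  # a filled region has no meaningful centerline length

    @property
    def arc_chord(self) -> float:
        return math.nan


Primitive = Segment | Arc | Disc


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic image.

    ``junctions`` states, by construction, how many points >= 3 vessel
    branches meet; ``speckle`` is the half-width of the multiplicative
    uniform noise factor (0 = noiseless).  ``roi_margin`` pads the
    bounding box of the primitives to form the rectangular lesion ROI.
    """

    name: str
    primitives: tuple[Primitive, ...]
    junctions: int = 0
    endpoints: int = 0
    shape: tuple[int, int] = (1024, 1024)
    scale: float = 170.0
    vessel_intensity: float = 200.0
    background_intensity: float = 20.0
    speckle: float = 0.0
    roi_margin: int = 15
    seed: int = 0


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth for one phantom, in the biomarkers' units."""

    mcnv_area_mm2: float
    vessel_mask: np.ndarray  # rendered noiseless membership mask (reference only)
    vessel_area_mm2: float
    vessel_length_mm: float
    vessel_junctions: int
    endpoints: int
    mean_width_um: float
    branch_arc_chord: tuple[float, ...]


def _distance_mask(shape: tuple[int, int], prim: Primitive) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    if isinstance(prim, Segment):
        (r0, c0), (r1, c1) = prim.p0, prim.p1
        dr, dc = r1 - r0, c1 - c0
        denom = dr * dr + dc * dc
        if denom == 0:
            d = np.hypot(yy - r0, xx - c0)
        else:
            t = np.clip(((yy - r0) * dr + (xx - c0) * dc) / denom, 0.0, 1.0)
            d = np.hypot(yy - (r0 + t * dr), xx - (c0 + t * dc))
        return d <= prim.width / 2.0
    if isinstance(prim, Arc):
        cy, cx = prim.center
        rad = np.hypot(yy - cy, xx - cx)
        ang = np.arctan2(yy - cy, xx - cx)
        # unwrap angles into [theta0, theta0 + 2pi)
        rel = np.mod(ang - prim.theta0, 2 * np.pi)
        span = prim.theta1 - prim.theta0
        in_band = (rel <= span) & (np.abs(rad - prim.radius) <= prim.width / 2.0)
        # round caps at the arc endpoints
        for th in (prim.theta0, prim.theta1):
            er = cy + prim.radius * math.sin(th)
            ec = cx + prim.radius * math.cos(th)
            in_band |= np.hypot(yy - er, xx - ec) <= prim.width / 2.0
        return in_band
    if isinstance(prim, Disc):
        return np.hypot(yy - prim.center[0], xx - prim.center[1]) <= prim.radius
    raise ValidationError(f"unknown primitive type {type(prim).__name__}")


def _primitive_bounds(prim: Primitive) -> tuple[float, float, float, float]:
    if isinstance(prim, Segment):
        w = prim.width / 2.0
        rs = (prim.p0[0], prim.p1[0])
        cs = (prim.p0[1], prim.p1[1])
        return min(rs) - w, min(cs) - w, max(rs) + w, max(cs) + w
    if isinstance(prim, Arc):
        w = prim.radius + prim.width / 2.0
        return prim.center[0] - w, prim.center[1] - w, prim.center[0] + w, prim.center[1] + w
    if isinstance(prim, Disc):
        return (
            prim.center[0] - prim.radius,
            prim.center[1] - prim.radius,
            prim.center[0] + prim.radius,
            prim.center[1] + prim.radius,
        )
    raise ValidationError(f"unknown primitive type {type(prim).__name__}")


def roi_for_spec(spec: PhantomSpec) -> np.ndarray:
    """Rectangular ROI: primitive bounding box padded by ``roi_margin``."""
    r0 = c0 = math.inf
    r1 = c1 = -math.inf
    for prim in spec.primitives:
        a, b, c, d = _primitive_bounds(prim)
        r0, c0, r1, c1 = min(r0, a), min(c0, b), max(r1, c), max(c1, d)
    r0 = int(math.floor(r0)) - spec.roi_margin
    c0 = int(math.floor(c0)) - spec.roi_margin
    r1 = int(math.ceil(r1)) + spec.roi_margin
    c1 = int(math.ceil(c1)) + spec.roi_margin
    if r0 < 0 or c0 < 0 or r1 >= spec.shape[0] or c1 >= spec.shape[1]:
        raise ValidationError(
            f"phantom '{spec.name}': primitives (+margin) extend outside the canvas"
        )
    roi = np.zeros(spec.shape, dtype=bool)
    roi[r0 : r1 + 1, c0 : c1 + 1] = True
    return roi


def render_phantom(spec: PhantomSpec) -> tuple[RasterImage, RoiMask, GroundTruth]:
    """Rasterize a phantom and return image, ROI mask and analytic truth.

    Rendering is deterministic given the seed; changing the seed changes
    only the noise realization, never the geometry or the ground truth.
    """
    if not spec.primitives:
        raise ValidationError("phantom needs at least one primitive")
    roi = roi_for_spec(spec)
    vessel = np.zeros(spec.shape, dtype=bool)
    for prim in spec.primitives:
        vessel |= _distance_mask(spec.shape, prim)
    img = np.full(spec.shape, spec.background_intensity, dtype=np.float64)
    img[vessel] = spec.vessel_intensity
    if spec.speckle > 0:
        rng = np.random.default_rng(spec.seed)
        img *= rng.uniform(1.0 - spec.speckle, 1.0 + spec.speckle, size=spec.shape)
    img[~roi] = 0.0
    raster = RasterImage(pixels=np.clip(np.rint(img), 0, 255).astype(np.uint8), scale=spec.scale)

    lengths = [p.length_px for p in spec.primitives if not isinstance(p, Disc)]
    widths = [p.width for p in spec.primitives if not isinstance(p, Disc)]
    truth = GroundTruth(
        mcnv_area_mm2=float(roi.sum()) / spec.scale**2,
        vessel_mask=vessel,
        vessel_area_mm2=float(vessel.sum()) / spec.scale**2,
        vessel_length_mm=float(np.sum(lengths)) / spec.scale if lengths else math.nan,
        vessel_junctions=spec.junctions,
        endpoints=spec.endpoints,
        mean_width_um=float(np.mean(widths)) / spec.scale * 1000.0 if widths else math.nan,
        branch_arc_chord=tuple(
            p.arc_chord for p in spec.primitives if not isinstance(p, Disc)
        ),
    )
    return raster, RoiMask(mask=roi, provenance="explicit-mask-file"), truth


def _bifurcating_tree(
    root: tuple[float, float], trunk_len: float, levels: int, width: float, spread: float = 0.6
) -> tuple[tuple[Segment, ...], int, int]:
    """Binary tree of segments growing upward; returns (segments, junctions, endpoints).

    Each of ``levels`` bifurcations splits the current tip into two branches
    at +-``spread`` radians from the parent direction, with lengths shrinking
    by 0.7 per level.  Junction count = number of internal bifurcation
    points; endpoints = leaves + the root tip.
    """
    segs: list[Segment] = []
    junctions = 0
    tips: list[tuple[tuple[float, float], float, float]] = []  # (point, direction, length)
    tip = (root[0] - trunk_len, root[1])
    segs.append(Segment(root, tip, width))
    tips.append((tip, -math.pi / 2, trunk_len * 0.7))
    for _ in range(levels):
        new_tips = []
        for point, direction, length in tips:
            junctions += 1
            for delta in (-spread, spread):
                ang = direction + delta
                end = (point[0] + length * math.sin(ang), point[1] + length * math.cos(ang))
                segs.append(Segment(point, end, width))
                new_tips.append((end, ang, length * 0.7))
        tips = new_tips
    return tuple(segs), junctions, len(tips) + 1


def standard_battery(
    shape: tuple[int, int] = (1024, 1024),
    scale: float = 170.0,
    width: float = 5.0,
    seed: int = 0,
    speckle: float = 0.2,
) -> tuple[PhantomSpec, ...]:
    """The standard phantom battery, noiseless plus noisy variants.

    Geometry is placed around the canvas center with sizes proportional to
    the canvas so the battery also works at reduced resolutions.
    """
    h, w = shape
    cy, cx = h / 2.0, w / 2.0
    arm = min(h, w) * 0.22
    radius = min(h, w) * 0.18
    base: list[PhantomSpec] = [
        PhantomSpec(
            name="line",
            primitives=(Segment((cy, cx - arm), (cy, cx + arm), width),),
            junctions=0,
            endpoints=2,
            shape=shape,
            scale=scale,
            seed=seed,
        ),
        PhantomSpec(
            name="half_circle",
            primitives=(Arc((cy, cx), radius, 0.0, math.pi, width),),
            junctions=0,
            endpoints=2,
            shape=shape,
            scale=scale,
            seed=seed,
        ),
        PhantomSpec(
            name="cross",
            primitives=(
                Segment((cy, cx - arm), (cy, cx + arm), width),
                Segment((cy - arm, cx), (cy + arm, cx), width),
            ),
            junctions=1,
            endpoints=4,
            shape=shape,
            scale=scale,
            seed=seed,
        ),
        PhantomSpec(
            name="h_shape",
            primitives=(
                Segment((cy - arm, cx - arm * 0.6), (cy + arm, cx - arm * 0.6), width),
                Segment((cy - arm, cx + arm * 0.6), (cy + arm, cx + arm * 0.6), width),
                Segment((cy, cx - arm * 0.6), (cy, cx + arm * 0.6), width),
            ),
            junctions=2,
            endpoints=4,
            shape=shape,
            scale=scale,
            seed=seed,
        ),
        PhantomSpec(
            name="disc",
            primitives=(Disc((cy, cx), radius),),
            junctions=0,
            endpoints=0,
            shape=shape,
            scale=scale,
            seed=seed,
        ),
    ]
    tree_segs, tree_junctions, tree_endpoints = _bifurcating_tree(
        (cy + arm, cx), arm * 0.9, 2, width
    )
    base.append(
        PhantomSpec(
            name="tree",
            primitives=tree_segs,
            junctions=tree_junctions,
            endpoints=tree_endpoints,
            shape=shape,
            scale=scale,
            seed=seed,
        )
    )
    noisy = [
        replace(spec, name=f"{spec.name}_noisy", speckle=speckle, seed=seed + 1)
        for spec in base
    ]
    return tuple(base + noisy)


def make_test_suite(out_dir: str | Path, seed: int = 0, shape=(1024, 1024)) -> pd.DataFrame:
    """Write the battery as TIFF image/mask pairs plus a ground-truth table.

    Returns the table (one row per phantom) that is also written to
    ``ground_truth.tsv``.  File naming: ``<name>.tif`` and ``<name>_mask.tif``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in standard_battery(shape=shape, seed=seed):
        img, roi, truth = render_phantom(spec)
        save_image(img, out / f"{spec.name}.tif")
        save_image(
            RasterImage(pixels=roi.mask.astype(np.uint8) * 255, scale=spec.scale),
            out / f"{spec.name}_mask.tif",
        )
        rows.append(
            {
                "name": spec.name,
                "speckle": spec.speckle,
                "mcnv_area_mm2": truth.mcnv_area_mm2,
                "vessel_area_mm2": truth.vessel_area_mm2,
                "vessel_length_mm": truth.vessel_length_mm,
                "vessel_junctions": truth.vessel_junctions,
                "endpoints": truth.endpoints,
                "mean_width_um": truth.mean_width_um,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    return table
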