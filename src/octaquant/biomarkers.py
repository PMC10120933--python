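"""The nine vascular biomarkers of an mCNV lesion.

Area metrics come from the ROI and the binary vessel map of pipeline
branch 1; skeletal metrics (length, junctions, tortuosity, fractal
dimension) from the pruned skeleton graph of branch 2; vessel diameter and
junction density are derived ratios.  Lengths are reported in mm, areas in
mm^2, diameter in micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .raster_io import RoiMask, ValidationError
from .skeleton_analysis import SkeletonGraph
from .vessel_filters import BinaryVesselMap

#: default box-counting sizes in pixels, clipped to <= min(h, w) / 2 at use
DEFAULT_BOX_SIZES: tuple[int, ...] = (2, 3, 4, 6, 8, 12, 16, 32, 64)

#: CSV column order: image id + the nine biomarkers
CSV_COLUMNS: tuple[str, ...] = (
    "image",
    "mcnv_area_mm2",
    "vessel_area_mm2",
    "vessel_junctions",
    "vessel_length_mm",
    "fractal_dimension",
    "tortuosity",
    "vessel_density",
    "junction_density_per_mm",
    "vessel_diameter_um",
)

#: units of each biomarker column, written as a CSV header comment
CSV_UNITS_COMMENT = (
    "# units: mcnv_area_mm2=mm^2, vessel_area_mm2=mm^2, vessel_junctions=count,"
    " vessel_length_mm=mm, fractal_dimension=dimensionless, tortuosity=dimensionless,"
    " vessel_density=ratio, junction_density_per_mm=n/mm, vessel_diameter_um=um"
)


class InternalConsistencyError(ValueError):
    """A biomarker record violated one of its defining identities."""


@dataclass(frozen=True)
class FractalDimensionResult:
    """Box-counting fractal dimension with its regression diagnostics.

    ``d_box`` is the least-squares slope of log N(s) against log(1/s),
    where N(s) counts occupied s-by-s grid cells (grid anchored at the
    image origin).
    """

    d_box: float
    box_sizes: tuple[int, ...]
    counts: tuple[int, ...]
    fit_r2: float


@dataclass(frozen=True)
class BiomarkerRecord:
    """The nine named metrics for one image; ``None`` marks a missing value."""

    mcnv_area: float
    vessel_area: float
    vessel_density: float
    vessel_length: float
    vessel_diameter: float | None
    vessel_junctions: int
    junction_density: float | None
    fractal_dimension: float | None
    tortuosity: float | None

    def __post_init__(self) -> None:
        eps = 1e-9
        if self.vessel_area > self.mcnv_area + eps:
            raise InternalConsistencyError("vessel_area exceeds mcnv_area")
        if self.mcnv_area > 0 and not math.isclose(
            self.vessel_density, self.vessel_area / self.mcnv_area, rel_tol=1e-9, abs_tol=1e-12
        ):
            raise InternalConsistencyError("vessel_density != vessel_area / mcnv_area")
        if self.vessel_length > 0 and self.junction_density is not None:
            if not math.isclose(
                self.junction_density,
                self.vessel_junctions / self.vessel_length,
                rel_tol=1e-9,
                abs_tol=1e-12,
            ):
                raise InternalConsistencyError("junction_density != junctions / length")
        if self.tortuosity is not None and self.tortuosity < 1 - 1e-9:
            raise InternalConsistencyError("tortuosity below 1")
        # the box-count slope can exceed 2 by O(1e-3) on dense masks because
        # partial grid cells at the far edges count fully (ceil effects)
        if self.fractal_dimension is not None and not (
            -eps <= self.fractal_dimension <= 2.01
        ):
            raise InternalConsistencyError("fractal_dimension outside [0, 2]")

    def as_row(self, image_id: str) -> dict[str, object]:
        """One CSV row; missing values become empty cells."""
        vals = {
            "image": image_id,
            "mcnv_area_mm2": self.mcnv_area,
            "vessel_area_mm2": self.vessel_area,
            "vessel_junctions": self.vessel_junctions,
            "vessel_length_mm": self.vessel_length,
            "fractal_dimension": self.fractal_dimension,
            "tortuosity": self.tortuosity,
            "vessel_density": self.vessel_density,
            "junction_density_per_mm": self.junction_density,
            "vessel_diameter_um": self.vessel_diameter,
        }
        return {k: ("" if v is None else v) for k, v in vals.items()}


def mcnv_area(roi: RoiMask, scale: float) -> float:
    """Lesion area in mm^2: ROI pixel count / scale^2."""
    if not (scale > 0):
        raise ValidationError("scale must be positive")
    return roi.pixel_count / scale**2


def vessel_area_and_density(vessels: BinaryVesselMap, roi: RoiMask) -> tuple[float, float]:
    """Vessel area (mm^2) and its ratio to the lesion area."""
    area = int((vessels.mask & roi.mask).sum()) / vessels.scale**2
    lesion = mcnv_area(roi, vessels.scale)
    return area, area / lesion


def vessel_length(graph: SkeletonGraph) -> float:
    """Total neovascular length in mm: sum of branch geodesic lengths."""
    return float(sum(b.geodesic_length for b in graph.branches))


def count_junctions(graph: SkeletonGraph) -> int:
    """Number of junction nodes (clustered junction-pixel clumps count once)."""
    return len(graph.junctions)


def junction_density(junctions: int, length: float) -> float | None:
    """Junctions per mm of vessel; undefined (None) at zero length."""
    if length <= 0:
        return None
    return junctions / length


def vessel_diameter(vessel_area_mm2: float, length_mm: float) -> float | None:
    """Mean vessel caliber in micrometres: (area / centerline length) * 1000."""
    if length_mm <= 0:
        return None
    return vessel_area_mm2 / length_mm * 1000.0


def tortuosity(graph: SkeletonGraph, length_weighted: bool = False) -> float | None:
    """Mean arc-chord ratio over branches (closed loops excluded).

    Each qualifying branch contributes geodesic/Euclidean length; 1.0 means
    perfectly straight vessels.  ``length_weighted`` weights branches by
    geodesic length instead of averaging ratios uniformly.
    """
    ratios, weights = [], []
    for b in graph.branches:
        if b.euclidean_length > 0:
            ratios.append(b.geodesic_length / b.euclidean_length)
            weights.append(b.geodesic_length)
    if not ratios:
        return None
    if length_weighted:
        return float(np.average(ratios, weights=weights))
    return float(np.mean(ratios))


def box_counts(mask: np.ndarray, size: int) -> int:
    """Number of size-by-size grid cells (anchored at the origin) holding foreground."""
    coords = np.argwhere(mask)
    if coords.size == 0:
        return 0
    cells = coords // size
    return len(np.unique(cells[:, 0] * ((mask.shape[1] // size) + 2) + cells[:, 1]))


def fractal_dimension(
    skeleton: BinaryVesselMap | np.ndarray,
    box_sizes: tuple[int, ...] | None = None,
) -> FractalDimensionResult:
    """Box-counting fractal dimension of a binary pattern.

    d_box is the least-squares slope of log N(s) versus log(1/s).  The
    default size ladder {2, 3, 4, 6, 8, 12, 16, 32, 64} is clipped to at
    most half the smaller image side; at least 3 usable sizes and a
    non-empty pattern are required.
    """
    mask = skeleton.mask if isinstance(skeleton, BinaryVesselMap) else skeleton
    if not mask.any():
        raise ValidationError("cannot measure fractal dimension of an empty skeleton")
    limit = min(mask.shape) // 2
    sizes = tuple(s for s in (box_sizes or DEFAULT_BOX_SIZES) if 1 <= s <= limit)
    if len(sizes) < 3:
        raise ValidationError(
            f"need at least 3 usable box sizes <= {limit}, got {len(sizes)}"
        )
    counts = tuple(box_counts(mask, s) for s in sizes)
    x = np.log(1.0 / np.asarray(sizes, dtype=np.float64))
    y = np.log(np.asarray(counts, dtype=np.float64))
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return FractalDimensionResult(
        d_box=float(slope), box_sizes=sizes, counts=counts, fit_r2=r2
    )


def assemble_record(
    roi: RoiMask,
    vessels: BinaryVesselMap,
    graph: SkeletonGraph,
    box_sizes: tuple[int, ...] | None = None,
) -> BiomarkerRecord:
    """Compute all nine biomarkers and enforce their defining identities.

    Degenerate inputs (no skeleton, zero length) yield missing values
    rather than errors; missing values propagate as empty CSV cells.
    """
    lesion = mcnv_area(roi, vessels.scale)
    area, density = vessel_area_and_density(vessels, roi)
    length = vessel_length(graph)
    junctions = count_junctions(graph)
    try:
        fd = fractal_dimension(
            BinaryVesselMap(mask=graph.skeleton, scale=graph.scale), box_sizes
        ).d_box
    except ValidationError:
        fd = None
    return BiomarkerRecord(
        mcnv_area=lesion,
        vessel_area=area,
        vessel_density=density,
        vessel_length=length,
        vessel_diameter=vessel_diameter(area, length),
        vessel_junctions=junctions,
        junction_density=junction_density(junctions, length),
        fractal_dimension=fd,
        tortuosity=tortuosity(graph),
    )
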