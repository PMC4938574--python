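"""Per-capillary ultrastructural quantification.

Areas come from the shoelace formula on the annotated vertex loops and are
reported in µm²; perimeters include the implicit closing edge and are
reported in µm; wall thickness is cytoplasm area divided by a cytoplasm
perimeter, in nm.

The cytoplasm of a capillary cross-section is an annulus and therefore has
two boundaries.  "Cytoplasm perimeter" is resolved by a configurable
convention:

``midline``  (default)
    mean of the outer-boundary and luminal perimeters — in the circular
    limit, area divided by the midline equals the true annulus width R − r.
``outer``
    outer-boundary perimeter only.
``summed``
    outer plus luminal perimeter (systematically halves the thickness of a
    thin annulus; provided for comparison only).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, NamedTuple, Optional, Sequence

import numpy as np
import shapely

from .core_io import (
    AnnotationError,
    CalibratedImage,
    CapillaryAnnotation,
    Polygon,
)

PERIMETER_CONVENTIONS = ("midline", "outer", "summed")

#: stable column order of the per-capillary metrics table
METRICS_COLUMNS = [
    "capillary_id",
    "total_area_um2",
    "lumen_area_um2",
    "nucleus_area_um2",
    "cytoplasm_area_um2",
    "cytoplasm_perimeter_um",
    "thickness_nm",
    "cdv",
    "n_caveolae",
    "mean_caveola_diameter_nm",
    "n_junctions",
]


# ---------------------------------------------------------------------------
# polygon primitives
# ---------------------------------------------------------------------------

def _shoelace_px2(vertices: np.ndarray) -> float:
    x = vertices[:, 0]
    y = vertices[:, 1]
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def polygon_area(polygon: Polygon, nm_per_px: float) -> float:
    """Absolute (orientation-independent) shoelace area of the loop, in µm²."""
    return _shoelace_px2(polygon.vertices) * nm_per_px**2 / 1.0e6


def polygon_perimeter(polygon: Polygon, nm_per_px: float) -> float:
    """Sum of Euclidean edge lengths including the closing edge, in µm."""
    v = polygon.vertices
    edges = np.roll(v, -1, axis=0) - v
    return float(np.hypot(edges[:, 0], edges[:, 1]).sum()) * nm_per_px / 1.0e3


def cytoplasm_area(annotation: CapillaryAnnotation, nm_per_px: float) -> float:
    """Total vessel area minus lumen and nucleus areas, in µm²."""
    total = polygon_area(annotation.vessel_outer, nm_per_px)
    lumen = polygon_area(annotation.lumen, nm_per_px)
    nuclei = sum(polygon_area(n, nm_per_px) for n in annotation.nuclei)
    cyto = total - lumen - nuclei
    if cyto < -1e-9 * max(total, 1.0):
        raise AnnotationError(
            f"capillary {annotation.capillary_id!r}: lumen and nucleus areas "
            f"({lumen + nuclei:.4g} um2) exceed the total vessel area ({total:.4g} um2)"
        )
    return max(cyto, 0.0)


def _cytoplasm_perimeter_nm(
    annotation: CapillaryAnnotation,
    nm_per_px: float,
    perimeter_convention: str,
) -> float:
    if perimeter_convention not in PERIMETER_CONVENTIONS:
        raise ValueError(
            f"unknown perimeter convention {perimeter_convention!r}; "
            f"choose from {PERIMETER_CONVENTIONS}"
        )
    p_outer = polygon_perimeter(annotation.vessel_outer, nm_per_px) * 1.0e3
    p_lumen = polygon_perimeter(annotation.lumen, nm_per_px) * 1.0e3
    if perimeter_convention == "midline":
        return 0.5 * (p_outer + p_lumen)
    if perimeter_convention == "outer":
        return p_outer
    return p_outer + p_lumen


def mean_cytoplasm_thickness(
    annotation: CapillaryAnnotation,
    nm_per_px: float,
    perimeter_convention: str = "midline",
) -> float:
    """Cytoplasm area divided by the cytoplasm perimeter, in nm.

    Nucleus boundaries never enter the perimeter term (nuclei do not bound
    the lumen in this model).
    """
    area_nm2 = cytoplasm_area(annotation, nm_per_px) * 1.0e6
    perim_nm = _cytoplasm_perimeter_nm(annotation, nm_per_px, perimeter_convention)
    if perim_nm <= 0.0:
        raise AnnotationError(
            f"capillary {annotation.capillary_id!r}: zero cytoplasm perimeter"
        )
    return area_nm2 / perim_nm


# ---------------------------------------------------------------------------
# raster sampling
# ---------------------------------------------------------------------------

def polygon_pixel_mask(polygon: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centres fall strictly inside the polygon.

    The same rule is used by the synthetic generator to lay down textures, so
    measurement and generation always agree on the pixel set.
    """
    h, w = shape
    v = polygon.vertices
    x0 = max(int(math.floor(v[:, 0].min())), 0)
    x1 = min(int(math.ceil(v[:, 0].max())) + 1, w)
    y0 = max(int(math.floor(v[:, 1].min())), 0)
    y1 = min(int(math.ceil(v[:, 1].max())) + 1, h)
    mask = np.zeros(shape, dtype=bool)
    if x1 <= x0 or y1 <= y0:
        return mask
    xs = np.arange(x0, x1, dtype=float)
    ys = np.arange(y0, y1, dtype=float)
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(polygon.as_shapely(), gx.ravel(), gy.ravel())
    mask[y0:y1, x0:x1] = inside.reshape(y1 - y0, x1 - x0)
    return mask


def chromatin_density_variation(img: CalibratedImage, nucleus: Polygon) -> float:
    """Sample standard deviation (n−1) of grey values inside the nucleus.

    The dispersion of grey values within the nuclear area quantifies
    chromatin condensation: a homogeneous, late-apoptotic nucleus has a low
    value, a normally speckled nucleus a high one.
    """
    mask = polygon_pixel_mask(nucleus, img.shape)
    n = int(mask.sum())
    if n < 2:
        raise ValueError(
            f"nucleus region has {n} interior pixels; need at least 2 for a "
            "sample standard deviation"
        )
    values = img.pixels[mask].astype(np.float64)
    return float(np.std(values, ddof=1))


# ---------------------------------------------------------------------------
# marks and the combined measurement
# ---------------------------------------------------------------------------

class MarkSummary(NamedTuple):
    count: int
    mean_diameter_nm: Optional[float]


def count_marks(annotation: CapillaryAnnotation, kind: str) -> MarkSummary:
    """Count caveola or junction marks; caveolae also report a mean diameter.

    The diameter is reported as missing (``None``) when there are no marks.
    """
    if kind == "caveolae":
        marks = annotation.caveolae
        if marks:
            diameter = float(np.mean([m.diameter_nm for m in marks]))
        else:
            diameter = None
        return MarkSummary(len(marks), diameter)
    if kind == "junctions":
        return MarkSummary(len(annotation.junctions), None)
    raise ValueError(f"unknown mark kind {kind!r}; choose 'caveolae' or 'junctions'")


@dataclass
class CapillaryMetrics:
    """All per-capillary quantities, areas in µm², thickness in nm."""

    capillary_id: str
    total_area_um2: float
    lumen_area_um2: float
    nucleus_area_um2: float
    cytoplasm_area_um2: float
    cytoplasm_perimeter_um: float
    thickness_nm: float
    cdv: Optional[float]
    n_caveolae: int
    mean_caveola_diameter_nm: Optional[float]
    n_junctions: int

    def as_record(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in METRICS_COLUMNS}


def measure_capillary(
    img: Optional[CalibratedImage],
    annotation: CapillaryAnnotation,
    nm_per_px: Optional[float] = None,
    perimeter_convention: str = "midline",
) -> CapillaryMetrics:
    """Measure one capillary.

    ``img`` may be ``None`` when no raster is available; all geometric
    quantities are still computed from the annotation and the chromatin
    value is reported as missing.  When several nuclei are annotated the
    chromatin value is computed on the largest one while the nucleus area
    sums over all of them.
    """
    if img is not None and nm_per_px is not None:
        if not math.isclose(img.nm_per_px, nm_per_px, rel_tol=1e-9):
            raise ValueError(
                f"conflicting calibration: image has {img.nm_per_px} nm/px, "
                f"annotation has {nm_per_px} nm/px"
            )
    scale = img.nm_per_px if img is not None else nm_per_px
    if scale is None:
        raise ValueError("nm_per_px is required when no image is supplied")

    total = polygon_area(annotation.vessel_outer, scale)
    lumen = polygon_area(annotation.lumen, scale)
    nucleus = sum(polygon_area(n, scale) for n in annotation.nuclei)
    cyto = total - lumen - nucleus
    if cyto < -1e-9 * max(total, 1.0):
        raise AnnotationError(
            f"capillary {annotation.capillary_id!r}: lumen and nucleus areas "
            "exceed the total vessel area"
        )
    cyto = max(cyto, 0.0)
    # keep the conservation invariant exact
    total = lumen + nucleus + cyto

    thickness = mean_cytoplasm_thickness(annotation, scale, perimeter_convention)
    perim_um = _cytoplasm_perimeter_nm(annotation, scale, perimeter_convention) / 1.0e3

    cdv: Optional[float] = None
    if img is not None and annotation.nuclei:
        largest = max(annotation.nuclei, key=lambda n: polygon_area(n, scale))
        cdv = chromatin_density_variation(img, largest)

    caveolae = count_marks(annotation, "caveolae")
    junctions = count_marks(annotation, "junctions")
    return CapillaryMetrics(
        capillary_id=annotation.capillary_id,
        total_area_um2=total,
        lumen_area_um2=lumen,
        nucleus_area_um2=nucleus,
        cytoplasm_area_um2=cyto,
        cytoplasm_perimeter_um=perim_um,
        thickness_nm=thickness,
        cdv=cdv,
        n_caveolae=caveolae.count,
        mean_caveola_diameter_nm=caveolae.mean_diameter_nm,
        n_junctions=junctions.count,
    )


def measure_all(
    annotations: Sequence[CapillaryAnnotation],
    images: Optional[dict[str, CalibratedImage]] = None,
    nm_per_px: Optional[float] = None,
    perimeter_convention: str = "midline",
) -> list[CapillaryMetrics]:
    """Measure a batch; ``images`` maps capillary_id to its raster (optional)."""
    out = []
    for ann in annotations:
        img = (images or {}).get(ann.capillary_id)
        out.append(
            measure_capillary(
                img, ann, nm_per_px=nm_per_px, perimeter_convention=perimeter_convention
            )
        )
    return out
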