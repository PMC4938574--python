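"""Seeded synthetic phantoms with exact ground truth.

Three generators cover the three measurement families:

* :func:`generate_capillary` — an elliptical-annulus capillary cross-section
  with a nucleus bulge, Gaussian chromatin texture, and Poisson caveola /
  junction marks.  The annotation polygons are the exact generating
  contours, so geometric measurements round-trip exactly; the wall-offset
  parameter is solved numerically so that the midline wall thickness of the
  emitted polygons equals the drawn target.
* :func:`generate_field` — Poisson frame counts at a preset density.
* :func:`generate_fluorescence` — a three-zone two-channel field whose zone
  means realise the preset intensity ratios and whose bright-pixel placement
  realises the preset colocalisation fraction exactly (up to rounding).

All randomness flows through a single :class:`numpy.random.Generator`, so a
seed fully determines every artefact.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm as _norm
from shapely.geometry import MultiPolygon as _MultiPolygon
from shapely.geometry import Point as _Point
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.ops import unary_union

from .core_io import (
    CalibratedImage,
    CapillaryAnnotation,
    CaveolaMark,
    FrameCount,
    JunctionMark,
    Polygon,
    ZoneMaskSet,
    write_annotation_file,
    write_image,
)
from .morphometry import polygon_pixel_mask

GROUPS = ("I30", "I90", "IR30-60")
ZONES = ("infarct", "control")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupPreset:
    """Named parameter bundle for one experimental group × zone.

    ``(mean, sd)`` pairs describe between-capillary variation on the scale
    of the printed group values; areas are µm², thickness and diameters nm,
    densities capillaries/mm².
    """

    name: str
    wall_thickness_nm: tuple[float, float]
    total_vessel_area_um2: float
    lumen_area_um2: tuple[float, float]
    nucleus_area_um2: tuple[float, float]
    cdv_grey: tuple[float, float]
    junctions_per_capillary: float
    caveolae_per_capillary: float
    caveola_diameter_nm: tuple[float, float]
    ihc_density_per_mm2: float
    tem_density_per_mm2: float
    mfi_ratio_infarct_control: float
    border_to_core_weighting: float
    colocalisation_target: float
    n_capillaries_per_animal: int = 20

    def validate(self) -> None:
        lumen_plus_nucleus = self.lumen_area_um2[0] + self.nucleus_area_um2[0]
        if lumen_plus_nucleus >= self.total_vessel_area_um2 + 5.0:
            raise ValueError(
                f"preset {self.name!r}: lumen + nucleus area inconsistent with "
                "total vessel area"
            )
        for label, (mean, sd) in (
            ("wall_thickness_nm", self.wall_thickness_nm),
            ("lumen_area_um2", self.lumen_area_um2),
            ("nucleus_area_um2", self.nucleus_area_um2),
            ("cdv_grey", self.cdv_grey),
            ("caveola_diameter_nm", self.caveola_diameter_nm),
        ):
            if mean <= 0 or sd < 0:
                raise ValueError(f"preset {self.name!r}: invalid {label} {(mean, sd)}")
        if not 0.0 <= self.colocalisation_target <= 1.0:
            raise ValueError(f"preset {self.name!r}: colocalisation target not in [0,1]")


PRESETS: dict[str, GroupPreset] = {
    p.name: p
    for p in [
        GroupPreset(
            name="I30.infarct",
            wall_thickness_nm=(407.8, 75.0),
            total_vessel_area_um2=36.8,
            lumen_area_um2=(17.9, 8.3),
            nucleus_area_um2=(8.4, 2.6),
            cdv_grey=(50.5, 9.4),
            junctions_per_capillary=2.5,
            caveolae_per_capillary=4.0,
            caveola_diameter_nm=(100.2, 12.35),
            ihc_density_per_mm2=1283.0,
            tem_density_per_mm2=1586.0,
            mfi_ratio_infarct_control=1.2,
            border_to_core_weighting=1.0,
            colocalisation_target=0.25,
        ),
        GroupPreset(
            name="I30.control",
            wall_thickness_nm=(700.0, 120.0),
            total_vessel_area_um2=19.56,
            lumen_area_um2=(2.2, 1.0),
            nucleus_area_um2=(8.4, 2.6),
            cdv_grey=(49.0, 8.0),
            junctions_per_capillary=2.5,
            caveolae_per_capillary=4.0,
            caveola_diameter_nm=(100.0, 12.0),
            ihc_density_per_mm2=1283.0,
            tem_density_per_mm2=1700.0,
            mfi_ratio_infarct_control=1.2,
            border_to_core_weighting=1.0,
            colocalisation_target=0.25,
        ),
        GroupPreset(
            name="I90.infarct",
            wall_thickness_nm=(407.5, 71.0),
            total_vessel_area_um2=30.2,
            lumen_area_um2=(9.75, 3.4),
            nucleus_area_um2=(9.9, 2.2),
            cdv_grey=(35.4, 7.1),
            junctions_per_capillary=1.8,
            caveolae_per_capillary=7.0,
            caveola_diameter_nm=(97.14, 7.8),
            ihc_density_per_mm2=638.1,
            tem_density_per_mm2=1716.0,
            mfi_ratio_infarct_control=3.0,
            border_to_core_weighting=1.0,
            colocalisation_target=0.25,
        ),
        GroupPreset(
            name="I90.control",
            wall_thickness_nm=(740.0, 130.0),
            total_vessel_area_um2=13.7,
            lumen_area_um2=(0.95, 0.5),
            nucleus_area_um2=(5.7, 2.0),
            cdv_grey=(49.0, 8.0),
            junctions_per_capillary=2.5,
            caveolae_per_capillary=4.0,
            caveola_diameter_nm=(97.0, 8.0),
            ihc_density_per_mm2=1283.0,
            tem_density_per_mm2=1700.0,
            mfi_ratio_infarct_control=3.0,
            border_to_core_weighting=1.0,
            colocalisation_target=0.25,
        ),
        GroupPreset(
            name="IR30-60.infarct",
            wall_thickness_nm=(207.0, 74.0),
            total_vessel_area_um2=49.0,
            lumen_area_um2=(35.6, 15.2),
            nucleus_area_um2=(7.7, 2.8),
            cdv_grey=(23.7, 3.8),
            junctions_per_capillary=0.15,
            caveolae_per_capillary=2.0,
            caveola_diameter_nm=(81.25, 26.0),
            ihc_density_per_mm2=638.1,
            tem_density_per_mm2=1185.0,
            mfi_ratio_infarct_control=3.0,
            border_to_core_weighting=10.0,
            colocalisation_target=0.25,
        ),
        GroupPreset(
            name="IR30-60.control",
            wall_thickness_nm=(1000.0, 180.0),
            total_vessel_area_um2=19.7,
            lumen_area_um2=(1.8, 0.8),
            nucleus_area_um2=(6.5, 2.3),
            cdv_grey=(49.0, 8.0),
            junctions_per_capillary=2.5,
            caveolae_per_capillary=4.0,
            caveola_diameter_nm=(100.0, 12.0),
            ihc_density_per_mm2=1283.0,
            tem_density_per_mm2=1700.0,
            mfi_ratio_infarct_control=3.0,
            border_to_core_weighting=10.0,
            colocalisation_target=0.25,
        ),
    ]
}
for _p in PRESETS.values():
    _p.validate()


def get_preset(name: str) -> GroupPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def _as_rng(
    seed: Optional[Union[int, Sequence[int], np.random.SeedSequence]],
    rng: Optional[np.random.Generator],
) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    if sd == 0.0:
        return max(mean, lo)
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if x > lo:
            return float(x)
    raise RuntimeError(f"truncated normal draw failed for N({mean}, {sd}) > {lo}")


# ---------------------------------------------------------------------------
# capillary phantom
# ---------------------------------------------------------------------------

def _ellipse_ring(
    cx: float, cy: float, area: float, aspect: float, angle: float, n: int = 128
) -> np.ndarray:
    """Vertex loop of an ellipse with exact shoelace area ``area``."""
    a = math.sqrt(area * aspect / math.pi)
    b = a / aspect
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    # an inscribed n-gon loses a factor (n / 2pi) sin(2pi / n) of area
    poly_area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    s = math.sqrt(area / poly_area)
    x *= s
    y *= s
    ca, sa = math.cos(angle), math.sin(angle)
    return np.column_stack([cx + ca * x - sa * y, cy + sa * x + ca * y])


def _clipped_normal_sd(sigma: float, mu: float = 127.5, lo: float = 0.0, hi: float = 255.0) -> float:
    """SD of a N(mu, sigma) variable clipped (not truncated) to [lo, hi]."""
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    pa, pb = _norm.cdf(a), _norm.cdf(b)
    da, db = _norm.pdf(a), _norm.pdf(b)
    mass = pb - pa
    ez = da - db                      # E[Z; a<Z<b]
    ez2 = mass + a * da - b * db      # E[Z^2; a<Z<b]
    m1 = lo * pa + hi * (1.0 - pb) + mu * mass + sigma * ez
    m2 = (
        lo**2 * pa
        + hi**2 * (1.0 - pb)
        + mu**2 * mass
        + 2.0 * mu * sigma * ez
        + sigma**2 * ez2
    )
    var = m2 - m1**2
    return math.sqrt(max(var, 0.0))


def _solve_texture_sigma(target_sd: float) -> float:
    """Generating sigma whose 8-bit clipped SD equals ``target_sd``."""
    if target_sd <= 0:
        raise ValueError("chromatin SD must be positive")
    if _clipped_normal_sd(target_sd) >= target_sd - 1e-9:
        return target_sd
    return float(
        brentq(lambda s: _clipped_normal_sd(s) - target_sd, target_sd, 3.0 * target_sd)
    )


def _midline_thickness_nm(
    union_geom, lumen: _ShapelyPolygon, nucleus: _ShapelyPolygon, offset_nm: float
) -> float:
    outer = union_geom.buffer(offset_nm, quad_segs=12)
    if isinstance(outer, _MultiPolygon):
        boundary = outer.length
    else:
        boundary = outer.exterior.length
    cyt_area = outer.area - lumen.area - nucleus.area
    midline = 0.5 * (boundary + lumen.exterior.length)
    return cyt_area / midline


def _sample_in(rng: np.random.Generator, region, n: int) -> list[tuple[float, float]]:
    """Rejection-sample ``n`` points uniformly inside a shapely region."""
    minx, miny, maxx, maxy = region.bounds
    out: list[tuple[float, float]] = []
    guard = 0
    while len(out) < n:
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if region.contains(_Point(x, y)):
            out.append((x, y))
        guard += 1
        if guard > 200_000:
            raise RuntimeError("rejection sampling failed; region too thin")
    return out


def generate_capillary(
    preset: GroupPreset,
    seed: Optional[Union[int, Sequence[int]]] = None,
    nm_per_px: float = 12.0,
    render: bool = True,
    rng: Optional[np.random.Generator] = None,
    capillary_id: str = "capillary_000",
) -> tuple[Optional[CalibratedImage], CapillaryAnnotation, dict[str, Any]]:
    """Generate one capillary scene with exact ground truth.

    Returns ``(image, annotation, truth)``; the image is ``None`` when
    ``render`` is false.  The chromatin texture SD equals the preset mean
    (the printed ± on that quantity reflects animal-level scatter, which is
    introduced by :func:`generate_cohort`, not per capillary).
    """
    preset.validate()
    rng = _as_rng(seed, rng)

    thickness_target = _trunc_normal(rng, *preset.wall_thickness_nm, lo=30.0)
    lumen_area_um2 = _trunc_normal(rng, *preset.lumen_area_um2, lo=0.3)
    nucleus_area_um2 = _trunc_normal(rng, *preset.nucleus_area_um2, lo=0.8)
    cdv_target = preset.cdv_grey[0]

    lumen_area_nm2 = lumen_area_um2 * 1.0e6
    nucleus_area_nm2 = nucleus_area_um2 * 1.0e6

    lumen_ring = _ellipse_ring(
        0.0,
        0.0,
        lumen_area_nm2,
        aspect=rng.uniform(1.0, 1.5),
        angle=rng.uniform(0.0, math.pi),
    )
    lumen = _ShapelyPolygon(lumen_ring)

    # place the nucleus just outside the lumen, near-tangent, at a random angle
    theta = rng.uniform(0.0, 2.0 * math.pi)
    nucleus_aspect = rng.uniform(1.7, 2.5)
    nucleus_angle = theta + math.pi / 2.0
    gap = max(0.15 * thickness_target, 20.0)

    def nucleus_at(d: float) -> tuple[np.ndarray, _ShapelyPolygon]:
        ring = _ellipse_ring(
            d * math.cos(theta),
            d * math.sin(theta),
            nucleus_area_nm2,
            aspect=nucleus_aspect,
            angle=nucleus_angle,
        )
        return ring, _ShapelyPolygon(ring)

    r_lumen = math.sqrt(lumen_area_nm2 / math.pi)
    r_nucleus = math.sqrt(nucleus_area_nm2 / math.pi)
    d_lo, d_hi = 0.0, 3.0 * (r_lumen + r_nucleus) + 10.0 * gap
    for _ in range(60):
        d_mid = 0.5 * (d_lo + d_hi)
        _, candidate = nucleus_at(d_mid)
        dist = candidate.distance(lumen)
        if dist < gap:
            d_lo = d_mid
        elif dist > 1.2 * gap:
            d_hi = d_mid
        else:
            break
    nucleus_ring, nucleus = nucleus_at(0.5 * (d_lo + d_hi))
    if nucleus.intersection(lumen).area > 0 or nucleus.distance(lumen) <= 0:
        nucleus_ring, nucleus = nucleus_at(d_hi)

    union_geom = unary_union([lumen, nucleus])

    def objective(t: float) -> float:
        return _midline_thickness_nm(union_geom, lumen, nucleus, t) - thickness_target

    t_lo = max(0.6 * gap, 0.05 * thickness_target)
    t_hi = 3.0 * thickness_target + gap
    while objective(t_hi) < 0.0:
        t_hi *= 1.5
        if t_hi > 1.0e6:
            raise RuntimeError("wall-offset solve failed to bracket")
    while objective(t_lo) > 0.0:
        t_lo *= 0.5
        if t_lo < 1e-3:
            raise RuntimeError("wall-offset solve failed to bracket")
    t_star = float(brentq(objective, t_lo, t_hi, xtol=max(1e-3 * thickness_target, 1e-2)))

    outer = union_geom.buffer(t_star, quad_segs=12)
    if isinstance(outer, _MultiPolygon):
        raise RuntimeError("generated vessel outline is disconnected")
    if outer.interiors:
        outer = _ShapelyPolygon(outer.exterior)
    thickness_truth = _midline_thickness_nm(union_geom, lumen, nucleus, t_star)

    # marks live in the cytoplasm (outer minus lumen minus nucleus)
    cytoplasm_region = outer.difference(lumen).difference(nucleus)
    n_caveolae = int(rng.poisson(preset.caveolae_per_capillary))
    n_junctions = int(rng.poisson(preset.junctions_per_capillary))
    caveola_points = _sample_in(rng, cytoplasm_region, n_caveolae)
    junction_points = _sample_in(rng, cytoplasm_region, n_junctions)
    caveola_diameters = [
        _trunc_normal(rng, *preset.caveola_diameter_nm, lo=30.0)
        for _ in range(n_caveolae)
    ]

    # shift to positive pixel coordinates with a margin
    margin_px = 8.0
    minx, miny, maxx, maxy = outer.bounds
    shift_x = margin_px * nm_per_px - minx
    shift_y = margin_px * nm_per_px - miny

    def to_px(coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return np.column_stack(
            [(coords[:, 0] + shift_x) / nm_per_px, (coords[:, 1] + shift_y) / nm_per_px]
        )

    outer_px = to_px(np.asarray(outer.exterior.coords)[:-1])
    lumen_px = to_px(lumen_ring)
    nucleus_px = to_px(nucleus_ring)
    annotation = CapillaryAnnotation(
        vessel_outer=Polygon(outer_px),
        lumen=Polygon(lumen_px),
        nuclei=[Polygon(nucleus_px)],
        caveolae=[
            CaveolaMark(
                (x + shift_x) / nm_per_px, (y + shift_y) / nm_per_px, diameter
            )
            for (x, y), diameter in zip(caveola_points, caveola_diameters)
        ],
        junctions=[
            JunctionMark((x + shift_x) / nm_per_px, (y + shift_y) / nm_per_px)
            for (x, y) in junction_points
        ],
        capillary_id=capillary_id,
    )

    truth: dict[str, Any] = {
        "capillary_id": capillary_id,
        "thickness_nm": thickness_truth,
        "target_thickness_nm": thickness_target,
        "lumen_area_um2": lumen_area_um2,
        "nucleus_area_um2": nucleus_area_um2,
        "total_area_um2": outer.area / 1.0e6,
        "cytoplasm_area_um2": (outer.area - lumen.area - nucleus.area) / 1.0e6,
        "cdv": cdv_target,
        "n_caveolae": n_caveolae,
        "caveola_diameters_nm": caveola_diameters,
        "n_junctions": n_junctions,
        "nm_per_px": nm_per_px,
    }

    image: Optional[CalibratedImage] = None
    if render:
        width = int(math.ceil((maxx + shift_x) / nm_per_px + margin_px))
        height = int(math.ceil((maxy + shift_y) / nm_per_px + margin_px))
        pixels = np.full((height, width), 70, dtype=np.uint8)
        outer_mask = polygon_pixel_mask(annotation.vessel_outer, (height, width))
        lumen_mask = polygon_pixel_mask(annotation.lumen, (height, width))
        nucleus_mask = polygon_pixel_mask(annotation.nuclei[0], (height, width))
        pixels[outer_mask] = 110
        pixels[lumen_mask] = 185
        sigma_gen = _solve_texture_sigma(cdv_target)
        texture = rng.normal(127.5, sigma_gen, size=int(nucleus_mask.sum()))
        pixels[nucleus_mask] = np.clip(np.rint(texture), 0, 255).astype(np.uint8)
        image = CalibratedImage(pixels, nm_per_px=nm_per_px, channel_label="TEM")

    return image, annotation, truth


# ---------------------------------------------------------------------------
# point fields (counting frames)
# ---------------------------------------------------------------------------

def generate_field(
    preset: GroupPreset,
    n_frames: int,
    seed: Optional[Union[int, Sequence[int]]] = None,
    rng: Optional[np.random.Generator] = None,
    modality: str = "ihc",
    frame_um: Optional[float] = None,
) -> list[FrameCount]:
    """Poisson frame counts at the preset capillary density.

    IHC framing defaults to the 200×200 µm counting frame; TEM sections are
    made explicit as 100×100 µm (0.01 mm²) frames.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = _as_rng(seed, rng)
    if modality == "ihc":
        density = preset.ihc_density_per_mm2
        frame_um = 200.0 if frame_um is None else frame_um
    elif modality == "tem":
        density = preset.tem_density_per_mm2
        frame_um = 100.0 if frame_um is None else frame_um
    else:
        raise ValueError(f"unknown modality {modality!r}; choose 'ihc' or 'tem'")
    area_mm2 = (frame_um / 1000.0) ** 2
    zone = preset.name.split(".", 1)[1] if "." in preset.name else "infarct"
    counts = rng.poisson(density * area_mm2, size=n_frames)
    return [
        FrameCount(frame_um, frame_um, int(c), zone_label=zone) for c in counts
    ]


# ---------------------------------------------------------------------------
# fluorescence fields
# ---------------------------------------------------------------------------

_SPHERE_BG = 60
_SPHERE_HI = 20_000
_CD31_BG = 100
_CD31_HI = 15_000
_SPHERE_THRESHOLD = 10_000.0
_CD31_THRESHOLD = 8_000.0
_CONTROL_MFI = 600.0
_FLUO_NM_PER_PX = 500.0


def _zone_rects(shape: tuple[int, int]) -> dict[str, tuple[int, int, int, int]]:
    h, w = shape
    pad = 8
    band = (w - 4 * pad) // 3
    x0 = pad
    rects = {}
    for name in ("infarct_core", "infarct_border", "control"):
        rects[name] = (x0, pad, x0 + band, h - pad)  # x0, y0, x1, y1
        x0 += band + pad
    return rects


def generate_fluorescence(
    preset: GroupPreset,
    seed: Optional[Union[int, Sequence[int]]] = None,
    shape: tuple[int, int] = (768, 768),
    rng: Optional[np.random.Generator] = None,
) -> tuple[CalibratedImage, CalibratedImage, ZoneMaskSet, dict[str, Any]]:
    """Two-channel fluorescence field realising the preset leakage metrics.

    The tracer channel is a flat background plus bright tracer pixels; the
    number of bright pixels per zone is chosen so the zone means realise the
    preset infarct/control ratio (border-weighted when the preset says so),
    and exactly the preset colocalisation fraction of them is placed on
    marker-positive pixels.
    """
    preset.validate()
    rng = _as_rng(seed, rng)
    h, w = shape
    rects = _zone_rects(shape)
    masks = {}
    for name, (x0, y0, x1, y1) in rects.items():
        m = np.zeros(shape, dtype=bool)
        m[y0:y1, x0:x1] = True
        masks[name] = m
    zones = ZoneMaskSet(masks)

    # endothelial marker channel: scattered vessel discs per zone
    cd31 = np.full(shape, _CD31_BG, dtype=np.uint16)
    disc_r = 4
    yy, xx = np.mgrid[-disc_r:disc_r + 1, -disc_r:disc_r + 1]
    disc = (xx**2 + yy**2) <= disc_r**2
    for name, (x0, y0, x1, y1) in rects.items():
        zone_area = (x1 - x0) * (y1 - y0)
        n_discs = int(math.ceil(0.10 * zone_area / disc.sum()))
        cx = rng.integers(x0 + disc_r, x1 - disc_r, size=n_discs)
        cy = rng.integers(y0 + disc_r, y1 - disc_r, size=n_discs)
        for x, y in zip(cx, cy):
            patch = cd31[y - disc_r:y + disc_r + 1, x - disc_r:x + disc_r + 1]
            patch[disc] = _CD31_HI
    cd31_pos = cd31 > _CD31_THRESHOLD

    ratio = preset.mfi_ratio_infarct_control
    weighting = preset.border_to_core_weighting
    m_core = 2.0 * ratio * _CONTROL_MFI / (1.0 + weighting)
    zone_targets = {
        "infarct_core": m_core,
        "infarct_border": weighting * m_core,
        "control": _CONTROL_MFI,
    }

    spheres = np.full(shape, _SPHERE_BG, dtype=np.uint16)
    fraction = preset.colocalisation_target
    expected_mfi: dict[str, float] = {}
    n_in_total = 0
    n_pos_total = 0
    for name, target in zone_targets.items():
        mask = masks[name]
        area = int(mask.sum())
        n_pos = int(round(area * (target - _SPHERE_BG) / (_SPHERE_HI - _SPHERE_BG)))
        n_in = int(round(fraction * n_pos))
        in_pool = np.flatnonzero(mask.ravel() & cd31_pos.ravel())
        out_pool = np.flatnonzero(mask.ravel() & ~cd31_pos.ravel())
        if n_in > len(in_pool) or (n_pos - n_in) > len(out_pool):
            raise RuntimeError("fluorescence field too small for preset intensities")
        chosen = np.concatenate(
            [
                rng.choice(in_pool, size=n_in, replace=False),
                rng.choice(out_pool, size=n_pos - n_in, replace=False),
            ]
        )
        spheres.ravel()[chosen] = _SPHERE_HI
        expected_mfi[name] = _SPHERE_BG + n_pos * (_SPHERE_HI - _SPHERE_BG) / area
        n_in_total += n_in
        n_pos_total += n_pos

    truth = {
        "preset": preset.name,
        "mfi_targets": zone_targets,
        "expected_mfi": expected_mfi,
        "ratio_infarct_control": ratio,
        "border_to_core_weighting": weighting,
        "colocalisation_fraction": n_in_total / n_pos_total,
        "colocalisation_target": fraction,
        "sphere_threshold": _SPHERE_THRESHOLD,
        "cd31_threshold": _CD31_THRESHOLD,
        "zone_polygons": {
            name: [[x0, y0], [x1, y0], [x1, y1], [x0, y1]]
            for name, (x0, y0, x1, y1) in rects.items()
        },
    }
    spheres_img = CalibratedImage(spheres, _FLUO_NM_PER_PX, "microspheres")
    cd31_img = CalibratedImage(cd31, _FLUO_NM_PER_PX, "CD31")
    return spheres_img, cd31_img, zones, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _animal_preset(
    rng: np.random.Generator, preset: GroupPreset, icc: float
) -> GroupPreset:
    """Two-level scheme: animal mean drawn from the group distribution.

    The printed ± is split into a between-animal part (fraction ``icc`` of
    the variance) and a within-animal part carried by the capillary draws.
    """
    between = math.sqrt(icc)
    within = math.sqrt(1.0 - icc)

    def split(pair: tuple[float, float], lo: float) -> tuple[float, float]:
        mean, sd = pair
        mu = _trunc_normal(rng, mean, between * sd, lo=lo)
        return (mu, within * sd)

    return dataclasses.replace(
        preset,
        wall_thickness_nm=split(preset.wall_thickness_nm, 50.0),
        lumen_area_um2=split(preset.lumen_area_um2, 0.4),
        nucleus_area_um2=split(preset.nucleus_area_um2, 1.0),
        cdv_grey=split(preset.cdv_grey, 3.0),
    )


def generate_cohort(
    group_names: Sequence[str],
    animals_per_group: int,
    seed: int,
    out_dir: Optional[Union[str, Path]] = None,
    capillaries_per_animal: int = 20,
    nm_per_px: float = 12.0,
    icc: float = 0.3,
    n_frames: int = 25,
    render: bool = True,
) -> dict[str, Any]:
    """Generate a full synthetic study and (optionally) write it to disk.

    The on-disk layout is consumable unchanged by the CLI commands::

        out/
          manifest.json
          counts.csv              (sample_id, group, zone, modality,
                                   frame_index, frame_um, count)
          <group>/
            fluorescence/spheres.tif, cd31.tif, zones.json
            animal_01/annotations.json, capillary_000.png, ...

    Returns the manifest (all ground truth), keyed by group and animal.
    """
    for g in group_names:
        if g not in GROUPS:
            raise KeyError(f"unknown group {g!r}; available: {GROUPS}")
    if animals_per_group < 1:
        raise ValueError("animals_per_group must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out_path = Path(out_dir) if out_dir is not None else None

    manifest: dict[str, Any] = {
        "seed": seed,
        "icc": icc,
        "nm_per_px": nm_per_px,
        "capillaries_per_animal": capillaries_per_animal,
        "groups": {},
    }
    count_rows: list[dict[str, Any]] = []

    for group in group_names:
        group_entry: dict[str, Any] = {"animals": [], "density": {}, "fluorescence": None}
        infarct = get_preset(f"{group}.infarct")
        control = get_preset(f"{group}.control")

        spheres, cd31, zones, fluo_truth = generate_fluorescence(infarct, rng=rng)
        group_entry["fluorescence"] = fluo_truth
        if out_path is not None:
            fdir = out_path / group / "fluorescence"
            fdir.mkdir(parents=True, exist_ok=True)
            write_image(spheres, fdir / "spheres.tif")
            write_image(cd31, fdir / "cd31.tif")
            with open(fdir / "zones.json", "w", encoding="utf-8") as fh:
                json.dump({"zones": fluo_truth["zone_polygons"]}, fh)

        for zone, preset in (("infarct", infarct), ("control", control)):
            for modality in ("ihc", "tem"):
                frames = generate_field(preset, n_frames, rng=rng, modality=modality)
                group_entry["density"][f"{modality}_{zone}"] = {
                    "expected_per_mm2": (
                        preset.ihc_density_per_mm2
                        if modality == "ihc"
                        else preset.tem_density_per_mm2
                    ),
                    "counts": [f.count for f in frames],
                    "frame_um": frames[0].frame_width_um,
                }
                for i, f in enumerate(frames):
                    count_rows.append(
                        {
                            "sample_id": f"{group}_{zone}_{modality}",
                            "group": group,
                            "zone": zone,
                            "modality": modality,
                            "frame_index": i,
                            "frame_um": f.frame_width_um,
                            "count": f.count,
                        }
                    )

        for a in range(animals_per_group):
            animal_id = f"{group}_animal_{a + 1:02d}"
            preset_a = _animal_preset(rng, infarct, icc)
            annotations = []
            truths = []
            images = {}
            for c in range(capillaries_per_animal):
                cid = f"{animal_id}_cap_{c:03d}"
                img, ann, truth = generate_capillary(
                    preset_a,
                    rng=rng,
                    nm_per_px=nm_per_px,
                    render=render,
                    capillary_id=cid,
                )
                annotations.append(ann)
                truths.append(truth)
                if out_path is not None and img is not None:
                    adir = out_path / group / f"animal_{a + 1:02d}"
                    image_name = f"capillary_{c:03d}.png"
                    write_image(img, adir / image_name)
                    images[cid] = image_name
            if out_path is not None:
                adir = out_path / group / f"animal_{a + 1:02d}"
                adir.mkdir(parents=True, exist_ok=True)
                write_annotation_file(
                    adir / "annotations.json",
                    nm_per_px,
                    annotations,
                    images=images or None,
                )
            group_entry["animals"].append(
                {
                    "animal_id": animal_id,
                    "animal_preset_means": {
                        "thickness_nm": preset_a.wall_thickness_nm[0],
                        "cdv": preset_a.cdv_grey[0],
                    },
                    "capillaries": truths,
                }
            )
        manifest["groups"][group] = group_entry

    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        from .core_io import write_metrics_table

        write_metrics_table(
            count_rows,
            out_path / "counts.csv",
            columns=[
                "sample_id",
                "group",
                "zone",
                "modality",
                "frame_index",
                "frame_um",
                "count",
            ],
        )
        with open(out_path / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, sort_keys=True)
    return manifest
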