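"""Shared data model, calibration and file I/O.

Conventions used throughout the package:

* Coordinates are 0-based pixel-centre coordinates, ``x`` = column and
  ``y`` = row.
* Physical calibration travels with every image as nanometres per pixel
  edge (``nm_per_px``) and is always supplied by the caller — it is never
  inferred from TIFF tags, which are unreliable when magnification varies.
* Polygon closure is implicit (last vertex connects back to the first);
  a repeated closing vertex is tolerated and deduplicated.
"""
from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, fields as dataclass_fields, is_dataclass, asdict
from pathlib import Path
from typing import Any, Iterable, Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np
import tifffile
from PIL import Image as _PILImage
from shapely.geometry import Polygon as _ShapelyPolygon


class ImageFormatError(ValueError):
    """A raster file cannot be used as a single-channel calibrated image."""


class AnnotationError(ValueError):
    """An annotation violates the documented geometric invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class CalibratedImage:
    """A grey-scale raster with physical pixel size.

    Parameters
    ----------
    pixels:
        2-D array of grey intensities.  Integer images are kept on their
        native scale (0–255 or 0–65535); float images must lie in [0, 1].
    nm_per_px:
        Physical calibration in nanometres per pixel edge; must be finite
        and strictly positive.
    channel_label:
        Free-text channel description (``"TEM"``, ``"microspheres"``, ...).
    """

    pixels: np.ndarray
    nm_per_px: float
    channel_label: str = "TEM"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ImageFormatError(
                f"pixels must be a non-empty 2-D array, got shape {px.shape}"
            )
        if not (math.isfinite(self.nm_per_px) and self.nm_per_px > 0):
            raise ValueError(
                f"nm_per_px must be finite and positive, got {self.nm_per_px!r}"
            )
        if np.issubdtype(px.dtype, np.floating):
            finite = np.isfinite(px)
            if not finite.all():
                raise ImageFormatError("float image contains non-finite values")
            if px.min() < 0.0 or px.max() > 1.0:
                raise ImageFormatError("float images must be on the unit interval")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def um_per_px(self) -> float:
        return self.nm_per_px / 1000.0


def _dedup_ring(vertices: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicate vertices and an explicit closing vertex."""
    keep = [0]
    for i in range(1, len(vertices)):
        if not np.allclose(vertices[i], vertices[keep[-1]], rtol=0.0, atol=1e-12):
            keep.append(i)
    v = vertices[keep]
    if len(v) > 1 and np.allclose(v[0], v[-1], rtol=0.0, atol=1e-12):
        v = v[:-1]
    return v


@dataclass(frozen=True, eq=False)
class Polygon:
    """A simple polygon given as an ordered vertex loop in pixel coordinates."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise AnnotationError(
                f"polygon vertices must be an (n, 2) array, got shape {v.shape}"
            )
        if not np.isfinite(v).all():
            raise AnnotationError("polygon vertices must be finite")
        v = _dedup_ring(v)
        if len(v) < 3:
            raise AnnotationError(
                f"degenerate polygon: {len(v)} distinct vertices (need >= 3)"
            )
        shp = _ShapelyPolygon(v)
        if not shp.is_valid or shp.area == 0.0:
            raise AnnotationError("polygon must be simple (non-self-intersecting)")
        v.setflags(write=False)
        object.__setattr__(self, "vertices", v)

    def as_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    def __len__(self) -> int:
        return len(self.vertices)


class CaveolaMark(NamedTuple):
    x: float
    y: float
    diameter_nm: float


class JunctionMark(NamedTuple):
    x: float
    y: float


@dataclass(eq=False)
class CapillaryAnnotation:
    """The manual-delineation record for one capillary cross-section."""

    vessel_outer: Polygon
    lumen: Polygon
    nuclei: list[Polygon] = field(default_factory=list)
    caveolae: list[CaveolaMark] = field(default_factory=list)
    junctions: list[JunctionMark] = field(default_factory=list)
    capillary_id: str = "capillary"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        vessel = self.vessel_outer.as_shapely()
        lumen = self.lumen.as_shapely()
        cid = self.capillary_id
        if not lumen.within(vessel):
            raise AnnotationError(f"capillary {cid!r}: lumen not inside vessel_outer")
        for i, nucleus in enumerate(self.nuclei):
            shp = nucleus.as_shapely()
            if not shp.within(vessel):
                raise AnnotationError(
                    f"capillary {cid!r}: nucleus {i} not inside vessel_outer"
                )
            overlap = shp.intersection(lumen).area
            if overlap > 1e-9 * max(shp.area, 1.0):
                raise AnnotationError(
                    f"capillary {cid!r}: nucleus {i} overlaps the lumen interior"
                )


@dataclass(eq=False)
class ZoneMaskSet:
    """Boolean rasters, pairwise disjoint, congruent with the annotated image."""

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("ZoneMaskSet requires at least one zone mask")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise ValueError(f"zone masks are not congruent: shapes {shapes}")
        names = list(self.masks)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if np.logical_and(self.masks[a], self.masks[b]).any():
                    raise ValueError(f"zone masks {a!r} and {b!r} overlap")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.masks.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks


@dataclass(frozen=True)
class FrameCount:
    """A capillary count inside one fixed counting frame."""

    frame_width_um: float
    frame_height_um: float
    count: int
    zone_label: str = "infarct"

    def __post_init__(self) -> None:
        if self.frame_width_um <= 0 or self.frame_height_um <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.count < 0 or int(self.count) != self.count:
            raise ValueError(f"count must be a non-negative integer, got {self.count}")

    @property
    def area_mm2(self) -> float:
        return (self.frame_width_um / 1000.0) * (self.frame_height_um / 1000.0)


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

_TIFF_SUFFIXES = {".tif", ".tiff"}
_PNG_SUFFIXES = {".png"}


def read_image(
    path: Union[str, Path],
    nm_per_px: float,
    channel_label: str = "TEM",
) -> CalibratedImage:
    """Read a single-channel TIFF or PNG without rescaling intensities."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
    elif suffix in _PNG_SUFFIXES:
        with _PILImage.open(path) as im:
            arr = np.asarray(im)
    else:
        raise ImageFormatError(f"unsupported image format {suffix!r}: {path}")
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ImageFormatError(
            f"expected single-channel image, got shape {arr.shape}: {path}"
        )
    if np.issubdtype(arr.dtype, np.signedinteger):
        # 16-bit PNGs come back as int32 through Pillow
        if arr.min() < 0 or arr.max() > 65535:
            raise ImageFormatError(f"unsupported bit depth {arr.dtype}: {path}")
        arr = arr.astype(np.uint16)
    elif not (
        np.issubdtype(arr.dtype, np.unsignedinteger)
        or np.issubdtype(arr.dtype, np.floating)
    ):
        raise ImageFormatError(f"unsupported pixel dtype {arr.dtype}: {path}")
    return CalibratedImage(arr, nm_per_px=nm_per_px, channel_label=channel_label)


def write_image(image: Union[CalibratedImage, np.ndarray], path: Union[str, Path]) -> None:
    """Write a single-channel raster to TIFF or PNG, preserving bit depth."""
    path = Path(path)
    arr = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(path, arr)
    elif suffix in _PNG_SUFFIXES:
        _PILImage.fromarray(arr).save(path)
    else:
        raise ImageFormatError(f"unsupported image format {suffix!r}: {path}")


# ---------------------------------------------------------------------------
# annotation JSON
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class AnnotationFile:
    """Parsed annotation document: calibration plus per-capillary records."""

    nm_per_px: float
    capillaries: list[CapillaryAnnotation]
    zones: Optional[dict[str, Any]] = None
    images: Optional[dict[str, str]] = None  # capillary_id -> image file name


def _polygon_from_json(coords: Any, cid: str, what: str) -> Polygon:
    try:
        return Polygon(np.asarray(coords, dtype=float))
    except AnnotationError as exc:
        raise AnnotationError(f"capillary {cid!r}: invalid {what}: {exc}") from exc


def load_annotation_file(path: Union[str, Path]) -> AnnotationFile:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    nm_per_px = float(doc["nm_per_px"])
    if not (math.isfinite(nm_per_px) and nm_per_px > 0):
        raise AnnotationError(f"invalid nm_per_px {nm_per_px!r} in {path}")
    capillaries: list[CapillaryAnnotation] = []
    images: dict[str, str] = {}
    for entry in doc.get("capillaries", []):
        cid = str(entry.get("id", f"capillary_{len(capillaries)}"))
        vessel = _polygon_from_json(entry["vessel_outer"], cid, "vessel_outer")
        lumen = _polygon_from_json(entry["lumen"], cid, "lumen")
        nuclei = [
            _polygon_from_json(coords, cid, f"nucleus {i}")
            for i, coords in enumerate(entry.get("nuclei", []))
        ]
        caveolae = [
            CaveolaMark(float(m["x"]), float(m["y"]), float(m["diameter_nm"]))
            for m in entry.get("caveolae", [])
        ]
        junctions = [
            JunctionMark(float(m["x"]), float(m["y"]))
            for m in entry.get("junctions", [])
        ]
        capillaries.append(
            CapillaryAnnotation(
                vessel_outer=vessel,
                lumen=lumen,
                nuclei=nuclei,
                caveolae=caveolae,
                junctions=junctions,
                capillary_id=cid,
            )
        )
        if "image" in entry:
            images[cid] = str(entry["image"])
    return AnnotationFile(
        nm_per_px=nm_per_px,
        capillaries=capillaries,
        zones=doc.get("zones"),
        images=images or None,
    )


def read_annotations(path: Union[str, Path]) -> list[CapillaryAnnotation]:
    """Load and validate all capillary annotations from a JSON document."""
    return load_annotation_file(path).capillaries


def write_annotation_file(
    path: Union[str, Path],
    nm_per_px: float,
    capillaries: Sequence[CapillaryAnnotation],
    zones: Optional[Mapping[str, Any]] = None,
    images: Optional[Mapping[str, str]] = None,
) -> None:
    """Serialise annotations to the documented JSON schema."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    entries = []
    for ann in capillaries:
        entry: dict[str, Any] = {
            "id": ann.capillary_id,
            "vessel_outer": np.asarray(ann.vessel_outer.vertices).tolist(),
            "lumen": np.asarray(ann.lumen.vertices).tolist(),
            "nuclei": [np.asarray(n.vertices).tolist() for n in ann.nuclei],
            "caveolae": [
                {"x": m.x, "y": m.y, "diameter_nm": m.diameter_nm}
                for m in ann.caveolae
            ],
            "junctions": [{"x": m.x, "y": m.y} for m in ann.junctions],
        }
        if images and ann.capillary_id in images:
            entry["image"] = images[ann.capillary_id]
        entries.append(entry)
    doc: dict[str, Any] = {"nm_per_px": nm_per_px, "capillaries": entries}
    if zones is not None:
        doc["zones"] = dict(zones)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _record_to_dict(record: Any) -> dict[str, Any]:
    if is_dataclass(record) and not isinstance(record, type):
        out = {}
        for f in dataclass_fields(record):
            out[f.name] = getattr(record, f.name)
        return out
    if isinstance(record, Mapping):
        return dict(record)
    raise TypeError(f"cannot serialise record of type {type(record).__name__}")


def write_metrics_table(
    records: Iterable[Any],
    path: Union[str, Path],
    metadata: Optional[Mapping[str, Any]] = None,
    columns: Optional[Sequence[str]] = None,
) -> None:
    """Write records sharing one schema to a UTF-8 CSV with a stable column order.

    ``metadata`` entries are emitted as leading ``# key=value`` comment lines
    (readable back with ``pandas.read_csv(..., comment="#")``).  ``columns``
    fixes the header explicitly, which also makes an empty record list emit a
    header-only file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [_record_to_dict(r) for r in records]
    if columns is not None:
        columns = list(columns)
        for row in rows:
            if list(row.keys()) != columns:
                raise ValueError("record schema does not match the requested columns")
    elif rows:
        columns = list(rows[0].keys())
        for row in rows[1:]:
            if list(row.keys()) != columns:
                raise ValueError("records do not share a common schema")
    else:
        columns = []
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if metadata:
            for key, value in metadata.items():
                fh.write(f"# {key}={value}\n")
        writer = csv.DictWriter(fh, fieldnames=columns)
        if columns:
            writer.writeheader()
            for row in rows:
                writer.writerow({k: ("" if v is None else v) for k, v in row.items()})
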