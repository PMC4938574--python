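"""Fluorescent-tracer extravasation metrics.

Zone MFI is the arithmetic mean pixel intensity under a zone mask; leakage
is summarised as the ratio of infarct to control MFI.  Pixel colocalisation
binarises the tracer and the endothelial-marker channel (Otsu per channel by
default, fixed cut-offs configurable) and reports the fraction of
tracer-positive pixels that also fall on marker-positive pixels.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from skimage.filters import threshold_otsu

from .core_io import CalibratedImage, ZoneMaskSet

ThresholdSpec = Union[str, float, int]


@dataclass
class LeakageMetrics:
    mfi_infarct: Optional[float] = None
    mfi_border: Optional[float] = None
    mfi_core: Optional[float] = None
    mfi_control: Optional[float] = None
    ratio_infarct_control: Optional[float] = None
    ratio_border_control: Optional[float] = None
    ratio_core_control: Optional[float] = None
    colocalisation_fraction: Optional[float] = None


def zone_mfi(img: CalibratedImage, mask: np.ndarray) -> float:
    """Arithmetic mean pixel intensity under a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {img.shape}"
        )
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty zone mask: MFI is undefined")
    return float(img.pixels[mask].astype(np.float64).mean())


def mfi_ratio(img: CalibratedImage, zones: ZoneMaskSet) -> LeakageMetrics:
    """Zone MFIs and infarct/control ratios.

    The headline infarct zone is the union of ``infarct_core`` and
    ``infarct_border`` unless a single ``infarct`` mask is supplied.
    """
    if "control" not in zones:
        raise ValueError("zone mask set must contain a 'control' zone")
    mfi_control = zone_mfi(img, zones["control"])
    if mfi_control <= 0.0:
        raise ValueError("control MFI is zero: the leakage ratio is undefined")

    metrics = LeakageMetrics(mfi_control=mfi_control)
    if "infarct" in zones:
        infarct_mask = np.asarray(zones["infarct"], dtype=bool)
    else:
        parts = [
            np.asarray(zones[name], dtype=bool)
            for name in ("infarct_core", "infarct_border")
            if name in zones
        ]
        if not parts:
            raise ValueError(
                "zone mask set must contain 'infarct' or core/border zones"
            )
        infarct_mask = np.logical_or.reduce(parts)
    metrics.mfi_infarct = zone_mfi(img, infarct_mask)
    metrics.ratio_infarct_control = metrics.mfi_infarct / mfi_control
    if "infarct_core" in zones:
        metrics.mfi_core = zone_mfi(img, zones["infarct_core"])
        metrics.ratio_core_control = metrics.mfi_core / mfi_control
    if "infarct_border" in zones:
        metrics.mfi_border = zone_mfi(img, zones["infarct_border"])
        metrics.ratio_border_control = metrics.mfi_border / mfi_control
    return metrics


def binarise(img: CalibratedImage, threshold: ThresholdSpec = "otsu") -> np.ndarray:
    """Boolean positivity mask for one channel.

    ``threshold`` is ``"otsu"``, a numeric cut-off, or ``"fixed:V"``.
    Positive means strictly above the cut-off.
    """
    if isinstance(threshold, str):
        if threshold == "otsu":
            cut = float(threshold_otsu(img.pixels))
        elif threshold.startswith("fixed:"):
            cut = float(threshold.split(":", 1)[1])
        else:
            raise ValueError(f"unknown threshold method {threshold!r}")
    else:
        cut = float(threshold)
    return img.pixels > cut


def colocalisation_fraction(
    spheres: CalibratedImage,
    cd31: CalibratedImage,
    threshold_method: Union[ThresholdSpec, Tuple[ThresholdSpec, ThresholdSpec]] = "otsu",
) -> float:
    """Fraction of tracer-positive pixels overlapping marker-positive pixels.

    ``threshold_method`` applies to both channels, or a pair applies one per
    channel (tracer first).
    """
    if spheres.shape != cd31.shape:
        raise ValueError(
            f"channel shapes differ: {spheres.shape} vs {cd31.shape}"
        )
    if isinstance(threshold_method, tuple):
        thr_spheres, thr_cd31 = threshold_method
    else:
        thr_spheres = thr_cd31 = threshold_method
    sphere_pos = binarise(spheres, thr_spheres)
    cd31_pos = binarise(cd31, thr_cd31)
    n_spheres = int(sphere_pos.sum())
    if n_spheres == 0:
        raise ValueError("undefined fraction: no sphere-positive pixels")
    overlap = int(np.logical_and(sphere_pos, cd31_pos).sum())
    return overlap / n_spheres
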