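"""Capillary density per mm² from fixed counting frames and from sections.

The counting-frame estimator treats each frame as one observation: the
per-frame density is count / frame area and the estimate is the mean and SD
across frames.  Frames are assumed to use a centroid edge rule (a capillary
counts when its centroid lies inside the frame), which is unbiased under
translation of the frame grid.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

from .core_io import FrameCount


@dataclass(frozen=True)
class DensityEstimate:
    zone_label: str
    n_frames: int
    mean_density: float  # capillaries / mm2
    sd_density: float    # capillaries / mm2

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.mean_density < 0:
            raise ValueError("mean_density must be >= 0")


def density_from_frames(
    frames: Sequence[FrameCount],
    zone_label: Optional[str] = None,
) -> DensityEstimate:
    """Mean and SD of per-frame densities across fixed counting frames."""
    if not frames:
        raise ValueError("density_from_frames requires at least one frame")
    w0, h0 = frames[0].frame_width_um, frames[0].frame_height_um
    for f in frames:
        if not (
            math.isclose(f.frame_width_um, w0, rel_tol=1e-9)
            and math.isclose(f.frame_height_um, h0, rel_tol=1e-9)
        ):
            raise ValueError("all frames must share the same dimensions")
    area = frames[0].area_mm2
    if area <= 0:
        raise ValueError("frame area must be positive")
    densities = np.array([f.count / area for f in frames], dtype=float)
    if zone_label is None:
        labels = {f.zone_label for f in frames}
        zone_label = labels.pop() if len(labels) == 1 else "mixed"
    sd = float(np.std(densities, ddof=1)) if len(densities) > 1 else 0.0
    return DensityEstimate(
        zone_label=zone_label,
        n_frames=len(frames),
        mean_density=float(densities.mean()),
        sd_density=sd,
    )


def tem_density(capillary_count: int, section_area_mm2: float) -> float:
    """Visible capillaries per mm² of section area."""
    if section_area_mm2 <= 0:
        raise ValueError(f"section area must be positive, got {section_area_mm2}")
    if capillary_count < 0:
        raise ValueError("capillary count must be non-negative")
    return capillary_count / section_area_mm2


@dataclass(frozen=True)
class ModalityComparison:
    """Paired comparison of densities measured by two modalities."""

    zone_label: str
    n_pairs: int
    mean_difference: float        # second modality minus first
    t_statistic: float
    p_value_two_sided: float
    p_value_one_sided: float      # H1: second modality > first


def compare_modalities(
    ihc_densities: Sequence[float],
    tem_densities: Sequence[float],
    zone_label: str = "control",
) -> ModalityComparison:
    """Paired t comparison of per-sample densities (TEM minus IHC).

    Inputs are per-sample density values from the same zone, one pair per
    sample.  When every difference is zero the t statistic is 0 and p = 1
    by convention.
    """
    a = np.asarray(ihc_densities, dtype=float)
    b = np.asarray(tem_densities, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired comparison needs equal-length 1-D sequences")
    n = len(a)
    if n < 2:
        raise ValueError("paired comparison needs at least 2 pairs")
    d = b - a
    mean_diff = float(d.mean())
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        t = 0.0 if mean_diff == 0.0 else math.copysign(math.inf, mean_diff)
    else:
        t = mean_diff / (sd / math.sqrt(n))
    df = n - 1
    if math.isinf(t):
        p_two = 0.0
        p_one = 0.0 if t > 0 else 1.0
    elif t == 0.0 and sd == 0.0:
        p_two = 1.0
        p_one = 0.5
    else:
        p_two = float(2.0 * _sps.t.sf(abs(t), df))
        p_one = float(_sps.t.sf(t, df))
    return ModalityComparison(
        zone_label=zone_label,
        n_pairs=n,
        mean_difference=mean_diff,
        t_statistic=float(t),
        p_value_two_sided=p_two,
        p_value_one_sided=p_one,
    )
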