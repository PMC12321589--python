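"""Image-quality metrics for phantom and clinical-style evaluation.

Phantom metrics (Hoffman 4:1:0 design):
  CRC          = (GM_mean / WM_mean - 1) / (4 - 1)
  COV          = WM_SD / WM_mean
  GM-WM        = GM_mean / WM_mean
  GM-CSF       = (GM_mean - CSF_mean) / GM_mean

Clinical-style metrics:
  CNR          = (GM_mean - WM_mean) / WM_SD
  edge sharpness = max profile slope, in % of the profile maximum per mm
  lesion SBR/SNR/CBR/CNR and putamen SUVR/CNR as ratio metrics on activity
  values (exact for every ratio; absolute SUV scaling cancels).

Standard deviations are sample SDs (ddof = 1) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .grid import ImageGrid, RoiLabelMap

__all__ = [
    "RoiStats",
    "LineProfile",
    "LesionRatios",
    "roi_stats",
    "crc",
    "cov",
    "tissue_contrasts",
    "cnr",
    "edge_sharpness",
    "lesion_ratios",
    "suvr_and_putamen_cnr",
    "profile_extract",
]


@dataclass(frozen=True)
class RoiStats:
    """Summary statistics over one region of interest."""

    mean: float
    sd: float
    max: float
    n_voxels: int


@dataclass
class LineProfile:
    """Counts sampled along a line, positions in mm (strictly increasing)."""

    positions_mm: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.positions_mm.size != self.counts.size:
            raise ValueError("positions and counts differ in length")
        if self.positions_mm.size < 3:
            raise ValueError("a profile needs at least 3 samples")
        if np.any(np.diff(self.positions_mm) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")


class LesionRatios(NamedTuple):
    sbr: float
    snr: float
    cbr: float
    cnr: float


def roi_stats(u: ImageGrid, rois: RoiLabelMap, label: "str | int") -> RoiStats:
    """Statistics over exactly the voxels carrying ``label`` (role or id)."""
    if u.shape != rois.shape:
        raise ValueError("image and label map shapes differ")
    m = rois.mask(label)
    vals = u.values[m]
    if vals.size == 0:
        raise ValueError(f"label {label!r} selects no voxels")
    sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else float("nan")
    return RoiStats(float(vals.mean()), sd, float(vals.max()), int(vals.size))


def crc(gm: RoiStats, wm: RoiStats, true_ratio: float = 4.0) -> float:
    """Contrast recovery coefficient (GM/WM - 1)/(true_ratio - 1)."""
    if wm.mean <= 0:
        raise ValueError("WM mean must be positive")
    return (gm.mean / wm.mean - 1.0) / (true_ratio - 1.0)


def cov(wm: RoiStats) -> float:
    """Coefficient of variance SD/mean of the reference (WM) region."""
    if wm.mean <= 0:
        raise ValueError("region mean must be positive")
    return wm.sd / wm.mean


def tissue_contrasts(
    gm: RoiStats, wm: RoiStats, csf: RoiStats
) -> tuple[float, float]:
    """(GM-WM contrast, GM-CSF contrast) = (GM/WM, (GM - CSF)/GM)."""
    if wm.mean <= 0 or gm.mean <= 0:
        raise ValueError("GM and WM means must be positive")
    return gm.mean / wm.mean, (gm.mean - csf.mean) / gm.mean


def cnr(gm: RoiStats, wm: RoiStats) -> float:
    """Contrast-to-noise ratio (GM_mean - WM_mean) / WM_SD."""
    if not wm.sd > 0:
        raise ValueError("WM SD must be positive (CNR undefined)")
    return (gm.mean - wm.mean) / wm.sd


def edge_sharpness(profile: LineProfile) -> float:
    """Maximum slope of the profile in percent of its maximum count per mm."""
    cmax = profile.counts.max()
    if cmax <= 0:
        raise ValueError("profile maximum must be positive")
    slopes = np.abs(np.diff(profile.counts)) / np.diff(profile.positions_mm)
    return float(slopes.max() / cmax * 100.0)


def lesion_ratios(lesion: RoiStats, background: RoiStats) -> LesionRatios:
    """SBR, SNR, CBR, CNR of a focal lesion against a background region.

    SBR = max_lesion/mean_bg, SNR = max_lesion/SD_bg,
    CBR = (mean_lesion - mean_bg)/mean_bg, CNR = (mean_lesion - mean_bg)/SD_bg.
    """
    if background.mean <= 0 or not background.sd > 0:
        raise ValueError("background must have positive mean and SD")
    return LesionRatios(
        sbr=lesion.max / background.mean,
        snr=lesion.max / background.sd,
        cbr=(lesion.mean - background.mean) / background.mean,
        cnr=(lesion.mean - background.mean) / background.sd,
    )


def suvr_and_putamen_cnr(
    target: RoiStats, reference: RoiStats, noise_region: RoiStats
) -> tuple[float, float]:
    """SUVR of a target (putamen) against a reference (cerebellum) and the
    CNR of the target against a noise region (centrum semiovale).

    SUVR = target_mean / reference_mean.  The CNR is computed on the
    SUVR-scaled image, where the reference scaling cancels:
    CNR = (target_mean - noise_mean) / noise_SD.  Target and noise stats
    must come from the same (consistently scaled) image.
    """
    if reference.mean <= 0:
        raise ValueError("reference mean must be positive")
    if not noise_region.sd > 0:
        raise ValueError("noise region SD must be positive")
    suvr = target.mean / reference.mean
    cnr_val = (target.mean - noise_region.mean) / noise_region.sd
    return suvr, cnr_val


def profile_extract(
    u: ImageGrid,
    p0: tuple[float, float],
    p1: tuple[float, float],
    step_mm: float,
) -> LineProfile:
    """Linearly interpolate the image along the segment p0 -> p1.

    Endpoints are (y, x) positions in mm relative to the image centre (the
    package-wide origin convention); samples are uniform with ``step_mm``
    spacing and always include both endpoints' span.
    """
    if step_mm <= 0:
        raise ValueError("step must be positive")
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    length = float(np.linalg.norm(p1 - p0))
    if length <= 0:
        raise ValueError("degenerate segment")
    n = int(np.floor(length / step_mm)) + 1
    if n < 3:
        raise ValueError("segment too short for the requested step")
    t = np.arange(n) * step_mm
    pts = p0[None, :] + (t / length)[:, None] * (p1 - p0)[None, :]
    spacing = np.asarray(u.spacing_mm)
    centre = (np.asarray(u.shape) - 1) / 2.0
    idx = (pts / spacing[None, :]) + centre[None, :]
    if np.any(idx < -1e-9) or np.any(idx > np.asarray(u.shape)[None, :] - 1 + 1e-9):
        raise ValueError("profile endpoints fall outside the image")
    counts = ndimage.map_coordinates(u.values, idx.T, order=1, mode="nearest")
    return LineProfile(t, counts)
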