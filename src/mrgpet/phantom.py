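"""Digital brain phantom emulating a Hoffman-type FDG uptake pattern.

The phantom is a 2-D (single-slice) brain-like object built from concentric
smooth shapes: an outer cerebrospinal-fluid (CSF) rim, a cortical grey-matter
(GM) ribbon whose inner boundary carries a pseudo-random sinusoidal "gyral"
perturbation, a white-matter (WM) core containing two ventricles (CSF) and
two deep GM nuclei (striatum-like, useful for edge-profile analysis).

Activity follows the Hoffman design exactly: GM : WM : CSF = 4 : 1 : 0, with
zero activity outside the head.  The co-registered anatomical prior is a
T1-weighted-like image sharing every tissue boundary with the activity map
but with the T1 intensity ordering WM > GM > CSF.

A 3-D phantom is obtained by passing a 3-tuple ``size``; the slice geometry
is extruded with an elliptical profile along the through-plane axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import ImageGrid, RoiLabelMap

__all__ = [
    "LesionSpec",
    "TISSUE_ACTIVITY",
    "PRIOR_INTENSITY",
    "TISSUE_LABELS",
    "generate_brain_phantom",
    "insert_lesion",
    "place_rois",
]

# Hoffman-type activity ratios (GM:WM:CSF = 4:1:0) and T1-like prior levels.
TISSUE_ACTIVITY = {"background_air": 0.0, "CSF": 0.0, "WM": 1.0, "GM": 4.0}
PRIOR_INTENSITY = {"background_air": 0.0, "CSF": 0.1, "WM": 1.0, "GM": 0.6}
TISSUE_LABELS = {0: "background_air", 1: "CSF", 2: "WM", 3: "GM"}

_MIN_SIZE = 32


@dataclass(frozen=True)
class LesionSpec:
    """A focal disk/sphere lesion with independent PET and MR contrast.

    ``pet_multiplier`` and ``mr_multiplier`` scale the host-tissue activity
    and prior intensity inside the lesion.  Setting them independently
    creates matched lesions (hot in both), or modality-mismatched ones such
    as a PET-cold but MR-bright cavernous-angioma-like lesion
    (``pet_multiplier < 1``, ``mr_multiplier > 1``).
    """

    center: tuple[float, ...]          # grid (row, col[, slice]) coordinates
    radius_mm: float
    pet_multiplier: float = 1.0
    mr_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if self.pet_multiplier < 0 or self.mr_multiplier < 0:
            raise ValueError("lesion multipliers must be nonnegative")


def _normalized_coords(shape, spacing):
    """Per-axis coordinates scaled so the head ellipse has radius 1."""
    axes = []
    for n, h in zip(shape, spacing):
        c = (np.arange(n) - (n - 1) / 2.0) * h
        semi = 0.45 * n * h
        axes.append(c / semi)
    return np.meshgrid(*axes, indexing="ij")


def generate_brain_phantom(
    size: "int | tuple[int, ...]" = (128, 128),
    spacing_mm: "float | tuple[float, ...]" = 1.2,
    seed: int = 0,
) -> tuple[ImageGrid, ImageGrid, RoiLabelMap]:
    """Build the activity image, the anatomical prior and the tissue labels.

    Deterministic given ``(size, spacing_mm, seed)``.  The seed only varies
    the pseudo-random gyral perturbation of the GM/WM interface, never the
    tissue activity levels.

    Returns
    -------
    (activity, prior, rois)
        ``activity`` has GM:WM:CSF exactly 4:1:0; ``prior`` has the T1-like
        levels of :data:`PRIOR_INTENSITY`; ``rois`` labels every voxel with
        one of :data:`TISSUE_LABELS`.
    """
    if np.isscalar(size):
        size = (int(size), int(size))
    size = tuple(int(n) for n in size)
    if len(size) not in (2, 3):
        raise ValueError("size must be 2-D or 3-D")
    if any(n < _MIN_SIZE for n in size):
        raise ValueError(
            f"grid size {size} too small to contain the brain geometry; "
            f"need at least {_MIN_SIZE} voxels per axis"
        )
    if np.isscalar(spacing_mm):
        spacing = (float(spacing_mm),) * len(size)
    else:
        spacing = tuple(float(s) for s in spacing_mm)
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")

    rng = np.random.default_rng(seed)
    phi1 = rng.uniform(0, 2 * np.pi)
    phi2 = rng.uniform(0, 2 * np.pi)
    amp2 = rng.uniform(0.02, 0.05)

    coords = _normalized_coords(size, spacing)
    yy, xx = coords[0], coords[1]
    if len(size) == 3:
        zz = coords[2]
        # extrude the slice geometry along z with an elliptical head profile
        r_z = np.sqrt(np.clip(1.0 - zz**2, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            yy = np.where(r_z > 0, yy / np.maximum(r_z, 1e-9), np.inf)
            xx = np.where(r_z > 0, xx / np.maximum(r_z, 1e-9), np.inf)

    r = np.sqrt(yy**2 + xx**2)
    theta = np.arctan2(yy, xx)

    # Gyral perturbation of the cortical GM / WM interface.
    g = 0.72 + 0.08 * np.sin(9 * theta + phi1) + amp2 * np.sin(5 * theta + phi2)

    labels = np.zeros(size, dtype=np.int16)            # background_air
    labels[r <= 1.0] = 1                               # CSF rim
    labels[r <= 0.94] = 3                              # cortical GM ribbon
    labels[r <= g] = 2                                 # WM core

    # Two lateral-ventricle-like CSF cavities.
    for sx in (-1.0, 1.0):
        vent = ((xx - sx * 0.13) / 0.10) ** 2 + ((yy + 0.08) / 0.22) ** 2
        labels[vent <= 1.0] = 1
    # Two deep GM nuclei (striatum-like), giving interior WM-GM interfaces.
    for sx in (-1.0, 1.0):
        nucleus = ((xx - sx * 0.33) / 0.10) ** 2 + ((yy - 0.12) / 0.16) ** 2
        labels[(nucleus <= 1.0) & (labels == 2)] = 3

    activity = np.zeros(size, dtype=np.float64)
    prior = np.zeros(size, dtype=np.float64)
    for lab, role in TISSUE_LABELS.items():
        m = labels == lab
        activity[m] = TISSUE_ACTIVITY[role]
        prior[m] = PRIOR_INTENSITY[role]

    act = ImageGrid(activity, spacing)
    pri = ImageGrid(prior, spacing)
    rois = RoiLabelMap(labels, dict(TISSUE_LABELS), spacing)
    return act, pri, rois


def insert_lesion(
    activity: ImageGrid,
    prior: ImageGrid,
    rois: RoiLabelMap,
    spec: LesionSpec,
) -> tuple[ImageGrid, ImageGrid, RoiLabelMap]:
    """Insert a focal lesion; inputs are not mutated.

    Voxels inside the lesion get ``activity × pet_multiplier`` and
    ``prior × mr_multiplier`` relative to the pre-insertion host values, and
    a fresh ``lesion_<k>`` label is added to the legend.
    """
    if activity.shape != rois.shape or prior.shape != rois.shape:
        raise ValueError("activity, prior and label map must share a shape")
    center = np.asarray(spec.center, dtype=np.float64)
    if center.size != activity.ndim:
        raise ValueError("lesion center dimensionality does not match grid")
    spacing = np.asarray(activity.spacing_mm)
    grids = np.meshgrid(*[np.arange(n) for n in activity.shape], indexing="ij")
    d2 = sum(((g - c) * h) ** 2 for g, c, h in zip(grids, center, spacing))
    mask = d2 <= spec.radius_mm**2
    if not mask.any():
        raise ValueError("lesion contains no voxels at this grid resolution")
    if np.any(rois.labels[mask] == 0):
        raise ValueError("lesion extends outside the brain mask")

    act = activity.copy()
    pri = prior.copy()
    act.values[mask] *= spec.pet_multiplier
    pri.values[mask] *= spec.mr_multiplier

    out_rois = rois.copy()
    new_label = int(out_rois.labels.max()) + 1
    n_lesions = sum(1 for r in out_rois.legend.values() if r.startswith("lesion_"))
    out_rois.labels[mask] = new_label
    out_rois.legend[new_label] = f"lesion_{n_lesions + 1}"
    return act, pri, out_rois


def place_rois(
    rois: RoiLabelMap,
    radius_mm: float = 2.4,
    n_per_class: int = 6,
    roles: tuple[str, ...] = ("CSF", "WM", "GM"),
) -> RoiLabelMap:
    """Auto-place circular measurement ROIs deep inside each tissue class.

    Candidate centres are local maxima of the Euclidean distance transform
    of each class mask (the deepest points of the tissue), picked greedily
    with a minimum separation of one diameter; each circle is shrunk if
    needed so it stays strictly inside its tissue.  The result is a new
    label map using the same label ids as the tissue legend, zero elsewhere.
    """
    spacing = np.asarray(rois.spacing_mm)
    out = np.zeros(rois.shape, dtype=np.int16)
    legend: dict[int, str] = {0: "unassigned"}
    grids = np.meshgrid(*[np.arange(n) for n in rois.shape], indexing="ij")
    for role in roles:
        lab = rois.label_for_role(role)
        m = rois.labels == lab
        if not m.any():
            continue
        dist = ndimage.distance_transform_edt(m, sampling=spacing)
        flat = dist.ravel()
        order = np.argsort(flat)[::-1]
        chosen: list[np.ndarray] = []
        for idx in order:
            depth = flat[idx]
            if depth < 1.001 * min(spacing):
                break
            c = np.array(np.unravel_index(idx, rois.shape), dtype=float)
            r_eff = min(radius_mm, depth - 0.5 * min(spacing))
            if r_eff <= 0:
                continue
            if any(
                np.sqrt(np.sum(((c - p) * spacing) ** 2)) < 2.0 * radius_mm
                for p in chosen
            ):
                continue
            d2 = sum(((g - ci) * h) ** 2 for g, ci, h in zip(grids, c, spacing))
            out[(d2 <= r_eff**2) & m] = lab
            chosen.append(c)
            if len(chosen) >= n_per_class:
                break
        if chosen:
            legend[lab] = role
    return RoiLabelMap(out, legend, rois.spacing_mm)
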