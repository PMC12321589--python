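"""Image-domain containers shared by every stage of the pipeline.

The physical origin sits at the centre of the array: voxel ``(i, j)`` of a
2-D image is at ``y = (i - (ny - 1)/2) * spacing_mm[0]``,
``x = (j - (nx - 1)/2) * spacing_mm[1]``.  All geometry (projector rays,
line profiles, lesion placement) uses this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageGrid", "RoiLabelMap"]


@dataclass
class ImageGrid:
    """A scalar image (activity, anatomical prior, or reconstruction) on a
    regular grid with physical voxel spacing.

    Parameters
    ----------
    values
        Voxel values, any floating dtype; stored as float64.  Must be finite.
    spacing_mm
        Per-axis voxel size in millimetres, one entry per array axis.
    """

    values: np.ndarray
    spacing_mm: tuple[float, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing_mm = tuple(float(s) for s in np.atleast_1d(self.spacing_mm))
        if len(self.spacing_mm) == 1 and self.values.ndim > 1:
            self.spacing_mm = self.spacing_mm * self.values.ndim
        if len(self.spacing_mm) != self.values.ndim:
            raise ValueError(
                f"spacing_mm has {len(self.spacing_mm)} entries for a "
                f"{self.values.ndim}-D image"
            )
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def copy(self) -> "ImageGrid":
        return ImageGrid(self.values.copy(), self.spacing_mm)

    def with_values(self, values: np.ndarray) -> "ImageGrid":
        """Same grid geometry, new voxel values."""
        return ImageGrid(np.asarray(values, dtype=np.float64), self.spacing_mm)


@dataclass
class RoiLabelMap:
    """Integer label image plus a legend mapping each label to a role.

    Roles follow the tissue vocabulary of the brain phantom:
    ``background_air``, ``CSF``, ``WM``, ``GM``, ``lesion_<k>`` and
    ``reference``.  Labels partition the grid: every voxel carries exactly
    one label.
    """

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)
    spacing_mm: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must be integer-valued")
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        self.spacing_mm = tuple(float(s) for s in np.atleast_1d(self.spacing_mm))
        if len(self.spacing_mm) == 1 and self.labels.ndim > 1:
            self.spacing_mm = self.spacing_mm * self.labels.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def label_for_role(self, role: str) -> int:
        for lab, r in self.legend.items():
            if r == role:
                return lab
        raise KeyError(f"role {role!r} not present in legend {self.legend}")

    def mask(self, role_or_label: "str | int") -> np.ndarray:
        """Boolean mask of the voxels carrying a role name or raw label."""
        if isinstance(role_or_label, str):
            lab = self.label_for_role(role_or_label)
        else:
            lab = int(role_or_label)
            if lab not in self.legend:
                raise KeyError(f"label {lab} not present in legend")
        return self.labels == lab

    def copy(self) -> "RoiLabelMap":
        return RoiLabelMap(self.labels.copy(), dict(self.legend), self.spacing_mm)
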