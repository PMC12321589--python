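"""Parallel-beam forward model: system matrix, PSF, counting noise, thinning.

The projector is a 2-D parallel-beam line integral with exact ray-pixel
intersection lengths (Siddon-style grid traversal), assembled once per
(geometry, grid) pair into a sparse matrix so that forward and back
projection are exact adjoints by construction.  Resolution is modelled as
an isotropic image-space Gaussian (symmetric, Neumann boundary), which is
self-adjoint and therefore keeps the full forward/backward pair adjoint.

The expected-count model for line of response i is

    ybar_i(u) = n_i * [A blur(u)]_i + r_i

with per-LOR multiplicative normalization ``n_i`` (attenuation, detector
efficiency, count-level calibration) and additive background ``r_i``
(scatter + randoms), defaults 1 and 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, sparse

from .grid import ImageGrid

__all__ = [
    "SystemModel",
    "Sinogram",
    "forward_project",
    "back_project",
    "sensitivity_image",
    "fov_mask",
    "add_poisson_noise",
    "thin_counts",
    "calibrate_to_counts",
    "gaussian_blur",
    "FWHM_TO_SIGMA",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_blur(values: np.ndarray, fwhm_mm: float, spacing_mm) -> np.ndarray:
    """Isotropic Gaussian blur with symmetric (Neumann) boundary.

    With a symmetric kernel and symmetric padding the operator is
    self-adjoint and maps flat images to themselves (hence preserves the
    total image sum).
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be nonnegative")
    if fwhm_mm == 0:
        return np.asarray(values, dtype=np.float64)
    spacing = np.atleast_1d(np.asarray(spacing_mm, dtype=np.float64))
    if spacing.size == 1:
        spacing = np.repeat(spacing, np.ndim(values))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / spacing
    return ndimage.gaussian_filter(
        np.asarray(values, dtype=np.float64), sigma=sigma_vox, mode="reflect"
    )


def _ray_pixel_lengths(x0, y0, dx, dy, x_edges, y_edges):
    """Siddon traversal: pixels crossed by one ray and intersection lengths.

    The ray is p(s) = (x0, y0) + s (dx, dy) with |d| = 1.  Returns
    (col_idx, row_idx, lengths) arrays.
    """
    eps = 1e-12
    smin, smax = -np.inf, np.inf
    for p0, d, edges in ((x0, dx, x_edges), (y0, dy, y_edges)):
        if abs(d) > eps:
            s1 = (edges[0] - p0) / d
            s2 = (edges[-1] - p0) / d
            smin = max(smin, min(s1, s2))
            smax = min(smax, max(s1, s2))
        elif not (edges[0] <= p0 <= edges[-1]):
            return (np.empty(0, int), np.empty(0, int), np.empty(0))
    if smax <= smin + eps:
        return (np.empty(0, int), np.empty(0, int), np.empty(0))

    crossings = [np.array([smin, smax])]
    for p0, d, edges in ((x0, dx, x_edges), (y0, dy, y_edges)):
        if abs(d) > eps:
            s = (edges - p0) / d
            crossings.append(s[(s > smin + eps) & (s < smax - eps)])
    ts = np.unique(np.concatenate(crossings))
    lengths = np.diff(ts)
    keep = lengths > eps
    ts_mid = 0.5 * (ts[:-1] + ts[1:])[keep]
    lengths = lengths[keep]
    xm = x0 + ts_mid * dx
    ym = y0 + ts_mid * dy
    hx = x_edges[1] - x_edges[0]
    hy = y_edges[1] - y_edges[0]
    col = np.clip(((xm - x_edges[0]) / hx).astype(int), 0, len(x_edges) - 2)
    row = np.clip(((ym - y_edges[0]) / hy).astype(int), 0, len(y_edges) - 2)
    return col, row, lengths


def _build_matrix(n_angles, n_radial_bins, bin_spacing_mm, shape, spacing_mm):
    ny, nx = shape
    hy, hx = spacing_mm
    x_edges = (np.arange(nx + 1) - nx / 2.0) * hx
    y_edges = (np.arange(ny + 1) - ny / 2.0) * hy
    offsets = (np.arange(n_radial_bins) - (n_radial_bins - 1) / 2.0) * bin_spacing_mm
    thetas = np.arange(n_angles) * np.pi / n_angles

    rows_out, cols_out, data_out = [], [], []
    for ai, th in enumerate(thetas):
        c, s = np.cos(th), np.sin(th)
        dx, dy = -s, c  # ray direction, orthogonal to the offset axis
        for bi, t in enumerate(offsets):
            col, row, w = _ray_pixel_lengths(t * c, t * s, dx, dy, x_edges, y_edges)
            if w.size == 0:
                continue
            rows_out.append(np.full(w.size, ai * n_radial_bins + bi, dtype=np.int64))
            cols_out.append(row.astype(np.int64) * nx + col.astype(np.int64))
            data_out.append(w)
    if rows_out:
        rows = np.concatenate(rows_out)
        cols = np.concatenate(cols_out)
        data = np.concatenate(data_out)
    else:  # pragma: no cover - degenerate geometry
        rows = cols = np.empty(0, dtype=np.int64)
        data = np.empty(0)
    A = sparse.coo_matrix(
        (data, (rows, cols)), shape=(n_angles * n_radial_bins, ny * nx)
    )
    return A.tocsr()


@dataclass
class SystemModel:
    """Projection geometry, image-space PSF, normalization and background.

    ``normalization`` is a scalar or an ``(n_angles, n_radial_bins)`` array
    of positive per-LOR factors; ``background`` a scalar or array of
    nonnegative additive expected counts.
    """

    n_angles: int = 120
    n_radial_bins: int = 128
    bin_spacing_mm: float = 1.2
    psf_fwhm_mm: float = 3.0
    normalization: "float | np.ndarray" = 1.0
    background: "float | np.ndarray" = 0.0
    _matrix_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.n_radial_bins < 1:
            raise ValueError("need at least one angle and one radial bin")
        if self.bin_spacing_mm <= 0:
            raise ValueError("bin spacing must be positive")
        if self.psf_fwhm_mm < 0:
            raise ValueError("PSF FWHM must be nonnegative")
        if np.any(np.asarray(self.normalization) <= 0):
            raise ValueError("normalization must be strictly positive")
        if np.any(np.asarray(self.background) < 0):
            raise ValueError("background must be nonnegative")

    @property
    def sino_shape(self) -> tuple[int, int]:
        return (self.n_angles, self.n_radial_bins)

    def matrix(self, shape: tuple[int, int], spacing_mm) -> sparse.csr_matrix:
        """Sparse line-integral matrix for an image grid (cached)."""
        spacing = tuple(float(s) for s in np.atleast_1d(spacing_mm))
        if len(spacing) == 1:
            spacing = spacing * 2
        key = (tuple(shape), spacing)
        if key not in self._matrix_cache:
            if len(shape) != 2:
                raise ValueError("the projector is 2-D; pass a single slice")
            self._matrix_cache[key] = _build_matrix(
                self.n_angles, self.n_radial_bins, self.bin_spacing_mm, shape, spacing
            )
        return self._matrix_cache[key]

    def norm_array(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.normalization, dtype=np.float64), self.sino_shape
        )

    def background_array(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.background, dtype=np.float64), self.sino_shape
        )

    def with_normalization(self, normalization) -> "SystemModel":
        out = replace(self, normalization=normalization)
        out._matrix_cache = self._matrix_cache  # geometry unchanged
        return out


@dataclass
class Sinogram:
    """Counts (or expected counts) indexed by (projection angle, radial bin)."""

    values: np.ndarray
    dose_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("sinogram must be 2-D (angles x radial bins)")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite and nonnegative")
        if not (0 < self.dose_fraction <= 1):
            raise ValueError("dose_fraction must lie in (0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "Sinogram":
        return Sinogram(self.values.copy(), self.dose_fraction)


def _check_compat(u: ImageGrid, model: SystemModel) -> None:
    if u.ndim != 2:
        raise ValueError("the projector operates on 2-D slices")
    if np.any(u.values < 0):
        raise ValueError("activity images must be nonnegative")


def forward_project(u: ImageGrid, model: SystemModel) -> Sinogram:
    """Expected-count sinogram ybar = n * A blur(u) + r."""
    _check_compat(u, model)
    blurred = gaussian_blur(u.values, model.psf_fwhm_mm, u.spacing_mm)
    A = model.matrix(u.shape, u.spacing_mm)
    proj = (A @ blurred.ravel()).reshape(model.sino_shape)
    ybar = model.norm_array() * proj + model.background_array()
    return Sinogram(ybar)


def back_project(s: Sinogram, model: SystemModel, grid: ImageGrid) -> ImageGrid:
    """Adjoint of the linear part of :func:`forward_project`.

    Computes blur(A^T (n * s)) on the geometry of ``grid`` (whose values are
    ignored).  Satisfies ⟨n*A blur(u), s⟩ = ⟨u, back_project(s)⟩.
    """
    if s.shape != model.sino_shape:
        raise ValueError(
            f"sinogram shape {s.shape} does not match model {model.sino_shape}"
        )
    A = model.matrix(grid.shape, grid.spacing_mm)
    weighted = (model.norm_array() * s.values).ravel()
    img = (A.T @ weighted).reshape(grid.shape)
    img = gaussian_blur(img, model.psf_fwhm_mm, grid.spacing_mm)
    return grid.with_values(img)


def sensitivity_image(model: SystemModel, grid: ImageGrid) -> ImageGrid:
    """s_j = backproject(n): total sensitivity of voxel j, > 0 inside FOV."""
    ones = Sinogram(np.ones(model.sino_shape))
    return back_project(ones, model, grid)


def fov_mask(model: SystemModel, grid: ImageGrid, rel_tol: float = 1e-9) -> np.ndarray:
    """Voxels seen by the scanner (positive sensitivity)."""
    s = sensitivity_image(model, grid).values
    return s > rel_tol * s.max()


def add_poisson_noise(ybar: Sinogram, seed: int) -> Sinogram:
    """Element-wise Poisson counts with mean ``ybar``; deterministic per seed."""
    if np.any(ybar.values < 0):
        raise ValueError("expected counts must be nonnegative")
    rng = np.random.default_rng(seed)
    y = rng.poisson(ybar.values).astype(np.float64)
    return Sinogram(y, ybar.dose_fraction)


def thin_counts(y: Sinogram, fraction: float, seed: int) -> Sinogram:
    """Binomial thinning of recorded counts, emulating a lower injected dose.

    Keeping each event independently with probability ``fraction`` is
    statistically identical to acquiring ``fraction`` of the listmode data.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    counts = y.values
    ints = np.rint(counts)
    if np.any(np.abs(counts - ints) > 1e-9):
        raise ValueError("thinning requires integer counts")
    if fraction == 1.0:
        return y.copy()
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(ints.astype(np.int64), fraction).astype(np.float64)
    return Sinogram(thinned, y.dose_fraction * fraction)


def calibrate_to_counts(
    model: SystemModel, activity: ImageGrid, total_counts: float
) -> tuple[SystemModel, Sinogram]:
    """Scale the model normalization so the full-dose expectation sums to
    ``total_counts``; returns the calibrated model and its noise-free sinogram.
    """
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    ybar = forward_project(activity, model)
    tot = ybar.values.sum()
    if tot <= 0:
        raise ValueError("phantom produces no counts under this model")
    scale = total_counts / tot
    cal = model.with_normalization(np.asarray(model.normalization) * scale)
    return cal, Sinogram(ybar.values * scale)
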