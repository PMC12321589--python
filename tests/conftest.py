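import numpy as np
import pytest

import mrgpet as m


@pytest.fixture(scope="session")
def small_phantom():
    """64x64 brain phantom at 1.2 mm, seed 0 (shared, read-only)."""
    return m.generate_brain_phantom((64, 64), 1.2, seed=0)


@pytest.fixture(scope="session")
def small_model():
    """Modest parallel-beam geometry matched to the 64x64 phantom."""
    return m.SystemModel(
        n_angles=96, n_radial_bins=96, bin_spacing_mm=1.2, psf_fwhm_mm=0.0
    )


@pytest.fixture(scope="session")
def calibrated(small_phantom, small_model):
    """(model, noise-free sinogram) calibrated to 2e6 total counts."""
    act, _, _ = small_phantom
    return m.calibrate_to_counts(small_model, act, 2.0e6)


def brute_force_projection(u: np.ndarray, spacing, n_angles, n_bins, bin_spacing):
    """Independent projector oracle: per-pixel line clipping.

    For every ray and every pixel, intersect the ray with the pixel square
    analytically (Liang-Barsky clipping) and accumulate length * value.
    O(n_pixels) per ray; completely independent of the package's Siddon
    grid traversal.
    """
    ny, nx = u.shape
    hy, hx = spacing
    sino = np.zeros((n_angles, n_bins))
    for ai in range(n_angles):
        th = ai * np.pi / n_angles
        c, s = np.cos(th), np.sin(th)
        dx, dy = -s, c
        for bi in range(n_bins):
            t = (bi - (n_bins - 1) / 2.0) * bin_spacing
            x0, y0 = t * c, t * s
            total = 0.0
            for iy in range(ny):
                for ix in range(nx):
                    xlo = (ix - nx / 2.0) * hx
                    ylo = (iy - ny / 2.0) * hy
                    length = _clip_length(
                        x0, y0, dx, dy, xlo, xlo + hx, ylo, ylo + hy
                    )
                    total += length * u[iy, ix]
            sino[ai, bi] = total
    return sino


def _clip_length(x0, y0, dx, dy, xlo, xhi, ylo, yhi):
    tmin, tmax = -np.inf, np.inf
    for p0, d, lo, hi in ((x0, dx, xlo, xhi), (y0, dy, ylo, yhi)):
        if abs(d) < 1e-14:
            if not (lo <= p0 <= hi):
                return 0.0
        else:
            t1, t2 = (lo - p0) / d, (hi - p0) / d
            tmin = max(tmin, min(t1, t2))
            tmax = min(tmax, max(t1, t2))
    return max(0.0, tmax - tmin)
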