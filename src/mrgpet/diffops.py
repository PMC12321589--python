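"""Discrete gradient/divergence pair used by the anatomical penalty.

Forward differences per axis, divided by the voxel spacing, with a
replicate (Neumann) boundary: the difference at the last sample of each
axis is zero.  The divergence is defined as the exact negative adjoint of
this gradient, so ⟨∇u, p⟩ = −⟨u, div p⟩ holds to round-off and analytic
penalty gradients are discretely consistent with the penalty value.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gradient", "gradient_adjoint", "divergence"]


def gradient(u: np.ndarray, spacing_mm) -> np.ndarray:
    """Forward-difference gradient, shape ``(ndim, *u.shape)``, units 1/mm."""
    u = np.asarray(u, dtype=np.float64)
    spacing = np.atleast_1d(np.asarray(spacing_mm, dtype=np.float64))
    if spacing.size == 1:
        spacing = np.repeat(spacing, u.ndim)
    g = np.zeros((u.ndim,) + u.shape, dtype=np.float64)
    for ax in range(u.ndim):
        sl_lo = [slice(None)] * u.ndim
        sl_hi = [slice(None)] * u.ndim
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        g[ax][tuple(sl_lo)] = (u[tuple(sl_hi)] - u[tuple(sl_lo)]) / spacing[ax]
    return g


def gradient_adjoint(p: np.ndarray, spacing_mm) -> np.ndarray:
    """Adjoint of :func:`gradient`: ⟨gradient(u), p⟩ = ⟨u, gradient_adjoint(p)⟩.

    ``p`` has shape ``(ndim, *image_shape)``.  The last slice of each axis of
    the corresponding component is ignored (the forward operator never
    produces it), matching the Neumann boundary.
    """
    p = np.asarray(p, dtype=np.float64)
    ndim = p.shape[0]
    spacing = np.atleast_1d(np.asarray(spacing_mm, dtype=np.float64))
    if spacing.size == 1:
        spacing = np.repeat(spacing, ndim)
    out = np.zeros(p.shape[1:], dtype=np.float64)
    for ax in range(ndim):
        comp = p[ax].copy()
        sl_last = [slice(None)] * ndim
        sl_last[ax] = slice(-1, None)
        comp[tuple(sl_last)] = 0.0
        # (D^T p)_j = (p_{j-1} - p_j) / h  with p_{-1} = 0
        shifted = np.zeros_like(comp)
        sl_dst = [slice(None)] * ndim
        sl_src = [slice(None)] * ndim
        sl_dst[ax] = slice(1, None)
        sl_src[ax] = slice(0, -1)
        shifted[tuple(sl_dst)] = comp[tuple(sl_src)]
        out += (shifted - comp) / spacing[ax]
    return out


def divergence(p: np.ndarray, spacing_mm) -> np.ndarray:
    """Divergence defined as the negative adjoint of :func:`gradient`."""
    return -gradient_adjoint(p, spacing_mm)
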