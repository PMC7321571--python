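"""Lanczos and linear resampling kernels shared by the deformation routines.

The virtual-deformation protocol resamples a volume through the inverse of
an affine map using Lanczos interpolation. scipy has no Lanczos resampler,
so the windowed-sinc kernel is implemented here:

    L(x) = sinc(x) * sinc(x / a)   for |x| < a, else 0

with kernel order ``a = 3`` by default. Weights are renormalized per output
sample so that a constant image is reproduced exactly. Samples that fall
outside the input lattice are flagged invalid and set to zero; inside the
domain, edge voxels are clamp-extended for the kernel support.

Two code paths exist: a fast separable path (per-axis weight matrices) used
whenever the source coordinate along each output axis depends on that axis
alone — pure translations and axis-aligned (diagonal) affine maps, which
cover the axial-compression protocol — and a general gather path for full
3x3 matrices.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "lanczos_kernel",
    "resample_separable",
    "resample_general",
]


def lanczos_kernel(x: np.ndarray, a: int = 3) -> np.ndarray:
    """Windowed sinc kernel of order ``a`` evaluated at offsets ``x``."""
    x = np.asarray(x, dtype=float)
    out = np.sinc(x) * np.sinc(x / a)
    return np.where(np.abs(x) < a, out, 0.0)


def _axis_weights(src: np.ndarray, n_in: int, interp: str, a: int):
    """Per-output-sample taps for one axis.

    Returns ``(idx, w, valid)`` where ``idx`` has shape (n_out, taps) of
    clamped input indices, ``w`` the matching normalized weights and
    ``valid`` flags outputs whose source position lies inside [0, n_in-1].
    """
    src = np.asarray(src, dtype=float)
    valid = (src >= 0.0) & (src <= n_in - 1.0)
    base = np.floor(src).astype(int)
    frac = src - base
    if interp == "lanczos":
        offsets = np.arange(-a + 1, a + 1)
        w = lanczos_kernel(frac[:, None] - offsets[None, :], a)
        w /= w.sum(axis=1, keepdims=True)
        # integer positions bypass the kernel exactly (sinc(k) != 0 in fp)
        on_node = frac == 0.0
        w[on_node] = 0.0
        w[on_node, list(offsets).index(0)] = 1.0
    elif interp == "linear":
        offsets = np.arange(0, 2)
        w = np.stack([1.0 - frac, frac], axis=1)
    else:
        raise ValueError(f"unknown interpolation {interp!r}")
    idx = np.clip(base[:, None] + offsets[None, :], 0, n_in - 1)
    return idx, w, valid


def resample_separable(
    data: np.ndarray,
    src_axes: tuple[np.ndarray, np.ndarray, np.ndarray],
    interp: str = "lanczos",
    a: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``data`` at the tensor-product grid of per-axis positions.

    ``src_axes[d][i]`` is the (fractional) source coordinate along axis
    ``d`` of output index ``i``. Returns ``(out, invalid)``.
    """
    out = np.asarray(data, dtype=float)
    valids = []
    for axis in range(3):
        idx, w, valid = _axis_weights(src_axes[axis], data.shape[axis], interp, a)
        moved = np.moveaxis(out, axis, 0)
        gathered = moved[idx]  # (n_out, taps, ...)
        moved = np.einsum("ot...,ot->o...", gathered, w)
        out = np.moveaxis(moved, 0, axis)
        valids.append(valid)
    invalid = ~(
        valids[0][:, None, None] & valids[1][None, :, None] & valids[2][None, None, :]
    )
    out[invalid] = 0.0
    return out, invalid


def resample_general(
    data: np.ndarray,
    coords: np.ndarray,
    interp: str = "lanczos",
    a: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``data`` at arbitrary source coordinates.

    ``coords`` has shape ``(3,) + out_shape``. Returns ``(out, invalid)``.
    """
    data = np.asarray(data, dtype=float)
    coords = np.asarray(coords, dtype=float)
    invalid = np.zeros(coords.shape[1:], dtype=bool)
    for axis in range(3):
        invalid |= (coords[axis] < 0.0) | (coords[axis] > data.shape[axis] - 1.0)
    if interp == "linear":
        out = ndimage.map_coordinates(data, coords, order=1, mode="nearest")
    elif interp == "lanczos":
        base = np.floor(coords).astype(int)
        frac = coords - base
        out = np.zeros(coords.shape[1:], dtype=float)
        wsum = np.zeros_like(out)
        for ox in range(-a + 1, a + 1):
            wx = lanczos_kernel(frac[0] - ox, a)
            ix = np.clip(base[0] + ox, 0, data.shape[0] - 1)
            for oy in range(-a + 1, a + 1):
                wy = lanczos_kernel(frac[1] - oy, a)
                iy = np.clip(base[1] + oy, 0, data.shape[1] - 1)
                wxy = wx * wy
                for oz in range(-a + 1, a + 1):
                    wz = lanczos_kernel(frac[2] - oz, a)
                    iz = np.clip(base[2] + oz, 0, data.shape[2] - 1)
                    w = wxy * wz
                    out += w * data[ix, iy, iz]
                    wsum += w
        out /= wsum
    else:
        raise ValueError(f"unknown interpolation {interp!r}")
    out[invalid] = 0.0
    return out, invalid
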