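"""Small-strain tensor and von Mises equivalent strain on the DVC grid.

The symmetric small-strain tensor is obtained from the nodal displacement
field by central differences on the sub-volume grid (one-sided at grid
borders and beside invalid nodes):

    eps_ij = (du_i/dx_j + du_j/dx_i) / 2

The von Mises equivalent strain combines the deviatoric normal components
``e_ii = (2/3) eps_ii - (1/3)(sum of the other two)`` and the engineering
shears ``gamma_ij = 2 eps_ij``:

    eps_eq = (2/3) * sqrt( 3 (e_xx^2 + e_yy^2 + e_zz^2) / 2
                          + 3 (g_xy^2 + g_xz^2 + g_yz^2) / 4 )

which is nonnegative, vanishes for purely hydrostatic states and scales
linearly with the strain magnitude. Compression is negative; all strains
are reported in microstrain (µε, strain × 1e6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .dvc import DisplacementField, SubvolumeGrid

__all__ = [
    "StrainTensorField",
    "COMPONENTS",
    "compute_strain",
    "equivalent_strain",
    "equivalent_strain_components",
    "interpolate_to_image",
]

#: Strain-component storage order.
COMPONENTS = ("exx", "eyy", "ezz", "exy", "exz", "eyz")


@dataclass
class StrainTensorField:
    """Six strain components per grid node, in µε.

    ``eps`` has shape ``n_nodes + (6,)`` ordered per :data:`COMPONENTS`
    (tensorial shears, not engineering shears). Invalid nodes carry NaN.
    """

    grid: SubvolumeGrid
    eps: np.ndarray
    valid: np.ndarray

    def component(self, name: str) -> np.ndarray:
        if name == "eeq":
            return self.equivalent()
        if name not in COMPONENTS:
            raise KeyError(f"unknown strain component {name!r}")
        return self.eps[..., COMPONENTS.index(name)]

    def deviatoric(self) -> np.ndarray:
        """Deviatoric normal components (e_xx, e_yy, e_zz), µε."""
        exx, eyy, ezz = self.eps[..., 0], self.eps[..., 1], self.eps[..., 2]
        mean = (exx + eyy + ezz) / 3.0
        return np.stack([exx - mean, eyy - mean, ezz - mean], axis=-1)

    def engineering_shears(self) -> np.ndarray:
        """Engineering shears gamma_ij = 2 eps_ij, µε."""
        return 2.0 * self.eps[..., 3:6]

    def equivalent(self) -> np.ndarray:
        """Von Mises equivalent strain per node, µε (NaN on invalid nodes)."""
        return equivalent_strain_components(self.eps)

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))


def _masked_gradient(f: np.ndarray, valid: np.ndarray, h: float, axis: int):
    """d f / d x along ``axis`` with invalid-aware stencils.

    Central differences where both neighbors are valid, one-sided next to
    borders or invalid nodes; returns ``(df, ok)`` where ``ok`` marks
    nodes with at least one usable neighbor.
    """
    fm = np.roll(f, 1, axis=axis)
    fp = np.roll(f, -1, axis=axis)
    vm = np.roll(valid, 1, axis=axis)
    vp = np.roll(valid, -1, axis=axis)
    # roll wraps around: edge nodes have no neighbor on that side
    sl_lo = [slice(None)] * f.ndim
    sl_lo[axis] = slice(0, 1)
    sl_hi = [slice(None)] * f.ndim
    sl_hi[axis] = slice(-1, None)
    vm[tuple(sl_lo)] = False
    vp[tuple(sl_hi)] = False

    df = np.full_like(f, np.nan, dtype=float)
    both = valid & vm & vp
    fwd = valid & vp & ~vm
    bwd = valid & vm & ~vp
    df[both] = (fp[both] - fm[both]) / (2.0 * h)
    df[fwd] = (fp[fwd] - f[fwd]) / h
    df[bwd] = (f[bwd] - fm[bwd]) / h
    ok = both | fwd | bwd
    return df, ok


def compute_strain(field: DisplacementField) -> StrainTensorField:
    """Differentiate the nodal displacement field into strain (µε).

    Requires at least 2 nodes along every axis. A node keeps its strain
    only if all nine displacement gradients could be formed there.
    """
    nn = field.grid.n_nodes
    if any(n < 2 for n in nn):
        raise ValueError(
            f"strain needs >= 2 nodes per axis, grid has {nn}; "
            "use a smaller sub-volume or more overlap"
        )
    h = float(field.grid.spacing)
    u = np.where(field.valid[..., None], field.u, np.nan)

    grads = np.empty(nn + (3, 3))
    ok = field.valid.copy()
    for i in range(3):  # displacement component
        for j in range(3):  # derivative axis
            g, g_ok = _masked_gradient(u[..., i], field.valid, h, axis=j)
            grads[..., i, j] = g
            ok &= g_ok

    eps = np.full(nn + (6,), np.nan)
    sym = 0.5 * (grads + np.swapaxes(grads, -1, -2)) * 1e6
    eps[..., 0] = sym[..., 0, 0]
    eps[..., 1] = sym[..., 1, 1]
    eps[..., 2] = sym[..., 2, 2]
    eps[..., 3] = sym[..., 0, 1]
    eps[..., 4] = sym[..., 0, 2]
    eps[..., 5] = sym[..., 1, 2]
    eps[~ok] = np.nan
    return StrainTensorField(field.grid, eps, ok)


def equivalent_strain_components(eps: np.ndarray) -> np.ndarray:
    """Von Mises equivalent strain from six components (..., 6) in µε.

    Components are ordered per :data:`COMPONENTS` with tensorial shears;
    the formula uses deviatoric normal parts and engineering shears.
    """
    eps = np.asarray(eps, dtype=float)
    exx, eyy, ezz = eps[..., 0], eps[..., 1], eps[..., 2]
    mean = (exx + eyy + ezz) / 3.0
    dx, dy, dz = exx - mean, eyy - mean, ezz - mean
    gxy, gxz, gyz = 2.0 * eps[..., 3], 2.0 * eps[..., 4], 2.0 * eps[..., 5]
    return (2.0 / 3.0) * np.sqrt(
        1.5 * (dx**2 + dy**2 + dz**2) + 0.75 * (gxy**2 + gxz**2 + gyz**2)
    )


def equivalent_strain(strain: StrainTensorField) -> np.ndarray:
    """Per-node von Mises equivalent strain in µε (NaN on invalid nodes)."""
    return strain.equivalent()


def interpolate_to_image(
    strain: StrainTensorField, shape: tuple[int, int, int], component: str = "eeq"
) -> np.ndarray:
    """Trilinearly interpolate a nodal strain component onto the voxel grid.

    Voxels outside the convex hull of the node lattice are NaN (no-data).
    """
    values = strain.component(component)
    axes = strain.grid.node_axes
    if any(len(a) < 2 for a in axes):
        raise ValueError("interpolation needs >= 2 nodes per axis")
    itp = RegularGridInterpolator(
        axes, values, method="linear", bounds_error=False, fill_value=np.nan
    )
    out = np.full(shape, np.nan, dtype=float)
    xs = np.arange(shape[0], dtype=float)
    ys = np.arange(shape[1], dtype=float)
    zs = np.arange(shape[2], dtype=float)
    gy, gz = np.meshgrid(ys, zs, indexing="ij")
    for i, x in enumerate(xs):  # slab-wise to bound memory
        pts = np.stack([np.full(gy.shape, x), gy, gz], axis=-1).reshape(-1, 3)
        out[i] = itp(pts).reshape(shape[1], shape[2])
    return out
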