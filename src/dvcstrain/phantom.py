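"""Synthetic cartilage-bone phantoms and virtual deformations.

The phantom emulates a micro-CT field of view across the osteochondral
interface: articular cartilage above, mineralized tissue (calcified
cartilage + subchondral bone) below, separated by a rough interface, with
dark ellipsoidal lacunae as gray-scale texture in both regions
(chondrocyte lacunae in cartilage; osteocyte / hypertrophic-chondrocyte
lacunae in mineralized tissue), additive Gaussian acquisition noise, and
optional bright/dark fringes mimicking propagation-based phase-contrast
edge enhancement.

Known virtual deformations (axial compression as an affine map about the
image center, resampled with Lanczos interpolation) provide analytic
ground-truth displacement and strain fields for the error protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._interp import resample_general, resample_separable
from .volume import CARTILAGE, MINERALIZED, RegionLabelMap, Volume

__all__ = [
    "PhantomSpec",
    "AffineDeformation",
    "generate_phantom",
    "apply_affine_deformation",
    "translate",
    "add_noise",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic cartilage-bone volume.

    Defaults emulate a ~2 µm voxel phase-contrast scan of the interface:
    chondrocyte-lacuna density of order 1.5e4 /mm³ in cartilage and
    osteocyte-lacuna density of 3e4 /mm³ in mineralized tissue, lacuna
    semi-axes of a few µm, and region gray levels separated well above the
    acquisition noise.
    """

    shape: tuple[int, int, int] = (160, 160, 160)
    voxel_size: float = 2.0  # µm
    interface_z_fraction: float = 0.5
    interface_roughness_amp: float = 8.0  # µm, SD of the interface height
    lacunae_density_per_region: tuple[float, float] = (15_000.0, 30_000.0)  # /mm³
    lacunae_radii: tuple[float, float] = (2.5, 7.5)  # µm, semi-axis range
    gray_levels: tuple[float, float, float, float] = (20.0, 90.0, 170.0, 40.0)
    noise_sd: float = 3.0  # gray units
    edge_enhancement_amp: float = 0.0  # gray units; 0 disables fringes
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError("shape must be three dimensions, each >= 1")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not 0.0 < self.interface_z_fraction < 1.0:
            raise ValueError("interface_z_fraction must lie in (0, 1)")
        if self.interface_roughness_amp < 0:
            raise ValueError("interface_roughness_amp must be >= 0")
        if any(d < 0 for d in self.lacunae_density_per_region):
            raise ValueError("lacunae densities must be >= 0")
        if not 0 < self.lacunae_radii[0] <= self.lacunae_radii[1]:
            raise ValueError("lacunae_radii must be an increasing positive range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class AffineDeformation:
    """A linear deformation about a fixed point, x' = M (x - c) + c.

    ``matrix`` is the dimensionless 3x3 linear map (e.g. diag(1, 1, 0.99)
    for 1% axial compression) and ``center`` the fixed point in voxel
    coordinates. The analytic displacement of a material point is
    ``u(x) = (M - I) (x - c)`` and the small-strain tensor is the
    symmetric part of ``M - I``.
    """

    matrix: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("matrix must be 3x3")
        if self.center.shape != (3,):
            raise ValueError("center must have 3 components")

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Ground-truth displacement u(x) = (M - I)(x - center), voxels."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.center) @ (self.matrix - np.eye(3)).T

    def strain_tensor(self) -> np.ndarray:
        """Small-strain tensor (symmetric part of M - I), dimensionless."""
        g = self.matrix - np.eye(3)
        return 0.5 * (g + g.T)

    def inverse(self) -> "AffineDeformation":
        return AffineDeformation(np.linalg.inv(self.matrix), self.center)

    @classmethod
    def axial_compression(cls, strain: float, shape: tuple[int, int, int]) -> "AffineDeformation":
        """Axial (z) compression of nominal strain ``strain`` about the image center."""
        m = np.diag([1.0, 1.0, 1.0 - strain])
        center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
        return cls(m, center)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _carve_lacunae(
    vol: np.ndarray,
    labels: np.ndarray,
    region: int,
    density_per_mm3: float,
    radii_um: tuple[float, float],
    voxel_size: float,
    lacuna_gray: float,
    rng: np.random.Generator,
) -> int:
    """Stamp Poisson-distributed dark ellipsoids into one region; returns the count."""
    region_voxels = int(np.count_nonzero(labels == region))
    if region_voxels == 0 or density_per_mm3 == 0:
        return 0
    region_mm3 = region_voxels * (voxel_size**3) * 1e-9
    n = int(rng.poisson(density_per_mm3 * region_mm3))
    shape = np.asarray(vol.shape)
    for _ in range(n):
        # rejection-sample a center inside the host region
        for _attempt in range(1000):
            c = rng.uniform(0, shape - 1)
            ci = tuple(np.round(c).astype(int))
            if labels[ci] == region:
                break
        else:  # pragma: no cover - pathological geometry
            continue
        semi = rng.uniform(*radii_um, size=3) / voxel_size  # voxels
        rot = _random_rotation(rng)
        r = float(np.max(semi))
        lo = np.maximum(np.floor(c - r).astype(int), 0)
        hi = np.minimum(np.ceil(c + r).astype(int) + 1, shape)
        grids = np.meshgrid(
            *[np.arange(lo[d], hi[d]) for d in range(3)], indexing="ij"
        )
        rel = np.stack([g - c[d] for d, g in enumerate(grids)], axis=-1)
        local = rel @ rot  # body-frame coordinates
        inside = np.sum((local / semi) ** 2, axis=-1) <= 1.0
        box = tuple(slice(lo[d], hi[d]) for d in range(3))
        inside &= labels[box] == region  # lacunae never cross the interface
        vol[box][inside] = lacuna_gray
    return n


def generate_phantom(
    spec: PhantomSpec, return_info: bool = False
) -> tuple[Volume, RegionLabelMap] | tuple[Volume, RegionLabelMap, dict]:
    """Generate a synthetic cartilage-bone volume with known ground truth.

    Returns ``(volume, labels)``; with ``return_info=True`` also a dict
    holding generator bookkeeping (lacunae counts per region, interface
    height map) for test oracles.

    The volume is filled entirely by tissue: articular cartilage (label 1)
    for z below the rough interface, mineralized tissue (label 2) above.
    Identical spec + seed gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = (int(n) for n in spec.shape)
    _, g_cart, g_min, g_lac = spec.gray_levels

    base = spec.interface_z_fraction * nz
    if spec.interface_roughness_amp > 0:
        rough = ndimage.gaussian_filter(
            rng.standard_normal((nx, ny)), sigma=6.0, mode="wrap"
        )
        rough -= rough.mean()
        sd = rough.std()
        if sd > 0:
            rough *= (spec.interface_roughness_amp / spec.voxel_size) / sd
        z_interface = base + rough
    else:
        z_interface = np.full((nx, ny), base)

    zz = np.arange(nz)
    labels = np.where(zz[None, None, :] < z_interface[:, :, None], CARTILAGE, MINERALIZED)
    labels = labels.astype(np.uint8)

    vol = np.where(labels == CARTILAGE, g_cart, g_min).astype(float)

    n_cart = _carve_lacunae(
        vol, labels, CARTILAGE, spec.lacunae_density_per_region[0],
        spec.lacunae_radii, spec.voxel_size, g_lac, rng,
    )
    n_min = _carve_lacunae(
        vol, labels, MINERALIZED, spec.lacunae_density_per_region[1],
        spec.lacunae_radii, spec.voxel_size, g_lac, rng,
    )

    if spec.edge_enhancement_amp > 0:
        # fringe = z-derivative of the blurred label image, scaled to amp
        smooth = ndimage.gaussian_filter(labels.astype(float), sigma=1.5)
        gz = np.gradient(smooth, axis=2)
        peak = np.max(np.abs(gz))
        if peak > 0:
            vol += spec.edge_enhancement_amp * gz / peak

    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=vol.shape)

    volume = Volume(vol.astype(np.float32), spec.voxel_size)
    label_map = RegionLabelMap(labels, spec.voxel_size)
    if return_info:
        info = {
            "n_lacunae": {CARTILAGE: n_cart, MINERALIZED: n_min},
            "interface_z": z_interface,
        }
        return volume, label_map, info
    return volume, label_map


def apply_affine_deformation(
    vol: Volume, d: AffineDeformation, interp: str = "lanczos"
) -> Volume:
    """Resample ``vol`` through the inverse of the affine map ``d``.

    The output voxel at x takes the input value at ``c + M^-1 (x - c)``
    (inverse mapping through voxel centers), so image content moves
    forward by ``u(x) = (M - I)(x - c)``. Voxels mapped from outside the
    input domain are zeroed and flagged in ``Volume.invalid``.
    """
    det = np.linalg.det(d.matrix)
    if abs(det) < 1e-12:
        raise ValueError("deformation matrix is singular")
    minv = np.linalg.inv(d.matrix)
    shape = vol.shape
    off_diag = minv - np.diag(np.diag(minv))
    if np.all(off_diag == 0.0):
        axes = tuple(
            d.center[ax] + (np.arange(shape[ax]) - d.center[ax]) * minv[ax, ax]
            for ax in range(3)
        )
        out, invalid = resample_separable(vol.data, axes, interp=interp)
    else:
        grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
        pts = np.stack(grids, axis=0)
        rel = pts - d.center.reshape(3, 1, 1, 1)
        coords = np.einsum("ij,j...->i...", minv, rel) + d.center.reshape(3, 1, 1, 1)
        out, invalid = resample_general(vol.data, coords, interp=interp)
    return Volume(out, vol.voxel_size, invalid)


def translate(vol: Volume, shift, interp: str = "lanczos") -> Volume:
    """Shift image content by ``shift`` voxels (fractional shifts interpolate).

    Integer shifts reproduce the input exactly in the interior since the
    Lanczos kernel is interpolating (L(0)=1, L(k)=0 at integers).
    """
    shift = np.asarray(shift, dtype=float)
    axes = tuple(np.arange(vol.shape[ax]) - shift[ax] for ax in range(3))
    out, invalid = resample_separable(vol.data, axes, interp=interp)
    return Volume(out, vol.voxel_size, invalid)


def add_noise(vol: Volume, sd: float, seed: int) -> Volume:
    """Add independent zero-mean Gaussian gray-value noise of SD ``sd``."""
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    if sd == 0:
        return vol.copy()
    rng = np.random.default_rng(seed)
    data = vol.data + rng.normal(0.0, sd, size=vol.shape)
    return Volume(data.astype(vol.data.dtype, copy=False), vol.voxel_size, vol.invalid)
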