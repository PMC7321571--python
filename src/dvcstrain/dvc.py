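"""Local-approach digital volume correlation (DVC).

Cubic sub-volumes of the reference image are tracked into the deformed
image by zero-normalized cross-correlation (ZNCC, computed via FFT): for
each grid node the integer displacement is the NCC peak inside a search
window centered on the (interpolated) predictor displacement, seeded to
sub-voxel precision by a separable 3-point Gaussian fit of the correlation
peak and then refined by a translation-only Lucas-Kanade gray-level
optimization against the cubic-spline-interpolated deformed image (the
peak fit alone shows the classic pull-to-integer bias of ~0.05 voxel; the
gray-level stage removes it). A multipass scheme runs a descending
sequence of sub-volume sizes in which each pass's displacement field
seeds the next pass's search windows, preventing peak loss at the small
final size.

Nodes with flat texture, a low correlation coefficient, or a peak on the
search-window border are flagged invalid and excluded from statistics —
never interpolated silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from skimage.feature import match_template

from .volume import RegionLabelMap, Volume

__all__ = [
    "SubvolumeGrid",
    "DisplacementField",
    "build_grid",
    "correlate_pass",
    "run_multipass",
    "mask_by_region",
]

#: Default correlation-coefficient validity threshold.
DEFAULT_CC_MIN = 0.1
#: Search radius (voxels) for refinement passes seeded by a predictor.
REFINE_SEARCH_RADIUS = 4


@dataclass(frozen=True)
class SubvolumeGrid:
    """Regular lattice of cubic interrogation windows inside an image.

    ``starts[d]`` holds the window start index of each node along axis
    ``d``; a node ``(i, j, k)`` covers voxels
    ``[starts[0][i], starts[0][i] + size)`` etc. The layout is symmetric
    about the image center.
    """

    shape: tuple[int, int, int]
    size: int
    overlap: float
    starts: tuple[np.ndarray, np.ndarray, np.ndarray]

    @property
    def n_nodes(self) -> tuple[int, int, int]:
        return tuple(len(s) for s in self.starts)  # type: ignore[return-value]

    @property
    def spacing(self) -> int:
        return max(1, int(round(self.size * (1.0 - self.overlap))))

    @property
    def node_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Node-center coordinates (voxels, possibly half-integer) per axis."""
        half = (self.size - 1) / 2.0
        return tuple(s + half for s in self.starts)  # type: ignore[return-value]

    def node_centers(self) -> np.ndarray:
        """All node centers as an (n, 3) array in C order."""
        ax = self.node_axes
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)


@dataclass
class DisplacementField:
    """Per-node 3D displacement with correlation quality.

    ``u`` has shape ``n_nodes + (3,)`` in voxels, ``cc`` the peak ZNCC
    value in [-1, 1] and ``valid`` flags trustworthy nodes. Invalid nodes
    carry NaN displacement.
    """

    grid: SubvolumeGrid
    u: np.ndarray
    cc: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        expected = self.grid.n_nodes
        if self.u.shape != expected + (3,):
            raise ValueError("u shape does not match grid")
        if self.cc.shape != expected or self.valid.shape != expected:
            raise ValueError("cc/valid shape does not match grid")

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.grid, self.u.copy(), self.cc.copy(), self.valid.copy())


def build_grid(shape: tuple[int, int, int], size: int, overlap: float = 0.0) -> SubvolumeGrid:
    """Lay out a regular sub-volume grid, symmetric about the image center.

    Node spacing is ``round(size * (1 - overlap))`` voxels; per axis the
    grid holds ``floor((dim - size) / spacing) + 1`` nodes.
    """
    size = int(size)
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    if size < 1:
        raise ValueError("sub-volume size must be >= 1")
    if any(size > n for n in shape):
        raise ValueError(f"sub-volume size {size} exceeds image shape {shape}")
    spacing = max(1, int(round(size * (1.0 - overlap))))
    starts = []
    for dim in shape:
        n = (dim - size) // spacing + 1
        start0 = (dim - (size + (n - 1) * spacing)) // 2
        starts.append(start0 + spacing * np.arange(n))
    return SubvolumeGrid(tuple(shape), size, overlap, tuple(starts))


def zncc_map(search: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Zero-normalized cross-correlation of ``template`` over ``search``.

    Output shape is ``search.shape - template.shape + 1``; values lie in
    [-1, 1] up to floating-point error. FFT-based (skimage match_template).
    """
    return match_template(
        np.ascontiguousarray(search, dtype=float),
        np.ascontiguousarray(template, dtype=float),
        pad_input=False,
    )


def _window_sums(a: np.ndarray, tshape: tuple[int, int, int]) -> np.ndarray:
    """Sliding-window box sums of ``a`` over windows of shape ``tshape``."""
    s = a
    for ax in range(3):
        c = np.cumsum(s, axis=ax)
        t = tshape[ax]
        lead = [slice(None)] * 3
        lead[ax] = slice(t - 1, t)
        head = c[tuple(lead)]
        hi = [slice(None)] * 3
        hi[ax] = slice(t, None)
        lo = [slice(None)] * 3
        lo[ax] = slice(None, -t)
        s = np.concatenate([head, c[tuple(hi)] - c[tuple(lo)]], axis=ax)
    return s


def zncc_map_direct(search: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Spatial-domain ZNCC, efficient for small search windows.

    Same output as :func:`zncc_map`; the numerator is a dot product per
    offset and window means/variances come from integral images, so the
    cost scales with (number of offsets) x (template size) — far below
    the FFT path when only a few voxels of search range are needed.
    """
    search = np.ascontiguousarray(search, dtype=float)
    template = np.asarray(template, dtype=float)
    t = template - template.mean()
    t_norm = np.sqrt(np.sum(t * t))
    n = template.size
    s1 = _window_sums(search, template.shape)
    s2 = _window_sums(search * search, template.shape)
    var = np.maximum(s2 - s1 * s1 / n, 0.0)
    tf = t.ravel()
    a, b, c = template.shape
    num = np.empty(s1.shape)
    for i in range(s1.shape[0]):
        for j in range(s1.shape[1]):
            for k in range(s1.shape[2]):
                num[i, j, k] = np.dot(
                    search[i : i + a, j : j + b, k : k + c].ravel(), tf
                )
    denom = t_norm * np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.where(denom > 1e-12 * max(t_norm, 1.0), num / denom, 0.0)
    return cc


def _subvoxel_offset(c_minus: float, c0: float, c_plus: float) -> float:
    """3-point peak interpolation along one axis.

    Gaussian (log-parabola) fit when all three samples are positive, plain
    parabola otherwise; a peak at the perfect-match ceiling (cc = 1 to
    machine precision) is taken as exactly on-node, since the log of
    floating-point noise ratios carries no information there.
    """
    if c0 >= 1.0 - 1e-9:
        return 0.0
    if c_minus > 0 and c_plus > 0 and c0 > 0:
        num = np.log(c_minus) - np.log(c_plus)
        den = 2.0 * (np.log(c_minus) + np.log(c_plus) - 2.0 * np.log(c0))
    else:
        num = c_minus - c_plus
        den = 2.0 * (c_minus + c_plus - 2.0 * c0)
    if den == 0.0 or not np.isfinite(den):
        return 0.0
    delta = num / den
    return float(np.clip(delta, -0.5, 0.5))


def _zncc(a: np.ndarray, b: np.ndarray) -> float:
    """Plain ZNCC of two equally sized arrays."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if denom == 0:
        return 0.0
    return float(np.sum(a * b) / denom)


def _lk_refine(
    tpl: np.ndarray,
    coef: np.ndarray,
    start: np.ndarray,
    u0: np.ndarray,
    max_iter: int = 10,
    tol: float = 1e-3,
) -> tuple[np.ndarray, float]:
    """Translation-only Lucas-Kanade refinement of one node.

    ``coef`` is the spline-prefiltered deformed volume; the template
    window of the reference is matched against the cubic-interpolated
    deformed image starting from ``u0``. The template gradient serves as
    the (constant) Jacobian. Photometric gain/offset are normalized each
    iteration so the residual is contrast-invariant. Returns the refined
    displacement and the final ZNCC; falls back to ``u0`` if the update
    diverges by more than 1.5 voxels.
    """
    size = tpl.shape[0]
    grads = np.gradient(tpl)
    jac = np.stack([g.ravel() for g in grads], axis=1)  # (n, 3)
    h = jac.T @ jac
    try:
        hinv = np.linalg.inv(h)
    except np.linalg.LinAlgError:
        return u0, np.nan
    mesh = np.mgrid[0:size, 0:size, 0:size].astype(float)
    mesh += start.reshape(3, 1, 1, 1)
    t_mean, t_std = tpl.mean(), tpl.std()
    u = u0.astype(float).copy()
    sample = None
    for _ in range(max_iter):
        coords = mesh + u.reshape(3, 1, 1, 1)
        sample = ndimage.map_coordinates(
            coef, coords, order=3, prefilter=False, mode="mirror"
        )
        s_std = sample.std()
        if s_std == 0:
            return u0, np.nan
        norm = (sample - sample.mean()) * (t_std / s_std) + t_mean
        r = (norm - tpl).ravel()
        delta = -hinv @ (jac.T @ r)
        u += delta
        if not np.all(np.isfinite(u)) or np.linalg.norm(u - u0) > 1.5:
            return u0, np.nan
        if np.linalg.norm(delta) < tol:
            break
    cc = _zncc(tpl, sample) if sample is not None else np.nan
    return u, cc


def _interp_predictor(predictor: DisplacementField, centers: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a (coarser) field onto new node centers."""
    grid_axes = predictor.grid.node_axes
    u = predictor.u.copy()
    if predictor.n_valid == 0:
        return np.zeros((len(centers), 3))
    # fill invalid nodes with the mean of valid ones so interpolation stays finite
    fill = np.nanmean(np.where(predictor.valid[..., None], u, np.nan), axis=(0, 1, 2))
    u[~predictor.valid] = fill
    pts = centers.copy()
    for d in range(3):  # clamp: nearest-edge extrapolation
        pts[:, d] = np.clip(pts[:, d], grid_axes[d][0], grid_axes[d][-1])
    out = np.empty((len(centers), 3))
    for comp in range(3):
        itp = RegularGridInterpolator(grid_axes, u[..., comp], method="linear")
        out[:, comp] = itp(pts)
    return out


def correlate_pass(
    reference: Volume,
    deformed: Volume,
    grid: SubvolumeGrid,
    predictor: DisplacementField | None = None,
    search_radius: int | None = None,
    cc_min: float = DEFAULT_CC_MIN,
    subvoxel: str = "lk",
    base_shift: np.ndarray | None = None,
) -> DisplacementField:
    """Track every grid node from ``reference`` into ``deformed``.

    ``search_radius`` defaults to half the sub-volume size without a
    predictor and to ±4 voxels when seeded by one; ``base_shift`` (used
    only without a predictor) centers every search window on a known
    global displacement. ``subvoxel`` selects
    the refinement: ``"lk"`` (Gaussian peak fit seeding a gray-level
    Lucas-Kanade optimization; default), ``"gaussian"`` (peak fit only)
    or ``"none"``. Nodes whose template is texture-free, whose NCC peak
    lands on the search-window border, whose correlation coefficient
    falls below ``cc_min``, or whose reference window / deformed search
    range touches flagged (out-of-domain) voxels are marked invalid.
    """
    if subvoxel not in ("lk", "gaussian", "none"):
        raise ValueError(f"unknown subvoxel mode {subvoxel!r}")
    if reference.shape != deformed.shape:
        raise ValueError("reference and deformed volumes must share a shape")
    ref = np.asarray(reference.data, dtype=float)
    dfm = np.asarray(deformed.data, dtype=float)
    size = grid.size
    if search_radius is None:
        search_radius = size // 2 if predictor is None else REFINE_SEARCH_RADIUS
    search_radius = max(1, int(search_radius))

    nn = grid.n_nodes
    u = np.full(nn + (3,), np.nan)
    cc = np.full(nn, np.nan)
    valid = np.zeros(nn, dtype=bool)

    centers = grid.node_centers()
    if predictor is not None:
        pred = np.round(_interp_predictor(predictor, centers)).astype(int)
    elif base_shift is not None:
        pred = np.tile(np.round(base_shift).astype(int), (len(centers), 1))
    else:
        pred = np.zeros((len(centers), 3), dtype=int)

    shape = np.asarray(reference.shape)
    ref_bad = reference.invalid
    dfm_bad = deformed.invalid
    coef = ndimage.spline_filter(dfm, order=3, mode="mirror") if subvoxel == "lk" else None

    flat_index = 0
    for i, sx in enumerate(grid.starts[0]):
        for j, sy in enumerate(grid.starts[1]):
            for k, sz in enumerate(grid.starts[2]):
                p = pred[flat_index]
                flat_index += 1
                start = np.array([sx, sy, sz])
                tpl = ref[sx : sx + size, sy : sy + size, sz : sz + size]
                if ref_bad is not None and ref_bad[
                    sx : sx + size, sy : sy + size, sz : sz + size
                ].any():
                    continue
                if tpl.std() == 0.0:
                    continue  # flat region: no trackable texture
                lo = np.maximum(start + p - search_radius, 0)
                hi = np.minimum(start + p + size + search_radius, shape)
                if np.any(hi - lo < size + 2):  # need at least one free voxel around
                    continue
                if dfm_bad is not None and dfm_bad[
                    lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]
                ].any():
                    # out-of-domain voxels inside the search range can block
                    # or distort the true peak: the node cannot be trusted
                    continue
                region = dfm[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
                n_offsets = int(np.prod(np.asarray(region.shape) - size + 1))
                # spatial path: cost ~ offsets x template; FFT: ~ padded volume
                if n_offsets <= 1331 or n_offsets * tpl.size <= 2e8:
                    ccmap = zncc_map_direct(region, tpl)
                else:
                    ccmap = zncc_map(region, tpl)
                ccmap = np.nan_to_num(ccmap, nan=-1.0)
                peak = np.unravel_index(int(np.argmax(ccmap)), ccmap.shape)
                c_top = float(ccmap[peak])
                ties = np.argwhere(ccmap >= c_top - 1e-12)
                if len(ties) > 1:
                    # translation-degenerate texture: prefer the smallest
                    # displacement magnitude, then lexicographic order
                    disps = ties + lo - start
                    mags = np.sum(disps * disps, axis=1)
                    order = np.lexsort((ties[:, 2], ties[:, 1], ties[:, 0], mags))
                    peak = tuple(int(v) for v in ties[order[0]])
                # a peak on the search-window border is untrustworthy (the true
                # peak may lie beyond) unless that border coincides with the
                # image boundary, where no further search is physically possible
                on_border = False
                missing_neighbor = [False, False, False]
                for d, pk in enumerate(peak):
                    if pk == 0:
                        if lo[d] > 0:
                            on_border = True
                        missing_neighbor[d] = True
                    if pk == ccmap.shape[d] - 1:
                        if lo[d] + ccmap.shape[d] - 1 + size < shape[d]:
                            on_border = True
                        missing_neighbor[d] = True
                if on_border:
                    continue
                c0 = float(ccmap[peak])
                if c0 < cc_min:
                    continue
                disp = np.asarray(peak) + lo - start
                frac = np.zeros(3)
                if subvoxel != "none":
                    for d in range(3):
                        if missing_neighbor[d]:
                            continue  # image-boundary peak: no 3-point stencil
                        m = list(peak)
                        m[d] -= 1
                        pl = list(peak)
                        pl[d] += 1
                        frac[d] = _subvoxel_offset(
                            float(ccmap[tuple(m)]), c0, float(ccmap[tuple(pl)])
                        )
                node_u = disp + frac
                node_cc = min(c0, 1.0)
                # a perfect match (cc = 1 to machine precision) is already exact;
                # anything else gets the gray-level refinement
                if coef is not None and c0 < 1.0 - 1e-9:
                    refined, cc_lk = _lk_refine(tpl, coef, start.astype(float), node_u)
                    if np.isfinite(cc_lk) and cc_lk >= node_cc - 0.05:
                        node_u, node_cc = refined, min(cc_lk, 1.0)
                u[i, j, k] = node_u
                cc[i, j, k] = node_cc
                valid[i, j, k] = True
    return DisplacementField(grid, u, cc, valid)


def run_multipass(
    reference: Volume,
    deformed: Volume,
    sizes: list[int] | tuple[int, ...],
    final_overlap: float = 0.0,
    cc_min: float = DEFAULT_CC_MIN,
    coarse_search_radius: int | None = None,
) -> DisplacementField:
    """Multipass DVC over a strictly descending list of sub-volume sizes.

    The coarsest pass is seeded by a single full-volume FFT phase
    correlation (the global integer shift) and searches
    ``coarse_search_radius`` voxels around it (default: an eighth of the
    coarsest sub-volume, at least the refinement radius); each subsequent
    pass's field, trilinearly interpolated onto the next grid, seeds the
    next pass's search windows. The field at the final (smallest) size is
    returned. Predictor passes use zero overlap; the final pass uses
    ``final_overlap``.
    """
    sizes = [int(s) for s in sizes]
    if not sizes:
        raise ValueError("sizes must be a non-empty descending list")
    if any(b >= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly descending")
    from skimage.registration import phase_cross_correlation

    # global rigid-shift seed: tracking ref into dfm means u = -shift(dfm->ref)
    shift, _, _ = phase_cross_correlation(
        np.asarray(reference.data, dtype=float),
        np.asarray(deformed.data, dtype=float),
        upsample_factor=1,
    )
    base = -np.asarray(shift, dtype=float)
    if coarse_search_radius is None:
        coarse_search_radius = max(REFINE_SEARCH_RADIUS, sizes[0] // 8)
    field: DisplacementField | None = None
    for idx, size in enumerate(sizes):
        overlap = final_overlap if idx == len(sizes) - 1 else 0.0
        grid = build_grid(reference.shape, size, overlap)
        field = correlate_pass(
            reference,
            deformed,
            grid,
            predictor=field,
            search_radius=coarse_search_radius if field is None else None,
            cc_min=cc_min,
            base_shift=base if field is None else None,
        )
    assert field is not None
    return field


def mask_by_region(
    field: DisplacementField, labels: RegionLabelMap, region: int, margin: int = 0
) -> DisplacementField:
    """Keep only nodes whose whole sub-volume lies inside one tissue region.

    Nodes straddling a region boundary are invalidated (strict-inclusion
    rule), so interface windows contribute to neither region. A positive
    ``margin`` additionally requires every window voxel to sit at least
    that many voxels away from other regions — a buffer against the
    border effect of windows whose edge plane abuts the strong interface
    gradient.
    """
    if labels.shape != field.grid.shape:
        raise ValueError("label map shape does not match the field's image shape")
    if region not in (0, 1, 2):
        raise ValueError(f"unknown region label {region}")
    mask = labels.labels == region
    if margin > 0:
        # border_value=1: the volume boundary itself is not a region boundary
        mask = ndimage.binary_erosion(mask, iterations=int(margin), border_value=1)
    out = field.copy()
    size = field.grid.size
    for i, sx in enumerate(field.grid.starts[0]):
        for j, sy in enumerate(field.grid.starts[1]):
            for k, sz in enumerate(field.grid.starts[2]):
                if not out.valid[i, j, k]:
                    continue
                window = mask[sx : sx + size, sy : sy + size, sz : sz + size]
                if not np.all(window):
                    out.valid[i, j, k] = False
                    out.u[i, j, k] = np.nan
                    out.cc[i, j, k] = np.nan
    return out
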