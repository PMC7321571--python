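"""Flat-punch micro-indentation and unconfined-compression metrics.

Load-controlled flat-punch indentation of the articular cartilage surface
yields load-displacement curves P(h); from these the module extracts the
contact stiffness S = dP/dh as the linear slope over the initial stage of
the unloading branch, and hardness as maximum force over the (nominal
flat-punch) contact area. Replicate indentations grouped by surface
location are summarized as per-condition mean ± SD. Unconfined-compression
force-displacement records of cylindrical osteochondral plugs are
converted into nominal stress-strain curves with the stress-relaxation
drop during the displacement hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IndentationCurve",
    "IndentationMetrics",
    "CompressionTestRecord",
    "segment_phases",
    "contact_stiffness",
    "hardness",
    "summarize_locations",
    "compression_stress_strain",
    "synthesize_indentation_curve",
]

#: Nominal flat-punch contact area: 50 µm x 50 µm tip base.
DEFAULT_TIP_AREA_UM2 = 2500.0


@dataclass
class IndentationCurve:
    """One indentation load-displacement record with phase labels.

    ``phase`` holds per-sample strings in {"loading", "hold",
    "unloading"}; ``load`` is in mN and ``depth`` in µm.
    """

    time: np.ndarray
    load: np.ndarray
    depth: np.ndarray
    phase: np.ndarray
    location_id: int | str | None = None
    replicate_id: int | str | None = None

    def samples(self, phase: str) -> np.ndarray:
        return np.flatnonzero(self.phase == phase)


@dataclass
class IndentationMetrics:
    """Contact stiffness (mN/µm) and hardness (MPa) of one indentation."""

    stiffness: float
    hardness: float
    tip_area: float = DEFAULT_TIP_AREA_UM2
    location_id: int | str | None = None
    replicate_id: int | str | None = None


@dataclass
class CompressionTestRecord:
    """Unconfined-compression record of a cylindrical plug.

    ``force`` in N, ``displacement`` in mm, geometry in mm.
    """

    time: np.ndarray
    force: np.ndarray
    displacement: np.ndarray
    specimen_diameter: float
    cartilage_thickness: float

    def __post_init__(self) -> None:
        if self.specimen_diameter <= 0 or self.cartilage_thickness <= 0:
            raise ValueError("specimen geometry must be positive")


def segment_phases(
    time, load, depth, hold_tolerance: float = 0.01,
    location_id=None, replicate_id=None,
) -> IndentationCurve:
    """Split a raw record into loading / hold / unloading phases.

    The hold is the contiguous run of samples around the load maximum that
    stay within ``hold_tolerance`` (fraction of max load) of it; a run
    shorter than 2 samples (a triangle-wave apex) counts as no hold.
    Everything before is loading, everything after unloading.
    """
    time = np.asarray(time, dtype=float)
    load = np.asarray(load, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if time.size < 3:
        raise ValueError("need at least 3 samples")
    if np.any(np.diff(time) <= 0):
        raise ValueError("time must be strictly increasing")
    pmax = load.max()
    imax = int(np.argmax(load))
    near = load >= (1.0 - hold_tolerance) * pmax
    lo = imax
    while lo > 0 and near[lo - 1]:
        lo -= 1
    hi = imax
    while hi < len(load) - 1 and near[hi + 1]:
        hi += 1
    phase = np.empty(len(load), dtype=object)
    if hi - lo + 1 >= 2:
        phase[:lo] = "loading"
        phase[lo : hi + 1] = "hold"
        phase[hi + 1 :] = "unloading"
    else:
        phase[: imax + 1] = "loading"
        phase[imax + 1 :] = "unloading"
    return IndentationCurve(time, load, depth, phase.astype("U9"),
                            location_id, replicate_id)


def contact_stiffness(curve: IndentationCurve, fit_fraction: float = 0.2) -> float:
    """S = dP/dh (mN/µm) from the initial stage of the unloading branch.

    Least-squares slope of P vs h over the top ``fit_fraction`` of the
    unloading load range (default: top 20%).
    """
    if not 0.0 < fit_fraction <= 1.0:
        raise ValueError("fit_fraction must lie in (0, 1]")
    idx = curve.samples("unloading")
    if idx.size == 0:
        raise ValueError("curve has no unloading phase")
    p = curve.load[idx]
    h = curve.depth[idx]
    p_hi, p_lo = p.max(), p.min()
    window = p >= p_hi - fit_fraction * (p_hi - p_lo)
    if np.count_nonzero(window) < 2:
        raise ValueError("fewer than 2 unloading samples in the fit window")
    slope = np.polyfit(h[window], p[window], 1)[0]
    return float(slope)


def hardness(curve: IndentationCurve, tip_area: float = DEFAULT_TIP_AREA_UM2) -> float:
    """Hardness (MPa) = max load / contact area for a flat punch.

    ``tip_area`` is in µm²; 1 mN/µm² = 1000 MPa.
    """
    if tip_area <= 0:
        raise ValueError("tip_area must be positive")
    return float(curve.load.max() / tip_area * 1000.0)


def summarize_locations(metrics: list[IndentationMetrics]) -> pd.DataFrame:
    """Replicate means per location, then condition mean ± SD across locations.

    Returns a one-row DataFrame per quantity with columns ``mean``, ``sd``
    (ddof=1 across locations; 0 for a single location) and ``n_locations``.
    """
    if not metrics:
        raise ValueError("no metrics to summarize")
    df = pd.DataFrame(
        {
            "location": [m.location_id for m in metrics],
            "stiffness": [m.stiffness for m in metrics],
            "hardness": [m.hardness for m in metrics],
        }
    )
    per_loc = df.groupby("location", dropna=False).mean()
    out = {}
    for col in ("stiffness", "hardness"):
        vals = per_loc[col].to_numpy()
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out[col] = {"mean": float(np.mean(vals)), "sd": sd, "n_locations": len(vals)}
    return pd.DataFrame(out).T


def compression_stress_strain(record: CompressionTestRecord, hold_tolerance: float = 0.01):
    """Nominal stress-strain curves plus peak stress and relaxation drop.

    stress (MPa) = force / (pi d^2 / 4); strain = displacement /
    cartilage thickness. The relaxation drop is the stress at the start of
    the displacement hold minus the stress at its end (0 when no hold is
    present). Returns a dict with ``stress``, ``strain``, ``max_stress``
    and ``relaxation``.
    """
    force = np.asarray(record.force, dtype=float)
    disp = np.asarray(record.displacement, dtype=float)
    area = np.pi * record.specimen_diameter**2 / 4.0  # mm^2; N/mm^2 = MPa
    stress = force / area
    strain = disp / record.cartilage_thickness
    dmax = disp.max()
    hold = disp >= dmax - hold_tolerance * max(dmax, 1e-12)
    hold_idx = np.flatnonzero(hold)
    if hold_idx.size >= 2:
        relaxation = float(stress[hold_idx[0]] - stress[hold_idx[-1]])
    else:
        relaxation = 0.0
    return {
        "stress": stress,
        "strain": strain,
        "max_stress": float(stress.max()),
        "relaxation": relaxation,
    }


def synthesize_indentation_curve(
    p_max: float = 45.0,
    stiffness: float = 2.0,
    n_load: int = 50,
    n_hold: int = 20,
    n_unload: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
    location_id=None,
    replicate_id=None,
):
    """Synthetic trapezoidal load-controlled indentation record.

    Load ramps linearly to ``p_max`` (mN), holds, then unloads; depth
    follows h = P / stiffness (µm) with optional Gaussian depth noise.
    Returns raw ``(time, load, depth)`` arrays; pass them through
    :func:`segment_phases`. ``n_hold = 0`` produces a triangle wave.
    """
    rng = np.random.default_rng(seed)
    if n_hold > 0:
        ramp = np.linspace(0.0, p_max, n_load, endpoint=False)
        plateau = np.full(n_hold, p_max)
    else:  # triangle wave: single apex sample, no plateau
        ramp = np.linspace(0.0, p_max, n_load)
        plateau = np.empty(0)
    unload = np.linspace(p_max, 0.0, n_unload + 1)[1:]
    load = np.concatenate([ramp, plateau, unload])
    time = np.arange(len(load), dtype=float)
    depth = load / stiffness
    if noise_sd > 0:
        depth = depth + rng.normal(0.0, noise_sd, size=depth.shape)
    return time, load, depth
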