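"""File formats: TIFF volumes with sidecar metadata, CSV/JSON/VTK export,
plain-text transforms and pipeline configuration.

Volumes travel as multi-page TIFF stacks (pages along the first axis) next
to a ``<name>.meta`` sidecar of ``key=value`` lines carrying at minimum
the voxel size in µm; integer data round-trips bit-identically. Field and
strain exports are CSV (one row per grid node) and legacy ASCII VTK
rectilinear grids for 3D rendering; every artifact embeds the pipeline
configuration hash so reruns are traceable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .dvc import DisplacementField
from .preprocess import RigidTransform
from .strain import COMPONENTS, StrainTensorField
from .volume import RegionLabelMap, Volume

__all__ = [
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "save_transform",
    "load_transform",
    "field_to_dataframe",
    "field_to_csv",
    "strain_to_dataframe",
    "strain_to_csv",
    "write_vtk_rectilinear",
    "PipelineConfig",
]


def _write_sidecar(path: Path, meta: dict) -> None:
    lines = [f"{k}={v}" for k, v in meta.items()]
    path.write_text("\n".join(lines) + "\n")


def _read_sidecar(path: Path) -> dict:
    meta = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, _, v = line.partition("=")
        meta[k.strip()] = v.strip()
    return meta


def write_volume(vol: Volume, path, **extra_meta) -> None:
    """Write a volume as a multi-page TIFF plus a ``.meta`` sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(vol.data))
    meta = {
        "voxel_size_um": repr(float(vol.voxel_size)),
        "dtype": str(vol.data.dtype),
        "shape": ",".join(str(n) for n in vol.shape),
    }
    meta.update({k: str(v) for k, v in extra_meta.items()})
    _write_sidecar(path.with_suffix(path.suffix + ".meta"), meta)


def read_volume(path) -> Volume:
    """Read a TIFF-stack volume; the sidecar must name the voxel size."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".meta")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {sidecar}")
    meta = _read_sidecar(sidecar)
    if "voxel_size_um" not in meta:
        raise KeyError(f"sidecar {sidecar} is missing required key 'voxel_size_um'")
    data = tifffile.imread(path)
    return Volume(np.asarray(data), float(meta["voxel_size_um"]))


def write_labels(labels: RegionLabelMap, path) -> None:
    """Write a region label map as an 8-bit TIFF with sidecar."""
    vol = Volume(labels.labels.astype(np.uint8), labels.voxel_size)
    write_volume(vol, path, content="region_labels")


def read_labels(path) -> RegionLabelMap:
    vol = read_volume(path)
    return RegionLabelMap(vol.data.astype(np.uint8), vol.voxel_size)


def save_transform(t: RigidTransform, path) -> None:
    meta = {
        "rotation_rad": ",".join(repr(float(v)) for v in t.rotation),
        "translation_vox": ",".join(repr(float(v)) for v in t.translation),
    }
    _write_sidecar(Path(path), meta)


def load_transform(path) -> RigidTransform:
    meta = _read_sidecar(Path(path))
    rot = np.array([float(v) for v in meta["rotation_rad"].split(",")])
    tr = np.array([float(v) for v in meta["translation_vox"].split(",")])
    return RigidTransform(rot, tr)


def field_to_dataframe(field: DisplacementField, voxel_size: float = 1.0) -> pd.DataFrame:
    """Displacement field as rows (x, y, z, ux, uy, uz, cc, valid), voxels."""
    centers = field.grid.node_centers()
    u = field.u.reshape(-1, 3)
    return pd.DataFrame(
        {
            "x": centers[:, 0],
            "y": centers[:, 1],
            "z": centers[:, 2],
            "ux": u[:, 0],
            "uy": u[:, 1],
            "uz": u[:, 2],
            "ux_um": u[:, 0] * voxel_size,
            "uy_um": u[:, 1] * voxel_size,
            "uz_um": u[:, 2] * voxel_size,
            "cc": field.cc.ravel(),
            "valid": field.valid.ravel().astype(int),
        }
    )


def _to_csv_with_hash(df: pd.DataFrame, path, config_hash: str | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def field_to_csv(field, path, voxel_size: float = 1.0, config_hash: str | None = None) -> None:
    _to_csv_with_hash(field_to_dataframe(field, voxel_size), path, config_hash)


def strain_to_dataframe(strain: StrainTensorField) -> pd.DataFrame:
    """Strain field as rows: node coords, six components, eps_eq (µε)."""
    centers = strain.grid.node_centers()
    df = pd.DataFrame({"x": centers[:, 0], "y": centers[:, 1], "z": centers[:, 2]})
    for c, name in enumerate(COMPONENTS):
        df[name] = strain.eps[..., c].ravel()
    df["eeq"] = strain.equivalent().ravel()
    df["valid"] = strain.valid.ravel().astype(int)
    return df


def strain_to_csv(strain, path, config_hash: str | None = None) -> None:
    _to_csv_with_hash(strain_to_dataframe(strain), path, config_hash)


def write_vtk_rectilinear(path, axes, point_data: dict, comment: str = "dvcstrain") -> None:
    """Write node-centered arrays as a legacy ASCII VTK rectilinear grid.

    ``axes`` are the three node-coordinate vectors; ``point_data`` maps
    array names to values of shape (nx, ny, nz) or (nx, ny, nz, 3). VTK
    expects x varying fastest, so arrays are emitted in Fortran order.
    """
    axes = [np.asarray(a, dtype=float) for a in axes]
    nx, ny, nz = (len(a) for a in axes)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(comment.replace("\n", " ") + "\n")
        fh.write("ASCII\nDATASET RECTILINEAR_GRID\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        for name, ax in zip(("X", "Y", "Z"), axes):
            fh.write(f"{name}_COORDINATES {len(ax)} float\n")
            fh.write(" ".join(f"{v:.6g}" for v in ax) + "\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            arr = np.nan_to_num(arr, nan=0.0)
            if arr.ndim == 3:
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                flat = arr.ravel(order="F")
                fh.write("\n".join(f"{v:.6g}" for v in flat) + "\n")
            elif arr.ndim == 4 and arr.shape[-1] == 3:
                fh.write(f"VECTORS {name} float\n")
                flat = np.stack(
                    [arr[..., c].ravel(order="F") for c in range(3)], axis=1
                )
                for row in flat:
                    fh.write(f"{row[0]:.6g} {row[1]:.6g} {row[2]:.6g}\n")
            else:
                raise ValueError(f"unsupported array shape for {name}: {arr.shape}")


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings, round-trippable as key=value text."""

    mode: str = "zero"  # "zero" or "synthetic"
    reference_path: str = ""  # empty: generate a phantom instead
    moving_path: str = ""
    labels_path: str = ""
    phantom_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 2.0
    phantom_seed: int = 0
    noise_sd: float = 3.0
    strain_level: float = 0.01
    multipass_sizes: tuple[int, ...] = (80, 72, 64, 56, 48)
    final_overlap: float = 0.0
    cc_min: float = 0.1
    sweep_sizes: tuple[int, ...] = (16, 32, 48, 64, 80)
    sweep_overlap: float = 0.5
    hist_bin_width: float = 100.0
    denoise_iterations: int = 0
    denoise_kappa: float = 30.0

    _TUPLE_INT = ("phantom_shape", "multipass_sizes", "sweep_sizes")

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            if f.name.startswith("_"):
                continue
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name}={v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        raw = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            raw[k.strip()] = v.strip()
        kwargs = {}
        for f in fields(cls):
            if f.name.startswith("_") or f.name not in raw:
                continue
            v = raw[f.name]
            if f.name in cls._TUPLE_INT:
                kwargs[f.name] = tuple(int(x) for x in v.split(",") if x)
            elif f.type in ("int",):
                kwargs[f.name] = int(v)
            elif f.type in ("float",):
                kwargs[f.name] = float(v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_text(Path(path).read_text())

    def hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]
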