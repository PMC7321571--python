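"""Core in-memory container for 3D grayscale volumes.

A :class:`Volume` is the unit every stage of the pipeline consumes and
produces: a 3D isotropic grayscale array together with its voxel size in
micrometres and an optional boolean mask of voxels whose values are not
trustworthy (e.g. sampled from outside the image domain during a virtual
deformation).

Axis convention: arrays are indexed ``(x, y, z)`` with 0-based voxel
indices; ``z`` (the third axis) is the compression axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["Volume", "RegionLabelMap", "BACKGROUND", "CARTILAGE", "MINERALIZED"]

#: Region label values used throughout the package.
BACKGROUND = 0  # background / bone marrow (zeroed before correlation)
CARTILAGE = 1  # articular cartilage
MINERALIZED = 2  # mineralized tissue (calcified cartilage + subchondral bone)


@dataclass
class Volume:
    """A 3D grayscale image with voxel-size metadata.

    Parameters
    ----------
    data:
        3D array of gray values. Any real dtype is accepted; float64 is
        used internally by most operations.
    voxel_size:
        Isotropic voxel edge length in µm.
    invalid:
        Optional boolean array of the same shape flagging voxels whose
        gray value is undefined (out-of-domain after resampling). ``None``
        means every voxel is valid.
    """

    data: np.ndarray
    voxel_size: float = 1.0
    invalid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got {self.data.ndim}D")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.invalid is not None:
            self.invalid = np.asarray(self.invalid, dtype=bool)
            if self.invalid.shape != self.data.shape:
                raise ValueError("invalid mask shape must match data shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def center(self) -> np.ndarray:
        """Geometric center of the voxel-center lattice, ``(n - 1) / 2``."""
        return (np.asarray(self.shape, dtype=float) - 1.0) / 2.0

    def astype(self, dtype) -> "Volume":
        return replace(self, data=self.data.astype(dtype))

    def copy(self) -> "Volume":
        return Volume(
            self.data.copy(),
            self.voxel_size,
            None if self.invalid is None else self.invalid.copy(),
        )


@dataclass
class RegionLabelMap:
    """Voxelwise tissue labels for a :class:`Volume`.

    Values are restricted to {0: background/marrow, 1: articular
    cartilage, 2: mineralized tissue}.
    """

    labels: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        bad = np.setdiff1d(np.unique(self.labels), [BACKGROUND, CARTILAGE, MINERALIZED])
        if bad.size:
            raise ValueError(f"labels contain values outside {{0,1,2}}: {bad}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def region_mask(self, region: int) -> np.ndarray:
        if region not in (BACKGROUND, CARTILAGE, MINERALIZED):
            raise ValueError(f"unknown region label {region}")
        return self.labels == region
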