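"""Shared spatial containers for the voxel-wise analysis.

Every per-subject image in a cohort lives on one :class:`VolumeGrid` (same
shape, same voxel size, same analysis mask), so downstream stages can stack
subjects into ``(n_subjects, n_voxels)`` matrices without resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed modality order used throughout: three resting-state functional
#: measures and one structural measure.
MODALITIES = ("falff", "lcor", "gcor", "gmv")


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel grid shared by all volumes of a cohort.

    Parameters
    ----------
    shape
        Grid dimensions in voxels, e.g. ``(24, 24, 24)``.
    voxel_size
        Edge length of a voxel per axis, in millimetres.
    mask
        Boolean analysis mask; statistics are computed only inside it.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != tuple(self.shape):
            raise ValueError(
                f"mask shape {mask.shape} does not match grid shape {self.shape}"
            )
        if not mask.any():
            raise ValueError("analysis mask is empty")
        object.__setattr__(self, "mask", mask)

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels."""
        return int(self.mask.sum())

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.voxel_size)) / 1000.0

    @property
    def affine(self) -> np.ndarray:
        """Diagonal voxel-to-mm affine (no rotation, origin at voxel 0)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff

    def flatten(self, volume: np.ndarray) -> np.ndarray:
        """Extract the in-mask voxels of a 3D volume as a 1D vector."""
        volume = np.asarray(volume)
        if volume.shape != tuple(self.shape):
            raise ValueError("volume does not match grid shape")
        return volume[self.mask]

    def unflatten(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place a 1D in-mask vector back into a full 3D volume."""
        values = np.asarray(values)
        if values.shape != (self.n_voxels,):
            raise ValueError("vector length does not match mask size")
        out = np.full(self.shape, fill, dtype=float)
        out[self.mask] = values
        return out

    @classmethod
    def full(
        cls,
        shape: tuple[int, int, int],
        voxel_size: tuple[float, float, float] = (4.0, 4.0, 4.0),
    ) -> "VolumeGrid":
        """Grid whose analysis mask covers every voxel."""
        return cls(tuple(shape), tuple(voxel_size), np.ones(shape, dtype=bool))


@dataclass(frozen=True)
class BandSpec:
    """A frequency band in Hz, e.g. the 0.008-0.09 Hz low-frequency band."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"need 0 < low < high, got [{self.low}, {self.high}]")

    def validate_nyquist(self, tr: float) -> None:
        nyq = 0.5 / tr
        if self.high >= nyq:
            raise ValueError(
                f"band edge {self.high} Hz is at or above Nyquist {nyq:.4f} Hz "
                f"for TR {tr} s"
            )


#: Default low-frequency fluctuation band (Hz).
DEFAULT_BAND = BandSpec(0.008, 0.09)


@dataclass
class MeasureMap:
    """Per-subject 3D scalar field for one modality on a shared grid."""

    modality: str
    subject_id: str
    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError("values do not match grid shape")

    def masked(self) -> np.ndarray:
        """In-mask values as a flat vector."""
        return self.grid.flatten(self.values)
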