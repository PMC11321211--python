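"""Shared domain types for HU-valued respiratory-phase image volumes.

Conventions used throughout the package:

* intensities are Hounsfield units, clipped to the 12-bit CT range
  [-1000, 3095] (a dynamic range of 4095);
* a breathing cycle is divided into ``n_phases`` phases (default 10,
  0%..90%), phase 0 being end-inspiration;
* images are row-major with 0-based indices and pixel-centre coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

HU_MIN = -1000.0
HU_MAX = 3095.0
#: dynamic range of the pixel values (HU_MAX - HU_MIN)
HU_RANGE = HU_MAX - HU_MIN

MODALITIES = ("CT", "CBCT", "sCT", "sCBCT")


def clip_hu(values: np.ndarray) -> np.ndarray:
    return np.clip(values, HU_MIN, HU_MAX)


@dataclass
class PhaseVolume:
    """A single respiratory phase's image grid in HU.

    ``voxels`` is 2-D (a slice) or 3-D (slices, rows, cols); ``spacing`` is
    mm per axis, matching the voxel dimensionality.
    """

    voxels: np.ndarray
    phase: int
    spacing: tuple
    modality: str = "CT"
    n_phases: int = 10
    subject_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim not in (2, 3):
            raise ValueError("voxels must be 2-D or 3-D")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if not (0 <= self.phase < self.n_phases):
            raise ValueError(f"phase {self.phase} outside [0, {self.n_phases})")
        self.spacing = tuple(float(s) for s in np.atleast_1d(self.spacing))
        if len(self.spacing) == 1:
            self.spacing = self.spacing * self.voxels.ndim
        if len(self.spacing) != self.voxels.ndim:
            raise ValueError("spacing length must match voxel dimensionality")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacings must be positive")
        self.voxels = clip_hu(self.voxels).astype(np.float32)

    @property
    def shape(self):
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray, modality: str | None = None) -> "PhaseVolume":
        return replace(self, voxels=np.asarray(voxels),
                       modality=modality or self.modality)


@dataclass
class SlicePair:
    """Spatially aligned (CT, CBCT) 2-D slices — the unit of training."""

    ct: np.ndarray
    cbct: np.ndarray
    subject_id: str
    phase: int
    slice_index: int = 0
    spacing: tuple = (2.0, 2.0)

    def __post_init__(self):
        self.ct = np.asarray(self.ct, dtype=np.float32)
        self.cbct = np.asarray(self.cbct, dtype=np.float32)
        if self.ct.ndim != 2 or self.cbct.ndim != 2:
            raise ValueError("slice pair images must be 2-D")
        if self.ct.shape != self.cbct.shape:
            raise ValueError(
                f"ct/cbct shape mismatch: {self.ct.shape} vs {self.cbct.shape}")
        if not (0 <= self.phase < 10):
            raise ValueError(f"phase {self.phase} outside [0, 10)")
        self.spacing = tuple(float(s) for s in self.spacing)
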