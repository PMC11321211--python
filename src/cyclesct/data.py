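"""Volume I/O, grid alignment, intensity normalisation and paired batching.

Real 4D-CT must be brought onto the 4D-CBCT grid before training; here that
alignment is a rigid resampling (deformable registration is an external
preprocessing step, and synthetic pairs are constructed aligned).  All
augmentations are *paired*: the same crop window and the same flip decision
are applied to the CT and CBCT slice of a pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .core import HU_MAX, HU_MIN, PhaseVolume, SlicePair


@dataclass(frozen=True)
class NormalizationSpec:
    """HU window mapped linearly onto [-1, 1] (network input scale)."""

    hu_min: float = HU_MIN
    hu_max: float = HU_MAX

    def __post_init__(self):
        if self.hu_max <= self.hu_min:
            raise ValueError("hu_max must exceed hu_min")


def normalize_hu(image: np.ndarray, spec: NormalizationSpec = NormalizationSpec()) -> np.ndarray:
    """Affine HU -> [-1, 1] with clipping at the window edges."""
    x = np.clip(np.asarray(image, dtype=np.float32), spec.hu_min, spec.hu_max)
    return (2.0 * (x - spec.hu_min) / (spec.hu_max - spec.hu_min) - 1.0).astype(np.float32)


def denormalize_hu(image: np.ndarray, spec: NormalizationSpec = NormalizationSpec()) -> np.ndarray:
    """Inverse of :func:`normalize_hu` for in-window values."""
    x = np.asarray(image, dtype=np.float32)
    return ((x + 1.0) * 0.5 * (spec.hu_max - spec.hu_min) + spec.hu_min).astype(np.float32)


def paired_random_crop(pair: SlicePair, crop_size: int, seed: int) -> SlicePair:
    """Cut the SAME window from both images of a pair (seeded)."""
    h, w = pair.ct.shape
    if crop_size > h or crop_size > w:
        raise ValueError(f"crop_size {crop_size} exceeds image size {(h, w)}")
    rng = np.random.default_rng(seed)
    top = int(rng.integers(0, h - crop_size + 1))
    left = int(rng.integers(0, w - crop_size + 1))
    return replace(pair,
                   ct=pair.ct[top:top + crop_size, left:left + crop_size].copy(),
                   cbct=pair.cbct[top:top + crop_size, left:left + crop_size].copy())


def paired_random_flip(pair: SlicePair, seed: int, axes: tuple = (1,),
                       force: bool | None = None) -> SlicePair:
    """Horizontal flip applied to both images or neither, probability 1/2."""
    rng = np.random.default_rng(seed)
    do_flip = bool(rng.random() < 0.5) if force is None else bool(force)
    if not do_flip:
        return pair
    ct, cbct = pair.ct, pair.cbct
    for ax in axes:
        ct = np.flip(ct, axis=ax)
        cbct = np.flip(cbct, axis=ax)
    return replace(pair, ct=ct.copy(), cbct=cbct.copy())


def resample_to_grid(volume: PhaseVolume, target_spacing: float,
                     target_size: int) -> PhaseVolume:
    """Linearly resample a 2-D slice onto a new grid about the shared centre."""
    if target_size <= 0:
        raise ValueError("target size must be positive")
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    img = volume.voxels
    if img.ndim != 2:
        raise ValueError("resample_to_grid expects a 2-D slice")
    if (target_size, target_size) == img.shape and \
            np.allclose(volume.spacing, (target_spacing, target_spacing)):
        return volume
    src_half = ((np.array(img.shape) - 1) / 2.0)
    tgt = (np.arange(target_size) - (target_size - 1) / 2.0) * target_spacing
    rows = tgt / volume.spacing[0] + src_half[0]
    cols = tgt / volume.spacing[1] + src_half[1]
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = ndimage.map_coordinates(img.astype(np.float64), [rr, cc],
                                  order=1, mode="nearest")
    return PhaseVolume(voxels=out, phase=volume.phase,
                       spacing=(target_spacing, target_spacing),
                       modality=volume.modality, n_phases=volume.n_phases,
                       subject_id=volume.subject_id)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def write_volume(volume: PhaseVolume, path) -> None:
    """Write a phase volume as NIfTI (float32, spacing on the affine)."""
    path = Path(path)
    img = volume.voxels.astype(np.float32)
    ndim = img.ndim
    affine = np.eye(4)
    for i, s in enumerate(volume.spacing[:3]):
        affine[i, i] = s
    nii = nib.Nifti1Image(np.asarray(img.T if ndim == 2 else img.transpose(2, 1, 0)),
                          affine)
    nii.header.set_xyzt_units("mm")
    nii.header["descrip"] = f"cyclesct:{volume.modality}:phase{volume.phase}".encode()
    nib.save(nii, str(path))


def read_volume(path, phase: int = 0, modality: str = "CT") -> PhaseVolume:
    """Read a NIfTI volume back into HU (scl slope/intercept applied)."""
    path = Path(path)
    if path.is_dir():
        raise IOError(
            f"{path}: DICOM series input is not supported in this build; "
            "convert to NIfTI first")
    if not path.exists():
        raise IOError(f"volume not found: {path}")
    try:
        nii = nib.load(str(path))
    except Exception as exc:  # corrupt file
        raise IOError(f"could not read {path}: {exc}") from exc
    data = np.asanyarray(nii.get_fdata(dtype=np.float64))
    zooms = nii.header.get_zooms()
    desc = bytes(nii.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
    if desc.startswith("cyclesct:"):
        _, modality, ph = desc.split(":")
        phase = int(ph.replace("phase", ""))
    if data.ndim == 2:
        img, spacing = data.T, (float(zooms[1]), float(zooms[0]))
    elif data.ndim == 3 and data.shape[2] == 1:
        img, spacing = data[:, :, 0].T, (float(zooms[1]), float(zooms[0]))
    else:
        img = data.transpose(2, 1, 0)
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return PhaseVolume(voxels=img, phase=phase, spacing=spacing, modality=modality)


def read_raw(path):
    """Read a NIfTI array without HU interpretation (e.g. dose grids, masks).

    Returns (array, spacing) with the same axis convention as read_volume.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume not found: {path}")
    nii = nib.load(str(path))
    data = np.asanyarray(nii.get_fdata(dtype=np.float64))
    zooms = nii.header.get_zooms()
    if data.ndim == 2:
        return data.T, (float(zooms[1]), float(zooms[0]))
    return data.transpose(2, 1, 0), (float(zooms[2]), float(zooms[1]), float(zooms[0]))


# ---------------------------------------------------------------------------
# dataset manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestRecord:
    subject_id: str
    phase: int
    slice_index: int
    ct_path: str
    cbct_path: str


@dataclass
class DatasetManifest:
    """Index of paired CT/CBCT slices; keys (subject, phase, slice) unique."""

    records: list
    spacing: tuple
    grid_size: int
    _arrays: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        keys = [(r.subject_id, r.phase, r.slice_index) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (subject, phase, slice) keys in manifest")

    def __len__(self):
        return len(self.records)

    def subjects(self) -> list:
        return sorted({r.subject_id for r in self.records})

    def _load(self, path: str) -> np.ndarray:
        if path.startswith("mem://"):
            return self._arrays[path]
        return read_volume(path).voxels

    def load_pair(self, record: ManifestRecord) -> SlicePair:
        return SlicePair(ct=self._load(record.ct_path),
                         cbct=self._load(record.cbct_path),
                         subject_id=record.subject_id, phase=record.phase,
                         slice_index=record.slice_index, spacing=self.spacing)

    def subset(self, subject_ids) -> "DatasetManifest":
        subject_ids = set(subject_ids)
        m = DatasetManifest(
            records=[r for r in self.records if r.subject_id in subject_ids],
            spacing=self.spacing, grid_size=self.grid_size)
        m._arrays = self._arrays
        return m

    def save(self, path) -> None:
        payload = {
            "spacing": list(self.spacing),
            "grid_size": self.grid_size,
            "records": [vars(r) for r in self.records],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        payload = json.loads(Path(path).read_text())
        recs = [ManifestRecord(**r) for r in payload["records"]]
        m = cls(records=recs, spacing=tuple(payload["spacing"]),
                grid_size=int(payload["grid_size"]))
        for r in recs:
            for p in (r.ct_path, r.cbct_path):
                if not p.startswith("mem://") and not Path(p).exists():
                    raise IOError(f"manifest refers to missing file: {p}")
        return m
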