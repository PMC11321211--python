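"""Synthetic 4-D breathing-thorax phantom and streak-artifact simulator.

Generates paired "CT" (clean raster or densely-sampled reconstruction) and
"CBCT" (sparse-view filtered back-projection with HU bias, cupping and
noise) data with known ground truth.  The acquisition surrogate is 2-D
parallel-beam: a Radon transform of the attenuation-mapped slice followed by
ramp-filtered back projection (scikit-image).  Reconstructing from few
angles produces the radial streaks characteristic of per-phase undersampled
cone-beam acquisitions; a global HU offset plus a radially quadratic
cupping term emulates the CT-number distortion the correction network is
meant to remove.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import radon as _radon
from skimage.transform import iradon as _iradon

from .core import HU_MAX, HU_MIN, PhaseVolume, clip_hu

#: linear attenuation of water, mm^-1 (approximately 0.2 cm^-1 at CT energies)
MU_WATER = 0.02

DEFAULT_TISSUE_HU = {
    "air": -1000.0,
    "lung": -700.0,
    "soft": 40.0,
    "bone": 700.0,
    "tumor": 60.0,
}


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in mm, centre (x, y) relative to image centre."""

    center: tuple
    semi_axes: tuple

    def __post_init__(self):
        if min(self.semi_axes) <= 0:
            raise ValueError(f"ellipse semi-axes must be positive, got {self.semi_axes}")

    def mask(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center
        a, b = self.semi_axes
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0


def _default_lungs():
    return (Ellipse((-55.0, -5.0), (40.0, 55.0)),
            Ellipse((55.0, -5.0), (40.0, 55.0)))


def _default_ribs():
    return (Ellipse((-100.0, 0.0), (6.0, 18.0)),
            Ellipse((100.0, 0.0), (6.0, 18.0)))


@dataclass
class PhantomSpec:
    """Geometry, tissue HU and motion of the 2-D thorax phantom."""

    grid_size: int = 128
    pixel_spacing: float = 2.0                 # mm
    body: Ellipse = field(default_factory=lambda: Ellipse((0.0, 0.0), (110.0, 80.0)))
    lungs: tuple = field(default_factory=_default_lungs)
    spine: Ellipse = field(default_factory=lambda: Ellipse((0.0, 62.0), (14.0, 13.0)))
    ribs: tuple = field(default_factory=_default_ribs)
    tumor_center: tuple = (55.0, -15.0)        # mm, at phase 0
    tumor_radius: float = 12.0                 # mm
    tissue_hu: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_HU))
    motion_amplitude: float = 10.0             # mm peak tumor/diaphragm excursion
    diaphragm_base: float = 45.0               # mm; lung below this line is replaced
    n_phases: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.grid_size < 8:
            raise ValueError("grid_size too small")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")
        if self.motion_amplitude < 0:
            raise ValueError("motion_amplitude must be >= 0")
        for k, v in self.tissue_hu.items():
            if not (HU_MIN <= v <= HU_MAX):
                raise ValueError(f"tissue_hu[{k!r}]={v} outside [{HU_MIN}, {HU_MAX}]")
        if self.tumor_radius <= 0:
            raise ValueError("tumor_radius must be positive")
        self._check_tumor_in_lung()

    def _check_tumor_in_lung(self) -> None:
        """The (moving) tumor must stay inside one lung at every phase."""
        cx, cy0 = self.tumor_center
        for p in range(self.n_phases):
            cy = cy0 + motion_displacement(self, p)
            ok = False
            for lung in self.lungs:
                a = lung.semi_axes[0] - self.tumor_radius
                b = lung.semi_axes[1] - self.tumor_radius
                if a <= 0 or b <= 0:
                    continue
                if (((cx - lung.center[0]) / a) ** 2
                        + ((cy - lung.center[1]) / b) ** 2) <= 1.0:
                    ok = True
                    break
            if not ok:
                raise ValueError(f"tumor leaves the lungs at phase {p}")


@dataclass
class DegradationParams:
    """Sparse-view + HU-distortion parameters of the CBCT surrogate.

    Defaults are calibrated so the simulated CBCT lands in the degradation
    regime of real per-phase undersampled 4D-CBCT: a global mean error near
    -117 HU against ground truth.  Because air is already at the -1000 HU
    floor and cannot shift further down, achieving that *observed* mean
    error requires an applied in-body offset of about -300 HU.
    """

    n_angles: int = 60
    hu_offset: float = -300.0
    cupping_coeff: float = 80.0
    noise_sd: float = 40.0

    def __post_init__(self):
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class ProjectionSet:
    """Parallel-beam sinogram: rows are view angles, columns detector bins."""

    sinogram: np.ndarray
    angles_deg: np.ndarray
    detector_spacing: float

    def __post_init__(self):
        self.sinogram = np.asarray(self.sinogram, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.angles_deg.size < 1:
            raise ValueError("at least one projection angle required")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")
        if np.any((self.angles_deg < 0) | (self.angles_deg >= 360)):
            raise ValueError("angles must lie in [0, 360)")
        if self.sinogram.shape[0] != self.angles_deg.size:
            raise ValueError("sinogram row count must equal the angle count")


def motion_displacement(spec: PhantomSpec, phase: int) -> float:
    """Respiratory displacement (mm) at a phase of the breathing cycle.

    A raised-cosine trajectory A*(1 - cos(2*pi*p/n))/2: zero at phase 0
    (end-inspiration), peaking at mid-cycle, smooth and periodic.
    """
    if not (0 <= phase < spec.n_phases):
        raise ValueError(f"phase {phase} outside [0, {spec.n_phases})")
    return spec.motion_amplitude * (1.0 - np.cos(2.0 * np.pi * phase / spec.n_phases)) / 2.0


def _grid_mm(spec: PhantomSpec):
    half = (spec.grid_size - 1) / 2.0
    coords = (np.arange(spec.grid_size) - half) * spec.pixel_spacing
    y, x = np.meshgrid(coords, coords, indexing="ij")
    return x, y


def render_phase(spec: PhantomSpec, phase: int) -> PhaseVolume:
    """Rasterise one respiratory phase of the phantom (modality CT)."""
    disp = motion_displacement(spec, phase)
    x, y = _grid_mm(spec)
    hu = spec.tissue_hu
    img = np.full((spec.grid_size, spec.grid_size), hu["air"], dtype=np.float64)
    img[spec.body.mask(x, y)] = hu["soft"]
    lung_mask = np.zeros_like(img, dtype=bool)
    for lung in spec.lungs:
        lung_mask |= lung.mask(x, y)
    img[lung_mask] = hu["lung"]
    # diaphragm: soft tissue fills the lung below a line that rises with phase
    diaphragm = lung_mask & (y > spec.diaphragm_base - disp)
    img[diaphragm] = hu["soft"]
    for rib in spec.ribs:
        img[rib.mask(x, y)] = hu["bone"]
    img[spec.spine.mask(x, y)] = hu["bone"]
    tx, ty = spec.tumor_center
    tumor = (x - tx) ** 2 + (y - (ty + disp)) ** 2 <= spec.tumor_radius ** 2
    img[tumor] = hu["tumor"]
    return PhaseVolume(voxels=img, phase=phase, spacing=(spec.pixel_spacing,) * 2,
                       modality="CT", n_phases=spec.n_phases)


def hu_to_attenuation(hu: np.ndarray) -> np.ndarray:
    """Linear HU -> mu (mm^-1), clipped at zero for physical plausibility."""
    return np.maximum(MU_WATER * (1.0 + np.asarray(hu, dtype=np.float64) / 1000.0), 0.0)


def attenuation_to_hu(mu: np.ndarray) -> np.ndarray:
    return clip_hu(1000.0 * (np.asarray(mu, dtype=np.float64) / MU_WATER - 1.0))


def uniform_angles(n_angles: int) -> np.ndarray:
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    return np.arange(n_angles) * (360.0 / n_angles)


def forward_project(volume: PhaseVolume, angles_deg) -> ProjectionSet:
    """Discrete line-integral (Radon) transform of the attenuation map.

    Sinogram entries are integrals of mu along rays (unit: dimensionless
    optical depth), i.e. pixel sums scaled by the pixel spacing.
    """
    img = volume.voxels
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("forward projection requires a square 2-D slice")
    angles = np.asarray(angles_deg, dtype=np.float64)
    if angles.size == 0:
        raise ValueError("empty angle list")
    mu = hu_to_attenuation(img)
    sino = _radon(mu, theta=angles, circle=True)        # (bins, n_angles)
    sino = sino.T * volume.spacing[0]
    return ProjectionSet(sinogram=sino, angles_deg=angles,
                         detector_spacing=volume.spacing[0])


def fbp_reconstruct(proj: ProjectionSet, grid_size: int) -> PhaseVolume:
    """Ramp-filtered back projection, mapped back to HU.

    With few view angles the reconstruction shows the radial streaks that
    motivate the correction network.
    """
    if proj.sinogram.shape[1] != grid_size:
        raise ValueError(
            f"detector bin count {proj.sinogram.shape[1]} does not match "
            f"grid size {grid_size}")
    mu = _iradon(proj.sinogram.T / proj.detector_spacing, theta=proj.angles_deg,
                 filter_name="ramp", interpolation="linear", circle=True,
                 output_size=grid_size)
    return PhaseVolume(voxels=attenuation_to_hu(mu), phase=0,
                       spacing=(proj.detector_spacing,) * 2, modality="CT")


def add_hu_bias(volume: PhaseVolume, offset: float,
                cupping_coeff: float = 0.0) -> PhaseVolume:
    """Global HU offset plus a radially quadratic (cupping-like) term.

    The quadratic term is ``cupping_coeff * (r / r_corner)**2`` so a corner
    pixel is shifted by ``offset + cupping_coeff`` and the centre by
    ``offset`` exactly.  Output is clipped to the HU range; with no clipping
    and zero cupping the mean error versus the input equals ``offset``.
    """
    img = volume.voxels.astype(np.float64)
    h, w = img.shape[-2:]
    yy = np.arange(h) - (h - 1) / 2.0
    xx = np.arange(w) - (w - 1) / 2.0
    y, x = np.meshgrid(yy, xx, indexing="ij")
    r2 = (x ** 2 + y ** 2) / (((h - 1) / 2.0) ** 2 + ((w - 1) / 2.0) ** 2)
    out = img + offset + cupping_coeff * r2
    return volume.with_voxels(clip_hu(out))


def simulate_cbct_phase(spec: PhantomSpec, phase: int,
                        params: DegradationParams | None = None,
                        seed: int = 0) -> PhaseVolume:
    """Render -> sparse-view project -> FBP -> HU bias -> noise (seeded)."""
    params = params or DegradationParams()
    truth = render_phase(spec, phase)
    proj = forward_project(truth, uniform_angles(params.n_angles))
    recon = fbp_reconstruct(proj, spec.grid_size)
    biased = add_hu_bias(recon, params.hu_offset, params.cupping_coeff)
    rng = np.random.default_rng(seed)
    noisy = biased.voxels + rng.normal(0.0, params.noise_sd, size=biased.voxels.shape) \
        if params.noise_sd > 0 else biased.voxels
    out = clip_hu(noisy)
    return PhaseVolume(voxels=out, phase=phase, spacing=(spec.pixel_spacing,) * 2,
                       modality="CBCT", n_phases=spec.n_phases)


def make_subject_specs(n_subjects: int, seed: int = 0,
                       grid_size: int = 128, pixel_spacing: float = 2.0) -> list:
    """Per-subject anatomical variation for a desk-scale cohort.

    Jitters body/lung axes (about 5%), tumor position/size and breathing
    amplitude around the default geometry, deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_subjects):
        sb = rng.uniform(0.95, 1.05, size=2)
        sl = rng.uniform(0.92, 1.05, size=2)
        lung_dx = rng.uniform(-4.0, 4.0)
        side = 1 if rng.random() < 0.5 else -1
        tumor_r = rng.uniform(9.0, 14.0)
        tumor_y = rng.uniform(-30.0, -5.0)
        amp = rng.uniform(8.0, 12.0)
        hu = dict(DEFAULT_TISSUE_HU)
        hu["lung"] += rng.uniform(-50.0, 50.0)
        hu["soft"] += rng.uniform(-15.0, 15.0)
        hu["bone"] += rng.uniform(-100.0, 100.0)
        lungs = (Ellipse((-55.0 - lung_dx, -5.0), (40.0 * sl[0], 55.0 * sl[1])),
                 Ellipse((55.0 + lung_dx, -5.0), (40.0 * sl[0], 55.0 * sl[1])))
        specs.append(PhantomSpec(
            grid_size=grid_size, pixel_spacing=pixel_spacing,
            body=Ellipse((0.0, 0.0), (110.0 * sb[0], 80.0 * sb[1])),
            lungs=lungs,
            tumor_center=(side * (55.0 + lung_dx), tumor_y),
            tumor_radius=tumor_r,
            motion_amplitude=amp,
            tissue_hu=hu,
            seed=seed + i,
        ))
    return specs


def generate_paired_dataset(specs, params: DegradationParams | None = None,
                            output_dir=None, n_slices: int = 1):
    """Write per-subject, per-phase paired CT/CBCT slices plus a manifest.

    Returns a :class:`cyclesct.data.DatasetManifest`; if ``output_dir`` is
    None the pairs are kept in memory on the manifest records instead of
    being written to NIfTI.
    """
    from . import data as _data

    if not specs:
        raise ValueError("at least one PhantomSpec required")
    params = params or DegradationParams()
    records = []
    arrays = {}
    out = None
    if output_dir is not None:
        from pathlib import Path
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
    spacing = (specs[0].pixel_spacing,) * 2
    for si, spec in enumerate(specs):
        subject = f"S{si:03d}"
        for sl in range(n_slices):
            # neighbouring slices: taper the tumor radius away from centre
            scale = 1.0 - 0.15 * abs(sl - (n_slices - 1) / 2.0)
            sspec = dataclasses.replace(spec, tumor_radius=spec.tumor_radius * scale)
            for p in range(spec.n_phases):
                ct = render_phase(sspec, p)
                cbct_seed = (spec.seed * 100003 + sl * 1009 + p) % (2 ** 31)
                cbct = simulate_cbct_phase(sspec, p, params, seed=cbct_seed)
                if out is not None:
                    ct_path = str(out / f"{subject}_p{p}_s{sl}_ct.nii.gz")
                    cbct_path = str(out / f"{subject}_p{p}_s{sl}_cbct.nii.gz")
                    _data.write_volume(ct, ct_path)
                    _data.write_volume(cbct, cbct_path)
                else:
                    ct_path = f"mem://{subject}/p{p}/s{sl}/ct"
                    cbct_path = f"mem://{subject}/p{p}/s{sl}/cbct"
                    arrays[ct_path] = ct.voxels
                    arrays[cbct_path] = cbct.voxels
                records.append(_data.ManifestRecord(
                    subject_id=subject, phase=p, slice_index=sl,
                    ct_path=ct_path, cbct_path=cbct_path))
    manifest = _data.DatasetManifest(records=records, spacing=spacing,
                                     grid_size=specs[0].grid_size)
    manifest._arrays = arrays
    if out is not None:
        manifest.save(out / "manifest.json")
    return manifest
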