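"""Quantitative evaluation: image-quality metrics in HU, tissue-ROI
CT-number analysis, DVH parameter extraction, relative percentage
difference, and Bonferroni-corrected paired t-tests.

Metric conventions (X = evaluated image, Y = reference CT):

* SSIM is computed from *global* image statistics — a single value per
  image, not a sliding window — with constants C1 = (0.01*2000)^2 = 400 and
  C2 = (0.03*2000)^2 = 3600 HU^2 (a windowed variant and constants based on
  the 4095 dynamic range are available via arguments);
* PSNR uses the evaluated image's own max by default (fixed peak 4095
  optionally), returning +inf with a flag when MSE is zero;
* MI uses 256 equal-width bins over [-1000, 3095] HU and natural logs,
  with 0*log(0) := 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity as _skimage_ssim

from .core import HU_MAX, HU_MIN, PhaseVolume

ROI_DEFAULT_SIZES = {"lung": 35, "bone": 15, "soft": 25, "tumor": 15}

C1_DEFAULT = (0.01 * 2000.0) ** 2   # 400 HU^2
C2_DEFAULT = (0.03 * 2000.0) ** 2   # 3600 HU^2


def _check_same_shape(x, y):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def ssim(x, y, c1: float = C1_DEFAULT, c2: float = C2_DEFAULT,
         windowed: bool = False) -> float:
    """Structural similarity from global statistics (single value).

    ``windowed=True`` switches to the conventional sliding-window SSIM
    (scikit-image) instead of the global-statistics form.
    """
    x, y = _check_same_shape(x, y)
    if windowed:
        return float(_skimage_ssim(x, y, data_range=HU_MAX - HU_MIN))
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    sx, sy = np.sqrt(vx), np.sqrt(vy)
    return float(((2 * mx * my + c1) * (2 * sx * sy + c2))
                 / ((mx * mx + my * my + c1) * (vx + vy + c2)))


def mse(x, y) -> float:
    x, y = _check_same_shape(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(x, y, peak: float | None = None) -> float:
    """10*log10(peak^2 / MSE); peak defaults to max|X| per the printed form.

    Returns +inf (not an exception) for identical images.
    """
    x, y = _check_same_shape(x, y)
    m = mse(x, y)
    p = float(np.max(np.abs(x))) if peak is None else float(peak)
    if m == 0.0:
        return float("inf")
    return float(10.0 * np.log10(p * p / m))


def me(x, y) -> float:
    """Mean error (HU): mean of X - Y."""
    x, y = _check_same_shape(x, y)
    return float(np.mean(x - y))


def mae(x, y) -> float:
    """Mean absolute error (HU)."""
    x, y = _check_same_shape(x, y)
    return float(np.mean(np.abs(x - y)))


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def mutual_information(x, y, bins: int = 256,
                       hu_range: tuple = (HU_MIN, HU_MAX)) -> float:
    """H(X) + H(Y) - H(X, Y) in nats from shared-binning histograms."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x, y = _check_same_shape(x, y)
    joint, _, _ = np.histogram2d(x.ravel(), y.ravel(), bins=bins,
                                 range=[hu_range, hu_range])
    joint = joint / joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    return _entropy(px) + _entropy(py) - _entropy(joint.ravel())


def entropy_of(x, bins: int = 256, hu_range: tuple = (HU_MIN, HU_MAX)) -> float:
    """Marginal intensity entropy under the same binning as MI."""
    h, _ = np.histogram(np.asarray(x, dtype=np.float64).ravel(), bins=bins,
                        range=hu_range)
    return _entropy(h / h.sum())


# ---------------------------------------------------------------------------
# ROI CT-number analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROISpec:
    """Square ROI for a tissue class; sizes default per tissue
    (lung 35, bone 15, soft 25, tumor 15 pixels on a side)."""

    tissue: str
    center: tuple                      # (row, col) pixel coordinates
    size: int | None = None

    def __post_init__(self):
        if self.tissue not in ROI_DEFAULT_SIZES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.size is None:
            object.__setattr__(self, "size", ROI_DEFAULT_SIZES[self.tissue])
        if self.size < 1:
            raise ValueError("ROI size must be >= 1")

    def slices(self, shape) -> tuple:
        r, c = self.center
        half = self.size // 2
        r0, c0 = int(r) - half, int(c) - half
        r1, c1 = r0 + self.size, c0 + self.size
        if r0 < 0 or c0 < 0 or r1 > shape[-2] or c1 > shape[-1]:
            raise ValueError(f"ROI {self.tissue} at {self.center} size "
                             f"{self.size} exceeds image {shape}")
        return slice(r0, r1), slice(c0, c1)


def roi_mean_ct(volume, roi: ROISpec) -> float:
    """Arithmetic mean HU inside the ROI (2-D slice or per-slice mean)."""
    img = volume.voxels if isinstance(volume, PhaseVolume) else np.asarray(volume)
    rs, cs = roi.slices(img.shape)
    return float(img[..., rs, cs].mean())


def roi_difference_table(volumes, reference, rois) -> pd.DataFrame:
    """(evaluated - reference) ROI mean HU per phase and tissue.

    ``volumes`` and ``reference`` are parallel per-phase sequences.  Returns
    a tidy DataFrame with columns (phase, tissue, evaluated, reference,
    difference) plus rows are per phase; the per-tissue mean absolute
    difference aggregate is available via ``.groupby('tissue')``.
    """
    rows = []
    for vol, ref in zip(volumes, reference):
        for roi in rois:
            ev = roi_mean_ct(vol, roi)
            rf = roi_mean_ct(ref, roi)
            rows.append({"phase": getattr(vol, "phase", 0), "tissue": roi.tissue,
                         "evaluated": ev, "reference": rf, "difference": ev - rf})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DVH and dose metrics
# ---------------------------------------------------------------------------

@dataclass
class DoseGrid:
    """Dose array (cGy) with named boolean structure masks."""

    dose: np.ndarray
    spacing: tuple
    structure_masks: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=np.float64)
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")
        for name, mask in self.structure_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.dose.shape:
                raise ValueError(f"mask {name!r} incongruent with dose grid")
            self.structure_masks[name] = mask


def dvh_metrics(grid: DoseGrid, structure: str, queries) -> dict:
    """Evaluate DVH queries like 'D98%', 'D2%', 'V20Gy', 'V5Gy'.

    Dx% is the minimum dose received by the hottest x% of the structure
    volume (linear interpolation over the sorted cumulative volume); VyGy
    is the percentage of the structure receiving at least y Gy.  Dose in
    the grid is cGy; V-queries take y in Gy.
    """
    if structure not in grid.structure_masks:
        raise ValueError(f"unknown structure {structure!r}")
    mask = grid.structure_masks[structure]
    if not mask.any():
        raise ValueError(f"structure {structure!r} has an empty mask")
    doses = np.sort(grid.dose[mask])[::-1]      # descending: hottest first
    nvox = doses.size
    out = {}
    for q in queries:
        q = q.strip()
        if q.upper().startswith("D"):
            x = float(q[1:].rstrip("%"))
            if not (0 < x <= 100):
                raise ValueError(f"Dx% query with x outside (0, 100]: {q}")
            frac = np.arange(1, nvox + 1) / nvox * 100.0  # % of volume covered
            out[q] = float(np.interp(x, frac, doses))
        elif q.upper().startswith("V"):
            y_gy = float(q[1:].lower().rstrip("gy"))
            out[q] = float(100.0 * np.mean(doses >= y_gy * 100.0))
        else:
            raise ValueError(f"unrecognised DVH query {q!r}")
    return out


def rpd(a: float, f: float) -> float:
    """Relative percentage difference |A - F| / ((A + F)/2) * 100.

    A is the reference (4D-CT) value, F the evaluated one.  Undefined when
    A + F = 0; returned as NaN rather than raising.
    """
    if a + f == 0:
        return float("nan")
    return float(abs(a - f) / ((a + f) / 2.0) * 100.0)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatTestResult:
    t: float
    p: float
    significant: bool
    degenerate: bool = False

    def __post_init__(self):
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def paired_test(sample_a, sample_b, threshold: float = 0.003) -> StatTestResult:
    """Two-sided paired t-test; significant iff p < threshold.

    The default threshold 0.003 is a Bonferroni-corrected cutoff.  A
    zero-variance difference is degenerate: p = 1 (not significant) when
    the samples are identical, p = 0 when they differ by a constant.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("samples must be equal-length 1-D with n >= 2")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            return StatTestResult(t=0.0, p=1.0, significant=False, degenerate=True)
        return StatTestResult(t=float("inf") if d[0] > 0 else float("-inf"),
                              p=0.0, significant=True, degenerate=True)
    res = stats.ttest_rel(a, b)
    p = float(res.pvalue)
    return StatTestResult(t=float(res.statistic), p=p, significant=p < threshold)


# ---------------------------------------------------------------------------
# pooled reports
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-phase and pooled image-quality metrics for one comparison."""

    ssim: float
    psnr: float
    me: float
    mae: float
    mi: float
    psnr_infinite: bool = False
    per_phase: pd.DataFrame | None = None

    def __post_init__(self):
        if self.mae < abs(self.me) - 1e-9:
            raise ValueError("MAE cannot be smaller than |ME|")
        if self.mi < -1e-12:
            raise ValueError("MI must be non-negative")
        if self.ssim > 1.0 + 1e-12:
            raise ValueError("SSIM cannot exceed 1")


def evaluate_pairwise(evaluated, reference, mi_bins: int = 256) -> MetricReport:
    """All image metrics per phase plus pooled means.

    ``evaluated`` and ``reference`` are parallel sequences of PhaseVolumes
    (or arrays) with congruent geometry; pooled values are means of the
    per-phase values (PSNR pooled over finite phases, flagged if any phase
    was infinite).
    """
    rows = []
    for ev, ref in zip(evaluated, reference):
        x = ev.voxels if isinstance(ev, PhaseVolume) else np.asarray(ev)
        y = ref.voxels if isinstance(ref, PhaseVolume) else np.asarray(ref)
        if x.shape != y.shape:
            raise ValueError("evaluated/reference geometry mismatch")
        rows.append({
            "phase": getattr(ev, "phase", len(rows)),
            "ssim": ssim(x, y),
            "psnr": psnr(x, y),
            "me": me(x, y),
            "mae": mae(x, y),
            "mi": mutual_information(x, y, bins=mi_bins),
        })
    if not rows:
        raise ValueError("no phases to evaluate")
    df = pd.DataFrame(rows)
    finite_psnr = df["psnr"][np.isfinite(df["psnr"])]
    inf_flag = bool((~np.isfinite(df["psnr"])).any())
    return MetricReport(
        ssim=float(df["ssim"].mean()),
        psnr=float(finite_psnr.mean()) if len(finite_psnr) else float("inf"),
        me=float(df["me"].mean()),
        mae=float(df["mae"].mean()),
        mi=float(df["mi"].mean()),
        psnr_infinite=inf_flag,
        per_phase=df)
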