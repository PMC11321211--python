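"""Desk-scale end-to-end benchmark.

Trains the desk preset on a small synthetic cohort and evaluates the
resulting sCT against the ground-truth CT on held-out subjects.  This is
the scaled-down stand-in for a full patient-cohort experiment: it verifies
the *direction* of the correction (sCT closer to CT than the degraded CBCT
was), not clinical-scale magnitudes.
"""

from __future__ import annotations

import numpy as np

from . import evaluation as E
from .data import NormalizationSpec
from .losses import LossWeights
from .phantom import DegradationParams, generate_paired_dataset, make_subject_specs
from .training import TrainConfig, generate_sct, train


def run_desk_benchmark(seed: int = 0, n_train_subjects: int = 8,
                       n_test_subjects: int = 2, iterations: int = 300,
                       grid_size: int = 64, pixel_spacing: float = 4.0,
                       degradation: DegradationParams | None = None) -> dict:
    """Train the desk preset and measure held-out improvement.

    Returns pooled held-out SSIM/MAE/ME for CBCT-vs-CT and sCT-vs-CT plus
    the mean generator total loss over the first and last 10% of
    iterations.
    """
    degradation = degradation or DegradationParams()
    specs = make_subject_specs(n_train_subjects + n_test_subjects, seed=seed,
                               grid_size=grid_size, pixel_spacing=pixel_spacing)
    manifest = generate_paired_dataset(specs, degradation, output_dir=None)
    subjects = manifest.subjects()
    train_manifest = manifest.subset(subjects[:n_train_subjects])
    test_manifest = manifest.subset(subjects[n_train_subjects:])

    config = TrainConfig.desk_preset(seed=seed, crop_size=min(64, grid_size),
                                     max_iterations=iterations)
    bundle, state = train(train_manifest, config, LossWeights())

    cbct_vols, ct_vols, sct_vols = [], [], []
    norm = config.norm_spec
    from .core import PhaseVolume
    for rec in test_manifest.records:
        pair = test_manifest.load_pair(rec)
        cbct = PhaseVolume(voxels=pair.cbct, phase=pair.phase,
                           spacing=pair.spacing, modality="CBCT")
        ct_vols.append(PhaseVolume(voxels=pair.ct, phase=pair.phase,
                                   spacing=pair.spacing, modality="CT"))
        cbct_vols.append(cbct)
        sct_vols.append(generate_sct(bundle, cbct, norm))

    rep_cbct = E.evaluate_pairwise(cbct_vols, ct_vols)
    rep_sct = E.evaluate_pairwise(sct_vols, ct_vols)

    totals = np.array([r.total for r in state.loss_history])
    tenth = max(1, len(totals) // 10)
    return {
        "seed": seed,
        "iterations": int(state.iteration),
        "ssim_cbct": rep_cbct.ssim, "ssim_sct": rep_sct.ssim,
        "mae_cbct": rep_cbct.mae, "mae_sct": rep_sct.mae,
        "me_cbct": rep_cbct.me, "me_sct": rep_sct.me,
        "mi_cbct": rep_cbct.mi, "mi_sct": rep_sct.mi,
        "psnr_cbct": rep_cbct.psnr, "psnr_sct": rep_sct.psnr,
        "loss_first_tenth": float(totals[:tenth].mean()),
        "loss_last_tenth": float(totals[-tenth:].mean()),
    }
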