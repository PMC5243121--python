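"""Built-in experiments: acquisition-dialect robustness and AIF sensitivity.

Both experiments probe how far a classifier trained on the native ~3 s
acquisition can be pushed: first by classifying curves rendered under a
coarser ~7.7 s protocol and resampled onto a ~4.1 s grid, and second by
perturbing the AIF onset (±1, ±2 frames) and peak (±10%) used during
normalization and re-classifying.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import subvolume
from .model import SubvolumeResults
from .phantom import (
    ALTERNATE_ACQUISITION,
    AcquisitionConfig,
    AifModel,
    ClassRanges,
    DceSeries,
    PhantomGeometry,
    generate_phantom,
)
from .preprocess import Aif, extract_aif, resample_series, windows_from_series

__all__ = ["run_aif_sensitivity", "run_resampling_robustness"]

DEFAULT_ONSET_SHIFTS = (-2, -1, 0, 1, 2)
DEFAULT_PEAK_SCALES = (0.9, 1.0, 1.1)


def classify_series(
    results: SubvolumeResults,
    series: DceSeries,
    tumor_mask: np.ndarray,
    aif: Aif,
    reference_labels_3d: np.ndarray,
    *,
    window_length: int = 32,
) -> float:
    """Usage-phase accuracy of a trained classifier on a (new) series.

    No PK fitting and no SVM training happen here: the series is normalized,
    windowed, transformed with the frozen feature state, and classified.
    """
    win = windows_from_series(series, tumor_mask, aif, window_length=window_length)
    yhat = results.predict_labels(win.values)
    ref = np.asarray(reference_labels_3d)[tuple(win.voxel_indices.T)]
    return subvolume.voxel_accuracy(yhat, ref)


def run_aif_sensitivity(
    results: SubvolumeResults,
    series: DceSeries,
    tumor_mask: np.ndarray,
    aif: Aif,
    reference_labels_3d: np.ndarray,
    *,
    onset_shifts=DEFAULT_ONSET_SHIFTS,
    peak_scales=DEFAULT_PEAK_SCALES,
    window_length: int = 32,
) -> pd.DataFrame:
    """Accuracy grid over perturbed AIF onset and peak.

    Each cell re-normalizes and re-windows the series with the perturbed
    onset/peak and re-classifies with the already-trained model.  Cells whose
    shifted window overruns the scan (or leaves too few baseline frames) are
    NaN.  The zero-shift, unit-scale cell is the unperturbed baseline by
    construction.
    """
    grid = np.full((len(onset_shifts), len(peak_scales)), np.nan)
    for i, shift in enumerate(onset_shifts):
        for j, scale in enumerate(peak_scales):
            onset = aif.onset_index + int(shift)
            try:
                perturbed = Aif(
                    curve=aif.curve,
                    onset_index=onset,
                    peak_enhancement=aif.peak_enhancement * float(scale),
                )
                grid[i, j] = classify_series(
                    results, series, tumor_mask, perturbed, reference_labels_3d,
                    window_length=window_length,
                )
            except ValueError:
                continue  # invalid cell: window overrun or onset out of range
    return pd.DataFrame(
        grid,
        index=pd.Index(onset_shifts, name="onset_shift"),
        columns=pd.Index(peak_scales, name="peak_scale"),
    )


def run_resampling_robustness(
    results: SubvolumeResults,
    *,
    seed: int,
    acq_alt: AcquisitionConfig = ALTERNATE_ACQUISITION,
    dt_out: float = 4.1,
    noise_sd_rel: float | None = None,
    geometry: PhantomGeometry | None = None,
    ranges: ClassRanges | None = None,
    aif_model: AifModel | None = None,
    window_length: int = 32,
) -> dict:
    """Classify an alternate-dialect rendering of the phantom after resampling.

    The phantom is re-rendered under ``acq_alt`` with the same seed and
    geometry (identical kinetic parameter maps and labels), its curves are
    linearly resampled onto a ``dt_out`` grid, the AIF is re-extracted from
    the resampled artery, and the frozen classifier from ``results`` is
    applied.  Returns the resampled-dialect accuracy plus bookkeeping.
    """
    if noise_sd_rel is not None:
        acq_alt = AcquisitionConfig(
            n_frames=acq_alt.n_frames,
            dt_seconds=acq_alt.dt_seconds,
            voxel_dims_mm=acq_alt.voxel_dims_mm,
            baseline_frames=acq_alt.baseline_frames,
            noise_sd_rel=noise_sd_rel,
            seed=acq_alt.seed,
        )
    series, tumor, artery, truth = generate_phantom(
        acq_alt, geometry=geometry, ranges=ranges, aif_model=aif_model, seed=seed
    )
    resampled = resample_series(series, dt_out)
    aif = extract_aif(resampled, artery)
    acc = classify_series(
        results, resampled, tumor, aif, truth.label_map, window_length=window_length
    )
    return {
        "resampled_accuracy_pct": acc,
        "n_frames_resampled": resampled.n_frames,
        "dt_out_seconds": dt_out,
        "n_tumor_voxels": int(tumor.sum()),
    }
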