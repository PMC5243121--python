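"""Curve normalization, AIF extraction, onset-aligned windowing, resampling.

Raw signal curves are converted to relative enhancement against a pre-onset
baseline, normalized by the peak arterial enhancement so patients (or
phantoms) with different injection dynamics become comparable, and cut to a
32-point dyadic window starting at the arterial onset.  An alternate-dialect
series with coarser temporal sampling is first resampled onto a finer uniform
grid so that the 32-point window covers a comparable physiologic interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d

from .phantom import DceSeries

__all__ = [
    "Aif",
    "NormalizedWindows",
    "estimate_baseline",
    "normalize_curve",
    "extract_aif",
    "window_curve",
    "resample_curve",
    "resample_series",
    "windows_from_series",
]

DEFAULT_WINDOW_LENGTH = 32
DEFAULT_AIF_TOP_FRACTION = 0.10
DEFAULT_AIF_ONSET_FRACTION = 0.10


@dataclass(frozen=True)
class Aif:
    """Arterial input function: enhancement curve, onset sample, peak."""

    curve: np.ndarray  # relative enhancement dS(t) of the artery
    onset_index: int
    peak_enhancement: float

    def __post_init__(self) -> None:
        curve = np.asarray(self.curve, dtype=float)
        object.__setattr__(self, "curve", curve)
        if not 0 <= self.onset_index < len(curve):
            raise ValueError("onset_index must lie inside the curve")
        if self.peak_enhancement <= 0:
            raise ValueError("peak_enhancement must be positive")


@dataclass
class NormalizedWindows:
    """Per-voxel 32-point normalized enhancement windows.

    ``values`` is (n_voxels, window_length); ``voxel_indices`` is
    (n_voxels, 3); ``excluded`` records voxels dropped during preprocessing as
    (index-triple, reason) pairs.
    """

    values: np.ndarray
    voxel_indices: np.ndarray
    dt_seconds: float
    excluded: list = None

    def __post_init__(self) -> None:
        if self.excluded is None:
            self.excluded = []


def estimate_baseline(curve, pre_onset_frames: int) -> float:
    """Mean signal over the pre-onset frames (the baseline S0)."""
    curve = np.asarray(curve, dtype=float)
    if pre_onset_frames < 3:
        raise ValueError("need at least 3 pre-onset frames for a baseline")
    if pre_onset_frames > len(curve):
        raise ValueError("pre_onset_frames exceeds curve length")
    s0 = float(curve[:pre_onset_frames].mean())
    if s0 <= np.finfo(float).eps:
        raise ValueError("nonpositive-baseline")
    return s0


def normalize_curve(curve, s0: float, aif_max: float) -> np.ndarray:
    """Relative enhancement normalized by the peak arterial enhancement.

    dS(t) = (S(t) - S0) / S0;  dS_N(t) = dS(t) / AIF_max.
    """
    if s0 <= 0:
        raise ValueError("nonpositive-baseline")
    if aif_max <= 0:
        raise ValueError("aif_max must be positive")
    curve = np.asarray(curve, dtype=float)
    return (curve - s0) / (s0 * aif_max)


def extract_aif(
    series: DceSeries,
    artery_mask: np.ndarray,
    *,
    top_fraction: float = DEFAULT_AIF_TOP_FRACTION,
    onset_fraction: float = DEFAULT_AIF_ONSET_FRACTION,
    baseline_frames: int = 3,
    noise_floor: float = 1e-6,
    onset_index: int | None = None,
    peak_enhancement: float | None = None,
) -> Aif:
    """Estimate the AIF from an artery region of interest.

    The enhancement curve is the mean relative enhancement of the
    ``top_fraction`` most-enhancing artery voxels (ranked by peak enhancement
    against a provisional early-frame baseline).  The onset sample is placed
    one frame before the first crossing of ``onset_fraction`` of the peak —
    the crossing sample already contains substantial enhancement, so backing
    off one frame lands on the bolus-arrival sample for curves rising from
    zero.  Passing ``onset_index`` and/or ``peak_enhancement`` overrides the
    automatic estimates (manual AIF specification).
    """
    artery_mask = np.asarray(artery_mask, dtype=bool)
    if not artery_mask.any():
        raise ValueError("aif-not-found: empty artery mask")
    curves = series.data[artery_mask]  # (n_voxels, t)
    s0 = curves[:, :baseline_frames].mean(axis=1)
    valid = s0 > np.finfo(float).eps
    if not valid.any():
        raise ValueError("aif-not-found: no artery voxel has a positive baseline")
    curves = curves[valid]
    s0 = s0[valid]
    ds = (curves - s0[:, None]) / s0[:, None]
    peaks = ds.max(axis=1)
    n_top = max(1, int(np.ceil(top_fraction * len(ds))))
    top = np.argsort(peaks)[::-1][:n_top]
    aif_curve = ds[top].mean(axis=0)

    peak = float(aif_curve.max())
    if peak < noise_floor:
        raise ValueError("aif-not-found: artery region does not enhance")

    if onset_index is None:
        crossing = int(np.argmax(aif_curve > onset_fraction * peak))
        onset_index = max(crossing - 1, 0)
    if peak_enhancement is None:
        peak_enhancement = peak
    return Aif(curve=aif_curve, onset_index=int(onset_index), peak_enhancement=float(peak_enhancement))


def window_curve(values, onset_index: int, window_length: int = DEFAULT_WINDOW_LENGTH) -> np.ndarray:
    """Cut the dyadic analysis window starting at the onset sample (inclusive)."""
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    if onset_index < 0:
        raise ValueError("onset_index must be nonnegative")
    if onset_index + window_length > n:
        raise ValueError("window-overrun: insufficient frames after onset")
    return values[..., onset_index : onset_index + window_length]


def resample_curve(curve, dt_in: float, dt_out: float) -> np.ndarray:
    """Linearly resample a curve onto a uniform ``dt_out`` grid.

    Output samples sit at k * dt_out inside the original span; length is
    floor(span / dt_out) + 1.
    """
    curve = np.asarray(curve, dtype=float)
    if dt_in <= 0 or dt_out <= 0:
        raise ValueError("sampling intervals must be positive")
    span = (curve.shape[-1] - 1) * dt_in
    if dt_out >= span:
        raise ValueError("dt_out must be smaller than the curve span")
    t_in = np.arange(curve.shape[-1]) * dt_in
    n_out = int(np.floor(span / dt_out)) + 1
    t_out = np.arange(n_out) * dt_out
    if curve.ndim == 1:
        return np.interp(t_out, t_in, curve)
    f = interp1d(t_in, curve, axis=-1, assume_sorted=True)
    return f(t_out)


def resample_series(series: DceSeries, dt_out: float) -> DceSeries:
    """Resample every voxel curve of a 4-D series onto a ``dt_out`` grid."""
    data = resample_curve(series.data, series.dt_seconds, dt_out)
    return DceSeries(data=data, dt_seconds=dt_out, voxel_dims_mm=series.voxel_dims_mm)


def windows_from_series(
    series: DceSeries,
    mask: np.ndarray,
    aif: Aif,
    *,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    min_baseline_frames: int = 3,
) -> NormalizedWindows:
    """Normalize and window every in-mask voxel curve.

    The per-voxel baseline is the mean signal over the frames before the AIF
    onset; curves are normalized by the AIF peak and cut to ``window_length``
    points starting at the onset sample.  Voxels whose baseline is nonpositive
    are excluded (with a reason) rather than imputed; a window overrunning the
    scan raises, since the caller should resample first.
    """
    mask = np.asarray(mask, dtype=bool)
    if aif.onset_index < min_baseline_frames:
        raise ValueError(
            "too few pre-onset frames for baseline estimation; resample or "
            "override the AIF onset"
        )
    if aif.onset_index + window_length > series.n_frames:
        raise ValueError("window-overrun: insufficient frames after onset")
    idx = np.argwhere(mask)
    curves = series.data[mask]
    s0 = curves[:, : aif.onset_index].mean(axis=1)
    good = s0 > np.finfo(float).eps
    excluded = [
        (tuple(i), "nonpositive-baseline") for i in idx[~good]
    ]
    ds_n = (curves[good] - s0[good, None]) / (s0[good, None] * aif.peak_enhancement)
    windows = ds_n[:, aif.onset_index : aif.onset_index + window_length]
    return NormalizedWindows(
        values=windows,
        voxel_indices=idx[good],
        dt_seconds=series.dt_seconds,
        excluded=excluded,
    )
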