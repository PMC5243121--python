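"""Two-compartment Tofts fitting, blood-volume maps, and voxel labeling.

This is the pharmacokinetic reference path: normalized enhancement curves are
fitted voxel-by-voxel with bounded nonlinear least squares, the plasma
fraction is converted to a blood-volume percentage, and voxels are labeled
low / high blood volume at a fixed threshold.  The resulting labels are the
training target for the feature-based classifier and the ground truth for
Dice evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .phantom import DceSeries, TissueParams, ToftsGrid

__all__ = [
    "DEFAULT_BV_THRESHOLD",
    "ToftsFitResult",
    "fit_tofts",
    "ToftsModel",
    "ToftsResults",
    "BvMap",
    "fit_bv_map",
    "label_by_bv",
]

#: Blood-volume threshold (percent) separating c-LBV from c-HBV voxels.
DEFAULT_BV_THRESHOLD = 7.6

#: Box constraints for (vp, ktrans [1/min], kep [1/min]).
FIT_BOUNDS = (np.array([0.0, 0.0, 0.0]), np.array([1.0, 5.0, 10.0]))

#: Multi-start initializations (vp, ktrans, kep).
FIT_STARTS = ((0.02, 0.1, 0.3), (0.1, 0.3, 0.8), (0.3, 1.0, 2.0))

_FIT_TOL = 1e-8
# residual RMS below which further starts cannot improve meaningfully
_EARLY_STOP_RMS = 1e-10


@dataclass
class ToftsFitResult:
    vp: float
    ktrans: float
    kep: float
    residual_norm: float
    converged: bool

    @property
    def params(self) -> TissueParams | None:
        if not self.converged:
            return None
        return TissueParams(self.vp, self.ktrans, self.kep)


def fit_tofts(
    curve,
    aif_curve,
    times_s,
    *,
    grid: ToftsGrid | None = None,
    starts=FIT_STARTS,
) -> ToftsFitResult:
    """Fit the Tofts model to one normalized enhancement curve.

    Bounded trust-region least squares (vp in [0,1], ktrans in [0,5]/min,
    kep in [0,10]/min) from three starting points; the start with the lowest
    residual wins.  If every start fails the voxel is flagged (params NaN)
    rather than raising, so map-level fitting can skip it.
    """
    y = np.asarray(curve, dtype=float)
    cp = np.asarray(aif_curve, dtype=float)
    if len(y) != len(cp):
        raise ValueError("curve and aif_curve must have the same length")
    if len(y) < 16:
        raise ValueError("need at least 16 time points to fit")
    if grid is None:
        grid = ToftsGrid(np.asarray(times_s, dtype=float))

    best = None
    for x0 in starts:
        try:
            res = least_squares(
                lambda x: grid.forward(cp, x[0], x[1], x[2]) - y,
                x0=np.asarray(x0, dtype=float),
                bounds=FIT_BOUNDS,
                method="trf",
                xtol=_FIT_TOL,
                ftol=_FIT_TOL,
                gtol=_FIT_TOL,
            )
        except Exception:  # optimizer failure on this start; try the next
            continue
        if res.status <= 0:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if np.sqrt(2.0 * best.cost / len(y)) < _EARLY_STOP_RMS:
            break

    if best is None:
        return ToftsFitResult(np.nan, np.nan, np.nan, np.nan, False)
    vp, ktrans, kep = best.x
    return ToftsFitResult(
        float(vp), float(ktrans), float(kep),
        float(np.sqrt(2.0 * best.cost)), True,
    )


class ToftsModel:
    """Tofts model for one normalized tissue curve, statsmodels style.

    Parameters
    ----------
    endog : array
        Normalized tissue enhancement curve.
    aif_curve : array
        Normalized arterial input curve on the same time grid.
    times_s : array
        Sample times in seconds.
    """

    param_names = ("vp", "ktrans", "kep")

    def __init__(self, endog, aif_curve, times_s):
        self.endog = np.asarray(endog, dtype=float)
        self.aif_curve = np.asarray(aif_curve, dtype=float)
        self.times_s = np.asarray(times_s, dtype=float)
        self.grid = ToftsGrid(self.times_s)

    def predict(self, params) -> np.ndarray:
        vp, ktrans, kep = params
        return self.grid.forward(self.aif_curve, vp, ktrans, kep)

    def fit(self) -> "ToftsResults":
        raw = fit_tofts(self.endog, self.aif_curve, self.times_s, grid=self.grid)
        return ToftsResults(self, raw)


class ToftsResults:
    """Fit results: parameter estimates, uncertainties, diagnostics."""

    def __init__(self, model: ToftsModel, raw: ToftsFitResult):
        self.model = model
        self._raw = raw
        self.params = pd.Series(
            [raw.vp, raw.ktrans, raw.kep], index=list(model.param_names)
        )
        self.converged = raw.converged
        self.residual_norm = raw.residual_norm

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.params.to_numpy())

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def bv_percent(self) -> float:
        return 100.0 * self.params["vp"]

    def bse(self) -> pd.Series:
        """Approximate standard errors from the Gauss-Newton covariance."""
        x = self.params.to_numpy()
        n, p = len(self.model.endog), len(x)
        if n <= p or not self.converged:
            return pd.Series(np.nan, index=self.params.index)
        eps = 1e-6
        cols = []
        for j in range(p):
            dx = np.zeros(p)
            dx[j] = eps * max(1.0, abs(x[j]))
            cols.append(
                (self.model.predict(x + dx) - self.model.predict(x - dx)) / (2 * dx[j])
            )
        jac = np.column_stack(cols)
        dof = n - p
        s2 = float(self.resid @ self.resid) / dof
        try:
            cov = s2 * np.linalg.inv(jac.T @ jac)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
        return pd.Series(se, index=self.params.index)

    def summary(self) -> str:
        se = self.bse()
        lines = [
            "Tofts model fit (two-compartment)",
            "=" * 44,
            f"{'n obs':<14}{len(self.model.endog):>10}",
            f"{'converged':<14}{str(self.converged):>10}",
            f"{'resid norm':<14}{self.residual_norm:>10.4g}",
            "-" * 44,
            f"{'param':<10}{'estimate':>12}{'std err':>12}",
        ]
        for name in self.params.index:
            lines.append(f"{name:<10}{self.params[name]:>12.5f}{se[name]:>12.5f}")
        lines.append("-" * 44)
        lines.append(f"{'BV (%)':<10}{self.bv_percent:>12.3f}")
        return "\n".join(lines)


@dataclass
class BvMap:
    """Voxelwise blood-volume percentages with fit diagnostics."""

    bv_percent: np.ndarray  # 3-D, NaN outside mask and on failed voxels
    residual_norm: np.ndarray
    converged: np.ndarray  # boolean 3-D
    vp: np.ndarray
    ktrans: np.ndarray
    kep: np.ndarray
    bv_scale: float = 100.0


def fit_bv_map(
    norm_curves: np.ndarray,
    aif_curve: np.ndarray,
    times_s: np.ndarray,
    voxel_indices: np.ndarray,
    shape: tuple[int, int, int],
    *,
    bv_scale: float = 100.0,
) -> BvMap:
    """Fit the Tofts model voxel-by-voxel and assemble a blood-volume map.

    ``norm_curves`` is (n_voxels, n_frames) of normalized enhancement;
    ``voxel_indices`` is (n_voxels, 3).  ``bv_scale`` converts the plasma
    fraction to a blood-volume percentage (default 100 * vp; a hematocrit-style
    correction can be folded in here).
    """
    grid = ToftsGrid(np.asarray(times_s, dtype=float))
    n = len(norm_curves)
    bv = np.full(shape, np.nan)
    resid = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)
    vp_m = np.full(shape, np.nan)
    kt_m = np.full(shape, np.nan)
    kep_m = np.full(shape, np.nan)
    for i in range(n):
        fit = fit_tofts(norm_curves[i], aif_curve, times_s, grid=grid)
        ix = tuple(voxel_indices[i])
        conv[ix] = fit.converged
        if fit.converged:
            bv[ix] = bv_scale * fit.vp
            resid[ix] = fit.residual_norm
            vp_m[ix] = fit.vp
            kt_m[ix] = fit.ktrans
            kep_m[ix] = fit.kep
    return BvMap(bv, resid, conv, vp_m, kt_m, kep_m, bv_scale)


def label_by_bv(bv_percent, threshold: float = DEFAULT_BV_THRESHOLD):
    """Label voxels 0 (low BV) where ``bv < threshold``, else 1 (high BV).

    A value exactly at the threshold is assigned the high-BV class.  NaN
    entries (outside the mask or failed fits) map to the background sentinel
    -1.  Accepts scalars or arrays.
    """
    bv = np.asarray(bv_percent, dtype=float)
    out = np.where(bv < threshold, 0, 1).astype(np.int8)
    out = np.where(np.isnan(bv), np.int8(-1), out)
    if np.ndim(bv_percent) == 0:
        return int(out)
    return out
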