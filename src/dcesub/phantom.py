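"""Synthetic 4-D DCE-MRI phantoms with known voxelwise kinetics.

The phantom emulates a T1-weighted dynamic contrast-enhanced acquisition of a
head-and-neck tumor: an ellipsoidal gross tumor volume whose voxels enhance
according to a two-compartment Tofts model, an artery region carrying the
arterial input function (AIF), and additive Gaussian noise.  Because every
voxel's plasma fraction ``vp`` is drawn from class-specific ranges that are
disjoint across the blood-volume threshold, the low/high blood-volume label of
every voxel is known by construction, giving closed-loop ground truth for the
classification pipeline and for the pharmacokinetic fitting path.

Two acquisition dialects are built in: the native ~3 s / 60-frame protocol the
classifier is trained on, and an alternate ~7.7 s / 32-frame protocol used to
probe robustness to different scanners (curves from the latter are resampled
before classification).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

SECONDS_PER_MINUTE = 60.0

__all__ = [
    "AcquisitionConfig",
    "AifModel",
    "TissueParams",
    "PhantomGeometry",
    "ClassRanges",
    "DceSeries",
    "PhantomTruth",
    "NATIVE_ACQUISITION",
    "ALTERNATE_ACQUISITION",
    "generate_aif",
    "tofts_forward",
    "ToftsGrid",
    "generate_phantom",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Temporal and spatial sampling of a dynamic acquisition.

    Parameters
    ----------
    n_frames : int
        Number of dynamic volumes.
    dt_seconds : float
        Temporal resolution (uniform frame spacing), seconds.
    voxel_dims_mm : tuple of float
        Voxel edge lengths (dx, dy, dz) in millimetres.
    baseline_frames : int
        Number of pre-contrast frames before the AIF onset.
    noise_sd_rel : float
        Standard deviation of additive Gaussian signal noise, relative to the
        baseline signal S0.
    seed : int
        Seed for the phantom noise stream.
    """

    n_frames: int = 60
    dt_seconds: float = 3.0
    voxel_dims_mm: tuple[float, float, float] = (1.56, 1.56, 1.5)
    baseline_frames: int = 10
    noise_sd_rel: float = 0.02
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.dt_seconds <= 0:
            raise ValueError("dt_seconds must be positive")
        if len(self.voxel_dims_mm) != 3 or any(d <= 0 for d in self.voxel_dims_mm):
            raise ValueError("voxel_dims_mm must be three positive lengths")
        if self.baseline_frames < 0 or self.baseline_frames >= self.n_frames:
            raise ValueError("baseline_frames must lie inside the scan")
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be nonnegative")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_seconds

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims_mm))


#: Native TWIST-like dialect: ~3 s resolution, 60 frames, 1.56x1.56x1.5 mm voxels.
NATIVE_ACQUISITION = AcquisitionConfig()

#: Alternate dialect: ~7.7 s resolution, 32 frames, 2 mm isotropic voxels.
ALTERNATE_ACQUISITION = AcquisitionConfig(
    n_frames=32, dt_seconds=7.7, voxel_dims_mm=(2.0, 2.0, 2.0), baseline_frames=4
)


@dataclass(frozen=True)
class AifModel:
    """Analytic arterial input function: gamma-variate rise + exponential washout.

    The enhancement is zero before ``onset_time_s``; afterwards it follows

        s(t') = gv(t') + w * (1 - exp(-t'/r)) * exp(-t'/tau),   t' = t - onset

    where ``gv`` is a gamma-variate with shape ``alpha`` and time-scale
    ``beta_s`` (mode at alpha*beta_s), normalized so the sampled curve peaks at
    ``peak_enhancement``.  With ``washout_weight=0`` the curve is a pure
    gamma-variate whose mode is analytically alpha*beta_s.
    """

    onset_time_s: float = 30.0
    peak_enhancement: float = 2.5
    alpha: float = 3.0
    beta_s: float = 4.0
    washout_weight: float = 0.3
    washout_rise_s: float = 12.0
    washout_tau_s: float = 120.0

    def __post_init__(self) -> None:
        if self.onset_time_s < 0:
            raise ValueError("onset_time_s must be nonnegative")
        if self.peak_enhancement <= 0:
            raise ValueError("peak_enhancement must be positive")
        if self.alpha <= 0 or self.beta_s <= 0:
            raise ValueError("gamma-variate shape parameters must be positive")
        if self.washout_weight < 0:
            raise ValueError("washout_weight must be nonnegative")
        if self.washout_rise_s <= 0 or self.washout_tau_s <= 0:
            raise ValueError("washout time constants must be positive")

    def shape(self, t_rel) -> np.ndarray:
        """Unnormalized enhancement shape at times ``t_rel`` after onset."""
        t = np.asarray(t_rel, dtype=float)
        pos = np.clip(t, 0.0, None)
        mode = self.alpha * self.beta_s
        with np.errstate(divide="ignore", invalid="ignore"):
            gv = (pos / mode) ** self.alpha * np.exp(self.alpha - pos / self.beta_s)
        tail = (
            self.washout_weight
            * (1.0 - np.exp(-pos / self.washout_rise_s))
            * np.exp(-pos / self.washout_tau_s)
        )
        out = np.where(t > 0, gv + tail, 0.0)
        return out


@dataclass(frozen=True)
class TissueParams:
    """Voxelwise Tofts parameters.

    vp: plasma volume fraction in [0, 1]; ktrans: transfer constant (1/min);
    kep: efflux rate constant (1/min).
    """

    vp: float
    ktrans: float
    kep: float

    def __post_init__(self) -> None:
        for name in ("vp", "ktrans", "kep"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.vp <= 1.0:
            raise ValueError("vp must lie in [0, 1]")
        if self.ktrans < 0 or self.kep < 0:
            raise ValueError("rate constants must be nonnegative")


def generate_aif(model: AifModel, cfg: AcquisitionConfig) -> np.ndarray:
    """Sample the AIF enhancement curve on the acquisition time grid.

    The sampled curve is normalized so its maximum equals
    ``model.peak_enhancement`` exactly; all samples before the onset time are
    zero.
    """
    t = cfg.times_s
    if model.onset_time_s >= t[-1]:
        raise ValueError("aif-onset-out-of-range: onset beyond scan duration")
    raw = model.shape(t - model.onset_time_s)
    peak = raw.max()
    if peak <= 0:
        raise ValueError("aif-onset-out-of-range: no post-onset samples enhance")
    return model.peak_enhancement * raw / peak


class ToftsGrid:
    """Precomputed trapezoid-convolution machinery for one uniform-or-not time grid.

    The extravasation term of the Tofts model is the causal convolution
    integral of the plasma curve with an exponential; on the sample grid it is
    evaluated by the trapezoid rule, which reduces to a masked matrix-vector
    product reused across optimizer iterations.
    """

    def __init__(self, times_s: np.ndarray):
        t = np.asarray(times_s, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("need at least two sample times")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        self.times_s = t
        self.t_min = t / SECONDS_PER_MINUTE
        n = len(t)
        # lower-triangular lag matrix (minutes) and trapezoid weights for
        # integral 0..t_i:  row i weights samples j<=i
        lag = self.t_min[:, None] - self.t_min[None, :]
        self._lag = np.where(lag > 0, lag, 0.0)
        w = np.zeros((n, n))
        dt = np.diff(self.t_min)
        for i in range(1, n):
            w[i, : i + 1][:-1] += dt[:i] / 2.0
            w[i, 1 : i + 1] += dt[:i] / 2.0
        self._w = w

    def exp_conv(self, cp: np.ndarray, kep: float) -> np.ndarray:
        """Trapezoid-rule \\int_0^t cp(tau) exp(-kep (t - tau)) dtau (minutes)."""
        kern = np.exp(-kep * self._lag) * self._w
        return kern @ cp

    def forward(self, cp: np.ndarray, vp: float, ktrans: float, kep: float) -> np.ndarray:
        return vp * cp + ktrans * self.exp_conv(cp, kep)

    def forward_many(
        self, cp: np.ndarray, vp: np.ndarray, ktrans: np.ndarray, kep: np.ndarray
    ) -> np.ndarray:
        """Vectorized forward model for many voxels; returns (n_voxels, n_frames)."""
        vp = np.asarray(vp, float)
        ktrans = np.asarray(ktrans, float)
        kep = np.asarray(kep, float)
        out = np.empty((len(vp), len(cp)))
        # group identical kep values are rare; simple per-voxel loop on the
        # cached matrices keeps memory bounded
        for i in range(len(vp)):
            out[i] = vp[i] * cp + ktrans[i] * (np.exp(-kep[i] * self._lag) * self._w) @ cp
        return out


def tofts_forward(aif_curve, params: TissueParams, cfg) -> np.ndarray:
    """Forward two-compartment Tofts model on the acquisition grid.

    C_t(t) = vp * Cp(t) + Ktrans * \\int_0^t Cp(tau) exp(-kep (t-tau)) dtau,
    with the convolution evaluated by the trapezoid rule on the sample grid.
    Input and output are in relative-enhancement units (signal assumed linear
    in concentration).

    ``cfg`` may be an :class:`AcquisitionConfig`, a time axis in seconds, or a
    prebuilt :class:`ToftsGrid`.
    """
    cp = np.asarray(aif_curve, dtype=float)
    if isinstance(cfg, ToftsGrid):
        grid = cfg
    elif isinstance(cfg, AcquisitionConfig):
        grid = ToftsGrid(cfg.times_s)
    else:
        grid = ToftsGrid(np.asarray(cfg, dtype=float))
    if len(cp) != len(grid.times_s):
        raise ValueError("aif_curve length must match the time grid")
    if not isinstance(params, TissueParams):
        params = TissueParams(*params)
    return grid.forward(cp, params.vp, params.ktrans, params.kep)


@dataclass(frozen=True)
class PhantomGeometry:
    """Placement of tumor, low-BV blobs and artery on the voxel grid.

    The tumor is an ellipsoid; low-blood-volume regions are spheres clipped to
    the tumor; the artery is an axis-aligned box disjoint from the tumor.
    Coordinates are voxel indices.
    """

    shape: tuple[int, int, int] = (40, 40, 16)
    tumor_center: tuple[float, float, float] = (20.0, 20.0, 8.0)
    tumor_semiaxes: tuple[float, float, float] = (11.0, 11.0, 6.0)
    lbv_centers: tuple[tuple[float, float, float], ...] = ((15.0, 19.0, 8.0), (25.0, 24.0, 8.0))
    lbv_radii: tuple[float, ...] = (5.0, 4.5)
    artery_origin: tuple[int, int, int] = (2, 2, 2)
    artery_size: tuple[int, int, int] = (3, 3, 10)

    def masks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (tumor_mask, lbv_mask, artery_mask) boolean volumes."""
        nx, ny, nz = self.shape
        x, y, z = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        cx, cy, cz = self.tumor_center
        ax, ay, az = self.tumor_semiaxes
        tumor = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0
        lbv = np.zeros(self.shape, dtype=bool)
        for (bx, by, bz), r in zip(self.lbv_centers, self.lbv_radii):
            lbv |= (x - bx) ** 2 + (y - by) ** 2 + (z - bz) ** 2 <= r**2
        lbv &= tumor
        artery = np.zeros(self.shape, dtype=bool)
        ox, oy, oz = self.artery_origin
        sx, sy, sz = self.artery_size
        artery[ox : ox + sx, oy : oy + sy, oz : oz + sz] = True
        if (artery & tumor).any():
            raise ValueError("artery and tumor masks overlap")
        return tumor, lbv, artery


#: Reduced grid for quick pharmacokinetic round-trip checks (~800 tumor voxels).
SMALL_GEOMETRY = PhantomGeometry(
    shape=(24, 24, 12),
    tumor_center=(12.0, 12.0, 6.0),
    tumor_semiaxes=(7.0, 7.0, 4.0),
    lbv_centers=((10.0, 11.0, 6.0),),
    lbv_radii=(3.5,),
    artery_origin=(1, 1, 1),
    artery_size=(2, 2, 8),
)


@dataclass(frozen=True)
class ClassRanges:
    """Per-class sampling ranges for the voxelwise kinetic parameters.

    ``vp`` ranges for the two classes must be disjoint across the blood-volume
    threshold so voxel labels are known by construction.  ``ktrans`` (1/min)
    and ``ve`` (extravascular extracellular fraction) are drawn independently
    of class to add realistic curve-shape diversity; ``kep = ktrans / ve``.
    """

    lbv_vp: tuple[float, float] = (0.01, 0.05)
    hbv_vp: tuple[float, float] = (0.10, 0.25)
    ktrans: tuple[float, float] = (0.05, 0.5)
    ve: tuple[float, float] = (0.2, 0.5)

    def validate_against_threshold(self, bv_threshold_percent: float) -> None:
        thr_vp = bv_threshold_percent / 100.0
        if not (self.lbv_vp[1] < thr_vp <= self.hbv_vp[0]):
            raise ValueError(
                "LBV and HBV vp ranges must be disjoint across the BV threshold"
            )


@dataclass
class DceSeries:
    """A 4-D dynamic signal-intensity volume with its sampling geometry."""

    data: np.ndarray  # (x, y, z, t) signal intensities
    dt_seconds: float
    voxel_dims_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DceSeries.data must be 4-D (x, y, z, t)")
        if self.dt_seconds <= 0:
            raise ValueError("dt_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_seconds

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims_mm))


BACKGROUND_LABEL = -1


@dataclass
class PhantomTruth:
    """Ground truth carried alongside a generated phantom."""

    bv_percent: np.ndarray  # 3-D, NaN outside the tumor
    label_map: np.ndarray  # 3-D int8: 0 = c-LBV, 1 = c-HBV, -1 background
    vp: np.ndarray
    ktrans: np.ndarray
    kep: np.ndarray
    aif_curve: np.ndarray
    aif_onset_index: int
    bv_threshold_percent: float
    lbv_fraction: float
    seed: int

    def to_metadata(self) -> dict:
        return {
            "bv_threshold_percent": self.bv_threshold_percent,
            "lbv_fraction": self.lbv_fraction,
            "aif_onset_index": int(self.aif_onset_index),
            "seed": int(self.seed),
        }


def generate_phantom(
    acq: AcquisitionConfig = NATIVE_ACQUISITION,
    geometry: PhantomGeometry | None = None,
    ranges: ClassRanges | None = None,
    aif_model: AifModel | None = None,
    *,
    s0: float = 100.0,
    bv_threshold_percent: float = 7.6,
    seed: int | None = None,
) -> tuple[DceSeries, np.ndarray, np.ndarray, PhantomTruth]:
    """Generate a seeded synthetic DCE series with known voxelwise kinetics.

    Returns ``(series, tumor_mask, artery_mask, truth)``.  Tumor voxels carry
    Tofts-model enhancement scaled to signal units ``S(t) = S0 (1 + dS(t))``;
    artery voxels carry the AIF; everything sees additive Gaussian noise with
    standard deviation ``noise_sd_rel * S0``.  Kinetic parameters are drawn
    from a random stream that depends only on the seed and the geometry, so
    re-rendering the same phantom under a different acquisition dialect keeps
    the identical parameter maps and labels.
    """
    geometry = geometry or PhantomGeometry()
    ranges = ranges or ClassRanges()
    aif_model = aif_model or AifModel()
    ranges.validate_against_threshold(bv_threshold_percent)
    if seed is None:
        seed = acq.seed

    tumor, lbv_region, artery = geometry.masks()
    n_tumor = int(tumor.sum())
    lbv_in_tumor = lbv_region[tumor]  # boolean per tumor voxel, row-major order

    rng_par = np.random.default_rng([int(seed) % (2**31), 161])
    rng_noise = np.random.default_rng([int(seed) % (2**31), 14])

    vp_vox = np.empty(n_tumor)
    n_lbv = int(lbv_in_tumor.sum())
    vp_vox[lbv_in_tumor] = rng_par.uniform(*ranges.lbv_vp, size=n_lbv)
    vp_vox[~lbv_in_tumor] = rng_par.uniform(*ranges.hbv_vp, size=n_tumor - n_lbv)
    ktrans_vox = rng_par.uniform(*ranges.ktrans, size=n_tumor)
    ve_vox = rng_par.uniform(*ranges.ve, size=n_tumor)
    kep_vox = ktrans_vox / ve_vox

    aif_curve = generate_aif(aif_model, acq)
    grid = ToftsGrid(acq.times_s)
    tissue_ds = grid.forward_many(aif_curve, vp_vox, ktrans_vox, kep_vox)

    data = np.full(geometry.shape + (acq.n_frames,), s0, dtype=float)
    data[tumor] = s0 * (1.0 + tissue_ds)
    data[artery] = s0 * (1.0 + aif_curve)
    if acq.noise_sd_rel > 0:
        data += rng_noise.normal(0.0, acq.noise_sd_rel * s0, size=data.shape)

    bv = np.full(geometry.shape, np.nan)
    bv[tumor] = 100.0 * vp_vox
    labels = np.full(geometry.shape, BACKGROUND_LABEL, dtype=np.int8)
    labels[tumor] = np.where(bv[tumor] < bv_threshold_percent, 0, 1)

    vp_map = np.full(geometry.shape, np.nan)
    kt_map = np.full(geometry.shape, np.nan)
    kep_map = np.full(geometry.shape, np.nan)
    vp_map[tumor] = vp_vox
    kt_map[tumor] = ktrans_vox
    kep_map[tumor] = kep_vox

    onset_index = int(np.searchsorted(acq.times_s, aif_model.onset_time_s))
    truth = PhantomTruth(
        bv_percent=bv,
        label_map=labels,
        vp=vp_map,
        ktrans=kt_map,
        kep=kep_map,
        aif_curve=aif_curve,
        aif_onset_index=onset_index,
        bv_threshold_percent=bv_threshold_percent,
        lbv_fraction=n_lbv / n_tumor,
        seed=int(seed),
    )
    series = DceSeries(data=data, dt_seconds=acq.dt_seconds, voxel_dims_mm=acq.voxel_dims_mm)
    return series, tumor, artery, truth
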