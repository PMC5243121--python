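"""Configuration and end-to-end pipeline orchestration.

A :class:`PipelineConfig` carries every module default (window length,
blood-volume threshold, probability threshold, minimum subvolume size, SVM
hyperparameters, seeds, paths) and round-trips through YAML without loss.
:func:`run_pipeline` executes the development phase on a phantom or on files:
simulate/load -> preprocess -> features -> select -> classify -> subvolume,
returning a metrics report with a stage audit.  :func:`run_predict` is the
usage phase: it consumes a trained bundle and performs no PK fitting and no
training.
"""

from __future__ import annotations

import dataclasses
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as dio
from .classify import DEFAULT_C, DEFAULT_GAMMA
from .experiments import run_aif_sensitivity as _sensitivity_grid
from .model import SubvolumeModel, SubvolumeResults
from .phantom import AcquisitionConfig, generate_phantom
from .pk_model import DEFAULT_BV_THRESHOLD, fit_bv_map, label_by_bv
from .preprocess import Aif, extract_aif, resample_series, windows_from_series

__all__ = ["PipelineConfig", "run_pipeline", "run_predict", "run_aif_sensitivity"]


@dataclass
class PipelineConfig:
    """All pipeline defaults; serializable to/from a single YAML file."""

    # analysis parameters
    window_length: int = 32
    bv_threshold: float = DEFAULT_BV_THRESHOLD
    prob_threshold: float = 0.5
    min_volume_cc: float = 1.0
    connectivity: int = 26
    C: float = DEFAULT_C
    gamma: float = DEFAULT_GAMMA
    pca_k: int = 4
    feature_kind: str = "pca"  # 'pca' or 'wt'
    test_fraction: float = 0.3
    per_class_cap: int = 20000
    seed: int = 17
    # AIF estimation
    aif_top_fraction: float = 0.10
    aif_onset_fraction: float = 0.10
    aif_onset_index: int | None = None
    aif_peak: float | None = None
    # preprocessing
    resample_dt_out: float | None = None
    # phantom rendering (used when no series path is given)
    use_phantom: bool = True
    noise_sd_rel: float = 0.02
    label_source: str = "truth"  # 'truth' or 'pk'
    # paths (optional)
    series_path: str | None = None
    tumor_mask_path: str | None = None
    artery_mask_path: str | None = None
    labels_path: str | None = None
    out_dir: str | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_inputs(config: PipelineConfig):
    """Return (series, tumor_mask, artery_mask, labels_3d_or_None, truth_or_None, stages)."""
    stages = []
    if config.series_path:
        series = dio.load_series(config.series_path)
        tumor, _ = dio.load_volume(config.tumor_mask_path)
        tumor = tumor.astype(bool)
        artery = None
        if config.artery_mask_path:
            artery, _ = dio.load_volume(config.artery_mask_path)
            artery = artery.astype(bool)
        labels = None
        if config.labels_path:
            labels, _ = dio.load_volume(config.labels_path)
        stages.append("load")
        return series, tumor, artery, labels, None, stages
    if not config.use_phantom:
        raise ValueError("stage=load: no series_path given and use_phantom is false")
    acq = AcquisitionConfig(noise_sd_rel=config.noise_sd_rel, seed=config.seed)
    series, tumor, artery, truth = generate_phantom(
        acq, seed=config.seed, bv_threshold_percent=config.bv_threshold
    )
    stages.append("simulate")
    return series, tumor, artery, truth.label_map, truth, stages


def _aif_for(config: PipelineConfig, series, artery) -> Aif:
    if artery is None and (config.aif_onset_index is None or config.aif_peak is None):
        raise ValueError("stage=aif: need an artery mask or explicit onset/peak")
    if artery is None:
        # fully manual AIF: synthesize a placeholder curve peaking at the peak
        curve = np.zeros(series.n_frames)
        curve[config.aif_onset_index :] = config.aif_peak
        return Aif(curve=curve, onset_index=config.aif_onset_index,
                   peak_enhancement=config.aif_peak)
    return extract_aif(
        series,
        artery,
        top_fraction=config.aif_top_fraction,
        onset_fraction=config.aif_onset_fraction,
        onset_index=config.aif_onset_index,
        peak_enhancement=config.aif_peak,
    )


def run_pipeline(config: PipelineConfig, mode: str | None = None) -> dict:
    """Development phase: train and evaluate the subvolume classifier.

    Returns a JSON-ready report with metrics and the executed-stage audit.
    Any stage failure raises with a stage-tagged message.
    """
    mode = mode or config.feature_kind
    if mode not in ("wt", "pca"):
        raise ValueError("mode must be 'wt' or 'pca'")
    series, tumor, artery, labels, truth, stages = _load_inputs(config)

    if config.resample_dt_out:
        series = resample_series(series, config.resample_dt_out)
        stages.append("resample")

    try:
        aif = _aif_for(config, series, artery)
    except ValueError as err:
        raise ValueError(f"stage=aif: {err}") from err
    stages.append("aif")

    if labels is None or config.label_source == "pk":
        # PK reference path: fit the Tofts model voxelwise, derive BV, label
        full = windows_from_series(series, tumor, aif, window_length=config.window_length)
        bv = fit_bv_map(
            full.values,
            aif.curve[aif.onset_index : aif.onset_index + config.window_length]
            / aif.peak_enhancement,
            np.arange(config.window_length) * series.dt_seconds,
            full.voxel_indices,
            tumor.shape,
        )
        labels = label_by_bv(bv.bv_percent, config.bv_threshold)
        stages.append("pk_fit")

    try:
        model = SubvolumeModel.from_series(
            series, tumor, aif, labels,
            window_length=config.window_length,
            feature_kind=mode,
            n_components=config.pca_k,
            C=config.C,
            gamma=config.gamma,
            prob_threshold=config.prob_threshold,
        )
    except ValueError as err:
        raise ValueError(f"stage=preprocess: {err}") from err
    stages += ["preprocess", "features", "select", "train"]
    results = model.fit(
        test_fraction=config.test_fraction,
        seed=config.seed,
        per_class_cap=config.per_class_cap,
    )
    stages.append("classify")

    metrics = results.evaluate(
        labels, min_volume_cc=config.min_volume_cc, connectivity=config.connectivity
    )
    stages.append("subvolume")

    report = {
        "mode": mode,
        "seed": config.seed,
        "stages": stages,
        "holdout_accuracy_pct": results.holdout_accuracy,
        "selected_features": list(results.selected_features),
        **metrics,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dio.save_json(report, out / f"metrics_{mode}.json")
        dio.save_model_bundle(results, out / f"bundle_{mode}")
        pm = results.probability_map()
        dio.save_volume(pm.values, series.voxel_dims_mm, out / f"prob_{mode}.nii.gz")
        sv = results.extract_subvolume(
            min_volume_cc=config.min_volume_cc, connectivity=config.connectivity
        )
        dio.save_volume(sv.mask, series.voxel_dims_mm, out / f"slbv_{mode}.nii.gz")
    report["_results"] = results  # in-memory handle; stripped before serialization
    return report


def run_predict(
    config: PipelineConfig,
    results: SubvolumeResults,
) -> dict:
    """Usage phase: classify new data with a trained model.

    Performs no PK fitting and no SVM training; the stage audit in the
    returned report proves it.
    """
    series, tumor, artery, labels, truth, stages = _load_inputs(config)
    if config.resample_dt_out:
        series = resample_series(series, config.resample_dt_out)
        stages.append("resample")
    aif = _aif_for(config, series, artery)
    stages.append("aif")
    win = windows_from_series(series, tumor, aif, window_length=config.window_length)
    stages += ["preprocess", "features", "predict"]
    proba = results.predict_proba(win.values)
    from . import subvolume as sv_mod
    from .classify import assign_labels

    pm = sv_mod.assemble_map(proba, win.voxel_indices, tumor, voxel_dims_mm=series.voxel_dims_mm)
    sv = sv_mod.extract_subvolume(
        pm, threshold=config.prob_threshold,
        min_volume_cc=config.min_volume_cc, connectivity=config.connectivity,
    )
    stages.append("subvolume")
    report = {
        "stages": stages,
        "n_classified": int(len(proba)),
        "slbv_voxels": sv.n_voxels,
        "slbv_volume_cc": sv.volume_cc,
    }
    if labels is not None:
        ref = np.asarray(labels)[tuple(win.voxel_indices.T)]
        yhat = assign_labels(proba, config.prob_threshold)
        report["accuracy_pct"] = float(100.0 * np.mean(yhat == ref))
    return report


def run_aif_sensitivity(config: PipelineConfig, results: SubvolumeResults, **kwargs):
    """AIF-perturbation experiment wired from a config (phantom inputs)."""
    series, tumor, artery, labels, truth, _ = _load_inputs(config)
    aif = _aif_for(config, series, artery)
    return _sensitivity_grid(
        results, series, tumor, aif, labels,
        window_length=config.window_length, **kwargs,
    )
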