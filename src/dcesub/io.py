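"""NIfTI and JSON I/O plus model-bundle persistence.

NIfTI is the sole imaging format: 4-D series carry the frame spacing in the
header's fourth zoom, masks and maps are 3-D volumes on the same grid.  A
trained pipeline is persisted as a directory bundle — JSON metadata next to a
joblib blob with the fitted scaler/SVM/feature state.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import nibabel as nib
import numpy as np

from .phantom import DceSeries

__all__ = [
    "save_series",
    "load_series",
    "save_volume",
    "load_volume",
    "save_json",
    "save_model_bundle",
    "load_model_bundle",
]


def _affine(voxel_dims_mm) -> np.ndarray:
    return np.diag(list(voxel_dims_mm) + [1.0])


def save_series(series: DceSeries, path) -> None:
    img = nib.Nifti1Image(np.asarray(series.data, dtype=np.float32), _affine(series.voxel_dims_mm))
    img.header.set_zooms(tuple(series.voxel_dims_mm) + (series.dt_seconds,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_series(path) -> DceSeries:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    if len(zooms) < 4 or zooms[3] <= 0:
        raise ValueError("series NIfTI must carry the frame spacing in its 4th zoom")
    return DceSeries(
        data=np.asanyarray(img.dataobj).astype(float),
        dt_seconds=float(zooms[3]),
        voxel_dims_mm=tuple(float(z) for z in zooms[:3]),
    )


def save_volume(volume: np.ndarray, voxel_dims_mm, path) -> None:
    vol = np.asarray(volume)
    if vol.dtype == bool:
        vol = vol.astype(np.uint8)
    else:
        vol = vol.astype(np.float32)
    nib.save(nib.Nifti1Image(vol, _affine(voxel_dims_mm)), str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asanyarray(img.dataobj), tuple(float(z) for z in zooms)


def save_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)!r}")


def save_model_bundle(results, path) -> None:
    """Persist a fitted :class:`~dcesub.model.SubvolumeResults` as a bundle dir."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    m = results.model
    meta = {
        "feature_kind": m.feature_kind,
        "selected_features": list(results.selected_features),
        "C": m.C,
        "gamma": m.gamma,
        "prob_threshold": m.prob_threshold,
        "seed": results.seed,
        "holdout_accuracy_pct": results.holdout_accuracy,
        "n_train": int(len(results.train_idx)),
        "n_test": int(len(results.test_idx)),
    }
    save_json(meta, path / "meta.json")
    joblib.dump(
        {"classifier": results.classifier, "transform_state": results.transform_state,
         "prob_threshold": m.prob_threshold},
        path / "model.joblib",
    )


def load_model_bundle(path) -> dict:
    """Load a bundle: {'classifier', 'transform_state', 'prob_threshold', 'meta'}."""
    path = Path(path)
    blob = joblib.load(path / "model.joblib")
    with open(path / "meta.json") as fh:
        blob["meta"] = json.load(fh)
    return blob
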