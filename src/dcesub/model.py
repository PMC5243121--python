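"""Model/Results objects tying the pipeline together.

:class:`SubvolumeModel` holds preprocessed 32-point windows and their
low/high blood-volume labels; :meth:`SubvolumeModel.fit` performs the
train/validation split, feature extraction (Haar coefficients with CFS
subset selection, or PCA projections with top-k selection), SVM training,
and held-out evaluation, returning a :class:`SubvolumeResults` that can
predict on new windows, assemble probability maps, extract subvolumes, and
score itself against a reference label map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify, features, select, subvolume
from .classify import HBV_CLASS, LBV_CLASS, TrainedClassifier
from .phantom import DceSeries
from .preprocess import Aif, NormalizedWindows, windows_from_series

__all__ = ["SubvolumeModel", "SubvolumeResults"]


class SubvolumeModel:
    """Low-blood-volume voxel classifier over temporal DCE features.

    Parameters
    ----------
    windows : array (n_voxels, 32)
        Normalized, onset-aligned enhancement windows.
    labels : array (n_voxels,)
        Binary labels: 0 = c-LBV, 1 = c-HBV.
    feature_kind : {"pca", "wt"}
        PCA projections onto the leading components, or Haar coefficients
        with CFS subset selection.
    n_components : int
        Number of leading principal components kept (PCA mode).
    feature_indices : sequence of int, optional
        Fixed 0-based Haar coefficient columns; bypasses the CFS search
        (WT mode only).
    search : {"best_first", "greedy"}
        CFS search strategy when ``feature_indices`` is not given.
    """

    def __init__(
        self,
        windows: np.ndarray,
        labels: np.ndarray,
        *,
        feature_kind: str = "pca",
        n_components: int = 4,
        feature_indices: Sequence[int] | None = None,
        search: str = "best_first",
        C: float = classify.DEFAULT_C,
        gamma: float = classify.DEFAULT_GAMMA,
        prob_threshold: float = 0.5,
        voxel_indices: np.ndarray | None = None,
        grid_shape: tuple[int, int, int] | None = None,
        voxel_dims_mm: tuple[float, float, float] | None = None,
    ):
        self.windows = np.asarray(windows, dtype=float)
        self.labels = np.asarray(labels)
        if self.windows.ndim != 2:
            raise ValueError("windows must be (n_voxels, window_length)")
        if len(self.labels) != len(self.windows):
            raise ValueError("labels must align with windows")
        if feature_kind not in ("pca", "wt"):
            raise ValueError("feature_kind must be 'pca' or 'wt'")
        if search not in ("best_first", "greedy"):
            raise ValueError("search must be 'best_first' or 'greedy'")
        self.feature_kind = feature_kind
        self.n_components = int(n_components)
        self.feature_indices = None if feature_indices is None else tuple(feature_indices)
        self.search = search
        self.C = C
        self.gamma = gamma
        self.prob_threshold = prob_threshold
        self.voxel_indices = voxel_indices
        self.grid_shape = grid_shape
        self.voxel_dims_mm = voxel_dims_mm

    @classmethod
    def from_series(
        cls,
        series: DceSeries,
        tumor_mask: np.ndarray,
        aif: Aif,
        labels_3d: np.ndarray,
        *,
        window_length: int = 32,
        **kwargs,
    ) -> "SubvolumeModel":
        """Preprocess a 4-D series and build the model from its tumor voxels.

        ``labels_3d`` is a 3-D label map (0/1 inside the tumor); labels are
        gathered at the surviving preprocessed voxel positions.
        """
        win = windows_from_series(series, tumor_mask, aif, window_length=window_length)
        idx = win.voxel_indices
        y = np.asarray(labels_3d)[tuple(idx.T)]
        return cls(
            win.values,
            y,
            voxel_indices=idx,
            grid_shape=np.asarray(tumor_mask).shape,
            voxel_dims_mm=tuple(series.voxel_dims_mm),
            **kwargs,
        )

    # feature extraction given a fitted transform state -------------------
    def _fit_transform_state(self, train_windows, train_labels):
        if self.feature_kind == "pca":
            basis = features.fit_pca(train_windows)
            k = select.select_top_pcs(basis, self.n_components)[-1]
            return {"kind": "pca", "basis": basis, "k": k}
        coeffs = features.haar_full(train_windows)
        if self.feature_indices is not None:
            subset = select.FeatureSubset(
                indices=tuple(self.feature_indices),
                merit=select.cfs_merit(coeffs, train_labels, self.feature_indices),
            )
        elif self.search == "greedy":
            subset = select.greedy_forward_search(coeffs, train_labels)
        else:
            subset = select.best_first_search(coeffs, train_labels)
        return {"kind": "wt", "subset": subset}

    @staticmethod
    def _transform(state, windows) -> np.ndarray:
        if state["kind"] == "pca":
            return features.project_pca(windows, state["basis"], state["k"])
        coeffs = features.haar_full(windows)
        return coeffs[:, list(state["subset"].indices)]

    def fit(
        self,
        *,
        test_fraction: float = 0.3,
        seed: int = 0,
        per_class_cap: int = classify.DEFAULT_PER_CLASS_CAP,
    ) -> "SubvolumeResults":
        """Split at curve level, extract features, train and evaluate the SVM."""
        if not 0.0 < test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        rng = np.random.default_rng(seed)
        n = len(self.windows)
        test_sel = np.zeros(n, dtype=bool)
        for cls_val in np.unique(self.labels):
            idx = np.flatnonzero(self.labels == cls_val)
            n_test = int(round(test_fraction * len(idx)))
            test_sel[rng.choice(idx, size=n_test, replace=False)] = True
        train_idx = np.flatnonzero(~test_sel)
        test_idx = np.flatnonzero(test_sel)

        state = self._fit_transform_state(self.windows[train_idx], self.labels[train_idx])
        x_train = self._transform(state, self.windows[train_idx])
        x_test = self._transform(state, self.windows[test_idx])
        clf = classify.train_svm(
            x_train,
            self.labels[train_idx],
            C=self.C,
            gamma=self.gamma,
            seed=seed,
            per_class_cap=per_class_cap,
        )
        p_test = clf.predict_proba(x_test)
        yhat_test = classify.assign_labels(p_test, self.prob_threshold)
        holdout_acc = subvolume.voxel_accuracy(yhat_test, self.labels[test_idx])

        all_proba = clf.predict_proba(self._transform(state, self.windows))
        return SubvolumeResults(
            model=self,
            classifier=clf,
            transform_state=state,
            train_idx=train_idx,
            test_idx=test_idx,
            holdout_accuracy=holdout_acc,
            all_proba=all_proba,
            seed=int(seed),
        )


@dataclass
class SubvolumeResults:
    """Fitted pipeline: classifier, selected features, held-out performance."""

    model: SubvolumeModel
    classifier: TrainedClassifier
    transform_state: dict
    train_idx: np.ndarray
    test_idx: np.ndarray
    holdout_accuracy: float  # percent
    all_proba: np.ndarray  # P(c-LBV) for every model voxel
    seed: int

    # ---- feature bookkeeping -------------------------------------------
    @property
    def selected_features(self) -> tuple[int, ...]:
        """0-based selected feature columns (Haar) or PC indices (PCA, 1-based)."""
        if self.transform_state["kind"] == "pca":
            return tuple(range(1, self.transform_state["k"] + 1))
        return self.transform_state["subset"].indices

    @property
    def feature_subset(self):
        return self.transform_state.get("subset")

    @property
    def pca_basis(self):
        return self.transform_state.get("basis")

    # ---- prediction on new data ----------------------------------------
    def transform(self, windows: np.ndarray) -> np.ndarray:
        return SubvolumeModel._transform(self.transform_state, np.asarray(windows, float))

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        return self.classifier.predict_proba(self.transform(windows))

    def predict_labels(self, windows: np.ndarray) -> np.ndarray:
        return classify.assign_labels(self.predict_proba(windows), self.model.prob_threshold)

    # ---- spatial products ----------------------------------------------
    def _require_spatial(self):
        m = self.model
        if m.voxel_indices is None or m.grid_shape is None or m.voxel_dims_mm is None:
            raise ValueError(
                "spatial outputs need voxel_indices/grid_shape/voxel_dims_mm; "
                "build the model with from_series"
            )

    def probability_map(self, mask: np.ndarray | None = None) -> subvolume.ProbabilityMap:
        self._require_spatial()
        m = self.model
        if mask is None:
            mask = np.zeros(m.grid_shape, dtype=bool)
            mask[tuple(m.voxel_indices.T)] = True
        return subvolume.assemble_map(
            self.all_proba, m.voxel_indices, mask, voxel_dims_mm=m.voxel_dims_mm
        )

    def extract_subvolume(
        self, *, min_volume_cc: float = 1.0, connectivity: int = 26
    ) -> subvolume.SubvolumeMask:
        return subvolume.extract_subvolume(
            self.probability_map(),
            threshold=self.model.prob_threshold,
            min_volume_cc=min_volume_cc,
            connectivity=connectivity,
        )

    def evaluate(
        self,
        reference_labels_3d: np.ndarray,
        *,
        min_volume_cc: float = 1.0,
        connectivity: int = 26,
    ) -> dict:
        """Accuracy over all voxels plus Dice of s-LBV and of the correct mask.

        The minimum-size filter is applied symmetrically to the predicted and
        the reference low-BV masks.  The LBV+HBV Dice compares the mask of
        correctly classified voxels with the full tumor mask.
        """
        self._require_spatial()
        m = self.model
        ref = np.asarray(reference_labels_3d)[tuple(m.voxel_indices.T)]
        yhat = classify.assign_labels(self.all_proba, m.prob_threshold)
        acc = subvolume.voxel_accuracy(yhat, ref)

        pred_sv = self.extract_subvolume(min_volume_cc=min_volume_cc, connectivity=connectivity)
        covered = np.zeros(m.grid_shape, dtype=bool)
        covered[tuple(m.voxel_indices.T)] = True
        ref_lbv = subvolume.assemble_map(
            (ref == LBV_CLASS).astype(float), m.voxel_indices, covered,
            voxel_dims_mm=m.voxel_dims_mm,
        )
        ref_sv = subvolume.extract_subvolume(
            ref_lbv, threshold=0.5, min_volume_cc=min_volume_cc, connectivity=connectivity
        )
        dsc_lbv = subvolume.dice(pred_sv, ref_sv)

        tumor = np.zeros(m.grid_shape, dtype=bool)
        tumor[tuple(m.voxel_indices.T)] = True
        correct = np.zeros(m.grid_shape, dtype=bool)
        correct[tuple(m.voxel_indices[yhat == ref].T)] = True
        dsc_correct = subvolume.dice(correct, tumor)

        n_tumor = int(tumor.sum())
        return {
            "accuracy_pct": acc,
            "dice_slbv": dsc_lbv,
            "dice_lbv_plus_hbv": dsc_correct,
            "slbv_fraction_pct": 100.0 * pred_sv.n_voxels / n_tumor,
            "n_voxels": n_tumor,
            "slbv_volume_cc": pred_sv.volume_cc,
        }

    # ---- reporting ------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        kind = "PCA projections" if m.feature_kind == "pca" else "Haar coefficients"
        if m.feature_kind == "pca":
            feat_line = f"first {self.transform_state['k']} principal components"
        else:
            sub = self.transform_state["subset"]
            feat_line = (
                f"coefficients {sub.coefficient_numbers} (CFS merit {sub.merit:.3f})"
            )
        n_tr, n_te = len(self.train_idx), len(self.test_idx)
        lines = [
            "Low-blood-volume subvolume classifier",
            "=" * 52,
            f"{'features':<22}{kind}",
            f"{'selected':<22}{feat_line}",
            f"{'SVM':<22}RBF, C={m.C:g}, gamma={m.gamma:g}",
            f"{'training curves':<22}{n_tr}",
            f"{'validation curves':<22}{n_te}",
            f"{'split seed':<22}{self.seed}",
            "-" * 52,
            f"{'held-out accuracy':<22}{self.holdout_accuracy:.1f}%",
            "=" * 52,
        ]
        return "\n".join(lines)
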