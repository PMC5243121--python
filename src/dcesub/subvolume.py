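"""Probability/label map assembly, subvolume extraction, and overlap metrics.

Classified voxel probabilities are scattered back into the 3-D tumor grid,
binarized at a strict probability threshold, and grouped into connected
components (26-neighborhood by default).  Components smaller than a minimum
physical volume (1 cc by default, the clinical-trial criterion) are discarded;
what survives is the low-blood-volume subvolume s-LBV.  Agreement with a
reference segmentation is quantified by voxelwise accuracy and the Dice
similarity coefficient 2|G∩R| / (|G|+|R|).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ProbabilityMap",
    "SubvolumeMask",
    "assemble_map",
    "extract_subvolume",
    "voxel_accuracy",
    "dice",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class ProbabilityMap:
    """3-D posterior P(c-LBV): values in [0,1] inside the mask, NaN elsewhere."""

    values: np.ndarray
    voxel_dims_mm: tuple[float, float, float]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims_mm))


@dataclass
class SubvolumeMask:
    """Binary subvolume after minimum-size filtering, with component inventory."""

    mask: np.ndarray  # boolean 3-D
    voxel_dims_mm: tuple[float, float, float]
    components: pd.DataFrame  # columns: component, n_voxels, volume_cc, retained

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cc(self) -> float:
        return self.n_voxels * float(np.prod(self.voxel_dims_mm)) / 1000.0


def assemble_map(
    values,
    voxel_indices,
    mask,
    *,
    voxel_dims_mm=(1.0, 1.0, 1.0),
) -> ProbabilityMap:
    """Scatter per-voxel values into the 3-D grid defined by ``mask``.

    In-mask voxels not covered by ``voxel_indices`` (preprocessing exclusions)
    stay NaN; an index outside the mask is an error.
    """
    mask = np.asarray(mask, dtype=bool)
    values = np.asarray(values, dtype=float)
    idx = np.asarray(voxel_indices)
    if idx.ndim != 2 or idx.shape[1] != 3:
        raise ValueError("voxel_indices must be (n, 3)")
    if len(values) != len(idx):
        raise ValueError("values and voxel_indices must align")
    ix = tuple(idx.T)
    if not mask[ix].all():
        raise ValueError("voxel index outside the mask")
    out = np.full(mask.shape, np.nan)
    out[ix] = values
    return ProbabilityMap(values=out, voxel_dims_mm=tuple(voxel_dims_mm))


def extract_subvolume(
    prob_map,
    *,
    voxel_dims_mm=None,
    threshold: float = 0.5,
    min_volume_cc: float = 1.0,
    connectivity: int = 26,
) -> SubvolumeMask:
    """Binarize, group into connected components, and apply the 1-cc filter.

    ``prob_map`` is a :class:`ProbabilityMap` or a bare 3-D array (then
    ``voxel_dims_mm`` is required).  Binarization is strict (> threshold);
    NaN counts as below threshold.  Components whose physical volume
    ``n_voxels * voxel_volume`` falls below ``min_volume_cc`` are removed.
    """
    if isinstance(prob_map, ProbabilityMap):
        values = prob_map.values
        dims = prob_map.voxel_dims_mm
    else:
        values = np.asarray(prob_map, dtype=float)
        if voxel_dims_mm is None:
            raise ValueError("voxel_dims_mm required for a bare array")
        dims = tuple(voxel_dims_mm)
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    with np.errstate(invalid="ignore"):
        binary = values > threshold  # NaN -> False
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labeled, n_comp = ndimage.label(binary, structure=structure)
    vox_cc = float(np.prod(dims)) / 1000.0
    rows = []
    keep = np.zeros_like(binary)
    for comp in range(1, n_comp + 1):
        comp_mask = labeled == comp
        n_vox = int(comp_mask.sum())
        vol_cc = n_vox * vox_cc
        retained = vol_cc >= min_volume_cc
        if retained:
            keep |= comp_mask
        rows.append(
            {"component": comp, "n_voxels": n_vox, "volume_cc": vol_cc, "retained": retained}
        )
    inventory = pd.DataFrame(rows, columns=["component", "n_voxels", "volume_cc", "retained"])
    return SubvolumeMask(mask=keep, voxel_dims_mm=dims, components=inventory)


def voxel_accuracy(predicted, reference) -> float:
    """Percentage of voxels whose predicted label matches the reference."""
    p = np.asarray(predicted).ravel()
    r = np.asarray(reference).ravel()
    if p.shape != r.shape or len(p) == 0:
        raise ValueError("predicted and reference must have the same nonzero length")
    return 100.0 * float(np.mean(p == r))


def dice(g, r) -> float:
    """Dice similarity coefficient 2|G∩R| / (|G|+|R|) between binary masks.

    Both masks empty is undefined: returns NaN with a warning (a patient may
    simply have no subvolume surviving the size filter).
    """
    gm = g.mask if isinstance(g, SubvolumeMask) else np.asarray(g, dtype=bool)
    rm = r.mask if isinstance(r, SubvolumeMask) else np.asarray(r, dtype=bool)
    if gm.shape != rm.shape:
        raise ValueError("masks must share the same grid")
    denom = int(gm.sum()) + int(rm.sum())
    if denom == 0:
        warnings.warn("both masks are empty; Dice undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    return 2.0 * int((gm & rm).sum()) / denom
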