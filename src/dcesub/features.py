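"""Temporal feature extraction: Haar wavelet coefficients and PCA projections.

The Haar transform here follows the averaging convention: each step replaces a
pair (a, b) by the average (a+b)/2 and the half-difference (a-b)/2.  Applied
J = log2(N) times to an N-point window it yields one approximation coefficient
A_J — exactly the window mean, hence proportional to the area under the curve
divided by 2^J — and N-1 detail coefficients.  Coefficients are ordered
[A_J, D_J, D_{J-1}, ..., D_1] with each detail block time-ascending, so for
N = 32 the global indices are: #1 = A_5, #2 = D_5, #3-4 = D_4, #5-8 = D_3,
#9-16 = D_2, #17-32 = D_1 (1-based).  The orthonormal sqrt(2) variant is
available via ``ortho=True``; it differs per-coefficient by known diagonal
factors only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "haar_full",
    "haar_inverse",
    "haar_block_slices",
    "PcaBasis",
    "fit_pca",
    "project_pca",
    "reconstruct_pca",
]


def _check_dyadic(n: int) -> int:
    if n < 2 or (n & (n - 1)) != 0:
        raise ValueError("non-dyadic: window length must be a power of two")
    return int(np.log2(n))


def haar_block_slices(n: int) -> dict[str, slice]:
    """Slices of the coefficient vector for A_J and each detail level D_j."""
    j_max = _check_dyadic(n)
    out = {f"A_{j_max}": slice(0, 1)}
    start = 1
    for j in range(j_max, 0, -1):
        size = n >> j  # 2^(J-j)
        out[f"D_{j}"] = slice(start, start + size)
        start += size
    return out


def haar_full(window, *, ortho: bool = False) -> np.ndarray:
    """Full Haar analysis of a dyadic window (vectorized over leading axes).

    Returns coefficients ordered [A_J, D_J, ..., D_1], each detail block
    time-ascending.  Detail sign convention: d = (first - second) / 2.
    """
    x = np.asarray(window, dtype=float)
    _check_dyadic(x.shape[-1])
    c = 1.0 / np.sqrt(2.0) if ortho else 0.5
    approx = x
    details = []  # finest level first
    while approx.shape[-1] > 1:
        even = approx[..., 0::2]
        odd = approx[..., 1::2]
        details.append((even - odd) * c)
        approx = (even + odd) * c
    return np.concatenate([approx] + details[::-1], axis=-1)


def haar_inverse(coefficients, *, ortho: bool = False) -> np.ndarray:
    """Invert :func:`haar_full`; exact reconstruction up to roundoff."""
    w = np.asarray(coefficients, dtype=float)
    n = w.shape[-1]
    j_max = _check_dyadic(n)
    inv = np.sqrt(2.0) / 2.0 if ortho else 1.0
    approx = w[..., 0:1]
    start = 1
    for j in range(j_max, 0, -1):
        size = n >> j
        d = w[..., start : start + size]
        start += size
        out = np.empty(approx.shape[:-1] + (2 * size,), dtype=float)
        out[..., 0::2] = (approx + d) * inv
        out[..., 1::2] = (approx - d) * inv
        approx = out
    return approx


@dataclass
class PcaBasis:
    """Principal-component basis fitted to training windows.

    ``components`` rows are mutually orthonormal; ``explained_variance_ratio``
    is non-increasing.  Component signs are fixed deterministically: the
    largest-magnitude loading of each component is positive.
    """

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca(windows: np.ndarray) -> PcaBasis:
    """Fit a complete PCA basis (as many components as window points)."""
    x = np.asarray(windows, dtype=float)
    if x.ndim != 2:
        raise ValueError("windows must be a 2-D (n_samples, n_points) matrix")
    n, p = x.shape
    if n < p:
        raise ValueError("insufficient-samples: need at least as many samples as points")
    pca = PCA(n_components=p, svd_solver="full")
    pca.fit(x)
    comp = pca.components_.copy()
    for i in range(comp.shape[0]):
        j = int(np.argmax(np.abs(comp[i])))
        if comp[i, j] < 0:
            comp[i] = -comp[i]
    return PcaBasis(
        mean=pca.mean_.copy(),
        components=comp,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        explained_variance=pca.explained_variance_.copy(),
    )


def project_pca(windows, basis: PcaBasis, k: int | None = None) -> np.ndarray:
    """Project windows onto the first ``k`` principal components."""
    if k is None:
        k = basis.n_components
    if not 1 <= k <= basis.n_components:
        raise ValueError("k must lie in 1..n_components")
    x = np.asarray(windows, dtype=float)
    return (x - basis.mean) @ basis.components[:k].T


def reconstruct_pca(coefficients, basis: PcaBasis) -> np.ndarray:
    """Map projection coefficients back to curve space (mean + sum c_i u_i)."""
    c = np.asarray(coefficients, dtype=float)
    k = c.shape[-1]
    if k > basis.n_components:
        raise ValueError("more coefficients than components")
    return basis.mean + c @ basis.components[:k]
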