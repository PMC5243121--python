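"""Haar transform correctness (matrix oracle, reconstruction) and PCA basis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcesub.features import (
    fit_pca,
    haar_block_slices,
    haar_full,
    haar_inverse,
    project_pca,
    reconstruct_pca,
)


def haar_analysis_matrix(n: int) -> np.ndarray:
    """Independent oracle: explicit analysis matrix from block means.

    Row 0 is the global mean.  The detail coefficient i at scale level j is
    (mean of first half - mean of second half) / 2 over its length-2^j block,
    i.e. entries +-1/2^j on the block halves.
    """
    j_max = int(np.log2(n))
    rows = [np.full(n, 1.0 / n)]
    for j in range(j_max, 0, -1):
        block = 2**j
        for i in range(n // block):
            row = np.zeros(n)
            row[i * block : i * block + block // 2] = 1.0 / block
            row[i * block + block // 2 : (i + 1) * block] = -1.0 / block
            rows.append(row)
    return np.vstack(rows)


class TestHaar:
    def test_matches_matrix_oracle_on_seeded_windows(self):
        mat = haar_analysis_matrix(32)
        rng = np.random.default_rng(42)
        windows = rng.normal(size=(100, 32))
        expected = windows @ mat.T
        got = haar_full(windows)
        assert np.abs(got - expected).max() < 1e-10

    def test_constant_window_annihilates_details(self):
        out = haar_full(np.full(32, 3.7))
        assert out[0] == pytest.approx(3.7)
        np.testing.assert_allclose(out[1:], 0.0, atol=1e-14)

    def test_coefficient_layout(self):
        blocks = haar_block_slices(32)
        assert blocks["A_5"] == slice(0, 1)
        assert blocks["D_5"] == slice(1, 2)
        assert blocks["D_4"] == slice(2, 4)
        assert blocks["D_3"] == slice(4, 8)
        assert blocks["D_2"] == slice(8, 16)
        assert blocks["D_1"] == slice(16, 32)
        # one approximation coefficient + 31 details
        sizes = [s.stop - s.start for s in blocks.values()]
        assert sizes[0] == 1 and sum(sizes) == 32

    def test_approximation_equals_window_mean(self, rng):
        w = rng.normal(size=32)
        assert haar_full(w)[0] == pytest.approx(w.mean(), abs=1e-14)

    def test_detail_sign_convention(self):
        # d = (first - second) / 2 at the finest level
        w = np.zeros(32)
        w[0], w[1] = 4.0, 2.0
        out = haar_full(w)
        assert out[16] == pytest.approx(1.0)  # first D_1 coefficient

    @settings(max_examples=25, derandomize=True)
    @given(
        a=st.floats(-5, 5),
        b=st.floats(-5, 5),
        seed=st.integers(0, 1000),
    )
    def test_linearity(self, a, b, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=32), r.normal(size=32)
        lhs = haar_full(a * x + b * y)
        rhs = a * haar_full(x) + b * haar_full(y)
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_non_dyadic_rejected(self):
        with pytest.raises(ValueError, match="non-dyadic"):
            haar_full(np.zeros(30))

    def test_orthonormal_variant_matches_pywavelets(self):
        pywt = pytest.importorskip("pywt")
        rng = np.random.default_rng(9)
        x = rng.normal(size=32)
        ours = haar_full(x, ortho=True)
        dec = pywt.wavedec(x, "haar", level=5)
        ref = np.concatenate(dec)  # [A5, D5, D4, D3, D2, D1]
        # identical up to each detail level's sign convention
        assert np.abs(np.abs(ours) - np.abs(ref)).max() < 1e-10


class TestHaarInverse:
    def test_zero_coefficients_give_zero_window(self):
        np.testing.assert_array_equal(haar_inverse(np.zeros(32)), np.zeros(32))

    def test_approximation_only_gives_constant(self):
        coeff = np.zeros(32)
        coeff[0] = 2.5
        np.testing.assert_allclose(haar_inverse(coeff), 2.5, atol=1e-14)

    @pytest.mark.parametrize("ortho", [False, True])
    def test_perfect_reconstruction(self, ortho):
        rng = np.random.default_rng(2024)
        windows = rng.normal(size=(100, 32))
        back = haar_inverse(haar_full(windows, ortho=ortho), ortho=ortho)
        assert np.abs(back - windows).max() < 1e-10


class TestPca:
    def test_full_component_count_and_orthonormality(self, rng):
        basis = fit_pca(rng.normal(size=(200, 32)))
        assert basis.n_components == 32
        gram = basis.components @ basis.components.T
        assert np.abs(gram - np.eye(32)).max() < 1e-8
        assert np.all(np.diff(basis.explained_variance_ratio) <= 1e-12)
        assert basis.explained_variance_ratio.sum() <= 1 + 1e-8

    def test_rank_one_data(self, rng):
        u = rng.normal(size=32)
        u /= np.linalg.norm(u)
        t = rng.normal(size=(100, 1))
        x = 5.0 + t * u
        basis = fit_pca(x)
        assert basis.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)
        dot = abs(basis.components[0] @ u)
        assert dot == pytest.approx(1.0, abs=1e-10)

    def test_known_diagonal_covariance(self):
        # sampling check: explained-variance fractions track the eigenvalues
        rng = np.random.default_rng(11)
        var = np.linspace(10.0, 0.5, 32)
        x = rng.normal(size=(10_000, 32)) * np.sqrt(var)
        basis = fit_pca(x)
        expected = np.sort(var)[::-1] / var.sum()
        assert np.abs(basis.explained_variance_ratio - expected).max() < 0.02

    def test_insufficient_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="insufficient-samples"):
            fit_pca(rng.normal(size=(31, 32)))

    def test_projection_of_mean_is_zero(self, rng):
        basis = fit_pca(rng.normal(size=(100, 32)))
        np.testing.assert_allclose(project_pca(basis.mean, basis), 0.0, atol=1e-10)

    def test_projection_orthonormality(self, rng):
        basis = fit_pca(rng.normal(size=(100, 32)))
        probe = basis.mean + 2.0 * basis.components[0]
        coeff = project_pca(probe, basis)
        assert coeff[0] == pytest.approx(2.0, abs=1e-10)
        np.testing.assert_allclose(coeff[1:], 0.0, atol=1e-10)

    def test_full_reconstruction(self, rng):
        x = rng.normal(size=(64, 32))
        basis = fit_pca(x)
        back = reconstruct_pca(project_pca(x, basis), basis)
        assert np.abs(back - x).max() < 1e-10

    def test_projection_energy_identity(self, rng):
        x = rng.normal(size=(64, 32))
        basis = fit_pca(x)
        coeff = project_pca(x, basis)
        centered = x - basis.mean
        np.testing.assert_allclose(
            (coeff**2).sum(axis=1), (centered**2).sum(axis=1), rtol=1e-8
        )
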