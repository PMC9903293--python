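"""PCA and EMD decomposition/recomposition of measurement frames."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eitsep import (
    Frame, adjacent_protocol, emd_decompose, emd_recompose, frame_to_matrix,
    matrix_to_frame, pca_decompose, pca_recompose, separate_heart_emd,
    separate_heart_pca, separate_lung_emd, separate_lung_pca,
)
from eitsep.separation import _local_extrema, zero_crossings


def random_matrix(seed, shape=(13, 16)):
    return np.random.default_rng(seed).normal(size=shape)


class TestReshape:
    def test_columns_follow_injection_blocks(self, protocol):
        f = Frame(np.arange(208.0), protocol)
        X = frame_to_matrix(f)
        assert X.shape == (13, 16)
        for s in range(16):
            np.testing.assert_array_equal(X[:, s], np.arange(13) + 13 * s)

    def test_round_trip_is_exact(self, protocol):
        values = np.random.default_rng(0).normal(size=208)
        f = Frame(values, protocol)
        back = matrix_to_frame(frame_to_matrix(f), protocol)
        np.testing.assert_array_equal(back.values, values)

    def test_constant_frame_constant_matrix(self, protocol):
        X = frame_to_matrix(Frame(np.full(208, 3.5), protocol))
        assert np.all(X == 3.5)

    def test_wrong_length_rejected(self, protocol):
        with pytest.raises(ValueError):
            frame_to_matrix(np.zeros(207), protocol)


class TestPCA:
    def test_rank_one_input_single_significant_eigenvalue(self):
        X = np.outer(np.arange(1.0, 14.0), np.linspace(-1, 1, 16))
        d = pca_decompose(X)
        assert d.significant_components() == 1

    def test_column_centered_rank_bound(self):
        # 13 rows centered -> rank <= 12, so at most 12 significant components
        d = pca_decompose(random_matrix(1))
        assert d.significant_components() == 12

    def test_eigenvalues_match_svd_oracle(self):
        for seed in range(50):
            X = random_matrix(seed)
            d = pca_decompose(X)
            sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
            oracle = np.zeros(16)
            oracle[:sv.size] = sv ** 2 / (13 - 1)
            np.testing.assert_allclose(d.eigenvalues, oracle, atol=1e-9)

    def test_basis_orthonormal(self):
        d = pca_decompose(random_matrix(2))
        np.testing.assert_allclose(d.eigenvectors.T @ d.eigenvectors,
                                   np.eye(16), atol=1e-10)

    def test_sign_convention_deterministic(self):
        X = random_matrix(3)
        a = pca_decompose(X)
        b = pca_decompose(X.copy())
        np.testing.assert_array_equal(a.eigenvectors, b.eigenvectors)
        idx = np.abs(a.eigenvectors).argmax(axis=0)
        assert np.all(a.eigenvectors[idx, np.arange(16)] > 0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_unit_weight_recomposition_reproduces_input(self, seed):
        X = random_matrix(seed)
        d = pca_decompose(X)
        err = np.abs(pca_recompose(d) - X).max() / np.abs(X).max()
        assert err < 1e-10

    def test_zero_weights_give_column_means(self):
        X = random_matrix(4)
        d = pca_decompose(X)
        out = pca_recompose(d, np.zeros(16))
        np.testing.assert_allclose(out, np.tile(X.mean(axis=0), (13, 1)),
                                   atol=1e-12)

    def test_single_component_matches_svd_truncation_oracle(self):
        X = random_matrix(5)
        d = pca_decompose(X)
        w = np.zeros(16)
        w[0] = 1.0
        ours = pca_recompose(d, w)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank1 = s[0] * np.outer(U[:, 0], Vt[0]) + X.mean(axis=0)
        np.testing.assert_allclose(ours, rank1, atol=1e-10)

    def test_phantom_frame_concentrates_in_first_eight(self, frame6_2d):
        d = pca_decompose(frame_to_matrix(frame6_2d))
        assert d.explained_share()[7] > 0.95
        assert d.significant_components() == 12


class TestPCASeparation:
    def test_heart_separation_is_projection_under_fixed_basis(self, frame6_2d):
        # removing a component is a projection: recomposing the separated
        # matrix with the same basis and weights changes nothing. (Re-running
        # the full separation instead re-estimates the basis, where the
        # removed component's slot is taken by the next one, so the operator
        # chain removes successive components by construction.)
        X = frame_to_matrix(frame6_2d)
        d = pca_decompose(X)
        w = np.ones(16)
        w[3] = 0.0
        once = pca_recompose(d, w)
        centered = once - d.column_means
        twice = d.column_means + (centered @ d.eigenvectors * w) @ d.eigenvectors.T
        scale = np.abs(once).max()
        assert np.abs(twice - once).max() / scale < 1e-9

    def test_lung_gain_one_is_identity(self, frame6_2d):
        out = separate_lung_pca(frame6_2d, gain=1.0)
        scale = np.abs(frame6_2d.values).max()
        assert np.abs(out.values - frame6_2d.values).max() / scale < 1e-10

    def test_lung_gain_zero_equals_heart_separation(self, frame6_2d):
        np.testing.assert_allclose(separate_lung_pca(frame6_2d, gain=0.0).values,
                                   separate_heart_pca(frame6_2d).values,
                                   atol=1e-12)

    def test_removed_component_share_bounds_change(self, frame6_2d):
        # removing PC4 changes the frame by exactly that component's energy
        d = pca_decompose(frame_to_matrix(frame6_2d))
        out = separate_heart_pca(frame6_2d)
        removed = np.linalg.norm(frame6_2d.values - out.values) ** 2
        expect = (13 - 1) * d.eigenvalues[3]
        np.testing.assert_allclose(removed, expect, rtol=1e-8)

    def test_negative_gain_rejected(self, frame6_2d):
        with pytest.raises(ValueError):
            separate_lung_pca(frame6_2d, gain=-0.1)
        with pytest.raises(ValueError):
            separate_heart_pca(frame6_2d, component=17)


class TestEMD:
    def test_pure_tone_yields_one_dominant_imf(self):
        n = 208
        t = np.arange(n)
        x = np.sin(2 * np.pi * 8 * t / n)
        d = emd_decompose(x)
        assert d.n_imfs >= 1
        corr = np.corrcoef(d.imfs[0], x)[0, 1]
        assert corr > 0.99
        assert np.abs(d.residue).max() < 0.05 * np.abs(x).max()

    def test_two_tone_separation(self):
        n = 208
        t = np.arange(n)
        fast = np.sin(2 * np.pi * 20 * t / n)
        slow = np.sin(2 * np.pi * 2 * t / n)
        d = emd_decompose(fast + slow)
        assert d.n_imfs >= 2
        assert np.corrcoef(d.imfs[0], fast)[0, 1] > 0.95
        assert np.corrcoef(d.imfs[1], slow)[0, 1] > 0.95

    @given(st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_completeness(self, seed):
        rng = np.random.default_rng(seed)
        # smooth random signal with multiple scales
        t = np.linspace(0, 1, 208)
        x = sum(rng.normal() * np.sin(2 * np.pi * f * t + rng.uniform(0, 6))
                for f in (3, 11, 29))
        d = emd_decompose(x)
        recon = d.reconstruct()
        assert np.abs(recon - x).max() / np.abs(x).max() < 1e-8

    def test_imf_zero_crossing_extrema_property(self, frame6_2d):
        d = emd_decompose(frame6_2d.values)
        for imf in d.imfs:
            mx, mn = _local_extrema(imf)
            n_ext = mx.size + mn.size
            assert abs(n_ext - zero_crossings(imf)) <= 1

    def test_residue_nearly_monotone(self, frame6_2d):
        d = emd_decompose(frame6_2d.values)
        mx, mn = _local_extrema(d.residue)
        assert mx.size + mn.size < 3

    def test_monotone_input_returns_no_imfs(self):
        x = np.linspace(0, 5, 100)
        d = emd_decompose(x)
        assert d.n_imfs == 0
        np.testing.assert_array_equal(d.residue, x)

    def test_too_short_or_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            emd_decompose(np.arange(5.0))
        bad = np.ones(50)
        bad[3] = np.nan
        with pytest.raises(ValueError):
            emd_decompose(bad)

    def test_recompose_is_linear_summation(self, frame6_2d):
        d = emd_decompose(frame6_2d.values)
        rng = np.random.default_rng(11)
        w = rng.uniform(0, 2, d.n_imfs)
        ours = emd_recompose(d, w, residue_weight=0.5)
        oracle = 0.5 * d.residue + sum(wi * imf for wi, imf in zip(w, d.imfs))
        np.testing.assert_allclose(ours, oracle, atol=1e-12)


class TestEMDSeparation:
    def test_heart_output_plus_imf1_restores_input(self, frame6_2d):
        out = separate_heart_emd(frame6_2d)
        d = emd_decompose(frame6_2d.values)
        np.testing.assert_allclose(out.values + d.imfs[0], frame6_2d.values,
                                   atol=1e-10)

    def test_lung_gain_one_is_identity(self, frame6_2d):
        out = separate_lung_emd(frame6_2d, gain=1.0)
        scale = np.abs(frame6_2d.values).max()
        assert np.abs(out.values - frame6_2d.values).max() / scale < 1e-8

    def test_lung_gain_zero_equals_heart_separation(self, frame6_2d):
        np.testing.assert_allclose(separate_lung_emd(frame6_2d, gain=0.0).values,
                                   separate_heart_emd(frame6_2d).values,
                                   atol=1e-12)

    def test_negative_gain_rejected(self, frame6_2d):
        with pytest.raises(ValueError):
            separate_lung_emd(frame6_2d, gain=-1.0)
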