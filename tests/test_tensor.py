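import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import nervedti as nd
from nervedti.tensor import fit_dti_volume

from conftest import forward_signal


def _es(d1, d2, d3):
    return nd.EigenSystem(
        d1=d1, d2=d2, d3=d3,
        e1=np.array([1.0, 0, 0]), e2=np.array([0, 1.0, 0]), e3=np.array([0, 0, 1.0]),
    )


spd_triples = st.tuples(
    st.floats(0.05, 3.0), st.floats(0.05, 3.0), st.floats(0.05, 3.0)
)
rotations = st.builds(
    lambda a, b, c: Rotation.from_euler("xyz", [a, b, c]).as_matrix(),
    st.floats(0, np.pi), st.floats(0, np.pi), st.floats(0, np.pi),
)


class TestFitTensorLLS:
    def test_noiseless_round_trip_diagonal(self, scheme):
        sig = forward_signal([0.8, 0.4, 0.4], np.eye(3), scheme)
        t = nd.fit_tensor_lls(sig, scheme)
        np.testing.assert_allclose(
            [t.dxx, t.dyy, t.dzz], [0.8, 0.4, 0.4], rtol=1e-9
        )
        np.testing.assert_allclose([t.dxy, t.dxz, t.dyz], 0.0, atol=1e-9)
        assert t.s0 == pytest.approx(100.0, rel=1e-9)

    def test_flat_signals_give_zero_tensor(self, scheme):
        t = nd.fit_tensor_lls(np.full(scheme.n_meas, 100.0), scheme)
        np.testing.assert_allclose(t.as_matrix(), 0.0, atol=1e-12)
        assert t.s0 == pytest.approx(100.0)

    def test_isotropic_attenuation(self, scheme):
        sig = np.where(scheme.bvals > 0, 100 * np.exp(-1150 * 0.0005), 100.0)
        t = nd.fit_tensor_lls(sig, scheme)
        np.testing.assert_allclose(t.as_matrix(), 0.5 * np.eye(3), atol=1e-9)

    def test_nonpositive_signals_floored_with_warning(self, scheme):
        sig = forward_signal([0.8, 0.4, 0.4], np.eye(3), scheme)
        sig[5] = 0.0
        with pytest.warns(RuntimeWarning, match="floor"):
            t = nd.fit_tensor_lls(sig, scheme)
        assert t.n_floored == 1

    def test_all_zero_signals_error(self, scheme):
        with pytest.raises(ValueError, match="non-positive"):
            nd.fit_tensor_lls(np.zeros(scheme.n_meas), scheme)

    @given(triple=spd_triples, rot=rotations)
    def test_round_trip_any_spd_tensor(self, triple, rot):
        """Simulate -> fit recovers any positive-definite tensor exactly."""
        scheme = nd.default_scheme()
        evals = np.sort(np.array(triple))[::-1]
        sig = forward_signal(evals, rot, scheme)
        t = nd.fit_tensor_lls(sig, scheme)
        expected = rot @ np.diag(evals) @ rot.T
        np.testing.assert_allclose(t.as_matrix(), expected, atol=1e-8)


class TestRegionFit:
    def test_homogeneous_region_equals_single_voxel(self, scheme):
        sig = forward_signal([0.9, 0.5, 0.3], np.eye(3), scheme)
        data = np.tile(sig, (3, 3, 2, 1))
        dwi = nd.DWIVolume(data=data, voxel_size=(0.1, 0.1, 0.6), scheme=scheme)
        t_region = nd.fit_tensor_region(dwi, np.ones((3, 3, 2), bool))
        t_single = nd.fit_tensor_lls(sig, scheme)
        np.testing.assert_allclose(
            t_region.as_matrix(), t_single.as_matrix(), atol=1e-10
        )

    def test_mixed_s0_same_tensor_averages_s0(self, scheme):
        s1 = forward_signal([0.9, 0.5, 0.3], np.eye(3), scheme, s0=100.0)
        s2 = forward_signal([0.9, 0.5, 0.3], np.eye(3), scheme, s0=200.0)
        data = np.stack([s1, s2])[:, None, None, :]
        dwi = nd.DWIVolume(data=data, voxel_size=(0.1, 0.1, 0.6), scheme=scheme)
        t = nd.fit_tensor_region(dwi, np.ones((2, 1, 1), bool))
        np.testing.assert_allclose(np.diag(t.as_matrix()), [0.9, 0.5, 0.3], rtol=1e-9)
        assert t.s0 == pytest.approx(150.0, rel=1e-9)

    def test_empty_mask_rejected(self, scheme):
        data = np.ones((2, 2, 2, scheme.n_meas))
        dwi = nd.DWIVolume(data=data, voxel_size=(0.1, 0.1, 0.6), scheme=scheme)
        with pytest.raises(ValueError, match="empty"):
            nd.fit_tensor_region(dwi, np.zeros((2, 2, 2), bool))


class TestEigendecompose:
    def test_diagonal_tensor(self):
        t = nd.DiffusionTensor(0.9, 0.5, 0.3, 0, 0, 0, s0=1.0)
        es = nd.eigendecompose(t)
        np.testing.assert_allclose(es.eigenvalues, [0.9, 0.5, 0.3])
        np.testing.assert_allclose(es.e1, [1, 0, 0])

    def test_rotation_invariance_of_eigenvalues(self):
        rot = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        m = rot @ np.diag([0.9, 0.5, 0.3]) @ rot.T
        es = nd.eigendecompose(nd.DiffusionTensor.from_matrix(m, s0=1.0))
        np.testing.assert_allclose(es.eigenvalues, [0.9, 0.5, 0.3], atol=1e-10)

    def test_isotropic_degenerate(self):
        es = nd.eigendecompose(nd.DiffusionTensor.from_matrix(0.7 * np.eye(3), 1.0))
        np.testing.assert_allclose(es.eigenvalues, 0.7)
        # any orthonormal basis is acceptable
        np.testing.assert_allclose(
            es.eigenvectors @ es.eigenvectors.T, np.eye(3), atol=1e-8
        )

    @given(triple=spd_triples, rot=rotations)
    def test_reconstruction_and_orthonormality(self, triple, rot):
        m = rot @ np.diag(triple) @ rot.T
        es = nd.eigendecompose(nd.DiffusionTensor.from_matrix(m, s0=1.0))
        assert es.d1 >= es.d2 >= es.d3
        v = es.eigenvectors
        np.testing.assert_allclose(v @ v.T, np.eye(3), atol=1e-8)
        recon = sum(
            d * np.outer(e, e)
            for d, e in zip(es.eigenvalues, [es.e1, es.e2, es.e3])
        )
        np.testing.assert_allclose(recon, m, atol=1e-8)
        # deterministic sign: largest-magnitude component positive
        for e in (es.e1, es.e2, es.e3):
            assert e[np.argmax(np.abs(e))] > 0


class TestIndices:
    @pytest.mark.parametrize(
        "triple, md",
        [((0.77, 0.40, 0.37), 0.51), ((1.06, 0.74, 0.55), 0.78), ((1, 1, 1), 1.0)],
    )
    def test_md(self, triple, md):
        assert round(nd.compute_md(_es(*triple)), 2) == md

    @pytest.mark.parametrize(
        "triple, fa",
        [((0.77, 0.40, 0.37), 0.41), ((1, 0, 0), 1.0), ((0.7, 0.7, 0.7), 0.0)],
    )
    def test_fa(self, triple, fa):
        assert round(nd.compute_fa(_es(*triple)), 2) == fa

    @pytest.mark.parametrize(
        "triple, ratio",
        [((2, 1, 1), 2.0), ((0.6, 0.6, 0.6), 1.0), ((0.77, 0.40, 0.37), 2.0)],
    )
    def test_axial_radial_ratio(self, triple, ratio):
        assert nd.compute_axial_radial_ratio(_es(*triple)) == pytest.approx(
            ratio, abs=5e-3
        )

    def test_degenerate_radial_errors(self):
        with pytest.raises(ValueError, match="degenerate radial"):
            nd.compute_axial_radial_ratio(_es(1.0, 0.0, 0.0))

    def test_negative_eigenvalues_clamped(self):
        es = _es(0.5, 0.1, -0.2)
        assert 0 <= nd.compute_fa(es) <= 1
        idx = nd.compute_indices(es)
        assert idx.clamped
        assert idx.md == pytest.approx((0.5 + 0.1) / 3)

    def test_all_zero_fa_is_zero(self):
        assert nd.compute_fa(_es(0, 0, 0)) == 0.0

    @given(triple=spd_triples)
    def test_fa_bounds_and_isotropy(self, triple):
        fa = nd.compute_fa(_es(*triple))
        assert 0 <= fa <= 1
        if np.ptp(triple) < 1e-12:
            assert fa == pytest.approx(0.0, abs=1e-6)

    @given(triple=spd_triples, c=st.floats(0.1, 10.0))
    def test_scale_equivariance(self, triple, c):
        es, es_c = _es(*triple), _es(*(c * t for t in triple))
        assert nd.compute_md(es_c) == pytest.approx(c * nd.compute_md(es), rel=1e-9)
        assert nd.compute_fa(es_c) == pytest.approx(nd.compute_fa(es), rel=1e-6, abs=1e-9)
        assert nd.compute_axial_radial_ratio(es_c) == pytest.approx(
            nd.compute_axial_radial_ratio(es), rel=1e-9
        )

    @given(triple=spd_triples, rot=rotations)
    def test_rotation_invariance_of_indices(self, triple, rot):
        m = rot @ np.diag(triple) @ rot.T
        es_rot = nd.eigendecompose(nd.DiffusionTensor.from_matrix(m, s0=1.0))
        es_ref = _es(*np.sort(triple)[::-1])
        assert nd.compute_md(es_rot) == pytest.approx(nd.compute_md(es_ref), abs=1e-10)
        assert nd.compute_fa(es_rot) == pytest.approx(nd.compute_fa(es_ref), abs=1e-9)


class TestVolumeFit:
    def test_matches_scalar_path(self, scheme):
        rng = np.random.default_rng(3)
        shape = (4, 3, 2)
        data = np.empty((*shape, scheme.n_meas))
        for idx in np.ndindex(shape):
            evals = np.sort(rng.uniform(0.1, 1.5, 3))[::-1]
            rot = Rotation.random(rng=42 + idx[0]).as_matrix()
            data[idx] = forward_signal(evals, rot, scheme, s0=rng.uniform(50, 150))
        dwi = nd.DWIVolume(data=data, voxel_size=(0.1, 0.1, 0.6), scheme=scheme)
        maps = fit_dti_volume(dwi)
        for idx in np.ndindex(shape):
            es = nd.eigendecompose(nd.fit_tensor_lls(data[idx], scheme))
            np.testing.assert_allclose(maps["evals"][idx], es.eigenvalues, atol=1e-8)
            np.testing.assert_allclose(
                maps["fa"][idx], nd.compute_fa(es), atol=1e-8
            )

    def test_mask_fill_values(self, scheme):
        data = np.tile(forward_signal([0.8, 0.4, 0.4], np.eye(3), scheme), (2, 2, 1, 1))
        dwi = nd.DWIVolume(data=data, voxel_size=(0.1, 0.1, 0.6), scheme=scheme)
        mask = np.zeros((2, 2, 1), bool)
        mask[0, 0, 0] = True
        maps = fit_dti_volume(dwi, mask)
        assert np.isfinite(maps["fa"][0, 0, 0])
        assert np.isnan(maps["fa"][1, 1, 0])
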