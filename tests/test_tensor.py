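import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myotract.io import DWIVolume, LabelMask
from myotract.tensor import (
    color_fa_map,
    fit_tensor,
    fractional_anisotropy,
    measure_snr,
    principal_direction,
)

from .conftest import full_mask


def tensor_signal(gtab, D, s0=1000.0):
    """Forward single-tensor signal: the independent oracle for the LS fit."""
    b, g = gtab.bvals, gtab.bvecs
    quad = np.einsum("ni,ij,nj->n", g, D, g)
    return (s0 * np.exp(-b * quad)).reshape(1, 1, 1, -1)


class TestFit:
    def test_noise_free_tensor_recovered_exactly(self, gtab):
        """Least squares is exact on a consistent log-linear system."""
        D = np.diag([1.5e-3, 0.3e-3, 0.3e-3])
        dwi = DWIVolume(data=tensor_signal(gtab, D), affine=np.eye(4), gtab=gtab)
        tf = fit_tensor(dwi, full_mask(dwi))
        np.testing.assert_allclose(tf.tensors[0, 0, 0], D, rtol=0, atol=1.5e-13)
        assert np.abs(tf.tensors[0, 0, 0] - D).max() / np.abs(D).max() < 1e-10
        np.testing.assert_allclose(tf.s0_map[0, 0, 0], 1000.0, rtol=1e-10)

    def test_rotated_tensor_recovered(self, gtab):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((3, 3))
        Q, _ = np.linalg.qr(A)
        D = Q @ np.diag([1.5e-3, 0.5e-3, 0.2e-3]) @ Q.T
        dwi = DWIVolume(data=tensor_signal(gtab, D), affine=np.eye(4), gtab=gtab)
        tf = fit_tensor(dwi, full_mask(dwi))
        np.testing.assert_allclose(tf.tensors[0, 0, 0], D, atol=1e-12)

    def test_constant_signal_is_isotropic_with_zero_fa(self, gtab):
        dwi = DWIVolume(
            data=np.full((1, 1, 1, len(gtab)), 500.0), affine=np.eye(4), gtab=gtab
        )
        tf = fit_tensor(dwi, full_mask(dwi))
        assert tf.fa_map[0, 0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_masked_out_and_zero_voxels_flagged_invalid(self, gtab):
        data = np.zeros((2, 1, 1, len(gtab)))
        data[0] = 500.0
        dwi = DWIVolume(data=data, affine=np.eye(4), gtab=gtab)
        mask = LabelMask(data=np.array([[[1]], [[1]]]), affine=np.eye(4))
        tf = fit_tensor(dwi, mask)
        assert tf.valid_mask[0, 0, 0]
        assert not tf.valid_mask[1, 0, 0]  # all-zero signal, no exception
        assert tf.fa_map[1, 0, 0] == 0.0

    def test_rotation_equivariance(self, gtab):
        """Rotating gradients and tensor together leaves FA unchanged."""
        from myotract.io import GradientTable

        D = np.diag([1.5e-3, 0.5e-3, 0.2e-3])
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        dwi1 = DWIVolume(data=tensor_signal(gtab, D), affine=np.eye(4), gtab=gtab)
        g2 = GradientTable(
            bvals=gtab.bvals, bvecs=gtab.bvecs @ Q.T, b0_mask=gtab.b0_mask
        )
        dwi2 = DWIVolume(
            data=tensor_signal(g2, Q @ D @ Q.T), affine=np.eye(4), gtab=g2
        )
        fa1 = fit_tensor(dwi1, full_mask(dwi1)).fa_map[0, 0, 0]
        fa2 = fit_tensor(dwi2, full_mask(dwi2)).fa_map[0, 0, 0]
        assert fa1 == pytest.approx(fa2, abs=1e-8)


class TestFA:
    @pytest.mark.parametrize(
        "evals,expected",
        [
            ((1.0, 1.0, 1.0), 0.0),
            ((1.0, 0.0, 0.0), 1.0),
            ((2.0, 1.0, 1.0), 0.40825),  # sqrt(3/2)*sqrt(2/3)/sqrt(6)
        ],
    )
    def test_closed_forms(self, evals, expected):
        assert fractional_anisotropy(evals) == pytest.approx(expected, abs=1e-5)

    def test_zero_input_returns_zero(self):
        assert fractional_anisotropy((0.0, 0.0, 0.0)) == 0.0

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            fractional_anisotropy((1.0, -0.1, 0.0))

    @given(
        st.tuples(
            st.floats(0.01, 10.0), st.floats(0.01, 10.0), st.floats(0.01, 10.0)
        ),
        st.floats(0.1, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, evals, c):
        ev = np.asarray(evals)
        assert fractional_anisotropy(c * ev) == pytest.approx(
            fractional_anisotropy(ev), rel=1e-9
        )


class TestDirections:
    def _field(self, gtab, D):
        dwi = DWIVolume(data=tensor_signal(gtab, D), affine=np.eye(4), gtab=gtab)
        return fit_tensor(dwi, full_mask(dwi))

    def test_principal_direction_and_antipodal_representative(self, gtab):
        tf = self._field(gtab, np.diag([1.5e-3, 0.3e-3, 0.3e-3]))
        pd = principal_direction(tf, (0, 0, 0))
        np.testing.assert_allclose(np.abs(pd), [1, 0, 0], atol=1e-8)
        assert pd[0] > 0  # canonical sign

    def test_invalid_voxel_query_raises(self, gtab):
        dwi = DWIVolume(
            data=np.ones((1, 1, 1, len(gtab))), affine=np.eye(4), gtab=gtab
        )
        mask = LabelMask(data=np.zeros((1, 1, 1)), affine=np.eye(4))
        tf = fit_tensor(dwi, mask)
        with pytest.raises(KeyError):
            principal_direction(tf, (0, 0, 0))

    def test_color_map_axis_conventions(self, gtab):
        # right-left fiber -> red only; cranio-caudal -> blue only
        tf_x = self._field(gtab, np.diag([1.5e-3, 0.3e-3, 0.3e-3]))
        rgb = color_fa_map(tf_x)[0, 0, 0]
        fa = tf_x.fa_map[0, 0, 0]
        np.testing.assert_allclose(rgb, [fa, 0, 0], atol=1e-6)
        tf_z = self._field(gtab, np.diag([0.3e-3, 0.3e-3, 1.5e-3]))
        rgb_z = color_fa_map(tf_z)[0, 0, 0]
        np.testing.assert_allclose(rgb_z, [0, 0, tf_z.fa_map[0, 0, 0]], atol=1e-6)
        swapped = color_fa_map(tf_x, convention="ap-red")[0, 0, 0]
        np.testing.assert_allclose(swapped, [0, fa, 0], atol=1e-6)

    def test_fa_zero_voxel_is_black(self, gtab):
        tf = self._field(gtab, np.diag([1e-3, 1e-3, 1e-3]))
        np.testing.assert_allclose(color_fa_map(tf)[0, 0, 0], 0.0, atol=1e-8)


class TestSNR:
    def _volumes(self, gtab, tissue_value, background):
        data = np.zeros((2, 1, 1, len(gtab)))
        data[0] = tissue_value
        data[1] = background[..., None] if np.ndim(background) else background
        dwi = DWIVolume(data=data, affine=np.eye(4), gtab=gtab)
        t = LabelMask(data=np.array([[[1]], [[0]]]), affine=np.eye(4))
        b = LabelMask(data=np.array([[[0]], [[1]]]), affine=np.eye(4))
        return dwi, t, b

    def test_plain_ratio(self, gtab):
        rng = np.random.default_rng(0)
        data = np.zeros((4, 4, 2, len(gtab)))
        data[:2] = 50.0
        noise = rng.normal(0, 1.0, (2, 4, 2, len(gtab)))
        data[2:] = noise
        dwi = DWIVolume(data=np.abs(data), affine=np.eye(4), gtab=gtab)
        tmask = np.zeros((4, 4, 2), dtype=int)
        tmask[:2] = 1
        bmask = np.zeros((4, 4, 2), dtype=int)
        bmask[2:] = 1
        t = LabelMask(data=tmask, affine=np.eye(4))
        b = LabelMask(data=bmask, affine=np.eye(4))
        snr = measure_snr(dwi, t, b, correction="none")
        assert snr == pytest.approx(50.0 / dwi.b0_image()[bmask > 0].std(), rel=1e-9)

    def test_zero_tissue_gives_zero(self, gtab):
        dwi, t, b = self._volumes(gtab, 0.0, 1.0)
        dwi.data[1, 0, 0, ::2] = 2.0  # nonzero background spread
        assert measure_snr(dwi, t, b, correction="none") == 0.0

    def test_zero_background_std_warns_and_returns_inf(self, gtab):
        dwi, t, b = self._volumes(gtab, 50.0, 1.0)
        with pytest.warns(UserWarning):
            assert np.isinf(measure_snr(dwi, t, b))


class TestWorldSpaceContract:
    def test_axis_permuted_storage_gives_same_world_maps(self, gtab):
        """Permuting the on-disk axis order (data + affine together) leaves
        world-space FA and principal directions unchanged."""
        from myotract.phantom import (
            PhantomSpec, bundle_mask, make_geometry, simulate_dwi,
        )

        spec = PhantomSpec(
            geometry_kind="straight", grid_shape=(16, 16, 8),
            geometry_params={"half_span": 8.0, "bundle_radius": 2.0}, seed=4,
        )
        truth = make_geometry(spec)
        dwi = simulate_dwi(truth, spec, gtab)
        mask = bundle_mask(truth)
        tf1 = fit_tensor(dwi, mask)

        perm = (1, 2, 0)
        data_p = np.transpose(dwi.data, perm + (3,))
        P = np.zeros((4, 4))
        P[3, 3] = 1.0
        for new_ax, old_ax in enumerate(perm):
            P[old_ax, new_ax] = 1.0
        affine_p = dwi.affine @ P
        dwi_p = DWIVolume(data=data_p, affine=affine_p, gtab=gtab)
        mask_p = LabelMask(data=np.transpose(mask.data, perm), affine=affine_p)
        tf2 = fit_tensor(dwi_p, mask_p)

        np.testing.assert_allclose(
            tf1.fa_map, np.transpose(tf2.fa_map, np.argsort(perm)), atol=1e-10
        )
        # principal directions are world vectors: identical up to antipodal sign
        for ijk in np.argwhere(mask.binary())[:20]:
            i, j, k = ijk
            v1 = tf1.eigenvectors[i, j, k, :, 0]
            v2 = tf2.eigenvectors[ijk[perm[0]], ijk[perm[1]], ijk[perm[2]], :, 0]
            assert abs(abs(v1 @ v2) - 1.0) < 1e-8
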