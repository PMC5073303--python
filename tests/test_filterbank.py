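"""Filter-bank construction and convolution contracts."""

import numpy as np
import pytest

from texton3d import filterbank as fb
from texton3d.exceptions import ConsistencyError, ParameterError

from conftest import brute_force_correlate


class TestKernelConstruction:
    def test_gaussian_unit_mass_and_symmetry(self):
        k = fb.make_gaussian_kernel((1, 1, 1), support=(4, 4, 4))
        assert k.values.sum() == pytest.approx(1.0, abs=1e-12)
        assert (k.values >= 0).all()
        for axis in range(3):
            assert np.allclose(k.values, np.flip(k.values, axis=axis))

    def test_gaussian_center_ratio_matches_formula(self):
        # value(center)/value(center+(2,0,0)) = exp(0.5*(2/2)^2) = e^0.5,
        # invariant under the L1 normalization
        k = fb.make_gaussian_kernel((2, 2, 2), support=(6, 6, 6))
        c = tuple(s // 2 for s in k.values.shape)
        ratio = k.values[c] / k.values[c[0] + 2, c[1], c[2]]
        assert ratio == pytest.approx(np.exp(0.5), rel=1e-12)

    def test_gaussian_rejects_bad_parameters(self):
        with pytest.raises(ParameterError):
            fb.make_gaussian_kernel((0, 1, 1))
        with pytest.raises(ParameterError):
            fb.make_gaussian_kernel((1, 1, 1), support=(0, 4, 4))

    def test_log_zero_sum_and_rotational_symmetry(self):
        k = fb.make_log_kernel(2.0, support=(6, 6, 6))
        assert abs(k.values.sum()) < 1e-10
        # isotropic: equal values at equal lattice radius
        c = k.values.shape[0] // 2
        vals = {}
        for p in [(1, 2, 2), (2, 1, 2), (2, 2, 1), (-1, 2, -2)]:
            vals[p] = k.values[c + p[0], c + p[1], c + p[2]]
        assert np.allclose(list(vals.values()), k.values[c + 1, c + 2, c + 2])

    def test_log_sign_change_near_sigma_sqrt3(self):
        # center negative, positive annulus; crossing near r = sigma*sqrt(3)
        sigma = 2.0
        k = fb.make_log_kernel(sigma, support=(8, 8, 8))
        c = k.values.shape[0] // 2
        assert k.values[c, c, c] < 0
        r_cross = sigma * np.sqrt(3)  # ~3.46
        assert k.values[c, c, c + 3] < 0  # just inside
        assert k.values[c, c, c + 4] > 0  # just outside

    def test_deriv1_antisymmetric_and_pi_negation(self):
        k0 = fb.make_oriented_derivative_kernel(1, (1, 1, 3), "z", 0.0)
        assert np.allclose(k0.values, -np.flip(k0.values, axis=2), atol=1e-15)
        kpi = fb.make_oriented_derivative_kernel(1, (1, 1, 3), "z", np.pi)
        assert np.allclose(kpi.values, -k0.values, atol=1e-12)

    def test_deriv2_symmetric_zero_sum(self):
        k = fb.make_oriented_derivative_kernel(2, (1, 1, 3), "y", 0.0)
        assert np.allclose(k.values, np.flip(k.values, axis=2), atol=1e-15)
        assert abs(k.values.sum()) < 1e-10

    def test_derivative_rejects_bad_axis_order(self):
        with pytest.raises(ParameterError):
            fb.make_oriented_derivative_kernel(3, (1, 1, 3), "z", 0.0)
        with pytest.raises(ParameterError):
            fb.make_oriented_derivative_kernel(1, (1, 1, 3), "w", 0.0)
        with pytest.raises(ParameterError):
            fb.make_oriented_derivative_kernel(1, (0, 1, 3), "z", 0.0)


class TestBankStructure:
    def test_default_bank_counts(self, default_bank):
        assert len(default_bank) == 110
        assert default_bank.n_channels == 20

    def test_channel_map_groups(self, default_bank):
        groups = default_bank.channel_groups()
        assert len(groups) == 20
        sizes = sorted(len(g) for g in groups)
        assert sizes == [1, 1] + [6] * 18

    @pytest.mark.parametrize(
        "n_orient,scales,expected",
        [(1, [(1, 1, 3)], 8), (6, [(1, 1, 3)], 38), (2, [(1, 1, 3), (2, 2, 6)], 26)],
    )
    def test_kernel_count_identity(self, n_orient, scales, expected):
        bank = fb.build_filter_bank(n_orient, scales, gauss_log_sigma=2)
        assert len(bank) == n_orient * len(scales) * 2 * 3 + 2 == expected

    def test_isotropic_bank_formula(self):
        assert fb.isotropic_bank_size() == 1298

    def test_all_derivative_kernels_zero_sum(self, default_bank):
        for k in default_bank.kernels:
            if k.kind in ("deriv1", "deriv2", "log"):
                assert abs(k.values.sum()) < 1e-10
            else:
                assert k.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_save_load_roundtrip(self, small_bank, tmp_path):
        fb.save_bank(tmp_path / "bank", small_bank)
        loaded = fb.load_bank(tmp_path / "bank")
        assert len(loaded) == len(small_bank)
        assert loaded.channel_names == small_bank.channel_names


class TestConvolution:
    def test_impulse_response_is_flipped_kernel(self, small_bank):
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        resp = fb.convolve_volume(vol, small_bank)
        k = small_bank.kernels[3]
        hz, hy, hx = k.half_extents
        sub = resp[3][7 - hz : 8 + hz, 7 - hy : 8 + hy, 7 - hx : 8 + hx]
        # cross-correlation with an impulse reproduces the point-reflected kernel
        assert np.allclose(sub, k.values[::-1, ::-1, ::-1], atol=1e-12)

    def test_linearity(self, small_bank, rng):
        v1 = rng.normal(size=(14, 14, 14))
        v2 = rng.normal(size=(14, 14, 14))
        a, b = 2.5, -1.25
        lhs = fb.convolve_volume(a * v1 + b * v2, small_bank)
        rhs = a * fb.convolve_volume(v1, small_bank) + b * fb.convolve_volume(v2, small_bank)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_matches_direct_sum_oracle(self, small_bank, rng):
        vol = rng.normal(size=(16, 16, 16))
        resp = fb.convolve_volume(vol, small_bank)
        for i in [0, 7, 17, 25, 36, 37]:  # spot-check across kinds/orientations
            ref = brute_force_correlate(vol, small_bank.kernels[i].values)
            err = np.abs(resp[i] - ref).max() / np.abs(ref).max()
            assert err < 1e-8

    def test_kernel_deeper_than_volume(self, rng):
        # scale (1,1,3) kernels span 19 voxels axially; volume is 12 deep
        bank = fb.build_filter_bank(2, [(1, 1, 3)], gauss_log_sigma=2)
        vol = rng.normal(size=(12, 18, 18))
        resp = fb.convolve_volume(vol, bank)
        for i, k in enumerate(bank.kernels):
            ref = brute_force_correlate(vol, k.values)
            assert np.abs(resp[i] - ref).max() / np.abs(ref).max() < 1e-8

    def test_constant_volume_channel_responses(self, small_bank):
        field = fb.response_field(np.full((14, 14, 14), 3.7), small_bank)
        g = field.channel_names.index("gaussian")
        assert np.allclose(field.values[..., g], 3.7, atol=1e-10)
        others = [c for c in range(field.n_channels) if c != g]
        assert max(np.abs(field.values[..., c]).max() for c in others) < 1e-10

    def test_non_isotropic_volume_rejected(self, small_bank):
        from texton3d.volumeio import Volume

        v = Volume(values=np.zeros((8, 8, 8)), spacing=(1.0, 0.4, 0.4))
        with pytest.raises(ConsistencyError):
            fb.convolve_volume(v, small_bank)


class TestMaxCollapse:
    def test_output_channel_count(self, small_bank, rng):
        vol = rng.normal(size=(14, 14, 14))
        field = fb.max_collapse(fb.convolve_volume(vol, small_bank), small_bank)
        assert field.values.shape == (14, 14, 14, small_bank.n_channels)

    def test_orientation_permutation_invariance(self, small_bank, rng):
        vol = rng.normal(size=(14, 14, 14))
        resp = fb.convolve_volume(vol, small_bank)
        ref = fb.max_collapse(resp, small_bank)
        perm = resp.copy()
        g = small_bank.channel_groups()[0]
        perm[g] = perm[g[::-1]]  # reverse the orientations within one group
        out = fb.max_collapse(perm, small_bank)
        assert np.array_equal(ref.values, out.values)

    def test_mismatched_stack_rejected(self, small_bank):
        with pytest.raises(ConsistencyError):
            fb.max_collapse(np.zeros((3, 8, 8, 8)), small_bank)

    def test_fused_field_equals_collapse_of_stack(self, small_bank, rng):
        vol = rng.normal(size=(14, 14, 14))
        a = fb.response_field(vol, small_bank)
        b = fb.max_collapse(fb.convolve_volume(vol, small_bank), small_bank)
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_roi_restriction_is_exact(self, small_bank, rng):
        vol = rng.normal(size=(14, 16, 18))
        full = fb.response_field(vol, small_bank)
        roi = ((3, 9), (2, 14), (5, 17))
        sub = fb.response_field(vol, small_bank, roi=roi)
        assert np.allclose(sub.values, full.values[3:9, 2:14, 5:17], atol=1e-12)
        assert sub.origin == (3, 2, 5)

    def test_rotation_tolerance_at_grid_exact_angle(self, rng):
        # rotating the volume by 90 deg about z maps the collapsed even-order
        # z-axis channels onto themselves (90 deg is in the orientation set);
        # odd-order channels are rotation-tolerant only up to sign
        bank = fb.build_filter_bank(6, [(1, 1, 2)], gauss_log_sigma=2)
        vol = rng.normal(size=(12, 16, 16))
        vol_rot = np.rot90(vol, k=1, axes=(1, 2)).copy()
        f = fb.response_field(vol, bank)
        f_rot = fb.response_field(vol_rot, bank)
        for c, name in enumerate(bank.channel_names):
            if not name.startswith("deriv2") or not name.endswith("_z"):
                continue
            rotated_back = np.rot90(f_rot.values[..., c], k=-1, axes=(1, 2))
            interior = (slice(2, -2),) * 3  # boundary reflection differs at edges
            assert np.allclose(
                f.values[(*interior, c)], rotated_back[interior], atol=1e-6
            ), name
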