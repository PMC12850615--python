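"""Tests of the synthetic phantom and the forward corruption chain."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from napvc.core import (
    AT_LABELS,
    SequenceParams,
    RelaxationTimes,
    VolumeGrid,
    achilles_tissue_table,
)
from napvc.phantom import (
    GeometryConfig,
    GeometryError,
    add_rician_noise,
    apply_sensitivity,
    block_downsample,
    build_psf_bank,
    generate_phantom,
    make_sensitivity,
    relaxation_weight,
    relaxation_weight_map,
    simulate_acquisition,
    spillover_forward,
    zerofill,
    _default_snr_roi,
)


@pytest.fixture(scope="module")
def bundle():
    return generate_phantom(seed=0)


class TestGeneratePhantom:
    def test_ground_truth_concentrations(self, bundle):
        """Tissue concentrations follow the tissue table (mM)."""
        labs = bundle.label_map.labels
        truth = bundle.ground_truth.values
        by_name = {s.name: s.label for s in bundle.label_map.legend.values()}
        for name, conc in [
            ("ins", 25.0),
            ("mid", 15.0),
            ("mtj", 18.0),
            ("ins_tip", 30.0),
            ("skin", 34.2),
            ("blood", 81.0),
            ("calcaneus", 0.0),
        ]:
            assert np.all(truth[labs == by_name[name]] == conc), name

    def test_determinism(self, bundle):
        again = generate_phantom(seed=0)
        assert np.array_equal(bundle.label_map.labels, again.label_map.labels)
        assert np.array_equal(
            bundle.ground_truth.values, again.ground_truth.values
        )

    def test_sections_are_30mm_and_disjoint(self, bundle):
        labs = bundle.label_map.labels
        g = GeometryConfig.preset("default")
        for sec_labels, z_lo in [((1, 4), 0), ((2, 5), 1), ((3, 6), 2)]:
            zs = np.where(np.isin(labs, sec_labels))[2]
            assert zs.min() >= g.tendon_z0 + z_lo * g.section_length
            assert zs.max() < g.tendon_z0 + (z_lo + 1) * g.section_length

    def test_reference_cylinders_have_expected_volume(self, bundle):
        # 5 mm radius, 35 mm height at 1 mm voxels
        count = int((bundle.label_map.labels == 13).sum())
        expected = np.pi * 5.0**2 * 35.0
        assert abs(count - expected) / expected < 0.05

    def test_out_of_grid_reference_raises(self):
        bad = GeometryConfig(reference_x=(3.0, 38.0, 58.0, 78.0))
        with pytest.raises(GeometryError, match="ref_"):
            generate_phantom(bad)

    def test_large_preset_shifts_geometry(self):
        big = generate_phantom("large")
        assert big.label_map.shape == (160, 160, 160)
        assert set(np.unique(big.label_map.labels)) == set(
            np.unique(generate_phantom(seed=0).label_map.labels)
        )


class TestRelaxationWeight:
    def test_closed_form(self, mid_relax):
        """MID at TR/TE = 15/0.1 ms matches the independent evaluation."""
        w = relaxation_weight(mid_relax, tr=15.0, te=0.1)
        expected = (1.0 - np.exp(-15.0 / 19.2)) * (
            0.6 * np.exp(-0.1 / 1.4) + 0.4 * np.exp(-0.1 / 14.2)
        )
        assert w == pytest.approx(expected, abs=1e-12)

    def test_fully_relaxed_limit(self):
        relax = RelaxationTimes(t1=1.0, t2l_star=10.0, t2s_star=1.0)
        assert relaxation_weight(relax, tr=1e9, te=0.0) == pytest.approx(1.0)

    def test_pure_long_component(self):
        relax = RelaxationTimes(19.2, 14.2, 1.4, short_fraction=0.0)
        w = relaxation_weight(relax, tr=15.0, te=0.1)
        expected = (1 - np.exp(-15 / 19.2)) * np.exp(-0.1 / 14.2)
        assert w == pytest.approx(expected, abs=1e-12)

    def test_weight_map_uses_legend(self, bundle):
        wmap = relaxation_weight_map(bundle.label_map, tr=15.0, te=0.1)
        mid_mask = bundle.label_map.labels == 2
        w_mid = relaxation_weight(
            bundle.label_map.legend[2].relax, 15.0, 0.1
        )
        assert np.allclose(wmap[mid_mask], w_mid)


class TestBlockDownsample:
    def test_constant_preserved(self):
        vol = VolumeGrid(np.full((8, 8, 8), 3.5), 1.0)
        out = block_downsample(vol, 2)
        assert np.allclose(out.values, 3.5)
        assert out.voxel_size == 2.0

    def test_single_block_mean(self):
        v = np.zeros((2, 2, 2))
        v[1] = 1.0
        out = block_downsample(VolumeGrid(v, 1.0), 2)
        assert out.values[0, 0, 0] == pytest.approx(0.5)

    def test_matches_loop_oracle(self, rng):
        v = rng.random((8, 8, 8))
        out = block_downsample(VolumeGrid(v, 1.0), 2).values
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    block = v[2 * i : 2 * i + 2, 2 * j : 2 * j + 2, 2 * k : 2 * k + 2]
                    assert out[i, j, k] == pytest.approx(block.mean(), abs=1e-12)

    def test_global_mean_preserved_exactly(self, rng):
        v = rng.random((12, 12, 12))
        out = block_downsample(VolumeGrid(v, 1.0), 3)
        assert out.values.mean() == pytest.approx(v.mean(), abs=1e-13)

    def test_non_divisible_edge_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            block_downsample(VolumeGrid(np.zeros((9, 8, 8)), 1.0), 2)


class TestSensitivity:
    def test_coil_plane_and_scale(self):
        g = GeometryConfig.preset("default")
        sens = make_sensitivity(g).values
        y_coil = int(g.coil_plane_y)
        assert sens[:, y_coil, :].max() == pytest.approx(1.0)
        y_far = int(g.coil_plane_y + g.sensitivity_scale)
        assert sens[0, y_far, 0] == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_monotone_decay_from_plane(self):
        g = GeometryConfig.preset("default")
        sens = make_sensitivity(g).values[0, :, 0]
        y_coil = int(g.coil_plane_y)
        assert np.all(np.diff(sens[y_coil:]) < 0)
        assert np.all(np.diff(sens[:y_coil]) > 0)

    def test_apply_identity_and_product(self, rng):
        v = VolumeGrid(rng.random((6, 6, 6)), 1.0)
        ones = VolumeGrid(np.ones((6, 6, 6)), 1.0)
        assert np.allclose(apply_sensitivity(v, ones).values, v.values)
        half = VolumeGrid(np.full((6, 6, 6), 0.5), 1.0)
        # normalised to max 1, so a constant 0.5 map is an identity
        assert np.allclose(apply_sensitivity(v, half).values, v.values)
        falloff = VolumeGrid(np.linspace(1, 0.2, 6)[None, :, None] * np.ones((6, 6, 6)), 1.0)
        out = apply_sensitivity(v, falloff)
        assert np.allclose(out.values, v.values * falloff.values, atol=1e-12)

    def test_grid_mismatch_rejected(self, rng):
        v = VolumeGrid(rng.random((6, 6, 6)), 1.0)
        s = VolumeGrid(np.ones((5, 6, 6)), 1.0)
        with pytest.raises(ValueError):
            apply_sensitivity(v, s)


@pytest.fixture(scope="module")
def small_bank(bundle):
    params = SequenceParams()
    return build_psf_bank(bundle.label_map, 2, params, kernel_halfwidth=6)


class TestSpilloverForward:
    def test_impulse_bank_is_identity(self, bundle, rng):
        params = SequenceParams()
        bank = build_psf_bank(bundle.label_map, 2, params, impulse=True)
        vol = VolumeGrid(rng.random((48, 48, 48)), 2.0)
        out = spillover_forward(vol, bank)
        assert np.allclose(out.values, vol.values, atol=1e-12)

    def test_matches_masked_convolution_oracle(self, bundle, small_bank, rng):
        """The forward model equals the direct sum of per-group masked
        convolutions."""
        vol = VolumeGrid(rng.random((48, 48, 48)), 2.0)
        out = spillover_forward(vol, small_bank)
        oracle = np.zeros_like(vol.values)
        for cid, psf in small_bank.psfs.items():
            masked = np.where(small_bank.combo_ids == cid, vol.values, 0.0)
            oracle += fftconvolve(masked, psf.values, mode="same")
        assert np.allclose(out.values, oracle, atol=1e-9)

    def test_linearity(self, bundle, small_bank, rng):
        a = VolumeGrid(rng.random((48, 48, 48)), 2.0)
        b = VolumeGrid(rng.random((48, 48, 48)), 2.0)
        lhs = spillover_forward(
            VolumeGrid(2.0 * a.values + 3.0 * b.values, 2.0), small_bank
        ).values
        rhs = (
            2.0 * spillover_forward(a, small_bank).values
            + 3.0 * spillover_forward(b, small_bank).values
        )
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_interior_sum_conservation(self, bundle, small_bank):
        """Unit-gain PSFs conserve the global sum up to boundary losses."""
        vol = VolumeGrid(np.ones((48, 48, 48)), 2.0)
        margin = 8
        interior = np.zeros((48, 48, 48), dtype=bool)
        interior[margin:-margin, margin:-margin, margin:-margin] = True
        vol.values[~interior] = 0.0
        out = spillover_forward(vol, small_bank)
        assert out.values.sum() == pytest.approx(vol.values.sum(), rel=1e-3)


class TestRicianNoise:
    def test_deterministic_given_seed(self):
        vol = VolumeGrid(np.full((16, 16, 16), 5.0), 1.0)
        roi = np.ones(vol.shape, dtype=bool)
        a, sa = add_rician_noise(vol, 10.0, roi, seed=42)
        b, sb = add_rician_noise(vol, 10.0, roi, seed=42)
        assert sa == sb
        assert np.array_equal(a.values, b.values)

    def test_sigma_definition(self):
        vol = VolumeGrid(np.full((8, 8, 8), 12.0), 1.0)
        roi = np.ones(vol.shape, dtype=bool)
        _, sigma = add_rician_noise(vol, 6.0, roi, seed=0)
        assert sigma == pytest.approx(2.0)

    def test_huge_snr_is_near_identity(self):
        vol = VolumeGrid(np.full((8, 8, 8), 5.0), 1.0)
        roi = np.ones(vol.shape, dtype=bool)
        out, sigma = add_rician_noise(vol, 1e9, roi, seed=0)
        assert np.allclose(out.values, vol.values, atol=1e-6)

    def test_background_is_rayleigh(self):
        """Zero-signal voxels have mean sigma*sqrt(pi/2) within 3 SE."""
        n = 24
        v = np.zeros((n, n, n))
        v[:4] = 10.0
        roi = v > 0
        out, sigma = add_rician_noise(VolumeGrid(v, 1.0), 10.0, roi, seed=3)
        bg = out.values[~roi]
        assert bg.size >= 10_000
        expected = sigma * np.sqrt(np.pi / 2)
        se = sigma * np.sqrt((4 - np.pi) / 2) / np.sqrt(bg.size)
        assert abs(bg.mean() - expected) < 3 * se

    def test_zero_roi_mean_rejected(self):
        vol = VolumeGrid(np.zeros((4, 4, 4)), 1.0)
        with pytest.raises(ValueError):
            add_rician_noise(vol, 10.0, np.ones((4, 4, 4), bool), seed=0)


class TestZerofill:
    def test_factor_one_identity(self, rng):
        v = VolumeGrid(rng.random((8, 8, 8)), 2.0)
        out = zerofill(v, 2.0)
        assert np.array_equal(out.values, v.values)

    def test_constant_preserved(self):
        v = VolumeGrid(np.full((8, 8, 8), 4.2), 2.0)
        out = zerofill(v, 1.0)
        assert out.values.shape == (16, 16, 16)
        assert np.allclose(out.values, 4.2, atol=1e-9)
        assert out.values.mean() == pytest.approx(4.2, abs=1e-9)

    def test_bandlimited_sinusoid_resampled_exactly(self):
        """A band-limited sinusoid is interpolated to its analytic values."""
        n, f = 16, 3
        x = np.arange(n)
        v = np.sin(2 * np.pi * f * x / n)
        vol = VolumeGrid(np.broadcast_to(v[:, None, None], (n, n, n)).copy(), 2.0)
        out = zerofill(vol, 1.0)
        xf = np.arange(2 * n) / 2.0
        expected = np.sin(2 * np.pi * f * xf / n)
        assert np.allclose(out.values[:, 0, 0], expected, atol=1e-6)

    def test_non_integer_factor_rejected(self):
        v = VolumeGrid(np.zeros((8, 8, 8)), 2.0)
        with pytest.raises(ValueError):
            zerofill(v, 1.5)


class TestSimulateAcquisition:
    def test_all_corruptions_off_reduces_to_block_mean(self, bundle):
        params = SequenceParams()
        bank = build_psf_bank(bundle.label_map, 2, params, impulse=True)
        uniform = generate_phantom(seed=0)
        uniform.sensitivity = VolumeGrid(
            np.ones(bundle.sensitivity.shape), bundle.sensitivity.voxel_size
        )
        acq = simulate_acquisition(
            uniform, params, resolution_factor=2, target_snr=None, psf_bank=bank
        )
        weights = relaxation_weight_map(uniform.label_map, params.tr, params.te)
        expected = block_downsample(
            VolumeGrid(uniform.ground_truth.values * weights, 1.0), 2
        )
        assert np.allclose(acq.lowres.values, expected.values, atol=1e-12)

    def test_deterministic_given_seed(self, bundle):
        params = SequenceParams()
        bank = build_psf_bank(bundle.label_map, 2, params, impulse=True)
        a = simulate_acquisition(bundle, params, target_snr=10.0, seed=9, psf_bank=bank)
        b = simulate_acquisition(bundle, params, target_snr=10.0, seed=9, psf_bank=bank)
        assert np.array_equal(a.lowres.values, b.lowres.values)
        assert a.noise_sigma == b.noise_sigma

    def test_stage_order_is_pinned(self, bundle):
        """The chain applies weighting, downsampling, sensitivity, spill,
        then noise, in that order; manual composition reproduces it and a
        swapped order (noise before sensitivity) does not."""
        params = SequenceParams()
        bank = build_psf_bank(bundle.label_map, 2, params, impulse=True)
        roi = _default_snr_roi(bundle.label_map, 2)
        acq = simulate_acquisition(
            bundle, params, target_snr=10.0, seed=5, psf_bank=bank, snr_roi=roi
        )

        weights = relaxation_weight_map(bundle.label_map, params.tr, params.te)
        lr = block_downsample(
            VolumeGrid(bundle.ground_truth.values * weights, 1.0), 2
        )
        sens_lr = block_downsample(bundle.sensitivity, 2)
        staged = apply_sensitivity(lr, sens_lr)
        staged = spillover_forward(staged, bank)
        noisy, sigma = add_rician_noise(staged, 10.0, roi, seed=5)
        assert np.array_equal(acq.lowres.values, noisy.values)

        swapped, _ = add_rician_noise(spillover_forward(lr, bank), 10.0, roi, seed=5)
        swapped = apply_sensitivity(swapped, sens_lr)
        assert not np.allclose(swapped.values, noisy.values)
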