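"""Tests of the spill-over corrections (GTM, STC, eSTC) and their RSFs."""

import numpy as np
import pytest
from scipy.ndimage import binary_erosion, generate_binary_structure

from napvc.core import RelaxationTimes, SequenceParams, achilles_tissue_table
from napvc.psf import PSFKernel, impulse_kernel, simulate_psf
from napvc.spillover import (
    CompartmentSet,
    build_rsf,
    erode_and_fill,
    estc_correct,
    gtm_correct,
    stc_correct,
    surround_psf,
)

from conftest import gaussian_kernel


def _ball_shell_fixture(n=40, r_in=8.0, r_out=15.0, c_in=30.0, c_out=10.0):
    """Nested two-compartment phantom forward-blurred with its own PSFs."""
    idx = np.arange(n) - n / 2 + 0.5
    radius = np.sqrt(
        idx[:, None, None] ** 2 + idx[None, :, None] ** 2 + idx[None, None, :] ** 2
    )
    target = radius <= r_in
    shell = (radius > r_in) & (radius <= r_out)
    comp = CompartmentSet(
        [target, shell],
        [gaussian_kernel(4, 1.2), gaussian_kernel(4, 1.6)],
        names=["target", "surround"],
        surround_index=1,
    )
    image = c_in * comp.convolve(0, target.astype(float)) + c_out * comp.convolve(
        1, shell.astype(float)
    )
    return image, comp, (c_in, c_out)


@pytest.fixture(scope="module")
def ball_shell():
    return _ball_shell_fixture()


class TestBuildRsf:
    def test_impulse_gives_mask(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[4:8, 4:8, 4:8] = True
        rsf = build_rsf(mask, impulse_kernel(1))
        assert np.allclose(rsf, mask.astype(float), atol=1e-12)

    def test_whole_grid_mask_is_one_away_from_boundary(self):
        mask = np.ones((24, 24, 24), bool)
        rsf = build_rsf(mask, gaussian_kernel(3, 1.0))
        assert np.allclose(rsf[4:-4, 4:-4, 4:-4], 1.0, atol=1e-9)

    def test_matches_direct_convolution_oracle(self, rng):
        from scipy.ndimage import convolve

        mask = rng.random((16, 16, 16)) < 0.2
        psf = gaussian_kernel(2, 0.9)
        rsf = build_rsf(mask, psf)
        oracle = convolve(mask.astype(float), psf.values, mode="constant")
        assert np.allclose(rsf, oracle, atol=1e-10)

    def test_masked_variant(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[4:8, 4:8, 4:8] = True
        rsf = build_rsf(mask, gaussian_kernel(2, 1.0), masked=True)
        assert np.all(rsf[~mask] == 0)

    def test_unnormalised_psf_rejected(self):
        bad = PSFKernel(np.full((3, 3, 3), 1.0), 1.0)
        with pytest.raises(ValueError, match="unit"):
            build_rsf(np.ones((8, 8, 8), bool), bad)


class TestCompartmentSet:
    def test_overlapping_masks_rejected(self):
        a = np.zeros((8, 8, 8), bool)
        a[:4] = True
        with pytest.raises(ValueError, match="disjoint"):
            CompartmentSet([a, a], [impulse_kernel(1), impulse_kernel(1)])

    def test_partition_of_unity(self):
        """Tiling masks sharing one unit-gain PSF give a recovery factor of
        1 away from the grid boundary."""
        n = 48
        psf = simulate_psf(
            RelaxationTimes(19.2, 14.2, 1.4),
            SequenceParams(nominal_resolution=2.0),
            kernel_halfwidth=8,
            voxel_size=2.0,
        )
        masks = []
        for ox in (0, 1):
            for oy in (0, 1):
                for oz in (0, 1):
                    m = np.zeros((n, n, n), bool)
                    m[
                        ox * n // 2 : (ox + 1) * n // 2,
                        oy * n // 2 : (oy + 1) * n // 2,
                        oz * n // 2 : (oz + 1) * n // 2,
                    ] = True
                    masks.append(m)
        comp = CompartmentSet(masks, [psf] * 8)
        h = psf.halfwidth
        total = np.sum(comp.rsfs_full, axis=0)
        interior = total[h:-h, h:-h, h:-h]
        assert np.max(np.abs(interior - 1.0)) < 1e-3


class TestGtm:
    def test_impulse_psfs_return_region_means(self, rng):
        a = np.zeros((12, 12, 12), bool)
        a[:6] = True
        b = ~a
        comp = CompartmentSet([a, b], [impulse_kernel(1), impulse_kernel(1)])
        img = rng.random((12, 12, 12))
        res = gtm_correct(img, comp)
        assert res.region_means["compartment_0"] == pytest.approx(img[a].mean())
        assert res.region_means["compartment_1"] == pytest.approx(img[b].mean())

    def test_exact_on_blurred_piecewise_constant(self, ball_shell):
        img, comp, (c_in, c_out) = ball_shell
        res = gtm_correct(img, comp)
        assert res.region_means["target"] == pytest.approx(c_in, rel=1e-6)
        assert res.region_means["surround"] == pytest.approx(c_out, rel=1e-6)

    def test_ill_conditioned_matrix_rejected(self):
        # two adjacent single-voxel compartments under a huge blur have
        # nearly identical RSFs -> the transfer matrix is unusable
        a = np.zeros((24, 24, 24), bool)
        b = a.copy()
        a[12, 12, 12] = True
        b[12, 12, 13] = True
        psf = gaussian_kernel(8, 6.0)
        comp = CompartmentSet([a, b], [psf, psf])
        with pytest.raises(np.linalg.LinAlgError, match="ill-conditioned"):
            gtm_correct(np.ones((24, 24, 24)), comp, cond_threshold=100.0)


class TestStc:
    def test_impulse_converges_immediately_to_input(self, rng):
        a = np.zeros((10, 10, 10), bool)
        a[:5] = True
        comp = CompartmentSet(
            [a, ~a], [impulse_kernel(1), impulse_kernel(1)], surround_index=1
        )
        img = rng.random((10, 10, 10)) + 0.5
        res = stc_correct(img, comp)
        assert res.converged
        assert res.iterations == 1
        assert np.allclose(res.image, img, atol=1e-9)

    def test_recovers_target_mean_on_blurred_phantom(self, ball_shell):
        img, comp, (c_in, _) = ball_shell
        res = stc_correct(img, comp, tol=1e-4, max_iter=100)
        assert res.converged
        assert res.iterations < 100
        target_mean = res.image[comp.masks[0]].mean()
        assert abs(target_mean - c_in) / c_in < 0.01

    def test_period_two_oscillation_detected(self):
        """A displaced-mass PSF over two thin slabs makes the fixed-point
        iteration flip between two states; both states are returned."""
        k = np.zeros((7, 7, 7))
        k[3, 3, 3] = 0.2
        k[3, 3, 1] = 0.4
        k[3, 3, 5] = 0.4
        psf = PSFKernel(k, 1.0)
        a = np.zeros((16, 16, 16), bool)
        b = a.copy()
        a[:, :, 6:8] = True
        b[:, :, 8:10] = True
        comp = CompartmentSet([a, b], [psf, psf], surround_index=1)
        img = comp.convolve(0, a.astype(float)) + comp.convolve(1, b.astype(float))
        res = stc_correct(img, comp, tol=1e-4, max_iter=60)
        assert res.oscillating
        assert not res.converged
        assert res.states is not None and len(res.states) == 2
        assert not np.allclose(res.states[0], res.states[1])

    def test_requires_two_compartments(self, ball_shell):
        _, comp, _ = ball_shell
        three = CompartmentSet(
            [comp.masks[0], comp.masks[1], ~(comp.masks[0] | comp.masks[1])],
            [comp.psfs[0], comp.psfs[1], comp.psfs[1]],
        )
        with pytest.raises(ValueError, match="two compartments"):
            stc_correct(np.ones((40, 40, 40)), three)


class TestErodeAndFill:
    def test_constant_volume_unchanged(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        vol = np.full((8, 8, 8), 3.0)
        out, fallback = erode_and_fill(vol, mask)
        assert not fallback
        assert np.allclose(out, 3.0)

    def test_thin_mask_falls_back_uneroded(self, rng):
        mask = np.zeros((8, 8, 8), bool)
        mask[:, :, 4] = True  # one voxel thick: 6-connected erosion empties it
        vol = rng.random((8, 8, 8))
        out, fallback = erode_and_fill(vol, mask)
        assert fallback
        assert np.array_equal(out, vol)

    def test_edge_voxels_take_nearest_interior_value(self, rng):
        """Distance-transform oracle: every refilled edge voxel carries the
        value of one of its minimum-distance surviving voxels."""
        mask = np.zeros((10, 10, 10), bool)
        mask[2:8, 2:8, 2:8] = True
        vol = rng.random((10, 10, 10))
        out, fallback = erode_and_fill(vol, mask)
        assert not fallback
        eroded = binary_erosion(mask, generate_binary_structure(3, 1))
        ring = mask & ~eroded
        sources = np.argwhere(eroded)
        for tgt in np.argwhere(ring):
            d = np.sum((sources - tgt) ** 2, axis=1)
            nearest_vals = {vol[tuple(s)] for s in sources[d == d.min()]}
            assert out[tuple(tgt)] in nearest_vals
        assert np.array_equal(out[~mask], vol[~mask])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            erode_and_fill(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), bool))


class TestEstc:
    def test_impulse_psfs_are_identity(self, rng):
        a = np.zeros((12, 12, 12), bool)
        a[3:9, 3:9, 3:6] = True
        b = np.zeros((12, 12, 12), bool)
        b[3:9, 3:9, 6:9] = True
        comp = CompartmentSet(
            [b, a], [impulse_kernel(1), impulse_kernel(1)], surround_index=0
        )
        img = rng.random((12, 12, 12)) + 0.5
        res = estc_correct(img, comp)
        assert np.allclose(res.image, img, atol=1e-9)

    def test_recovers_target_mean_within_one_percent(self, ball_shell):
        img, comp, (c_in, _) = ball_shell
        res = estc_correct(img, comp)
        target_mean = res.image[comp.masks[0]].mean()
        assert abs(target_mean - c_in) / c_in < 0.01

    def test_not_worse_than_stc_on_standard_fixture(self, ball_shell):
        img, comp, (c_in, _) = ball_shell
        err_estc = abs(estc_correct(img, comp).image[comp.masks[0]].mean() - c_in)
        err_stc = abs(
            stc_correct(img, comp, tol=1e-4, max_iter=100).image[
                comp.masks[0]
            ].mean()
            - c_in
        )
        assert err_estc <= err_stc + 0.01 * c_in

    def test_completes_in_a_single_sweep(self, ball_shell):
        """eSTC is a one-pass method: it reports exactly one iteration and
        already matches the converged STC accuracy on the same fixture."""
        img, comp, (c_in, _) = ball_shell
        res = estc_correct(img, comp)
        assert res.iterations == 1
        assert abs(res.image[comp.masks[0]].mean() - c_in) / c_in < 0.01

    def test_zero_signal_surround_reduces_to_recovery_division(self):
        """With no surrounding signal the correction is a pure division by
        the RSF inside the target (plus edge repair)."""
        n = 32
        idx = np.arange(n) - n / 2 + 0.5
        radius = np.sqrt(
            idx[:, None, None] ** 2
            + idx[None, :, None] ** 2
            + idx[None, None, :] ** 2
        )
        target = radius <= 7
        shell = (radius > 7) & (radius <= 12)
        psf = gaussian_kernel(4, 1.3)
        comp = CompartmentSet(
            [target, shell], [psf, psf], names=["t", "s"], surround_index=1
        )
        img = 20.0 * comp.convolve(0, target.astype(float))
        img[~target] = 0.0  # isolate the target signal
        res = estc_correct(img, comp)

        rsf = comp.rsfs_masked[0]
        ok = target & (rsf >= comp.rsf_floor)
        oracle = np.zeros_like(img)
        oracle[ok] = img[ok] / rsf[ok]
        oracle, _ = erode_and_fill(oracle, target)
        assert np.allclose(res.image[target], oracle[target], atol=1e-9)

    def test_requires_designated_surround(self, ball_shell):
        _, comp, _ = ball_shell
        no_sur = CompartmentSet(comp.masks, comp.psfs)
        with pytest.raises(ValueError, match="surround"):
            estc_correct(np.ones((40, 40, 40)), no_sur)

    def test_deterministic(self, ball_shell):
        img, comp, _ = ball_shell
        a = estc_correct(img, comp).image
        b = estc_correct(img, comp).image
        assert np.array_equal(a, b)


class TestSurroundPsf:
    def test_single_tissue_matches_direct_simulation(self, params, mid_relax):
        direct = simulate_psf(mid_relax, params, kernel_halfwidth=5)
        via = surround_psf([mid_relax], params, kernel_halfwidth=5)
        assert np.allclose(direct.values, via.values, atol=1e-15)

    def test_skin_fat_muscle_mean(self, params):
        """The averaged PSF equals the PSF simulated at the mean relaxation
        times of skin, fat and muscle."""
        table = {s.name: s for s in achilles_tissue_table().values()}
        specs = [table["skin"], table["fat"], table["muscle"]]
        via = surround_psf(specs, params, kernel_halfwidth=5)
        mean_relax = RelaxationTimes(
            t1=(27.0 + 25.2 + 25.2) / 3,
            t2l_star=(7.6 + 14.3 + 14.3) / 3,
            t2s_star=(0.5 + 1.4 + 1.4) / 3,
        )
        direct = simulate_psf(mean_relax, params, kernel_halfwidth=5)
        assert np.allclose(via.values, direct.values, atol=1e-12)

    def test_identical_tissues_identical_psf(self, params, mid_relax):
        one = surround_psf([mid_relax], params, kernel_halfwidth=4)
        three = surround_psf([mid_relax] * 3, params, kernel_halfwidth=4)
        assert np.allclose(one.values, three.values, atol=1e-12)
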