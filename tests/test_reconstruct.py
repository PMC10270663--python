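"""Reconstruction pipelines: FBP, sinogram denoisers, SIRT/CGLS solvers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nldct.phantom import AttenuationImage, mu_value_to_hu
from nldct.projection import Sinogram, forward_project, system_matrix
from nldct.reconstruct import (
    ReconConfig,
    cgls,
    cgls_matrix,
    contrast_renormalize,
    fbp,
    median3x3,
    reconstruct,
    sirt,
    tvl1_denoise,
    tvl1_denoise_values,
    tvl1_objective,
)

from conftest import SEED


def _noisy_sinogram(geom, phantom, scale=0.03, seed=0):
    rng = np.random.default_rng(seed)
    nf = forward_project(phantom, geom).values
    return Sinogram(nf + rng.normal(0.0, scale, nf.shape), geom)


class TestFbp:
    def test_zero_sinogram_is_air(self, desk_geom):
        img = fbp(Sinogram(np.zeros(desk_geom.sinogram_shape), desk_geom))
        assert np.allclose(img.values, -1000.0)
        assert img.units == "HU"

    def test_linearity(self, desk_geom, phantom128):
        rng = np.random.default_rng(3)
        s1 = forward_project(phantom128, desk_geom).values
        s2 = rng.normal(size=s1.shape)
        a_, b_ = 1.7, -0.6
        left = fbp(Sinogram(a_ * s1 + b_ * s2, desk_geom)).values
        right = a_ * fbp(Sinogram(s1, desk_geom)).values + b_ * fbp(
            Sinogram(s2, desk_geom)
        ).values
        # the affine HU map adds (a+b-1)*1000 HU to the combined side;
        # compare in linear (offset-free) terms
        offset = (a_ + b_ - 1.0) * 1000.0
        assert np.allclose(left - offset, right, rtol=0, atol=1e-9 * np.abs(right).max())

    def test_noise_free_phantom_liver_accuracy(self, desk_geom, phantom128, rois128):
        img = fbp(forward_project(phantom128, desk_geom))
        liver = rois128["liver"].extract(img.values).mean()
        nominal = mu_value_to_hu(rois128["liver"].extract(phantom128.values)).mean()
        assert abs(liver - nominal) <= 10.0

    def test_unknown_window_rejected(self, desk_geom):
        sino = Sinogram(np.zeros(desk_geom.sinogram_shape), desk_geom)
        with pytest.raises(ValueError):
            fbp(sino, desk_geom, window="blackman")


class TestMedian:
    def test_constant_unchanged(self, desk_geom):
        sino = Sinogram(np.full(desk_geom.sinogram_shape, 2.5), desk_geom)
        assert np.array_equal(median3x3(sino).values, sino.values)

    def test_impulse_removed(self, desk_geom):
        vals = np.full(desk_geom.sinogram_shape, 1.0)
        vals[50, 60] = 100.0
        out = median3x3(Sinogram(vals, desk_geom)).values
        assert np.all(out == 1.0)

    def test_gaussian_noise_reduction_factor(self):
        """3x3 median of an iid Gaussian field reduces sigma to ~0.45."""
        import scipy.ndimage as ndi

        rng = np.random.default_rng(SEED)
        field = rng.normal(size=(1000, 1000))
        ratio = ndi.median_filter(field, size=3, mode="reflect").std() / field.std()
        assert ratio == pytest.approx(0.45, rel=0.1)

    def test_nonlinearity_counterexample(self, desk_geom):
        """The median filter violates superposition on random fields."""
        rng = np.random.default_rng(3)
        a = rng.normal(size=desk_geom.sinogram_shape)
        b = rng.normal(size=desk_geom.sinogram_shape)
        fa = median3x3(Sinogram(a, desk_geom)).values
        fb = median3x3(Sinogram(b, desk_geom)).values
        fab = median3x3(Sinogram(a + b, desk_geom)).values
        assert not np.allclose(fab, fa + fb)


class TestTvL1:
    def test_constant_input_is_fixed_point(self):
        g = np.full((40, 50), 3.2)
        out = tvl1_denoise_values(g, 1.0, 50)
        assert np.array_equal(out, g)

    def test_objective_non_increasing(self, desk_geom, phantom128):
        sino = _noisy_sinogram(desk_geom, phantom128, seed=SEED)
        objectives = []
        tvl1_denoise_values(sino.values, 0.8, 50, record_objective=objectives)
        diffs = np.diff(objectives)
        assert np.all(diffs <= 1e-9 * objectives[0])

    def test_weak_regularisation_returns_input(self, desk_geom, phantom128):
        sino = _noisy_sinogram(desk_geom, phantom128, seed=SEED)
        out = tvl1_denoise_values(sino.values, 1e-8, 50)
        dyn = sino.values.max() - sino.values.min()
        assert np.abs(out - sino.values).max() <= 1e-6 * dyn

    def test_larger_lambda_smooths_more(self, desk_geom, phantom128):
        sino = _noisy_sinogram(desk_geom, phantom128, seed=SEED)
        tv = lambda u: tvl1_objective(u, np.zeros_like(u), 1.0)
        weak = tvl1_denoise_values(sino.values, 0.3, 50)
        strong = tvl1_denoise_values(sino.values, 1.5, 50)
        assert tv(strong) < tv(weak)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            tvl1_denoise_values(np.zeros((8, 8)), 0.0, 10)

    def test_nonlinearity_counterexample(self, desk_geom):
        rng = np.random.default_rng(1)
        a = rng.normal(size=desk_geom.sinogram_shape)
        b = rng.normal(size=desk_geom.sinogram_shape)
        fa = tvl1_denoise_values(a, 0.8, 20)
        fb = tvl1_denoise_values(b, 0.8, 20)
        fab = tvl1_denoise_values(a + b, 0.8, 20)
        assert not np.allclose(fab, fa + fb)


class TestContrastRenormalize:
    def test_identity_when_unchanged(self, desk_geom):
        rng = np.random.default_rng(2)
        s = Sinogram(rng.uniform(1, 2, desk_geom.sinogram_shape), desk_geom)
        out = contrast_renormalize(s, s.copy())
        assert np.allclose(out.values, s.values, rtol=1e-14)

    def test_halved_mean_doubles_output(self, desk_geom):
        orig = Sinogram(np.full(desk_geom.sinogram_shape, 2.0), desk_geom)
        den = Sinogram(np.full(desk_geom.sinogram_shape, 1.0), desk_geom)
        assert np.allclose(contrast_renormalize(orig, den).values, 2.0)

    @given(
        arrays(np.float64, (6, 7), elements=st.floats(0.5, 3.0)),
        arrays(np.float64, (6, 7), elements=st.floats(0.5, 3.0)),
    )
    @settings(max_examples=25, deadline=None)
    def test_mean_preserved(self, a, b):
        from nldct.projection import FanBeamGeometry

        geom = FanBeamGeometry(7, 2.0, 6, 200.0, 100.0, 4, 4, 1.0)
        out = contrast_renormalize(Sinogram(a, geom), Sinogram(b, geom))
        assert out.values.mean() == pytest.approx(a.mean(), rel=1e-12)

    def test_zero_mean_rejected(self, desk_geom):
        orig = Sinogram(np.ones(desk_geom.sinogram_shape), desk_geom)
        den = Sinogram(np.zeros(desk_geom.sinogram_shape), desk_geom)
        with pytest.raises(ValueError):
            contrast_renormalize(orig, den)


class TestSirt:
    def test_zero_iterations_returns_init(self, toy_geom):
        rng = np.random.default_rng(4)
        sino = Sinogram(rng.uniform(0, 1, toy_geom.sinogram_shape), toy_geom)
        init = AttenuationImage(rng.uniform(0, 0.02, (32, 32)), 2.0, "mu")
        out = sirt(sino, toy_geom, n_iter=0, init=init)
        assert np.allclose(out.values, mu_value_to_hu(init.values))

    def test_residual_non_increasing_on_consistent_data(self, toy_geom):
        rng = np.random.default_rng(5)
        x_true = rng.uniform(0, 0.03, (32, 32))
        sino = Sinogram(
            forward_project(AttenuationImage(x_true, 2.0, "mu"), toy_geom).values,
            toy_geom,
        )
        residuals = []
        sirt(sino, toy_geom, n_iter=100, residuals=residuals)
        r = np.array([v[0] for v in residuals])
        assert np.all(np.diff(r) <= 1e-10 * r[0])

    def test_recovers_known_image_from_zero_init(self, toy_geom):
        rng = np.random.default_rng(6)
        x_true = rng.uniform(0, 0.03, (32, 32))
        sino = Sinogram(
            forward_project(AttenuationImage(x_true, 2.0, "mu"), toy_geom).values,
            toy_geom,
        )
        out = sirt(sino, toy_geom, n_iter=100)
        err_final = np.linalg.norm(out.values - mu_value_to_hu(x_true))
        err_init = np.linalg.norm(mu_value_to_hu(np.zeros((32, 32))) - mu_value_to_hu(x_true))
        assert err_final < 0.5 * err_init

    def test_joint_linearity_in_data_and_init(self, toy_geom):
        """SIRT with these normalizations is linear in (b, init) jointly —
        the property behind the near-zero NLD of linear pipelines."""
        rng = np.random.default_rng(7)
        b1 = rng.normal(size=toy_geom.sinogram_shape)
        b2 = rng.normal(size=toy_geom.sinogram_shape)
        i1 = rng.normal(size=(32, 32)) * 0.01
        i2 = rng.normal(size=(32, 32)) * 0.01
        a_, c_ = 0.7, 1.9

        def run(b, i):
            from nldct.reconstruct import sirt_mu_stack

            return sirt_mu_stack(b, toy_geom, 20, i)

        combined = run(a_ * b1 + c_ * b2, a_ * i1 + c_ * i2)
        split = a_ * run(b1, i1) + c_ * run(b2, i2)
        assert np.allclose(combined, split, atol=1e-12)


class TestCgls:
    def test_zero_iterations_returns_init(self, toy_geom):
        rng = np.random.default_rng(8)
        sino = Sinogram(rng.uniform(0, 1, toy_geom.sinogram_shape), toy_geom)
        init = AttenuationImage(rng.uniform(0, 0.02, (32, 32)), 2.0, "mu")
        out = cgls(sino, toy_geom, n_iter=0, init=init)
        assert np.allclose(out.values, mu_value_to_hu(init.values))

    def test_matches_direct_least_squares_on_tiny_system(self):
        """After n iterations CGLS equals the directly solved LS solution."""
        rng = np.random.default_rng(42)
        a = rng.normal(size=(12, 9))
        b = rng.normal(size=(12, 1))
        x = cgls_matrix(a, a.T, b, np.zeros((9, 1)), 9)
        x_direct, *_ = np.linalg.lstsq(a, b, rcond=None)
        assert np.linalg.norm(x - x_direct) <= 1e-6 * np.linalg.norm(x_direct)

    def test_ls_residual_monotone_on_tiny_system(self):
        rng = np.random.default_rng(42)
        a = rng.normal(size=(12, 9))
        b = rng.normal(size=(12, 1))
        ls = []
        cgls_matrix(a, a.T, b, np.zeros((9, 1)), 9, ls_residuals=ls)
        r = np.array([v[0] for v in ls])
        assert np.all(np.diff(r) <= 1e-12 * r[0])

    def test_warm_start_equivalence(self, toy_geom):
        """Warm-started CGLS equals zero-start CGLS on the shifted problem."""
        rng = np.random.default_rng(9)
        a, at = system_matrix(toy_geom)
        b = rng.normal(size=(a.shape[0], 1))
        x0 = rng.normal(size=(a.shape[1], 1)) * 0.01
        warm = cgls_matrix(a, at, b, x0, 15)
        shifted = x0 + cgls_matrix(a, at, b - a @ x0, np.zeros_like(x0), 15)
        assert np.allclose(warm, shifted, atol=1e-12)


class TestDispatch:
    def test_fbp_preset_is_fbp(self, desk_geom, phantom128):
        sino = forward_project(phantom128, desk_geom)
        via_dispatch = reconstruct(sino, ReconConfig.fbp_preset(), desk_geom)
        direct = fbp(sino, desk_geom, "hamming")
        assert np.array_equal(via_dispatch.values, direct.values)

    def test_bit_reproducible(self, desk_geom, phantom128):
        sino = _noisy_sinogram(desk_geom, phantom128, seed=SEED)
        cfg = ReconConfig(
            algorithm="sirt", n_iterations=8, denoiser="median3x3", init="fbp_of_denoised"
        )
        a = reconstruct(sino, cfg, desk_geom)
        b = reconstruct(sino, cfg, desk_geom)
        assert np.array_equal(a.values, b.values)

    def test_denoisers_reduce_fbp_noise(self, desk_geom, phantom128, rois128):
        """Both sinogram denoisers lower the muscle-ROI sigma of the FBP
        probe reconstruction — the qualitative noise-reduction direction."""
        sino = _noisy_sinogram(desk_geom, phantom128, scale=0.05, seed=SEED)
        muscle = rois128["muscle"]
        sig_raw = muscle.extract(fbp(sino).values).std(ddof=1)
        sig_med = muscle.extract(fbp(median3x3(sino)).values).std(ddof=1)
        tv = contrast_renormalize(sino, tvl1_denoise(sino, 0.6, 50))
        sig_tv = muscle.extract(fbp(tv).values).std(ddof=1)
        assert sig_med < sig_raw
        assert sig_tv < sig_raw

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError):
            ReconConfig(algorithm="fbp", denoiser="median3x3")
        with pytest.raises(ValueError):
            ReconConfig(algorithm="cgls", denoiser="tvl1", tv_lambda=-1.0)
        with pytest.raises(ValueError):
            ReconConfig(algorithm="sart")
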