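import numpy as np
import pytest

from conftest import random_weights
from raki.data import MultiCoilKSpace, SamplingScheme
from raki.fourier import ifft2c
from raki.image_space import extract_image_weights, reconstruct_kspace_path
from raki.network import NetworkConfig, grappa_calibrate
from raki.noise import (
    ReplicaStack,
    analytic_gfactor,
    analytic_gfactor_map,
    analytic_jacobian,
    coil_combination,
    crop_lowres,
    grappa_gfactor_classical,
    ks_normality,
    montecarlo_gfactor,
    numeric_jacobian,
)
from raki.noise import linearized_forward
from raki.training import TrainingConfig, train


class TestCoilCombination:
    def test_single_coil(self):
        img = np.full((4, 4, 1), 3 + 4j)
        sos, P = coil_combination(img)
        assert sos[0, 0] == pytest.approx(5.0)
        assert P.P[0, 0, 0] == pytest.approx((3 - 4j) / 5)

    def test_algebraic_identities(self, rng):
        img = rng.standard_normal((8, 8, 4)) + 1j * rng.standard_normal((8, 8, 4))
        sos, P = coil_combination(img)
        norms = (np.abs(P.P) ** 2).sum(-1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)
        comb = (P.P * img).sum(-1)
        assert np.abs(comb.imag).max() < 1e-12
        np.testing.assert_allclose(comb.real, sos, atol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            coil_combination(np.zeros((4, 4, 2), complex))


@pytest.fixture(scope="module")
def tiny_models(tiny_study):
    """Random small networks on the 16x16 study, one per slope."""
    _, _, und = tiny_study
    out = {}
    for a in (0.0, 0.5, 1.0):
        cfg = NetworkConfig(
            nc=und.nc, R=und.scheme.R, channels=(4, 2),
            kernel_sizes=((2, 3), (1, 1), (1, 3)), a=a,
        )
        w = random_weights(cfg, np.random.default_rng(11))
        coil = reconstruct_kspace_path(cfg, w, und)
        _, P = coil_combination(coil)
        isw, _ = extract_image_weights(cfg, w, und)
        out[a] = (cfg, w, isw, P)
    return out


class TestJacobians:
    @pytest.mark.parametrize("a", [0.0, 0.5, 1.0])
    def test_analytic_matches_finite_differences(self, tiny_study, tiny_models, a):
        _, _, und = tiny_study
        _, _, isw, P = tiny_models[a]
        Ja = analytic_jacobian(isw, P)
        Jn = numeric_jacobian(linearized_forward(isw, P), ifft2c(und.grid_only()))
        assert np.abs(Ja.J - Jn.J).max() < 1e-6

    def test_numeric_jacobian_of_scalar_map(self):
        c = 1.3 - 0.4j
        J = numeric_jacobian(lambda x: c * x[:, :, 0], np.zeros((4, 4, 1), complex))
        expect = np.zeros((4, 4, 4, 4, 1), complex)
        for i in range(4):
            for j in range(4):
                expect[i, j, i, j, 0] = c
        assert np.abs(J.J - expect).max() < 1e-8

    def test_identity_network_jacobian(self):
        """R=1 identity 'reconstruction': J_acc[l; m, t] = P[l, t] delta(l-m)."""
        nx = ny = 8
        nc = 2
        rng = np.random.default_rng(0)
        data = rng.standard_normal((nx, ny, nc)) + 1j * rng.standard_normal((nx, ny, nc))
        scheme = SamplingScheme(npe=nx, nro=ny, R=1, acs=(0, nx))
        ks = MultiCoilKSpace(data, scheme)
        W = np.zeros((1, 1, nc, nc), complex)
        W[0, 0] = np.eye(nc)
        from raki.network import LayerWeights

        cfg = NetworkConfig(nc=nc, R=1, channels=(), kernel_sizes=((1, 1),), a=1.0)
        coil = reconstruct_kspace_path(cfg, LayerWeights([W]), ks, keep_acquired=False)
        _, P = coil_combination(coil)
        isw, _ = extract_image_weights(cfg, LayerWeights([W]), ks, keep_acquired=False)
        J = analytic_jacobian(isw, P).J
        for t in range(nc):
            diag = J[np.arange(nx)[:, None], np.arange(ny)[None, :],
                     np.arange(nx)[:, None], np.arange(ny)[None, :], t]
            np.testing.assert_allclose(diag, P.P[:, :, t], atol=1e-12)
        offdiag = J.copy()
        for t in range(nc):
            offdiag[np.arange(nx)[:, None], np.arange(ny)[None, :],
                    np.arange(nx)[:, None], np.arange(ny)[None, :], t] = 0
        assert np.abs(offdiag).max() < 1e-12

    def test_memory_guard(self, tiny_models):
        _, _, isw, P = tiny_models[0.5]
        with pytest.raises(MemoryError):
            analytic_jacobian(isw, P, memory_budget_bytes=1e3)


class TestGFactor:
    def test_identity_reconstruction_gives_unity(self):
        nx = ny = 8
        nc = 2
        rng = np.random.default_rng(1)
        data = rng.standard_normal((nx, ny, nc)) + 1j * rng.standard_normal((nx, ny, nc))
        scheme = SamplingScheme(npe=nx, nro=ny, R=1, acs=(0, nx))
        ks = MultiCoilKSpace(data, scheme)
        from raki.network import LayerWeights

        W = np.zeros((1, 1, nc, nc), complex)
        W[0, 0] = np.eye(nc)
        cfg = NetworkConfig(nc=nc, R=1, channels=(), kernel_sizes=((1, 1),), a=1.0)
        coil = reconstruct_kspace_path(cfg, LayerWeights([W]), ks, keep_acquired=False)
        _, P = coil_combination(coil)
        isw, _ = extract_image_weights(cfg, LayerWeights([W]), ks, keep_acquired=False)
        g = analytic_gfactor_map(isw, P)
        np.testing.assert_allclose(g.g[g.valid], 1.0, atol=1e-10)

    def test_whitened_denominator_is_unity(self, tiny_models):
        _, _, _, P = tiny_models[0.5]
        den = (np.abs(P.P) ** 2).sum(-1)
        on = den > 0
        np.testing.assert_allclose(den[on], 1.0, atol=1e-12)

    def test_grappa_limit_matches_classical_formula(self, small_study):
        """One linearly activated layer: the chain-rule g map equals the
        independently coded classical GRAPPA g-factor."""
        _, _, und = small_study
        cfg, w = grappa_calibrate(und.acs_block(), (2, 5), und.scheme.R)
        coil = reconstruct_kspace_path(cfg, w, und)
        _, P = coil_combination(coil)
        isw, _ = extract_image_weights(cfg, w, und)
        g_chain = analytic_gfactor_map(isw, P)
        g_classic = grappa_gfactor_classical(w.layers[0], und.scheme, P)
        assert np.abs(g_chain.g - g_classic.g)[g_chain.valid].max() < 1e-6

    def test_from_jacobian_equals_streaming_map(self, tiny_study, tiny_models):
        _, _, und = tiny_study
        _, _, isw, P = tiny_models[0.5]
        J = analytic_jacobian(isw, P)
        g1 = analytic_gfactor(J, P, None, und.scheme.R, grid_offset=und.scheme.grid_offset)
        g2 = analytic_gfactor_map(isw, P)
        assert np.abs(g1.g - g2.g).max() < 1e-10

    def test_nondiagonal_covariance_rejected(self, tiny_models):
        _, _, isw, P = tiny_models[0.5]
        bad = np.ones((isw.nc, isw.nc))
        with pytest.raises(ValueError):
            analytic_gfactor_map(isw, P, sigma2=bad)


class TestMonteCarlo:
    def test_linear_model_agreement(self, small_study):
        """Pseudo-replica g of a GRAPPA reconstruction tracks the analytic
        map closely (small-sample version of the full validation)."""
        phantom, _, und = small_study
        cfg, w = grappa_calibrate(und.acs_block(), (2, 5), und.scheme.R)
        coil = reconstruct_kspace_path(cfg, w, und)
        _, P = coil_combination(coil)
        isw, _ = extract_image_weights(cfg, w, und)
        g_an = analytic_gfactor_map(isw, P)

        def rec(data):
            c = reconstruct_kspace_path(cfg, w, MultiCoilKSpace(data, und.scheme))
            return np.sqrt((np.abs(c) ** 2).sum(-1))

        g_mc, var, snr, stack = montecarlo_gfactor(rec, und, P, nrep=250, seed=9)
        sup = (np.abs(phantom.data) > 0.1) & g_an.valid & g_mc.valid
        r = np.corrcoef(g_an.g[sup], g_mc.g[sup])[0, 1]
        assert r > 0.95
        assert np.median(np.abs(g_an.g - g_mc.g)[sup] / g_mc.g[sup]) < 0.1
        assert stack.nrep == 250 and np.all(var >= 0)

    def test_fixed_seed_reproducible(self, small_study):
        _, _, und = small_study
        cfg, w = grappa_calibrate(und.acs_block(), (2, 5), und.scheme.R)
        coil = reconstruct_kspace_path(cfg, w, und)
        _, P = coil_combination(coil)

        def rec(data):
            c = reconstruct_kspace_path(cfg, w, MultiCoilKSpace(data, und.scheme))
            return np.sqrt((np.abs(c) ** 2).sum(-1))

        g1, *_ = montecarlo_gfactor(rec, und, P, nrep=5, seed=3)
        g2, *_ = montecarlo_gfactor(rec, und, P, nrep=5, seed=3)
        np.testing.assert_array_equal(g1.g, g2.g)

    def test_too_few_replicas_rejected(self, small_study):
        _, _, und = small_study
        _, P = coil_combination(ifft2c(und.data) + 1.0)
        with pytest.raises(ValueError):
            montecarlo_gfactor(lambda d: np.zeros(d.shape[:2]), und, P, nrep=1)


class TestKSNormality:
    def test_calibration_on_exact_normal_stack(self):
        rng = np.random.default_rng(0)
        reps = 10.0 + rng.standard_normal((2000, 6, 6))
        stack = ReplicaStack(replicas=reps, seed=0, noise_std=1.0)
        pmap, mask, frac = ks_normality(stack)
        # parameters fitted from the sample make the test conservative:
        # nearly all truly normal voxels pass
        assert frac > 1 - 0.05 - 0.05

    def test_power_against_exponential(self):
        rng = np.random.default_rng(1)
        reps = rng.exponential(1.0, (5000, 4, 4))
        stack = ReplicaStack(replicas=reps, seed=0, noise_std=1.0)
        _, _, frac = ks_normality(stack)
        assert frac < 0.05

    def test_zero_variance_voxels_excluded(self):
        rng = np.random.default_rng(2)
        reps = 5.0 + rng.standard_normal((500, 3, 3))
        reps[:, 0, 0] = 7.0
        stack = ReplicaStack(replicas=reps, seed=0, noise_std=1.0)
        pmap, mask, frac = ks_normality(stack)
        assert np.isnan(pmap[0, 0]) and not mask[0, 0]

    def test_minimum_replica_count(self):
        stack = ReplicaStack(replicas=np.zeros((10, 2, 2)), seed=0, noise_std=1.0)
        with pytest.raises(ValueError):
            ks_normality(stack)


class TestCropLowres:
    def test_full_size_is_identity(self, small_study):
        _, _, und = small_study
        crop = crop_lowres(und, und.data.shape[:2])
        np.testing.assert_array_equal(crop.data, und.data)
        assert crop.scheme.acs == und.scheme.acs

    def test_center_block_kept_exactly(self, small_study):
        _, _, und = small_study
        crop = crop_lowres(und, (12, 14))
        nx, ny = und.data.shape[:2]
        np.testing.assert_array_equal(
            crop.data, und.data[nx // 2 - 6 : nx // 2 + 6, ny // 2 - 7 : ny // 2 + 7]
        )

    def test_grid_alignment_preserved(self, small_study):
        _, _, und = small_study
        crop = crop_lowres(und, (16, 16))
        x0 = und.data.shape[0] // 2 - 8
        orig = set(und.scheme.grid_lines())
        for g in crop.scheme.grid_lines():
            assert g + x0 in orig

    def test_cropped_recon_is_lowpass_reference(self, small_study):
        """Reconstructing the cropped k-space gives the low-pass-filtered
        version of the full reconstruction (Fourier truncation)."""
        phantom, full, und = small_study
        cfg, w = grappa_calibrate(und.acs_block(), (2, 5), und.scheme.R)
        low = crop_lowres(und, (16, 16))
        sos_low, _ = coil_combination(reconstruct_kspace_path(cfg, w, low))
        lowpass_full = crop_lowres(full, (16, 16))
        ref = np.sqrt((np.abs(ifft2c(lowpass_full.data)) ** 2).sum(-1))
        from raki.metrics import nmse

        # truncation ringing and the shorter circular wrap leave a few
        # percent residual; the structure must still match the low-pass image
        assert nmse(sos_low, ref) < 0.05

    def test_oversized_crop_rejected(self, small_study):
        _, _, und = small_study
        with pytest.raises(ValueError):
            crop_lowres(und, (64, 64))
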