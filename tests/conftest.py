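import numpy as np
import pytest

from raki.data import (
    NoiseModel,
    SamplingScheme,
    make_coils,
    make_phantom,
    prewhiten,
    simulate_kspace,
    undersample,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def random_weights(cfg, rng, scale=0.3):
    """Random complex kernels matching a network configuration."""
    from raki.network import LayerWeights

    return LayerWeights(
        [
            scale
            * (
                rng.standard_normal((bx, by, ci, co))
                + 1j * rng.standard_normal((bx, by, ci, co))
            )
            for (bx, by), (ci, co) in zip(cfg.kernel_sizes, cfg.layer_channels())
        ]
    )


def make_study(nx=32, ny=32, nc=4, R=2, n_acs=12, noise_std=1e-3, seed=0,
               kind="shepp_logan"):
    """Prewhitened synthetic acquisition: (phantom, full k-space, undersampled)."""
    phantom = make_phantom(nx, ny, kind, seed)
    coils = make_coils(nx, ny, nc, seed)
    nm = NoiseModel(noise_std**2 * np.eye(nc), seed)
    full = prewhiten(simulate_kspace(phantom, coils, nm), nm)
    und = undersample(full, SamplingScheme.centered(nx, ny, R, n_acs))
    return phantom, full, und


@pytest.fixture(scope="session")
def small_study():
    """32x32, 4 coils, R=2 prewhitened acquisition with high base SNR."""
    return make_study()


@pytest.fixture(scope="session")
def tiny_study():
    """16x16, 3 coils, R=2 — small enough for dense Jacobians."""
    return make_study(nx=16, ny=16, nc=3, R=2, n_acs=8, kind="smooth_blobs", seed=2)


@pytest.fixture(scope="session")
def harmonic_study():
    """Acquisition with pure PE-harmonic coil profiles, for which an exact
    linear interpolation kernel exists (noiseless)."""
    from raki.data import CoilSensitivitySet, MultiCoilKSpace

    nx, ny, nc, R = 32, 32, 4, 2
    phantom = make_phantom(nx, ny, "smooth_blobs", 1)
    p = np.arange(nx)[:, None] - nx // 2
    maps = np.stack(
        [np.exp(2j * np.pi * m * p / nx) * np.ones((nx, ny)) for m in (-2, -1, 0, 1)],
        axis=-1,
    )
    coils = CoilSensitivitySet(maps=maps)
    full = simulate_kspace(phantom, coils, NoiseModel(np.zeros((nc, nc)), 0))
    und = undersample(full, SamplingScheme.centered(nx, ny, R, 12))
    return phantom, full, und
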