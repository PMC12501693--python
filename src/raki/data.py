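"""Synthetic multicoil Cartesian k-space data with known ground truth.

This module provides everything needed to exercise scan-specific k-space
interpolation without access to scanner raw data: a complex-valued phantom,
smooth (bandlimited) coil sensitivity profiles, a forward model producing
multicoil k-space with correlated complex Gaussian noise of known coil
covariance, retrospective undersampling with an auto-calibration (ACS)
block, and noise prewhitening.

Array layout convention: ``[PE, RO, coil]`` with phase encoding on axis 0.
k-space is stored centered, DC at index ``n // 2`` on each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.data import shepp_logan_phantom
from skimage.transform import resize

from .fourier import fft2c, ifft2c

__all__ = [
    "PhantomImage",
    "CoilSensitivitySet",
    "NoiseModel",
    "SamplingScheme",
    "MultiCoilKSpace",
    "make_phantom",
    "make_coils",
    "simulate_kspace",
    "undersample",
    "prewhiten",
]


@dataclass(frozen=True)
class PhantomImage:
    """Fully sampled complex reference object.

    The magnitude is normalized to a maximum modulus of 1 and carries a
    smooth low-order phase so that the real/imaginary sign structure of
    k-space signals is nontrivial (required for nondegenerate activation
    masks). The outer 2-pixel border is exactly zero.
    """

    data: np.ndarray
    extent: tuple[int, int]

    def support(self, rel_threshold: float = 1e-6) -> np.ndarray:
        """Boolean mask of voxels carrying signal."""
        mag = np.abs(self.data)
        return mag > rel_threshold * mag.max()


@dataclass(frozen=True)
class CoilSensitivitySet:
    """Smooth complex coil sensitivity profiles, ``maps[PE, RO, coil]``."""

    maps: np.ndarray

    @property
    def nc(self) -> int:
        return self.maps.shape[-1]


@dataclass(frozen=True)
class NoiseModel:
    """Circular complex Gaussian coil noise with covariance ``sigma2``.

    ``sigma2`` is the complex covariance E[n n^H] (Hermitian positive
    definite, nc x nc); real and imaginary parts each carry half of it.
    """

    covariance: np.ndarray
    seed: int = 0

    def __post_init__(self):
        cov = np.asarray(self.covariance, dtype=complex)
        if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
            raise ValueError("noise covariance must be a square matrix")
        if not np.allclose(cov, cov.conj().T, atol=1e-12 * max(1.0, np.abs(cov).max())):
            raise ValueError("noise covariance must be Hermitian")
        object.__setattr__(self, "covariance", cov)

    @property
    def nc(self) -> int:
        return self.covariance.shape[0]

    def is_zero(self) -> bool:
        return not np.any(self.covariance)

    def cholesky(self) -> np.ndarray:
        try:
            return np.linalg.cholesky(self.covariance)
        except np.linalg.LinAlgError as err:
            raise ValueError("noise covariance must be positive definite") from err

    def draw(self, shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
        """Draw correlated circular complex noise, coil on the last axis."""
        if self.is_zero():
            return np.zeros(shape + (self.nc,), dtype=complex)
        L = self.cholesky()
        w = (
            rng.standard_normal(shape + (self.nc,))
            + 1j * rng.standard_normal(shape + (self.nc,))
        ) / np.sqrt(2.0)
        return w @ L.T  # n_i = sum_j L[i, j] w_j  =>  E[n n^H] = L L^H


@dataclass(frozen=True)
class SamplingScheme:
    """Uniform undersampling along PE with a fully sampled central ACS block.

    Outside the ACS interval ``[acs_start, acs_stop)`` only every R-th PE
    line is sampled; the regular grid is anchored at ``grid_offset`` so that
    the central (DC) line is always acquired.
    """

    npe: int
    nro: int
    R: int
    acs: tuple[int, int]
    grid_offset: int | None = None
    pe_axis: int = 0

    def __post_init__(self):
        if self.R < 1:
            raise ValueError("undersampling rate R must be >= 1")
        start, stop = self.acs
        if not (0 <= start <= stop <= self.npe):
            raise ValueError("ACS interval exceeds the PE matrix extent")
        if self.grid_offset is None:
            object.__setattr__(self, "grid_offset", (self.npe // 2) % self.R)

    @classmethod
    def centered(cls, npe: int, nro: int, R: int, n_acs: int) -> "SamplingScheme":
        """Scheme with an ``n_acs``-line ACS block centered on the PE axis."""
        start = npe // 2 - n_acs // 2
        return cls(npe=npe, nro=nro, R=R, acs=(start, start + n_acs))

    @property
    def n_acs(self) -> int:
        return self.acs[1] - self.acs[0]

    def grid_lines(self) -> np.ndarray:
        """PE indices on the regular R-spaced sampling grid."""
        idx = np.arange(self.npe)
        return idx[idx % self.R == self.grid_offset % self.R]

    def sampled_lines(self) -> np.ndarray:
        idx = np.arange(self.npe)
        on_grid = idx % self.R == self.grid_offset % self.R
        in_acs = (idx >= self.acs[0]) & (idx < self.acs[1])
        return idx[on_grid | in_acs]

    def mask(self) -> np.ndarray:
        m = np.zeros((self.npe, self.nro), dtype=bool)
        m[self.sampled_lines()] = True
        return m


@dataclass
class MultiCoilKSpace:
    """Multicoil Cartesian k-space ``data[PE, RO, coil]`` plus acquisition
    metadata. ``scheme`` is None for fully sampled data."""

    data: np.ndarray
    scheme: SamplingScheme | None = None
    noise_cov: np.ndarray | None = None
    coils: np.ndarray | None = None
    phantom: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def nc(self) -> int:
        return self.data.shape[-1]

    def coil_images(self) -> np.ndarray:
        return ifft2c(self.data)

    def grid_only(self) -> np.ndarray:
        """Zero-filled k-space retaining only the regular R-grid lines.

        This is the network inference input: auto-calibration lines off the
        uniform grid are used for training only and are not re-inserted.
        """
        if self.scheme is None:
            return self.data.copy()
        out = np.zeros_like(self.data)
        g = self.scheme.grid_lines()
        out[g] = self.data[g]
        return out

    def acs_block(self) -> np.ndarray:
        if self.scheme is None:
            raise ValueError("fully sampled data carries no ACS metadata")
        a, b = self.scheme.acs
        return self.data[a:b]


def _low_order_phase(nx: int, ny: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-order 2D phase in radians, coefficients ~ O(1)."""
    x = np.linspace(-1, 1, nx)[:, None]
    y = np.linspace(-1, 1, ny)[None, :]
    c = rng.uniform(-1.0, 1.0, size=5)
    return np.pi * (
        0.6 * c[0] * x + 0.6 * c[1] * y + 0.4 * c[2] * x * y
        + 0.3 * c[3] * (x**2 - y**2) + 0.2 * c[4] * (x**2 + y**2)
    )


def make_phantom(nx: int, ny: int, kind: str = "shepp_logan", seed: int = 0) -> PhantomImage:
    """Deterministic complex phantom with zeroed 2-pixel border.

    Parameters
    ----------
    kind : ``"shepp_logan"`` or ``"smooth_blobs"``.
    seed : fixes the smooth phase (and blob geometry for ``smooth_blobs``).
    """
    if nx < 16 or ny < 16:
        raise ValueError("phantom must be at least 16 x 16 for kernel footprints")
    rng = np.random.default_rng(seed)
    if kind == "shepp_logan":
        mag = resize(shepp_logan_phantom(), (nx - 4, ny - 4), anti_aliasing=True)
    elif kind == "smooth_blobs":
        x = np.linspace(-1, 1, nx - 4)[:, None]
        y = np.linspace(-1, 1, ny - 4)[None, :]
        mag = np.zeros((nx - 4, ny - 4))
        for _ in range(6):
            cx, cy = rng.uniform(-0.55, 0.55, size=2)
            w = rng.uniform(0.15, 0.4)
            amp = rng.uniform(0.3, 1.0)
            mag += amp * np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2 * w**2)))
        # soft circular field-of-view cutoff keeps support inside the border
        mag *= np.clip(1.2 - np.hypot(x, y), 0.0, 1.0) ** 0.5
    else:
        raise ValueError(f"unknown phantom kind: {kind!r}")
    full = np.zeros((nx, ny))
    full[2:-2, 2:-2] = mag
    full /= full.max()
    data = full * np.exp(1j * _low_order_phase(nx, ny, rng))
    return PhantomImage(data=data, extent=(nx, ny))


def make_coils(nx: int, ny: int, nc: int, seed: int = 0) -> CoilSensitivitySet:
    """Smooth complex coil profiles arranged on a ring around the object.

    Each profile is a broad Gaussian lobe with a seeded linear + smooth
    random phase, explicitly low-pass limited to the central quarter of
    k-space, then globally scaled so the root-sum-of-squares is ~1 on a
    centered disc of radius ``min(nx, ny) / 3``.
    """
    if nc < 2:
        raise ValueError("at least 2 coils are required for any R > 1")
    rng = np.random.default_rng(seed)
    x = np.arange(nx)[:, None] - nx / 2
    y = np.arange(ny)[None, :] - ny / 2
    rad = 0.55 * min(nx, ny)
    width = 0.75 * min(nx, ny)
    maps = np.empty((nx, ny, nc), dtype=complex)
    for c in range(nc):
        th = 2 * np.pi * c / nc + rng.uniform(-0.2, 0.2)
        cx, cy = rad * np.cos(th), rad * np.sin(th)
        amp = np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2 * width**2)))
        kx, ky = rng.uniform(-1.5, 1.5, size=2)
        phase = 2 * np.pi * (kx * x / nx + ky * y / ny) + rng.uniform(0, 2 * np.pi)
        maps[:, :, c] = amp * np.exp(1j * phase)
    # enforce the bandlimit: retain only the central quarter of k-space
    spec = fft2c(maps)
    keep = np.zeros((nx, ny), dtype=bool)
    keep[
        nx // 2 - nx // 8 : nx // 2 + (nx + 7) // 8,
        ny // 2 - ny // 8 : ny // 2 + (ny + 7) // 8,
    ] = True
    maps = ifft2c(spec * keep[:, :, None])
    disc = x**2 + y**2 <= (min(nx, ny) / 3.0) ** 2
    sos = np.sqrt((np.abs(maps) ** 2).sum(-1))
    maps /= np.median(sos[disc])
    return CoilSensitivitySet(maps=maps)


def simulate_kspace(
    phantom: PhantomImage, coils: CoilSensitivitySet, noise: NoiseModel
) -> MultiCoilKSpace:
    """Forward model: centered 2D DFT of phantom x coil maps plus correlated
    circular complex Gaussian noise drawn independently per k-space sample."""
    if phantom.data.shape != coils.maps.shape[:2]:
        raise ValueError("phantom and coil map shapes disagree")
    if noise.nc != coils.nc:
        raise ValueError("noise covariance size does not match coil count")
    noise.cholesky() if not noise.is_zero() else None  # validate PD early
    coil_imgs = phantom.data[:, :, None] * coils.maps
    ks = fft2c(coil_imgs)
    rng = np.random.default_rng(noise.seed)
    ks = ks + noise.draw(ks.shape[:2], rng)
    return MultiCoilKSpace(
        data=ks,
        noise_cov=noise.covariance.copy(),
        coils=coils.maps.copy(),
        phantom=phantom.data.copy(),
    )


def undersample(ks: MultiCoilKSpace, scheme: SamplingScheme) -> MultiCoilKSpace:
    """Retrospective undersampling: zero-fill all PE lines off the sampling
    pattern; sampled lines (grid and ACS) are kept bit-identical."""
    if (scheme.npe, scheme.nro) != ks.data.shape[:2]:
        raise ValueError("sampling scheme incompatible with k-space shape")
    out = np.zeros_like(ks.data)
    lines = scheme.sampled_lines()
    out[lines] = ks.data[lines]
    return replace(ks, data=out, scheme=scheme)


def prewhiten(ks: MultiCoilKSpace, noise: NoiseModel) -> MultiCoilKSpace:
    """Decorrelate the coil dimension with the inverse Cholesky factor of the
    noise covariance; the whitened data has identity noise covariance."""
    L = noise.cholesky()
    if not np.all(np.isfinite(L)):
        raise ValueError("singular noise covariance")
    Linv = np.linalg.inv(L)
    data = ks.data @ Linv.T
    out = replace(ks, data=data, noise_cov=np.eye(noise.nc, dtype=complex))
    if ks.coils is not None:
        out = replace(out, coils=ks.coils @ Linv.T)
    return out
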