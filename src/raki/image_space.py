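"""Image-space formalism of k-space interpolation networks.

The two building blocks of the k-space network translate to image space
through the convolution theorem:

* a (dilated) convolution with kernel W in k-space is an elementwise
  multiplication with its transfer function W-hat in image space;
* the complex leaky ReLU, rewritten as an elementwise multiplication of the
  pre-activation signal S' with an *activation mask* A = CLReLU(S') / S',
  becomes a circular convolution with the mask image A-hat.

Inference can therefore be run entirely in image space:
``x_k = cconv(x_{k-1} .* W-hat_k, A-hat_k)``, final layer ``.* W-hat_int``,
followed by recombination of the R offset channel blocks via linear phase
ramps (shift theorem). Under the circular convolution convention the two
domains agree to floating-point rounding.

The masks depend on the input data, so the image-space parameterization is
extracted from a recorded k-space forward pass at the operating point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MultiCoilKSpace, SamplingScheme
from .fourier import cconv2, fft2c, ifft2c, pe_shift_ramp
from .network import (
    LayerWeights,
    NetworkConfig,
    _tap_offsets,
    assemble_reconstruction,
    clrelu,
    forward_kspace,
)

__all__ = [
    "ActivationMaskSet",
    "ImageSpaceWeights",
    "activation_mask",
    "kernel_to_image",
    "mask_to_image",
    "extract_image_weights",
    "forward_image",
    "domain_equivalence",
]


@dataclass
class ActivationMaskSet:
    """Per-hidden-layer activation masks in k-space and image domain."""

    kspace: list[np.ndarray]  # A^(k), [PE, RO, ch_k]
    image: list[np.ndarray]  # A-hat^(k), same shape, zero lag at center


@dataclass
class ImageSpaceWeights:
    """Full image-domain parameterization of one inference pass."""

    what: list[np.ndarray]  # W-hat^(k), [PE, RO, ch_in, ch_out] per hidden layer
    ahat: list[np.ndarray]  # A-hat^(k), [PE, RO, ch_k]
    what_int: np.ndarray  # W-hat^(int), [PE, RO, ch_nhid, R*nc]
    R: int
    nc: int
    grid_offset: int
    keep_acquired: bool = True

    @property
    def shape(self) -> tuple[int, int]:
        return self.what_int.shape[:2]


def activation_mask(Sprime: np.ndarray, a: float) -> np.ndarray:
    """Elementwise mask A with ``S' * A == CLReLU(S', a)``.

    Obtained by dividing the activated signal by the signal to be activated;
    entries where S' is exactly zero are set to 1 (any finite value preserves
    the identity there since CLReLU(0) = 0, and 1 keeps the linear limit
    exact with zero spurious mask energy).
    """
    act = clrelu(Sprime, a)
    out = np.ones_like(Sprime, dtype=complex)
    nz = Sprime != 0
    np.divide(act, Sprime, out=out, where=nz)
    return out


def kernel_to_image(
    W: np.ndarray, R: int, nx: int, ny: int
) -> np.ndarray:
    """Transfer function of a dilated k-space convolution kernel.

    Embeds each tap at its signed k-space offset (PE offsets scaled by R) on
    an ``nx x ny`` grid and evaluates the discrete Fourier sum, so that
    elementwise multiplication by the result in image space is exactly the
    circular dilated convolution in k-space.
    """
    bx, by, ci, co = W.shape
    if (bx - 1) * R + 1 > nx or by > ny:
        raise ValueError("dilated kernel footprint exceeds the requested matrix")
    dpe, dro = _tap_offsets(bx, by, R)
    E = np.zeros((nx, ny, ci, co), dtype=complex)
    cx, cy = nx // 2, ny // 2
    for i in range(bx):
        for j in range(by):
            E[(cx + int(dpe[i])) % nx, (cy + int(dro[j])) % ny] += W[i, j]
    # unnormalized centered DFT: a central unit tap maps to the constant 1
    Eu = np.fft.ifftshift(E, axes=(0, 1))
    T = np.fft.fftshift(np.fft.fft2(Eu, axes=(0, 1)), axes=(0, 1))
    return T


def mask_to_image(A: np.ndarray) -> np.ndarray:
    """Image-domain activation mask, scaled so that centered circular
    convolution (:func:`raki.fourier.cconv2`) with it reproduces the
    elementwise k-space multiplication exactly. The constant mask A = 1
    (linear limit) maps to a one-pixel delta at zero lag."""
    n = A.shape[0] * A.shape[1]
    return ifft2c(A) / np.sqrt(n)


def extract_image_weights(
    cfg: NetworkConfig,
    weights: LayerWeights,
    S0: MultiCoilKSpace | np.ndarray,
    scheme: SamplingScheme | None = None,
    keep_acquired: bool = True,
) -> tuple[ImageSpaceWeights, ActivationMaskSet]:
    """Run a recorded k-space forward pass at the operating point and build
    the complete image-space parameterization (weights plus masks)."""
    if isinstance(S0, MultiCoilKSpace):
        scheme = scheme or S0.scheme
    if scheme is None:
        raise ValueError("a sampling scheme is required")
    _, preacts = forward_kspace(cfg, weights, S0, record_preactivations=True)
    nx, ny = (S0.data.shape if isinstance(S0, MultiCoilKSpace) else S0.shape)[:2]
    masks_k = [activation_mask(Sp, cfg.a) for Sp in preacts]
    masks_img = [mask_to_image(A) for A in masks_k]
    what = [kernel_to_image(W, cfg.R, nx, ny) for W in weights.layers[:-1]]
    what_int = kernel_to_image(weights.layers[-1], cfg.R, nx, ny)
    isw = ImageSpaceWeights(
        what=what,
        ahat=masks_img,
        what_int=what_int,
        R=cfg.R,
        nc=cfg.nc,
        grid_offset=scheme.grid_offset % cfg.R,
        keep_acquired=keep_acquired,
    )
    return isw, ActivationMaskSet(kspace=masks_k, image=masks_img)


def _recombine_offsets(y_int: np.ndarray, isw: ImageSpaceWeights) -> np.ndarray:
    """Merge the R offset channel blocks into de-aliased coil images using
    image-domain phase ramps (shift theorem).

    Because the network input is zero off the sampling grid and all PE taps
    are R-spaced, the offset-r interpolant vanishes on lines that are not
    grid-shifted by r; summing the ramp-modulated offset images therefore
    reproduces the k-space line placement exactly, with no explicit comb
    projection.
    """
    npe = y_int.shape[-3]
    R, nc = isw.R, isw.nc
    r_start = 1 if isw.keep_acquired else 0
    coil = np.zeros(y_int.shape[:-1] + (nc,), dtype=complex)
    for r in range(r_start, R):
        ramp = pe_shift_ramp(npe, r)[:, None, None]
        coil += ramp * y_int[..., r * nc : (r + 1) * nc]
    return coil


def forward_image(
    x0: np.ndarray, isw: ImageSpaceWeights
) -> np.ndarray:
    """Image-space inference on aliased coil images ``x0[..., PE, RO, nc]``.

    Per hidden layer: channel contraction with W-hat, then circular
    convolution with the layer's activation-mask image; final elementwise
    contraction with W-hat-int; offset recombination via phase ramps. When
    ``isw.keep_acquired`` the acquired grid lines enter as the identity
    passthrough of the input. Returns de-aliased coil images ``[..., nc]``.

    Given fixed masks this map is complex-linear; the nonlinearity of the
    network lives entirely in the dependence of the masks on the data.
    """
    x = np.asarray(x0, dtype=complex)
    batched = x.ndim == 4
    axes = (1, 2) if batched else (0, 1)
    for What, Ahat in zip(isw.what, isw.ahat):
        x = np.einsum("...xyc,xyco->...xyo", x, What)
        x = cconv2(x, Ahat if not batched else Ahat[None], axes=axes)
    y_int = np.einsum("...xyc,xyco->...xyo", x, isw.what_int)
    coil = _recombine_offsets(y_int, isw)
    if isw.keep_acquired:
        coil = coil + x0
    return coil


def reconstruct_kspace_path(
    cfg: NetworkConfig,
    weights: LayerWeights,
    ks: MultiCoilKSpace,
    keep_acquired: bool = True,
    circular: bool = True,
) -> np.ndarray:
    """Conventional k-space inference: network forward on the grid-only
    zero-filled data, offset placement, inverse FFT. Returns coil images."""
    grid = MultiCoilKSpace(data=ks.grid_only(), scheme=ks.scheme)
    Sint = forward_kspace(cfg, weights, grid.data, circular=circular)
    recon_k = assemble_reconstruction(grid, Sint, ks.scheme, keep_acquired)
    return ifft2c(recon_k)


def domain_equivalence(
    cfg: NetworkConfig,
    weights: LayerWeights,
    ks: MultiCoilKSpace,
    keep_acquired: bool = True,
    circular: bool = True,
) -> float:
    """Max relative deviation between k-space and image-space inference.

    Runs both paths on identical input and compares the coil-combined
    magnitude images: ``max |img_image - img_kspace| / max |img_kspace|``.
    Exact (< 1e-9) under the circular convolution convention; the
    zero-padded k-space mode leaves small edge deviations.
    """
    coil_k = reconstruct_kspace_path(cfg, weights, ks, keep_acquired, circular)
    isw, _ = extract_image_weights(cfg, weights, ks, keep_acquired=keep_acquired)
    x0 = ifft2c(ks.grid_only())
    coil_i = forward_image(x0, isw)
    sos_k = np.sqrt((np.abs(coil_k) ** 2).sum(-1))
    sos_i = np.sqrt((np.abs(coil_i) ** 2).sum(-1))
    return float(np.max(np.abs(sos_i - sos_k)) / np.max(sos_k))
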