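"""Complex-valued k-space interpolation networks (RAKI) and the GRAPPA limit.

The forward model is a stack of complex 2D convolutions in k-space with
kernels dilated by the undersampling rate R along the phase-encoding axis,
interleaved with the complex leaky ReLU applied separately to real and
imaginary parts. The final layer is linear and emits ``R * nc`` channels:
all coils are interpolated simultaneously, one channel block per PE-shift
offset (offset-major channel ordering ``r * nc + c``).

Setting the negative slope ``a = 1`` makes the network globally linear; a
single linear layer calibrated by least squares is exactly GRAPPA, which is
provided here through :func:`grappa_calibrate`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MultiCoilKSpace, SamplingScheme

__all__ = [
    "NetworkConfig",
    "LayerWeights",
    "clrelu",
    "dilated_conv",
    "forward_kspace",
    "assemble_reconstruction",
    "count_parameters",
    "grappa_calibrate",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture description.

    ``channels`` are the hidden-layer widths (``nhid = len(channels)``);
    ``kernel_sizes`` holds one ``(bx, by)`` pair per hidden layer plus the
    final linear layer. ``a`` is the negative-slope parameter of the complex
    leaky ReLU, in [0, 1]; no bias terms anywhere.
    """

    nc: int
    R: int
    channels: tuple[int, ...] = (128, 64)
    kernel_sizes: tuple[tuple[int, int], ...] = ((2, 5), (1, 1), (1, 5))
    a: float = 0.5

    def __post_init__(self):
        if len(self.kernel_sizes) != len(self.channels) + 1:
            raise ValueError("need one kernel size per hidden layer plus the final layer")
        if any(b < 1 for ks in self.kernel_sizes for b in ks):
            raise ValueError("kernel sizes must be >= 1 along each axis")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("negative slope a must lie in [0, 1]")
        if self.nc < 1 or self.R < 1:
            raise ValueError("nc and R must be positive")

    @property
    def nhid(self) -> int:
        return len(self.channels)

    @property
    def n_out(self) -> int:
        return self.R * self.nc

    def layer_channels(self) -> list[tuple[int, int]]:
        """(ch_in, ch_out) per layer, ending in ``R * nc``."""
        chain = (self.nc, *self.channels, self.n_out)
        return list(zip(chain[:-1], chain[1:]))


@dataclass
class LayerWeights:
    """Complex 4D kernels ``[bx, by, ch_in, ch_out]`` per layer; the last
    entry is the final (identity-activated) interpolation layer."""

    layers: list[np.ndarray]

    def validate(self, cfg: NetworkConfig) -> None:
        chans = cfg.layer_channels()
        if len(self.layers) != len(chans):
            raise ValueError("layer count does not match configuration")
        for W, (bx, by), (ci, co) in zip(self.layers, cfg.kernel_sizes, chans):
            if W.shape != (bx, by, ci, co):
                raise ValueError(
                    f"weight shape {W.shape} does not match ({bx}, {by}, {ci}, {co})"
                )
            if not np.all(np.isfinite(W)):
                raise ValueError("non-finite weights")


def clrelu(z: np.ndarray, a: float) -> np.ndarray:
    """Complex leaky ReLU: LReLU on the real and imaginary parts separately.

    ``LReLU(q) = q`` for ``q >= 0`` and ``a * q`` otherwise; ``a = 1`` is the
    identity, ``a = 0`` the complex ReLU.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("negative slope a must lie in [0, 1]")
    re, im = z.real, z.imag
    return np.where(re >= 0, re, a * re) + 1j * np.where(im >= 0, im, a * im)


def _tap_offsets(bx: int, by: int, R: int) -> tuple[np.ndarray, np.ndarray]:
    """Signed k-space offsets of kernel taps; PE taps spaced R apart."""
    dpe = (np.arange(bx) - (bx - 1) // 2) * R
    dro = np.arange(by) - (by - 1) // 2
    return dpe, dro


def _shift2(S: np.ndarray, dpe: int, dro: int, circular: bool) -> np.ndarray:
    """S[p + dpe, q + dro] with circular or zero boundary."""
    if circular:
        return np.roll(S, (-dpe, -dro), axis=(0, 1))
    out = np.zeros_like(S)
    npe, nro = S.shape[:2]
    ps = slice(max(0, -dpe), min(npe, npe - dpe))
    qs = slice(max(0, -dro), min(nro, nro - dro))
    out[ps, qs] = S[slice(ps.start + dpe, ps.stop + dpe), slice(qs.start + dro, qs.stop + dro)]
    return out


def dilated_conv(
    S: np.ndarray, W: np.ndarray, R: int, circular: bool = True
) -> np.ndarray:
    """Dilated complex 2D convolution (cross-correlation orientation).

    ``out[p, q, o] = sum_{i j c} W[i, j, c, o] * S[p + R*(i - cx), q + (j - cy), c]``
    with ``cx = (bx-1)//2``, ``cy = (by-1)//2`` and periodic boundary by
    default (a zero-padded variant is available via ``circular=False``).
    """
    bx, by, ci, co = W.shape
    if S.shape[-1] != ci:
        raise ValueError("input channel count does not match kernel")
    npe, nro = S.shape[:2]
    if (bx - 1) * R + 1 > npe or by > nro:
        raise ValueError("dilated kernel footprint exceeds the matrix size")
    dpe, dro = _tap_offsets(bx, by, R)
    out = np.zeros(S.shape[:2] + (co,), dtype=complex)
    for i in range(bx):
        for j in range(by):
            out += _shift2(S, int(dpe[i]), int(dro[j]), circular) @ W[i, j]
    return out


def forward_kspace(
    cfg: NetworkConfig,
    weights: LayerWeights,
    S0: np.ndarray | MultiCoilKSpace,
    circular: bool = True,
    record_preactivations: bool = False,
):
    """Run the interpolation network on zero-filled multicoil k-space.

    Returns the interpolated ``[PE, RO, R * nc]`` k-space, and optionally the
    list of pre-activation signals S'(k) per hidden layer (needed to extract
    activation masks for the image-space formalism).
    """
    weights.validate(cfg)
    S = S0.grid_only() if isinstance(S0, MultiCoilKSpace) else np.asarray(S0)
    preacts = []
    for k in range(cfg.nhid):
        S = dilated_conv(S, weights.layers[k], cfg.R, circular)
        if record_preactivations:
            preacts.append(S)
        S = clrelu(S, cfg.a)
    Sint = dilated_conv(S, weights.layers[-1], cfg.R, circular)
    if record_preactivations:
        return Sint, preacts
    return Sint


def assemble_reconstruction(
    S0: MultiCoilKSpace,
    Sint: np.ndarray,
    scheme: SamplingScheme | None = None,
    keep_acquired: bool = True,
) -> np.ndarray:
    """Fill the full k-space from the network's offset channels.

    Output channel ``r * nc + c`` evaluated at a sampled grid line ``p``
    provides coil ``c`` at PE line ``p + r``; every PE line is covered
    exactly once. Grid lines keep the acquired data when ``keep_acquired``
    (the offset-0 channels are then unused at inference); off-grid ACS lines
    are never re-inserted — the network output is used there as well.
    """
    scheme = scheme or S0.scheme
    if scheme is None:
        raise ValueError("a sampling scheme is required to place offset channels")
    npe, nro, n_out = Sint.shape
    nc, R = scheme_nc(scheme, n_out), scheme.R
    if npe % R != 0:
        raise ValueError("PE extent must be divisible by R for offset placement")
    recon = np.empty((npe, nro, nc), dtype=complex)
    s = scheme.grid_offset % R
    q = np.arange(npe)
    r_of_q = (q - s) % R
    for r in range(R):
        sel = r_of_q == r
        src = (q[sel] - r) % npe
        recon[sel] = Sint[src][:, :, r * nc : (r + 1) * nc]
    if keep_acquired:
        g = scheme.grid_lines()
        recon[g] = S0.data[g]
    return recon


def scheme_nc(scheme: SamplingScheme, n_out: int) -> int:
    if n_out % scheme.R != 0:
        raise ValueError("output channel count is not a multiple of R")
    return n_out // scheme.R


def count_parameters(cfg: NetworkConfig) -> int:
    """Number of real trainable parameters: 2 (real + imaginary) times the
    complex kernel entries; there are no biases."""
    return 2 * sum(
        bx * by * ci * co
        for (bx, by), (ci, co) in zip(cfg.kernel_sizes, cfg.layer_channels())
    )


def grappa_calibrate(
    acs: np.ndarray,
    kernel_size: tuple[int, int],
    R: int,
    tikhonov: float = 0.0,
) -> tuple[NetworkConfig, LayerWeights]:
    """Least-squares GRAPPA calibration on an ACS block.

    Slides the dilated source neighborhood over every ACS position whose PE
    taps are fully supported (RO is treated circularly, matching inference),
    and solves for the single linear kernel mapping sources to all ``R * nc``
    offset targets, optionally with Tikhonov regularization. The result is
    packaged as a zero-hidden-layer network with ``a = 1`` so all downstream
    machinery (image-space transfer, g-factor) applies unchanged.
    """
    acs = np.asarray(acs)
    npe, nro, nc = acs.shape
    bx, by = kernel_size
    if tikhonov < 0:
        raise ValueError("tikhonov must be >= 0")
    dpe, dro = _tap_offsets(bx, by, R)
    p_lo, p_hi = -int(dpe.min()), npe - int(dpe.max())
    p_hi = min(p_hi, npe - (R - 1))  # targets p + r must stay inside the ACS
    positions = np.arange(p_lo, p_hi)
    if positions.size == 0:
        raise ValueError("ACS too small for the dilated kernel footprint")
    rows = positions.size * nro
    n_unknown = bx * by * nc
    if rows < n_unknown and tikhonov == 0.0:
        raise ValueError(
            f"underdetermined calibration ({rows} equations, {n_unknown} unknowns); "
            "use tikhonov > 0 or a larger ACS"
        )
    A = np.empty((positions.size, nro, bx * by * nc), dtype=complex)
    col = 0
    for i in range(bx):
        for j in range(by):
            src = acs[positions + int(dpe[i])]
            src = np.roll(src, -int(dro[j]), axis=1)
            A[:, :, col : col + nc] = src
            col += nc
    B = np.empty((positions.size, nro, R * nc), dtype=complex)
    for r in range(R):
        B[:, :, r * nc : (r + 1) * nc] = acs[positions + r]
    A = A.reshape(rows, n_unknown)
    B = B.reshape(rows, R * nc)
    if tikhonov > 0.0:
        AHA = A.conj().T @ A + tikhonov * np.eye(n_unknown)
        X = np.linalg.solve(AHA, A.conj().T @ B)
    else:
        X, *_ = np.linalg.lstsq(A, B, rcond=None)
    kernel = np.ascontiguousarray(
        X.reshape(bx, by, nc, R * nc)
    )
    cfg = NetworkConfig(nc=nc, R=R, channels=(), kernel_sizes=(kernel_size,), a=1.0)
    return cfg, LayerWeights([kernel])
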