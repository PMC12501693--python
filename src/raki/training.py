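"""Scan-specific calibration of the interpolation network on the ACS block.

All layers are trained jointly by minimizing the mean squared complex error
between interpolated and ground-truth ACS signals with Adam (learning rate
5e-4, the full ACS as one batch per iteration). Gradients with respect to
the complex kernels follow the Wirtinger convention (real and imaginary
parts treated as independent real parameters), which for this architecture
— dilated complex convolutions and a split real/imaginary leaky ReLU — has
a short closed form implemented directly in NumPy.

The ACS is normalized by its maximum modulus before training; because the
network (leaky ReLU included) is positively homogeneous, the trained
weights apply unchanged to data at any scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import LayerWeights, NetworkConfig, _shift2, _tap_offsets, clrelu

__all__ = ["TrainingConfig", "build_training_pairs", "train"]


@dataclass(frozen=True)
class TrainingConfig:
    lr: float = 5e-4
    epochs: int = 2000
    seed: int = 0
    early_stop_patience: int | None = 200

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _composite_pe_offsets(cfg: NetworkConfig) -> np.ndarray:
    """Minkowski sum of the per-layer dilated PE tap offsets (the receptive
    field of the whole network along PE)."""
    offs = np.array([0])
    for bx, _ in cfg.kernel_sizes:
        d, _ = _tap_offsets(bx, 1, cfg.R)
        offs = np.unique((offs[:, None] + d[None, :]).ravel())
    return offs


def build_training_pairs(
    acs: np.ndarray, cfg: NetworkConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Source/target pair emulating the undersampled geometry inside the ACS.

    The source is the ACS with only every R-th PE line retained; the target
    holds the true ACS values for all R PE-shift offsets in the same
    offset-major channel layout used at inference. Returns
    ``(source, target, valid_pe)`` where ``valid_pe`` marks the source-grid
    PE positions whose dilated receptive field and targets are fully
    supported by the ACS (the loss is evaluated only there).
    """
    acs = np.asarray(acs)
    npe, nro, nc = acs.shape
    if nc != cfg.nc:
        raise ValueError("ACS coil count does not match the configuration")
    R = cfg.R
    source = np.zeros_like(acs)
    source[::R] = acs[::R]
    target = np.empty((npe, nro, R * nc), dtype=complex)
    for r in range(R):
        rolled = np.roll(acs, -r, axis=0)  # wrapped rows removed by valid mask
        target[:, :, r * nc : (r + 1) * nc] = rolled
    offs = _composite_pe_offsets(cfg)
    p = np.arange(npe)
    valid = (
        (p % R == 0)
        & (p + offs.min() >= 0)
        & (p + offs.max() <= npe - 1)
        & (p + R - 1 <= npe - 1)
    )
    if not valid.any():
        raise ValueError(
            f"ACS with {npe} PE lines is too small for the dilated receptive field"
        )
    return source, target, valid


class _Adam:
    """Adam on the real/imaginary components of complex parameter arrays."""

    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.vr = [np.zeros_like(p, dtype=float) for p in params]
        self.vi = [np.zeros_like(p, dtype=float) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, (p, g) in enumerate(zip(params, grads)):
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.vr[k] = self.b2 * self.vr[k] + (1 - self.b2) * g.real**2
            self.vi[k] = self.b2 * self.vi[k] + (1 - self.b2) * g.imag**2
            mh = self.m[k] / b1t
            upd = mh.real / (np.sqrt(self.vr[k] / b2t) + self.eps) + 1j * (
                mh.imag / (np.sqrt(self.vi[k] / b2t) + self.eps)
            )
            p -= self.lr * upd


def _conv_forward(S, W, R):
    """Dilated circular conv via an im2col matrix (kept for the backward pass)."""
    bx, by, ci, co = W.shape
    npe, nro = S.shape[:2]
    dpe, dro = _tap_offsets(bx, by, R)
    cols = np.empty((npe * nro, bx * by * ci), dtype=complex)
    t = 0
    for i in range(bx):
        for j in range(by):
            cols[:, t * ci : (t + 1) * ci] = _shift2(
                S, int(dpe[i]), int(dro[j]), True
            ).reshape(npe * nro, ci)
            t += 1
    out = (cols @ W.reshape(bx * by * ci, co)).reshape(npe, nro, co)
    return out, cols


def _conv_backward(G, W, cols, R):
    """Gradients of a dilated conv: w.r.t. the kernel and the input."""
    bx, by, ci, co = W.shape
    npe, nro = G.shape[:2]
    dpe, dro = _tap_offsets(bx, by, R)
    G2 = G.reshape(npe * nro, co)
    gW = (cols.conj().T @ G2).reshape(W.shape)
    Gcol = G2 @ W.reshape(bx * by * ci, co).conj().T
    gS = np.zeros((npe, nro, ci), dtype=complex)
    t = 0
    for i in range(bx):
        for j in range(by):
            gS += _shift2(
                Gcol[:, t * ci : (t + 1) * ci].reshape(npe, nro, ci),
                -int(dpe[i]),
                -int(dro[j]),
                True,
            )
            t += 1
    return gW, gS


def _init_weights(cfg: NetworkConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Complex Glorot-style initialization, seeded."""
    out = []
    for (bx, by), (ci, co) in zip(cfg.kernel_sizes, cfg.layer_channels()):
        std = np.sqrt(1.0 / (bx * by * (ci + co)))
        w = std * (
            rng.standard_normal((bx, by, ci, co))
            + 1j * rng.standard_normal((bx, by, ci, co))
        ) / np.sqrt(2.0)
        out.append(w)
    return out


def train(
    acs: np.ndarray,
    net_cfg: NetworkConfig,
    train_cfg: TrainingConfig = TrainingConfig(),
) -> tuple[LayerWeights, np.ndarray]:
    """Jointly calibrate all layers on the ACS block.

    Returns the trained weights and the loss trace (one entry per epoch).
    Deterministic for a fixed seed. The weights returned are those with the
    lowest training loss encountered.
    """
    source, target, valid = build_training_pairs(acs, net_cfg)
    scale = np.abs(acs).max()
    if scale == 0:
        raise ValueError("all-zero ACS")
    source = source / scale
    target = target / scale
    vmask = valid[:, None, None]
    n_valid = int(valid.sum()) * target.shape[1] * target.shape[2]

    rng = np.random.default_rng(train_cfg.seed)
    params = _init_weights(net_cfg, rng)
    opt = _Adam(params, train_cfg.lr)
    a, R = net_cfg.a, net_cfg.R
    nhid = net_cfg.nhid
    trace = np.empty(train_cfg.epochs)
    best_loss, best_params, best_epoch = np.inf, None, 0

    for epoch in range(train_cfg.epochs):
        # forward
        S = source
        caches = []
        for k in range(nhid):
            pre, shifted = _conv_forward(S, params[k], R)
            S = clrelu(pre, a)
            caches.append((pre, shifted))
        out, shifted_f = _conv_forward(S, params[-1], R)

        resid = (out - target) * vmask
        loss = float((resid.real**2 + resid.imag**2).sum() / n_valid)
        trace[epoch] = loss
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}; "
                "check input scaling or reduce the learning rate"
            )
        if loss < best_loss:
            best_loss, best_epoch = loss, epoch
            best_params = [p.copy() for p in params]
        elif (
            train_cfg.early_stop_patience is not None
            and epoch - best_epoch > train_cfg.early_stop_patience
        ):
            trace = trace[: epoch + 1]
            break

        # backward (gradient w.r.t. real/imag parts: G = 2 * residual / n)
        G = 2.0 * resid / n_valid
        grads = [None] * len(params)
        grads[-1], G = _conv_backward(G, params[-1], shifted_f, R)
        for k in range(nhid - 1, -1, -1):
            pre, shifted = caches[k]
            G = np.where(pre.real >= 0, G.real, a * G.real) + 1j * np.where(
                pre.imag >= 0, G.imag, a * G.imag
            )
            grads[k], G = _conv_backward(G, params[k], shifted, R)
        opt.step(params, grads)

    return LayerWeights(best_params), trace
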