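"""Noise propagation through k-space interpolation networks.

Because the image-space parameterization renders inference as a chain of
elementwise multiplications and circular convolutions with fixed operators
once the activation masks are frozen at the operating point (first-order
linearization of the leaky ReLU), the Jacobian of every voxel of the
de-aliased, coil-combined image with respect to every voxel of the aliased
input coil images has a closed algebraic form. From it the g-factor — the
spatially resolved noise amplification of the accelerated reconstruction
relative to the fully sampled reference, normalized for the reduced sample
count — follows voxelwise:

    g_l = sqrt( sum_{m,t} |(J Pi)_l;mt|^2 Sigma2_tt )
          / sqrt( sum_h |P_lh|^2 Sigma2_hh ) / sqrt(R)

with P the sum-of-squares coil-combination weights and Sigma2 the coil
noise covariance (identity after prewhitening). ``Pi`` projects the input
coordinates onto the noise-carrying subspace — aliased images whose k-space
lives on the acquired R-spaced grid lines — which is exactly the set of
directions the pseudo-replica experiment perturbs. Row sums without this
projection are not equivalent: the activation masks carry an unavoidable
comb structure along PE (pre-activations vanish off the sampling grid), so
the free-input Jacobian has systematically correlated entries at aliasing
lags that an independent-voxel sum overcounts. For a one-linear-layer
network the Jacobian is voxel-diagonal, the projection reduces to the
factor 1/R, and the expression collapses to the classical image-space
GRAPPA g-factor.

Validation tooling included here: a frozen-mask central-finite-difference
Jacobian, pseudo-multiple-replica Monte Carlo g-factor maps, a classical
GRAPPA g-factor (independent closed form), and a voxelwise
Kolmogorov–Smirnov normality map for the replica magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .data import MultiCoilKSpace, SamplingScheme
from .fourier import ifft2c, pe_shift_ramp
from .image_space import ImageSpaceWeights, forward_image

__all__ = [
    "CoilCombinationWeights",
    "Jacobian",
    "GFactorMap",
    "ReplicaStack",
    "coil_combination",
    "analytic_jacobian",
    "numeric_jacobian",
    "analytic_gfactor",
    "analytic_gfactor_map",
    "montecarlo_gfactor",
    "grappa_gfactor_classical",
    "ks_normality",
    "crop_lowres",
]


@dataclass
class CoilCombinationWeights:
    """SOS combination as a linear map: ``combined_l = sum_h P[l, h] * coil_lh``.

    ``P_lh = conj(coil image)_lh / sos_l``; rows are unit-norm on the signal
    support and the combined value is real and equal to the SOS magnitude.
    """

    P: np.ndarray  # [PE, RO, nc]

    @property
    def support(self) -> np.ndarray:
        return (np.abs(self.P) ** 2).sum(-1) > 0


@dataclass
class Jacobian:
    """Derivative of each combined-image voxel w.r.t. each voxel of each
    aliased input coil image, ``J[l1, l2, m1, m2, t]`` (activation masks and
    coil-combination weights frozen at the operating point)."""

    J: np.ndarray  # [PE, RO, PE, RO, nc]


@dataclass
class GFactorMap:
    g: np.ndarray
    method: str
    valid: np.ndarray | None = None


@dataclass
class ReplicaStack:
    """Magnitude images of repeated reconstructions under resampled noise."""

    replicas: np.ndarray  # [nrep, PE, RO]
    seed: int
    noise_std: float  # per real/imaginary component, per k-space sample

    @property
    def nrep(self) -> int:
        return self.replicas.shape[0]


def coil_combination(coil_images: np.ndarray) -> tuple[np.ndarray, CoilCombinationWeights]:
    """Root-sum-of-squares magnitude combination and its linear weights."""
    if not np.any(coil_images):
        raise ValueError("all-zero coil images")
    sos = np.sqrt((np.abs(coil_images) ** 2).sum(-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(sos[..., None] > 0, coil_images.conj() / sos[..., None], 0.0)
    return sos, CoilCombinationWeights(P=P)


def _sigma_diag(sigma2, nc: int) -> np.ndarray:
    if sigma2 is None:
        return np.ones(nc)
    sigma2 = np.asarray(sigma2)
    if sigma2.ndim == 2:
        off = sigma2 - np.diag(np.diag(sigma2))
        if np.abs(off).max() > 1e-10 * max(np.abs(sigma2).max(), 1e-300):
            raise ValueError("g-factor evaluation expects a diagonal (prewhitened) covariance")
        sigma2 = np.diag(sigma2)
    return sigma2.real


def _circulant_from_mask(ahat: np.ndarray) -> np.ndarray:
    """Dense matrix of the centered circular convolution with one mask image."""
    n1, n2 = ahat.shape
    c1, c2 = n1 // 2, n2 // 2
    l = np.arange(n1 * n2)
    L1, L2 = l // n2, l % n2
    I1 = (c1 + L1[:, None] - L1[None, :]) % n1
    I2 = (c2 + L2[:, None] - L2[None, :]) % n2
    return ahat[I1, I2]


def analytic_jacobian(
    isw: ImageSpaceWeights,
    P: CoilCombinationWeights,
    memory_budget_bytes: float = 4e9,
) -> Jacobian:
    """Closed-form Jacobian by explicit layer-by-layer operator composition.

    Per hidden layer the operator factorizes into a diagonal channel
    contraction with W-hat followed by a circulant convolution with the
    activation-mask image; the final layer contracts with W-hat-int and the
    offset-recombination phase ramps; the coil dimension is folded with the
    frozen combination weights P. Intermediate Jacobians are held one layer
    at a time and contracted eagerly.

    Raises ``MemoryError`` when an intermediate would exceed the budget; use
    :func:`crop_lowres` for a centered low-resolution analysis in that case
    (32 x 32 typically captures the noise characteristics adequately), or
    :func:`analytic_gfactor_map` which never materializes the Jacobian.
    """
    nx, ny = isw.shape
    n = nx * ny
    nc = isw.nc
    ch_max = max([nc] + [w.shape[-1] for w in isw.what])
    need = n * n * nc * ch_max * 16
    if need > memory_budget_bytes:
        raise MemoryError(
            f"intermediate Jacobian would need ~{need / 1e9:.1f} GB; "
            "crop to a lower resolution (e.g. 32 x 32) or use analytic_gfactor_map"
        )
    # J: [n, ch, n * nc], base case: identity over (voxel, coil)
    J = np.zeros((n, nc, n * nc), dtype=complex)
    idx = np.arange(n)
    for t in range(nc):
        J[idx, t, idx * nc + t] = 1.0
    for What, Ahat in zip(isw.what, isw.ahat):
        Wf = What.reshape(n, What.shape[2], What.shape[3])
        Jd = np.einsum("xco,xcm->xom", Wf, J)
        ch_out = What.shape[3]
        J = np.empty((n, ch_out, n * nc), dtype=complex)
        for o in range(ch_out):
            C = _circulant_from_mask(Ahat[:, :, o])
            J[:, o, :] = C @ Jd[:, o, :]
    Wf = isw.what_int.reshape(n, isw.what_int.shape[2], isw.what_int.shape[3])
    Jint = np.einsum("xco,xcm->xom", Wf, J)
    # offset recombination via phase ramps, then P contraction
    r_start = 1 if isw.keep_acquired else 0
    Jcoil = np.zeros((n, nc, n * nc), dtype=complex)
    for r in range(r_start, isw.R):
        ramp = np.repeat(pe_shift_ramp(nx, r), ny)
        Jcoil += ramp[:, None, None] * Jint[:, r * nc : (r + 1) * nc, :]
    if isw.keep_acquired:
        for t in range(nc):
            Jcoil[idx, t, idx * nc + t] += 1.0
    Pf = P.P.reshape(n, nc)
    Jacc = np.einsum("xh,xhm->xm", Pf, Jcoil)
    return Jacobian(J=Jacc.reshape(nx, ny, nx, ny, nc))


def linearized_forward(isw: ImageSpaceWeights, P: CoilCombinationWeights):
    """The frozen-mask (complex-linear) map from aliased coil images to the
    combined image, as a callable accepting ``[..., PE, RO, nc]`` batches."""

    def apply(x: np.ndarray) -> np.ndarray:
        coil = forward_image(x, isw)
        return (coil * P.P).sum(-1)

    return apply


def numeric_jacobian(
    forward,
    x0: np.ndarray,
    eps: float = 1e-6,
) -> Jacobian:
    """Central-finite-difference Jacobian of a frozen-mask reconstruction.

    Perturbs each input voxel along the real and imaginary axes separately
    and assembles the complex derivative from the two; valid because the
    mask-frozen map is complex-linear. ``forward`` maps ``[PE, RO, nc]``
    aliased coil images to the complex combined image.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    nx, ny, nc = x0.shape
    J = np.empty((nx, ny, nx, ny, nc), dtype=complex)
    for m1 in range(nx):
        for m2 in range(ny):
            for t in range(nc):
                e = np.zeros_like(x0)
                e[m1, m2, t] = eps
                d_re = (forward(x0 + e) - forward(x0 - e)) / (2 * eps)
                d_im = (forward(x0 + 1j * e) - forward(x0 - 1j * e)) / (2 * eps)
                J[:, :, m1, m2, t] = 0.5 * (d_re - 1j * d_im)
    return Jacobian(J=J)


def analytic_gfactor(
    J: Jacobian,
    P: CoilCombinationWeights,
    sigma2=None,
    R: int = 1,
    grid_offset: int | None = None,
) -> GFactorMap:
    """g-factor map from a materialized Jacobian (see module docstring).

    The rows of J are transformed to k-space along the input-voxel axes and
    restricted to the acquired grid lines before the weighted row sum —
    the exact first-order noise propagation for comb-supported input noise.
    """
    nx, ny, _, _, nc = J.J.shape
    s2 = _sigma_diag(sigma2, nc)
    if grid_offset is None:
        grid_offset = (nx // 2) % R
    # k-space representation of each row over the input voxel axes
    rows_k = np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(J.J, axes=(2, 3)), axes=(2, 3), norm="ortho"),
        axes=(2, 3),
    )
    grid = np.arange(nx) % R == grid_offset % R
    num = np.einsum(
        "lkmnt,t->lk", np.abs(rows_k[:, :, grid, :, :]) ** 2, s2
    )
    den = ((np.abs(P.P) ** 2) * s2).sum(-1)
    valid = den > 0
    g = np.zeros_like(num)
    g[valid] = np.sqrt(num[valid] / den[valid]) / np.sqrt(R)
    return GFactorMap(g=g, method="analytic", valid=valid)


def analytic_gfactor_map(
    isw: ImageSpaceWeights,
    P: CoilCombinationWeights,
    sigma2=None,
    chunk: int = 256,
    grid_offset: int | None = None,
) -> GFactorMap:
    """g-factor map without materializing the Jacobian.

    Propagates an orthonormal basis of the noise-carrying subspace — unit
    k-space impulses on the acquired grid lines — through the frozen-mask
    linear map in chunks and accumulates the weighted squared responses;
    algebraically identical to :func:`analytic_jacobian` +
    :func:`analytic_gfactor` but with memory bounded by the chunk size.
    """
    nx, ny = isw.shape
    nc = isw.nc
    s2 = _sigma_diag(sigma2, nc)
    fwd = linearized_forward(isw, P)
    if grid_offset is None:
        grid_offset = isw.grid_offset
    glines = np.arange(nx)[np.arange(nx) % isw.R == grid_offset % isw.R]
    cols = [(gl, q) for gl in glines for q in range(ny)]
    num = np.zeros((nx, ny))
    for t in range(nc):
        for start in range(0, len(cols), chunk):
            batch = cols[start : start + chunk]
            kb = np.zeros((len(batch), nx, ny, nc), dtype=complex)
            for b, (gl, q) in enumerate(batch):
                kb[b, gl, q, t] = 1.0
            xb = ifft2c(kb, axes=(1, 2))
            num += s2[t] * (np.abs(fwd(xb)) ** 2).sum(0)
    den = ((np.abs(P.P) ** 2) * s2).sum(-1)
    valid = den > 0
    g = np.zeros_like(num)
    g[valid] = np.sqrt(num[valid] / den[valid]) / np.sqrt(isw.R)
    return GFactorMap(g=g, method="analytic", valid=valid)


def montecarlo_gfactor(
    reconstruct,
    ks: MultiCoilKSpace,
    P: CoilCombinationWeights,
    nrep: int = 1000,
    seed: int = 0,
    noise_std: float = 1.0 / np.sqrt(2.0),
    sigma2=None,
    R: int | None = None,
) -> tuple[GFactorMap, np.ndarray, np.ndarray, ReplicaStack]:
    """Pseudo-multiple-replica g-factor estimation.

    Repeats the (fixed-weight) reconstruction ``nrep`` times on the measured
    k-space superimposed with iid circular complex Gaussian noise on the
    sampled entries (``noise_std`` per real/imaginary component), records the
    combined magnitude image, and converts the voxelwise variance of the
    stack into a g-factor map using the analytic fully-sampled reference
    variance. The magnitude variance estimates the along-signal noise
    component, so the reference variance enters per component; data should
    be prewhitened.

    ``reconstruct`` maps a noisy k-space data array to the combined
    magnitude image. Returns (g map, variance map, SNR map, replica stack).
    """
    if nrep < 2:
        raise ValueError("nrep must be >= 2")
    if ks.scheme is None:
        raise ValueError("undersampled data with a sampling scheme is required")
    R = R if R is not None else ks.scheme.R
    nc = ks.nc
    s2 = _sigma_diag(sigma2, nc)
    rng = np.random.default_rng(seed)
    mask = ks.scheme.mask()[:, :, None]
    nx, ny = ks.data.shape[:2]
    replicas = np.empty((nrep, nx, ny))
    for i in range(nrep):
        noise = noise_std * (
            rng.standard_normal((nx, ny, nc)) + 1j * rng.standard_normal((nx, ny, nc))
        )
        replicas[i] = reconstruct(ks.data + noise * mask)
    var = replicas.var(axis=0, ddof=1)
    mean = replicas.mean(axis=0)
    # per-component reference variance for the added-noise level
    den = (noise_std**2) * ((np.abs(P.P) ** 2) * s2).sum(-1)
    valid = den > 0
    g = np.zeros_like(var)
    g[valid] = np.sqrt(var[valid] / den[valid]) / np.sqrt(R)
    with np.errstate(invalid="ignore", divide="ignore"):
        snr = np.where(var > 0, mean / np.sqrt(var), 0.0)
    stack = ReplicaStack(replicas=replicas, seed=seed, noise_std=noise_std)
    return GFactorMap(g=g, method="montecarlo", valid=valid), var, snr, stack


def grappa_gfactor_classical(
    kernel: np.ndarray,
    scheme: SamplingScheme,
    P: CoilCombinationWeights,
    sigma2=None,
    keep_acquired: bool = True,
) -> GFactorMap:
    """Classical image-space GRAPPA g-factor (independent closed form).

    Builds the effective elementwise image-domain weights of a one-layer
    linear interpolation directly from the kernel taps — each tap at PE
    offset ``d`` contributing to the line placed ``r`` above a sampled line
    lands at net k-space offset ``d - r`` — evaluates the Fourier sum
    explicitly, and applies the standard formula

        g_l = sqrt( sum_t |sum_h P_lh W_lht|^2 S2_tt )
              / sqrt( sum_h |P_lh|^2 S2_hh ) / R .

    Shares no code with the chain-rule Jacobian machinery.
    """
    bx, by, nc_in, n_out = kernel.shape
    R = scheme.R
    nc = n_out // R
    nx, ny = scheme.npe, scheme.nro
    s2 = _sigma_diag(sigma2, nc_in)
    dpe = (np.arange(bx) - (bx - 1) // 2) * R
    dro = np.arange(by) - (by - 1) // 2
    px = (np.arange(nx) - nx // 2)[:, None]
    qy = (np.arange(ny) - ny // 2)[None, :]
    W_img = np.zeros((nx, ny, nc, nc_in), dtype=complex)  # [voxel, target h, source t]
    r_start = 1 if keep_acquired else 0
    for r in range(r_start, R):
        for i in range(bx):
            for j in range(by):
                phase = np.exp(
                    -2j * np.pi * ((dpe[i] - r) * px / nx + dro[j] * qy / ny)
                )
                W_img += phase[:, :, None, None] * kernel[i, j, :, r * nc : (r + 1) * nc].T
    if keep_acquired:
        W_img += np.eye(nc)[None, None]
    comb = np.einsum("xyh,xyht->xyt", P.P, W_img)
    num = ((np.abs(comb) ** 2) * s2).sum(-1)
    den = ((np.abs(P.P) ** 2) * s2[:nc]).sum(-1)
    valid = den > 0
    g = np.zeros_like(num)
    g[valid] = np.sqrt(num[valid] / den[valid]) / R
    return GFactorMap(g=g, method="analytic-classical", valid=valid)


def ks_normality(
    stack: ReplicaStack, alpha: float = 0.05, support: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Voxelwise Kolmogorov–Smirnov normality test of the replica magnitudes.

    A normal distribution with the voxel's sample mean and standard deviation
    is fitted and the KS statistic evaluated against it (parameters estimated
    from the same sample, as is conventional for this diagnostic; this makes
    the test conservative). Returns (p-value map, pass mask ``p > alpha``,
    pass fraction over the evaluated voxels). Zero-variance voxels are
    excluded from the mask and the fraction.
    """
    if stack.nrep < 100:
        raise ValueError("need at least 100 replicas for a meaningful KS map")
    nrep, nx, ny = stack.replicas.shape
    if support is None:
        support = np.ones((nx, ny), dtype=bool)
    pmap = np.full((nx, ny), np.nan)
    passmask = np.zeros((nx, ny), dtype=bool)
    n_eval = 0
    n_pass = 0
    for l1, l2 in zip(*np.nonzero(support)):
        sample = stack.replicas[:, l1, l2]
        mu, sd = sample.mean(), sample.std(ddof=1)
        if sd == 0:
            continue
        p = stats.kstest(sample, "norm", args=(mu, sd)).pvalue
        pmap[l1, l2] = p
        ok = p > alpha
        passmask[l1, l2] = ok
        n_eval += 1
        n_pass += int(ok)
    frac = n_pass / n_eval if n_eval else float("nan")
    return pmap, passmask, frac


def crop_lowres(ks: MultiCoilKSpace, size: tuple[int, int]) -> MultiCoilKSpace:
    """Centered k-space crop for low-resolution noise analysis.

    Keeps the central ``px x py`` samples exactly and re-derives the
    sampling metadata (grid offset, ACS interval) on the cropped grid so
    trained kernels — translation invariant — apply unchanged.
    """
    px, py = size
    nx, ny = ks.data.shape[:2]
    if px > nx or py > ny:
        raise ValueError("crop exceeds the matrix size")
    x0 = nx // 2 - px // 2
    y0 = ny // 2 - py // 2
    data = ks.data[x0 : x0 + px, y0 : y0 + py]
    scheme = ks.scheme
    new_scheme = None
    if scheme is not None:
        acs0 = max(scheme.acs[0] - x0, 0)
        acs1 = min(scheme.acs[1] - x0, px)
        new_scheme = SamplingScheme(
            npe=px,
            nro=py,
            R=scheme.R,
            acs=(min(max(acs0, 0), px), min(max(acs1, acs0), px)),
            grid_offset=(scheme.grid_offset - x0) % scheme.R,
        )
    out = replace(ks, data=data.copy(), scheme=new_scheme)
    if ks.coils is not None:
        out = replace(out, coils=None)
    if ks.phantom is not None:
        out = replace(out, phantom=None)
    return out
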