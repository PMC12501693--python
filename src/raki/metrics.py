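"""Reconstruction metrics, parameter sweeps, and activation-mask structure.

The negative-slope sweep quantifies the regularization role of the leaky
ReLU slope ``a``: reconstruction error (NMSE against the known ground
truth) and mean analytic g-factor as functions of ``a``, with ``a = 1`` the
linear multi-layer (GRAPPA-like) limit and ``a = 0`` maximum nonlinearity /
maximum noise suppression. The mask characterization measures how much the
image-domain activation masks deviate from the delta of the linear limit
and how strongly they resemble the signal they activate — the resemblance
that produces the zero-lag "autocorrelation" peak at the image center.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from skimage.metrics import structural_similarity

from .data import MultiCoilKSpace, SamplingScheme, undersample
from .fourier import fft2c, ifft2c
from .image_space import ImageSpaceWeights, extract_image_weights, reconstruct_kspace_path
from .network import NetworkConfig
from .noise import (
    analytic_gfactor_map,
    coil_combination,
    crop_lowres,
    montecarlo_gfactor,
)
from .training import TrainingConfig, train

__all__ = [
    "SweepResult",
    "MaskCharacterization",
    "nmse",
    "ssim_psnr",
    "sweep_slope",
    "base_snr_sweep",
    "mask_autocorrelation",
    "center_peak_score",
]


def nmse(recon: np.ndarray, reference: np.ndarray, support: np.ndarray | None = None) -> float:
    """Normalized mean squared error over the support: sum|x-ref|^2 / sum|ref|^2."""
    recon = np.asarray(recon)
    reference = np.asarray(reference)
    if recon.shape != reference.shape:
        raise ValueError("shapes disagree")
    if support is None:
        support = np.ones(reference.shape, dtype=bool)
    if not support.any():
        raise ValueError("empty support")
    num = (np.abs(recon - reference)[support] ** 2).sum()
    den = (np.abs(reference)[support] ** 2).sum()
    return float(num / den)


def ssim_psnr(
    recon: np.ndarray, reference: np.ndarray, support: np.ndarray | None = None
) -> tuple[float, float]:
    """Structural similarity and peak SNR of magnitude images over a support.

    SSIM uses the standard constants (K1=0.01, K2=0.03, 7x7 window) with the
    reference's dynamic range; the SSIM map is averaged over the support.
    PSNR is ``10 log10(peak^2 / MSE)`` with the peak taken from the
    reference over the support.
    """
    x = np.abs(np.asarray(recon)).astype(float)
    ref = np.abs(np.asarray(reference)).astype(float)
    if support is None:
        support = np.ones(ref.shape, dtype=bool)
    if not support.any():
        raise ValueError("empty support")
    drange = ref.max() - ref.min()
    _, smap = structural_similarity(ref, x, data_range=drange, full=True)
    ssim = float(smap[support].mean())
    mse = float(((x - ref)[support] ** 2).mean())
    peak = float(ref[support].max())
    psnr = float(10 * np.log10(peak**2 / mse)) if mse > 0 else float("inf")
    return ssim, psnr


@dataclass
class SweepResult:
    a_values: list[float]
    nmse: list[float]
    mean_g: list[float]
    g_maps: list[np.ndarray | None]
    recons: list[np.ndarray | None]


@dataclass
class MaskCharacterization:
    """Per hidden layer: off-center energy fraction and signal resemblance
    (peak normalized cross-correlation) per channel; plus the center-peak
    score of the combined reconstruction (an invented quantification of the
    qualitative central-artifact description)."""

    off_center_energy: list[np.ndarray]
    signal_correlation: list[np.ndarray]
    center_peak: float | None = None


def _reference_sos(full_ks: MultiCoilKSpace) -> np.ndarray:
    return np.sqrt((np.abs(ifft2c(full_ks.data)) ** 2).sum(-1))


def _support_from(ks: MultiCoilKSpace, threshold: float = 0.1) -> np.ndarray:
    if ks.phantom is not None:
        return np.abs(ks.phantom) > threshold * np.abs(ks.phantom).max()
    sos = _reference_sos(ks)
    return sos > threshold * sos.max()


def sweep_slope(
    full_ks: MultiCoilKSpace,
    scheme: SamplingScheme,
    net_cfg: NetworkConfig,
    train_cfg: TrainingConfig,
    a_values=None,
    gfactor_size: tuple[int, int] | None = (32, 32),
    support_threshold: float = 0.1,
) -> SweepResult:
    """Train/reconstruct/measure across negative-slope values.

    For each ``a`` the network is trained from the same seed on the ACS of
    the retrospectively undersampled data, the reconstruction NMSE against
    the fully sampled reference is evaluated on the signal support, and the
    mean analytic g-factor is computed on a centered low-resolution crop
    (trained kernels are translation invariant, so they apply unchanged).
    Per-``a`` failures are recorded as NaN without aborting the sweep.
    """
    if a_values is None:
        a_values = [round(0.1 * i, 1) for i in range(11)]
    und = undersample(full_ks, scheme)
    ref = _reference_sos(full_ks)
    support = _support_from(full_ks, support_threshold)
    out = SweepResult(list(a_values), [], [], [], [])
    for a in a_values:
        try:
            cfg = dc_replace(net_cfg, a=float(a))
            weights, _ = train(und.acs_block(), cfg, train_cfg)
            coil = reconstruct_kspace_path(cfg, weights, und)
            sos, _ = coil_combination(coil)
            err = nmse(sos, ref, support)
            if gfactor_size is not None:
                low = crop_lowres(und, gfactor_size)
                low_full = crop_lowres(full_ks, gfactor_size)
                isw, _ = extract_image_weights(cfg, weights, low)
                coil_low = reconstruct_kspace_path(cfg, weights, low)
                _, P = coil_combination(coil_low)
                gmap = analytic_gfactor_map(isw, P)
                sup_low = _support_from(low_full, support_threshold) & gmap.valid
                mg = float(gmap.g[sup_low].mean())
                out.g_maps.append(gmap.g)
            else:
                mg, gmap = float("nan"), None
                out.g_maps.append(None)
            out.nmse.append(err)
            out.mean_g.append(mg)
            out.recons.append(sos)
        except Exception:
            out.nmse.append(float("nan"))
            out.mean_g.append(float("nan"))
            out.g_maps.append(None)
            out.recons.append(None)
    return out


def base_snr_sweep(
    full_ks: MultiCoilKSpace,
    scheme: SamplingScheme,
    net_cfg: NetworkConfig,
    train_cfg: TrainingConfig,
    sigmas=(0.0, 3.0, 5.0),
    gfactor_size: tuple[int, int] = (32, 32),
    nrep: int = 200,
    seed: int = 0,
    support_threshold: float = 0.1,
):
    """Baseline-SNR dependence of the g-factor.

    Per noise level sigma (per real/imaginary component, in units of the
    prewhitened noise std) Gaussian noise is added to both the retrospectively
    undersampled and the fully sampled reference data, the network retrained,
    and analytic and Monte Carlo g maps computed on a centered crop. Returns
    one record per sigma with the recon, both g maps and their agreement.
    """
    rng = np.random.default_rng(seed)
    ref0 = _reference_sos(full_ks)
    support = _support_from(full_ks, support_threshold)
    records = []
    for sigma in sigmas:
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        noisy = full_ks
        if sigma > 0:
            extra = sigma * (
                rng.standard_normal(full_ks.data.shape)
                + 1j * rng.standard_normal(full_ks.data.shape)
            )
            noisy = dc_replace(full_ks, data=full_ks.data + extra)
        und = undersample(noisy, scheme)
        weights, _ = train(und.acs_block(), net_cfg, train_cfg)
        coil = reconstruct_kspace_path(net_cfg, weights, und)
        sos, _ = coil_combination(coil)
        low = crop_lowres(und, gfactor_size)
        isw, _ = extract_image_weights(net_cfg, weights, low)
        coil_low = reconstruct_kspace_path(net_cfg, weights, low)
        _, P = coil_combination(coil_low)
        g_an = analytic_gfactor_map(isw, P)

        def _mc_recon(data, cfg=net_cfg, w=weights, sch=low.scheme):
            ci = reconstruct_kspace_path(cfg, w, MultiCoilKSpace(data=data, scheme=sch))
            return np.sqrt((np.abs(ci) ** 2).sum(-1))

        g_mc, _, _, _ = montecarlo_gfactor(
            _mc_recon, low, P, nrep=nrep, seed=seed, R=scheme.R
        )
        low_full = crop_lowres(noisy, gfactor_size)
        sup_low = _support_from(low_full, support_threshold) & g_an.valid & g_mc.valid
        r = float(np.corrcoef(g_an.g[sup_low], g_mc.g[sup_low])[0, 1])
        records.append(
            {
                "sigma": float(sigma),
                "nmse": nmse(sos, ref0, support),
                "recon": sos,
                "g_analytic": g_an,
                "g_montecarlo": g_mc,
                "mean_g": float(g_an.g[sup_low].mean()),
                "correlation": r,
            }
        )
    return records


def center_peak_score(
    image: np.ndarray, r_inner: int = 2, r_outer: int = 8
) -> float:
    """Magnitude at the center pixel over the median magnitude in a
    surrounding annulus — > 1 indicates a central bright-spot artifact."""
    mag = np.abs(image)
    nx, ny = mag.shape
    cx, cy = nx // 2, ny // 2
    x = np.arange(nx)[:, None] - cx
    y = np.arange(ny)[None, :] - cy
    rad = np.hypot(x, y)
    annulus = (rad > r_inner) & (rad <= r_outer)
    med = np.median(mag[annulus])
    return float(mag[cx, cy] / med) if med > 0 else float("inf")


def mask_autocorrelation(
    isw: ImageSpaceWeights,
    preactivations: list[np.ndarray],
    recon_image: np.ndarray | None = None,
) -> MaskCharacterization:
    """Characterize the image-domain activation masks of one inference pass.

    Per hidden layer and channel: (i) the fraction of mask energy off the
    zero-lag (center) pixel — zero in the linear limit where every mask is a
    delta; (ii) the peak normalized cross-correlation between the mask
    magnitude and the magnitude image of the signal being activated, which
    measures the spatial resemblance behind the zero-lag artifact. If a
    combined reconstruction is supplied its center-peak score is attached.
    """
    off = []
    corr = []
    for Ahat, Sprime in zip(isw.ahat, preactivations):
        nx, ny, ch = Ahat.shape
        cx, cy = nx // 2, ny // 2
        energy = (np.abs(Ahat) ** 2).sum(axis=(0, 1))
        center = np.abs(Ahat[cx, cy]) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            off.append(np.where(energy > 0, 1.0 - center / energy, 0.0))
        sig_img = np.abs(ifft2c(Sprime))
        mask_img = np.abs(Ahat)
        cc = np.empty(ch)
        for c in range(ch):
            f = mask_img[:, :, c] - mask_img[:, :, c].mean()
            g = sig_img[:, :, c] - sig_img[:, :, c].mean()
            nf, ng = np.linalg.norm(f), np.linalg.norm(g)
            if nf == 0 or ng == 0:
                cc[c] = 0.0
                continue
            # circular cross-correlation over all lags via the FFT
            x = np.fft.ifft2(np.fft.fft2(f) * np.conj(np.fft.fft2(g))).real
            cc[c] = float(x.max() / (nf * ng))
        corr.append(cc)
    score = center_peak_score(recon_image) if recon_image is not None else None
    return MaskCharacterization(
        off_center_energy=off, signal_correlation=corr, center_peak=score
    )
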