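"""HDF5 containers for datasets and weight checkpoints; map exports."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .data import MultiCoilKSpace, SamplingScheme
from .network import LayerWeights, NetworkConfig

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_weights",
    "load_weights",
    "save_nifti",
    "save_png",
]


def save_dataset(path, ks: MultiCoilKSpace, group: str = "dataset") -> None:
    """One group per dataset: /kspace complex [PE, RO, coil], /mask uint8,
    optional /coils and /phantom; acquisition metadata as attributes."""
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("kspace", data=ks.data)
        if ks.scheme is not None:
            g.create_dataset("mask", data=ks.scheme.mask().astype(np.uint8))
            g.attrs["R"] = ks.scheme.R
            g.attrs["acs_start"], g.attrs["acs_stop"] = ks.scheme.acs
            g.attrs["grid_offset"] = ks.scheme.grid_offset
        g.attrs["pe_axis"] = 0
        if ks.noise_cov is not None:
            g.create_dataset("noise_cov", data=ks.noise_cov)
        if ks.coils is not None:
            g.create_dataset("coils", data=ks.coils)
        if ks.phantom is not None:
            g.create_dataset("phantom", data=ks.phantom)


def load_dataset(path, group: str = "dataset") -> MultiCoilKSpace:
    with h5py.File(path, "r") as f:
        g = f[group]
        data = g["kspace"][()]
        scheme = None
        if "R" in g.attrs:
            scheme = SamplingScheme(
                npe=data.shape[0],
                nro=data.shape[1],
                R=int(g.attrs["R"]),
                acs=(int(g.attrs["acs_start"]), int(g.attrs["acs_stop"])),
                grid_offset=int(g.attrs["grid_offset"]),
            )
        return MultiCoilKSpace(
            data=data,
            scheme=scheme,
            noise_cov=g["noise_cov"][()] if "noise_cov" in g else None,
            coils=g["coils"][()] if "coils" in g else None,
            phantom=g["phantom"][()] if "phantom" in g else None,
        )


def save_weights(path, cfg: NetworkConfig, weights: LayerWeights) -> None:
    """Checkpoint: one complex dataset per layer plus the JSON-serialized
    network configuration as a file attribute."""
    with h5py.File(path, "w") as f:
        for k, W in enumerate(weights.layers):
            f.create_dataset(f"layer{k}/weights", data=W)
        f.attrs["config"] = json.dumps(
            {
                "nc": cfg.nc,
                "R": cfg.R,
                "channels": list(cfg.channels),
                "kernel_sizes": [list(ks) for ks in cfg.kernel_sizes],
                "a": cfg.a,
            }
        )


def load_weights(path) -> tuple[NetworkConfig, LayerWeights]:
    with h5py.File(path, "r") as f:
        d = json.loads(f.attrs["config"])
        cfg = NetworkConfig(
            nc=d["nc"],
            R=d["R"],
            channels=tuple(d["channels"]),
            kernel_sizes=tuple(tuple(ks) for ks in d["kernel_sizes"]),
            a=d["a"],
        )
        layers = [
            f[f"layer{k}/weights"][()] for k in range(len(cfg.kernel_sizes))
        ]
        return cfg, LayerWeights(layers)


def save_nifti(path, image: np.ndarray) -> None:
    """Export a real 2D map (g-factor, SNR, |mask|) as NIfTI."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(image, dtype=np.float64)[:, :, None], np.eye(4))
    nib.save(img, str(path))


def save_png(path, image: np.ndarray, cmap: str = "viridis") -> None:
    """Export a real 2D map as PNG (magnitude taken for complex input)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    arr = np.abs(np.asarray(image)).astype(float)
    plt.imsave(str(path), arr, cmap=cmap)
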