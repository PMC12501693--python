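"""scikit-learn style reconstruction estimators.

Scan-specific k-space interpolation is a fit/transform problem: ``fit``
calibrates the interpolation weights on the ACS block of an undersampled
acquisition, ``transform`` fills the missing k-space lines of (that or
compatible) data. Both estimators follow the scikit-learn contract —
constructor parameters mirrored by ``get_params``/``set_params``, fitted
state in trailing-underscore attributes — so they compose with sklearn
pipelines and model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data import MultiCoilKSpace
from .image_space import extract_image_weights, reconstruct_kspace_path
from .network import (
    LayerWeights,
    NetworkConfig,
    assemble_reconstruction,
    count_parameters,
    forward_kspace,
    grappa_calibrate,
)
from .noise import analytic_gfactor_map, coil_combination, montecarlo_gfactor
from .training import TrainingConfig, train

__all__ = ["RakiReconstructor", "GrappaReconstructor"]


class _BaseReconstructor(TransformerMixin, BaseEstimator):
    """Shared inference/analysis surface; subclasses provide calibration."""

    keep_acquired: bool

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise AttributeError("reconstructor is not fitted; call fit(ks) first")

    def transform(self, X: MultiCoilKSpace) -> np.ndarray:
        """De-aliased coil k-space ``[PE, RO, nc]``."""
        self._check_fitted()
        grid = MultiCoilKSpace(data=X.grid_only(), scheme=X.scheme)
        Sint = forward_kspace(self.config_, self.weights_, grid.data)
        return assemble_reconstruction(grid, Sint, X.scheme, self.keep_acquired)

    def coil_images(self, X: MultiCoilKSpace) -> np.ndarray:
        self._check_fitted()
        return reconstruct_kspace_path(
            self.config_, self.weights_, X, self.keep_acquired
        )

    def reconstruct(self, X: MultiCoilKSpace) -> np.ndarray:
        """Combined (root-sum-of-squares) magnitude image."""
        sos, _ = coil_combination(self.coil_images(X))
        return sos

    def gfactor(
        self,
        X: MultiCoilKSpace,
        method: str = "analytic",
        nrep: int = 1000,
        seed: int = 0,
    ):
        """Noise-amplification map of the fitted reconstruction on ``X``."""
        self._check_fitted()
        coil = self.coil_images(X)
        _, P = coil_combination(coil)
        if method == "analytic":
            isw, _ = extract_image_weights(
                self.config_, self.weights_, X, keep_acquired=self.keep_acquired
            )
            return analytic_gfactor_map(isw, P)
        if method == "montecarlo":

            def _recon(data):
                ks = MultiCoilKSpace(data=data, scheme=X.scheme)
                return self.reconstruct(ks)

            g, _, _, _ = montecarlo_gfactor(_recon, X, P, nrep=nrep, seed=seed)
            return g
        raise ValueError(f"unknown g-factor method: {method!r}")


class RakiReconstructor(_BaseReconstructor):
    """Scan-specific nonlinear k-space interpolation (RAKI).

    Parameters
    ----------
    channels : hidden-layer widths (two hidden layers of 128/64 by default).
    kernel_sizes : (bx, by) per hidden layer plus the final linear layer.
    a : negative slope of the complex leaky ReLU; 1.0 recovers a linear
        multi-layer (GRAPPA-like) model, 0.0 is maximally nonlinear.
    lr, epochs, early_stop_patience, seed : Adam calibration settings.

    Attributes (after fit)
    ----------------------
    config_ : resolved :class:`NetworkConfig` (R and nc from the data).
    weights_ : trained :class:`LayerWeights`.
    loss_trace_ : per-epoch training loss.
    n_parameters_ : real trainable parameter count.
    """

    def __init__(
        self,
        channels=(128, 64),
        kernel_sizes=((2, 5), (1, 1), (1, 5)),
        a=0.5,
        lr=5e-4,
        epochs=2000,
        early_stop_patience=200,
        seed=0,
        keep_acquired=True,
    ):
        self.channels = channels
        self.kernel_sizes = kernel_sizes
        self.a = a
        self.lr = lr
        self.epochs = epochs
        self.early_stop_patience = early_stop_patience
        self.seed = seed
        self.keep_acquired = keep_acquired

    def fit(self, X: MultiCoilKSpace, y=None):
        if X.scheme is None:
            raise ValueError("fit requires undersampled data with ACS metadata")
        cfg = NetworkConfig(
            nc=X.nc,
            R=X.scheme.R,
            channels=tuple(self.channels),
            kernel_sizes=tuple(tuple(k) for k in self.kernel_sizes),
            a=float(self.a),
        )
        tcfg = TrainingConfig(
            lr=self.lr,
            epochs=self.epochs,
            seed=self.seed,
            early_stop_patience=self.early_stop_patience,
        )
        self.weights_, self.loss_trace_ = train(X.acs_block(), cfg, tcfg)
        self.config_ = cfg
        self.n_parameters_ = count_parameters(cfg)
        return self


class GrappaReconstructor(_BaseReconstructor):
    """Linear k-space interpolation with a least-squares calibrated kernel.

    Equivalent to a zero-hidden-layer network with identity activation, so
    the image-space transfer and g-factor machinery apply unchanged.
    """

    def __init__(self, kernel_size=(2, 5), tikhonov=0.0, keep_acquired=True):
        self.kernel_size = kernel_size
        self.tikhonov = tikhonov
        self.keep_acquired = keep_acquired

    def fit(self, X: MultiCoilKSpace, y=None):
        if X.scheme is None:
            raise ValueError("fit requires undersampled data with ACS metadata")
        self.config_, self.weights_ = grappa_calibrate(
            X.acs_block(), tuple(self.kernel_size), X.scheme.R, self.tikhonov
        )
        self.n_parameters_ = count_parameters(self.config_)
        return self
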