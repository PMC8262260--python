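"""Two-component Gaussian-mixture thresholding for QC covariates.

Fitted on the per-droplet mito-ribo ratio, the local minimum of the mixture
density between the two component means provides a data-driven cutoff for
putative apoptotic/low-quality droplets; the same machinery applies to any 1-D
covariate (e.g. log nGenes).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture


class GmmThreshold(BaseEstimator):
    """1-D two-component Gaussian mixture with a density-minimum threshold.

    Attributes (after fit): ``weights_`` (sum to 1), ``means_`` (ascending),
    ``variances_``, ``converged_``, and ``threshold_`` — the local minimum of
    the mixture density strictly between the component means.
    """

    def __init__(
        self,
        n_init: int = 10,
        tol: float = 1e-6,
        max_iter: int = 500,
        random_state: int = 0,
        grid_step: float = 1e-3,
    ):
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.grid_step = grid_step

    def fit(self, values, y=None):
        x = np.asarray(values, dtype=float).ravel()
        if x.size < 50:
            raise ValueError("GMM fit needs at least 50 values")
        if np.ptp(x) == 0 or x.std() == 0:
            raise ValueError("degenerate input: zero variance")
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            n_init=self.n_init,
            tol=self.tol,
            max_iter=self.max_iter,
            random_state=self.random_state,
        ).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        self.weights_ = gm.weights_[order]
        self.means_ = gm.means_.ravel()[order]
        self.variances_ = gm.covariances_.ravel()[order]
        self.converged_ = bool(gm.converged_)
        if not self.converged_:
            warnings.warn("EM did not converge in any restart")
        self.threshold_ = mixture_local_min(self, grid_step=self.grid_step)
        return self

    @classmethod
    def from_params(cls, weights, means, variances) -> "GmmThreshold":
        """Build an already-'fitted' model from explicit mixture parameters."""
        self = cls()
        w = np.asarray(weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        order = np.argsort(np.asarray(means, dtype=float))
        self.weights_ = w[order]
        self.means_ = np.asarray(means, dtype=float)[order]
        self.variances_ = np.asarray(variances, dtype=float)[order]
        self.converged_ = True
        self.threshold_ = mixture_local_min(self)
        return self

    def density(self, x):
        x = np.asarray(x, dtype=float)
        return sum(
            w * norm.pdf(x, loc=m, scale=np.sqrt(v))
            for w, m, v in zip(self.weights_, self.means_, self.variances_)
        )

    def predict(self, values) -> np.ndarray:
        """Flag values strictly above the fitted threshold."""
        return np.asarray(values, dtype=float) > self.threshold_


def fit_gmm2(
    values, seed: int = 0, n_init: int = 10, tol: float = 1e-6, max_iter: int = 500
) -> GmmThreshold:
    """EM fit with seeded restarts; best log-likelihood kept (deterministic per seed)."""
    return GmmThreshold(
        n_init=n_init, tol=tol, max_iter=max_iter, random_state=seed
    ).fit(values)


def mixture_local_min(fit: GmmThreshold, grid_step: float = 1e-3) -> float:
    """Local minimum of the mixture density between the component means.

    Grid argmin over [mean1, mean2], refined to ~1e-6 by bounded scalar
    minimisation. A density monotone on the interval (no interior minimum)
    raises: the fitted mixture is effectively unimodal and a threshold is not
    meaningful.
    """
    m1, m2 = fit.means_
    if not m2 > m1:
        raise ValueError("component means must be separated")
    grid = np.arange(m1, m2 + grid_step, grid_step)
    dens = fit.density(grid)
    idx = int(np.argmin(dens))
    if idx == 0 or idx == len(grid) - 1:
        raise ValueError(
            "mixture density is monotone between the means; data look unimodal"
        )
    res = minimize_scalar(
        lambda x: float(fit.density(x)),
        bounds=(grid[idx - 1], grid[idx + 1]),
        method="bounded",
        options={"xatol": 1e-9},
    )
    return float(res.x)


def flag_dying(features: pd.DataFrame, threshold: float) -> pd.Series:
    """Per-barcode apoptosis flag: mito-ribo ratio strictly above the threshold."""
    return (features["mito_ribo_ratio"] > threshold).rename("dying")
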