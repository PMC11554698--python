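"""Functional-network inference from parcel time series.

The functional connectome edge weight between two parcels is their partial
correlation — the correlation that remains after regressing out every other
parcel's signal. Rather than inverting a (possibly rank-deficient) sample
covariance, each parcel is regressed on all others with an elastic-net
penalty (node-wise neighborhood regression); the penalty simultaneously
sparsifies and regularizes, which is what makes the estimate usable when the
number of parcels approaches or exceeds the number of timepoints. The two
directed coefficients b_ij (i on j) and b_ji are combined into a symmetric
edge weight by a sign-consistent geometric mean, zero when the signs
disagree — in the unpenalized limit this recovers the analytic partial
correlation -Omega_ij / sqrt(Omega_ii * Omega_jj) exactly.

A parcel's summary signal is the principal left singular vector of its
(time x voxels) BOLD block — the first temporal principal component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import ElasticNet, ElasticNetCV

from .connectome import Connectome
from .exceptions import DegenerateInputError, InvalidParameterError

__all__ = ["TimeSeriesPanel", "summary_signal", "partial_correlation_network", "DEFAULT_PENALTY_GRID"]

#: Log-spaced candidate penalties used when ``penalty`` is left to internal CV.
DEFAULT_PENALTY_GRID = np.logspace(-3, 0, 20)


@dataclass
class TimeSeriesPanel:
    """Parcels x timepoints matrix of BOLD-like signals."""

    parcel_signals: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.parcel_signals, dtype=float)
        if X.ndim != 2:
            raise InvalidParameterError("parcel_signals must be 2-D (parcels x timepoints)")
        if not np.all(np.isfinite(X)):
            raise InvalidParameterError("parcel_signals contain missing/non-finite values")
        self.parcel_signals = X

    @property
    def parcel_count(self) -> int:
        return self.parcel_signals.shape[0]

    @property
    def timepoint_count(self) -> int:
        return self.parcel_signals.shape[1]


def summary_signal(voxel_block: np.ndarray) -> np.ndarray:
    """First temporal principal component of a voxels x time BOLD block.

    Returns the unit-norm principal left singular vector of the time x voxel
    arrangement, with its sign chosen so the correlation with the voxel-mean
    signal is non-negative (SVD leaves the sign arbitrary).
    """
    V = np.asarray(voxel_block, dtype=float)
    if V.ndim != 2 or V.shape[0] < 1 or V.shape[1] < 2:
        raise InvalidParameterError("voxel block must be voxels x time with >=1 voxel, >=2 timepoints")
    if not np.any(V):
        raise DegenerateInputError("all-zero voxel block has no summary signal")
    U, _, _ = np.linalg.svd(V.T, full_matrices=False)
    u = U[:, 0]
    mean_sig = V.mean(axis=0)
    if float(u @ mean_sig) < 0:
        u = -u
    return u


def _standardize(panel: np.ndarray) -> np.ndarray:
    mu = panel.mean(axis=1, keepdims=True)
    sd = panel.std(axis=1, keepdims=True)
    # relative tolerance: a constant-but-nonzero signal has std ~ eps*|mean|
    flat = np.nonzero(sd.ravel() <= 1e-12 * np.maximum(1.0, np.abs(mu.ravel())))[0]
    if flat.size:
        raise DegenerateInputError(f"constant signal at parcel(s) {flat.tolist()}: cannot standardize")
    return (panel - mu) / sd


def partial_correlation_network(
    panel: TimeSeriesPanel | np.ndarray,
    l1_weight: float = 0.5,
    penalty: float | None = None,
    penalty_grid: np.ndarray | None = None,
    node_labels=None,
) -> Connectome:
    """Sparse partial-correlation network via node-wise elastic-net regression.

    Parameters
    ----------
    panel:
        Parcels x timepoints matrix (standardized internally per parcel).
    l1_weight:
        Mixing between L1 (sparsity) and L2 (shrinkage), in [0, 1].
    penalty:
        Overall regularization strength. ``0`` means ordinary least squares
        (the exact partial correlations when timepoints >> parcels); ``None``
        selects the penalty per regression by 5-fold cross-validation on
        ``penalty_grid``.

    Returns
    -------
    Connectome
        Functional network; symmetric, zero diagonal, weights in [-1, 1].
    """
    if isinstance(panel, TimeSeriesPanel):
        X = panel.parcel_signals
    else:
        X = TimeSeriesPanel(np.asarray(panel)).parcel_signals
    if not 0.0 <= l1_weight <= 1.0:
        raise InvalidParameterError("l1_weight must lie in [0, 1]")
    if penalty is not None and penalty < 0:
        raise InvalidParameterError("penalty must be >= 0")
    p, t = X.shape
    if p < 2:
        raise InvalidParameterError("need at least 2 parcels")
    Z = _standardize(X).T  # time x parcels, each column zero-mean unit-sd
    B = np.zeros((p, p))
    grid = DEFAULT_PENALTY_GRID if penalty_grid is None else np.asarray(penalty_grid, dtype=float)
    others = np.arange(p)
    for i in range(p):
        idx = others[others != i]
        y = Z[:, i]
        D = Z[:, idx]
        if penalty == 0:
            coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        elif penalty is None:
            # l1_ratio=0 (pure ridge) is unsupported by the CV path; floor it
            model = ElasticNetCV(
                l1_ratio=max(l1_weight, 1e-3), alphas=grid, cv=5,
                fit_intercept=False, max_iter=5000,
            ).fit(D, y)
            # one-standard-error rule: the CV minimum under-sparsifies (it
            # optimizes prediction, not support); take the largest penalty
            # whose CV error is within 1 SE of the minimum
            mse = model.mse_path_.mean(axis=1)
            se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(model.mse_path_.shape[1])
            alphas = model.alphas_
            best = int(np.argmin(mse))
            ok = mse <= mse[best] + se[best]
            alpha_1se = alphas[ok].max()
            coef = ElasticNet(
                alpha=alpha_1se, l1_ratio=max(l1_weight, 1e-3),
                fit_intercept=False, max_iter=5000,
            ).fit(D, y).coef_
        else:
            model = ElasticNet(
                alpha=penalty, l1_ratio=l1_weight, fit_intercept=False, max_iter=5000,
            ).fit(D, y)
            coef = model.coef_
        B[i, idx] = coef
    # sign-consistent geometric mean ("and" rule): keep an edge only when both
    # neighborhood regressions agree on its sign
    prod = B * B.T
    W = np.where(prod > 0, np.sign(B) * np.sqrt(np.abs(prod)), 0.0)
    W = np.clip((W + W.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(W, 0.0)
    return Connectome(W, modality="functional", node_labels=node_labels)
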