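"""Two-block partial least squares correlation.

Given z-scored blocks X (n x p risk traits) and Y (n x q social indicators),
PLS correlation finds paired unit weight vectors (v_l, u_l) whose latent
variates l_X,l = X v_l and l_Y,l = Y u_l have maximal covariance, mode by
mode.  These are exactly the left/right singular vectors of the cross-
covariance matrix C = X'Y / (n - 1); the singular values order the modes and
s_l^2 / sum s^2 gives each mode's share of the total cross-covariance.

The mode "canonical correlation" reported here is the Pearson correlation of
the paired variates.  No deflation is performed — the decomposition is
symmetric in X and Y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["PLSResult", "fit_pls", "mode_correlations", "covariance_explained"]

_STD_TOL = 1e-6


@dataclass
class PLSResult:
    """Weights, variates and spectrum of a fitted two-block PLS correlation."""

    x_weights: np.ndarray  # p x L, columns v_l, unit norm
    y_weights: np.ndarray  # q x L, columns u_l, unit norm
    x_variates: np.ndarray  # n x L, L_X = X V
    y_variates: np.ndarray  # n x L, L_Y = Y U
    singular_values: np.ndarray  # length L, nonincreasing
    all_singular_values: np.ndarray  # full spectrum, length min(p, q)

    @property
    def n_modes(self) -> int:
        return self.x_weights.shape[1]

    @property
    def mode_correlations(self) -> np.ndarray:
        return mode_correlations(self)

    @property
    def covariance_explained(self) -> np.ndarray:
        return covariance_explained(self)

    def structure_correlations(self, X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Variable-variate correlations (loadings as correlations), per block."""
        n = X.shape[0]
        sx = X.T @ _unit_columns(self.x_variates) / (n - 1)
        sy = Y.T @ _unit_columns(self.y_variates) / (n - 1)
        return sx, sy


def _unit_columns(m: np.ndarray) -> np.ndarray:
    sd = m.std(0, ddof=1)
    return (m - m.mean(0)) / sd


def _check_standardized(block: np.ndarray, name: str) -> np.ndarray:
    block = np.asarray(block, dtype=float)
    if block.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array")
    if np.isnan(block).any():
        raise ValueError(f"{name} contains missing values; impute before PLS")
    mu = np.abs(block.mean(0)).max()
    sd = np.abs(block.std(0, ddof=1) - 1.0).max()
    if mu > _STD_TOL or sd > _STD_TOL:
        raise ValueError(
            f"{name} is not z-scored (max |mean| = {mu:.2e}, max |sd - 1| = {sd:.2e})"
        )
    return block


def fit_pls(X: np.ndarray, Y: np.ndarray, n_modes: int | None = None) -> PLSResult:
    """SVD of the cross-covariance of two z-scored blocks.

    Weights are ordered by singular value; within each mode, signs are flipped
    so the largest-magnitude Y-weight entry is positive (removes the SVD sign
    ambiguity).  ``n_modes`` defaults to q, the number of Y-block variables.
    """
    X = _check_standardized(X, "X")
    Y = _check_standardized(Y, "Y")
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"row-count mismatch: X has {X.shape[0]} rows, Y has {Y.shape[0]}")
    n, p = X.shape
    q = Y.shape[1]
    if n_modes is None:
        n_modes = q
    if not 1 <= n_modes <= min(p, q):
        raise ValueError(f"n_modes must lie in [1, min(p, q)] = [1, {min(p, q)}]")

    cross_cov = X.T @ Y / (n - 1)
    u, s, vt = linalg.svd(cross_cov, full_matrices=False)
    v = u[:, :n_modes].copy()  # X-side weights
    w = vt[:n_modes].T.copy()  # Y-side weights
    for l in range(n_modes):
        if w[np.argmax(np.abs(w[:, l])), l] < 0:
            v[:, l] *= -1
            w[:, l] *= -1
    return PLSResult(
        x_weights=v,
        y_weights=w,
        x_variates=X @ v,
        y_variates=Y @ w,
        singular_values=s[:n_modes],
        all_singular_values=s,
    )


def mode_correlations(result: PLSResult) -> np.ndarray:
    """Pearson correlation of the paired variates, one value per mode."""
    lx, ly = result.x_variates, result.y_variates
    sx = lx.std(0, ddof=1)
    sy = ly.std(0, ddof=1)
    if np.any(sx == 0) or np.any(sy == 0):
        raise ValueError("zero-variance variate; mode correlation undefined")
    cx = (lx - lx.mean(0)) / sx
    cy = (ly - ly.mean(0)) / sy
    return (cx * cy).sum(0) / (lx.shape[0] - 1)


def covariance_explained(result: PLSResult) -> np.ndarray:
    """Fraction of total squared cross-covariance captured by each mode."""
    s_all = result.all_singular_values
    total = float(np.sum(s_all**2))
    if total == 0:
        return np.zeros(result.n_modes)
    return result.singular_values**2 / total
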