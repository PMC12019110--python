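"""Bivariate VAR fitting and Gaussian transfer-entropy / NDTE computation.

For an ordered node pair (X, Y) we fit, by ordinary least squares pooled
over trials, the bivariate VAR(T)

    Z_t = sum_{k=1..T} A_k Z_{t-k} + eps_t,      Z_t = (X_t, Y_t)',

and the nested univariate AR(T) of the target Y.  Under the linear-Gaussian
model the information quantities reduce to log ratios of residual variances:

    TE(X->Y)        = 1/2 ln( s2_reduced / s2_full )
    I(Y_{i+1}; Y^i) = 1/2 ln( Var(Y) / s2_reduced )
    norm factor     = 1/2 ln( Var(Y) / s2_full )    (their sum)
    NDTE F_XY       = TE / norm factor  in [0, 1].

All variances are maximum-likelihood (SSR / n_eff) over the *same* response
rows, so the nesting SSR_full <= SSR_reduced <= SST holds exactly and the
bounds TE >= 0, 0 <= NDTE <= 1 are structural, not approximate.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class EstimationParams:
    """Configuration for directed-network estimation.

    lag_order is the VAR order T; block_size is the surrogate permutation
    block length (recommended equal to the VAR order); alpha is the per-test
    significance level, Bonferroni-corrected over ordered pairs when
    ``correction == "bonferroni"``; density is the fraction of the n(n-1)
    possible directed edges kept after thresholding.
    """

    lag_order: int = 10
    n_surrogates: int = 100
    block_size: int = 10
    alpha: float = 0.05
    correction: str = "bonferroni"
    density: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag_order < 1:
            raise ValueError("lag_order must be a positive integer")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be a positive integer")
        if self.block_size < 1:
            raise ValueError("block_size must be a positive integer")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must lie in (0, 1]")


@dataclasses.dataclass
class BivariateVarModel:
    """OLS estimates for one ordered pair: A_k coefficient matrices and residual covariance."""

    coefficients: list[np.ndarray]  # T matrices, each 2x2; column order (X, Y)
    residual_covariance: np.ndarray  # 2x2, ML convention
    lag_order: int
    n_effective_obs: int
    intercept: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.lag_order:
            raise ValueError("coefficients list must have exactly lag_order entries")
        sigma = np.asarray(self.residual_covariance, float)
        if not np.allclose(sigma, sigma.T, atol=1e-10):
            raise ValueError("residual covariance must be symmetric")
        if np.linalg.eigvalsh(sigma).min() < -1e-10:
            raise ValueError("residual covariance must be positive semidefinite")


@dataclasses.dataclass
class EdgeEstimate:
    """NDTE estimate for one ordered pair (source -> target)."""

    source: str
    target: str
    te: float
    norm_factor: float
    ndte: float
    p_value: float | None = None


def _lagged_design(series: np.ndarray, lag_order: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-trial lag matrices for a (n_trials, n_time, n_vars) array.

    Returns (design, response): design rows are (1, z_{t-1}, ..., z_{t-T})
    flattened over variables, responses are z_t for t = T..n_time-1, pooled
    over trials with no cross-trial contamination.
    """
    n_trials, n_time, n_vars = series.shape
    T = lag_order
    if n_time - T < 2:
        raise ValueError(
            f"need at least 2 usable frames per trial beyond lag order {T}; "
            f"trial length is {n_time}"
        )
    rows = n_time - T
    design = np.empty((n_trials * rows, 1 + T * n_vars))
    design[:, 0] = 1.0
    response = np.empty((n_trials * rows, n_vars))
    for tr in range(n_trials):
        sl = slice(tr * rows, (tr + 1) * rows)
        response[sl] = series[tr, T:]
        for k in range(1, T + 1):
            design[sl, 1 + (k - 1) * n_vars : 1 + k * n_vars] = series[tr, T - k : n_time - k]
    return design, response


def _ols_residual_ss(design: np.ndarray, response: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit returning (coefficients, residual sum-of-squares matrix).

    Rank-deficient designs fall back to the pseudo-inverse solution (logged).
    """
    coef, _, rank, _ = np.linalg.lstsq(design, response, rcond=None)
    if rank < design.shape[1]:
        logger.warning(
            "rank-deficient design (rank %d < %d columns); pseudo-inverse solution used",
            rank, design.shape[1],
        )
    resid = response - design @ coef
    return coef, resid.T @ resid


def fit_bivariate_var(
    x: np.ndarray, y: np.ndarray, lag_order: int
) -> BivariateVarModel:
    """Fit a bivariate VAR(T) to trial-wise series x, y of shape (n_trials, n_time).

    Trials are pooled as independent realizations; the first T frames of each
    trial are excluded from the response.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    if x.shape != y.shape:
        raise ValueError(f"x and y must share shape, got {x.shape} vs {y.shape}")
    series = np.stack([x, y], axis=2)
    design, response = _lagged_design(series, lag_order)
    coef, rss = _ols_residual_ss(design, response)
    n_eff = design.shape[0]
    a_k = [coef[1 + 2 * k : 3 + 2 * k].T for k in range(lag_order)]
    sigma = rss / n_eff
    sigma = (sigma + sigma.T) / 2.0
    return BivariateVarModel(
        coefficients=a_k, residual_covariance=sigma, lag_order=lag_order,
        n_effective_obs=n_eff, intercept=coef[0],
    )


def fit_univariate_ar_variance(y: np.ndarray, lag_order: int) -> float:
    """ML residual variance of the univariate AR(T) of y, pooled over trials."""
    y = np.atleast_2d(np.asarray(y, float))
    design, response = _lagged_design(y[:, :, None], lag_order)
    _, rss = _ols_residual_ss(design, response)
    return float(rss[0, 0]) / design.shape[0]


def transfer_entropy(full: BivariateVarModel, reduced_resid_var: float) -> float:
    """Gaussian transfer entropy (nats) from the nested variance comparison.

    ``reduced_resid_var`` is the residual variance of the target's univariate
    AR(T) on the same sample range.  Negative sampling values are clipped to
    zero with the raw value logged.
    """
    if reduced_resid_var <= 0.0:
        raise ValueError(f"reduced residual variance must be positive, got {reduced_resid_var}")
    full_var = float(full.residual_covariance[1, 1])
    if full_var <= 0.0:
        raise ValueError(f"full-model residual variance must be positive, got {full_var}")
    te = 0.5 * np.log(reduced_resid_var / full_var)
    if te < 0.0:
        logger.info("sample transfer entropy %.3e < 0 clipped to 0", te)
        te = 0.0
    return float(te)


def ndte(x: np.ndarray, y: np.ndarray, params: EstimationParams,
         source: str = "X", target: str = "Y") -> EdgeEstimate:
    """Normalized directed transfer entropy for the ordered pair (x -> y).

    The normalization factor I(Y_{i+1}; X^i, Y^i) is the total predictability
    of the target's next value from the joint past; it decomposes as
    TE + I(Y_{i+1}; Y^i), both evaluated from the same pooled fits.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    full = fit_bivariate_var(x, y, params.lag_order)
    reduced_var = fit_univariate_ar_variance(y, params.lag_order)
    te = transfer_entropy(full, reduced_var)

    # Var(Y) about its mean over the same response rows as the fits.
    T = params.lag_order
    resp = y[:, T:]
    var_y = float(np.mean((resp - resp.mean()) ** 2))
    full_var = float(full.residual_covariance[1, 1])
    norm = 0.5 * np.log(var_y / full_var) if var_y > 0 else 0.0
    norm = max(norm, te)  # guard against round-off breaking the nesting
    if norm <= 0.0:
        logger.warning("normalization factor ~ 0 for (%s -> %s); NDTE set to 0", source, target)
        value = 0.0
    else:
        value = min(te / norm, 1.0)
    return EdgeEstimate(source=source, target=target, te=te, norm_factor=float(norm), ndte=float(value))
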