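"""Directed functional network estimation from multi-trial time series.

For every ordered node pair the NDTE weight is computed, its significance
is assessed against block-permutation surrogates of the source series, and
edges surviving the (Bonferroni-corrected) threshold form the network,
optionally pruned to a target edge density.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import linalg

from .network import DirectedNetwork
from .surrogates import block_permutation, edge_pvalue
from .timeseries import RoiTimeSeriesSet
from .var import EdgeEstimate, EstimationParams

logger = logging.getLogger(__name__)


def _lag_block(x: np.ndarray, lag_order: int) -> np.ndarray:
    """Trial-pooled lag matrix: column k-1 holds x_{t-k}, rows t = T..n-1 per trial."""
    _, n_time = x.shape
    T = lag_order
    rows = n_time - T
    out = np.empty((x.shape[0] * rows, T))
    for k in range(1, T + 1):
        out[:, k - 1] = x[:, T - k : n_time - k].reshape(-1)
    return out


def _resid_var(design: np.ndarray, resp: np.ndarray, yty: float) -> float:
    """ML residual variance of an OLS fit via the normal equations.

    Falls back to a pseudo-inverse solution for singular Gram matrices.
    """
    G = design.T @ design
    rhs = design.T @ resp
    try:
        beta = linalg.solve(G, rhs, assume_a="pos")
    except linalg.LinAlgError:
        logger.warning("singular design; pseudo-inverse fallback used")
        beta = np.linalg.pinv(G) @ rhs
    ssr = max(yty - rhs @ beta, 0.0)
    return float(ssr) / design.shape[0]


class _PairWorkspace:
    """Per-target precomputation shared across sources and surrogates."""

    def __init__(self, y: np.ndarray, lag_order: int):
        if y.shape[1] - lag_order < 2:
            raise ValueError(
                f"need at least 2 usable frames per trial beyond lag order {lag_order}"
            )
        self.lag_order = lag_order
        self.resp = y[:, lag_order:].reshape(-1)
        self.yty = float(self.resp @ self.resp)
        rows = self.resp.size
        self.fixed = np.empty((rows, 1 + lag_order))
        self.fixed[:, 0] = 1.0
        self.fixed[:, 1:] = _lag_block(y, lag_order)
        self.reduced_var = _resid_var(self.fixed, self.resp, self.yty)
        self.var_y = float(np.mean((self.resp - self.resp.mean()) ** 2))

    def ndte(self, x: np.ndarray) -> tuple[float, float, float]:
        """(te, norm_factor, ndte) for source series x against this target."""
        T = self.lag_order
        design = np.hstack([self.fixed, _lag_block(x, T)])
        full_var = _resid_var(design, self.resp, self.yty)
        if full_var <= 0.0 or self.reduced_var <= 0.0:
            raise ValueError("nonpositive residual variance in NDTE computation")
        te = max(0.5 * np.log(self.reduced_var / full_var), 0.0)
        norm = 0.5 * np.log(self.var_y / full_var) if self.var_y > 0 else 0.0
        norm = max(norm, te)
        if norm <= 0.0:
            return te, 0.0, 0.0
        return te, norm, min(te / norm, 1.0)


def estimate_edge(
    x: np.ndarray,
    y: np.ndarray,
    params: EstimationParams,
    source: str = "X",
    target: str = "Y",
    pair_index: tuple[int, int] = (0, 1),
    workspace: "_PairWorkspace | None" = None,
) -> EdgeEstimate:
    """NDTE and surrogate p-value for one ordered pair.

    Surrogate NDTE values are obtained by block-permuting the source series
    within each trial (coupling destroyed, source autocorrelation preserved)
    and re-fitting the bivariate model.  Surrogate random streams are
    derived from counter-based substreams keyed by (seed, pair, surrogate
    index), so per-edge results do not depend on iteration order.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    ws = workspace if workspace is not None else _PairWorkspace(y, params.lag_order)
    te, norm, value = ws.ndte(x)

    surr_values = np.empty(params.n_surrogates)
    for k in range(params.n_surrogates):
        rng = np.random.default_rng([params.seed, pair_index[0], pair_index[1], k])
        x_surr = np.stack(
            [block_permutation(x[tr], params.block_size, rng) for tr in range(x.shape[0])]
        )
        _, _, surr_values[k] = ws.ndte(x_surr)
    p = edge_pvalue(value, surr_values)
    return EdgeEstimate(
        source=source, target=target, te=te, norm_factor=norm, ndte=value, p_value=p
    )


def build_directed_network(
    ts: RoiTimeSeriesSet, params: EstimationParams, return_estimates: bool = False
):
    """Estimate the significance-filtered, density-thresholded directed network.

    For every ordered pair (X, Y) the NDTE weight F_XY is kept iff its
    surrogate p-value beats alpha / m (m = number of ordered pairs under
    Bonferroni correction).  The surviving network is then pruned to
    ``params.density`` of all possible directed edges.
    """
    n = ts.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    m = n * (n - 1)
    threshold = params.alpha / m if params.correction == "bonferroni" else params.alpha
    estimates: list[EdgeEstimate] = []
    edges: dict[tuple[str, str], float] = {}
    for j, target in enumerate(ts.node_labels):
        ws = _PairWorkspace(ts.values[:, :, j], params.lag_order)
        for i, source in enumerate(ts.node_labels):
            if i == j:
                continue
            try:
                est = estimate_edge(
                    ts.values[:, :, i], ts.values[:, :, j], params,
                    source, target, (i, j), workspace=ws,
                )
            except Exception as exc:  # pragma: no cover - propagate with pair identity
                raise RuntimeError(f"edge estimation failed for pair ({source} -> {target})") from exc
            estimates.append(est)
            if est.p_value < threshold and est.ndte > 0:
                edges[(source, target)] = est.ndte
    net = DirectedNetwork(nodes=list(ts.node_labels), edges=edges)
    net = threshold_to_density(net, params.density)
    if return_estimates:
        return net, estimates
    return net


def threshold_to_density(net: DirectedNetwork, density: float) -> DirectedNetwork:
    """Keep the floor(density * n(n-1)) largest-weight directed edges.

    Ties at the cutoff weight are broken by lexicographic (source, target)
    order for reproducibility.  If fewer significant edges exist than the
    quota, all are kept and the shortfall is logged.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    n = net.n_nodes
    quota = int(np.floor(density * n * (n - 1)))
    ranked = sorted(net.edges.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    if len(ranked) < quota:
        logger.info(
            "only %d significant edges available for density quota %d", len(ranked), quota
        )
    kept = dict(ranked[:quota])
    return DirectedNetwork(nodes=list(net.nodes), edges=kept)
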