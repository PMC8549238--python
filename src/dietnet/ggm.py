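"""Sparse Gaussian graphical model estimation over food groups.

The conditional-dependence structure of intakes is summarized by the
precision (inverse covariance) matrix Omega: a zero off-diagonal entry
means two food groups are conditionally independent given all others.
Omega is estimated on the correlation scale by the graphical lasso,

    maximize  log det(Omega) - trace(S Omega) - lambda * sum_{i != j} |omega_ij|,

solved by block coordinate descent (one lasso subproblem per row/column).
The penalty applies to off-diagonal entries only, so lambda = 0 recovers the
unpenalized maximum-likelihood estimate inv(S) and lambda >= max|S_ij|
yields an exactly diagonal precision matrix.

Partial correlations follow as rho_ij = -omega_ij / sqrt(omega_ii omega_jj);
|rho| >= 0.20 is flagged "strong" by convention.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PrecisionMatrix",
    "PartialCorrelationNetwork",
    "sample_correlation",
    "graphical_lasso",
    "select_penalty",
    "default_penalty_grid",
    "precision_to_partial",
    "STRONG_PARTIAL_THRESHOLD",
    "EDGE_NUMERICAL_ZERO",
]

#: |partial correlation| at or above which an edge is considered strong.
STRONG_PARTIAL_THRESHOLD = 0.20

#: |omega_ij| above which an off-diagonal entry counts as an edge.
EDGE_NUMERICAL_ZERO = 1e-10


@dataclasses.dataclass
class PrecisionMatrix:
    """Estimated precision matrix with the penalty and convergence record."""

    omega: np.ndarray
    lam: float
    n_iter: int
    max_change: float
    converged: bool = True

    def __post_init__(self):
        omega = np.asarray(self.omega, dtype=float)
        if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
            raise ValueError("precision matrix must be square")
        if np.max(np.abs(omega - omega.T)) > 1e-8:
            raise ValueError("precision matrix not symmetric")
        if np.any(np.diag(omega) <= 0):
            raise ValueError("precision matrix diagonal must be positive")
        np.linalg.cholesky(omega)  # raises if not positive definite
        self.omega = omega


@dataclasses.dataclass
class PartialCorrelationNetwork:
    """Partial-correlation matrix plus its thresholded signed edge list.

    ``edges`` rows are (group_i, group_j, partial_correlation, sign, strong)
    for every off-diagonal precision entry above numerical zero.
    """

    nodes: list
    rho: np.ndarray
    edges: pd.DataFrame

    def edge_weight(self, u, v) -> float:
        i, j = self.nodes.index(u), self.nodes.index(v)
        return float(self.rho[i, j])

    def edge_tuples(self) -> list[tuple]:
        return [tuple(sorted((a, b))) for a, b in zip(self.edges["group_i"], self.edges["group_j"])]


def sample_correlation(standardized: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the (standardized) intake columns."""
    x = np.asarray(standardized, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 subjects to form a correlation matrix")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant columns have no defined correlation")
    s = np.corrcoef(x, rowvar=False)
    return np.clip((s + s.T) / 2.0, -1.0, 1.0)


def _lasso_cd(gram: np.ndarray, target: np.ndarray, lam: float, beta: np.ndarray,
              tol: float, max_iter: int = 200) -> np.ndarray:
    """Coordinate descent for min 0.5 b'Gb - t'b + lam*||b||_1 (warm start)."""
    p = gram.shape[0]
    for _ in range(max_iter):
        delta = 0.0
        for k in range(p):
            old = beta[k]
            resid = target[k] - gram[k] @ beta + gram[k, k] * old
            new = math.copysign(max(abs(resid) - lam, 0.0), resid) / gram[k, k]
            if new != old:
                beta[k] = new
                delta = max(delta, abs(new - old))
        if delta < tol:
            break
    return beta


def graphical_lasso(
    s: np.ndarray,
    lam: float,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
    warm_w: np.ndarray | None = None,
) -> PrecisionMatrix:
    """L1-penalized precision estimate by block coordinate descent.

    Parameters
    ----------
    s
        Sample correlation (or covariance) matrix; symmetric, unit diagonal
        expected on the correlation scale.
    lam
        Nonnegative off-diagonal penalty. ``lam = 0`` returns inv(S)
        directly (the unpenalized MLE) and requires S nonsingular.
    tol
        Convergence: maximum elementwise change of the working covariance
        between full sweeps.
    warm_w
        Optional working covariance from a previous fit at a nearby
        penalty, used to warm-start a penalty-grid search.
    """
    s = np.asarray(s, dtype=float)
    p = s.shape[0]
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("S must be square")
    if np.max(np.abs(s - s.T)) > 1e-8:
        raise ValueError("S must be symmetric")
    if lam < 0:
        raise ValueError("penalty must be nonnegative")

    if lam == 0:
        try:
            c = np.linalg.cholesky(s)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "S is singular at lambda = 0; use a positive penalty"
            ) from exc
        ident = np.eye(p)
        omega = np.linalg.solve(c.T, np.linalg.solve(c, ident))
        omega = (omega + omega.T) / 2.0
        return PrecisionMatrix(omega, 0.0, 0, 0.0)

    w = s.copy() if warm_w is None else warm_w.copy()
    np.fill_diagonal(w, np.diag(s))  # no diagonal penalty: w_ii = s_ii
    betas = np.zeros((p, p - 1))
    idx = [np.array([k for k in range(p) if k != j]) for j in range(p)]
    inner_tol = tol * 0.1

    n_iter = 0
    max_change = np.inf
    for n_iter in range(1, max_iter + 1):
        w_old = w.copy()
        for j in range(p):
            ix = idx[j]
            gram = w[np.ix_(ix, ix)]
            betas[j] = _lasso_cd(gram, s[ix, j], lam, betas[j], inner_tol)
            w12 = gram @ betas[j]
            w[ix, j] = w12
            w[j, ix] = w12
        max_change = float(np.max(np.abs(w - w_old)))
        if max_change < tol:
            break
    else:
        raise RuntimeError(
            f"graphical lasso did not converge in {max_iter} sweeps "
            f"(last max change {max_change:.3e}, lambda={lam})"
        )

    # Recover Omega from the working covariance and regression coefficients.
    omega = np.zeros_like(w)
    for j in range(p):
        ix = idx[j]
        denom = w[j, j] - w[ix, j] @ betas[j]
        omega[j, j] = 1.0 / denom
        omega[ix, j] = -betas[j] * omega[j, j]
    omega = (omega + omega.T) / 2.0
    omega[np.abs(omega) < EDGE_NUMERICAL_ZERO] = 0.0
    result = PrecisionMatrix(omega, float(lam), n_iter, max_change)
    result._working_covariance = w  # retained for warm starts
    return result


def default_penalty_grid(s: np.ndarray, n_points: int = 30, decades: float = 2.0) -> np.ndarray:
    """Descending log-spaced grid from lambda_max = max|S_ij| down ``decades``."""
    off = np.abs(s[~np.eye(s.shape[0], dtype=bool)])
    lam_max = float(off.max())
    if lam_max <= 0:
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * 10.0 ** (-decades), n_points)


def select_penalty(
    standardized: pd.DataFrame | np.ndarray,
    lam_grid: np.ndarray | None = None,
    gamma: float = 0.5,
) -> tuple[float, pd.DataFrame]:
    """Choose the graphical-lasso penalty by the extended BIC.

    EBIC(lambda) = -2 loglik(Omega_hat) + k log n + 4 k gamma log p, where
    k counts nonzero upper-triangle off-diagonals and gamma in [0, 1] sets
    the extra sparsity pressure (gamma = 0.5 is the usual default when
    p is non-trivial relative to n). Ties prefer the larger (sparser)
    penalty. Returns (lambda, per-lambda diagnostics table).
    """
    x = np.asarray(standardized, dtype=float)
    n = x.shape[0]
    p = x.shape[1]
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    s = sample_correlation(x)
    if lam_grid is None:
        lam_grid = default_penalty_grid(s)
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size == 0:
        raise ValueError("empty penalty grid")
    if np.any(np.diff(lam_grid) > 0):
        raise ValueError("penalty grid must be descending")

    rows = []
    failures = []
    warm = None
    upper = np.triu_indices(p, k=1)
    for lam in lam_grid:
        try:
            fit = graphical_lasso(s, float(lam), warm_w=warm)
        except Exception as exc:  # aggregate and report at the end
            failures.append((float(lam), repr(exc)))
            continue
        warm = fit._working_covariance
        omega = fit.omega
        k = int(np.count_nonzero(np.abs(omega[upper]) > EDGE_NUMERICAL_ZERO))
        sign, logdet = np.linalg.slogdet(omega)
        loglik = 0.5 * n * (logdet - np.trace(s @ omega))
        ebic = -2.0 * loglik + k * np.log(n) + 4.0 * k * gamma * np.log(p)
        rows.append({"lam": float(lam), "n_edges": k, "loglik": loglik, "ebic": ebic})
    if not rows:
        raise RuntimeError(f"every penalty failed to fit: {failures}")
    diag = pd.DataFrame(rows)
    best = diag.loc[diag["ebic"].idxmin()]  # first minimum = largest lambda on ties
    logger.info("EBIC selected lambda=%.4g with %d edges", best["lam"], best["n_edges"])
    return float(best["lam"]), diag


def precision_to_partial(
    omega: PrecisionMatrix | np.ndarray,
    nodes: list | None = None,
    *,
    strong_threshold: float = STRONG_PARTIAL_THRESHOLD,
) -> PartialCorrelationNetwork:
    """Convert a precision matrix to its partial-correlation network.

    rho_ij = -omega_ij / sqrt(omega_ii * omega_jj); the sign convention makes
    rho_ij > 0 a conditional *positive* association between foods i and j.
    """
    m = omega.omega if isinstance(omega, PrecisionMatrix) else np.asarray(omega, dtype=float)
    d = np.diag(m)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be strictly positive")
    scale = 1.0 / np.sqrt(d)
    rho = -m * np.outer(scale, scale)
    np.fill_diagonal(rho, 1.0)
    p = m.shape[0]
    if nodes is None:
        nodes = list(range(p))
    if len(nodes) != p:
        raise ValueError("node labels do not match matrix dimension")

    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            if abs(m[i, j]) > EDGE_NUMERICAL_ZERO:
                r = float(rho[i, j])
                rows.append(
                    {
                        "group_i": nodes[i],
                        "group_j": nodes[j],
                        "partial_correlation": r,
                        "sign": "positive" if r > 0 else "negative",
                        "strong": abs(r) >= strong_threshold,
                    }
                )
    edges = pd.DataFrame(
        rows, columns=["group_i", "group_j", "partial_correlation", "sign", "strong"]
    )
    return PartialCorrelationNetwork(nodes=list(nodes), rho=rho, edges=edges)
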