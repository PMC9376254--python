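"""Gaussian graphical model estimation via EBIC-tuned graphical lasso.

The network over the 12 subscale variables is the regularized partial
correlation network: edge weights are ``w_ij = -K_ij / sqrt(K_ii K_jj)``
where ``K`` is the L1-penalized maximum-likelihood precision matrix.  The
penalty level is chosen by minimizing the extended Bayesian information
criterion (EBIC) over a descending log-spaced grid, the standard recipe in
psychometric network analysis.

The solver is a block coordinate-descent graphical lasso (one lasso
sub-problem per column, Friedman-style) with off-diagonal-only penalty and
duality-gap convergence.  It is numba-compiled and warm-started along the
lambda path, which makes the thousands of re-fits required by case-dropping
bootstraps cheap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .datasets import COMMUNITIES, NODE_LABELS

logger = logging.getLogger(__name__)

# Solver defaults: duality-gap tolerance and iteration cap for the outer
# block sweeps; the inner per-column lasso runs to coefficient stability.
DUALITY_GAP_TOL = 1e-7
MAX_OUTER_ITER = 10_000
_INNER_TOL = 1e-10
_INNER_MAX = 200

#: Numerical threshold below which a precision entry counts as a zero edge.
EDGE_EPS = 1e-10


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Pairwise correlation matrix with its method and effective n."""

    values: np.ndarray
    method: str
    n: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(v) > 1 + 1e-8):
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.values = v

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass
class WeightedNetwork:
    """Symmetric signed edge-weight matrix with node and community labels."""

    labels: list[str]
    weights: np.ndarray
    communities: dict[str, str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        p = len(self.labels)
        if w.shape != (p, p):
            raise ValueError("weight matrix shape must match label count")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.abs(np.diag(w)) > 1e-12):
            raise ValueError("weight matrix must have zero diagonal")
        if np.any(np.abs(w) >= 1.0):
            raise ValueError("partial correlations must satisfy |w| < 1")
        missing = [lab for lab in self.labels if lab not in self.communities]
        if missing:
            raise ValueError(f"nodes without community label: {missing}")
        self.weights = (w + w.T) / 2.0

    @property
    def p(self) -> int:
        return len(self.labels)

    def edges(self, eps: float = EDGE_EPS) -> list[tuple[str, str, float]]:
        """Nonzero edges as (label_i, label_j, weight), i < j."""
        out = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if abs(self.weights[i, j]) > eps:
                    out.append((self.labels[i], self.labels[j],
                                float(self.weights[i, j])))
        return out

    def edge(self, a: str, b: str) -> float:
        return float(self.weights[self.labels.index(a), self.labels.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.labels,
                            columns=self.labels)

    # -- serialization -----------------------------------------------------

    def to_weight_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="node")

    @classmethod
    def from_weight_csv(cls, path, communities: Mapping[str, str] | None = None,
                        meta: dict | None = None) -> "WeightedNetwork":
        df = pd.read_csv(path, index_col=0)
        labels = [str(c) for c in df.columns]
        if communities is None:
            if set(labels) != set(NODE_LABELS):
                raise ValueError(
                    "communities must be given for non-standard node sets")
            communities = {lab: COMMUNITIES[lab] for lab in labels}
        return cls(labels=labels, weights=df.to_numpy(float),
                   communities=dict(communities), meta=dict(meta or {}))

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_graph(), path)

    def to_graph(self):
        """networkx Graph with signed ``weight`` edge attribute and
        ``community`` node attribute; only nonzero edges are present."""
        import networkx as nx

        g = nx.Graph()
        for lab in self.labels:
            g.add_node(lab, community=self.communities[lab])
        for a, b, w in self.edges():
            g.add_edge(a, b, weight=w)
        return g

    def to_json(self, path) -> None:
        payload = {
            "labels": self.labels,
            "weights": [[round(float(x), 6) for x in row]
                        for row in self.weights],
            "communities": self.communities,
            "meta": {k: v for k, v in self.meta.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


@dataclass
class GlassoPath:
    """Solution path of the graphical lasso over a descending lambda grid."""

    lambdas: np.ndarray
    precisions: np.ndarray          # (n_lambda, p, p)
    ebics: np.ndarray
    selected: int

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.lambdas) < 0):
            raise ValueError("lambda grid must be strictly decreasing")

    def edge_counts(self) -> np.ndarray:
        off = ~np.eye(self.precisions.shape[1], dtype=bool)
        return np.array([
            int((np.abs(k[off]) > EDGE_EPS).sum() // 2)
            for k in self.precisions
        ])


# ---------------------------------------------------------------------------
# Correlation input
# ---------------------------------------------------------------------------

def correlation_matrix(scores: pd.DataFrame, method: str = "pearson",
                       ) -> CorrelationMatrix:
    """Pairwise Pearson or Spearman correlations of the score columns.

    Raises a ``ValueError`` naming any constant column, for which the
    correlation is undefined.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method: {method!r}")
    x = scores.to_numpy(dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("scores contain non-finite values")
    sd = x.std(axis=0, ddof=1)
    constant = [str(c) for c, s in zip(scores.columns, sd) if s == 0]
    if constant:
        raise ValueError(f"constant column(s), correlation undefined: "
                         f"{', '.join(constant)}")
    r = scores.corr(method=method).to_numpy(float)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(values=(r + r.T) / 2, method=method,
                             n=x.shape[0])


def nearest_psd(corr: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue-floored PSD repair of a correlation matrix.

    Clips eigenvalues at ``eig_floor``, reconstructs, and rescales back to
    unit diagonal. Returns the input unchanged when already PSD.
    """
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= eig_floor:
        return corr
    logger.warning("correlation matrix not PSD (min eigenvalue %.3e); "
                   "applying eigenvalue floor %.1e", vals.min(), eig_floor)
    fixed = (vecs * np.maximum(vals, eig_floor)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2


# ---------------------------------------------------------------------------
# Graphical lasso solver
# ---------------------------------------------------------------------------

@njit(cache=False)
def _glasso_cd(S, lam, W, B, wtol, max_outer, inner_tol, inner_max):
    """Block coordinate-descent sweeps for the graphical lasso.

    W is the working covariance estimate (diagonal pinned to diag(S) since
    the diagonal is unpenalized), B[k, j] the lasso coefficient of variable
    k in column j's sub-problem. Both are modified in place so a caller can
    warm-start the next lambda. Sweeps until the largest entrywise change
    of W over a full sweep drops below ``wtol``; returns the sweep count.
    """
    p = S.shape[0]
    it = 0
    for it in range(1, max_outer + 1):
        wmax = 0.0
        for j in range(p):
            # inner lasso: 0.5 b'W11 b - s12'b + lam |b|_1
            for _ in range(inner_max):
                dmax = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = S[k, j]
                    for l in range(p):
                        if l != j and l != k:
                            r -= W[k, l] * B[l, j]
                    if r > lam:
                        b = (r - lam) / W[k, k]
                    elif r < -lam:
                        b = (r + lam) / W[k, k]
                    else:
                        b = 0.0
                    d = b - B[k, j]
                    if d < 0.0:
                        d = -d
                    if d > dmax:
                        dmax = d
                    B[k, j] = b
                if dmax < inner_tol:
                    break
            # w12 = W11 @ beta
            for k in range(p):
                if k == j:
                    continue
                acc = 0.0
                for l in range(p):
                    if l != j:
                        acc += W[k, l] * B[l, j]
                d = acc - W[k, j]
                if d < 0.0:
                    d = -d
                if d > wmax:
                    wmax = d
                W[k, j] = acc
                W[j, k] = acc
        if wmax < wtol:
            break
    return it


def _kkt_and_gap(K: np.ndarray, S: np.ndarray, lam: float,
                 ) -> tuple[float, float]:
    """Stationarity residual and duality gap of a candidate optimum.

    KKT: ``K^-1 = S + lam * Z`` with ``Z_ij`` in the subgradient of
    ``|K_ij|`` off-diagonally; gap: ``tr(S K) - p + lam * ||K||_1,off``.
    """
    p = S.shape[0]
    R = np.linalg.inv(K) - S
    kkt = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                kkt = max(kkt, abs(R[i, j]))
            elif K[i, j] > EDGE_EPS:
                kkt = max(kkt, abs(R[i, j] - lam))
            elif K[i, j] < -EDGE_EPS:
                kkt = max(kkt, abs(R[i, j] + lam))
            else:
                kkt = max(kkt, max(0.0, abs(R[i, j]) - lam))
    off = np.abs(K).sum() - np.abs(np.diag(K)).sum()
    gap = float(np.sum(S * K)) - p + lam * off
    return kkt, gap


def glasso_fit(corr: CorrelationMatrix | np.ndarray, lam: float,
               warm: tuple[np.ndarray, np.ndarray] | None = None,
               tol: float = DUALITY_GAP_TOL,
               max_iter: int = MAX_OUTER_ITER) -> np.ndarray:
    """L1-penalized precision estimate for one penalty level.

    Maximizes ``log det K - tr(S K) - lam * sum_{i != j} |K_ij|``; the
    diagonal is unpenalized. Convergence is certified on the returned
    estimate itself (KKT residual and duality gap), not on the internal
    sweep criterion; raises on non-convergence, reporting the gap.
    """
    S = corr.values if isinstance(corr, CorrelationMatrix) else np.asarray(
        corr, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if warm is None:
        W = S.copy()
        B = np.zeros_like(S)
    else:
        W, B = warm
    wtol, spent = 1e-9, 0
    kkt, gap = np.inf, np.inf
    while spent < max_iter:
        spent += _glasso_cd(S, float(lam), W, B, wtol,
                            max_iter - spent, _INNER_TOL, _INNER_MAX)
        K = np.linalg.inv(W)
        K = (K + K.T) / 2.0
        # exact zeros where the lasso support excludes the edge
        K[(np.abs(B) <= EDGE_EPS) & (np.abs(B.T) <= EDGE_EPS)
          & ~np.eye(S.shape[0], dtype=bool)] = 0.0
        kkt, gap = _kkt_and_gap(K, S, float(lam))
        if kkt < 10 * tol and abs(gap) < tol:
            return K
        wtol /= 100.0
        if wtol < 1e-16:
            break
    raise RuntimeError(
        f"graphical lasso did not converge (duality gap {gap:.3e}, "
        f"KKT residual {kkt:.3e} after {spent} sweeps)")


def lambda_grid(corr: CorrelationMatrix | np.ndarray, n_lambda: int = 100,
                ratio: float = 0.01) -> np.ndarray:
    """Descending log-spaced penalty grid from lambda_max (empty graph)
    down to ``ratio * lambda_max``."""
    S = corr.values if isinstance(corr, CorrelationMatrix) else np.asarray(corr)
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = float(off.max())
    if lam_max <= 0:
        raise ValueError("all off-diagonal correlations are zero; "
                         "no meaningful penalty grid")
    return np.logspace(np.log10(lam_max), np.log10(ratio * lam_max), n_lambda)


def ebic_score(K: np.ndarray, corr: CorrelationMatrix | np.ndarray, n: int,
               gamma: float = 0.5) -> float:
    """Extended BIC: Gaussian deviance plus edge penalties,
    ``n (tr(S K) - log det K - p) + |E| log n + 4 |E| gamma log p``.

    The deviance is measured against the saturated model (K = S^-1 up to
    the constant), so the fully saturated fit on its own data scores 0;
    the constant offset leaves model selection unchanged.
    """
    S = corr.values if isinstance(corr, CorrelationMatrix) else np.asarray(corr)
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValueError("precision estimate is not positive definite")
    deviance = n * (float(np.sum(S * K)) - logdet - p)
    iu = np.triu_indices(p, 1)
    n_edges = int((np.abs(K[iu]) > EDGE_EPS).sum())
    return float(deviance + n_edges * np.log(n)
                 + 4.0 * n_edges * gamma * np.log(p))


def glasso_path(corr: CorrelationMatrix, gamma: float = 0.5,
                n_lambda: int = 100, ratio: float = 0.01,
                lambdas: np.ndarray | None = None) -> GlassoPath:
    """Warm-started glasso solution path with per-lambda EBIC.

    EBIC ties are broken toward the larger (sparser) lambda; the grid is
    descending, so the first minimum wins.
    """
    S = nearest_psd(corr.values)
    if lambdas is None:
        lambdas = lambda_grid(S, n_lambda=n_lambda, ratio=ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    p = S.shape[0]
    W = S.copy()
    B = np.zeros_like(S)
    Ks = np.empty((lambdas.size, p, p))
    ebics = np.empty(lambdas.size)
    for i, lam in enumerate(lambdas):
        Ks[i] = glasso_fit(S, lam, warm=(W, B))
        ebics[i] = ebic_score(Ks[i], S, corr.n, gamma)
    selected = int(np.argmin(ebics))
    return GlassoPath(lambdas=lambdas, precisions=Ks, ebics=ebics,
                      selected=selected)


def precision_to_partial(K: np.ndarray) -> np.ndarray:
    """Partial correlations ``w_ij = -K_ij / sqrt(K_ii K_jj)``, zero diag."""
    d = np.sqrt(np.diag(K))
    w = -K / np.outer(d, d)
    np.fill_diagonal(w, 0.0)
    w[np.abs(w) <= EDGE_EPS] = 0.0
    return (w + w.T) / 2


def estimate_network(scores: pd.DataFrame, gamma: float = 0.5,
                     method: str = "pearson", n_lambda: int = 100,
                     ratio: float = 0.01,
                     communities: Mapping[str, str] | None = None,
                     ) -> WeightedNetwork:
    """EBIC-GLASSO regularized partial-correlation network of the scores.

    Parameters
    ----------
    scores
        Screened participants x subscale scores (one column per node).
    gamma
        EBIC hyperparameter; 0.5 is the conventional default.
    method
        ``pearson`` (default) or ``spearman`` input correlations.
    communities
        Node -> community map; defaults to instrument membership when the
        columns are the 12 standard subscales.
    """
    corr = correlation_matrix(scores, method=method)
    path = glasso_path(corr, gamma=gamma, n_lambda=n_lambda, ratio=ratio)
    K = path.precisions[path.selected]
    w = precision_to_partial(K)
    labels = [str(c) for c in scores.columns]
    if communities is None:
        if set(labels) == set(NODE_LABELS):
            communities = {lab: COMMUNITIES[lab] for lab in labels}
        else:
            communities = {lab: "all" for lab in labels}
    meta = {
        "n": corr.n,
        "gamma": gamma,
        "lambda": float(path.lambdas[path.selected]),
        "method": method,
        "n_lambda": int(path.lambdas.size),
        "ebic": float(path.ebics[path.selected]),
    }
    return WeightedNetwork(labels=labels, weights=w,
                           communities=dict(communities), meta=meta)
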