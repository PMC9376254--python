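"""Node predictability: variance of each node explained by all others.

For continuous data this is the nodewise R-squared from regressing each
subscale on the remaining eleven — the Gaussian special case of the
nodewise mixed-model approach used for mixed graphical models. The
default estimator is ordinary least squares; a lasso-regularized nodewise
variant tuned by EBIC is provided as an option, and the two can be
compared in the run report. The network's average predictability is the
arithmetic mean of the node values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _check_design(x: np.ndarray, columns) -> None:
    """Reject exactly duplicated (or negated) column pairs, for which the
    nodewise R2 is degenerate; more diffuse rank deficiency is tolerated
    (least squares then reports the attainable R2, e.g. 1 for a column
    that is an exact linear combination of others)."""
    if np.any(x.std(axis=0) == 0):
        bad = [str(c) for c, s in zip(columns, x.std(axis=0)) if s == 0]
        raise ValueError(f"constant column(s): {', '.join(bad)}")
    corr = np.corrcoef(x, rowvar=False)
    pairs = [(str(columns[i]), str(columns[j]))
             for i in range(len(columns))
             for j in range(i + 1, len(columns))
             if abs(corr[i, j]) >= 1 - 1e-12]
    if pairs:
        raise ValueError(f"exactly collinear column pair(s): {pairs}")


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = np.sum((y - y.mean()) ** 2)
    return 1.0 - np.sum(resid ** 2) / tss


def _lasso_ebic_r2(y: np.ndarray, X: np.ndarray, gamma: float = 0.5) -> float:
    """R2 of an L1-penalized nodewise fit with the penalty chosen by EBIC.

    Uses the LARS path; EBIC(k) = n log(RSS/n) + k log n + 2 gamma k log p.
    """
    from sklearn.linear_model import lars_path

    n, p = X.shape
    xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    yc = y - y.mean()
    _, _, coefs = lars_path(xs, yc, method="lasso")
    tss = np.sum(yc ** 2)
    best = (np.inf, 0.0)
    for step in range(coefs.shape[1]):
        b = coefs[:, step]
        rss = np.sum((yc - xs @ b) ** 2)
        k = int(np.sum(b != 0))
        ebic = n * np.log(max(rss, 1e-300) / n) + k * np.log(n) \
            + 2.0 * gamma * k * np.log(p)
        if ebic < best[0]:
            best = (ebic, 1.0 - rss / tss)
    return best[1]


def node_predictability(scores: pd.DataFrame, method: str = "ols",
                        ) -> pd.DataFrame:
    """Per-node R2 (clipped to [0, 1]) and its network average.

    Parameters
    ----------
    scores
        Screened participants x subscale scores; needs n > p.
    method
        ``"ols"`` (default) or ``"lasso_ebic"``.

    Returns a frame indexed by node with an ``r2`` column; the average is
    stored in ``frame.attrs["average_r2"]``.
    """
    if method not in ("ols", "lasso_ebic"):
        raise ValueError(f"unknown predictability method: {method!r}")
    x = scores.to_numpy(dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need n > p for nodewise regression (n={n}, p={p})")
    _check_design(x, list(scores.columns))
    r2 = np.empty(p)
    for j in range(p):
        y = x[:, j]
        X = np.delete(x, j, axis=1)
        r2[j] = _ols_r2(y, X) if method == "ols" else _lasso_ebic_r2(y, X)
    r2 = np.clip(r2, 0.0, 1.0)
    out = pd.DataFrame({"r2": r2}, index=list(scores.columns))
    out.index.name = "node"
    out.attrs["average_r2"] = float(r2.mean())
    out.attrs["method"] = method
    return out


def average_predictability(table: pd.DataFrame) -> float:
    """Arithmetic mean of the node R2 values."""
    return float(table["r2"].mean())


def population_r2(K: np.ndarray) -> np.ndarray:
    """Population nodewise R2 implied by a precision matrix:
    ``1 - 1 / (K_ii * Sigma_ii)`` with ``Sigma = K^-1``."""
    sigma = np.linalg.inv(K)
    return 1.0 - 1.0 / (np.diag(K) * np.diag(sigma))
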