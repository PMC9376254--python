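"""EBIC-GLASSO estimation: solver optimality, model selection, and
network recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from netpsych import (CorrelationMatrix, correlation_matrix, ebic_score,
                      estimate_network, glasso_fit, glasso_path,
                      lambda_grid, nearest_psd, precision_to_partial,
                      sample_scores)


def penalized_loglik(K, S, lam):
    sign, logdet = np.linalg.slogdet(K)
    off = np.abs(K).sum() - np.abs(np.diag(K)).sum()
    return logdet - np.sum(S * K) - lam * off


def brute_force_glasso_3node(S, lam):
    """Brute-force oracle: enumerate all 27 sign/support patterns of the
    3 free off-diagonals; for each, solve the smooth sign-restricted
    problem with BFGS and keep the best pattern-consistent candidate by
    the true penalized objective. Independent of the coordinate-descent
    route."""
    tri = [(0, 1), (0, 2), (1, 2)]

    def unpack(diag, offs):
        K = np.diag(np.asarray(diag, dtype=float))
        for m, (i, j) in enumerate(tri):
            K[i, j] = K[j, i] = offs[m]
        return K

    best_K, best_val = None, -np.inf
    for pattern in np.ndindex(3, 3, 3):
        signs = np.array(pattern) - 1  # each in {-1, 0, +1}
        free = signs != 0

        def neg_smooth(u, signs=signs, free=free):
            offs = np.zeros(3)
            offs[free] = u[3:]
            K = unpack(u[:3], offs)
            if np.linalg.eigvalsh(K).min() <= 1e-9:
                return 1e10
            logdet = np.linalg.slogdet(K)[1]
            return -(logdet - np.sum(S * K)
                     - 2 * lam * np.sum(signs[free] * offs[free]))

        u0 = np.concatenate([np.ones(3), 0.05 * signs[free]])
        res = minimize(neg_smooth, u0, method="BFGS",
                       options=dict(gtol=1e-12, maxiter=10000))
        offs = np.zeros(3)
        offs[free] = res.x[3:]
        if np.any(signs[free] * offs[free] < -1e-12):
            continue  # BFGS left the sign orthant: invalid candidate
        K = unpack(res.x[:3], offs)
        if np.linalg.eigvalsh(K).min() <= 0:
            continue
        val = penalized_loglik(K, S, lam)
        if val > best_val:
            best_K, best_val = K, val
    return best_K


# ---------------------------------------------------------------------------
# correlation input
# ---------------------------------------------------------------------------

def test_correlation_of_duplicated_and_negated_columns(rng):
    x = rng.standard_normal(200)
    df = pd.DataFrame({"a": x, "b": x, "c": -x + 0.0,
                       "d": rng.standard_normal(200)})
    corr = correlation_matrix(df)
    i = {c: k for k, c in enumerate(df.columns)}
    assert corr.values[i["a"], i["b"]] == pytest.approx(1.0)
    assert corr.values[i["a"], i["c"]] == pytest.approx(-1.0)
    assert corr.n == 200


def test_correlation_of_independent_columns_is_near_zero():
    rng = np.random.default_rng(99)
    df = pd.DataFrame(rng.standard_normal((100_000, 2)), columns=["x", "y"])
    corr = correlation_matrix(df)
    assert abs(corr.values[0, 1]) < 0.02  # ~3/sqrt(n) sampling bound


def test_correlation_rejects_constant_column_by_name(rng):
    df = pd.DataFrame({"ok": rng.standard_normal(50), "flat": np.ones(50)})
    with pytest.raises(ValueError, match="flat"):
        correlation_matrix(df)


def test_nearest_psd_repairs_indefinite_matrix():
    bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
    assert np.linalg.eigvalsh(bad).min() < 0
    fixed = nearest_psd(bad)
    assert np.linalg.eigvalsh(fixed).min() >= 0
    np.testing.assert_allclose(np.diag(fixed), 1.0)


# ---------------------------------------------------------------------------
# glasso solver
# ---------------------------------------------------------------------------

def test_glasso_identity_input_returns_identity():
    S = np.eye(5)
    for lam in (0.0, 0.1, 0.5):
        np.testing.assert_allclose(glasso_fit(S, lam), np.eye(5),
                                   atol=1e-10)


def test_glasso_full_shrinkage_gives_diagonal_precision(rng):
    S = np.corrcoef(rng.standard_normal((6, 100)))
    lam = np.abs(S - np.diag(np.diag(S))).max() * 1.001
    K = glasso_fit(S, lam)
    off = K - np.diag(np.diag(K))
    assert np.abs(off).max() == 0.0
    np.testing.assert_allclose(np.diag(K), 1 / np.diag(S), atol=1e-12)


def test_glasso_matches_brute_force_on_random_3node_suite():
    rng = np.random.default_rng(7)
    for _ in range(20):
        S = np.corrcoef(rng.standard_normal((3, 30)))
        lam = rng.uniform(0.02, 0.4)
        K = glasso_fit(S, lam)
        K_brute = brute_force_glasso_3node(S, lam)
        np.testing.assert_allclose(K, K_brute, atol=1e-4)


def test_glasso_objective_not_worse_than_sklearn(rng):
    from sklearn.covariance import graphical_lasso

    S = np.corrcoef(rng.standard_normal((12, 60)))
    for lam in (0.05, 0.15, 0.3):
        K = glasso_fit(S, lam)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, K_sk = graphical_lasso(S, alpha=lam, max_iter=2000,
                                          tol=1e-10)
        assert penalized_loglik(K, S, lam) >= \
            penalized_loglik(K_sk, S, lam) - 1e-8
        np.testing.assert_allclose(K, K_sk, atol=5e-3)


def test_lambda_zero_equals_closed_form_partial_correlations(rng):
    x = rng.standard_normal((500, 6))
    df = pd.DataFrame(x, columns=list("abcdef"))
    corr = correlation_matrix(df)
    K = glasso_fit(corr, 0.0)
    w = precision_to_partial(K)
    K_exact = np.linalg.inv(corr.values)
    d = np.sqrt(np.diag(K_exact))
    w_exact = -K_exact / np.outer(d, d)
    np.fill_diagonal(w_exact, 0.0)
    np.testing.assert_allclose(w, w_exact, atol=1e-8)


def test_edge_count_grows_as_lambda_decreases(rng):
    # the glasso support is not exactly nested, so isolated single-edge
    # drops can occur; the count must still be monotone as a trend
    x = rng.standard_normal((200, 8)) @ rng.standard_normal((8, 8))
    corr = correlation_matrix(pd.DataFrame(x))
    path = glasso_path(corr, n_lambda=60)
    counts = path.edge_counts()
    assert counts[0] == 0  # lambda_max empties the graph
    diffs = np.diff(counts)
    assert (diffs < 0).sum() <= 3
    assert np.all(diffs >= -1)
    assert counts[-1] >= counts.max() - 1


def test_negative_lambda_rejected():
    with pytest.raises(ValueError):
        glasso_fit(np.eye(3), -0.1)


# ---------------------------------------------------------------------------
# EBIC
# ---------------------------------------------------------------------------

def test_ebic_identity_model_scores_zero():
    K = np.eye(2)
    assert ebic_score(K, np.eye(2), n=100, gamma=0.5) == pytest.approx(0.0)


def test_ebic_matches_hand_formula_on_4node_case(rng):
    S = np.corrcoef(rng.standard_normal((4, 50)))
    K = glasso_fit(S, 0.05)
    n, gamma, p = 80, 0.5, 4
    iu = np.triu_indices(p, 1)
    n_edges = int((np.abs(K[iu]) > 1e-10).sum())
    deviance = n * (np.sum(S * K) - np.linalg.slogdet(K)[1] - p)
    expected = deviance + n_edges * np.log(n) \
        + 4 * n_edges * gamma * np.log(p)
    assert ebic_score(K, S, n=n, gamma=gamma) == pytest.approx(expected)
    assert n_edges > 0


def test_ebic_penalty_increases_with_edges():
    # the penalty term alone is monotone in edge count by construction
    n, p, gamma = 100, 6, 0.5
    pen = [e * np.log(n) + 4 * e * gamma * np.log(p) for e in range(10)]
    assert np.all(np.diff(pen) > 0)


# ---------------------------------------------------------------------------
# estimate_network
# ---------------------------------------------------------------------------

def test_independent_columns_give_near_empty_network():
    rng = np.random.default_rng(11)
    df = pd.DataFrame(rng.standard_normal((5000, 6)),
                      columns=list("abcdef"))
    net = estimate_network(df)
    assert len(net.edges()) <= 1
    assert np.abs(net.weights).max() < 0.05


def test_network_is_scale_invariant(rng):
    x = rng.standard_normal((300, 5)) @ rng.standard_normal((5, 5))
    df = pd.DataFrame(x, columns=list("abcde"))
    net1 = estimate_network(df)
    scaled = df.copy()
    scaled["c"] = scaled["c"] * 37.5
    net2 = estimate_network(scaled)
    np.testing.assert_allclose(net1.weights, net2.weights, atol=1e-8)


def test_recovery_of_known_sparse_structure():
    """True edges of a known sparse precision matrix are detected at
    n=5000 (sensitivity >= 0.9) while every spurious edge stays weak —
    EBIC-GLASSO admits a few tiny false partials at large n, so the
    false-edge criterion is on magnitude, not a near-zero count."""
    from netpsych import generate_precision, paper_like_spec

    sens, fpr, max_false = [], [], 0.0
    for seed in range(10):
        spec = paper_like_spec(seed=seed)
        truth, K = generate_precision(spec)
        df = sample_scores(K, 5000, seed=seed)
        net = estimate_network(df)
        true_edges = np.abs(truth.weights) > 1e-10
        est_edges = np.abs(net.weights) > 1e-10
        iu = np.triu_indices(12, 1)
        t, e = true_edges[iu], est_edges[iu]
        sens.append((t & e).sum() / t.sum())
        fpr.append((~t & e).sum() / (~t).sum())
        false_mask = (~true_edges) & est_edges
        if false_mask.any():
            max_false = max(max_false,
                            np.abs(net.weights[false_mask]).max())
    assert np.mean(sens) >= 0.9
    assert np.mean(fpr) <= 0.25
    assert max_false < 0.05


def test_estimated_metadata_records_selection(ref_scores_small):
    net = estimate_network(ref_scores_small)
    assert net.meta["n"] == 560
    assert net.meta["gamma"] == 0.5
    assert net.meta["lambda"] > 0
    assert set(net.communities.values()) == {"cerq", "alexithymia"}
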