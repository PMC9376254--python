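"""Synthetic ground-truth networks and questionnaire-like cohorts.

Everything the pipeline consumes can be generated here with known ground
truth, so each stage is testable without any external data:

* sparse two-community precision matrices with planted cross-community
  (bridge) edges, positive definite by diagonal dominance;
* multivariate-normal subscale scores sampled from a precision matrix
  (ground truth is defined at the partial-correlation scale — exactly
  what the estimator targets);
* 5-level Likert discretization and item-level questionnaire generation
  (IAT 20 items, TAS-20 with reverse-keyed items, CERQ 9 x 4) that
  aggregates back to the subscales under the shipped scoring keys;
* a synthetic study cohort emulating the survey this package models:
  1,677 students of whom exactly 560 exceed the IAT > 50 screening cutoff,
  with the screened participants' subscale structure following the
  published reference network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datasets import COMMUNITIES, NODE_LABELS, reference_weight_matrix
from .network import WeightedNetwork, precision_to_partial
from .scales import DEFAULT_CERQ_KEY, DEFAULT_TAS_KEY, CerqKey, TasKey


# ---------------------------------------------------------------------------
# Ground-truth networks
# ---------------------------------------------------------------------------

@dataclass
class SyntheticNetworkSpec:
    """Recipe for a sparse two-community ground-truth network.

    ``bridge_edges`` are explicit cross-community edges (i, j, weight) in
    node-index terms; ``within_edges`` optionally pins within-community
    edges explicitly instead of sampling them.
    """

    p: int = 12
    community_sizes: tuple[int, ...] = (9, 3)
    within_prob: float = 0.35
    weight_range: tuple[float, float] = (0.15, 0.7)
    negative_fraction: float = 0.1
    bridge_edges: tuple[tuple[int, int, float], ...] = ()
    within_edges: tuple[tuple[int, int, float], ...] | None = None
    n: int = 560
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 3:
            raise ValueError("need p >= 3")
        if sum(self.community_sizes) != self.p:
            raise ValueError("community sizes must sum to p")
        if len(self.community_sizes) < 2:
            raise ValueError("need at least two communities")
        lo, hi = self.weight_range
        if not 0 < lo <= hi < 1:
            raise ValueError("weight range must satisfy 0 < lo <= hi < 1")

    @property
    def labels(self) -> list[str]:
        if self.p == 12 and tuple(self.community_sizes) == (9, 3):
            return list(NODE_LABELS)
        return [f"V{i + 1}" for i in range(self.p)]

    @property
    def communities(self) -> dict[str, str]:
        if self.p == 12 and tuple(self.community_sizes) == (9, 3):
            return dict(COMMUNITIES)
        names = {}
        start = 0
        for ci, size in enumerate(self.community_sizes):
            for i in range(start, start + size):
                names[self.labels[i]] = f"community_{ci + 1}"
            start += size
        return names

    def community_index(self) -> np.ndarray:
        out = np.empty(self.p, dtype=int)
        start = 0
        for ci, size in enumerate(self.community_sizes):
            out[start:start + size] = ci
            start += size
        return out


def generate_precision(spec: SyntheticNetworkSpec,
                       ) -> tuple[WeightedNetwork, np.ndarray]:
    """Build the ground-truth network and its precision matrix.

    Off-diagonal structure follows the spec; positive definiteness is
    enforced by diagonal dominance (diagonal = 1.05 x row sum of absolute
    off-diagonals, floored at 1). The returned network holds the exact
    partial correlations implied by the precision matrix.
    """
    rng = np.random.default_rng(spec.seed)
    comm = spec.community_index()
    A = np.zeros((spec.p, spec.p))
    if spec.within_edges is not None:
        for i, j, w in spec.within_edges:
            if comm[i] != comm[j]:
                raise ValueError(f"within edge ({i},{j}) crosses communities")
            A[i, j] = A[j, i] = w
    else:
        lo, hi = spec.weight_range
        for i in range(spec.p):
            for j in range(i + 1, spec.p):
                if comm[i] == comm[j] and rng.random() < spec.within_prob:
                    w = rng.uniform(lo, hi)
                    if rng.random() < spec.negative_fraction:
                        w = -w
                    A[i, j] = A[j, i] = w
    for i, j, w in spec.bridge_edges:
        if comm[i] == comm[j]:
            raise ValueError(f"bridge edge ({i},{j}) is within a community")
        A[i, j] = A[j, i] = w
    if np.any(np.abs(A) >= 1):
        raise ValueError("edge magnitudes must be < 1")
    K = -A
    diag = np.maximum(1.0, 1.05 * np.abs(A).sum(axis=1))
    K[np.diag_indices_from(K)] = diag
    if np.linalg.eigvalsh(K).min() <= 0:
        raise ValueError("constructed precision matrix is not positive "
                         "definite")
    w_true = precision_to_partial(K)
    if np.any(np.abs(w_true) >= 1):
        raise ValueError("implied partial correlations reach |w| >= 1")
    net = WeightedNetwork(labels=spec.labels, weights=w_true,
                          communities=spec.communities,
                          meta={"truth": True, "seed": spec.seed})
    return net, K


def paper_like_spec(n: int = 560, seed: int = 0) -> SyntheticNetworkSpec:
    """Preset mirroring the study's topology: 12 nodes in a 9 + 3 split,
    strong within-community pairs, and two dominant planted bridge edges
    linking one node of each community (analogous to the published
    EOTS-Cts coupling), without copying the published weights."""
    within = (
        # community 1 (9 nodes, indices 0..8)
        (0, 1, 0.35), (1, 2, 0.25), (2, 3, 0.30), (3, 4, 0.20),
        (4, 5, 0.65), (5, 6, 0.15), (6, 7, 0.28), (7, 8, 0.45),
        (0, 4, 0.18), (2, 7, 0.16),
        # community 2 (3 nodes, indices 9..11)
        (9, 10, 0.66), (9, 11, 0.15),
    )
    bridges = ((7, 11, 0.32), (3, 9, 0.12))
    return SyntheticNetworkSpec(within_edges=within, bridge_edges=bridges,
                                n=n, seed=seed)


def reference_precision() -> np.ndarray:
    """Precision matrix whose partial correlations equal the published
    reference network exactly (unit diagonal, K = I - W)."""
    return np.eye(len(NODE_LABELS)) - reference_weight_matrix()


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_scores(precision: np.ndarray, n: int, seed: int = 0,
                  labels: list[str] | None = None,
                  standardize: bool = True) -> pd.DataFrame:
    """Draw n observations from the zero-mean Gaussian with covariance
    ``precision^-1`` (rescaled to unit variances when ``standardize``)."""
    K = np.asarray(precision, dtype=float)
    vals = np.linalg.eigvalsh(K)
    if vals.min() <= 0:
        raise ValueError("precision matrix must be positive definite")
    sigma = np.linalg.inv(K)
    if standardize:
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)
    L = np.linalg.cholesky(sigma)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, K.shape[0])) @ L.T
    if labels is None:
        labels = (list(NODE_LABELS) if K.shape[0] == len(NODE_LABELS)
                  else [f"V{i + 1}" for i in range(K.shape[0])])
    return pd.DataFrame(x, columns=labels)


def sample_reference_scores(n: int, seed: int = 0) -> pd.DataFrame:
    """Continuous subscale scores whose population partial correlations
    equal the published reference network."""
    return sample_scores(reference_precision(), n, seed=seed)


def discretize_likert(table: pd.DataFrame, levels: int = 5,
                      thresholds: np.ndarray | None = None) -> pd.DataFrame:
    """Cut each (approximately standard-normal) column into 1..levels.

    Default thresholds are the standard-normal quantiles of
    equal-probability bins; supplied thresholds must be strictly
    increasing with length ``levels - 1``.
    """
    if thresholds is None:
        thresholds = norm.ppf(np.arange(1, levels) / levels)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size != levels - 1:
        raise ValueError(f"need {levels - 1} thresholds for {levels} levels")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    out = table.copy()
    for col in out.columns:
        out[col] = np.digitize(out[col].to_numpy(float), thresholds) + 1
    return out.astype(int)


# ---------------------------------------------------------------------------
# Item-level generation
# ---------------------------------------------------------------------------

def _items_from_factor(z: np.ndarray, n_items: int, loading: float,
                       rng: np.random.Generator,
                       discretize: bool = True) -> np.ndarray:
    noise = rng.standard_normal((z.size, n_items))
    latent = loading * z[:, None] + np.sqrt(1.0 - loading ** 2) * noise
    if not discretize:
        return latent
    cuts = norm.ppf(np.arange(1, 5) / 5)
    return np.digitize(latent, cuts) + 1


def generate_item_level(subscales: pd.DataFrame, loading: float = 0.8,
                        seed: int = 0, tas_key: TasKey = DEFAULT_TAS_KEY,
                        cerq_key: CerqKey = DEFAULT_CERQ_KEY,
                        discretize: bool = True,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Likert item responses consistent with given subscale z-scores.

    Each item is ``loading * z + sqrt(1 - loading^2) * noise`` discretized
    to 1..5 (``discretize=False`` keeps the continuous item latents, e.g.
    to verify that scoring recovers the subscales exactly at loading 1).
    TAS reverse-keyed items are emitted pre-reversed (``6 - x``) so that
    standard scoring recovers the intended factor ordering.
    Returns (tas_items, cerq_items), indexed like ``subscales``.
    """
    if not 0 < loading <= 1:
        raise ValueError("loading must be in (0, 1]")
    rng = np.random.default_rng(seed)
    tas = pd.DataFrame(index=subscales.index)
    for factor, item_ids in tas_key.factors.items():
        z = subscales[factor].to_numpy(float)
        z = (z - z.mean()) / (z.std(ddof=1) or 1.0)
        vals = _items_from_factor(z, len(item_ids), loading, rng,
                                  discretize)
        for col, item_id in enumerate(item_ids):
            v = vals[:, col]
            if item_id in tas_key.reverse:
                v = 6 - v
            tas[f"TAS_{item_id}"] = v
    tas = tas[[f"TAS_{k}" for k in range(1, 21)]]

    cerq = pd.DataFrame(index=subscales.index)
    for sub, item_ids in cerq_key.blocks.items():
        z = subscales[sub].to_numpy(float)
        z = (z - z.mean()) / (z.std(ddof=1) or 1.0)
        vals = _items_from_factor(z, len(item_ids), loading, rng,
                                  discretize)
        for col, item_id in enumerate(item_ids):
            cerq[f"CERQ_{item_id}"] = vals[:, col]
    cerq = cerq[[f"CERQ_{k}" for k in range(1, 37)]]
    return tas, cerq


def _iat_items_conditional(n: int, addicted: bool, rng: np.random.Generator,
                           cutoff: int = 50, max_tries: int = 1000,
                           ) -> np.ndarray:
    """IAT item rows drawn conditional on the screening outcome.

    Severity is a per-person latent trait; rows are resampled until the
    total lands on the requested side of the cutoff (a designed cohort
    composition, matching a survey that reports a fixed screened count).
    """
    mu = 3.35 if addicted else 2.15
    out = np.empty((n, 20), dtype=int)
    for i in range(n):
        for _ in range(max_tries):
            sev = rng.normal(0.0, 0.45)
            latent = mu + sev + 0.9 * rng.standard_normal(20)
            row = np.clip(np.round(latent), 1, 5).astype(int)
            total = row.sum()
            if (total > cutoff) == addicted:
                out[i] = row
                break
        else:
            raise RuntimeError("IAT rejection sampling failed")
    return out


@dataclass
class StudyCohort:
    """Item-level synthetic cohort plus its generating ground truth."""

    iat_items: pd.DataFrame
    tas_items: pd.DataFrame
    cerq_items: pd.DataFrame
    latent_subscales: pd.DataFrame
    addicted: pd.Series
    truth: WeightedNetwork
    seed: int = 0


def study_cohort(n_total: int = 1677, n_addicted: int = 560, seed: int = 0,
                 loading: float = 0.85) -> StudyCohort:
    """Synthetic survey cohort emulating the modeled study's composition.

    ``n_addicted`` of ``n_total`` participants have IAT totals strictly
    above 50 (the screened subgroup); their latent subscale z-scores
    follow the published reference network's Gaussian graphical model,
    while the remainder follow the same topology at half strength.
    TAS and CERQ item responses aggregate back to the subscales under the
    default scoring keys. Fully deterministic given the seed.
    """
    if not 0 <= n_addicted <= n_total:
        raise ValueError("need 0 <= n_addicted <= n_total")
    rng = np.random.default_rng(seed)
    W = reference_weight_matrix()
    k_addicted = np.eye(12) - W
    k_rest = np.eye(12) - 0.5 * W

    z_a = sample_scores(k_addicted, n_addicted,
                        seed=int(rng.integers(2 ** 31)))
    z_r = sample_scores(k_rest, n_total - n_addicted,
                        seed=int(rng.integers(2 ** 31)))
    latent = pd.concat([z_a, z_r], ignore_index=True)
    addicted = pd.Series([True] * n_addicted
                         + [False] * (n_total - n_addicted))
    # shuffle so group membership is not encoded in participant order
    order = rng.permutation(n_total)
    latent = latent.iloc[order].reset_index(drop=True)
    addicted = addicted.iloc[order].reset_index(drop=True)
    ids = [f"P{i + 1:04d}" for i in range(n_total)]
    latent.index = pd.Index(ids, name="participant_id")
    addicted.index = latent.index

    tas_items, cerq_items = generate_item_level(
        latent, loading=loading, seed=int(rng.integers(2 ** 31)))

    iat = np.empty((n_total, 20), dtype=int)
    a_mask = addicted.to_numpy()
    iat[a_mask] = _iat_items_conditional(int(a_mask.sum()), True, rng)
    iat[~a_mask] = _iat_items_conditional(int((~a_mask).sum()), False, rng)
    iat_items = pd.DataFrame(iat, index=latent.index,
                             columns=[f"IAT_{k}" for k in range(1, 21)])

    for frame in (iat_items, tas_items, cerq_items):
        frame.reset_index(inplace=True)

    truth = WeightedNetwork(labels=list(NODE_LABELS), weights=W,
                            communities=dict(COMMUNITIES),
                            meta={"truth": True, "population": "screened"})
    return StudyCohort(iat_items=iat_items, tas_items=tas_items,
                       cerq_items=cerq_items,
                       latent_subscales=latent.reset_index(),
                       addicted=addicted, truth=truth, seed=seed)
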