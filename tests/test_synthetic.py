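"""Ground-truth generators: precision construction, Gaussian sampling,
Likert discretization, item-level emulation, and the study cohort."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from netpsych import (SyntheticNetworkSpec, build_score_table,
                      discretize_likert, generate_item_level,
                      generate_precision, paper_like_spec, sample_scores,
                      score_cerq, score_tas, study_cohort)


def test_zero_edge_spec_gives_identity_precision():
    spec = SyntheticNetworkSpec(p=6, community_sizes=(3, 3),
                                within_prob=0.0, seed=0)
    net, K = generate_precision(spec)
    np.testing.assert_array_equal(K, np.eye(6))
    assert net.edges() == []


def test_single_edge_spec_has_correct_sign_and_support():
    spec = SyntheticNetworkSpec(p=4, community_sizes=(2, 2),
                                within_prob=0.0,
                                bridge_edges=((0, 2, 0.4),), seed=0)
    net, K = generate_precision(spec)
    off = K - np.diag(np.diag(K))
    assert np.count_nonzero(off) == 2
    assert K[0, 2] == pytest.approx(-0.4)
    assert net.weights[0, 2] > 0  # positive partial correlation
    assert len(net.edges()) == 1


@pytest.mark.parametrize("seed", range(5))
def test_generated_precision_is_positive_definite(seed):
    spec = SyntheticNetworkSpec(within_prob=0.5, negative_fraction=0.3,
                                bridge_edges=((0, 9, 0.3), (8, 11, -0.25)),
                                seed=seed)
    _, K = generate_precision(spec)
    assert np.linalg.eigvalsh(K).min() > 0


def test_bridge_edge_inside_community_rejected():
    with pytest.raises(ValueError, match="within a community"):
        generate_precision(SyntheticNetworkSpec(
            bridge_edges=((0, 1, 0.3),)))


def test_sampling_from_identity_precision_is_uncorrelated():
    df = sample_scores(np.eye(4), 200_000, seed=3,
                       labels=list("abcd"))
    corr = df.corr().to_numpy()
    assert np.abs(corr - np.eye(4)).max() < 0.01


def test_sample_covariance_converges_to_precision_inverse():
    _, K = generate_precision(paper_like_spec(seed=1))
    df = sample_scores(K, 100_000, seed=4, standardize=False)
    sigma_hat = np.cov(df.to_numpy(), rowvar=False)
    np.testing.assert_allclose(sigma_hat, np.linalg.inv(K), atol=0.02)


def test_sampling_is_seed_deterministic():
    _, K = generate_precision(paper_like_spec(seed=2))
    a = sample_scores(K, 100, seed=5)
    b = sample_scores(K, 100, seed=5)
    pd.testing.assert_frame_equal(a, b)


def test_likert_middle_category_most_frequent_for_symmetric_cuts():
    df = pd.DataFrame({"z": np.random.default_rng(6).standard_normal(20000)})
    cut = discretize_likert(df)
    counts = cut["z"].value_counts()
    assert set(counts.index) <= {1, 2, 3, 4, 5}
    # equal-probability bins: all five roughly 20%
    assert counts.max() / len(df) < 0.25


def test_likert_all_below_first_threshold_maps_to_one():
    df = pd.DataFrame({"z": np.full(10, -50.0)})
    assert (discretize_likert(df)["z"] == 1).all()


def test_likert_rejects_non_monotone_thresholds():
    df = pd.DataFrame({"z": np.zeros(5)})
    with pytest.raises(ValueError, match="increasing"):
        discretize_likert(df, thresholds=[-1.0, -1.5, 0.5, 1.0])


def test_likert_preserves_rank_order():
    rng = np.random.default_rng(7)
    df = pd.DataFrame({"z": rng.standard_normal(10_000)})
    cut = discretize_likert(df)
    rho = spearmanr(df["z"], cut["z"]).statistic
    assert rho > 0.9


def test_item_level_loading_one_without_discretization_is_exact():
    from netpsych import DEFAULT_TAS_KEY, reference_precision

    sub = sample_scores(reference_precision(), 2000, seed=8)
    tas, cerq = generate_item_level(sub, loading=1.0, seed=8,
                                    discretize=False)
    # DIF has no reverse-keyed items: its item sum is 7x the factor z-score
    dif_sum = tas[[f"TAS_{k}" for k in DEFAULT_TAS_KEY.dif]].sum(axis=1)
    r = np.corrcoef(sub["DIF"], dif_sum)[0, 1]
    assert r == pytest.approx(1.0, abs=1e-12)
    # with discretization the recovery is monotone up to binning ties
    tas_d, _ = generate_item_level(sub, loading=1.0, seed=8)
    rho = spearmanr(sub["DIF"], score_tas(tas_d)["DIF"]).statistic
    assert rho > 0.97


def test_item_level_loading_08_reproduces_subscales():
    from netpsych import reference_precision

    sub = sample_scores(reference_precision(), 5000, seed=9)
    tas, cerq = generate_item_level(sub, loading=0.8, seed=9)
    rescored_cerq = score_cerq(cerq)
    for col in ("Slb", "Cts", "Blo"):
        r = np.corrcoef(sub[col], rescored_cerq[col])[0, 1]
        assert r > 0.85
    rescored_tas = score_tas(tas)
    for col in ("DIF", "DDF", "EOTS"):
        r = np.corrcoef(sub[col], rescored_tas[col])[0, 1]
        assert r > 0.85


def test_item_level_is_seed_deterministic():
    from netpsych import reference_precision

    sub = sample_scores(reference_precision(), 50, seed=10)
    a = generate_item_level(sub, seed=11)
    b = generate_item_level(sub, seed=11)
    pd.testing.assert_frame_equal(a[0], b[0])
    pd.testing.assert_frame_equal(a[1], b[1])


def test_study_cohort_composition_and_determinism():
    cohort = study_cohort(n_total=200, n_addicted=70, seed=12)
    assert len(cohort.iat_items) == 200
    totals = cohort.iat_items.set_index("participant_id").sum(axis=1)
    assert (totals > 50).sum() == 70
    assert ((totals > 50) == cohort.addicted).all()
    again = study_cohort(n_total=200, n_addicted=70, seed=12)
    pd.testing.assert_frame_equal(cohort.iat_items, again.iat_items)
    pd.testing.assert_frame_equal(cohort.cerq_items, again.cerq_items)


def test_study_cohort_screens_to_designed_count():
    cohort = study_cohort(n_total=150, n_addicted=60, seed=13)
    table = build_score_table(cohort.iat_items, cohort.tas_items,
                              cohort.cerq_items)
    assert len(table) == 60
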