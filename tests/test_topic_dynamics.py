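import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import topiclens as tl
from topiclens.topic_dynamics import TrendResult

from _oracles import permutation_trend_distribution


class TestDominantTopic:
    def test_argmax_per_row(self):
        assert tl.dominant_topic(np.array([[0.7, 0.3]])).tolist() == [0]

    def test_tie_goes_to_lower_index(self):
        assert tl.dominant_topic(np.array([[0.5, 0.5]])).tolist() == [0]

    def test_pure_documents(self):
        theta = np.eye(3)
        assert tl.dominant_topic(theta).tolist() == [0, 1, 2]


class TestYearlyShare:
    def test_hand_counted_shares(self):
        series = tl.yearly_share(np.array([0, 0, 1, 1]), np.array([2000] * 4), n_topics=2)
        assert series.share.tolist() == [[0.5, 0.5]]

    def test_single_topic_takes_all(self):
        series = tl.yearly_share(np.zeros(5, dtype=int), np.array([2000] * 5), n_topics=3)
        assert series.share.tolist() == [[1.0, 0.0, 0.0]]

    def test_shares_sum_to_one_per_year(self):
        rng = np.random.default_rng(0)
        dom = rng.integers(0, 4, size=200)
        years = rng.integers(1990, 1995, size=200)
        series = tl.yearly_share(dom, years, n_topics=4)
        np.testing.assert_allclose(series.share.sum(axis=1), 1.0, atol=1e-9)
        assert (series.x.sum(axis=1) == series.n).all()

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            tl.yearly_share(np.array([]), np.array([]))


class TestLinearTrend:
    def test_constant_series_has_zero_slope(self):
        slope, _ = tl.linear_trend([2000, 2001, 2002], [0.2, 0.2, 0.2])
        assert slope == 0.0

    def test_exact_linear_series(self):
        years = np.arange(2000, 2005)
        shares = 0.1 + 0.02 * (years - 2000)
        slope, p = tl.linear_trend(years, shares)
        assert slope == pytest.approx(0.02, rel=1e-9)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_closed_form(self):
        years = np.arange(1990, 1995).astype(float)
        shares = np.array([0.11, 0.09, 0.14, 0.13, 0.18])
        expected = (((years - years.mean()) * (shares - shares.mean())).sum()
                    / ((years - years.mean()) ** 2).sum())
        slope, _ = tl.linear_trend(years, shares)
        assert slope == pytest.approx(expected, rel=1e-12)

    def test_too_few_years_is_error(self):
        with pytest.raises(ValueError):
            tl.linear_trend([2000, 2001], [0.1, 0.2])


class TestCochranArmitage:
    def test_equal_proportions_give_zero_statistic(self):
        z, p = tl.cochran_armitage([2, 2, 2], [10, 10, 10])
        assert z == 0.0 and p == 1.0

    def test_hand_worked_two_year_table(self):
        # x=[1,3], n=[4,4], scores=[0,1]: p̄=1/2, T=1, Var=1/2 → z=√2
        z, p = tl.cochran_armitage([1, 3], [4, 4], scores=[0, 1])
        assert z == pytest.approx(np.sqrt(2.0), rel=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(np.sqrt(2.0)), rel=1e-12)

    def test_against_exhaustive_permutation_distribution(self):
        # all C(8,4) arrangements of the successes across the two years
        x, n, scores = [1, 3], [4, 4], [0.0, 1.0]
        z, p = tl.cochran_armitage(x, n, scores=scores)
        vals, probs = permutation_trend_distribution(x, n, scores)
        p_bar = sum(x) / sum(n)
        t_obs = sum(s * (xi - ni * p_bar) for s, xi, ni in zip(scores, x, n))
        # T is centred under permutation, and the permutation variance equals
        # the closed-form Var(T) up to the finite-population factor N/(N-1)
        N = sum(n)
        mean_perm = float((probs * vals).sum())
        var_perm = float((probs * vals**2).sum()) - mean_perm**2
        var_closed = (t_obs / z) ** 2
        assert mean_perm == pytest.approx(0.0, abs=1e-12)
        assert var_perm == pytest.approx(var_closed * N / (N - 1), rel=1e-9)
        # exact two-sided permutation p-value brackets the normal one
        p_exact = float(probs[np.abs(vals) >= abs(t_obs) - 1e-12].sum())
        assert abs(p - p_exact) < 0.35

    def test_degenerate_table_flagged(self):
        z, p = tl.cochran_armitage([0, 0], [5, 5])
        assert (z, p) == (0.0, 1.0)

    def test_rejects_impossible_counts(self):
        with pytest.raises(ValueError):
            tl.cochran_armitage([6], [5])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(1, 1000), st.integers(-50, 50), st.integers(0, 10**6))
    def test_affine_score_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 50, size=6)
        x = rng.binomial(n, 0.3)
        if x.sum() in (0, n.sum()):
            return
        scores = np.arange(6, dtype=float)
        z1, _ = tl.cochran_armitage(x, n, scores=scores)
        z2, _ = tl.cochran_armitage(x, n, scores=a * scores + b)
        assert z2 == pytest.approx(z1, rel=1e-9, abs=1e-12)

    def test_sign_agrees_with_ols_on_monotone_series(self):
        n = np.full(5, 100)
        x = np.array([10, 14, 19, 25, 31])
        years = np.arange(2000, 2005)
        z, _ = tl.cochran_armitage(x, n, scores=years.astype(float))
        slope, _ = tl.linear_trend(years, x / n)
        assert np.sign(z) == np.sign(slope) == 1.0
        z2, _ = tl.cochran_armitage(x[::-1], n, scores=years.astype(float))
        assert z2 == pytest.approx(-z, rel=1e-12)


class TestClassifyTrend:
    def _result(self, slope, ca_p, mean_share):
        return TrendResult(slope=slope, slope_p=0.01, ca_z=np.sign(slope) * 3,
                           ca_p=ca_p, mean_share=mean_share)

    def test_infrequent_overrides_slope(self):
        assert tl.classify_trend(self._result(0.01, 0.001, 0.01)) == "infrequent"

    def test_hot_rule(self):
        assert tl.classify_trend(self._result(0.002, 0.001, 0.08)) == "hot"

    def test_cold_rule(self):
        assert tl.classify_trend(self._result(-0.002, 0.001, 0.08)) == "cold"

    def test_insignificant_is_stable(self):
        assert tl.classify_trend(self._result(0.002, 0.4, 0.08)) == "stable"


def test_single_rising_topic_is_the_only_hot_label(stopwords):
    """With one injected rising topic and the rest flat, the rising topic is
    labelled hot and no flat topic is, across 5 seeds."""
    profiles = (("rising", 0.01), ("flat", 0.0), ("flat", 0.0),
                ("flat", 0.0), ("flat", 0.0))
    for seed in range(5):
        spec = tl.GeneratorSpec(trend_profiles=profiles, seed=seed)
        corpus, truth = tl.generate_corpus(spec)
        dtm = tl.build_dtm(corpus, stopwords, min_doc_freq=5)
        model, _ = tl.fit(dtm, tl.LdaConfig(n_topics=5, alpha=0.02, eta=0.02,
                                            n_iter=500, seed=seed))
        phi = tl.align_phi(model.phi, dtm.vocabulary.index, truth.vocabulary)
        est_of_true = {j: i for i, j, _ in tl.match_topics(phi, truth.phi_true)}
        series = tl.yearly_share(tl.dominant_topic(model.theta), dtm.doc_years,
                                 n_topics=5)
        labels = tl.trend_table(series).set_index("topic")["label"]
        assert labels[est_of_true[0]] == "hot", seed
        for true_k in range(1, 5):
            assert labels[est_of_true[true_k]] != "hot", (seed, true_k)


def test_trend_table_labels_injected_trends(recovery_runs):
    """On the reference synthetic corpus the injected rising topic comes out
    hot and the falling topic cold (checked per matched estimated topic)."""
    hits = 0
    for run in recovery_runs:
        truth, model, dtm = run["truth"], run["model"], run["dtm"]
        series = tl.yearly_share(tl.dominant_topic(model.theta), dtm.doc_years,
                                 n_topics=model.n_topics)
        table = tl.trend_table(series)
        est_of_true = {j: i for i, j, _ in run["matches"]}
        labels = table.set_index("topic")["label"]
        if labels[est_of_true[0]] == "hot" and labels[est_of_true[1]] == "cold":
            hits += 1
    assert hits >= 4
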