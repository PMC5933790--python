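"""Markov chains, entropy rates, deviation bands and the day detector."""

import warnings

import numpy as np
import pandas as pd
import pytest

from adlsense.macro import (EntropyRateDetector, MarkovModel,
                            anomaly_notification_correlation, cluster_days,
                            deviation_bounds, entropy, entropy_rate,
                            fit_markov, map_states, weekly_sensitivity)


def oracle_markov(sequences, n_states):
    """Independent count-and-normalise estimate used to check fit_markov."""
    trans = np.zeros((n_states, n_states))
    occ = np.zeros(n_states)
    for seq in sequences:
        for s in seq:
            occ[s] += 1
        for a, b in zip(seq[:-1], seq[1:]):
            trans[a, b] += 1
    T = np.zeros_like(trans)
    for a in range(n_states):
        if trans[a].sum():
            T[a] = trans[a] / trans[a].sum()
    return T, occ / occ.sum()


class TestFitMarkov:
    def test_worked_six_state_chain(self):
        """The chain a,b,a,a,c,b: transitions {ab,ba,aa,ac,cb} with
        P_aa = P_ab = P_ac = 1/3, P_ba = P_cb = 1, occupancies 1/2, 1/3, 1/6,
        and entropy rate (1/2) log 3."""
        seq = np.array([0, 1, 0, 0, 2, 1])
        model = fit_markov([seq], 3)
        T, P = oracle_markov([seq], 3)
        np.testing.assert_allclose(model.transitions, T, atol=1e-15)
        np.testing.assert_allclose(model.state_probs, P, atol=1e-15)
        np.testing.assert_allclose(
            model.transitions[0], [1 / 3, 1 / 3, 1 / 3])
        assert model.transitions[1, 0] == 1.0
        assert model.transitions[2, 1] == 1.0
        np.testing.assert_allclose(model.state_probs, [1 / 2, 1 / 3, 1 / 6])
        assert abs(entropy_rate(model) - 0.5 * np.log(3)) < 1e-12

    def test_alternating_chain(self):
        model = fit_markov([np.array([0, 1, 0, 1])], 2)
        assert model.transitions[0, 1] == 1.0
        assert model.transitions[1, 0] == 1.0
        np.testing.assert_allclose(model.state_probs, [0.5, 0.5])

    def test_duplicated_corpus_changes_nothing(self):
        seq = np.array([0, 1, 0, 0, 2, 1])
        one = fit_markov([seq], 3)
        two = fit_markov([seq, seq], 3)
        np.testing.assert_allclose(one.transitions, two.transitions)
        np.testing.assert_allclose(one.state_probs, two.state_probs)

    def test_no_transition_across_sequence_boundary(self):
        model = fit_markov([np.array([0, 0]), np.array([1, 1])], 2)
        assert model.transitions[0, 1] == 0.0
        assert model.transitions[1, 0] == 0.0

    def test_rejects_empty_and_short_input(self):
        with pytest.raises(ValueError):
            fit_markov([], 2)
        with pytest.raises(ValueError):
            fit_markov([np.array([0])], 2)


def random_model(rng, k):
    T = rng.dirichlet(np.ones(k), size=k)
    P = rng.dirichlet(np.ones(k))
    return MarkovModel(k, T, P, np.ones(k, dtype=bool))


class TestEntropy:
    def test_deterministic_cycle_has_zero_entropy(self):
        T = np.roll(np.eye(3), 1, axis=1)
        model = MarkovModel(3, T, np.full(3, 1 / 3), np.ones(3, bool))
        assert entropy(model) == 0.0
        assert entropy_rate(model) == 0.0

    def test_uniform_row_contributes_log_k(self):
        k = 5
        T = np.zeros((k, k))
        T[0] = 1 / k
        model = MarkovModel(k, T, np.eye(k)[0], np.eye(k)[0].astype(bool))
        assert abs(entropy(model) - np.log(k)) < 1e-12

    def test_entropy_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            model = random_model(rng, 3)
            direct = -sum(p * np.log(p) for row in model.transitions
                          for p in row if p > 0)
            assert abs(entropy(model) - direct) < 1e-12

    @pytest.mark.parametrize("k", range(2, 9))
    def test_uniform_chain_entropy_rate_is_log_k(self, k):
        model = MarkovModel(k, np.full((k, k), 1 / k), np.full(k, 1 / k),
                            np.ones(k, bool))
        assert abs(entropy_rate(model) - np.log(k)) < 1e-12

    def test_entropy_rate_distinguishes_directions_entropy_does_not(self):
        """With a symmetric transition matrix but asymmetric occupancy,
        epsilon is blind to the direction of traffic while xi is not."""
        T = np.array([[0.8, 0.1, 0.1],
                      [0.1, 0.45, 0.45],
                      [0.1, 0.45, 0.45]])
        m1 = MarkovModel(3, T, np.array([0.8, 0.1, 0.1]), np.ones(3, bool))
        m2 = MarkovModel(3, T, np.array([0.1, 0.8, 0.1]), np.ones(3, bool))
        assert entropy(m1) == entropy(m2)
        assert abs(entropy_rate(m1) - entropy_rate(m2)) > 0.1

    def test_rate_bounded_by_entropy_and_log_states(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            k = int(rng.integers(2, 7))
            model = random_model(rng, k)
            xi, eps = entropy_rate(model), entropy(model)
            assert xi <= eps + 1e-12
            assert xi <= np.log(k) + 1e-12
            assert xi >= 0


class TestDeviationBounds:
    def test_worked_example(self):
        prof = deviation_bounds(1.0, np.array([0.8, 1.2]), mu=2.0)
        assert abs(prof.sigma - 0.2) < 1e-15
        assert prof.delta == pytest.approx((0.6, 1.4))

    def test_zero_deviation_collapses_band(self):
        prof = deviation_bounds(1.5, np.array([1.5, 1.5, 1.5]), mu=2.0)
        assert prof.sigma == 0.0
        assert prof.delta == (1.5, 1.5)

    def test_band_width_linear_in_mu(self):
        xi_v = np.array([0.9, 1.3, 1.1])
        narrow = deviation_bounds(1.0, xi_v, mu=1.0)
        wide = deviation_bounds(1.0, xi_v, mu=2.0)
        assert (wide.delta[1] - wide.delta[0]) == pytest.approx(
            2 * (narrow.delta[1] - narrow.delta[0]))

    def test_empty_verification_set_rejected(self):
        with pytest.raises(ValueError):
            deviation_bounds(1.0, np.array([]), mu=2.0)


class TestDayClustering:
    def test_separates_away_like_from_dense_days(self):
        rng = np.random.default_rng(0)
        quiet = rng.normal(0.1, 0.02, size=(20, 144, 2)).clip(0)
        dense = rng.normal(6.0, 0.5, size=(20, 144, 2)).clip(0)
        days = np.concatenate([quiet, dense])
        cats = cluster_days(days, seed=0)
        assert (cats.labels[:20] == "D1").all()
        assert (cats.labels[20:] == "D2").all()

    def test_identical_days_collapse_with_warning(self):
        days = np.ones((5, 144, 2))
        with pytest.warns(UserWarning, match="identical"):
            cats = cluster_days(days, seed=0)
        assert set(cats.labels) == {"D1"}

    def test_day_equal_to_centroid_assigned_there(self):
        rng = np.random.default_rng(1)
        days = np.concatenate([rng.normal(0, 0.1, (10, 288)),
                               rng.normal(5, 0.1, (10, 288))])
        cats = cluster_days(days, seed=0)
        assert cats.assign(cats.centroids[None, 0])[0] == "D1"
        assert cats.assign(cats.centroids[None, 1])[0] == "D2"


class TestStateCodebook:
    def test_two_distinct_vectors_recovered_exactly(self):
        windows = np.array([[0.0, 0.0], [4.0, 4.0]] * 10)
        codebook, km = map_states(windows, 2, seed=0)
        assert sorted(codebook.sum(axis=1)) == [0.0, 8.0]

    def test_zero_window_maps_to_zero_state(self):
        windows = np.concatenate([np.zeros((30, 3)),
                                  np.full((30, 3), 5.0)])
        codebook, km = map_states(windows, 2, seed=0)
        zero_state = km.predict(np.zeros((1, 3)))[0]
        assert np.allclose(codebook[zero_state], 0.0)

    def test_small_perturbations_never_change_the_state(self):
        rng = np.random.default_rng(3)
        windows = rng.uniform(0, 10, size=(200, 4))
        codebook, km = map_states(windows, 5, seed=0)
        dists = np.linalg.norm(
            codebook[:, None, :] - codebook[None, :, :], axis=2)
        margin = dists[dists > 0].min() / 2
        probe = codebook[2]
        for _ in range(50):
            delta = rng.normal(size=4)
            delta *= 0.99 * margin * rng.random() / np.linalg.norm(delta)
            assert km.predict((probe + delta)[None])[0] == \
                km.predict(probe[None])[0]

    def test_more_states_than_distinct_windows_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            map_states(np.zeros((10, 2)), 2, seed=0)


def test_transition_matrix_recovery_from_long_chain():
    """Count estimation recovers a known 4-state generator within 0.05."""
    rng = np.random.default_rng(5)
    T = rng.dirichlet(np.full(4, 2.0), size=4)
    chain = [0]
    for _ in range(10_000):
        chain.append(rng.choice(4, p=T[chain[-1]]))
    model = fit_markov([np.array(chain)], 4)
    assert np.abs(model.transitions - T).max() < 0.05


class TestWeeklySensitivity:
    def test_three_of_four_validated_weeks(self):
        flags = np.zeros(28, bool)
        flags[[0, 1, 7, 8, 14, 15, 21, 22]] = True  # 2 flags per week
        truth = np.array(["normal"] * 28, dtype=object)
        truth[[0, 7, 14]] = "visitor"  # 3 of 4 labelled weeks confirmed
        assert weekly_sensitivity(flags, truth) == 0.75

    def test_all_validated_weeks(self):
        flags = np.array([True, True] + [False] * 5)
        truth = np.array(["away"] + ["normal"] * 6, dtype=object)
        assert weekly_sensitivity(flags, truth) == 1.0

    def test_flag_position_within_week_is_irrelevant(self):
        rng = np.random.default_rng(0)
        flags = rng.random(21) < 0.4
        truth = np.where(rng.random(21) < 0.2, "aia", "normal").astype(object)
        base = weekly_sensitivity(flags, truth)
        shuffled = flags.copy()
        for w in range(3):
            rng.shuffle(shuffled[7 * w:7 * (w + 1)])
        assert weekly_sensitivity(shuffled, truth) == base

    def test_no_labelled_weeks_is_undefined(self):
        assert weekly_sensitivity(np.zeros(14, bool),
                                  np.array(["normal"] * 14)) is None


class TestNotificationCorrelation:
    def test_proportional_counts_correlate_perfectly(self):
        n_a = np.array([1.0, 3.0, 5.0, 9.0])
        assert anomaly_notification_correlation(n_a, 2 * n_a) == \
            pytest.approx(1.0)

    def test_antiproportional_counts(self):
        n_a = np.array([1.0, 3.0, 5.0])
        assert anomaly_notification_correlation(n_a, 10 - n_a) == \
            pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(30), rng.random(30)
        oracle = (np.mean((a - a.mean()) * (b - b.mean()))
                  / (a.std() * b.std()))
        assert abs(anomaly_notification_correlation(a, b) - oracle) < 1e-12

    def test_constant_vector_is_undefined(self):
        with pytest.warns(UserWarning):
            assert anomaly_notification_correlation(
                np.ones(5), np.arange(5.0)) is None


class TestDetector:
    @pytest.fixture
    def fitted(self):
        rng = np.random.default_rng(8)
        train = rng.poisson(3.0, size=(30, 144, 4)).astype(float)
        verif = rng.poisson(3.0, size=(8, 144, 4)).astype(float)
        det = EntropyRateDetector(n_states=4, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            det.fit(train, verif)
        return det, train

    def test_training_day_scores_inside_its_band(self, fitted):
        det, train = fitted
        scores = det.score_days(train[:5])
        assert not scores["flagged"].any()

    def test_pipeline_is_deterministic(self, fitted):
        det, train = fitted
        rng = np.random.default_rng(9)
        test = rng.poisson(3.0, size=(6, 144, 4)).astype(float)
        a = det.score_days(test)
        b = det.score_days(test)
        pd.testing.assert_frame_equal(a, b)

    def test_mu_infinity_flags_nothing(self):
        rng = np.random.default_rng(10)
        train = rng.poisson(3.0, size=(20, 144, 3)).astype(float)
        det = EntropyRateDetector(n_states=3, mu=np.inf, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            det.fit(train, train[:5])
            wild = np.zeros((4, 144, 3))
            assert not det.predict(wild).any()

    def test_one_sided_mode_ignores_low_entropy_days(self):
        rng = np.random.default_rng(12)
        train = rng.poisson(3.0, size=(20, 144, 3)).astype(float)
        two = EntropyRateDetector(n_states=3, random_state=0)
        one = EntropyRateDetector(n_states=3, mode="one_sided", random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            two.fit(train, train[:6])
            one.fit(train, train[:6])
            silent = np.zeros((1, 144, 3))  # near-deterministic, xi below band
            assert two.predict(silent)[0]
            assert not one.predict(silent)[0]
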