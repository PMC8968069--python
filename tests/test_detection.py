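"""GMM-HMM fitting and decoding, baselines, three-fold CV."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.mixture import GaussianMixture

from seegstate.containers import ACTIVE, IDLE
from seegstate.detection import (
    FoldPlan,
    HmmModel,
    fit_baseline,
    fit_gmm_emissions,
    fit_transition_matrix,
    hmm_decode,
    run_cv,
)
from seegstate.features import WindowFeatureMatrix


class TestTransitionMatrix:
    def test_pair_count_example(self):
        labels = np.array([IDLE, IDLE, ACTIVE, ACTIVE, IDLE], object)
        T, pi, states = fit_transition_matrix(labels)
        assert states == [IDLE, ACTIVE]
        assert np.allclose(T, [[0.5, 0.5], [0.5, 0.5]])
        assert np.allclose(pi, [0.6, 0.4])

    def test_unseen_state_errors(self):
        labels = np.full(10, IDLE, object)
        with pytest.raises(ValueError):
            fit_transition_matrix(labels, states=[IDLE, ACTIVE])

    def test_no_cross_segment_transitions(self):
        seg1 = np.array([IDLE, IDLE], object)
        seg2 = np.array([ACTIVE, ACTIVE], object)
        T, _, states = fit_transition_matrix([seg1, seg2])
        # without the boundary pair, idle never transitions to active
        assert T[states.index(IDLE), states.index(ACTIVE)] == 0.0

    def test_zero_row_uniform_with_warning(self):
        labels = np.array([IDLE, IDLE, ACTIVE], object)  # active never exits
        with pytest.warns(UserWarning, match="uniform"):
            T, _, states = fit_transition_matrix(labels)
        assert np.allclose(T[states.index(ACTIVE)], 0.5)

    def test_recovery_on_long_markov_stream(self):
        rng = np.random.default_rng(0)
        # sticky states, as for 50 ms steps through long idle stretches
        T_true = np.array([[0.98, 0.02], [0.07, 0.93]])
        states = [IDLE, ACTIVE]
        seq, s = [], 0
        for _ in range(10_000):
            seq.append(states[s])
            s = rng.choice(2, p=T_true[s])
        T, _, order = fit_transition_matrix(np.array(seq, object))
        assert np.abs(T - T_true).max() < 0.02


class TestGmmEmissions:
    def test_single_gaussian_state_chooses_one_component(self, rng):
        X = rng.standard_normal((400, 2))
        labels = np.array([ACTIVE, IDLE] * 200, object)
        _, comps = fit_gmm_emissions(X, labels, [IDLE, ACTIVE], seed=0)
        assert comps[IDLE] == 1 and comps[ACTIVE] == 1

    def test_two_clusters_choose_two_components(self, rng):
        X = np.vstack([
            rng.standard_normal((200, 2)) * 0.2,
            rng.standard_normal((200, 2)) * 0.2 + 8.0,
        ])
        labels = np.full(400, ACTIVE, object)
        emissions, comps = fit_gmm_emissions(
            X, labels, [ACTIVE], seed=0, k_max=5
        )
        assert comps[ACTIVE] == 2

    def test_duplicate_rows_do_not_fail(self):
        X = np.ones((30, 3))
        labels = np.array([ACTIVE, IDLE] * 15, object)
        with pytest.warns(UserWarning):
            emissions, _ = fit_gmm_emissions(X, labels, [IDLE, ACTIVE], seed=0,
                                             k_max=5)
        assert np.isfinite(emissions[IDLE].score_samples(X)).all()


def _brute_force_path(logpi, logT, logB, states):
    """Exhaustive enumeration of the joint MAP path with the same preference
    order as the decoder (earlier state in `states` wins ties)."""
    n, S = logB.shape
    best, best_score = None, -np.inf
    for path in itertools.product(range(S), repeat=n):
        sc = logpi[path[0]] + logB[0, path[0]]
        for t in range(1, n):
            sc += logT[path[t - 1], path[t]] + logB[t, path[t]]
        if sc > best_score + 1e-12:
            best, best_score = path, sc
    return [states[i] for i in best]


class _StubMix:
    """Deterministic stand-in emission with fixed log densities."""

    def __init__(self, col):
        self.col = np.asarray(col)

    def score_samples(self, X):
        return self.col[: len(X)]


def _model_from_logB(logB_by_state, T, pi, states):
    emissions = {s: _StubMix(logB_by_state[:, i]) for i, s in enumerate(states)}
    return HmmModel(states, T, pi, emissions)


class TestDecoder:
    def test_identity_transitions_keep_initial_state(self, rng):
        states = [IDLE, ACTIVE]
        logB = rng.standard_normal((6, 2))
        model = _model_from_logB(logB, np.eye(2), np.array([1.0, 0.0]), states)
        out = hmm_decode(np.zeros((6, 1)), model)
        assert list(out) == [IDLE] * 6

    def test_matches_exhaustive_enumeration(self, rng):
        for trial in range(200):
            S = int(rng.integers(2, 4))
            n = int(rng.integers(2, 9))
            states = ([IDLE, ACTIVE, "own"])[:S]
            T = rng.random((S, S)) + 0.05
            T /= T.sum(1, keepdims=True)
            pi = rng.random(S) + 0.05
            pi /= pi.sum()
            logB = rng.standard_normal((n, S)) * 2
            model = _model_from_logB(
                logB, T, pi, states
            )
            got = list(hmm_decode(np.zeros((n, 1)), model))
            want = _brute_force_path(np.log(pi), np.log(T), logB, states)
            assert got == want, f"trial {trial}"

    def test_tie_breaks_toward_idle(self):
        states = [IDLE, ACTIVE]
        logB = np.zeros((5, 2))
        T = np.full((2, 2), 0.5)
        pi = np.array([0.5, 0.5])
        model = _model_from_logB(logB, T, pi, states)
        assert list(hmm_decode(np.zeros((5, 1)), model)) == [IDLE] * 5

    def test_filter_mode_runs(self, rng):
        states = [IDLE, ACTIVE]
        logB = rng.standard_normal((10, 2))
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        model = _model_from_logB(logB, T, np.array([0.5, 0.5]), states)
        out = hmm_decode(np.zeros((10, 1)), model, mode="filter")
        assert set(out) <= set(states)

    def test_nonfinite_features_rejected(self):
        states = [IDLE, ACTIVE]
        model = _model_from_logB(np.zeros((2, 2)), np.eye(2),
                                 np.array([1.0, 0.0]), states)
        with pytest.raises(ValueError):
            hmm_decode(np.array([[np.nan]]), model)


class TestBaselines:
    @pytest.fixture
    def separable(self, rng):
        X = np.vstack([rng.standard_normal((50, 3)),
                       rng.standard_normal((50, 3)) + 10.0])
        y = np.array([IDLE] * 50 + [ACTIVE] * 50, object)
        return X, y

    @pytest.mark.parametrize("kind", ["lda", "svm", "rf"])
    def test_separable_perfect_train_accuracy(self, kind, separable):
        X, y = separable
        clf = fit_baseline(kind, X, y, seed=0)
        assert (clf.predict(X) == y.astype(str)).all()

    def test_rf_seed_reproducible(self, separable):
        X, y = separable
        a = fit_baseline("rf", X, y, seed=3).predict(X)
        b = fit_baseline("rf", X, y, seed=3).predict(X)
        assert (a == b).all()

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            fit_baseline("lda", X, np.full(10, IDLE, object), seed=0)


def _toy_matrix(rng, n=600, informative=True):
    labels = np.full(n, IDLE, dtype=object)
    for s in range(50, n - 20, 60):
        labels[s : s + 15] = ACTIVE
    sig = (labels == ACTIVE).astype(float)
    X = pd.DataFrame(
        {
            "f0": (sig * 4.0 if informative else 0.0) + rng.standard_normal(n),
            "f1": (sig * 3.0 if informative else 0.0) + rng.standard_normal(n),
            "f2": rng.standard_normal(n),
        }
    )
    start = np.arange(n) * 0.05
    return WindowFeatureMatrix(X, labels, start, start + 0.4)


class TestRunCv:
    def test_fold_boundaries(self):
        plan = FoldPlan(10)
        assert plan.bounds == [0, 3, 6, 10]

    def test_predictions_cover_stream(self, rng):
        m = _toy_matrix(rng)
        cv = run_cv(m, "hmm", n_perm=50, seed=0)
        assert len(cv.predictions) == m.n_windows
        assert all(p in (IDLE, ACTIVE) for p in cv.predictions)

    def test_informative_stream_high_window_accuracy(self, rng):
        m = _toy_matrix(rng)
        cv = run_cv(m, "hmm", n_perm=50, seed=0)
        acc = np.mean(cv.predictions == m.labels)
        assert acc > 0.9

    def test_shuffled_label_control_near_chance(self, rng):
        m = _toy_matrix(rng)
        sh = rng.permutation(m.labels)
        cv = run_cv(m, "lda", n_perm=50, seed=0, train_labels=sh)
        active_acc = np.mean(
            cv.predictions[m.labels == ACTIVE] == ACTIVE
        )
        assert active_acc < 0.6

    def test_fold_lacking_state_errors(self, rng):
        m = _toy_matrix(rng)
        labels = m.labels.copy()
        labels[:400] = IDLE  # folds 0 and 1 lose the active state
        m2 = WindowFeatureMatrix(m.X, labels, m.start_s, m.end_s)
        with pytest.raises(ValueError, match="lack"):
            run_cv(m2, "hmm", n_perm=50, seed=0)

    def test_no_leakage_from_test_rows(self, rng):
        """Feature screening and PCA depend only on training-fold rows."""
        m = _toy_matrix(rng)
        cv1 = run_cv(m, "lda", n_perm=50, seed=0)
        X2 = m.X.copy()
        b = FoldPlan(m.n_windows).bounds
        # corrupt fold 0's rows: rotation 0 (test=fold 0) must be unaffected
        X2.iloc[: b[1]] = rng.standard_normal((b[1], X2.shape[1])) * 100
        m2 = WindowFeatureMatrix(X2, m.labels, m.start_s, m.end_s)
        cv2 = run_cv(m2, "lda", n_perm=50, seed=0)
        assert cv1.selections[0].kept == cv2.selections[0].kept
        assert np.allclose(
            cv1.selections[0].pca.components_, cv2.selections[0].pca.components_
        )

    def test_same_streams_for_all_classifiers(self, rng):
        m = _toy_matrix(rng)
        preds = {}
        for kind in ("hmm", "lda"):
            cv = run_cv(m, kind, n_perm=50, seed=0)
            preds[kind] = cv.predictions
        assert len(preds["hmm"]) == len(preds["lda"])
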