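"""State decoding of windowed feature streams.

The primary classifier is a GMM-HMM: per-state emission densities are
Gaussian mixtures fitted to training windows (component count chosen by BIC
up to ``k_max``), and the transition matrix is the empirical pair-count
matrix of the training label sequence.  Decoding is max-product (joint most
probable path) in log space by default; a forward-filtering argmax is
available via ``mode='filter'``.  Ties are resolved toward idle, then toward
the lower state index, by ordering the state alphabet idle-first.

LDA, SVM and RF baselines classify each window independently.  Evaluation
uses consecutive three-fold cross-validation: the window stream is split
into three equal consecutive segments; each rotation fits feature selection,
PCA and the classifier on two segments and predicts the third, so training
and test windows never overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.mixture import GaussianMixture
from sklearn.svm import SVC

from .containers import ACTIVE, IDLE
from .features import (
    FeatureSelection,
    WindowFeatureMatrix,
    pca_reduce,
    select_feature_dims,
)

__all__ = [
    "HmmModel",
    "FoldPlan",
    "fit_transition_matrix",
    "fit_gmm_emissions",
    "hmm_decode",
    "fit_baseline",
    "run_cv",
]

CLASSIFIERS = ("hmm", "lda", "svm", "rf")


def state_order(states: set[str] | list[str]) -> list[str]:
    """Deterministic state alphabet with idle first (the tie-preferred
    state), remaining states sorted."""
    rest = sorted(s for s in set(states) if s != IDLE)
    return ([IDLE] if IDLE in set(states) else []) + rest


@dataclass
class HmmModel:
    """State alphabet, row-stochastic transition matrix, initial distribution
    and per-state Gaussian-mixture emission densities (in PCA space)."""

    states: list[str]
    T: np.ndarray
    pi: np.ndarray
    emissions: dict[str, GaussianMixture]
    components: dict[str, int] = field(default_factory=dict)

    def log_emission(self, X: np.ndarray) -> np.ndarray:
        """Log density of every window under every state: (n, n_states)."""
        return np.column_stack(
            [self.emissions[s].score_samples(X) for s in self.states]
        )


def fit_transition_matrix(
    label_segments: list[np.ndarray] | np.ndarray,
    states: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Empirical transition matrix and initial distribution from labelled
    training sequences.

    ``label_segments`` may be one sequence or a list of contiguous segments
    (transitions are never counted across segment boundaries).  Every state
    of the alphabet must be observed; a zero-count row falls back to uniform
    with a warning.  The initial distribution is the empirical state
    frequency.
    """
    if isinstance(label_segments, np.ndarray) and label_segments.ndim == 1:
        label_segments = [label_segments]
    all_labels = np.concatenate([np.asarray(s, object) for s in label_segments])
    if len(all_labels) < 2:
        raise ValueError("need at least 2 labels")
    observed = set(all_labels.tolist())
    states = states or state_order(observed)
    missing = set(states) - observed
    if missing:
        raise ValueError(f"states never observed in training labels: {missing}")
    idx = {s: i for i, s in enumerate(states)}
    S = len(states)
    counts = np.zeros((S, S))
    for seg in label_segments:
        seg = np.asarray(seg, object)
        for a, b in zip(seg[:-1], seg[1:]):
            counts[idx[a], idx[b]] += 1
    T = np.empty_like(counts)
    for i in range(S):
        row = counts[i].sum()
        if row == 0:
            warnings.warn(
                f"state {states[i]!r} has no outgoing transitions; uniform row",
                stacklevel=2,
            )
            T[i] = 1.0 / S
        else:
            T[i] = counts[i] / row
    pi = np.array([np.mean(all_labels == s) for s in states])
    return T, pi, states


def fit_gmm_emissions(
    X: np.ndarray,
    labels: np.ndarray,
    states: list[str],
    k_max: int = 5,
    seed: int = 0,
    reg_frac: float = 1e-6,
) -> tuple[dict[str, GaussianMixture], dict[str, int]]:
    """Per-state Gaussian mixtures with BIC-selected component count.

    Full covariances with a floor of ``reg_frac`` times the mean feature
    variance; too few rows for a mixture fall back to a single Gaussian with
    a warning.
    """
    d = X.shape[1]
    reg = max(reg_frac * float(np.mean(np.var(X, axis=0))), 1e-10)
    emissions: dict[str, GaussianMixture] = {}
    comps: dict[str, int] = {}
    for s in states:
        Xs = X[labels == s]
        if len(Xs) == 0:
            raise ValueError(f"no training rows for state {s!r}")
        k_feasible = min(k_max, max(len(Xs) // max(d, 1), 1))
        if k_feasible < k_max:
            warnings.warn(
                f"state {s!r}: only {len(Xs)} rows for {d}-d features; "
                f"mixture size capped at {k_feasible}",
                stacklevel=2,
            )
        best, best_bic, best_k = None, np.inf, 1
        for k in range(1, k_feasible + 1):
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                reg_covar=reg,
                random_state=seed,
                n_init=1,
            )
            try:
                gm.fit(Xs)
            except ValueError:
                continue
            bic = gm.bic(Xs)
            if bic < best_bic:
                best, best_bic, best_k = gm, bic, k
        if best is None:  # fully degenerate rows: single floored Gaussian
            best = GaussianMixture(
                n_components=1, reg_covar=max(reg, 1e-6), random_state=seed
            ).fit(Xs)
            best_k = 1
        emissions[s] = best
        comps[s] = best_k
    return emissions, comps


def hmm_decode(
    X: np.ndarray, model: HmmModel, mode: str = "viterbi"
) -> np.ndarray:
    """Decode the most probable state sequence of a feature stream.

    ``mode='viterbi'`` returns the max-product joint path;
    ``mode='filter'`` returns the per-window argmax of the forward-filtered
    state posterior.  With states ordered idle-first, exact ties resolve to
    idle, then to the lower state index.
    """
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    with np.errstate(divide="ignore"):
        logT = np.log(model.T)
        logpi = np.log(model.pi)
    logB = model.log_emission(X)
    n, S = logB.shape
    if mode == "viterbi":
        delta = logpi + logB[0]
        back = np.zeros((n, S), dtype=np.int64)
        for t in range(1, n):
            cand = delta[:, None] + logT  # prev x cur
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(S)] + logB[t]
        path = np.empty(n, dtype=np.int64)
        path[-1] = int(np.argmax(delta))
        for t in range(n - 2, -1, -1):
            path[t] = back[t + 1, path[t + 1]]
    elif mode == "filter":
        path = np.empty(n, dtype=np.int64)
        log_alpha = logpi + logB[0]
        path[0] = int(np.argmax(log_alpha))
        for t in range(1, n):
            log_alpha = _logsumexp_cols(log_alpha[:, None] + logT) + logB[t]
            log_alpha -= log_alpha.max()
            path[t] = int(np.argmax(log_alpha))
    else:
        raise ValueError("mode must be 'viterbi' or 'filter'")
    return np.array([model.states[i] for i in path], dtype=object)


def _logsumexp_cols(M: np.ndarray) -> np.ndarray:
    m = M.max(axis=0)
    with np.errstate(invalid="ignore"):
        out = m + np.log(np.sum(np.exp(M - m), axis=0))
    return np.where(np.isfinite(m), out, m)


def fit_hmm(
    X: np.ndarray,
    label_segments: list[np.ndarray],
    k_max: int = 5,
    seed: int = 0,
) -> HmmModel:
    """Fit transition matrix and GMM emissions from labelled training data."""
    T, pi, states = fit_transition_matrix(label_segments)
    labels = np.concatenate([np.asarray(s, object) for s in label_segments])
    emissions, comps = fit_gmm_emissions(X, labels, states, k_max=k_max, seed=seed)
    return HmmModel(states, T, pi, emissions, comps)


def fit_baseline(kind: str, X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Window-independent baseline classifiers (LDA / SVM / RF) with
    class-frequency weighting for the active/idle imbalance."""
    if len(np.unique(y.astype(str))) < 2:
        raise ValueError("training labels contain a single class")
    if kind == "lda":
        clf = LinearDiscriminantAnalysis()
    elif kind == "svm":
        clf = SVC(class_weight="balanced", random_state=seed)
    elif kind == "rf":
        clf = RandomForestClassifier(
            n_estimators=100, class_weight="balanced", random_state=seed
        )
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    clf.fit(X, y.astype(str))
    return clf


@dataclass(frozen=True)
class FoldPlan:
    """Three consecutive equal segments of the window stream."""

    n_windows: int

    @property
    def bounds(self) -> list[int]:
        n = self.n_windows
        return [0, n // 3, (2 * n) // 3, n]

    def rotation(self, r: int) -> tuple[np.ndarray, np.ndarray]:
        """(train indices, test indices) for rotation ``r`` in {0,1,2}."""
        b = self.bounds
        test = np.arange(b[r], b[r + 1])
        train = np.concatenate([np.arange(0, b[r]), np.arange(b[r + 1], self.n_windows)])
        return train, test

    def train_segments(self, r: int) -> list[np.ndarray]:
        b = self.bounds
        segs = []
        if r > 0:
            segs.append(np.arange(0, b[r]))
        if r < 2:
            segs.append(np.arange(b[r + 1], self.n_windows))
        return segs


@dataclass
class CvResult:
    """Concatenated test-segment predictions covering the stream once, plus
    the per-rotation fitted artifacts."""

    predictions: np.ndarray
    selections: list[FeatureSelection]
    models: list[object]


def run_cv(
    matrix: WindowFeatureMatrix,
    classifier: str = "hmm",
    keep: int = 10,
    n_perm: int = 200,
    pca_threshold: float = 0.95,
    k_max: int = 5,
    seed: int = 0,
    decode_mode: str = "viterbi",
    train_labels: np.ndarray | None = None,
    builder=None,
    select_dims: bool = True,
    dim_selector=None,
) -> CvResult:
    """Consecutive three-fold cross-validation over the window stream.

    For each rotation, feature-dimension selection and PCA are fitted on the
    two training segments only, then the classifier is fitted and the held-out
    segment decoded; the concatenated predictions cover the stream exactly
    once.  ``train_labels`` overrides the labels used for fitting (label
    permutations for chance levels) while leaving the stream untouched.
    ``builder``, if given, is called with the training-window index set and
    must return the full-stream ``WindowFeatureMatrix`` for that rotation
    (used to renormalize traces from training-fold baselines only).
    """
    if classifier not in CLASSIFIERS:
        raise ValueError(f"classifier must be one of {CLASSIFIERS}")
    n = matrix.n_windows
    plan = FoldPlan(n)
    labels_all = matrix.labels if train_labels is None else np.asarray(train_labels, object)
    states = state_order(set(labels_all.tolist()))

    preds = np.empty(n, dtype=object)
    sels: list[FeatureSelection] = []
    models: list[object] = []
    rng = np.random.default_rng(seed)
    for r in range(3):
        train_idx, test_idx = plan.rotation(r)
        m = builder(train_idx) if builder is not None else matrix
        y_tr = labels_all[train_idx]
        present = set(y_tr.tolist())
        if present != set(states):
            raise ValueError(
                f"rotation {r}: training folds lack state(s) "
                f"{set(states) - present}"
            )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if dim_selector is not None:
            fsel = dim_selector(m.X.iloc[train_idx], y_tr, sub_seed)
        elif select_dims:
            fsel = select_feature_dims(
                m.X.iloc[train_idx], y_tr, keep=keep, n_perm=n_perm, seed=sub_seed
            )
        else:
            fsel = FeatureSelection(
                p=pd.Series(1.0, index=m.X.columns), kept=list(m.X.columns)
            )
        fsel = pca_reduce(fsel, m.X.iloc[train_idx], threshold=pca_threshold)
        Z_tr = fsel.transform(m.X.iloc[train_idx])
        Z_te = fsel.transform(m.X.iloc[test_idx])
        if classifier == "hmm":
            segs = [labels_all[s] for s in plan.train_segments(r)]
            model = fit_hmm(Z_tr, segs, k_max=k_max, seed=sub_seed)
            preds[test_idx] = hmm_decode(Z_te, model, mode=decode_mode)
        else:
            model = fit_baseline(classifier, Z_tr, y_tr, seed=sub_seed)
            preds[test_idx] = model.predict(Z_te).astype(object)
        sels.append(fsel)
        models.append(model)
    return CvResult(preds, sels, models)
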