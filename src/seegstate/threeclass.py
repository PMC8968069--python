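"""Three-class detection: idle vs. own-name vs. other-name states.

Feature screening runs the label-permutation test once per state pair
(idle/own, idle/other, own/other), keeps the ten smallest-p dimensions per
pair and classifies on the union (at most 30 columns) after PCA.  A single
3-state GMM-HMM decodes the stream.  Accuracy is summarized as a
row-normalized actual x detected table, at the period level (a period's
detected state is the modal window label inside it) and at the window level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import IDLE, OTHER, OWN, _runs
from .detection import CvResult, run_cv, state_order
from .features import (
    FeatureSelection,
    WindowFeatureMatrix,
    permutation_p_columns,
)

__all__ = [
    "select_feature_dims_pairwise",
    "detect_three_state",
    "period_state_table",
    "window_state_table",
    "collapse_to_binary",
]

PAIRS = ((IDLE, OWN), (IDLE, OTHER), (OWN, OTHER))


def select_feature_dims_pairwise(
    X_train: pd.DataFrame,
    labels3: np.ndarray,
    keep_per_pair: int = 10,
    n_perm: int = 200,
    seed: int = 0,
    states: tuple[str, ...] = (IDLE, OWN, OTHER),
) -> FeatureSelection:
    """Ten smallest-p columns per state pair; final set is the union.

    Raises when a state is absent from the training labels.  The stored p of
    a column is its smallest p over the three pairwise contrasts.
    """
    labels3 = np.asarray(labels3, object)
    present = set(labels3.tolist())
    missing = set(states) - present
    if missing:
        raise ValueError(f"missing state(s) in training labels: {missing}")
    pairs = [(a, b) for a, b in PAIRS if a in states and b in states]
    rng = np.random.default_rng(seed)
    kept: set[str] = set()
    p_min = pd.Series(1.0, index=X_train.columns)
    for a, b in pairs:
        mask = (labels3 == a) | (labels3 == b)
        sign = np.where(labels3[mask] == a, -1.0, 1.0)
        p = permutation_p_columns(
            X_train.loc[mask], sign, n_perm=n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        p_min = np.minimum(p_min, p)
        if X_train.shape[1] <= keep_per_pair:
            kept.update(X_train.columns)
        else:
            order = sorted(X_train.columns, key=lambda c: (p[c], c))
            kept.update(order[:keep_per_pair])
    kept_ordered = [c for c in X_train.columns if c in kept]
    return FeatureSelection(p=p_min, kept=kept_ordered)


def detect_three_state(
    matrix: WindowFeatureMatrix,
    keep_per_pair: int = 10,
    n_perm: int = 200,
    k_max: int = 5,
    seed: int = 0,
    decode_mode: str = "viterbi",
    train_labels: np.ndarray | None = None,
    builder=None,
) -> tuple[CvResult, pd.DataFrame, pd.DataFrame]:
    """Three-fold CV with a 3-state GMM-HMM.

    Returns the CV result plus the period-level and window-level
    row-normalized actual x detected accuracy tables (percent).
    """
    states = tuple(state_order(set(np.asarray(matrix.labels).tolist())))

    def selector(X_tr, y_tr, sub_seed):
        return select_feature_dims_pairwise(
            X_tr, y_tr, keep_per_pair=keep_per_pair, n_perm=n_perm,
            seed=sub_seed, states=states,
        )

    cv = run_cv(
        matrix,
        classifier="hmm",
        k_max=k_max,
        seed=seed,
        decode_mode=decode_mode,
        train_labels=train_labels,
        builder=builder,
        dim_selector=selector,
    )
    per = period_state_table(matrix.labels, cv.predictions, list(states))
    win = window_state_table(matrix.labels, cv.predictions, list(states))
    return cv, per, win


def period_state_table(
    actual: np.ndarray, predicted: np.ndarray, states: list[str]
) -> pd.DataFrame:
    """Row-normalized (percent) actual x detected table at the period level.

    Actual periods are maximal runs of the actual window labels (idle runs
    included); each period's detected state is the modal predicted window
    label inside it (ties toward idle, then alphabetical).
    """
    actual = np.asarray(actual, object)
    predicted = np.asarray(predicted, object)
    counts = pd.DataFrame(0.0, index=states, columns=states)
    labs, starts, ends = _runs(actual)
    for lab, s, e in zip(labs, starts, ends):
        seg = predicted[s:e].astype(str)
        vals, cnt = np.unique(seg, return_counts=True)
        best = cnt.max()
        winners = set(vals[cnt == best])
        modal = IDLE if IDLE in winners else sorted(winners)[0]
        counts.loc[lab, modal] += 1
    return _row_normalize(counts)


def window_state_table(
    actual: np.ndarray, predicted: np.ndarray, states: list[str]
) -> pd.DataFrame:
    """Row-normalized (percent) actual x detected table over windows."""
    counts = pd.DataFrame(0.0, index=states, columns=states)
    for a, p in zip(np.asarray(actual, object), np.asarray(predicted, object)):
        counts.loc[a, p] += 1
    return _row_normalize(counts)


def _row_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    sums = counts.sum(axis=1)
    out = counts.div(sums.replace(0, np.nan), axis=0) * 100.0
    return out


def collapse_to_binary(labels: np.ndarray, active_label: str = "active") -> np.ndarray:
    """Map own/other (any non-idle state) to a single active label."""
    labels = np.asarray(labels, object)
    return np.where(labels == IDLE, IDLE, active_label).astype(object)
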