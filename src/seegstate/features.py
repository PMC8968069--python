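"""Sliding-window time-domain features and per-dimension selection.

From each selected channel's continuous trace, four operators are computed
in overlapping windows: average amplitude ``A``, root-mean-square ``RMS``,
ordinary-least-squares slope ``k`` (per second) and line-length ``L`` (the
running sum of absolute first differences, an amplitude/frequency
demodulator).  A channel therefore contributes four features per trace kind,
up to 16 feature types in total across high-gamma, beta, alpha and ERP.

Feature dimensions are screened with the same label-permutation Spearman test
used for channel selection (ten smallest p kept), then reduced with PCA
retaining >95% explained variance.  Both are fitted on training-fold rows
only.

Continuous traces are z-scored with per-channel baseline statistics pooled
from pre-stimulus segments (of the training folds, when a fold plan is in
play), since window classification runs on the continuous stream rather than
on trial epochs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.decomposition import PCA

from .channel_selection import ChannelSelection, _ranks_z, _tail_p
from .containers import ACTIVE, IDLE, EventTable, GroundTruth, TraceSet

__all__ = [
    "WindowSpec",
    "WindowFeatureMatrix",
    "FeatureSelection",
    "make_windows",
    "label_window",
    "label_windows",
    "avg_amplitude",
    "rms",
    "slope",
    "line_length",
    "extract_features",
    "restrict_feature_set",
    "select_feature_dims",
    "pca_reduce",
    "pooled_baseline_stats",
]

OPERATORS = ("A", "RMS", "k", "L")
TRACE_ORDER = ("high_gamma", "beta", "alpha", "erp")

# Sign convention of the permutation test labels: -1 active, +1 idle.
STATE_SIGN = {ACTIVE: -1.0, IDLE: 1.0}


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window layout: window length and inter-window step (both ms).

    Windows start at 0, step, 2*step, ...; the last window lies fully inside
    the session.  A step larger than the window leaves gaps and is refused
    unless ``allow_gaps`` is set.
    """

    window_len_ms: float = 400.0
    step_ms: float = 50.0
    allow_gaps: bool = False

    def __post_init__(self) -> None:
        if self.window_len_ms <= 0 or self.step_ms <= 0:
            raise ValueError("window and step must be positive")
        if self.step_ms > self.window_len_ms and not self.allow_gaps:
            raise ValueError(
                "step larger than window leaves gaps; set allow_gaps to permit"
            )

    def length_samples(self, fs: float) -> int:
        return int(round(self.window_len_ms * fs / 1000.0))

    def step_samples(self, fs: float) -> int:
        return int(round(self.step_ms * fs / 1000.0))


def make_windows(n_samples: int, fs: float, spec: WindowSpec) -> np.ndarray:
    """Start samples of all windows fitting fully inside the session."""
    length = spec.length_samples(fs)
    step = spec.step_samples(fs)
    if n_samples < length:
        raise ValueError("session shorter than one window")
    n_win = (n_samples - length) // step + 1
    return np.arange(n_win, dtype=np.int64) * step


def label_window(
    start: int, length: int, timeline: np.ndarray, rule: str = "midpoint"
) -> str:
    """State label of one window: the state at the window midpoint (default)
    or the majority state across the window (ties resolved toward idle)."""
    if rule == "midpoint":
        return timeline[start + length // 2]
    if rule == "majority":
        seg = timeline[start : start + length]
        vals, counts = np.unique(seg.astype(str), return_counts=True)
        best = counts.max()
        winners = set(vals[counts == best])
        if IDLE in winners:
            return IDLE
        return sorted(winners)[0]
    raise ValueError("rule must be 'midpoint' or 'majority'")


def label_windows(
    starts: np.ndarray,
    length: int,
    truth: GroundTruth,
    rule: str = "midpoint",
    binary: bool = True,
) -> np.ndarray:
    """Labels for every window; with ``binary`` any non-idle state collapses
    to 'active'."""
    tl = truth.timeline
    if rule == "midpoint":
        labels = tl[starts + length // 2].copy()
    else:
        labels = np.array(
            [label_window(s, length, tl, rule="majority") for s in starts],
            dtype=object,
        )
    if binary:
        labels = np.where(labels == IDLE, IDLE, ACTIVE).astype(object)
    return labels


# ---------------------------------------------------------------------------
# The four time-domain operators.  Each accepts a 1-D window or a 2-D
# (windows x samples) stack and reduces over the last axis.

def _check(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    if x.shape[-1] < 2:
        raise ValueError("a window needs at least 2 samples")
    return x


def avg_amplitude(x: np.ndarray) -> np.ndarray | float:
    """A: mean of the window."""
    return _check(x).mean(axis=-1)


def rms(x: np.ndarray) -> np.ndarray | float:
    """RMS: sqrt of the mean square."""
    x = _check(x)
    return np.sqrt(np.mean(x * x, axis=-1))


def slope(x: np.ndarray, fs: float) -> np.ndarray | float:
    """k: ordinary-least-squares slope of the window against time in seconds."""
    x = _check(x)
    n = x.shape[-1]
    t = np.arange(n) / fs
    tc = t - t.mean()
    w = tc / np.sum(tc * tc)
    return x @ w


def line_length(x: np.ndarray) -> np.ndarray | float:
    """L: running sum of absolute differences between consecutive samples."""
    x = _check(x)
    return np.sum(np.abs(np.diff(x, axis=-1)), axis=-1)


def _window_features(row: np.ndarray, starts: np.ndarray, length: int, fs: float):
    """All four operators over every window of one trace row."""
    W = sliding_window_view(row, length)[starts]
    return {
        "A": avg_amplitude(W),
        "RMS": rms(W),
        "k": slope(W, fs),
        "L": line_length(W),
    }


@dataclass
class WindowFeatureMatrix:
    """Windows x named features, with window times, state labels and an
    optional fold assignment.

    Column names are ``<trace>:<channel>:<operator>``.
    """

    X: pd.DataFrame
    labels: np.ndarray
    start_s: np.ndarray
    end_s: np.ndarray
    fold: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate feature column names")

    @property
    def n_windows(self) -> int:
        return len(self.X)

    @property
    def step_s(self) -> float:
        return float(self.start_s[1] - self.start_s[0]) if len(self.start_s) > 1 else 0.0

    def to_tsv(self, path: str) -> None:
        df = self.X.copy()
        df.insert(0, "start_s", self.start_s)
        df.insert(1, "end_s", self.end_s)
        df.insert(2, "label", self.labels)
        if self.fold is not None:
            df.insert(3, "fold", self.fold)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "WindowFeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        meta = ["start_s", "end_s", "label"] + (["fold"] if "fold" in df else [])
        fold = df["fold"].to_numpy() if "fold" in df else None
        return cls(
            df.drop(columns=meta),
            df["label"].to_numpy(dtype=object),
            df["start_s"].to_numpy(),
            df["end_s"].to_numpy(),
            fold,
        )


def pooled_baseline_stats(
    trace: TraceSet,
    events: EventTable,
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
    event_mask: np.ndarray | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-channel mean/SD of the trace over the pooled pre-stimulus baseline
    segments (optionally restricted to a subset of events, e.g. those inside
    the training folds)."""
    fs = trace.fs
    s0 = int(round(baseline_ms[0] * fs / 1000.0))
    s1 = int(round(baseline_ms[1] * fs / 1000.0))
    onsets = events.onset_sample
    if event_mask is not None:
        onsets = onsets[event_mask]
    segs = []
    for onset in onsets:
        a, b = onset + s0, onset + s1
        if a >= 0 and b <= trace.data.shape[1]:
            segs.append(trace.data[:, a:b])
    if not segs:
        raise ValueError("no baseline segment inside the recording")
    pooled = np.concatenate(segs, axis=1)
    mu = pooled.mean(axis=1)
    sd = pooled.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero baseline SD on some channel")
    return {
        c.id: (float(m), float(s)) for c, m, s in zip(trace.channels, mu, sd)
    }


def extract_features(
    traces: dict[str, TraceSet],
    selections: dict[str, "ChannelSelection | list[str]"],
    starts: np.ndarray,
    spec: WindowSpec,
    baseline_stats: dict[str, dict[str, tuple[float, float]]] | None = None,
    truth: GroundTruth | None = None,
    label_rule: str = "midpoint",
    binary_labels: bool = True,
) -> WindowFeatureMatrix:
    """Window x feature matrix over the continuous session.

    Columns are ordered deterministically by (trace kind, channel id,
    operator); each selected channel of each trace kind contributes its four
    operators.  ``baseline_stats`` (kind -> channel -> (mean, SD)) z-scores
    each trace before windowing.
    """
    cols: dict[str, np.ndarray] = {}
    fs = None
    for kind in TRACE_ORDER:
        if kind not in traces or kind not in selections:
            continue
        sel = selections[kind]
        chans = sel.selected if isinstance(sel, ChannelSelection) else list(sel)
        if not chans:
            continue
        ts = traces[kind]
        fs = ts.fs
        length = spec.length_samples(fs)
        for ch in sorted(chans):
            row = ts.data[ts.channel_ids.index(ch)]
            if baseline_stats is not None:
                mu, sd = baseline_stats[kind][ch]
                row = (row - mu) / sd
            feats = _window_features(row, starts, length, fs)
            for op in OPERATORS:
                cols[f"{kind}:{ch}:{op}"] = feats[op]
    if not cols:
        raise ValueError("no selected channel in any trace kind")
    length = spec.length_samples(fs)
    start_s = starts / fs
    end_s = (starts + length) / fs
    labels = (
        label_windows(starts, length, truth, rule=label_rule, binary=binary_labels)
        if truth is not None
        else np.full(len(starts), "", dtype=object)
    )
    return WindowFeatureMatrix(pd.DataFrame(cols), labels, start_s, end_s)


FOUR_TYPE = [("high_gamma", "A"), ("high_gamma", "RMS"), ("high_gamma", "L"),
             ("erp", "L")]


def restrict_feature_set(matrix: WindowFeatureMatrix, feature_set: str) -> WindowFeatureMatrix:
    """Column subsets named after the feature combinations studied:
    ``all16`` (everything), ``four_type`` (high-gamma A/RMS/L + ERP L), or
    ``single:<trace>:<op>``."""
    if feature_set == "all16":
        return matrix
    if feature_set == "four_type":
        wanted = {(k, o) for k, o in FOUR_TYPE}
    elif feature_set.startswith("single:"):
        _, kind, op = feature_set.split(":")
        wanted = {(kind, op)}
    else:
        raise ValueError(f"unknown feature set {feature_set!r}")
    keep = [
        c for c in matrix.X.columns
        if (c.split(":")[0], c.split(":")[2]) in wanted
    ]
    if not keep:
        raise ValueError(f"feature set {feature_set!r} matches no columns")
    return WindowFeatureMatrix(
        matrix.X[keep], matrix.labels, matrix.start_s, matrix.end_s, matrix.fold
    )


@dataclass
class FeatureSelection:
    """Per-column permutation p-values, the kept columns, and the PCA basis
    fitted on the kept training columns."""

    p: pd.Series
    kept: list[str]
    pca: PCA | None = None
    n_components: int = 0
    contrast: tuple[str, str] | None = None

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        Z = X[self.kept].to_numpy()
        return self.pca.transform(Z)[:, : self.n_components] if self.pca else Z


def permutation_p_columns(
    X: pd.DataFrame,
    sign_labels: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
    method: str = "normal",
) -> pd.Series:
    """Label-permutation Spearman p for every column (shared label shuffles
    across columns; degenerate columns get p = 1)."""
    rng = np.random.default_rng(seed)
    rl = _ranks_z(sign_labels)
    if rl is None:
        raise ValueError("labels are constant")
    RV = np.empty((X.shape[1], X.shape[0]))
    const = np.zeros(X.shape[1], bool)
    for j, c in enumerate(X.columns):
        r = _ranks_z(X[c].to_numpy())
        if r is None:
            const[j] = True
            RV[j] = 0.0
        else:
            RV[j] = r
    perm = rng.permuted(np.tile(rl, (n_perm, 1)), axis=1)
    R_surr = perm @ RV.T  # n_perm x n_cols
    r_obs = RV @ rl
    ps = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        if const[j]:
            continue
        mu, sd = float(R_surr[:, j].mean()), float(R_surr[:, j].std())
        ps[j] = _tail_p(float(r_obs[j]), R_surr[:, j], mu, sd, method, "two-sided")
    return pd.Series(ps, index=X.columns)


def select_feature_dims(
    X_train: pd.DataFrame,
    labels_train: np.ndarray,
    keep: int = 10,
    n_perm: int = 200,
    seed: int = 0,
    method: str = "normal",
) -> FeatureSelection:
    """Keep the ``keep`` columns with the smallest permutation p (all columns
    when there are no more than ``keep``).  Must be fed training rows only."""
    sign = np.array([STATE_SIGN.get(l, -1.0) for l in labels_train])
    p = permutation_p_columns(X_train, sign, n_perm=n_perm, seed=seed, method=method)
    if X_train.shape[1] <= keep:
        kept = list(X_train.columns)
    else:
        order = sorted(X_train.columns, key=lambda c: (p[c], c))
        kept = order[:keep]
        kept = [c for c in X_train.columns if c in set(kept)]  # stable order
    return FeatureSelection(p=p, kept=kept)


def pca_reduce(
    fs: FeatureSelection, X_train: pd.DataFrame, threshold: float = 0.95
) -> FeatureSelection:
    """Fit PCA on the kept training columns and retain the minimal number of
    components whose cumulative explained variance exceeds ``threshold``."""
    Z = X_train[fs.kept].to_numpy()
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 training rows for PCA")
    pca = PCA()
    pca.fit(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, threshold) + 1)
    n_comp = min(n_comp, len(cum))
    fs.pca = pca
    fs.n_components = n_comp
    return fs
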