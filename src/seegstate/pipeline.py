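"""End-to-end orchestration: recording -> traces -> channel selection ->
window features -> cross-validated detection -> period-level report.

This is the module the CLI, the examples and the acceptance script drive.
The stages mirror the analysis flow: four per-channel traces, per-trace
responsive-channel selection, sliding-window features on the continuous
z-scored traces, consecutive three-fold CV with per-fold feature screening
and PCA, and period-level scoring with optional permutation chance levels.

Continuous traces are z-scored per channel against pre-stimulus baseline
statistics pooled over the training folds of each CV rotation (the
``_FoldBuilder``); the per-rotation matrices are cached so chance-level
permutations reuse them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channel_selection import ChannelSelection, select_channels
from .containers import EventTable, GroundTruth, Recording, TraceSet
from .detection import CvResult, run_cv
from .evaluation import (
    DetectionReport,
    MatchLedger,
    PeriodSet,
    chance_level,
    match_periods,
    report,
    score,
    windows_to_periods,
)
from .features import (
    WindowFeatureMatrix,
    WindowSpec,
    extract_features,
    make_windows,
    pooled_baseline_stats,
    restrict_feature_set,
)
from .baseline_features import extract_baseline_features
from .preprocessing import (
    band_power_trace,
    comb_notch,
    epoch_and_normalize,
    erp_trace,
    gaussian_smooth,
    laplacian_rereference,
)
from .threeclass import collapse_to_binary, detect_three_state

__all__ = [
    "kinds_for_feature_set",
    "preprocess_session",
    "select_session_channels",
    "build_matrix",
    "run_two_class",
    "run_three_class",
    "TwoClassResult",
    "ThreeClassResult",
]

BAND_KINDS = ("high_gamma", "beta", "alpha")
COMPARATOR_SETS = ("ar", "stft", "wavelet")


def kinds_for_feature_set(feature_set: str) -> list[str]:
    """Trace kinds a feature set needs (drives which traces are computed)."""
    if feature_set == "all16":
        return ["high_gamma", "beta", "alpha", "erp"]
    if feature_set == "four_type":
        return ["high_gamma", "erp"]
    if feature_set.startswith("single:"):
        return [feature_set.split(":")[1]]
    if feature_set in COMPARATOR_SETS:
        # comparator extractors run per band; high-gamma is the band that
        # carries the evoked responses, and its channel selection is reused
        return ["high_gamma"]
    raise ValueError(f"unknown feature set {feature_set!r}")


def preprocess_session(
    rec: Recording, kinds: list[str], zero_phase: bool = True
) -> dict[str, TraceSet]:
    """Compute the requested traces, sharing one notch-filtered pass."""
    notched = comb_notch(rec, zero_phase=zero_phase)
    traces: dict[str, TraceSet] = {}
    for kind in kinds:
        if kind == "erp":
            traces[kind] = erp_trace(rec, zero_phase=zero_phase, notched=notched)
        else:
            traces[kind] = band_power_trace(
                rec, kind, zero_phase=zero_phase, notched=notched
            )
    return traces


def select_session_channels(
    traces: dict[str, TraceSet],
    events: EventTable,
    n_perm: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    max_keep: int = 10,
    smooth_ms: float = 80.0,
) -> dict[str, ChannelSelection]:
    """Per-trace responsive-channel selection from z-scored, smoothed trial
    epochs."""
    out: dict[str, ChannelSelection] = {}
    for i, (kind, ts) in enumerate(sorted(traces.items())):
        epochs = gaussian_smooth(
            epoch_and_normalize(ts, events, mode="pooled"), width_ms=smooth_ms
        )
        out[kind] = select_channels(
            epochs, alpha=alpha, max_keep=max_keep, n_perm=n_perm, seed=seed + i
        )
    return out


class _FoldBuilder:
    """Rebuilds the full-stream feature matrix for each CV rotation with
    baseline statistics pooled from the training folds only; results are
    cached per rotation so chance permutations do not recompute them."""

    def __init__(
        self,
        traces: dict[str, TraceSet],
        selections: dict[str, ChannelSelection],
        starts: np.ndarray,
        spec: WindowSpec,
        events: EventTable,
        truth: GroundTruth,
        feature_set: str,
        binary_labels: bool = True,
    ):
        self.traces = traces
        self.selections = selections
        self.starts = starts
        self.spec = spec
        self.events = events
        self.truth = truth
        self.feature_set = feature_set
        self.binary_labels = binary_labels
        self._cache: dict[tuple, WindowFeatureMatrix] = {}
        any_trace = next(iter(traces.values()))
        self.fs = any_trace.fs
        self.length = spec.length_samples(self.fs)

    def _event_mask(self, train_idx: np.ndarray) -> np.ndarray:
        # contiguous training blocks in sample coordinates
        breaks = np.flatnonzero(np.diff(train_idx) > 1)
        block_bounds = np.split(train_idx, breaks + 1)
        blocks = [
            (self.starts[b[0]], self.starts[b[-1]] + self.length)
            for b in block_bounds
            if len(b)
        ]
        s0 = int(round(-200.0 * self.fs / 1000.0))
        mask = np.zeros(len(self.events), bool)
        for i, onset in enumerate(self.events.onset_sample):
            a, b = onset + s0, onset
            mask[i] = any(a >= lo and b <= hi for lo, hi in blocks)
        if not mask.any():
            warnings.warn(
                "no baseline segment inside the training folds; using all events",
                stacklevel=2,
            )
            mask[:] = True
        return mask

    def __call__(self, train_idx: np.ndarray) -> WindowFeatureMatrix:
        key = (int(train_idx[0]), int(train_idx[-1]), len(train_idx))
        if key not in self._cache:
            mask = self._event_mask(train_idx)
            stats = {
                kind: pooled_baseline_stats(ts, self.events, event_mask=mask)
                for kind, ts in self.traces.items()
            }
            m = extract_features(
                self.traces,
                self.selections,
                self.starts,
                self.spec,
                baseline_stats=stats,
                truth=self.truth,
                binary_labels=self.binary_labels,
            )
            self._cache[key] = restrict_feature_set(m, self.feature_set)
        return self._cache[key]


def build_matrix(
    traces: dict[str, TraceSet],
    selections: dict[str, ChannelSelection],
    events: EventTable,
    truth: GroundTruth,
    spec: WindowSpec,
    feature_set: str = "four_type",
    binary_labels: bool = True,
) -> tuple[WindowFeatureMatrix, np.ndarray]:
    """Session-wide feature matrix with baselines pooled over all events
    (the fold-unaware variant; CV uses the fold-aware builder)."""
    any_trace = next(iter(traces.values()))
    starts = make_windows(any_trace.data.shape[1], any_trace.fs, spec)
    stats = {
        kind: pooled_baseline_stats(ts, events) for kind, ts in traces.items()
    }
    m = extract_features(
        traces, selections, starts, spec, baseline_stats=stats, truth=truth,
        binary_labels=binary_labels,
    )
    return restrict_feature_set(m, feature_set), starts


@dataclass
class TwoClassResult:
    report: DetectionReport
    cv: CvResult
    matrix: WindowFeatureMatrix
    selections: dict[str, ChannelSelection]
    actual: PeriodSet
    detected: PeriodSet


def _evaluate_predictions(
    predictions: np.ndarray,
    matrix: WindowFeatureMatrix,
    actual: PeriodSet,
    span: tuple[float, float],
    tol_s: float = 0.4,
) -> MatchLedger:
    binary = collapse_to_binary(predictions)
    detected = windows_to_periods(binary, matrix.start_s, matrix.end_s)
    return match_periods(actual, detected, tol_s=tol_s, span=span)


def run_two_class(
    rec: Recording,
    events: EventTable,
    truth: GroundTruth,
    spec: WindowSpec | None = None,
    feature_set: str = "four_type",
    classifier: str = "hmm",
    channel_n_perm: int = 200,
    feature_n_perm: int = 200,
    keep: int = 10,
    k_max: int = 5,
    seed: int = 0,
    decode_mode: str = "viterbi",
    chance_perms: int = 0,
    fold_norm: bool = True,
    tol_s: float = 0.4,
    traces: dict[str, TraceSet] | None = None,
    selections: dict[str, ChannelSelection] | None = None,
) -> TwoClassResult:
    """Full two-class (active vs idle) detection run on one session.

    Precomputed ``traces``/``selections`` may be passed to reuse them across
    classifiers.  ``chance_perms > 0`` adds permutation chance levels for the
    three indicators.
    """
    spec = spec or WindowSpec()
    kinds = kinds_for_feature_set(feature_set)
    if traces is None:
        traces = preprocess_session(rec, kinds)
    if selections is None:
        selections = select_session_channels(
            traces, events, n_perm=channel_n_perm, seed=seed
        )
    any_trace = next(iter(traces.values()))
    starts = make_windows(any_trace.data.shape[1], any_trace.fs, spec)
    if feature_set in COMPARATOR_SETS:
        # comparator features run on the re-referenced broadband signal with
        # the band's own selected channels; no baseline renormalization
        reref = laplacian_rereference(comb_notch(rec))
        matrix = extract_baseline_features(
            reref,
            {k: s.selected for k, s in selections.items()},
            starts,
            spec,
            method=feature_set,
            bands=list(selections),
            truth=truth,
        )
        builder = None
        fold_norm = False
    else:
        builder = _FoldBuilder(
            traces, selections, starts, spec, events, truth, feature_set
        )
        matrix = builder(np.arange(len(starts)))
    span = (0.0, rec.n_samples / rec.fs)
    actual = PeriodSet(truth.active_periods(), source="actual")

    cv = run_cv(
        matrix,
        classifier=classifier,
        keep=keep,
        n_perm=feature_n_perm,
        k_max=k_max,
        seed=seed,
        decode_mode=decode_mode,
        builder=builder if fold_norm else None,
    )
    ledger = _evaluate_predictions(cv.predictions, matrix, actual, span, tol_s)
    detected = windows_to_periods(
        collapse_to_binary(cv.predictions), matrix.start_s, matrix.end_s
    )

    chance = None
    if chance_perms > 0:

        def _eval(shuffled: np.ndarray) -> tuple[float, float, float]:
            cv_p = run_cv(
                matrix,
                classifier=classifier,
                keep=keep,
                n_perm=feature_n_perm,
                k_max=k_max,
                seed=seed,
                decode_mode=decode_mode,
                train_labels=shuffled,
                builder=builder if fold_norm else None,
            )
            led = _evaluate_predictions(cv_p.predictions, matrix, actual, span, tol_s)
            return score(led)

        chance = chance_level(_eval, matrix.labels, n_perm=chance_perms, seed=seed)

    rep = report(ledger, chance=chance)
    rep.timing = {
        "onset_mean_s": float(np.mean(ledger.onset_diffs)) if ledger.onset_diffs else float("nan"),
        "end_mean_s": float(np.mean(ledger.end_diffs)) if ledger.end_diffs else float("nan"),
    }
    return TwoClassResult(rep, cv, matrix, selections, actual, detected)


@dataclass
class ThreeClassResult:
    cv: CvResult
    period_table: pd.DataFrame
    window_table: pd.DataFrame
    matrix: WindowFeatureMatrix
    selections: dict[str, ChannelSelection]
    binary_ledger: MatchLedger


def run_three_class(
    rec: Recording,
    events: EventTable,
    truth: GroundTruth,
    spec: WindowSpec | None = None,
    feature_set: str = "four_type",
    channel_n_perm: int = 200,
    feature_n_perm: int = 200,
    keep_per_pair: int = 10,
    k_max: int = 5,
    seed: int = 0,
    fold_norm: bool = True,
    traces: dict[str, TraceSet] | None = None,
    selections: dict[str, ChannelSelection] | None = None,
) -> ThreeClassResult:
    """Three-class (idle / own / other) detection with a 3-state GMM-HMM."""
    spec = spec or WindowSpec()
    kinds = kinds_for_feature_set(feature_set)
    if traces is None:
        traces = preprocess_session(rec, kinds)
    if selections is None:
        selections = select_session_channels(
            traces, events, n_perm=channel_n_perm, seed=seed
        )
    any_trace = next(iter(traces.values()))
    starts = make_windows(any_trace.data.shape[1], any_trace.fs, spec)
    builder = _FoldBuilder(
        traces, selections, starts, spec, events, truth, feature_set,
        binary_labels=False,
    )
    matrix = builder(np.arange(len(starts)))
    cv, per_table, win_table = detect_three_state(
        matrix,
        keep_per_pair=keep_per_pair,
        n_perm=feature_n_perm,
        k_max=k_max,
        seed=seed,
        builder=builder if fold_norm else None,
    )
    span = (0.0, rec.n_samples / rec.fs)
    actual = PeriodSet(truth.active_periods(), source="actual")
    ledger = _evaluate_predictions(cv.predictions, matrix, actual, span)
    return ThreeClassResult(cv, per_table, win_table, matrix, selections, ledger)
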