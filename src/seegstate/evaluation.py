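"""Period-level detection metrics.

Window predictions are merged into contiguous state *periods*; detection is
scored at the period level, not the window level.  An actual active period
overlapped by a detected one is a TP (with onset/end time differences,
detected minus actual); an unmatched actual period is an FN; an unmatched
detected period is an FP.  Two stricter rules apply:

* a TP whose onset (end) difference exceeds 400 ms additionally counts one
  FP (FN);
* a detected period penetrating two (or more) actual periods counts one TP
  plus one FP per extra actual period, with the onset difference taken
  against the first actual period and the end difference against the last.

Symmetrically, extra detected periods overlapping an already-matched actual
period count as FPs.  TNs are the actual idle periods (gaps between actual
active periods within the evaluated span) that contain no detected active
interval.  Sensitivity, precision and accuracy are then

    sensitivity = 100 * TP / (TP + FN)
    precision   = 100 * TP / (TP + FP)
    accuracy    = 100 * (TP + TN) / (TP + FP + TN + FN)

Chance levels are the 95th percentile of each indicator under label
shuffling repeated before feature selection and classification.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import ACTIVE, IDLE, _runs

__all__ = [
    "PeriodSet",
    "MatchLedger",
    "DetectionReport",
    "windows_to_periods",
    "match_periods",
    "score",
    "timing_summary",
    "chance_level",
]


@dataclass
class PeriodSet:
    """Sorted non-overlapping (start_s, end_s) intervals of one state."""

    intervals: list[tuple[float, float]]
    state: str = ACTIVE
    source: str = "actual"  # actual | detected

    def __post_init__(self) -> None:
        iv = sorted((float(a), float(b)) for a, b in self.intervals)
        for a, b in iv:
            if b <= a:
                raise ValueError("intervals must have end > start")
        for (a0, b0), (a1, b1) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ValueError("intervals must not overlap")
        self.intervals = iv

    def __len__(self) -> int:
        return len(self.intervals)


def windows_to_periods(
    predictions: np.ndarray,
    start_s: np.ndarray,
    end_s: np.ndarray,
    state: str = ACTIVE,
    source: str = "detected",
) -> PeriodSet:
    """Merge maximal runs of identically-labelled windows into periods.

    Overlapping sliding windows are attributed to their midpoints: a run of
    windows i..j becomes the interval [mid_i - step/2, mid_j + step/2), which
    for a 50 ms step localizes period edges to +/-25 ms.  For a lone window
    (or unit-step windows) the window's own span is used.
    """
    predictions = np.asarray(predictions, object)
    mids = (np.asarray(start_s) + np.asarray(end_s)) / 2.0
    if len(mids) > 1:
        half = float(mids[1] - mids[0]) / 2.0
    else:
        half = float(end_s[0] - start_s[0]) / 2.0
    labels, starts, ends = _runs(predictions)
    intervals = []
    for lab, s, e in zip(labels, starts, ends):
        if lab == state:
            intervals.append((mids[s] - half, mids[e - 1] + half))
    return PeriodSet(intervals, state=state, source=source)


@dataclass
class MatchLedger:
    """Period-level match counts plus per-TP timing differences (seconds)."""

    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0
    onset_diffs: list[float] = field(default_factory=list)
    end_diffs: list[float] = field(default_factory=list)
    annotations: list[str] = field(default_factory=list)

    def __add__(self, other: "MatchLedger") -> "MatchLedger":
        return MatchLedger(
            self.TP + other.TP,
            self.FP + other.FP,
            self.FN + other.FN,
            self.TN + other.TN,
            self.onset_diffs + other.onset_diffs,
            self.end_diffs + other.end_diffs,
            self.annotations + other.annotations,
        )


def _overlaps(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def match_periods(
    actual: PeriodSet,
    detected: PeriodSet,
    tol_s: float = 0.4,
    span: tuple[float, float] | None = None,
) -> MatchLedger:
    """Match detected against actual active periods (overlap-based).

    ``span`` bounds the idle gaps counted as TNs; it defaults to the hull of
    all intervals of both sets.
    """
    led = MatchLedger()
    matched = [False] * len(actual)
    for d in detected.intervals:
        overl = [i for i, a in enumerate(actual.intervals) if _overlaps(a, d)]
        fresh = [i for i in overl if not matched[i]]
        if not overl:
            led.FP += 1
            led.annotations.append(f"FP spurious {d}")
            continue
        if not fresh:
            # converse of penetration: extra detection on a matched actual
            led.FP += 1
            led.annotations.append(f"FP extra-detection {d}")
            continue
        first, last = actual.intervals[fresh[0]], actual.intervals[fresh[-1]]
        onset_diff = d[0] - first[0]
        end_diff = d[1] - last[1]
        led.TP += 1
        led.onset_diffs.append(onset_diff)
        led.end_diffs.append(end_diff)
        led.annotations.append(f"TP {d} vs {first}..{last}")
        for i in fresh:
            matched[i] = True
        if len(fresh) > 1:  # penetration
            led.FP += len(fresh) - 1
            led.annotations.append(f"FP penetration x{len(fresh) - 1} {d}")
        if abs(onset_diff) > tol_s:
            led.FP += 1
            led.annotations.append(f"FP onset-diff>{tol_s}s {d}")
        if abs(end_diff) > tol_s:
            led.FN += 1
            led.annotations.append(f"FN end-diff>{tol_s}s {d}")
    for i, a in enumerate(actual.intervals):
        if not matched[i]:
            led.FN += 1
            led.annotations.append(f"FN missed {a}")
    led.TN = _count_tn(actual, detected, span)
    return led


def _count_tn(
    actual: PeriodSet, detected: PeriodSet, span: tuple[float, float] | None
) -> int:
    allv = actual.intervals + detected.intervals
    if span is None:
        if not allv:
            return 0
        span = (min(a for a, _ in allv), max(b for _, b in allv))
    edges = [span[0]] + [x for iv in actual.intervals for x in iv] + [span[1]]
    tn = 0
    for a, b in zip(edges[::2], edges[1::2]):
        if b <= a:
            continue
        # the gap stays a TN unless a detected interval lies fully inside it
        # (boundary jitter of a neighbouring TP does not consume the gap)
        if not any(d0 >= a and d1 <= b for d0, d1 in detected.intervals):
            tn += 1
    return tn


@dataclass
class DetectionReport:
    """Headline indicators (percent), the underlying ledger and optional
    chance levels and timing summaries."""

    sensitivity: float
    precision: float
    accuracy: float
    ledger: MatchLedger
    confusion: dict[str, dict[str, int]] | None = None
    timing: dict[str, float] | None = None
    chance: dict[str, float] | None = None

    def to_json(self, path: str) -> None:
        out = {
            "sensitivity_pct": self.sensitivity,
            "precision_pct": self.precision,
            "accuracy_pct": self.accuracy,
            "counts": {
                "TP": self.ledger.TP,
                "FP": self.ledger.FP,
                "FN": self.ledger.FN,
                "TN": self.ledger.TN,
            },
            "timing": self.timing,
            "chance": self.chance,
        }
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2, default=float)


def score(ledger: MatchLedger) -> tuple[float, float, float]:
    """Sensitivity, precision, accuracy in percent (NaN with a warning when
    a denominator is zero)."""

    def _pct(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return float("nan")
        return 100.0 * num / den

    sens = _pct(ledger.TP, ledger.TP + ledger.FN, "sensitivity")
    prec = _pct(ledger.TP, ledger.TP + ledger.FP, "precision")
    total = ledger.TP + ledger.FP + ledger.TN + ledger.FN
    acc = _pct(ledger.TP + ledger.TN, total, "accuracy")
    return sens, prec, acc


def report(ledger: MatchLedger, **extra) -> DetectionReport:
    sens, prec, acc = score(ledger)
    return DetectionReport(sens, prec, acc, ledger, **extra)


def timing_summary(ledgers: list[MatchLedger]) -> dict[str, object]:
    """Mean +/- standard error of onset/end differences across runs, plus the
    pooled distributions (only overlapping TP pairs contribute)."""
    per_run_on = [np.mean(l.onset_diffs) for l in ledgers if l.onset_diffs]
    per_run_end = [np.mean(l.end_diffs) for l in ledgers if l.end_diffs]
    pooled_on = np.concatenate([l.onset_diffs for l in ledgers]) if any(
        l.onset_diffs for l in ledgers
    ) else np.array([])
    pooled_end = np.concatenate([l.end_diffs for l in ledgers]) if any(
        l.end_diffs for l in ledgers
    ) else np.array([])
    if len(pooled_on) == 0:
        raise ValueError("no TP with timing information")

    def _se(v: list[float]) -> float:
        return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")

    return {
        "onset_mean_s": float(np.mean(per_run_on)),
        "onset_se_s": _se(per_run_on),
        "end_mean_s": float(np.mean(per_run_end)),
        "end_se_s": _se(per_run_end),
        "pooled_onset_s": pooled_on,
        "pooled_end_s": pooled_end,
    }


def chance_level(
    evaluate_with_train_labels,
    labels: np.ndarray,
    n_perm: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation chance levels of the three indicators.

    ``evaluate_with_train_labels(shuffled_labels)`` must re-run feature
    selection, dimensionality reduction and classification with the shuffled
    window labels and return ``(sensitivity, precision, accuracy)`` scored
    against the *actual* labels.  The chance level of each indicator is the
    ``percentile``-th percentile (linear interpolation) of its distribution
    over ``n_perm`` shuffles; undefined indicators enter the distribution
    as 0.
    """
    rng = np.random.default_rng(seed)
    sens, prec, acc = [], [], []
    for _ in range(n_perm):
        shuffled = rng.permutation(np.asarray(labels, object))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s, p, a = evaluate_with_train_labels(shuffled)
        sens.append(0.0 if np.isnan(s) else s)
        prec.append(0.0 if np.isnan(p) else p)
        acc.append(0.0 if np.isnan(a) else a)
    return {
        "sensitivity": float(np.percentile(sens, percentile)),
        "precision": float(np.percentile(prec, percentile)),
        "accuracy": float(np.percentile(acc, percentile)),
    }
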