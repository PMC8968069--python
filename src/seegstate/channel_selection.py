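"""Responsive-channel selection by a randomization (permutation) test.

For each channel the per-trial mean trace amplitude of the active period
(300-1000 ms post-onset, ``x``) and of the idle/baseline period (-200-0 ms,
``y``) are concatenated into ``z`` and correlated (Spearman) with the state
labels (-1 active / +1 idle).  Shuffling the labels 1000 times yields a
surrogate distribution of r; the observed r is converted to a significance
probability from a normal fit to the surrogates (an empirical-tail p is
available as an option).  Channels significant after Bonferroni correction
are ranked by p and at most the ten most informative are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EpochSet

__all__ = [
    "PermResult",
    "ChannelSelection",
    "trial_state_means",
    "permutation_spearman",
    "select_channels",
]


@dataclass(frozen=True)
class PermResult:
    """Observed Spearman r, its significance probability, and the mean/SD of
    the surrogate r distribution."""

    r_obs: float
    p: float
    surrogate_mean: float
    surrogate_sd: float


@dataclass
class ChannelSelection:
    """Per-channel test results for one trace kind plus the kept subset."""

    kind: str
    table: pd.DataFrame  # columns: channel, r_obs, p, significant, selected
    alpha_corrected: float

    @property
    def selected(self) -> list[str]:
        return self.table.loc[self.table["selected"], "channel"].tolist()

    def to_tsv(self, path: str) -> None:
        self.table.assign(kind=self.kind).to_csv(path, sep="\t", index=False)


def trial_state_means(
    epochs: EpochSet,
    active_ms: tuple[float, float] = (300.0, 1000.0),
    idle_ms: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial mean amplitude over the active and idle periods.

    Returns arrays ``x`` and ``y`` of shape (n_channels, n_trials).  The idle
    period defaults to the epoch's baseline window.
    """
    idle_ms = idle_ms or epochs.baseline_ms
    x = epochs.data[:, :, epochs.sample_slice(active_ms)].mean(axis=2)
    y = epochs.data[:, :, epochs.sample_slice(idle_ms)].mean(axis=2)
    return x, y


def _ranks_z(v: np.ndarray) -> np.ndarray | None:
    """Centred, unit-norm ranks; None when the input is constant."""
    r = stats.rankdata(v)
    r = r - r.mean()
    norm = np.linalg.norm(r)
    if norm == 0:
        return None
    return r / norm


def permutation_spearman(
    values: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "normal",
    alternative: str = "two-sided",
) -> PermResult:
    """Permutation test of the Spearman correlation between ``values`` and
    binary state ``labels``.

    ``method='normal'`` fits a Gaussian to the surrogate r values and reports
    the tail probability of the observed r; ``method='empirical'`` uses the
    surrogate distribution directly.  Constant input values make r undefined
    and give p = 1 with a warning.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels, float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("both labels must be present")
    rv = _ranks_z(values)
    if rv is None:
        warnings.warn("constant values: Spearman r undefined, p set to 1",
                      stacklevel=2)
        return PermResult(np.nan, 1.0, np.nan, np.nan)
    rl = _ranks_z(labels)
    r_obs = float(rv @ rl)

    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(rl, (n_perm, 1)), axis=1)
    r_surr = perm @ rv
    mu, sd = float(r_surr.mean()), float(r_surr.std())
    p = _tail_p(r_obs, r_surr, mu, sd, method, alternative)
    return PermResult(r_obs, p, mu, sd)


def _tail_p(
    r_obs: float,
    r_surr: np.ndarray,
    mu: float,
    sd: float,
    method: str,
    alternative: str,
) -> float:
    if method == "empirical":
        if alternative == "two-sided":
            hits = np.sum(np.abs(r_surr) >= abs(r_obs))
        else:
            hits = np.sum(r_surr >= r_obs)
        return float((1 + hits) / (1 + len(r_surr)))
    if method != "normal":
        raise ValueError("method must be 'normal' or 'empirical'")
    if sd == 0:
        return 0.0 if abs(r_obs) > abs(mu) else 1.0
    if alternative == "two-sided":
        return float(
            stats.norm.sf(abs(r_obs), mu, sd) + stats.norm.cdf(-abs(r_obs), mu, sd)
        )
    if alternative == "greater":
        return float(stats.norm.sf(r_obs, mu, sd))
    raise ValueError("alternative must be 'two-sided' or 'greater'")


def channel_perm_test(
    epochs: EpochSet,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "normal",
    alternative: str = "two-sided",
    active_ms: tuple[float, float] = (300.0, 1000.0),
) -> list[PermResult]:
    """Run the permutation test independently for every channel of an epoch
    set (active/idle labels -1/+1, one seeded stream per channel)."""
    x, y = trial_state_means(epochs, active_ms=active_ms)
    n_trials = x.shape[1]
    labels = np.concatenate([-np.ones(n_trials), np.ones(n_trials)])
    seeds = np.random.SeedSequence(seed).spawn(x.shape[0])
    out = []
    for ci in range(x.shape[0]):
        z = np.concatenate([x[ci], y[ci]])
        child_seed = int(seeds[ci].generate_state(1)[0] % (2**31 - 1))
        out.append(
            permutation_spearman(
                z, labels, n_perm=n_perm, seed=child_seed,
                method=method, alternative=alternative,
            )
        )
    return out


def select_channels(
    epochs: EpochSet,
    alpha: float = 0.05,
    max_keep: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "normal",
    alternative: str = "two-sided",
) -> ChannelSelection:
    """Keep at most ``max_keep`` channels significant at the Bonferroni-
    corrected level, smallest p first (ties broken by larger \\|r\\|, then
    channel id)."""
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials")
    results = channel_perm_test(
        epochs, n_perm=n_perm, seed=seed, method=method, alternative=alternative
    )
    n_ch = len(results)
    alpha_c = alpha / n_ch
    ids = [c.id for c in epochs.channels]
    df = pd.DataFrame(
        {
            "channel": ids,
            "r_obs": [r.r_obs for r in results],
            "p": [r.p for r in results],
        }
    )
    df["significant"] = df["p"] < alpha_c
    order = sorted(
        range(n_ch),
        key=lambda i: (df["p"][i], -abs(np.nan_to_num(df["r_obs"][i])), ids[i]),
    )
    selected = [i for i in order if df["significant"][i]][:max_keep]
    df["selected"] = False
    df.loc[selected, "selected"] = True
    if not selected:
        warnings.warn("no channel reached Bonferroni significance", stacklevel=2)
    return ChannelSelection(epochs.kind, df, alpha_c)
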