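"""Decision-time-advantage estimation.

The anticipation question is *how much earlier than its training position can
the classification window slide while the classifier still fires reliably*.
A sliding window is moved from the cue onset to 1 s before it in 0.1 s steps;
at each lag the positive-class windows are re-cut, preprocessed identically
and labeled, giving a true-positive-rate profile over lag (on slid
positive-only windows TPR and accuracy coincide). A monotone piecewise-cubic
(PCHIP) spline through the profile is evaluated on a dense 1 ms grid, and the
Decision Time Advantage at consistency ``k`` is

    DTA_k = the largest lag L such that the interpolated TPR stays >= k/100
            at *every* lag in [0, L]  (the sustained-crossing rule),

so a transient dip below ``k`` blocks any later re-crossing. Profiles that
never drop below ``k`` are right-censored at the 1000 ms grid edge (reported
as ">1,000"); profiles already below ``k`` at lag 0 are undefined (reported
as a dash). Confidence intervals come from a seeded trial-level percentile
bootstrap.

The Computational Time Delay (CTD) is the measured per-epoch preprocessing +
inference wall-clock time, and the Total Time Advantage is
``TTA = DTA - CTD`` — the net anticipation a downstream controller receives.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .preprocessing import DEFAULT_LAG_GRID, EpochSet, PreprocConfig, \
    extract_epochs
from .simulate import Recording

__all__ = [
    "LagProfile",
    "DtaEstimate",
    "TimingBudget",
    "TtaResult",
    "compute_lag_profile",
    "estimate_dta",
    "measure_ctd",
    "compute_tta",
]


@dataclass
class LagProfile:
    """TPR as a function of window lag (s), plus per-trial outcomes.

    ``outcomes[i, j]`` is 1 when trial ``i``'s positive window at lag ``j``
    was labeled anticipation; it feeds the trial-level bootstrap.
    """

    lags: np.ndarray
    tpr: np.ndarray
    n_windows: np.ndarray
    outcomes: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=np.float64)
        self.tpr = np.asarray(self.tpr, dtype=np.float64)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any((self.tpr < 0) | (self.tpr > 1)):
            raise ValueError("tpr values must lie in [0, 1]")

    @property
    def interpolant(self) -> PchipInterpolator:
        """Shape-preserving monotone cubic through the grid points."""
        return PchipInterpolator(self.lags, self.tpr)


@dataclass(frozen=True)
class DtaEstimate:
    """DTA_k in ms with its censoring status and bootstrap CI."""

    k: float
    dta_ms: float | None
    status: str  # estimated | censored_at_grid_max | undefined
    ci_ms: tuple[float, float] | None = None
    n_boot: int = 0
    seed: int | None = None


@dataclass(frozen=True)
class TimingBudget:
    """Per-epoch wall-clock costs (ms): CTD = preprocessing + inference."""

    preprocess_mean_ms: float
    preprocess_sd_ms: float
    inference_mean_ms: float
    inference_sd_ms: float

    @property
    def ctd_ms(self) -> float:
        return self.preprocess_mean_ms + self.inference_mean_ms


@dataclass(frozen=True)
class TtaResult:
    dta_ms: float
    ctd_ms: float

    @property
    def tta_ms(self) -> float:
        return self.dta_ms - self.ctd_ms


def compute_lag_profile(
    clf,
    rec: Recording,
    cfg: PreprocConfig = PreprocConfig(),
    lags=None,
    trial_subset=None,
    edge_exclude: int = 0,
) -> LagProfile:
    """Label re-cut positive windows at every lag with a trained classifier.

    ``rec`` must already be preprocessed the same way as the training data;
    windows are pure slices, so the conditioning the classifier saw is
    preserved. ``trial_subset`` restricts profiling to held-out trials.
    Raises if more than half the trials lack a window at any lag.
    """
    lags = np.asarray(DEFAULT_LAG_GRID if lags is None else lags, float)
    per_lag: list[dict[int, int]] = []
    for lag in lags:
        es = extract_epochs(rec, cfg, lag=float(lag), include_negative=False,
                            edge_exclude=edge_exclude)
        if trial_subset is not None:
            keep = np.isin(es.trial_ids, trial_subset)
            es = EpochSet(es.epochs[keep], es.labels[keep], es.lag,
                          es.srate, es.trial_ids[keep])
        n_expected = (len(rec.events) if trial_subset is None
                      else len(trial_subset))
        if len(es) < n_expected / 2:
            raise ValueError(
                f"lag {lag:.1f}s: windows available for only {len(es)} of "
                f"{n_expected} trials")
        pred = clf.predict(es.epochs)
        per_lag.append(dict(zip(es.trial_ids.tolist(), pred.tolist())))

    common = sorted(set.intersection(*(set(d) for d in per_lag)))
    outcomes = np.array([[d[t] for d in per_lag] for t in common], int)
    tpr = outcomes.mean(axis=0)
    n_windows = np.full(len(lags), len(common))
    return LagProfile(lags, tpr, n_windows, outcomes)


def _scan_dta(lags_ms: np.ndarray, tpr: np.ndarray, k: float,
              grid_step_ms: float = 1.0) -> tuple[float | None, str]:
    """Sustained-crossing scan of the PCHIP interpolant on a dense grid."""
    interp = PchipInterpolator(lags_ms, tpr)
    grid = np.arange(0.0, lags_ms[-1] + grid_step_ms / 2, grid_step_ms)
    vals = interp(grid)
    below = vals < k / 100.0
    if below[0]:
        return None, "undefined"
    if not below.any():
        return float(grid[-1]), "censored_at_grid_max"
    first = int(np.argmax(below))
    return float(grid[first - 1]), "estimated"


def estimate_dta(
    profile: LagProfile,
    k: float,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> DtaEstimate:
    """DTA_k (ms) with a trial-resampling percentile bootstrap CI.

    Bootstrap replicates that never drop below ``k`` are mapped to the grid
    maximum and replicates undefined at lag 0 to 0 ms before taking
    percentiles. The CI is omitted when the profile carries no per-trial
    outcomes or ``n_boot`` is 0.
    """
    if not 0 < k < 100:
        raise ValueError("k must be in (0, 100)")
    lags_ms = profile.lags * 1000.0
    dta, status = _scan_dta(lags_ms, profile.tpr, k)

    ci = None
    if n_boot and profile.outcomes is not None and len(profile.outcomes):
        rng = np.random.default_rng(seed)
        n_trials = len(profile.outcomes)
        grid_max = float(lags_ms[-1])
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n_trials, size=n_trials)
            tpr_b = profile.outcomes[idx].mean(axis=0)
            d, s = _scan_dta(lags_ms, tpr_b, k)
            reps[b] = grid_max if s == "censored_at_grid_max" else (
                0.0 if s == "undefined" else d)
        alpha = (1.0 - ci_level) / 2.0
        lo = float(np.quantile(reps, alpha))
        hi = float(np.quantile(reps, 1.0 - alpha))
        if status == "estimated":  # the interval always covers the estimate
            lo, hi = min(lo, dta), max(hi, dta)
        ci = (lo, hi)

    return DtaEstimate(k=k, dta_ms=dta, status=status, ci_ms=ci,
                       n_boot=n_boot if ci else 0,
                       seed=seed if ci else None)


def measure_ctd(preprocess_fn, predict_fn, epochs: np.ndarray,
                n_reps: int = 50) -> TimingBudget:
    """Wall-clock per-epoch preprocessing and inference time.

    ``preprocess_fn(epoch)`` conditions one channels x samples epoch;
    ``predict_fn(processed)`` labels it. Epochs are cycled until ``n_reps``
    measurements are collected. Results are hardware-specific by nature.
    """
    if n_reps < 10:
        warnings.warn("fewer than 10 timing repetitions gives an unstable "
                      "CTD estimate", RuntimeWarning)
    epochs = np.asarray(epochs)
    pre_ms, inf_ms = [], []
    for r in range(n_reps):
        epoch = epochs[r % len(epochs)]
        t0 = time.perf_counter()
        processed = preprocess_fn(epoch)
        t1 = time.perf_counter()
        predict_fn(processed)
        t2 = time.perf_counter()
        pre_ms.append((t1 - t0) * 1e3)
        inf_ms.append((t2 - t1) * 1e3)
    pre = np.array(pre_ms)
    inf = np.array(inf_ms)
    return TimingBudget(float(pre.mean()), float(pre.std()),
                        float(inf.mean()), float(inf.std()))


def compute_tta(dta: DtaEstimate, ctd) -> TtaResult:
    """Net anticipation: DTA minus CTD (ms). Requires an estimated DTA."""
    if dta.status != "estimated":
        raise ValueError(
            f"DTA status is {dta.status!r}; report the status instead of a "
            "TTA")
    ctd_ms = ctd.ctd_ms if isinstance(ctd, TimingBudget) else float(ctd)
    return TtaResult(dta_ms=dta.dta_ms, ctd_ms=ctd_ms)
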