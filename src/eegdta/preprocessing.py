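"""Signal conditioning and cue-locked epoching.

The fixed chain is: zero-phase FIR high-pass (0.1 Hz) -> zero-phase FIR notch
(50 Hz) -> common average reference -> ICA artifact removal -> epoching.
Windows are cut relative to the arrow-cue onset: ``[0, 1)`` s holds action
anticipation (label 1), ``[-1, 0)`` s holds idle baseline (label 0). For
latency profiling the positive window is slid earlier by a lag on a 0.1 s
grid, keeping its 1 s length.

"One-pass, zero-phase" filtering is realized as a single forward pass of an
odd-length linear-phase (symmetric) FIR kernel with the group delay
compensated by centering — not forward-backward filtering.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats
from sklearn.decomposition import FastICA

from .simulate import ConfigurationError, Recording

__all__ = [
    "PreprocConfig",
    "EpochSet",
    "IcaReport",
    "highpass_filter",
    "notch_filter",
    "common_average_reference",
    "ica_artifact_removal",
    "extract_epochs",
    "Preprocessor",
    "preprocess",
    "save_epochs",
    "load_epochs",
]

logger = logging.getLogger(__name__)

DEFAULT_LAG_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


@dataclass(frozen=True)
class PreprocConfig:
    """Conditioning-chain parameters.

    ``hp_transition`` defaults to the cutoff itself (very long kernel at
    0.1 Hz); ``max_filter_length`` caps the kernel with a logged warning, at
    the cost of a wider transition. ``notch_bandwidth`` is the full stop-band
    width. ICA components are rejected when their kurtosis z-score exceeds
    ``ica_kurtosis_z`` or their absolute correlation with a frontal channel
    exceeds ``ica_frontal_corr`` — tuned to catch only blatant blink/EMG
    components.
    """

    hp_cutoff: float = 0.1
    hp_transition: float | None = None
    notch_freq: float = 50.0
    notch_bandwidth: float = 2.0
    notch_transition: float = 1.0
    max_filter_length: int | None = None
    ica_n_components: int | None = None
    ica_kurtosis_z: float = 3.0
    ica_frontal_corr: float = 0.8
    epoch_positive_window: tuple[float, float] = (0.0, 1.0)
    epoch_negative_window: tuple[float, float] = (-1.0, 0.0)
    lag_grid: tuple[float, ...] = DEFAULT_LAG_GRID

    def __post_init__(self) -> None:
        if self.hp_cutoff <= 0:
            raise ConfigurationError("hp_cutoff must be > 0")
        if self.notch_freq <= self.hp_cutoff:
            raise ConfigurationError("notch_freq must exceed hp_cutoff")
        for a, b in (self.epoch_positive_window, self.epoch_negative_window):
            if not b > a:
                raise ConfigurationError("epoch windows must be increasing")
        if any(l < 0 for l in self.lag_grid):
            raise ConfigurationError("lags must be >= 0")
        if list(self.lag_grid) != sorted(self.lag_grid):
            raise ConfigurationError("lag_grid must be sorted")


@dataclass
class EpochSet:
    """Labeled fixed-length windows: ``epochs`` is n_epochs x channels x
    samples (uV), labels 1 = anticipation, 0 = idle. ``lag`` is the shift (s)
    applied to the positive window relative to its training position."""

    epochs: np.ndarray
    labels: np.ndarray
    lag: float
    srate: float
    trial_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n, channels, samples)")
        if len(self.labels) != len(self.epochs):
            raise ValueError("labels length mismatch")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if self.trial_ids is None:
            self.trial_ids = np.arange(len(self.epochs))
        self.trial_ids = np.asarray(self.trial_ids, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.epochs)


@dataclass
class IcaReport:
    n_components: int
    removed: list[int]
    kurtosis_z: np.ndarray
    frontal_corr: np.ndarray


def _design_highpass(srate: float, cfg: PreprocConfig) -> np.ndarray:
    transition = cfg.hp_transition or cfg.hp_cutoff
    numtaps = int(np.ceil(3.3 * srate / transition))
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay
    if cfg.max_filter_length and numtaps > cfg.max_filter_length:
        capped = cfg.max_filter_length - (1 - cfg.max_filter_length % 2)
        logger.warning(
            "high-pass kernel capped from %d to %d taps; transition widens "
            "to ~%.3g Hz", numtaps, capped, 3.3 * srate / capped)
        numtaps = capped
    return sps.firwin(numtaps, cfg.hp_cutoff, fs=srate,
                      pass_zero=False, window="hamming")


def _design_notch(srate: float, cfg: PreprocConfig) -> np.ndarray:
    if cfg.notch_freq >= srate / 2:
        raise ConfigurationError(
            f"notch_freq {cfg.notch_freq} Hz must be below Nyquist "
            f"{srate / 2} Hz")
    numtaps = int(np.ceil(3.3 * srate / cfg.notch_transition))
    numtaps += 1 - numtaps % 2
    if cfg.max_filter_length and numtaps > cfg.max_filter_length:
        capped = cfg.max_filter_length - (1 - cfg.max_filter_length % 2)
        logger.warning(
            "notch kernel capped from %d to %d taps; transition widens to "
            "~%.3g Hz", numtaps, capped, 3.3 * srate / capped)
        numtaps = capped
    half = cfg.notch_bandwidth / 2.0
    edges = [cfg.notch_freq - half, cfg.notch_freq + half]
    return sps.firwin(numtaps, edges, fs=srate, pass_zero=True,
                      window="hamming")


def _apply_fir(rec: Recording, taps: np.ndarray) -> Recording:
    if rec.n_samples < len(taps):
        raise ValueError(
            f"signal has {rec.n_samples} samples but the filter needs at "
            f"least {len(taps)}; lengthen the recording or cap "
            "max_filter_length")
    # symmetric odd kernel + 'same' alignment == delay-compensated one pass
    filtered = sps.fftconvolve(rec.data, taps[None, :], mode="same", axes=1)
    out = rec.copy()
    out.data = filtered
    return out


def filter_edge_samples(srate: float, cfg: PreprocConfig) -> int:
    """Number of samples at each end distorted by the filter edges."""
    hp = len(_design_highpass(srate, cfg))
    notch = len(_design_notch(srate, cfg))
    return (max(hp, notch) - 1) // 2


def highpass_filter(rec: Recording, cfg: PreprocConfig = PreprocConfig()
                    ) -> Recording:
    """Zero-phase FIR high-pass: removes DC and slow drift."""
    return _apply_fir(rec, _design_highpass(rec.srate, cfg))


def notch_filter(rec: Recording, cfg: PreprocConfig = PreprocConfig()
                 ) -> Recording:
    """Zero-phase FIR band-stop at the mains frequency."""
    return _apply_fir(rec, _design_notch(rec.srate, cfg))


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    out = rec.copy()
    out.data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return out


_FRONTAL = ("Fp1", "Fp2")


def ica_artifact_removal(
    rec: Recording,
    cfg: PreprocConfig = PreprocConfig(),
    random_state: int = 0,
) -> tuple[Recording, IcaReport]:
    """Remove blatant artifact components by ICA.

    A FastICA decomposition is fitted; components whose kurtosis z-score
    (across components) exceeds ``cfg.ica_kurtosis_z`` or whose absolute
    correlation with a frontal channel exceeds ``cfg.ica_frontal_corr`` are
    zeroed and the signal reconstructed. With thresholds at their most
    permissive the output equals the full reconstruction (~ the input).
    """
    n_comp = cfg.ica_n_components or rec.n_channels
    recommended = 20 * n_comp ** 2
    if rec.n_samples < recommended:
        logger.warning(
            "ICA on %d samples; >= %d recommended for %d components",
            rec.n_samples, recommended, n_comp)
    X = rec.data.T
    ica = FastICA(n_components=n_comp, random_state=random_state,
                  whiten="unit-variance", max_iter=500, tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on clean data
        sources = ica.fit_transform(X)  # samples x components

    kurt = spstats.kurtosis(sources, axis=0)
    kz = (kurt - kurt.mean()) / (kurt.std() + 1e-12)

    frontal_idx = [i for i, c in enumerate(rec.channel_names)
                   if c in _FRONTAL]
    if frontal_idx:
        fr = rec.data[frontal_idx].T
        corr = np.abs(np.corrcoef(sources.T, fr.T)[:n_comp, n_comp:])
        frontal_corr = corr.max(axis=1)
    else:
        frontal_corr = np.zeros(n_comp)

    removed = sorted(
        set(np.flatnonzero(np.abs(kz) > cfg.ica_kurtosis_z))
        | set(np.flatnonzero(frontal_corr > cfg.ica_frontal_corr))
    )
    if len(removed) > n_comp / 2:
        warnings.warn(
            f"ICA removed {len(removed)}/{n_comp} components; rejection "
            "threshold looks miscalibrated", RuntimeWarning)

    cleaned_sources = sources.copy()
    cleaned_sources[:, removed] = 0.0
    reconstructed = ica.inverse_transform(cleaned_sources).T

    out = rec.copy()
    out.data = reconstructed
    report = IcaReport(n_comp, [int(i) for i in removed], kz, frontal_corr)
    return out, report


def extract_epochs(
    rec: Recording,
    cfg: PreprocConfig = PreprocConfig(),
    lag: float = 0.0,
    include_negative: bool | None = None,
    edge_exclude: int = 0,
) -> EpochSet:
    """Cut cue-locked windows.

    At lag 0 each trial yields a positive epoch ``[cue, cue + 1 s)`` and a
    negative epoch ``[cue - 1 s, cue)``. At lag ``l > 0`` the positive window
    is slid earlier to ``[cue - l, cue - l + 1 s)``, still labeled 1 (the
    MRCP extends ~1.5 s before movement, so for l <= 1 with a 1 s arrow the
    window stays inside the anticipation period); negative windows are not
    slid and by default are only cut at lag 0. Trials whose windows leave the
    recording (or its filter-edge margin) are skipped with a warning.
    """
    if include_negative is None:
        include_negative = lag == 0.0
    srate = rec.srate
    a, b = cfg.epoch_positive_window
    n_win = int(round((b - a) * srate))
    na, nb = cfg.epoch_negative_window
    n_neg = int(round((nb - na) * srate))
    lag_samp = int(round(lag * srate))

    epochs, labels, trial_ids = [], [], []
    lo_valid, hi_valid = edge_exclude, rec.n_samples - edge_exclude
    skipped = 0
    for i, ev in enumerate(rec.events):
        pos_start = ev.cue_sample + int(round(a * srate)) - lag_samp
        windows = [(pos_start, pos_start + n_win, 1)]
        if include_negative:
            neg_start = ev.cue_sample + int(round(na * srate))
            windows.append((neg_start, neg_start + n_neg, 0))
        if any(s < lo_valid or e > hi_valid for s, e, _ in windows):
            skipped += 1
            logger.warning("trial %d skipped: window outside recording", i)
            continue
        for s, e, lab in windows:
            epochs.append(rec.data[:, s:e])
            labels.append(lab)
            trial_ids.append(i)
    if not epochs:
        raise ValueError("all trials skipped: no extractable windows")
    if skipped:
        logger.warning("%d/%d trials skipped", skipped, len(rec.events))
    return EpochSet(np.stack(epochs), np.array(labels), lag, srate,
                    np.array(trial_ids))


class Preprocessor:
    """The full conditioning chain as a transformer.

    ``fit`` runs the filters and fits the ICA decomposition on the given
    recording; ``transform`` applies the chain and returns the cleaned
    recording. ``fit_transform(rec)`` is the usual single-session path.
    ``run_ica=False`` skips the ICA stage (useful for artifact-free synthetic
    sessions where it is a costly no-op).
    """

    def __init__(self, cfg: PreprocConfig = PreprocConfig(),
                 run_ica: bool = True, random_state: int = 0):
        self.cfg = cfg
        self.run_ica = run_ica
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"cfg": self.cfg, "run_ica": self.run_ica,
                "random_state": self.random_state}

    def set_params(self, **params) -> "Preprocessor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_transform(self, rec: Recording) -> Recording:
        out = highpass_filter(rec, self.cfg)
        out = notch_filter(out, self.cfg)
        out = common_average_reference(out)
        if self.run_ica:
            out, self.ica_report_ = ica_artifact_removal(
                out, self.cfg, self.random_state)
        else:
            self.ica_report_ = None
        self.edge_exclude_ = filter_edge_samples(rec.srate, self.cfg)
        return out

    # alias pair so the object quacks like an sklearn transformer
    def fit(self, rec: Recording) -> "Preprocessor":
        self.fit_transform(rec)
        return self

    def transform(self, rec: Recording) -> Recording:
        return self.fit_transform(rec)

    def extract(self, rec: Recording, lag: float = 0.0,
                include_negative: bool | None = None) -> EpochSet:
        edge = getattr(self, "edge_exclude_", 0)
        return extract_epochs(rec, self.cfg, lag, include_negative,
                              edge_exclude=edge)


def preprocess(rec: Recording, cfg: PreprocConfig = PreprocConfig(),
               run_ica: bool = True, random_state: int = 0) -> Recording:
    """Apply high-pass -> notch -> CAR -> ICA and return the cleaned data."""
    return Preprocessor(cfg, run_ica, random_state).fit_transform(rec)


def save_epochs(es: EpochSet, path) -> None:
    """NPZ + JSON-manifest serialization of an epoch set."""
    np.savez(path, epochs=es.epochs, labels=es.labels,
             trial_ids=es.trial_ids,
             lag=np.float64(es.lag), srate=np.float64(es.srate))
    manifest = {"lag": es.lag, "srate": es.srate, "n_epochs": len(es),
                "n_positive": int(es.labels.sum())}
    from pathlib import Path
    p = Path(path)
    p.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_epochs(path) -> EpochSet:
    with np.load(path, allow_pickle=False) as z:
        return EpochSet(z["epochs"], z["labels"], float(z["lag"]),
                        float(z["srate"]), z["trial_ids"])
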