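"""Synthetic cue-paradigm EEG sessions.

Generates Graz-paradigm recordings (fixation baseline, directional arrow cue,
movement or imagery after arrow offset, inter-trial rest) whose statistical
structure carries the two pre-movement signatures an anticipation pipeline
relies on:

* a movement-related cortical potential (MRCP): a slow negativity whose early
  component starts ~1.5 s before movement onset with low amplitude and whose
  late component steepens from ~0.5 s, peaking at movement onset over the
  central midline;
* event-related desynchronization (ERD): contralateral-dominant suppression of
  the mu (8-12 Hz) and low-beta rhythms beginning together with the early
  MRCP component.

On top of these the generator layers 1/f background noise, mains interference,
and frontal blink / temporal EMG artifacts so that the downstream cleaning
chain has realistic work to do. Everything is seeded and the generated signal
is linear in every component amplitude: doubling all amplitudes with the same
seed exactly doubles the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "SessionConfig",
    "MrcpParams",
    "ErdParams",
    "NoiseParams",
    "TrialEvent",
    "Recording",
    "mrcp_waveform",
    "erd_envelope",
    "generate_session",
    "CHANNEL_NAMES_32",
]

# Approximate 2-D scalp positions (x: left->right, y: posterior->anterior is
# inverted here: +y anterior) for a standard 32-electrode 10-20 montage.
_MONTAGE_32 = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.45, 0.55), "Fz": (0.0, 0.50),
    "F4": (0.45, 0.55), "F8": (0.81, 0.59),
    "FC5": (-0.69, 0.27), "FC1": (-0.25, 0.25), "FC2": (0.25, 0.25),
    "FC6": (0.69, 0.27),
    "T7": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0), "T8": (1.0, 0.0),
    "TP9": (-1.05, -0.30), "CP5": (-0.69, -0.27), "CP1": (-0.25, -0.25),
    "CP2": (0.25, -0.25), "CP6": (0.69, -0.27), "TP10": (1.05, -0.30),
    "P7": (-0.81, -0.59), "P3": (-0.45, -0.55), "Pz": (0.0, -0.50),
    "P4": (0.45, -0.55), "P8": (0.81, -0.59),
    "PO9": (-0.63, -0.82), "O1": (-0.31, -0.95), "Oz": (0.0, -1.0),
    "O2": (0.31, -0.95), "PO10": (0.63, -0.82),
}
CHANNEL_NAMES_32 = tuple(_MONTAGE_32)


class ConfigurationError(ValueError):
    """Raised when a generator or preprocessing configuration is invalid."""


@dataclass(frozen=True)
class SessionConfig:
    """Trial-structure parameters of a cue-paradigm session.

    Defaults follow the pilot-style protocol: 18 s trials opening with a 4 s
    fixation-cross baseline and a 1 s directional arrow, 4 s inter-trial rest,
    a 15 s setup wait, 32 channels sampled at 500 Hz, and left/right trials in
    randomized, balanced order.
    """

    n_trials_per_arm: int = 8
    condition: Literal["motor_execution", "motor_imagery"] = "motor_execution"
    srate: float = 500.0
    n_channels: int = 32
    trial_length: float = 18.0
    baseline_length: float = 4.0
    arrow_length: float = 1.0
    intertrial_length: float = 4.0
    setup_wait: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.srate <= 0:
            raise ConfigurationError("srate must be positive")
        if self.n_trials_per_arm < 1:
            raise ConfigurationError("n_trials_per_arm must be >= 1")
        if self.trial_length < self.baseline_length + self.arrow_length:
            raise ConfigurationError(
                "trial_length must cover baseline + arrow cue"
            )
        if self.n_channels < 1 or self.n_channels > len(_MONTAGE_32):
            raise ConfigurationError(
                f"n_channels must be in [1, {len(_MONTAGE_32)}]"
            )

    @property
    def n_trials(self) -> int:
        return 2 * self.n_trials_per_arm

    @property
    def total_duration(self) -> float:
        return self.setup_wait + self.n_trials * (
            self.trial_length + self.intertrial_length
        )


@dataclass(frozen=True)
class MrcpParams:
    """Shape of the pre-movement negativity.

    The waveform is a two-slope ramp: flat until ``early_bp_onset`` seconds
    before movement, a shallow rise to ``early_fraction`` of the peak by
    ``late_bp_onset``, a steeper rise to ``peak_amplitude`` (negative, uV) at
    movement onset, then recovery to baseline over ``motor_potential_width``.
    """

    early_bp_onset: float = 1.5
    late_bp_onset: float = 0.5
    peak_amplitude: float = -8.0
    early_fraction: float = 0.2
    motor_potential_width: float = 0.5
    topography_sigma: float = 0.75  # Gaussian falloff from Cz; 0.8 at C3/C4
    ipsilateral_weight: float = 0.8

    def __post_init__(self) -> None:
        if not self.early_bp_onset > self.late_bp_onset > 0:
            raise ConfigurationError(
                "need early_bp_onset > late_bp_onset > 0"
            )
        if self.peak_amplitude > 0:
            raise ConfigurationError("peak_amplitude must be <= 0 (uV)")
        if not 0 < self.early_fraction < 1:
            raise ConfigurationError("early_fraction must be in (0, 1)")
        if self.motor_potential_width <= 0:
            raise ConfigurationError("motor_potential_width must be > 0")


@dataclass(frozen=True)
class ErdParams:
    """Mu/beta rhythm and its pre-movement desynchronization."""

    mu_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (13.0, 30.0)
    rhythm_amplitude: float = 3.0
    erd_onset: float = 1.5
    erd_depth: float = 0.4
    laterality: float = 1.5  # contralateral / ipsilateral ERD depth ratio
    recovery_time: float = 1.0

    def __post_init__(self) -> None:
        for lo, hi in (self.mu_band, self.beta_band):
            if not lo < hi:
                raise ConfigurationError("band lower edge must be < upper")
        if not 0 <= self.erd_depth <= 1:
            raise ConfigurationError("erd_depth must be in [0, 1]")
        if self.laterality < 1:
            raise ConfigurationError("laterality must be >= 1")


@dataclass(frozen=True)
class NoiseParams:
    """Background and artifact model.

    Amplitudes in uV; event rates in events/minute. ``line_freq`` should match
    the notch target of the preprocessing configuration.
    """

    pink_noise_sd: float = 4.0
    spatial_correlation: float = 0.3
    line_freq: float = 50.0
    line_amplitude: float = 2.0
    blink_rate: float = 2.0
    blink_amplitude: float = 80.0
    blink_duration: float = 0.3
    emg_burst_rate: float = 1.0
    emg_amplitude: float = 20.0
    emg_band: tuple[float, float] = (20.0, 100.0)
    emg_burst_duration: float = 0.5

    def __post_init__(self) -> None:
        for name in ("pink_noise_sd", "line_amplitude", "blink_amplitude",
                     "emg_amplitude", "blink_rate", "emg_burst_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TrialEvent:
    """One cue event: sample indices are 0-based into the recording."""

    cue_sample: int
    movement_sample: int
    side: Literal["left", "right"]
    condition: Literal["move", "nomove"] = "move"


@dataclass
class Recording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    srate: float
    channel_names: list[str]
    events: list[TrialEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match data rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")
        for ev in self.events:
            if not (0 <= ev.cue_sample < self.n_samples
                    and 0 <= ev.movement_sample < self.n_samples):
                raise ValueError("event sample outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.srate

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(), self.srate, list(self.channel_names),
            list(self.events),
        )


def _half_cosine(s: np.ndarray) -> np.ndarray:
    # smoothstep on [0, 1] with zero slope at both ends
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(s, 0.0, 1.0)))


def mrcp_waveform(t, p: MrcpParams = MrcpParams()):
    """MRCP amplitude (uV) at time ``t`` (s) relative to movement onset.

    Piecewise ramp with cosine-smoothed corners: zero before the early
    readiness-potential onset, ``early_fraction * peak_amplitude`` at the late
    onset, ``peak_amplitude`` at t = 0, back to zero ``motor_potential_width``
    seconds after onset. Continuous and monotone between knots.
    """
    t = np.asarray(t, dtype=np.float64)
    out = np.zeros_like(t)
    knee = p.early_fraction * p.peak_amplitude

    early = (t >= -p.early_bp_onset) & (t < -p.late_bp_onset)
    s = (t[early] + p.early_bp_onset) / (p.early_bp_onset - p.late_bp_onset)
    out[early] = knee * _half_cosine(s)

    late = (t >= -p.late_bp_onset) & (t < 0)
    s = (t[late] + p.late_bp_onset) / p.late_bp_onset
    out[late] = knee + (p.peak_amplitude - knee) * _half_cosine(s)

    rec = (t >= 0) & (t < p.motor_potential_width)
    s = t[rec] / p.motor_potential_width
    out[rec] = p.peak_amplitude * (1.0 - _half_cosine(s))
    return out


def erd_envelope(t, p: ErdParams = ErdParams()):
    """Multiplicative rhythm gain at time ``t`` (s) relative to movement.

    1 before ``erd_onset`` seconds pre-movement, smoothly decreasing to
    ``1 - erd_depth`` at movement onset, held there briefly, recovering to 1
    over ``recovery_time``.
    """
    t = np.asarray(t, dtype=np.float64)
    gain = np.ones_like(t)
    floor = 1.0 - p.erd_depth

    drop = (t >= -p.erd_onset) & (t < 0)
    s = (t[drop] + p.erd_onset) / p.erd_onset
    gain[drop] = 1.0 - p.erd_depth * _half_cosine(s)

    hold = (t >= 0) & (t < 0.5)
    gain[hold] = floor

    rec = (t >= 0.5) & (t < 0.5 + p.recovery_time)
    s = (t[rec] - 0.5) / p.recovery_time
    gain[rec] = floor + p.erd_depth * _half_cosine(s)
    return gain


def _positions(channel_names: list[str]) -> np.ndarray:
    return np.array([_MONTAGE_32[c] for c in channel_names])


def _mrcp_topography(channel_names: list[str], side: str,
                     p: MrcpParams) -> np.ndarray:
    """Per-channel MRCP gain: Gaussian falloff from Cz, max gain 1.

    For lateralized trials the hemisphere ipsilateral to the moving arm is
    down-weighted, leaving the contralateral hand area dominant.
    """
    pos = _positions(channel_names)
    d2 = (pos ** 2).sum(axis=1)  # Cz at origin
    gain = np.exp(-d2 / (2.0 * p.topography_sigma ** 2))
    x = pos[:, 0]
    ipsi = x < 0 if side == "left" else x > 0
    gain = np.where(ipsi, gain * p.ipsilateral_weight, gain)
    return gain / gain.max()


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int) -> np.ndarray:
    """Unit-variance 1/f ('pink') noise, channels x samples."""
    from scipy.fft import next_fast_len

    m = next_fast_len(n)  # avoid slow prime-length transforms
    white = rng.standard_normal((n_ch, m))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(m)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # no DC
    pink = np.fft.irfft(spec * scale, n=m, axis=1)[:, :n]
    sd = pink.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def _bandlimited_noise(rng: np.random.Generator, n_ch: int, n: int,
                       band: tuple[float, float],
                       srate: float) -> np.ndarray:
    """Unit-RMS Gaussian noise restricted to a frequency band."""
    from scipy.fft import next_fast_len

    m = next_fast_len(n)
    white = rng.standard_normal((n_ch, m))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(m, d=1.0 / srate)
    lo, hi = band
    spec[:, (f < lo) | (f > min(hi, srate / 2))] = 0.0
    out = np.fft.irfft(spec, n=m, axis=1)[:, :n]
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _poisson_times(rng: np.random.Generator, rate_per_min: float,
                   duration: float) -> np.ndarray:
    lam = rate_per_min / 60.0 * duration
    n = rng.poisson(lam)
    return np.sort(rng.uniform(0.0, duration, size=n))


def generate_session(
    cfg: SessionConfig = SessionConfig(),
    mrcp: MrcpParams = MrcpParams(),
    erd: ErdParams = ErdParams(),
    noise: NoiseParams = NoiseParams(),
) -> Recording:
    """Simulate one cue-paradigm session.

    The event list carries exactly ``2 * cfg.n_trials_per_arm`` cue events
    with balanced, seeded-shuffled sides. Each trial's signal is the sum of
    background noise, line interference, artifacts, a topography-weighted
    MRCP time-locked to movement onset, and ERD-modulated mu/beta rhythms.
    Identical inputs (including seed) reproduce the output bit for bit.
    """
    srate = cfg.srate
    n_samples = int(round(cfg.total_duration * srate))
    names = list(CHANNEL_NAMES_32[: cfg.n_channels])
    pos = _positions(names)
    t_global = np.arange(n_samples) / srate

    # independent, amplitude-agnostic random streams: draw structure first so
    # that amplitudes only ever scale the output (linearity invariant)
    root = np.random.SeedSequence(cfg.seed)
    keys = ("sides", "pink", "line", "rhythm", "blink", "emg")
    rngs = {k: np.random.default_rng(s)
            for k, s in zip(keys, root.spawn(len(keys)))}

    sides = ["left"] * cfg.n_trials_per_arm + ["right"] * cfg.n_trials_per_arm
    order = rngs["sides"].permutation(cfg.n_trials)
    sides = [sides[i] for i in order]

    condition = "move" if cfg.condition == "motor_execution" else "nomove"
    events = []
    for i, side in enumerate(sides):
        start = cfg.setup_wait + i * (cfg.trial_length + cfg.intertrial_length)
        cue = int(round((start + cfg.baseline_length) * srate))
        movement = cue + int(round(cfg.arrow_length * srate))
        events.append(TrialEvent(cue, movement, side, condition))

    data = np.zeros((cfg.n_channels, n_samples))

    # --- background: per-channel pink noise + spatially shared component
    pink = _pink_noise(rngs["pink"], cfg.n_channels, n_samples)
    shared = _pink_noise(rngs["pink"], 1, n_samples)
    data += noise.pink_noise_sd * (
        pink + noise.spatial_correlation * shared
    )

    # --- mains interference: common phase, mild per-channel gain spread
    phase = rngs["line"].uniform(0, 2 * np.pi)
    gains = 1.0 + 0.1 * rngs["line"].standard_normal(cfg.n_channels)
    data += noise.line_amplitude * gains[:, None] * np.sin(
        2 * np.pi * noise.line_freq * t_global + phase
    )

    # --- ongoing rhythms with per-trial ERD modulation; carriers are
    # band-limited noise (stochastic phase, like real mu/beta rhythms),
    # so with zero ERD depth the windows carry no trial-locked structure
    rhythm_gain = np.exp(-(pos ** 2).sum(axis=1) / (2 * 0.9 ** 2))
    for band, rel_amp in ((erd.mu_band, 1.0), (erd.beta_band, 0.5)):
        carrier = _bandlimited_noise(rngs["rhythm"], cfg.n_channels,
                                     n_samples, band, srate)
        env = np.ones((cfg.n_channels, n_samples))
        for ev, side in zip(events, sides):
            t_rel = t_global - ev.movement_sample / srate
            mask = (t_rel >= -erd.erd_onset) & (
                t_rel < 0.5 + erd.recovery_time)
            if not mask.any():
                continue
            g = erd_envelope(t_rel[mask], erd)
            # contralateral hemisphere desynchronizes fully; ipsilateral
            # by 1/laterality of the depth
            contra = pos[:, 0] > 0 if side == "left" else pos[:, 0] < 0
            depth_scale = np.where(contra, 1.0, 1.0 / erd.laterality)
            env[:, mask] *= 1.0 - depth_scale[:, None] * (1.0 - g[None, :])
        data += erd.rhythm_amplitude * rel_amp * (
            rhythm_gain[:, None] * env * carrier
        )

    # --- MRCP, time-locked to each movement onset
    span = (mrcp.early_bp_onset, mrcp.motor_potential_width)
    for ev, side in zip(events, sides):
        topo = _mrcp_topography(names, side, mrcp)
        lo = max(0, ev.movement_sample - int(np.ceil(span[0] * srate)) - 1)
        hi = min(n_samples,
                 ev.movement_sample + int(np.ceil(span[1] * srate)) + 1)
        t_rel = (np.arange(lo, hi) - ev.movement_sample) / srate
        data[:, lo:hi] += topo[:, None] * mrcp_waveform(t_rel, mrcp)[None, :]

    # --- blinks: frontal-weighted biphasic pulses
    frontal = np.clip(pos[:, 1], 0.0, None) ** 2
    frontal = frontal / frontal.max() if frontal.max() > 0 else frontal
    blink_n = int(round(noise.blink_duration * srate))
    tau = np.linspace(0, 1, blink_n, endpoint=False)
    blink_shape = np.sin(2 * np.pi * tau) * np.sin(np.pi * tau)
    for t0 in _poisson_times(rngs["blink"], noise.blink_rate,
                             cfg.total_duration):
        s0 = int(t0 * srate)
        seg = slice(s0, min(s0 + blink_n, n_samples))
        w = blink_shape[: seg.stop - seg.start]
        data[:, seg] += noise.blink_amplitude * frontal[:, None] * w[None, :]

    # --- EMG: band-limited bursts on temporal channels
    temporal = np.clip(np.abs(pos[:, 0]) - 0.6, 0.0, None)
    temporal = temporal / temporal.max() if temporal.max() > 0 else temporal
    burst_n = int(round(noise.emg_burst_duration * srate))
    for t0 in _poisson_times(rngs["emg"], noise.emg_burst_rate,
                             cfg.total_duration):
        raw = rngs["emg"].standard_normal(burst_n)
        spec = np.fft.rfft(raw)
        f = np.fft.rfftfreq(burst_n, d=1.0 / srate)
        lo, hi = noise.emg_band
        spec[(f < lo) | (f > min(hi, srate / 2))] = 0.0
        burst = np.fft.irfft(spec, n=burst_n)
        sd = burst.std()
        if sd > 0:
            burst = burst / sd
        burst *= np.hanning(burst_n)
        s0 = int(t0 * srate)
        seg = slice(s0, min(s0 + burst_n, n_samples))
        w = burst[: seg.stop - seg.start]
        data[:, seg] += noise.emg_amplitude * temporal[:, None] * w[None, :]

    return Recording(data, srate, names, events)


def scale_amplitudes(mrcp: MrcpParams, erd: ErdParams, noise: NoiseParams,
                     factor: float):
    """Return copies of the parameter sets with every amplitude scaled.

    Convenience for linearity checks: the generated signal is linear in the
    amplitudes, so scaling them all by ``factor`` (same seed) scales the
    output by ``factor``.
    """
    return (
        replace(mrcp, peak_amplitude=mrcp.peak_amplitude * factor),
        replace(erd, rhythm_amplitude=erd.rhythm_amplitude * factor),
        replace(noise,
                pink_noise_sd=noise.pink_noise_sd * factor,
                line_amplitude=noise.line_amplitude * factor,
                blink_amplitude=noise.blink_amplitude * factor,
                emg_amplitude=noise.emg_amplitude * factor),
    )
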