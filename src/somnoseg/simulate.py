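"""Synthetic polysomnography: continuous truth, signals, and a 30-s scorer.

The generator produces everything the pipeline needs end to end with no
data download:

* a continuous two-state ground truth — an alternating renewal process
  of sleep and wake bouts with short wake-like intrusions (arousal
  analogues, >= 3 s, preceded by >= 10 s of uninterrupted sleep)
  inserted into sleep at a configurable hourly rate;
* spectrally distinct EEG/EOG-like signals — sleep carries delta/theta
  dominance, wakefulness-like segments carry an 8-12 Hz alpha rhythm
  plus elevated broadband power, with raised-cosine crossfades at state
  changes and slow (<1 Hz) EOG rolling waves near wake-to-sleep
  transitions;
* a simulated conventional scorer that reduces the continuous truth to
  30-second majority-stage epochs plus arousal event intervals (marked
  regardless of the epoch's own label, as scoring guidelines require).

Because the conventional scoring is a deterministic function of the
continuous truth, the post hoc label modifications can be validated
against known ground truth on every simulated night.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ContractError
from .hypnogram import (SLEEP, WAKE_LIKE, ArousalEvents, ContinuousHypnogram,
                        EpochHypnogram, wake_overlap)
from .signal_io import Channel, PsgRecord


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated night.

    Durations are seconds, amplitudes are microvolts. The defaults are
    the package's standard scaled-down night: 30 minutes of moderately
    fragmented sleep (mean sleep bout 5 min, mean wake bout 1 min,
    arousal intrusions at 10 per hour of sleep).
    """

    duration_s: float = 1800.0
    mean_sleep_bout_s: float = 300.0
    mean_wake_bout_s: float = 60.0
    arousal_rate_per_h: float = 10.0
    arousal_min_s: float = 3.0
    arousal_mean_extra_s: float = 4.0
    stable_sleep_s: float = 10.0
    fs: float = 128.0
    eeg_channels: tuple[str, ...] = ("C4-M1", "Cz-Oz")
    eog_channels: tuple[str, ...] = ("E1-FPz",)
    sleep_delta_amp: float = 30.0
    sleep_theta_amp: float = 20.0
    sleep_alpha_amp: float = 0.0  # alpha intrusion into sleep (0 = none)
    wake_alpha_amp: float = 25.0
    wake_broadband_amp: float = 6.0
    base_noise_amp: float = 5.0
    alpha_center_hz: float = 10.0
    alpha_halfwidth_hz: float = 2.0
    crossfade_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.mean_sleep_bout_s <= 0:
            raise ContractError("durations must be positive")
        if self.arousal_min_s < 3.0:
            raise ContractError("arousal minimum duration must be >= 3 s")
        if self.stable_sleep_s < 10.0:
            raise ContractError("stable-sleep gap must be >= 10 s")
        # mean arousal cycle (gap + event) must fit the requested rate
        cycle = self.stable_sleep_s + self.arousal_min_s + self.arousal_mean_extra_s
        if self.arousal_rate_per_h * cycle / 3600.0 >= 1.0:
            raise ContractError(
                f"arousal rate {self.arousal_rate_per_h}/h is infeasible with a "
                f">= {self.stable_sleep_s} s stable-sleep gap before each event"
            )


@dataclass(frozen=True)
class ShiftConfig:
    """Distribution shift emulating a new scorer/population.

    The defaults model an older/clinical cohort with attenuated wake
    alpha, alpha intrusion into sleep ("alpha-delta sleep"), weaker
    slow-wave content, and more fragmented sleep — enough to move the
    class-conditional spectra across a boundary learned on the default
    population, so that fine-tuning is actually needed.
    """

    alpha_amp_factor: float = 0.45
    broadband_factor: float = 1.8
    theta_amp_factor: float = 0.6
    delta_amp_factor: float = 0.6
    sleep_alpha_amp: float = 12.0  # absolute µV of alpha intrusion in sleep
    mean_sleep_factor: float = 0.7
    mean_wake_factor: float = 1.0
    arousal_rate_factor: float = 1.5


def apply_shift(cfg: SimConfig, shift: ShiftConfig) -> SimConfig:
    return dataclasses.replace(
        cfg,
        wake_alpha_amp=cfg.wake_alpha_amp * shift.alpha_amp_factor,
        wake_broadband_amp=cfg.wake_broadband_amp * shift.broadband_factor,
        sleep_theta_amp=cfg.sleep_theta_amp * shift.theta_amp_factor,
        sleep_delta_amp=cfg.sleep_delta_amp * shift.delta_amp_factor,
        sleep_alpha_amp=shift.sleep_alpha_amp,
        mean_sleep_bout_s=cfg.mean_sleep_bout_s * shift.mean_sleep_factor,
        mean_wake_bout_s=cfg.mean_wake_bout_s * shift.mean_wake_factor,
        arousal_rate_per_h=cfg.arousal_rate_per_h * shift.arousal_rate_factor,
    )


@dataclass(frozen=True)
class SyntheticNight:
    """One simulated recording bundle."""

    truth: ContinuousHypnogram
    record: PsgRecord
    epochs: EpochHypnogram
    arousals: ArousalEvents
    participant_id: str
    seed: int


# ---------------------------------------------------------------------------
# Ground-truth process
# ---------------------------------------------------------------------------

def simulate_truth(cfg: SimConfig,
                   rng: np.random.Generator | None = None) -> ContinuousHypnogram:
    """Sample a continuous sleep/wake-like process.

    Macro-structure is an alternating renewal process with exponential
    bout durations (the recording starts awake, at lights-off). Arousal
    analogues are then inserted into sleep bouts as a Poisson process at
    ``arousal_rate_per_h`` per hour of sleep; candidates violating the
    >= 10 s preceding-sleep constraint or not fitting inside the bout
    are rejected.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    T = cfg.duration_s
    bouts: list[tuple[float, float, int]] = []
    if np.isinf(cfg.mean_wake_bout_s) or cfg.mean_wake_bout_s <= 0:
        bouts.append((0.0, T, SLEEP))
    else:
        t, state = 0.0, WAKE_LIKE
        while t < T:
            mean = (cfg.mean_wake_bout_s if state == WAKE_LIKE
                    else cfg.mean_sleep_bout_s)
            d = rng.exponential(mean)
            bouts.append((t, min(t + d, T), state))
            t += d
            state = 1 - state

    intervals: list[tuple[float, float, int]] = []
    for a, b, s in bouts:
        if s == WAKE_LIKE or cfg.arousal_rate_per_h <= 0:
            intervals.append((a, b, s))
            continue
        n_cand = rng.poisson(cfg.arousal_rate_per_h * (b - a) / 3600.0)
        onsets = np.sort(rng.uniform(a, b, size=n_cand))
        cursor = a  # start of the current uninterrupted sleep stretch
        events = []
        for on in onsets:
            dur = cfg.arousal_min_s + rng.exponential(cfg.arousal_mean_extra_s)
            if on - cursor < cfg.stable_sleep_s or on + dur > b:
                continue
            events.append((on, on + dur))
            cursor = on + dur
        t0 = a
        for on, off in events:
            if on > t0:
                intervals.append((t0, on, SLEEP))
            intervals.append((on, off, WAKE_LIKE))
            t0 = off
        if t0 < b:
            intervals.append((t0, b, SLEEP))
    return ContinuousHypnogram.from_intervals(intervals)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _unit_rms(x: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _band_noise(rng, n, fs, low, high):
    white = rng.standard_normal(n)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return _unit_rms(sps.sosfilt(sos, white))


def _pink_noise(rng, n):
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    return _unit_rms(np.fft.irfft(spec / np.sqrt(f), n))


def _wake_envelope(truth: ContinuousHypnogram, n: int, fs: float,
                   crossfade_s: float) -> np.ndarray:
    """Per-sample wake activation in [0, 1] with raised-cosine crossfades."""
    t = (np.arange(n) + 0.5) / fs + truth.onset_s
    w = np.zeros(n)
    for a, b, s in truth.intervals:
        if s == WAKE_LIKE:
            w[(t >= a) & (t < b)] = 1.0
    m = max(int(round(crossfade_s * fs)), 1)
    win = np.hanning(2 * m + 1)
    win /= win.sum()
    return np.convolve(np.pad(w, m, mode="edge"), win, mode="valid")[:n]


def synthesize_signals(truth: ContinuousHypnogram, cfg: SimConfig,
                       rng: np.random.Generator | None = None) -> PsgRecord:
    """Render state-dependent EEG/EOG-like signals for a truth process.

    Each channel is an independent realization sharing the same truth:
    pink base noise plus a sleep component (delta 0.5-3 Hz + theta
    4-7 Hz) and a wake component (alpha around ``alpha_center_hz`` +
    broadband white), mixed by the crossfaded wake envelope. EOG
    channels additionally carry slow (<1 Hz) rolling waves around
    wake-to-sleep transitions.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = int(round(truth.duration_s * fs))
    w = _wake_envelope(truth, n, fs, cfg.crossfade_s)
    ws_boundaries = [b for (a, b, s), nxt in
                     zip(truth.intervals[:-1], truth.intervals[1:])
                     if s == WAKE_LIKE and nxt[2] == SLEEP]
    t = (np.arange(n) + 0.5) / fs + truth.onset_s
    channels = []
    for name in tuple(cfg.eeg_channels) + tuple(cfg.eog_channels):
        base = cfg.base_noise_amp * _pink_noise(rng, n)
        delta = cfg.sleep_delta_amp * _band_noise(rng, n, fs, 0.5, 3.0)
        theta = cfg.sleep_theta_amp * _band_noise(rng, n, fs, 4.0, 7.0)
        alpha = cfg.wake_alpha_amp * _band_noise(
            rng, n, fs, cfg.alpha_center_hz - cfg.alpha_halfwidth_hz,
            cfg.alpha_center_hz + cfg.alpha_halfwidth_hz)
        broad = cfg.wake_broadband_amp * _unit_rms(rng.standard_normal(n))
        sleep_comp = delta + theta
        if cfg.sleep_alpha_amp > 0:
            sleep_comp = sleep_comp + cfg.sleep_alpha_amp * _band_noise(
                rng, n, fs, cfg.alpha_center_hz - cfg.alpha_halfwidth_hz,
                cfg.alpha_center_hz + cfg.alpha_halfwidth_hz)
        x = base + (1 - w) * sleep_comp + w * (alpha + broad)
        if name in cfg.eog_channels:
            roll = np.zeros(n)
            for tb in ws_boundaries:
                lo, hi = tb - 2.5, tb + 7.5
                mask = (t >= lo) & (t < hi)
                phase = 2 * np.pi * 0.3 * (t[mask] - lo)
                env = np.sin(np.pi * (t[mask] - lo) / (hi - lo)) ** 2
                roll[mask] += 25.0 * np.sin(phase) * env
            x = x + roll
        channels.append(Channel(name, x, fs))
    return PsgRecord(tuple(channels))


# ---------------------------------------------------------------------------
# Simulated conventional scorer
# ---------------------------------------------------------------------------

def conventional_scorer(truth: ContinuousHypnogram, epoch_len_s: float = 30.0
                        ) -> tuple[EpochHypnogram, ArousalEvents]:
    """Reduce continuous truth to 30-s epochs + arousal events.

    An epoch is scored W when wakefulness-like strictly exceeds half of
    it (an exact 50/50 split stays sleep — scorer conservatism); sleep
    epochs are emitted as N2 since stage identity is irrelevant after
    binarization. Arousal events are all truth wake-like intervals of
    duration >= 3 s preceded by >= 10 s of sleep, marked regardless of
    the containing epoch's label.
    """
    span = truth.duration_s
    n_epochs = int(np.floor(span / epoch_len_s + 1e-9))
    if n_epochs < 1:
        raise ContractError("truth span shorter than one epoch")
    edges = truth.onset_s + epoch_len_s * np.arange(n_epochs + 1)
    wake = wake_overlap(truth, edges)
    stages = tuple("W" if wk > epoch_len_s / 2 + 1e-9 else "N2" for wk in wake)
    events = []
    for prev, cur in zip(truth.intervals[:-1], truth.intervals[1:]):
        if (cur[2] == WAKE_LIKE and cur[1] - cur[0] >= 3.0 - 1e-9
                and prev[2] == SLEEP and prev[1] - prev[0] >= 10.0 - 1e-9):
            events.append((cur[0], cur[1]))
    return (EpochHypnogram(stages, epoch_len_s, truth.onset_s),
            ArousalEvents(tuple(events)))


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

def simulate_night(cfg: SimConfig, participant_id: str = "P000",
                   seed: int | None = None) -> SyntheticNight:
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    truth = simulate_truth(cfg, rng)
    record = synthesize_signals(truth, cfg, rng)
    epochs, arousals = conventional_scorer(truth)
    return SyntheticNight(truth, record, epochs, arousals, participant_id, seed)


def make_dataset(n_nights: int, cfg: SimConfig,
                 shift: ShiftConfig | None = None,
                 repeat_participants: int = 0,
                 seed: int | None = None) -> list[SyntheticNight]:
    """Generate a reproducible cohort of synthetic nights.

    ``repeat_participants`` participants contribute two nights each (the
    rest one night each); ``shift`` perturbs spectral and bout
    statistics to emulate a different population/scorer for the
    transfer-learning experiment.
    """
    if n_nights < 1:
        raise ContractError("n_nights must be >= 1")
    if 2 * repeat_participants > n_nights:
        raise ContractError("too many repeated participants for n_nights")
    if shift is not None:
        cfg = apply_shift(cfg, shift)
    base_seed = cfg.seed if seed is None else seed
    night_seeds = np.random.SeedSequence(base_seed).generate_state(n_nights)
    ids = []
    for k in range(repeat_participants):
        ids += [f"P{k:03d}", f"P{k:03d}"]
    nxt = repeat_participants
    while len(ids) < n_nights:
        ids.append(f"P{nxt:03d}")
        nxt += 1
    return [
        simulate_night(cfg, pid, int(s) % (2 ** 31))
        for pid, s in zip(ids, night_seeds)
    ]
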