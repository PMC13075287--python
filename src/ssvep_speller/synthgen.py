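"""Synthetic two-channel SSVEP EEG and frame-locked flicker schedules.

This module is the hardware-free test bed for the whole pipeline.  It
emulates what the acquisition side of the speller produces:

* flicker schedules whose frequencies are integer divisions of the display
  refresh rate (60 Hz -> frame periods 9, 8, 7, 6, 5 -> 6.67, 7.5, 8.57,
  10, 12 Hz);
* occipital EEG as a sum of a stimulus-locked sinusoidal SSVEP response
  (with harmonics), 1/f^alpha background noise, a ~10 Hz alpha idle rhythm
  (deliberately colliding with the 10 Hz stimulus), and power-line
  interference, on two imperfectly correlated channels (common SSVEP source
  with per-channel gain and phase offset, independent noise).

Everything is a pure function of (config, seed): identical inputs produce
bit-identical sample arrays.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .commands import (
    ACTIVE_COMMANDS,
    Command,
    STIMULUS_FREQUENCIES_HZ,
    map_frequency_to_command,
)


class FrameLockError(ValueError):
    """A requested flicker frequency is not an integer division of refresh."""


@dataclass(frozen=True)
class FlickerSpec:
    """One flicker stimulus: a command tile blinking at refresh/frame_period."""

    command: Command | None
    nominal_freq_hz: float
    frame_period: int
    realized_freq_hz: float


def make_flicker_schedule(
    frequencies_hz: list[float] | tuple[float, ...],
    refresh_hz: float = 60.0,
    duration_s: float = 0.0,
    on_frames: str = "ceil",
):
    """Build frame-locked flicker specs and a per-frame on/off timeline.

    Each frequency must be representable as ``refresh_hz / k`` for an
    integer ``k >= 2`` within 0.01 Hz, otherwise a :class:`FrameLockError`
    names the offending frequency.  The duty cycle is 50%: for odd frame
    periods the "on" phase takes ``ceil(k/2)`` frames by default
    (``on_frames="floor"`` flips the convention).

    Returns ``(specs, timeline)`` where ``timeline`` is a boolean array of
    shape ``(n_frames, n_frequencies)`` and ``n_frames =
    round(duration_s * refresh_hz)``.
    """
    if refresh_hz <= 0:
        raise ValueError("refresh_hz must be positive")
    if on_frames not in ("ceil", "floor"):
        raise ValueError("on_frames must be 'ceil' or 'floor'")
    specs: list[FlickerSpec] = []
    for f in frequencies_hz:
        if f <= 0:
            raise FrameLockError(f"{f} Hz is not a positive frequency")
        k = int(round(refresh_hz / f))
        if k < 2 or abs(refresh_hz / k - f) >= 0.01:
            raise FrameLockError(
                f"{f} Hz is not frame-locked to a {refresh_hz} Hz refresh "
                f"(nearest integer division {refresh_hz}/{k} = {refresh_hz / max(k, 1):.4f} Hz)"
            )
        try:
            cmd = map_frequency_to_command(f)
        except ValueError:
            cmd = None
        specs.append(
            FlickerSpec(
                command=cmd,
                nominal_freq_hz=float(f),
                frame_period=k,
                realized_freq_hz=refresh_hz / k,
            )
        )
    n_frames = int(round(duration_s * refresh_hz))
    timeline = np.zeros((n_frames, len(specs)), dtype=bool)
    frame_idx = np.arange(n_frames)
    for j, spec in enumerate(specs):
        k = spec.frame_period
        n_on = math.ceil(k / 2) if on_frames == "ceil" else k // 2
        timeline[:, j] = (frame_idx % k) < n_on
    return specs, timeline


def realized_frequencies(
    frequencies_hz=STIMULUS_FREQUENCIES_HZ, refresh_hz: float = 60.0
) -> dict[Command, float]:
    """Command -> exact frame-locked frequency (e.g. DOWN -> 60/7 Hz)."""
    specs, _ = make_flicker_schedule(frequencies_hz, refresh_hz, 0.0)
    return {s.command: s.realized_freq_hz for s in specs if s.command is not None}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic EEG generator.

    Amplitudes are in microvolts.  ``ssvep_amp_uV[h-1]`` is the amplitude of
    the h-th harmonic of the attended frequency; the background is
    1/f^``noise_exponent`` Gaussian noise scaled to ``noise_rms_uV``, plus a
    narrowband alpha rhythm near ``alpha_freq_hz`` and a power-line
    sinusoid.  The SSVEP source is common to all channels up to a
    per-channel gain and phase offset; the noise terms are independent per
    channel (line noise shares its phase).  ``response_latency_s`` delays
    the entrained response after stimulus onset (and sustains it equally
    long after offset).
    """

    fs_hz: float = 200.0
    n_channels: int = 2
    ssvep_amp_uV: tuple[float, ...] = (1.0, 0.4, 0.15)
    noise_exponent: float = 1.0
    noise_rms_uV: float = 1.0
    sensor_noise_rms_uV: float = 0.0
    alpha_band_amp_uV: float = 0.7
    alpha_freq_hz: float = 10.0
    line_noise_hz: float = 60.0
    line_noise_amp_uV: float = 0.3
    channel_gain: tuple[float, ...] = (1.0, 0.85)
    channel_phase_jitter_rad: tuple[float, ...] = (0.0, 0.35)
    response_latency_s: float = 0.14
    seed: int = 0

    def __post_init__(self):
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if any(a < 0 for a in self.ssvep_amp_uV):
            raise ValueError("SSVEP amplitudes must be >= 0")
        if min(self.noise_rms_uV, self.sensor_noise_rms_uV, self.alpha_band_amp_uV, self.line_noise_amp_uV) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if len(self.channel_gain) < self.n_channels:
            raise ValueError("channel_gain shorter than n_channels")
        if len(self.channel_phase_jitter_rad) < self.n_channels:
            raise ValueError("channel_phase_jitter_rad shorter than n_channels")
        fmax = max(STIMULUS_FREQUENCIES_HZ) * max(1, len(self.ssvep_amp_uV))
        if self.fs_hz <= 2 * fmax:
            raise ValueError(
                f"fs_hz = {self.fs_hz} must exceed twice the highest SSVEP "
                f"harmonic ({fmax} Hz)"
            )

    def with_snr(self, scale: float) -> "SimConfig":
        """Copy with all SSVEP harmonic amplitudes multiplied by ``scale``."""
        return dataclasses.replace(
            self, ssvep_amp_uV=tuple(a * scale for a in self.ssvep_amp_uV)
        )

    def with_seed(self, seed: int) -> "SimConfig":
        return dataclasses.replace(self, seed=int(seed))


def _shaped_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """Unit-RMS Gaussian noise with a 1/f^exponent amplitude spectrum."""
    white = rng.standard_normal(n)
    if exponent == 0 or n < 4:
        x = white
    else:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        scale = np.zeros_like(f)
        scale[1:] = f[1:] ** (-exponent / 2.0)
        x = np.fft.irfft(spec * scale, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _alpha_rhythm(
    rng: np.random.Generator, n: int, fs: float, f0: float, width_hz: float = 0.6
) -> np.ndarray:
    """Unit-RMS narrowband noise centered at ``f0`` (waxing/waning alpha)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = np.exp(-0.5 * ((f - f0) / width_hz) ** 2)
    x = np.fft.irfft(spec * mask, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _background(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    """Ongoing (non-stimulus) EEG: 1/f noise + alpha + line, per channel."""
    fs = config.fs_hz
    t = np.arange(n) / fs
    line_phase = rng.uniform(0, 2 * np.pi)
    out = np.empty((n, config.n_channels))
    for c in range(config.n_channels):
        x = config.noise_rms_uV * _shaped_noise(rng, n, fs, config.noise_exponent)
        if config.sensor_noise_rms_uV > 0:
            x = x + config.sensor_noise_rms_uV * rng.standard_normal(n)
        if config.alpha_band_amp_uV > 0:
            x = x + config.alpha_band_amp_uV * _alpha_rhythm(
                rng, n, fs, config.alpha_freq_hz
            )
        if config.line_noise_amp_uV > 0:
            x = x + config.line_noise_amp_uV * np.sin(
                2 * np.pi * config.line_noise_hz * t + line_phase
            )
        out[:, c] = x
    return out


def _ssvep_waveform(
    config: SimConfig, t: np.ndarray, f_hz: float, stimulus_phase: float
) -> np.ndarray:
    """Common-source harmonic SSVEP sampled at times ``t`` for each channel."""
    out = np.zeros((t.size, config.n_channels))
    for c in range(config.n_channels):
        phase_c = stimulus_phase + config.channel_phase_jitter_rad[c]
        wave = np.zeros_like(t)
        for h, amp in enumerate(config.ssvep_amp_uV, start=1):
            if amp > 0:
                wave += amp * np.sin(2 * np.pi * h * f_hz * t + h * phase_c)
        out[:, c] = config.channel_gain[c] * wave
    return out


def simulate_ssvep_epoch(config: SimConfig, attended_freq_hz: float | None, duration_s: float):
    """One epoch of synthetic EEG, attending a single frequency (or resting).

    Returns a :class:`~ssvep_speller.preprocess.SignalWindow` of
    ``round(duration_s * fs)`` samples by ``n_channels``.  When
    ``attended_freq_hz`` is set, the entrained response starts
    ``response_latency_s`` after epoch onset; when ``None`` the epoch is
    background activity only.
    """
    from .preprocess import SignalWindow  # local import avoids cycle

    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(config.seed)
    n = int(round(duration_s * config.fs_hz))
    samples = _background(rng, n, config)
    if attended_freq_hz is not None:
        t = np.arange(n) / config.fs_hz
        phase = rng.uniform(0, 2 * np.pi)
        wave = _ssvep_waveform(config, t - config.response_latency_s, float(attended_freq_hz), phase)
        wave[t < config.response_latency_s] = 0.0
        samples = samples + wave
    return SignalWindow(samples=samples, fs_hz=config.fs_hz, t_start_s=0.0)


@dataclass(frozen=True)
class ProtocolScript:
    """Ordered attend/rest schedule: (command or NONE, dwell seconds)."""

    entries: tuple[tuple[Command, float], ...]
    inter_command_gap_s: float = 2.0

    def __post_init__(self):
        for cmd, dwell in self.entries:
            if dwell <= 0:
                raise ValueError("dwell_s must be positive")

    @property
    def n_selections(self) -> int:
        return sum(1 for cmd, _ in self.entries if cmd != Command.NONE)

    def total_duration_s(self) -> float:
        dwell = sum(d for _, d in self.entries)
        return dwell + self.inter_command_gap_s * len(self.entries)

    @staticmethod
    def experiment1(
        n_sets: int = 1,
        dwell_s: float = 3.0,
        gap_s: float = 2.0,
        seed: int | None = None,
    ) -> "ProtocolScript":
        """Single-step command recognition: each of the five commands twice
        per set (10 selections/set), order shuffled within each set."""
        rng = np.random.default_rng(seed)
        entries = []
        for _ in range(n_sets):
            block = list(ACTIVE_COMMANDS) * 2
            if seed is not None:
                rng.shuffle(block)
            entries.extend((cmd, dwell_s) for cmd in block)
        return ProtocolScript(entries=tuple(entries), inter_command_gap_s=gap_s)

    @staticmethod
    def from_commands(
        commands, dwell_s: float = 3.0, gap_s: float = 2.0
    ) -> "ProtocolScript":
        return ProtocolScript(
            entries=tuple((cmd, dwell_s) for cmd in commands),
            inter_command_gap_s=gap_s,
        )


@dataclass
class Session:
    """A continuous labeled synthetic recording."""

    samples: np.ndarray  # (n, C) microvolts
    fs_hz: float
    labels: np.ndarray  # (n,) command-name strings, "NONE" during rest
    segments: list  # [(Command, t_on_s, t_off_s)] attend segments only

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.fs_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.samples.shape[0]) / self.fs_hz


def simulate_session(
    script: ProtocolScript,
    config: SimConfig,
    frequencies: dict[Command, float] | None = None,
) -> Session:
    """Render a protocol script into a continuous labeled EEG stream.

    ``frequencies`` maps commands to the stimulation frequency actually
    flickered; by default the frame-locked realizations on a 60 Hz refresh
    (60/9, 60/8, 60/7, 60/6, 60/5 Hz).  Each attend segment gets the
    attended command's SSVEP waveform (delayed by the response latency and
    sustained equally long past offset), with an independent random
    stimulus phase per segment; rest gaps carry background only.
    """
    if not script.entries:
        return Session(
            samples=np.zeros((0, config.n_channels)),
            fs_hz=config.fs_hz,
            labels=np.array([], dtype=object),
            segments=[],
        )
    if frequencies is None:
        frequencies = realized_frequencies()
    fs = config.fs_hz
    rng = np.random.default_rng(config.seed)

    # Lay out segment boundaries on the sample clock.
    bounds = []  # (command, i_on, i_off)
    i = 0
    for cmd, dwell in script.entries:
        n_dwell = int(round(dwell * fs))
        bounds.append((cmd, i, i + n_dwell))
        i += n_dwell + int(round(script.inter_command_gap_s * fs))
    n_total = i
    samples = _background(rng, n_total, config)
    labels = np.full(n_total, Command.NONE.value, dtype=object)
    segments = []

    lat = config.response_latency_s
    n_lat = int(round(lat * fs))
    for cmd, i_on, i_off in bounds:
        if cmd == Command.NONE:
            continue
        f = frequencies[cmd]
        phase = rng.uniform(0, 2 * np.pi)
        j0, j1 = i_on + n_lat, min(i_off + n_lat, n_total)
        t = (np.arange(j0, j1) - i_on) / fs - lat
        samples[j0:j1] += _ssvep_waveform(config, t, f, phase)
        labels[i_on:i_off] = cmd.value
        segments.append((cmd, i_on / fs, i_off / fs))
    return Session(samples=samples, fs_hz=fs, labels=labels, segments=segments)
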