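"""Online-style preprocessing: detrending, IIR filtering, sliding windows.

Mirrors the real-time pipeline: a causal second-order Butterworth band-pass
(5-45 Hz) followed by sequential band-stops at 48-52 Hz and 58-62 Hz, then
segmentation into 1.5 s analysis windows updated every 50 ms.  Causal
filtering carries IIR state across chunks so that chunked and whole-stream
processing agree sample for sample; a zero-phase variant is available for
offline spectral figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps


@dataclass
class SignalWindow:
    """A fixed-duration multi-channel EEG segment (microvolts)."""

    samples: np.ndarray  # (N, C)
    fs_hz: float
    t_start_s: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2:
            raise ValueError("samples must be (N, C)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


def detrend(window: SignalWindow) -> SignalWindow:
    """Remove the per-channel least-squares line (DC offset and drift)."""
    if window.n_samples < 2:
        raise ValueError("detrend needs at least 2 samples")
    out = sps.detrend(window.samples, axis=0, type="linear")
    return SignalWindow(samples=out, fs_hz=window.fs_hz, t_start_s=window.t_start_s)


@dataclass(frozen=True)
class FilterChain:
    """Band-pass + sequential band-stop IIR chain.

    Each section is a Butterworth filter of the given order ("second-order"
    applies to every section independently).  Application order is fixed:
    band-pass 5-45 Hz, then band-stop 48-52 Hz, then band-stop 58-62 Hz.
    """

    band_pass: tuple[float, float] = (5.0, 45.0)
    band_pass_order: int = 2
    band_stops: tuple[tuple[float, float], ...] = ((48.0, 52.0), (58.0, 62.0))
    band_stop_order: int = 2
    causal: bool = True

    def design(self, fs_hz: float) -> list[np.ndarray]:
        """Second-order-section coefficients for every filter in the chain.

        Band-stops whose band lies entirely at/above Nyquist are skipped
        (nothing to remove); a band-pass edge at/above Nyquist is an error.
        """
        nyq = fs_hz / 2.0
        lo, hi = self.band_pass
        if not (0 < lo < hi):
            raise ValueError("band-pass edges must be strictly increasing")
        if hi >= nyq:
            raise ValueError(f"band-pass edge {hi} Hz >= Nyquist {nyq} Hz")
        sos_list = [
            sps.butter(self.band_pass_order, [lo, hi], btype="bandpass", fs=fs_hz, output="sos")
        ]
        for lo_s, hi_s in self.band_stops:
            if not (0 < lo_s < hi_s):
                raise ValueError("band-stop edges must be strictly increasing")
            if lo_s >= nyq:
                continue
            if hi_s >= nyq:
                raise ValueError(f"band-stop edge {hi_s} Hz >= Nyquist {nyq} Hz")
            sos_list.append(
                sps.butter(self.band_stop_order, [lo_s, hi_s], btype="bandstop", fs=fs_hz, output="sos")
            )
        return sos_list

    def frequency_response(self, f_hz: np.ndarray, fs_hz: float) -> np.ndarray:
        """Complex gain of the whole chain at the given frequencies."""
        h = np.ones_like(np.asarray(f_hz, dtype=float), dtype=complex)
        for sos in self.design(fs_hz):
            _, hi = sps.sosfreqz(sos, worN=np.asarray(f_hz, dtype=float), fs=fs_hz)
            h = h * hi
        return h


class FilterState:
    """Carry-over IIR state for chunked causal filtering."""

    def __init__(self, chain: FilterChain, fs_hz: float, n_channels: int):
        self.chain = chain
        self.fs_hz = fs_hz
        self.zi = [
            np.zeros((sos.shape[0], 2, n_channels)) for sos in chain.design(fs_hz)
        ]


def apply_filter_chain(
    samples: np.ndarray,
    chain: FilterChain,
    fs_hz: float,
    state: FilterState | None = None,
    detrend_first: bool = False,
):
    """Filter a stream or chunk through the chain.

    In causal mode (default) filtering is forward-only, and passing the
    returned :class:`FilterState` back in on the next chunk makes chunked
    processing bit-compatible with whole-stream processing.  With
    ``chain.causal = False`` a zero-phase (filtfilt) pass is used instead,
    for offline analysis only (no state carry-over).  ``detrend_first``
    removes the least-squares line of this input before filtering; note it
    operates on the chunk it is given, so it is meant for whole-stream use.

    Returns ``(filtered, state)``.
    """
    x = np.asarray(samples, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if detrend_first and x.shape[0] >= 2:
        x = sps.detrend(x, axis=0, type="linear")
    if chain.causal:
        if state is None:
            state = FilterState(chain, fs_hz, x.shape[1])
        elif state.fs_hz != fs_hz:
            raise ValueError("filter state was built for a different sample rate")
        sos_list = chain.design(fs_hz)
        for i, sos in enumerate(sos_list):
            x, state.zi[i] = sps.sosfilt(sos, x, axis=0, zi=state.zi[i])
    else:
        for sos in chain.design(fs_hz):
            x = sps.sosfiltfilt(sos, x, axis=0)
        state = None
    return (x[:, 0] if squeeze else x), state


def _count_samples(duration_s: float, fs_hz: float, name: str) -> int:
    n = duration_s * fs_hz
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"{name} = {duration_s} s is not an integer number of samples at {fs_hz} Hz")
    return int(round(n))


def sliding_windows(
    samples: np.ndarray,
    fs_hz: float,
    window_s: float = 1.5,
    hop_s: float = 0.05,
    t_start_s: float = 0.0,
):
    """Segment a stream into analysis windows at t = 0, hop, 2*hop, ...

    Yields :class:`SignalWindow` objects (views into the stream; copy before
    mutating).  A stream shorter than one window yields nothing.  Window and
    hop durations must land exactly on the sample grid.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n_win = _count_samples(window_s, fs_hz, "window_s")
    n_hop = _count_samples(hop_s, fs_hz, "hop_s")
    if n_win < 1 or n_hop < 1:
        raise ValueError("window_s and hop_s must be at least one sample")
    for start in range(0, x.shape[0] - n_win + 1, n_hop):
        yield SignalWindow(
            samples=x[start : start + n_win],
            fs_hz=fs_hz,
            t_start_s=t_start_s + start / fs_hz,
        )


def window_view(samples: np.ndarray, n_win: int, n_hop: int) -> np.ndarray:
    """Strided view of shape (n_windows, n_win, C) over a (N, C) stream."""
    x = np.ascontiguousarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    n_windows = max(0, (n - n_win) // n_hop + 1) if n >= n_win else 0
    if n_windows == 0:
        return np.zeros((0, n_win, x.shape[1]))
    sn, sc = x.strides
    return np.lib.stride_tricks.as_strided(
        x,
        shape=(n_windows, n_win, x.shape[1]),
        strides=(sn * n_hop, sn, sc),
        writeable=False,
    )
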