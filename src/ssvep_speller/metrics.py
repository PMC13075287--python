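"""Evaluation: confusion metrics, information transfer rate, spectra, ERSP.

Classification metrics follow the standard confusion-matrix definitions
(accuracy, precision, recall, F1, all in percent; multi-class values are
macro-averages over one-vs-rest reductions).  The information transfer
rate is the Wolpaw formula

    ITR = [log2 N + P log2 P + (1 - P) log2((1 - P)/(N - 1))] * 60 / T

in bits per minute, for N commands, accuracy P and mean selection time T
seconds.  Spectral tools cover one-sided amplitude spectra, a neighbor-bin
SNR, and event-related spectral perturbation (ERSP) maps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .commands import ACTIVE_COMMANDS, Command
from .preprocess import SignalWindow

DEFAULT_LABELS = tuple(c.value for c in ACTIVE_COMMANDS)


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    labels: tuple[str, ...]
    counts: np.ndarray  # (n, n); rows = true, cols = predicted

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def _label_name(x) -> str:
    return x.value if isinstance(x, Command) else str(x)


def confusion_matrix(true_labels, predicted_labels, labels=None) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a square matrix.

    ``labels`` fixes row/column order; by default the five commands, plus
    any extra label observed in the data (e.g. ``NONE`` for segments where
    the decoder stayed silent), appended in order of appearance.
    """
    t = [_label_name(x) for x in true_labels]
    p = [_label_name(x) for x in predicted_labels]
    if len(t) != len(p):
        raise ValueError("true and predicted label lists differ in length")
    if labels is None:
        lab = list(DEFAULT_LABELS)
        for x in t + p:
            if x not in lab:
                lab.append(x)
    else:
        lab = [_label_name(x) for x in labels]
    idx = {x: i for i, x in enumerate(lab)}
    counts = np.zeros((len(lab), len(lab)), dtype=int)
    for ti, pi in zip(t, p):
        if ti not in idx or pi not in idx:
            raise ValueError(f"label {ti if ti not in idx else pi!r} not in label set")
        counts[idx[ti], idx[pi]] += 1
    return ConfusionMatrix(labels=tuple(lab), counts=counts)


def classification_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy / precision / recall / F1 in percent from a confusion matrix.

    Accuracy is trace/total; precision and recall are per-class one-vs-rest
    values macro-averaged over classes with at least one true instance.  A
    class that is never predicted gets precision 0 (with a warning), and a
    class pair with zero precision+recall gets F1 0.  The averaging
    convention is included in the output.
    """
    c = cm.counts.astype(float)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(c)
    pred_pos = c.sum(axis=0)
    true_pos = c.sum(axis=1)
    support = true_pos > 0
    precision = np.zeros(len(cm.labels))
    nonzero_pred = pred_pos > 0
    precision[nonzero_pred] = tp[nonzero_pred] / pred_pos[nonzero_pred]
    if np.any(support & ~nonzero_pred):
        missing = [cm.labels[i] for i in np.flatnonzero(support & ~nonzero_pred)]
        warnings.warn(
            f"classes never predicted, precision set to 0: {missing}", stacklevel=2
        )
    recall = np.zeros(len(cm.labels))
    recall[support] = tp[support] / true_pos[support]
    denom = precision + recall
    f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    return {
        "accuracy": 100.0 * tp.sum() / total,
        "precision": 100.0 * precision[support].mean(),
        "recall": 100.0 * recall[support].mean(),
        "f1": 100.0 * f1[support].mean(),
        "averaging": "macro (one-vs-rest, classes with support)",
        "per_class": {
            cm.labels[i]: {
                "precision": 100.0 * precision[i],
                "recall": 100.0 * recall[i],
                "f1": 100.0 * f1[i],
            }
            for i in np.flatnonzero(support)
        },
    }


# ---------------------------------------------------------------------------
# Information transfer rate
# ---------------------------------------------------------------------------

def itr_bits_per_selection(n_commands: int, p: float) -> float:
    """Bits conveyed per selection for an N-choice system at accuracy P."""
    if n_commands < 2:
        raise ValueError("need at least 2 commands")
    if not 0.0 <= p <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    bits = math.log2(n_commands)
    if p > 0:
        bits += p * math.log2(p)
    if p < 1:
        bits += (1 - p) * math.log2((1 - p) / (n_commands - 1))
    return bits


def itr_bits_per_min(n_commands: int, p: float, t_s: float) -> float:
    """Wolpaw information transfer rate in bits/min.

    ``t_s`` is the mean time per selection in seconds.  When derived from
    the decision rule's nominal timing this is the 1.5 s collection window
    plus the 1.0 s ignore interval, i.e. 2.5 s.
    """
    if t_s <= 0:
        raise ValueError("selection time must be positive")
    return itr_bits_per_selection(n_commands, p) * 60.0 / t_s


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectrumReport:
    freqs_hz: np.ndarray  # (n_bins,)
    amplitude: np.ndarray  # (n_bins, C), same units as the input signal

    @property
    def df_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])

    def channel_mean(self) -> np.ndarray:
        return self.amplitude.mean(axis=1)


def amplitude_spectrum(window: SignalWindow | np.ndarray, fs_hz: float | None = None) -> SpectrumReport:
    """One-sided amplitude spectrum (2/N scaling; DC and Nyquist unscaled)."""
    if isinstance(window, SignalWindow):
        x, fs = window.samples, window.fs_hz
    else:
        if fs_hz is None:
            raise ValueError("fs_hz required for raw arrays")
        x, fs = np.atleast_2d(np.asarray(window, dtype=float)), fs_hz
        if x.shape[0] == 1:
            x = x.T
    n = x.shape[0]
    if n < 64:
        raise ValueError("need at least 64 samples for a spectrum")
    spec = np.fft.rfft(x, axis=0)
    amp = np.abs(spec) * (2.0 / n)
    amp[0] /= 2.0
    if n % 2 == 0:
        amp[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return SpectrumReport(freqs_hz=freqs, amplitude=amp)


SNR_CAP_DB = 100.0  # guard for zero-noise degenerate inputs


def snr_at(
    spectrum: SpectrumReport,
    f_hz: float,
    k_neighbors: int = 10,
    mask_freqs_hz=(),
    channel: int | None = None,
) -> float:
    """Neighbor-bin SNR in dB at a stimulus frequency.

    20*log10 of the amplitude at the bin nearest ``f_hz`` over the mean
    amplitude of ``k_neighbors`` bins on each side, excluding the bin
    itself, its immediate neighbors (+-1 bin), and +-1 bin around each
    frequency in ``mask_freqs_hz`` (typically other stimuli/harmonics).
    Capped at +100 dB for noise-free inputs.
    """
    amp = spectrum.channel_mean() if channel is None else spectrum.amplitude[:, channel]
    freqs = spectrum.freqs_hz
    if not freqs[0] <= f_hz <= freqs[-1]:
        raise ValueError(f"{f_hz} Hz outside the spectrum range")
    i0 = int(np.argmin(np.abs(freqs - f_hz)))
    excluded = {i0 - 1, i0, i0 + 1}
    for fm in mask_freqs_hz:
        im = int(np.argmin(np.abs(freqs - fm)))
        excluded.update((im - 1, im, im + 1))
    neighbors = []
    for direction in (-1, 1):
        found = 0
        i = i0
        while found < k_neighbors:
            i += direction
            if i < 0 or i >= len(freqs):
                break
            if i in excluded:
                continue
            neighbors.append(i)
            found += 1
        if found < k_neighbors:
            raise ValueError("insufficient usable neighbor bins")
    noise = amp[neighbors].mean()
    if noise <= 0:
        return SNR_CAP_DB if amp[i0] > 0 else 0.0
    return float(min(20.0 * np.log10(amp[i0] / noise), SNR_CAP_DB))


# ---------------------------------------------------------------------------
# ERSP
# ---------------------------------------------------------------------------

@dataclass
class ErspResult:
    times_s: np.ndarray  # (n_times,) relative to epoch time axis
    freqs_hz: np.ndarray  # (n_freqs,)
    db: np.ndarray  # (n_freqs, n_times) power change vs baseline, dB

    def row(self, f_hz: float) -> np.ndarray:
        return self.db[int(np.argmin(np.abs(self.freqs_hz - f_hz)))]


def ersp(
    epochs: list[SignalWindow],
    baseline_interval_s: tuple[float, float],
    segment_s: float = 0.5,
    overlap: float = 0.9,
) -> ErspResult:
    """Event-related spectral perturbation averaged over epochs.

    Each epoch is short-time transformed (Hann window of ``segment_s``
    seconds, 90% overlap by default), power is averaged across epochs and
    channels, and each frequency row is expressed in dB relative to its
    mean power inside the baseline interval (epoch time axis, i.e.
    ``t_start_s`` offsets apply).
    """
    if not epochs:
        raise ValueError("need at least one epoch")
    fs = epochs[0].fs_hz
    nper = int(round(segment_s * fs))
    nover = int(round(overlap * nper))
    b0, b1 = baseline_interval_s
    if b1 <= b0:
        raise ValueError("baseline interval must have positive length")
    power_sum = None
    for ep in epochs:
        if ep.fs_hz != fs:
            raise ValueError("epochs must share a sample rate")
        if b0 < ep.t_start_s or b1 > ep.t_start_s + ep.duration_s:
            raise ValueError("baseline interval lies outside the epoch")
        f, t, sxx = sps.spectrogram(
            ep.samples,
            fs=fs,
            window="hann",
            nperseg=nper,
            noverlap=nover,
            axis=0,
            mode="psd",
        )
        p = sxx.mean(axis=1)  # average channels -> (n_freqs, n_times)
        power_sum = p if power_sum is None else power_sum + p
    power = power_sum / len(epochs)
    times = t + epochs[0].t_start_s
    in_base = (times >= b0) & (times <= b1)
    if not in_base.any():
        raise ValueError("no spectrogram frames fall inside the baseline")
    base = power[:, in_base].mean(axis=1, keepdims=True)
    db = 10.0 * np.log10(np.maximum(power, 1e-300) / np.maximum(base, 1e-300))
    return ErspResult(times_s=times, freqs_hz=f, db=db)
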