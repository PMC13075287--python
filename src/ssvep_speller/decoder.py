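"""CCA-based SSVEP frequency recognition and the accumulation decision rule.

For each analysis window X (N samples x C channels) and each candidate
stimulation frequency f_k, a sine/cosine reference matrix Y_k is built and
the leading canonical correlation rho_k = max_{w_x, w_y}
corr(X w_x, Y_k w_y) is computed.  Correlations are computed per channel
and the maximum across channels is kept ("channel-max"), yielding one
correlation profile per window.  The classified frequency is the argmax of
the profile.

Command emission uses temporal accumulation: profiles are collected over a
fixed 1.5 s collection window (30 updates at a 50 ms hop); a frequency is a
valid candidate only if its correlation reached the threshold (r >= 0.25)
in at least 30% of the updates in the collection window; among valid
candidates the one with the highest mean accumulated correlation wins; if
none qualifies, no command is issued.  A 1 s refractory ("ignore") interval
follows every emission to prevent repeated selections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .commands import (
    Command,
    STIMULUS_FREQUENCIES_HZ,
    map_command_to_frequency,
    map_frequency_to_command,
)
from .preprocess import SignalWindow, window_view


# ---------------------------------------------------------------------------
# Reference templates
# ---------------------------------------------------------------------------

def reference_matrix(
    f_hz: float, fs_hz: float, n_samples: int, n_harmonics: int = 1
) -> np.ndarray:
    """Sine/cosine reference template for one stimulation frequency.

    Column 2h-2 is sin(2*pi*h*f*t_n) and column 2h-1 is cos(2*pi*h*f*t_n)
    for harmonics h = 1..n_harmonics, with t_n = n/fs from n = 0.  The time
    origin is irrelevant to CCA (a shifted sin/cos pair spans the same
    subspace), but fixing it makes templates reproducible.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if f_hz * n_harmonics >= fs_hz / 2:
        raise ValueError(
            f"harmonic {n_harmonics} of {f_hz} Hz is at/above Nyquist ({fs_hz / 2} Hz)"
        )
    if n_samples < 4 * n_harmonics:
        raise ValueError("n_samples too small for the requested template")
    t = np.arange(n_samples) / fs_hz
    cols = []
    for h in range(1, n_harmonics + 1):
        w = 2 * np.pi * h * f_hz * t
        cols.append(np.sin(w))
        cols.append(np.cos(w))
    return np.column_stack(cols)


class ReferenceSet:
    """Per-frequency reference templates for a fixed window length."""

    def __init__(
        self,
        n_samples: int,
        fs_hz: float = 200.0,
        frequencies_hz=STIMULUS_FREQUENCIES_HZ,
        n_harmonics: int = 1,
    ):
        self.frequencies_hz = tuple(float(f) for f in frequencies_hz)
        self.fs_hz = float(fs_hz)
        self.n_samples = int(n_samples)
        self.n_harmonics = int(n_harmonics)
        self.matrices = [
            reference_matrix(f, fs_hz, n_samples, n_harmonics)
            for f in self.frequencies_hz
        ]
        # Orthonormal bases of the column-centered templates, for the fast
        # single-channel path: rho(x, Y) = ||Q^T x_c|| / ||x_c||.
        self._q = []
        for y in self.matrices:
            yc = y - y.mean(axis=0)
            q, _ = np.linalg.qr(yc)
            self._q.append(q)

    def __len__(self) -> int:
        return len(self.frequencies_hz)


# ---------------------------------------------------------------------------
# Canonical correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CanonicalResult:
    rho: float
    w_x: np.ndarray
    w_y: np.ndarray


def _inv_sqrt(s: np.ndarray, reg: float) -> np.ndarray:
    """Inverse symmetric square root of a covariance with trace-scaled ridge."""
    s = s + np.eye(s.shape[0]) * (reg * max(np.trace(s), 1.0))
    vals, vecs = np.linalg.eigh(s)
    vals = np.maximum(vals, np.finfo(float).tiny)
    return (vecs / np.sqrt(vals)) @ vecs.T


def canonical_correlation(
    X: np.ndarray, Y: np.ndarray, reg: float = 1e-12
) -> CanonicalResult:
    """Leading canonical correlation between two column-centered blocks.

    Solved via the whitened cross-covariance: with Sxx^{-1/2} Sxy Syy^{-1/2}
    = U diag(rho) V^T, the first singular value is the canonical
    correlation and w_x = Sxx^{-1/2} u_1, w_y = Syy^{-1/2} v_1.  A ridge of
    ``reg * trace`` on each covariance diagonal guards rank-deficient
    inputs.  The returned rho is the absolute correlation, clipped to [0, 1].
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    if Y.shape[0] == 1:
        Y = Y.T
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if n <= X.shape[1] + Y.shape[1]:
        raise ValueError("need more samples than total dimensions")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = Xc.T @ Xc
    syy = Yc.T @ Yc
    sxy = Xc.T @ Yc
    wx_half = _inv_sqrt(sxx, reg)
    wy_half = _inv_sqrt(syy, reg)
    u, s, vt = np.linalg.svd(wx_half @ sxy @ wy_half)
    rho = float(np.clip(s[0], 0.0, 1.0))
    w_x = wx_half @ u[:, 0]
    w_y = wy_half @ vt[0, :]
    return CanonicalResult(rho=rho, w_x=w_x, w_y=w_y)


# ---------------------------------------------------------------------------
# Correlation profiles
# ---------------------------------------------------------------------------

@dataclass
class CorrelationProfile:
    """Per-window correlation vector: one rho per stimulation frequency."""

    t_s: float
    rho_by_freq: np.ndarray  # (n_freqs,)

    def __post_init__(self):
        self.rho_by_freq = np.asarray(self.rho_by_freq, dtype=float)
        if np.any((self.rho_by_freq < -1e-9) | (self.rho_by_freq > 1 + 1e-9)):
            raise ValueError("correlations must lie in [0, 1]")


def correlation_profile(
    window: SignalWindow, refs: ReferenceSet, mode: str = "per_channel_max"
) -> CorrelationProfile:
    """Reduce one analysis window to a per-frequency correlation vector.

    ``per_channel_max`` (the deployed strategy) computes the canonical
    correlation independently for each channel and keeps the maximum across
    channels per frequency; ``joint`` feeds all channels to CCA at once.
    """
    if window.n_samples != refs.n_samples:
        raise ValueError(
            f"window has {window.n_samples} samples but references were built "
            f"for {refs.n_samples}"
        )
    if mode not in ("per_channel_max", "joint"):
        raise ValueError("mode must be 'per_channel_max' or 'joint'")
    rhos = np.empty(len(refs))
    for k, y in enumerate(refs.matrices):
        if mode == "joint":
            rhos[k] = canonical_correlation(window.samples, y).rho
        else:
            rhos[k] = max(
                canonical_correlation(window.samples[:, c : c + 1], y).rho
                for c in range(window.n_channels)
            )
    return CorrelationProfile(t_s=window.t_start_s, rho_by_freq=rhos)


def batch_correlation_profiles(
    samples: np.ndarray,
    fs_hz: float,
    refs: ReferenceSet,
    window_s: float = 1.5,
    hop_s: float = 0.05,
    t_start_s: float = 0.0,
) -> list[CorrelationProfile]:
    """Vectorized channel-max profiles over every sliding window of a stream.

    Equivalent to running :func:`correlation_profile` (per_channel_max, with
    per-window linear detrending) on each window from
    :func:`~ssvep_speller.preprocess.sliding_windows`, but computed with a
    strided view and matrix products; used by the experiment harness.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n_win = int(round(window_s * fs_hz))
    n_hop = int(round(hop_s * fs_hz))
    if n_win != refs.n_samples:
        raise ValueError("window length does not match the reference set")
    w = window_view(x, n_win, n_hop)  # (nw, N, C)
    if w.shape[0] == 0:
        return []
    # Per-window, per-channel linear detrend: subtract mean and slope*(t - tbar).
    t = np.arange(n_win)
    tc = t - t.mean()
    tt = float(tc @ tc)
    mean = w.mean(axis=1, keepdims=True)
    slope = np.einsum("wnc,n->wc", w, tc) / tt
    wd = w - mean - slope[:, None, :] * tc[None, :, None]
    norms = np.sqrt(np.einsum("wnc,wnc->wc", wd, wd))
    norms = np.maximum(norms, np.finfo(float).tiny)
    nw = w.shape[0]
    rho = np.empty((nw, len(refs)))
    for k, q in enumerate(refs._q):
        proj = np.einsum("wnc,nm->wmc", wd, q)
        rho_ch = np.sqrt(np.einsum("wmc,wmc->wc", proj, proj)) / norms
        rho[:, k] = rho_ch.max(axis=1)
    rho = np.clip(rho, 0.0, 1.0)
    times = t_start_s + np.arange(nw) * n_hop / fs_hz
    return [CorrelationProfile(t_s=ts, rho_by_freq=r) for ts, r in zip(times, rho)]


def classify_frequency(profile: CorrelationProfile, refs_or_freqs=None) -> float:
    """Pick the frequency with the maximal correlation (ties: lowest index)."""
    freqs = STIMULUS_FREQUENCIES_HZ
    if refs_or_freqs is not None:
        freqs = getattr(refs_or_freqs, "frequencies_hz", refs_or_freqs)
    rho = profile.rho_by_freq
    if rho.size == 0:
        raise ValueError("empty correlation profile")
    return float(freqs[int(np.argmax(rho))])


# ---------------------------------------------------------------------------
# Decision rule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecisionConfig:
    """Parameters of the accumulation/threshold decision rule."""

    frequencies_hz: tuple[float, ...] = STIMULUS_FREQUENCIES_HZ
    threshold: float = 0.25
    consistency: float = 0.30
    collection_s: float = 1.5
    hop_s: float = 0.05
    ignore_s: float = 1.0
    counting: str = "window"  # "window": hits anywhere in the collection
    #                           "run": longest consecutive run of hits

    @property
    def n_collect(self) -> int:
        return int(math.ceil(self.collection_s / self.hop_s - 1e-9))

    @property
    def n_required(self) -> int:
        return int(math.ceil(self.consistency * self.n_collect - 1e-9))


@dataclass
class Emission:
    t_s: float
    command: Command
    frequency_hz: float
    mean_rho: float


class DecisionState:
    """Streaming state: collection buffer, refractory clock, event log.

    Collection windows are consecutive non-overlapping blocks of
    ``n_collect`` updates; the buffer resets after every decision (emission
    or empty).  Profiles arriving during the refractory interval are
    dropped entirely.
    """

    def __init__(self, config: DecisionConfig | None = None):
        self.config = config or DecisionConfig()
        self.buffer: list[CorrelationProfile] = []
        self.ignore_until_s = -np.inf
        self.last_t_s = -np.inf
        self.emissions: list[Emission] = []


def decision_update(
    state: DecisionState, profile: CorrelationProfile
) -> Command | None:
    """Feed one correlation profile; possibly emit a command.

    Within each full collection window a frequency is *valid* iff its
    correlation reached the threshold in at least ``n_required`` updates
    (>= 9 of 30 at defaults); among valid candidates the highest mean
    accumulated (supra-threshold) correlation wins, ties going to the
    lowest frequency index.  After an emission all profiles earlier than
    ``t + ignore_s`` are ignored, so emissions are never closer than the
    ignore interval.
    """
    cfg = state.config
    t = profile.t_s
    if t <= state.last_t_s:
        raise ValueError(f"profiles must arrive in time order ({t} <= {state.last_t_s})")
    state.last_t_s = t
    if t < state.ignore_until_s:
        return None
    state.buffer.append(profile)
    if len(state.buffer) < cfg.n_collect:
        return None

    rho = np.stack([p.rho_by_freq for p in state.buffer])  # (n_collect, n_freq)
    state.buffer = []
    hits = rho >= cfg.threshold
    if cfg.counting == "window":
        counts = hits.sum(axis=0)
    elif cfg.counting == "run":
        counts = np.array([_longest_run(hits[:, k]) for k in range(hits.shape[1])])
    else:
        raise ValueError("counting must be 'window' or 'run'")
    valid = counts >= cfg.n_required
    if not valid.any():
        return None
    means = np.full(hits.shape[1], -np.inf)
    for k in np.flatnonzero(valid):
        means[k] = rho[hits[:, k], k].mean()
    k_best = int(np.argmax(means))  # argmax takes the first (lowest) index on ties
    f_best = cfg.frequencies_hz[k_best]
    cmd = map_frequency_to_command(f_best)
    state.ignore_until_s = t + cfg.ignore_s
    state.emissions.append(
        Emission(t_s=t, command=cmd, frequency_hz=f_best, mean_rho=float(means[k_best]))
    )
    return cmd


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for m in mask:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def run_decoder(
    profiles, config: DecisionConfig | None = None
) -> list[Emission]:
    """Run the decision rule over an ordered profile stream."""
    state = DecisionState(config)
    for p in profiles:
        decision_update(state, p)
    return state.emissions
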