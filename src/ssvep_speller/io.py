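"""Stream and report I/O: CSV streams, optional EDF reading, JSON-lines logs.

The canonical interchange format is a plain CSV with a ``time_s`` column,
one ``chN_uV`` column per channel, and an optional ``label`` column holding
command names (``NONE`` during rest).  EDF reading is available when
``mne`` is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .commands import Command
from .synthgen import Session


def write_stream_csv(path, session: Session, include_labels: bool = True) -> None:
    """Write a session as ``time_s,ch1_uV,ch2_uV[,label]``."""
    cols = {"time_s": session.time_s}
    for c in range(session.samples.shape[1]):
        cols[f"ch{c + 1}_uV"] = session.samples[:, c]
    if include_labels:
        cols["label"] = session.labels
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def read_stream_csv(path) -> Session:
    """Read a stream CSV back into a :class:`~ssvep_speller.synthgen.Session`."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("stream CSV must have a time_s column")
    ch_cols = [c for c in df.columns if c.startswith("ch") and c.endswith("_uV")]
    if not ch_cols:
        raise ValueError("stream CSV has no chN_uV channel columns")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("stream too short to infer the sample rate")
    fs = 1.0 / np.median(np.diff(t))
    samples = df[ch_cols].to_numpy(dtype=float)
    if "label" in df.columns:
        labels = df["label"].astype(str).to_numpy(dtype=object)
    else:
        labels = np.full(len(df), Command.NONE.value, dtype=object)
    segments = _segments_from_labels(labels, fs)
    return Session(samples=samples, fs_hz=float(round(fs, 6)), labels=labels, segments=segments)


def _segments_from_labels(labels: np.ndarray, fs: float):
    segments = []
    current, start = None, 0
    for i, lab in enumerate(list(labels) + [Command.NONE.value]):
        if lab != current:
            if current is not None and current != Command.NONE.value:
                segments.append((Command(current), start / fs, i / fs))
            current, start = lab, i
    return segments


def read_edf(path) -> Session:
    """Read a continuous EEG recording from EDF (requires ``mne``)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF reading requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    samples = raw.get_data().T * 1e6  # volts -> microvolts
    fs = float(raw.info["sfreq"])
    labels = np.full(samples.shape[0], Command.NONE.value, dtype=object)
    return Session(samples=samples, fs_hz=fs, labels=labels, segments=[])


def write_events_jsonl(path, emissions) -> None:
    """Decoder event log: one JSON object per emitted command."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in emissions:
            fh.write(
                json.dumps(
                    {
                        "t": round(e.t_s, 6),
                        "command": e.command.value,
                        "frequency_hz": e.frequency_hz,
                        "mean_rho": round(e.mean_rho, 6),
                    }
                )
                + "\n"
            )


def write_report_json(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonify), "utf-8")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, Command):
        return x.value
    raise TypeError(f"cannot serialize {type(x)}")
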