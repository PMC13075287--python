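"""Spectral fingerprints of the synthetic SSVEP response.

Simulates attending each stimulation frequency, then prints the amplitude
spectrum peak, the neighbor-bin SNR at the stimulus, and an ERSP summary
for intermittent 12 Hz flicker (on at 0-1, 2-3, 4-6, 7-10 s relative to a
-2-0 s baseline).
"""

import numpy as np

from ssvep_speller import (
    Command,
    ProtocolScript,
    SimConfig,
    amplitude_spectrum,
    ersp,
    simulate_session,
    simulate_ssvep_epoch,
    snr_at,
)
from ssvep_speller.preprocess import SignalWindow

print("per-stimulus spectra (5 s epochs, calibrated high SNR):")
for f in (6.67, 7.5, 8.57, 10.0, 12.0):
    ep = simulate_ssvep_epoch(SimConfig(seed=int(f * 100)).with_snr(3.0), f, 5.0)
    spec = amplitude_spectrum(ep)
    band = (spec.freqs_hz >= 4) & (spec.freqs_hz <= 45)
    peak = spec.freqs_hz[band][np.argmax(spec.channel_mean()[band])]
    snr = snr_at(spec, f, mask_freqs_hz=[2 * f, 3 * f])
    print(f"  {f:5.2f} Hz: in-band peak at {peak:5.2f} Hz, SNR {snr:5.1f} dB")

entries = (
    (Command.NONE, 2.0), (Command.SELECT, 1.0), (Command.NONE, 1.0),
    (Command.SELECT, 1.0), (Command.NONE, 1.0), (Command.SELECT, 2.0),
    (Command.NONE, 1.0), (Command.SELECT, 3.0),
)
script = ProtocolScript(entries=entries, inter_command_gap_s=0.0)
epochs = [
    SignalWindow(simulate_session(script, SimConfig(seed=100 + s)).samples,
                 200.0, t_start_s=-2.0)
    for s in range(10)
]
res = ersp(epochs, baseline_interval_s=(-2.0, 0.0))
row = res.row(12.0)
on = np.zeros_like(res.times_s, dtype=bool)
off = np.zeros_like(res.times_s, dtype=bool)
for a, b in [(0, 1), (2, 3), (4, 6), (7, 10)]:
    on |= (res.times_s >= a + 0.45) & (res.times_s <= b - 0.11)
for a, b in [(1, 2), (3, 4), (6, 7)]:
    off |= (res.times_s >= a + 0.5) & (res.times_s <= b - 0.11)
print(f"\nERSP at 12 Hz: {row[on].mean():.1f} dB during flicker-on intervals vs "
      f"{row[off].mean():+.1f} dB inside off intervals — power enhancement is "
      "time-locked to the stimulation.")
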