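# ssvep-speller

A hardware-free, fully testable implementation of a two-channel SSVEP
(steady-state visual evoked potential) brain–computer-interface speller for
Korean text entry on the Cheonjiin keyboard layout.

It is written for BCI researchers and students who want to study, stress or
extend a minimal online SSVEP pipeline without an EEG amplifier on the
desk: every stage — stimulus scheduling, the EEG itself, filtering, CCA
decoding, the command decision rule, Hangul composition and evaluation —
is simulated, seeded and unit-tested.

## The system in brief

Five flicker frequencies, chosen as integer divisions of a 60 Hz display
refresh, drive five control commands:

| command | frame period | frequency |
|---------|--------------|-----------|
| UP      | 9 frames     | 6.67 Hz   |
| RIGHT   | 8 frames     | 7.5 Hz    |
| DOWN    | 7 frames     | 8.57 Hz   |
| LEFT    | 6 frames     | 10 Hz     |
| SELECT  | 5 frames     | 12 Hz     |

Two occipital channels are sampled at 200 Hz, detrended and filtered
(order-2 Butterworth band-pass 5–45 Hz, band-stops 48–52 and 58–62 Hz),
then cut into 1.5 s sliding windows every 50 ms.  For each window `X ∈
R^{N×C}` and each frequency `f_k` with sine/cosine template `Y_k`,
canonical correlation analysis finds

    ρ_k = max_{w_x, w_y} corr(X w_x, Y_k w_y),

computed per channel with the maximum across channels retained.  Commands
are emitted by temporal accumulation: within a 1.5 s collection window (30
updates) a frequency is valid only if ρ_k ≥ 0.25 in at least 30% of the
updates; among valid candidates the highest mean accumulated correlation
wins; each emission is followed by a 1 s refractory ("ignore") interval.
The emitted command moves a cursor on a 14-key, 4×4 Cheonjiin grid where
all vowels are composed from ㆍ, ㅡ, ㅣ and consonants cycle by repeated
selection (ㄱ→ㅋ→ㄲ …).

Evaluation uses confusion-matrix metrics and the Wolpaw information
transfer rate

    ITR = [log2 N + P log2 P + (1−P) log2((1−P)/(N−1))] · 60/T  (bits/min).

## Worked example

```bash
python examples/type_korean_word.py
```

```
typing plan for '머리': 23 cursor movements + 9 selections = 32 commands
  trial 1: typed '머리' (correct)
  ...
5/5 trials typed the word exactly; per-decision accuracy 100.0%
```

Each of the 32 planned commands (cursor moves plus selections, with an
ENTER after each syllable) becomes one attend segment of simulated EEG at
a calibrated high SNR; the decoder's per-segment decisions are replayed
through the Hangul automaton, and a trial counts as a success only if the
final committed text equals the target word exactly.

Other examples: `simulate_and_decode.py` (one protocol set, decision by
decision), `window_sweep.py` (accuracy/ITR vs window length),
`spectral_analysis.py` (FFT peaks, SNR, ERSP), `keystroke_economy.py`
(Cheonjiin vs QWERTY cursor costs — 34 vs 53 movements for "안녕하세요"
from the home position).

A thin CLI wraps the same functions:

```bash
speller simulate --seed 7 --snr 1.0 --sets 1 --out session.csv
speller exp1 --trials 10 --snr 3.0 --seed 1
speller exp2 --word 머리 --trials 5 --snr 3.0
speller sweep --trials 3 --snr 1.5
speller plan 안녕하세요
```

## Layout of the package

- `ssvep_speller.synthgen` — flicker schedules, synthetic EEG, protocols
- `ssvep_speller.preprocess` — filter chain, detrending, sliding windows
- `ssvep_speller.decoder` — reference templates, CCA, decision rule
- `ssvep_speller.cheonjiin` — layouts, composition automaton, typing planner
- `ssvep_speller.metrics` — confusion metrics, ITR, spectra, SNR, ERSP
- `ssvep_speller.harness` — experiment protocols end to end
- `ssvep_speller.io` / `ssvep_speller.cli` — streams, logs, shell front end

See `docs/methods.md` for the signal model, parameter choices and known
limitations of the simulation.
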