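# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the simulation does and does not establish
about real EEG.

## Signal model

The synthetic two-channel "occipital EEG" is a sum of four parts, all in
microvolts at 200 Hz:

1. **SSVEP response.** When a stimulus at frequency *f* is attended, each
   channel receives Σ_h a_h sin(2π h f t + h φ_c), h = 1…3, with default
   harmonic amplitudes a = (1.0, 0.4, 0.15) µV.  The source is common to
   both channels up to a per-channel gain (1.0, 0.85) and phase offset
   (0, 0.35 rad), plus one random stimulus phase per attend segment.  The
   response starts `response_latency_s` = 0.14 s after stimulus onset and
   persists equally long after offset; cortical latency of this order is
   typical for visual responses, and the exact value only shifts decision
   timing.  Harmonic (not square-wave) structure matches both the sin/cos
   CCA reference model and the harmonic spectral peaks such systems show.
2. **Background 1/f activity.** Gaussian noise with amplitude spectrum
   f^(−α/2), α = 1, scaled to 1.0 µV RMS per channel, independent across
   channels.  An optional flat `sensor_noise_rms_uV` component (default 0)
   can whiten the floor, emulating noisier dry-electrode front ends.
3. **Alpha rhythm.** Narrowband Gaussian noise centered at 10 Hz
   (σ = 0.6 Hz), 0.7 µV RMS.  The center deliberately coincides with the
   LEFT stimulus so the decision rule is exercised against a structured
   confound rather than only against white noise.
4. **Line interference.** A 60 Hz sinusoid (0.3 µV, common phase), largely
   removed by the 58–62 Hz band-stop.

Amplitude ratios are free parameters, not estimates of any particular
recording; `SimConfig.with_snr(x)` scales the SSVEP amplitudes jointly.
Throughout the tests "calibrated high SNR" means `with_snr(3.0)`, i.e.
3 µV fundamental against the 1 µV background — a strong but not
unrealistic response, chosen once so that single-set decoding is nearly
error-free and end-to-end properties are not borderline.

Flicker schedules are frame-locked: a frequency is accepted only if it is
refresh/k for integer k (within 0.01 Hz).  For odd frame periods the duty
cycle puts the extra frame in the "on" phase (⌈k/2⌉ on, ⌊k/2⌋ off);
`on_frames="floor"` flips this.  The session generator drives the SSVEP at
the *realized* frequencies (60/9, 60/8, 60/7, 60/6, 60/5 Hz) while the
decoder's templates use the nominal two-decimal values; the ≤0.004 Hz
mismatch is far below the ~0.7 Hz resolution of a 1.5 s window.

Everything is a pure function of (config, seed); identical inputs give
bit-identical output.

## Preprocessing

The online path filters causally (forward-only), carrying second-order-
section state across chunks so chunked and whole-stream processing agree
to machine precision.  "Second order" applies to each section: band-pass
5–45 Hz order 2, then band-stops 48–52 and 58–62 Hz, each order 2, in that
fixed order.  A zero-phase (filtfilt) mode exists for offline spectral
figures only.

Detrending is per analysis window and linear (least-squares line removal),
not part of the stateful stream filter: per-chunk detrending would break
the chunked-equals-batch guarantee, and a per-window fit is what an online
implementation can actually do.  Windows are 1.5 s (300 samples) hopped by
50 ms (10 samples); non-integer sample counts are rejected rather than
rounded so window bookkeeping stays exact.

## Decoding

Reference templates use t_n = n/fs from n = 0 per window; since a shifted
sin/cos pair spans the same two-dimensional subspace, the origin is
immaterial to CCA (tested).  The default template holds only the
fundamental pair (N×2); up to 3 harmonics can be enabled, in which case
the channel-max reduction is taken over the full per-channel CCA with all
template columns.

The CCA solver whitens with inverse symmetric square roots of the two
covariance blocks and takes the leading singular value of the whitened
cross-covariance.  A ridge of 1e-12 × trace on each covariance diagonal
handles rank-deficient inputs (duplicate channels, zero segments) without
special cases.  The returned ρ is the absolute correlation clipped to
[0, 1].  For single-channel blocks against an orthonormalized template the
computation reduces to a projection-norm ratio; the stream decoder
exploits this in a vectorized path that is tested to agree with the
windowed solver to 1e-9.

The decision rule collects profiles in consecutive, non-overlapping
30-update blocks (1.5 s at the 50 ms hop), resetting after every decision;
"30% of updates" is read as ≥ ⌈0.3·30⌉ = 9 hits anywhere in the block
(`counting="window"`), with a stricter longest-consecutive-run variant
(`counting="run"`) available.  The winner among valid candidates is the
highest mean of its supra-threshold correlations; ties break to the lowest
frequency index everywhere.  After an emission, profiles earlier than
t + 1 s are discarded, which both rate-limits output and restarts
collection cleanly.

## Rest-state behavior (a deliberate, measured property)

With the default colored background the rest state is *chatty*: filtered
1/f noise and the 10 Hz alpha rhythm hold canonical correlations near or
above the 0.25 threshold often enough that the rule emits roughly one
(mostly LEFT) command per collection-plus-ignore cycle on rest-only
streams.  This is a property of the paper-fixed pipeline constants, not of
the noise scale: ρ is scale-invariant, and even a *purely white*
background leaves ~17% of 1.5 s windows with some ρ ≥ 0.25, so no noise
shape makes the rest state essentially silent at this threshold.  Working
systems suppress this in closed loop because users look away from all
flickers between selections for only a couple of seconds.  Users who want
a quieter simulated rest can raise `sensor_noise_rms_uV`, lower
`alpha_band_amp_uV`, or raise the decision threshold.

A useful consequence: with the stimulus amplitude at zero, nearly every
scored segment still receives some (noise-driven, heavily biased) command,
and since the protocols balance the five commands, any biased or constant
classifier scores exactly 1/N = 20% — the chance level the end-to-end
tests assert, with missing emissions scored as errors.

## Scoring and experiments

Every ground-truth attend segment yields exactly one scored decision.  An
emission at time t is attributed to the segment active at its *evidence
time* t − window_s, because the trailing analysis window means a decision
at t reflects [t − window − collection, t]; plain onset-interval
attribution systematically credits end-of-segment carryover to the
following segment.  The first emission attributed to a segment is its
prediction; no emission scores as a NONE error.  A forced-choice
prediction (argmax of the mean profile over the segment's fully-contained
windows) is reported alongside every log.

Experiment 1 runs n sets of 10 selections (each command twice, shuffled),
3 s dwell and 2 s gaps; dwell is the package's choice (long enough for one
full collection after the response latency).  Experiment 2 plans the
target word (default "머리") into a command script with an ENTER after
each syllable, attends each command in turn, and replays the per-segment
decisions (NONE skipped) through the composition automaton.  Replaying the
scored decisions rather than the raw emission stream is the open-loop
stand-in for the paper-style closed loop, where a subject proceeds only
after feedback.  The window sweep re-runs Experiment 1 at 0.5–3.0 s
windows; its ITR uses T = window + ignore.  Two ITRs are reported
throughout: the rule-timing value with T = collection + ignore = 2.5 s and
an empirical value with T = mean inter-emission interval.  Under the
simulator's stationary signals accuracy keeps improving with window
length; the decline real subjects show beyond ~2 s (fatigue,
non-stationarity) is outside the model and not asserted anywhere.

## Hangul engine

Syllables are composed with the Unicode formula 0xAC00 + (L·21 + V)·28 + T
and verified exhaustively against NFC for all 19×21×28 combinations.  The
automaton implements: multi-tap cycling with wrap-around, committed by any
other key press or any cursor movement (no dwell timeout — a BCI has no
key-up events); vowel-element resolution by a 21-row table over
{ㅣ, ㆍ, ㅡ} with longest-prefix semantics; final-consonant attachment
including the 11 compound finals; stealing of the final by a following
vowel; detachment when a tap cycle reaches a jamo that is illegal in the
final slot (받→밭→바ㄸ); and re-merging when a split-off bare initial
cycles to a jamo that does fit the previous final slot (옐ㅇ→옒), matching
phone IME behavior.  DELETE removes the last element/jamo.

Cursor movement clamps at grid edges and skips through the two empty
cells, continuing in the same direction (a toroidal `wrap` option exists,
off by default, since movement counts depend on it).  The planner maps
text to press units, inserts a minimal two-move detour when two distinct
consonant jamo fall consecutively on the same key (to break the armed
cycle), and routes between keys with BFS shortest paths (deterministic
direction order for ties).  Movements and selections are counted
separately because published keystroke comparisons differ in which they
include; the home position (default (0,0)) is always reported.  The
bundled QWERTY 2-beolsik grid is a synthetic comparison fixture for
movement costs only, never used for composition.

## Known limitations

- No eye-movement, blink or EMG artifacts, and no artifact removal — the
  modeled pipeline applies none.
- Stationary SSVEP amplitude within a segment; no fatigue, adaptation or
  attention drift, hence no window-length optimum like human subjects
  show and no inter-subject variability model.
- The rest state is chattier than a closed-loop deployment would be (see
  above).
- The spectral SNR is a neighbor-bin estimator (k = 10 bins per side,
  ±1 bin and harmonic bins excluded, capped at 100 dB); its absolute
  values carry the usual small-sample bias of log-ratio estimators.
- ERSP uses a Hann short-time transform with 0.5 s segments and 90%
  overlap; off/on transitions are smeared by roughly half a segment plus
  the response latency, so assessments use interval interiors.
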