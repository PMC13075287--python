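"""Confusion metrics, ITR, spectra, SNR, and ERSP."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ssvep_speller import (
    Command,
    SimConfig,
    amplitude_spectrum,
    classification_metrics,
    confusion_matrix,
    ersp,
    itr_bits_per_min,
    snr_at,
)
from ssvep_speller.metrics import ConfusionMatrix, SNR_CAP_DB
from ssvep_speller.preprocess import SignalWindow

FS = 200.0
CMDS = [Command.UP, Command.RIGHT, Command.DOWN, Command.LEFT, Command.SELECT]


class TestConfusionMatrix:
    def test_all_correct_diagonal(self):
        cm = confusion_matrix(CMDS * 2, CMDS * 2)
        assert np.trace(cm.counts) == 10 and cm.total == 10

    def test_hand_count(self):
        cm = confusion_matrix(
            [Command.UP, Command.UP, Command.DOWN],
            [Command.UP, Command.DOWN, Command.DOWN],
        )
        i_up = cm.labels.index("UP")
        i_down = cm.labels.index("DOWN")
        assert cm.counts[i_up, i_down] == 1
        assert cm.counts[i_up, i_up] == 1
        assert cm.counts[i_down, i_down] == 1

    def test_marginals_on_random_pairing(self):
        rng = np.random.default_rng(0)
        t = [CMDS[i] for i in rng.integers(0, 5, 500)]
        p = [CMDS[i] for i in rng.integers(0, 5, 500)]
        cm = confusion_matrix(t, p)
        assert cm.total == 500
        for i, lab in enumerate(cm.labels[:5]):
            assert cm.counts[i].sum() == sum(1 for x in t if x.value == lab)
            assert cm.counts[:, i].sum() == sum(1 for x in p if x.value == lab)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([Command.UP], [])


class TestClassificationMetrics:
    def test_perfect_diagonal_is_all_100(self):
        cm = confusion_matrix(CMDS * 3, CMDS * 3)
        m = classification_metrics(cm)
        for k in ("accuracy", "precision", "recall", "f1"):
            assert m[k] == pytest.approx(100.0)

    def test_binary_toy_per_class_values(self):
        """TP=8, FN=2, FP=1, TN=9 gives precision 88.89, recall 80, F1 84.21."""
        cm = ConfusionMatrix(labels=("pos", "neg"), counts=np.array([[8, 2], [1, 9]]))
        m = classification_metrics(cm)
        pc = m["per_class"]["pos"]
        assert pc["precision"] == pytest.approx(88.89, abs=0.01)
        assert pc["recall"] == pytest.approx(80.00, abs=0.01)
        assert pc["f1"] == pytest.approx(84.21, abs=0.01)
        assert m["accuracy"] == pytest.approx(85.0)

    def test_macro_metrics_invariant_to_class_order(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 20, (5, 5))
        cm = ConfusionMatrix(labels=tuple("ABCDE"), counts=counts)
        m1 = classification_metrics(cm)
        perm = [2, 0, 4, 1, 3]
        cm2 = ConfusionMatrix(
            labels=tuple("ABCDE"[i] for i in perm), counts=counts[np.ix_(perm, perm)]
        )
        m2 = classification_metrics(cm2)
        for k in ("accuracy", "precision", "recall", "f1"):
            assert m1[k] == pytest.approx(m2[k])

    def test_accuracy_equals_micro_recall(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 30, (4, 4))
        cm = ConfusionMatrix(labels=tuple("ABCD"), counts=counts)
        m = classification_metrics(cm)
        micro_recall = 100.0 * np.trace(counts) / counts.sum()
        assert m["accuracy"] == pytest.approx(micro_recall)

    def test_never_predicted_class_warns_and_scores_zero(self):
        cm = ConfusionMatrix(labels=("a", "b"), counts=np.array([[3, 0], [2, 0]]))
        with pytest.warns(UserWarning, match="never predicted"):
            m = classification_metrics(cm)
        assert m["per_class"]["b"]["precision"] == 0.0

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(3)
        t = rng.integers(0, 5, 300)
        p = rng.integers(0, 5, 300)
        cm = confusion_matrix([CMDS[i] for i in t], [CMDS[i] for i in p])
        m = classification_metrics(cm)
        pr, rc, f1, _ = precision_recall_fscore_support(
            t, p, average="macro", zero_division=0
        )
        assert m["precision"] == pytest.approx(100 * pr, abs=1e-9)
        assert m["recall"] == pytest.approx(100 * rc, abs=1e-9)
        assert m["f1"] == pytest.approx(100 * f1, abs=1e-9)


class TestITR:
    def test_printed_worked_example(self):
        assert itr_bits_per_min(5, 0.83, 2.5) == pytest.approx(31.8, abs=0.05)

    def test_chance_level_is_zero(self):
        assert itr_bits_per_min(5, 0.2, 1.7) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_accuracy_closed_form(self):
        assert itr_bits_per_min(5, 1.0, 2.5) == pytest.approx(np.log2(5) * 24, abs=1e-9)

    @given(p=st.floats(0.21, 0.99), dp=st.floats(0.001, 0.2))
    def test_strictly_increasing_above_chance(self, p, dp):
        hi = min(p + dp, 1.0)
        assert itr_bits_per_min(5, hi, 2.5) > itr_bits_per_min(5, p, 2.5)

    @given(t=st.floats(0.5, 10.0), p=st.floats(0.3, 1.0))
    def test_scales_inversely_with_time(self, t, p):
        a = itr_bits_per_min(5, p, t)
        b = itr_bits_per_min(5, p, 2 * t)
        assert a == pytest.approx(2 * b, rel=1e-12)


class TestAmplitudeSpectrum:
    def test_unit_tone_integer_cycles(self):
        t = np.arange(400) / FS
        x = np.sin(2 * np.pi * 10 * t)
        spec = amplitude_spectrum(x, FS)
        amp = spec.amplitude[:, 0]
        i10 = int(np.argmin(np.abs(spec.freqs_hz - 10)))
        assert amp[i10] == pytest.approx(1.0, abs=1e-6)
        others = np.delete(amp, i10)
        assert np.max(others) < 1e-6

    def test_linearity_of_two_tones(self):
        t = np.arange(400) / FS
        x = 0.5 * np.sin(2 * np.pi * 10 * t) + 0.25 * np.sin(2 * np.pi * 20 * t)
        spec = amplitude_spectrum(x, FS)
        amp = spec.amplitude[:, 0]
        assert amp[int(np.argmin(np.abs(spec.freqs_hz - 10)))] == pytest.approx(0.5, abs=1e-6)
        assert amp[int(np.argmin(np.abs(spec.freqs_hz - 20)))] == pytest.approx(0.25, abs=1e-6)

    def test_zero_signal(self):
        spec = amplitude_spectrum(np.zeros(256), FS)
        assert np.all(spec.amplitude == 0)

    def test_parseval_power_identity(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(512)
        x -= x.mean()
        spec = amplitude_spectrum(x, FS)
        amp = spec.amplitude[:, 0]
        power = amp[0] ** 2 + amp[-1] ** 2 + 0.5 * np.sum(amp[1:-1] ** 2)
        assert power == pytest.approx(np.mean(x**2), rel=1e-6)


class TestSnr:
    def _tone_over_floor(self, floor):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 10 * t)
        spec = amplitude_spectrum(x, FS)
        if floor:
            i10 = int(np.argmin(np.abs(spec.freqs_hz - 10)))
            mask = np.ones(len(spec.freqs_hz), dtype=bool)
            mask[i10] = False
            spec.amplitude[mask, 0] += floor
        return spec

    def test_tone_amplitude_1_over_floor_0p1_is_20db(self):
        spec = self._tone_over_floor(0.1)
        assert snr_at(spec, 10.0) == pytest.approx(20.0, abs=0.1)

    def test_noise_free_tone_capped(self):
        spec = self._tone_over_floor(0.0)
        assert snr_at(spec, 10.0) == SNR_CAP_DB

    def test_white_noise_centered_near_zero(self):
        # Rayleigh-magnitude bins give a small negative (Jensen) bias of
        # a couple of dB; the distribution is centered near 0 relative to
        # the ~+-10 dB single-bin spread.
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            spec = amplitude_spectrum(rng.standard_normal(1000), FS)
            vals.append(snr_at(spec, 10.0))
        assert abs(np.mean(vals)) < 3.0
        assert np.std(vals) > 1.0

    def test_insufficient_neighbors_rejected(self):
        spec = amplitude_spectrum(np.random.default_rng(0).standard_normal(128), FS)
        with pytest.raises(ValueError):
            snr_at(spec, 99.0, k_neighbors=10)


class TestErsp:
    def _noise_epochs(self, n=12):
        out = []
        for s in range(n):
            rng = np.random.default_rng(s)
            out.append(SignalWindow(rng.standard_normal((1200, 2)), FS, t_start_s=-2.0))
        return out

    def test_stationary_noise_is_flat(self):
        # no structure: mean near 0 dB; isolated pixels fluctuate a few dB
        res = ersp(self._noise_epochs(), baseline_interval_s=(-2.0, 0.0))
        assert abs(res.db.mean()) < 0.5
        assert np.quantile(np.abs(res.db), 0.95) < 2.5

    def test_doubling_power_raises_about_3db(self):
        base, boost = [], []
        for s in range(6):
            rng = np.random.default_rng(s)
            x = rng.standard_normal((1200, 2))
            y = x.copy()
            y[400:] *= np.sqrt(2.0)
            base.append(SignalWindow(x, FS, t_start_s=-2.0))
            boost.append(SignalWindow(y, FS, t_start_s=-2.0))
        r0 = ersp(base, (-2.0, 0.0))
        r1 = ersp(boost, (-2.0, 0.0))
        late = r1.times_s > 0.5
        diff = (r1.db[:, late] - r0.db[:, late]).mean()
        assert diff == pytest.approx(3.0, abs=0.7)

    def test_baseline_outside_epoch_rejected(self):
        with pytest.raises(ValueError):
            ersp(self._noise_epochs(1), baseline_interval_s=(-5.0, -3.0))
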