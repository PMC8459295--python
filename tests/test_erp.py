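"""Evoked subtraction, response-locked epoching, window finding, amplitudes."""

import numpy as np
import pandas as pd
import pytest

from crnpipe.config import EpochConfig
from crnpipe.erp import (
    ComponentWindow,
    EpochSet,
    apply_trial_criteria,
    evoked_average,
    extract_response_epochs,
    find_component_window,
    mean_amplitude,
)
from crnpipe.preprocessing import Recording

RATE = 512.0


def _trials(rows):
    defaults = dict(subject=0, condition="gain", block=1, trial=1, trial_type="go", onset_s=2.0, rt_s=0.4, responded=1, correct=1)
    return pd.DataFrame([{**defaults, **r} for r in rows])


def _rec(data, labels=("FCz", "Cz"), **kw):
    return Recording(np.asarray(data, float), RATE, list(labels), **kw)


def _flat_rec(n_s=30.0, n_ch=2):
    return _rec(np.zeros((n_ch, int(n_s * RATE))))


class TestEvokedAverage:
    def test_identical_trials_average_to_single_trial(self, rng):
        rec = _flat_rec()
        template = rng.standard_normal(int(1.5 * RATE))
        trials = _trials([{"trial": i + 1, "onset_s": 2.0 + 3.0 * i} for i in range(5)])
        for onset in trials.onset_s:
            k = int(onset * RATE)
            rec.data[:, k : k + template.size] += template
        ev = evoked_average(rec, trials, "CRN")
        assert np.allclose(ev[0], template)

    def test_ern_average_uses_all_nogo_trials(self):
        """The ERN evoked average pools all no-go trials, not only false alarms."""
        rec = _flat_rec()
        trials = _trials(
            [
                {"trial": 1, "trial_type": "nogo", "onset_s": 2.0, "correct": 0, "responded": 1, "rt_s": 0.3},
                {"trial": 2, "trial_type": "nogo", "onset_s": 6.0, "correct": 1, "responded": 0, "rt_s": np.nan},
            ]
        )
        # distinct constant payloads on the two no-go trials
        for onset, value in zip(trials.onset_s, (1.0, 3.0)):
            k = int(onset * RATE)
            rec.data[:, k : k + int(1.5 * RATE)] += value
        ev = evoked_average(rec, trials, "ERN")
        assert np.allclose(ev, 2.0)  # mean of both trials, not just the false alarm

    def test_zero_qualifying_trials_is_error(self):
        rec = _flat_rec()
        trials = _trials([{"correct": 0, "responded": 0, "rt_s": np.nan}])
        with pytest.raises(ValueError, match="qualifying"):
            evoked_average(rec, trials, "CRN")

    def test_average_converges_to_template(self, rng):
        """With zero-mean noise, the 200-trial average is within 3 SE of the
        template at every sample."""
        n_samples = int(700.0 * RATE)
        rec = _rec(rng.standard_normal((1, n_samples)), labels=("FCz",))
        template = np.sin(np.linspace(0, 6 * np.pi, int(1.5 * RATE)))
        trials = _trials([{"trial": i + 1, "onset_s": 2.0 + 3.0 * i} for i in range(200)])
        for onset in trials.onset_s:
            k = int(onset * RATE)
            rec.data[0, k : k + template.size] += template
        ev = evoked_average(rec, trials, "CRN")
        se = 1.0 / np.sqrt(200)
        assert np.all(np.abs(ev[0] - template) < 3.5 * se)


class TestEpochExtraction:
    def test_perfect_subtraction_leaves_zero(self, rng):
        """A trial consisting only of stimulus-evoked activity is ~0 after
        evoked subtraction."""
        rec = _flat_rec()
        template = rng.standard_normal(int(1.5 * RATE))
        trials = _trials([{"trial": i + 1, "onset_s": 2.0 + 3.0 * i} for i in range(4)])
        for onset in trials.onset_s:
            k = int(onset * RATE)
            rec.data[:, k : k + template.size] += template
        ev = evoked_average(rec, trials, "CRN")
        epochs, log = extract_response_epochs(rec, trials, ev, "CRN")
        assert epochs.n_trials == 4 and not log
        assert np.abs(epochs.waveforms).max() < 1e-10

    def test_baseline_removes_constant_offset(self):
        rec = _flat_rec()
        rec.data += 3.0
        trials = _trials([{}])
        ev = np.zeros((2, int(1.5 * RATE)))
        epochs, _ = extract_response_epochs(rec, trials, ev, "CRN")
        assert np.abs(epochs.waveforms).max() < 1e-12

    def test_epoch_overlapping_bad_segment_is_rejected_and_logged(self):
        rec = _flat_rec()
        trials = _trials([{"trial": 1, "onset_s": 2.0}, {"trial": 2, "onset_s": 8.0}])
        resp = int((2.0 + 0.4) * RATE)
        rec.bad_segments = [(resp, resp + 10)]
        ev = np.zeros((2, int(1.5 * RATE)))
        epochs, log = extract_response_epochs(rec, trials, ev, "CRN")
        assert epochs.n_trials == 1
        assert log == [{"subject": 0, "block": 1, "trial": 1, "reason": "overlaps bad segment"}]

    def test_epoch_past_recording_end_is_dropped(self):
        rec = _flat_rec(4.0)
        trials = _trials([{"onset_s": 3.8}])
        ev = np.zeros((2, int(1.5 * RATE)))
        epochs, log = extract_response_epochs(rec, trials, ev, "CRN")
        assert epochs.n_trials == 0
        assert log[0]["reason"] == "epoch outside recording"

    def test_epoch_time_axis_spans_plus_minus_500ms(self):
        rec = _flat_rec()
        epochs, _ = extract_response_epochs(rec, _trials([{}]), np.zeros((2, int(1.5 * RATE))), "CRN")
        assert epochs.times_ms[0] == pytest.approx(-500.0)
        assert epochs.times_ms[-1] == pytest.approx(500.0)


class TestComponentWindow:
    def _epochs(self, wave):
        times = np.arange(-256, 257) / RATE * 1000
        return times, wave

    def test_synthetic_deflection_at_40ms(self):
        times = np.arange(-256, 257) / RATE * 1000
        grand = -np.exp(-0.5 * ((times - 40.0) / 12.0) ** 2)
        w = find_component_window(grand, times)
        assert (w.start_ms, w.peak_ms, w.end_ms) == (-10.0, 40.0, 90.0)

    def test_window_is_peak_plus_minus_50(self):
        w = ComponentWindow(peak_ms=20.0)
        assert (w.start_ms, w.end_ms) == (-30.0, 70.0)
        w = ComponentWindow(peak_ms=59.0)
        assert (w.start_ms, w.end_ms) == (9.0, 109.0)

    def test_search_range_restricts_peak(self):
        times = np.arange(-256, 257) / RATE * 1000
        grand = -np.exp(-0.5 * ((times + 100.0) / 10.0) ** 2)  # deflection before the response
        grand += -0.5 * np.exp(-0.5 * ((times - 50.0) / 10.0) ** 2)
        w = find_component_window(grand, times)
        assert w.peak_ms == 50.0

    def test_non_finite_grand_mean_is_error(self):
        times = np.arange(-256, 257) / RATE * 1000
        grand = np.full_like(times, np.nan)
        with pytest.raises(ValueError, match="finite"):
            find_component_window(grand, times)


class TestMeanAmplitude:
    def _epochset(self, waveforms):
        times = np.arange(-256, 257) / RATE * 1000
        trials = _trials([{"trial": i + 1} for i in range(waveforms.shape[0])])
        return EpochSet(waveforms, times, ["FCz", "Cz"], trials, "CRN", 0)

    def test_constant_epoch(self):
        es = self._epochset(-np.ones((3, 2, 513)))
        out = mean_amplitude(es, ComponentWindow(20.0))
        assert np.allclose(out.amplitude, -1.0)

    def test_antisymmetric_window_averages_to_zero(self):
        times = np.arange(-256, 257) / RATE * 1000
        wave = np.zeros((1, 2, 513))
        sel = (times >= -30 - 1e-9) & (times <= 70 + 1e-9)
        idx = np.flatnonzero(sel)
        half = len(idx) // 2
        wave[0, 0, idx[:half]] = 2.0
        wave[0, 0, idx[half : 2 * half]] = -2.0
        out = mean_amplitude(self._epochset(wave), ComponentWindow(20.0))
        assert out.amplitude.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_missing_channel_is_error(self):
        es = self._epochset(np.zeros((1, 2, 513)))
        with pytest.raises(KeyError):
            mean_amplitude(es, ComponentWindow(20.0), channel="Pz")

    def test_window_outside_epoch_is_error(self):
        es = self._epochset(np.zeros((1, 2, 513)))
        with pytest.raises(ValueError, match="window"):
            mean_amplitude(es, ComponentWindow(480.0))


class TestTrialCriteria:
    def _amps(self, counts):
        rows = []
        for subject, n in counts.items():
            for k in range(n):
                rows.append({"subject": subject, "condition": "gain", "block": 1 + k % 20, "trial": k, "rt_s": 0.4, "amplitude": -1.0, "kind": "ERN", "usable": True})
        return pd.DataFrame(rows)

    def _trials_fa(self, fa_blocks, n_blocks=20, subject=0):
        """Trial table where `fa_blocks` blocks have 5/6 false alarms."""
        rows = []
        for blk in range(1, n_blocks + 1):
            n_fa = 5 if blk <= fa_blocks else 1
            for t in range(6):
                fa = t < n_fa
                rows.append(
                    dict(subject=subject, condition="gain", block=blk, trial=t, trial_type="nogo", onset_s=0.0, rt_s=0.3 if fa else np.nan, responded=int(fa), correct=int(not fa))
                )
        return pd.DataFrame(rows)

    def test_few_error_trials_excluded_from_ern_only(self):
        amps = self._amps({0: 5, 1: 10})
        trials = pd.concat([self._trials_fa(0, subject=0), self._trials_fa(0, subject=1)], ignore_index=True)
        ern, report = apply_trial_criteria(amps, trials, "ERN")
        assert set(ern.subject) == {1}
        assert any(r["subject"] == 0 and "fewer than 6" in r["rule"] for r in report)
        crn, report_crn = apply_trial_criteria(amps, trials, "CRN")
        assert set(crn.subject) == {0, 1}

    def test_high_fa_rate_on_many_blocks_excludes_entirely(self):
        """5/6 false alarms (83%) on 12 blocks triggers the inattention rule."""
        amps = self._amps({0: 30, 1: 30})
        trials = pd.concat([self._trials_fa(12, subject=0), self._trials_fa(2, subject=1)], ignore_index=True)
        for kind in ("CRN", "ERN"):
            kept, report = apply_trial_criteria(amps, trials, kind)
            assert 0 not in set(kept.subject)
            assert any(r["subject"] == 0 and "83%" in r["rule"] for r in report)

    def test_nine_high_fa_blocks_not_excluded(self):
        amps = self._amps({0: 30})
        trials = self._trials_fa(9, subject=0)
        kept, report = apply_trial_criteria(amps, trials, "CRN")
        assert set(kept.subject) == {0} and report == []

    def test_no_exclusions_is_identity(self):
        amps = self._amps({0: 10, 1: 12})
        trials = pd.concat([self._trials_fa(0, subject=0), self._trials_fa(0, subject=1)], ignore_index=True)
        kept, report = apply_trial_criteria(amps, trials, "ERN")
        assert kept.equals(amps.reset_index(drop=True)) and report == []
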