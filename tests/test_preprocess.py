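"""Filtering, resampling, epoching, rejection, and HDF5 round trips."""

import numpy as np
import pytest
from scipy.signal import periodogram

from emdecode.preprocess import (
    Epochs,
    RawRecording,
    bandpass,
    baseline_correct,
    epoch,
    load_epochs,
    reject_peak_to_peak,
    resample,
    save_epochs,
)


def make_raw(x, fs=1000.0, events=()):
    data = np.atleast_2d(x)
    return RawRecording(
        data=data,
        fs=fs,
        channel_ids=[f"ch{i}" for i in range(data.shape[0])],
        events=list(events),
    )


class TestBandpass:
    def test_passband_identity(self):
        # the 0.5 Hz edge rings for seconds; judge fidelity away from edges
        t = np.arange(20000) / 1000.0
        raw = make_raw(np.sin(2 * np.pi * 10 * t))
        out = bandpass(raw, 0.5, 100.0)
        interior = slice(5000, -5000)
        assert np.max(np.abs(out.data[0][interior] - raw.data[0][interior])) < 0.01

    def test_dc_rejected(self):
        raw = make_raw(np.full(4000, 3.0))
        out = bandpass(raw, 0.5, 100.0)
        assert np.max(np.abs(out.data)) < 0.05

    def test_stopband_attenuation_exceeds_20db(self):
        t = np.arange(8000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 150 * t)
        out = bandpass(make_raw(x), 0.5, 100.0)
        f, p = periodogram(out.data[0], fs=1000.0)
        p10 = p[np.argmin(np.abs(f - 10))]
        p150 = p[np.argmin(np.abs(f - 150))]
        assert 10 * np.log10(p10 / p150) > 20

    def test_edge_above_nyquist_rejected(self):
        raw = make_raw(np.zeros(100), fs=200.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(raw, 0.5, 100.0)


class TestResample:
    def test_length_arithmetic_1000_to_200(self):
        raw = make_raw(np.zeros(1100))  # 1100 ms at 1000 Hz
        out = resample(raw, 200.0)
        assert out.data.shape[-1] == 220
        assert out.fs == 200.0

    def test_sinusoid_matches_analytic_resampling(self):
        t = np.arange(2000) / 1000.0
        raw = make_raw(np.sin(2 * np.pi * 3 * t))
        out = resample(raw, 200.0)
        t_new = np.arange(out.data.shape[-1]) / 200.0
        ref = np.sin(2 * np.pi * 3 * t_new)
        r = np.corrcoef(out.data[0][5:-5], ref[5:-5])[0, 1]
        assert r > 0.999

    def test_same_rate_is_identity(self):
        raw = make_raw(np.random.default_rng(0).standard_normal(500))
        assert resample(raw, 1000.0) is raw

    def test_event_indices_rescaled(self):
        raw = make_raw(np.zeros(1000), events=[(500, "a")])
        out = resample(raw, 200.0)
        assert out.events == [(100, "a")]


class TestEpoch:
    def test_trial_count_and_length(self):
        raw = make_raw(np.zeros(2000), fs=200.0, events=[(200, "a"), (700, "b"), (1200, "a")])
        ep = epoch(raw, tmin=-100.0, tmax=1000.0)
        assert ep.data.shape == (3, 1, 221)
        assert list(ep.labels) == ["a", "b", "a"]
        assert ep.tmin == -100.0

    def test_out_of_bounds_event_dropped(self):
        raw = make_raw(np.zeros(2000), fs=200.0, events=[(5, "a"), (500, "b")])
        ep = epoch(raw, tmin=-100.0, tmax=1000.0)
        assert ep.n_trials == 1
        assert list(ep.labels) == ["b"]

    def test_copy_semantics_on_ramp(self):
        x = np.arange(1000, dtype=float)
        raw = make_raw(x, fs=200.0, events=[(400, "a")])
        ep = epoch(raw, tmin=-100.0, tmax=100.0)
        assert np.array_equal(ep.data[0, 0], x[380:421])


class TestRejectPeakToPeak:
    @staticmethod
    def epochs_with_p2p(p2ps):
        data = np.stack([np.linspace(0, p, 50)[None, :] for p in p2ps])
        return Epochs(data=data, fs=200.0, tmin=-100.0, labels=np.array(["x"] * len(p2ps)))

    def test_threshold_partitions_trials(self):
        ep = self.epochs_with_p2p([1.0, 5.0, 9.0])
        kept, n_rej = reject_peak_to_peak(ep, 6.0)
        assert kept.n_trials == 2
        assert n_rej == 1

    def test_infinite_threshold_keeps_all(self):
        ep = self.epochs_with_p2p([1.0, 5.0, 9.0])
        kept, n_rej = reject_peak_to_peak(ep, np.inf)
        assert kept.n_trials == 3 and n_rej == 0

    def test_survivors_unaltered(self):
        ep = self.epochs_with_p2p([1.0, 9.0])
        kept, _ = reject_peak_to_peak(ep, 6.0)
        assert np.array_equal(kept.data[0], ep.data[0])

    def test_all_rejected_errors_with_threshold_named(self):
        ep = self.epochs_with_p2p([5.0, 9.0])
        with pytest.raises(ValueError, match="0.5"):
            reject_peak_to_peak(ep, 0.5)

    def test_spiked_trials_counted_exactly(self, rng):
        data = 0.1 * rng.standard_normal((20, 3, 50))
        spiked = rng.choice(20, size=2, replace=False)
        data[spiked, 0, 10] += 100.0
        ep = Epochs(data=data, fs=200.0, tmin=0.0, labels=np.array(["x"] * 20))
        _, n_rej = reject_peak_to_peak(ep, 10.0)
        assert n_rej == 2


class TestBaselineAndIO:
    def test_baseline_zeroes_prestim_mean(self, rng):
        data = rng.standard_normal((4, 3, 221)) + 5.0
        ep = Epochs(data=data, fs=200.0, tmin=-100.0, labels=np.array(["x"] * 4))
        out = baseline_correct(ep)
        pre = out.times <= 0
        assert np.allclose(out.data[:, :, pre].mean(axis=-1), 0.0, atol=1e-12)

    def test_hdf5_roundtrip(self, tmp_path, rng):
        ep = Epochs(
            data=rng.standard_normal((3, 2, 50)),
            fs=200.0,
            tmin=-100.0,
            labels=np.array(["famous", "scrambled", "famous"]),
            participant_id="sub-01",
            channel_ids=["MEG001", "MEG002"],
        )
        path = tmp_path / "ep.h5"
        save_epochs(ep, path)
        back = load_epochs(path)
        assert np.array_equal(back.data, ep.data)
        assert list(back.labels) == list(ep.labels)
        assert back.fs == ep.fs and back.tmin == ep.tmin
        assert back.channel_ids == ep.channel_ids


class TestOrderOfOperations:
    def test_filter_resample_epoch_commutes_with_analytic_reference(self):
        """bandpass->resample->epoch of a long sinusoid matches epoching the
        analytically filtered/resampled signal (passband tone is untouched)."""
        fs = 1000.0
        t = np.arange(16000) / fs
        x = np.sin(2 * np.pi * 7 * t)
        raw = make_raw(x, fs=fs, events=[(8000, "a")])  # mid-record: edge ring decayed
        out = epoch(resample(bandpass(raw, 0.5, 100.0), 200.0), -100.0, 1000.0)
        t_trial = (1600 + np.arange(-20, 201)) / 200.0  # event lands at sample 1600
        ref = np.sin(2 * np.pi * 7 * t_trial)
        assert np.max(np.abs(out.data[0, 0] - ref)) < 0.02
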