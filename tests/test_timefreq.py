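"""EEG filtering, epoching, Morlet power, dB baselining, band averaging."""

import numpy as np
import pandas as pd
import pytest

from reachadapt import timefreq
from reachadapt.timefreq import EEGRecording, Epochs

FS = 500.0


def _recording(data, markers=None, channels=None):
    n_ch = data.shape[0]
    channels = channels or tuple(f"ch{i}" for i in range(n_ch))
    markers = (
        markers
        if markers is not None
        else pd.DataFrame(dict(label=[], sample=[], trial=[]))
    )
    return EEGRecording(channels=tuple(channels), fs=FS, data=data, markers=markers)


def _epochs(data, fs=FS, alignment="feedback"):
    n_tr, n_ch, n_s = data.shape
    times = (np.arange(n_s) - n_s // 2) / fs
    return Epochs(
        alignment=alignment,
        window=(times[0], times[-1]),
        data=data,
        times=times,
        fs=fs,
        channels=tuple(f"ch{i}" for i in range(n_ch)),
        trial_keys=np.arange(n_tr),
    )


def _component_amplitude(x, freq, fs=FS):
    """Amplitude of the ``freq`` component by complex demodulation, immune to
    the slow edge transients of the 0.05 Hz high-pass."""
    n = int(len(x) // (fs / freq)) * int(fs / freq)  # integer number of cycles
    t = np.arange(n) / fs
    return 2.0 * np.abs(np.mean(x[:n] * np.exp(-2j * np.pi * freq * t)))


class TestPreprocess:
    def test_passband_sinusoid_preserved(self):
        t = np.arange(int(30 * FS)) / FS
        sig = np.sin(2 * np.pi * 10.0 * t)[None, :]
        out = timefreq.preprocess_raw(_recording(sig)).data[0]
        core = out[int(2 * FS) : -int(2 * FS)]
        assert _component_amplitude(core, 10.0) == pytest.approx(1.0, rel=0.02)

    def test_line_frequency_notched_by_20_db(self):
        t = np.arange(int(30 * FS)) / FS
        sig = np.sin(2 * np.pi * 50.0 * t)[None, :]
        out = timefreq.preprocess_raw(_recording(sig)).data[0]
        core = out[int(2 * FS) : -int(2 * FS)]
        assert 20 * np.log10(_component_amplitude(core, 50.0)) < -20.0

    def test_dc_offset_removed(self, rng):
        sig = np.full((1, int(60 * FS)), 100.0) + rng.normal(0, 1, (1, int(60 * FS)))
        out = timefreq.preprocess_raw(_recording(sig)).data[0]
        assert abs(out.mean()) < 1.0

    def test_low_sampling_rate_rejected(self):
        rec = EEGRecording(
            channels=("a",), fs=150.0, data=np.zeros((1, 1000)),
            markers=pd.DataFrame(dict(label=[], sample=[], trial=[])),
        )
        with pytest.raises(ValueError):
            timefreq.preprocess_raw(rec)


class TestEpoching:
    def test_interior_markers_give_full_epochs(self, rng):
        data = rng.normal(size=(2, int(60 * FS)))
        samples = (np.arange(10) * 5 + 5) * int(FS)
        markers = pd.DataFrame(
            dict(label="feedback", sample=samples, trial=np.arange(len(samples)))
        )
        ep = timefreq.epoch_by_event(_recording(data, markers), "feedback")
        assert ep.data.shape == (10, 2, int(4 * FS))

    def test_edge_marker_dropped(self, rng):
        data = rng.normal(size=(1, int(20 * FS)))
        markers = pd.DataFrame(
            dict(label="feedback", sample=[int(5 * FS), int(19.5 * FS)], trial=[0, 1])
        )
        ep = timefreq.epoch_by_event(_recording(data, markers), "feedback")
        assert ep.data.shape[0] == 1
        assert ep.trial_keys.tolist() == [0]

    def test_epoch_is_a_direct_slice_of_the_recording(self, rng):
        data = rng.normal(size=(2, int(20 * FS)))
        m = int(9 * FS)
        markers = pd.DataFrame(dict(label="go", sample=[m], trial=[0]))
        ep = timefreq.epoch_by_event(_recording(data, markers), "go")
        assert np.array_equal(ep.data[0], data[:, m - int(2 * FS) : m + int(2 * FS)])

    def test_unknown_label_rejected(self, rng):
        data = rng.normal(size=(1, int(20 * FS)))
        markers = pd.DataFrame(dict(label="go", sample=[int(9 * FS)], trial=[0]))
        with pytest.raises(ValueError):
            timefreq.epoch_by_event(_recording(data, markers), "feedback")


class TestMorlet:
    def test_pure_tone_peaks_at_its_frequency(self):
        t = np.arange(int(4 * FS)) / FS
        data = np.sin(2 * np.pi * 10.0 * t)[None, None, :]
        tf = timefreq.morlet_tfr(_epochs(data))
        interior = np.abs(tf.times) < 1.0
        peak_freqs = tf.freqs[np.nanargmax(tf.values[0, 0][:, interior], axis=0)]
        assert np.all(peak_freqs == 10.0)

    def test_power_is_quadratic_in_amplitude(self):
        t = np.arange(int(4 * FS)) / FS
        base = np.sin(2 * np.pi * 10.0 * t)[None, None, :]
        tf1 = timefreq.morlet_tfr(_epochs(base))
        tf2 = timefreq.morlet_tfr(_epochs(2.0 * base))
        sel = (tf1.freqs == 10.0, np.abs(tf1.times) < 1.0)
        p1 = tf1.values[0, 0][sel[0]][:, sel[1]]
        p2 = tf2.values[0, 0][sel[0]][:, sel[1]]
        assert np.allclose(p2, 4.0 * p1, rtol=0.01)

    def test_time_bins_on_50ms_grid(self, rng):
        data = rng.normal(size=(1, 1, int(4 * FS)))
        tf = timefreq.morlet_tfr(_epochs(data))
        steps = np.diff(tf.times)
        assert np.allclose(steps, 0.05, atol=1e-12)
        assert np.allclose(np.round(tf.times / 0.05), tf.times / 0.05, atol=1e-9)

    def test_burst_time_course_matches_spectrogram_oracle(self, rng):
        from scipy import signal as sp_signal

        t = np.arange(int(4 * FS)) / FS
        on = (t >= 1.5) & (t < 2.0)
        sos = sp_signal.butter(4, (18, 22), btype="bandpass", fs=FS, output="sos")
        trials = []
        for _ in range(10):
            carrier = sp_signal.sosfiltfilt(sos, rng.normal(size=t.size))
            burst = np.zeros_like(t)
            burst[on] = carrier[on] * 40.0
            trials.append(rng.normal(size=t.size) + burst)
        data = np.asarray(trials)[:, None, :]
        tf = timefreq.morlet_tfr(_epochs(data))
        mine = np.nanmean(tf.values[:, 0], axis=0)[tf.freqs == 20.0][0]
        oracles = []
        for k in range(len(trials)):
            f, tt, S = sp_signal.spectrogram(
                data[k, 0], fs=FS, nperseg=int(0.2 * FS), noverlap=int(0.2 * FS) - 25
            )
            oracles.append(S[np.argmin(np.abs(f - 20.0))])
        grid = tt - 2.0  # spectrogram times run from epoch start
        interior = (tf.times > -1.2) & (tf.times < 1.2)
        oracle_interp = np.interp(tf.times[interior], grid, np.mean(oracles, axis=0))
        r = np.corrcoef(mine[interior], oracle_interp)[0, 1]
        assert r > 0.95

    def test_matches_mne_where_defined(self, rng):
        mne = pytest.importorskip("mne")
        data = rng.normal(size=(3, 2, int(4 * FS)))
        freqs = np.arange(8.0, 31.0)
        tf = timefreq.morlet_tfr(_epochs(data), freqs=freqs)
        ref = mne.time_frequency.tfr_array_morlet(
            data, FS, freqs, n_cycles=3.0, output="power", zero_mean=True,
            decim=int(FS / 20), verbose="error",
        )
        # Units differ; per-frequency time courses must be proportional.
        for k in range(len(freqs)):
            interior = np.abs(tf.times) < 1.5
            a = tf.values[0, 0, k][interior]
            b = ref[0, 0, k][interior]
            r = np.corrcoef(a, b)[0, 1]
            assert r > 0.99

    def test_frequency_above_nyquist_rejected(self, rng):
        data = rng.normal(size=(1, 1, int(4 * FS)))
        with pytest.raises(ValueError):
            timefreq.morlet_tfr(_epochs(data), freqs=np.array([260.0]))

    def test_edge_bins_are_invalid_not_zero(self, rng):
        data = rng.normal(size=(1, 1, int(4 * FS)))
        tf = timefreq.morlet_tfr(_epochs(data))
        assert np.isnan(tf.values[0, 0, 0, 0])  # 1 Hz at the epoch edge
        assert not np.isnan(tf.values[0, 0, -1, len(tf.times) // 2])


class TestDbNormalize:
    def test_time_constant_power_normalizes_to_zero_everywhere(self, rng):
        # A map whose power is constant over time equals its own baseline,
        # so the dB values vanish identically.
        vals = np.repeat(rng.uniform(0.5, 5.0, size=(5, 2, 30, 1)), 40, axis=-1)
        times = (np.arange(40) - 20) * 0.05
        tf = timefreq.TimeFrequencyMap(
            values=vals, freqs=np.arange(1.0, 31.0), times=times,
            channels=("a", "b"), alignment="feedback",
        )
        db = timefreq.db_normalize(tf, (-0.1, 0.0))
        assert np.allclose(db.values, 0.0, atol=1e-9)

    def test_tenfold_power_is_10_db(self):
        vals = np.ones((1, 1, 3, 20))
        vals[0, 0, :, 10] = 10.0
        tf = timefreq.TimeFrequencyMap(
            values=vals, freqs=np.array([1.0, 2.0, 3.0]),
            times=np.arange(-10, 10) * 0.05, channels=("a",), alignment="feedback",
        )
        db = timefreq.db_normalize(tf, (-0.5, -0.05))
        assert db.values[0, 0, 0, 10] == pytest.approx(10.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        vals = rng.uniform(0.5, 5.0, size=(2, 2, 4, 30))
        times = (np.arange(30) - 15) * 0.05
        tf = timefreq.TimeFrequencyMap(
            values=vals, freqs=np.arange(1.0, 5.0), times=times,
            channels=("a", "b"), alignment="feedback",
        )
        db = timefreq.db_normalize(tf, (-0.1, 0.0))
        in_base = (times >= -0.1) & (times <= 0.0)
        expect = 10 * np.log10(vals / vals[..., in_base].mean(axis=-1, keepdims=True))
        assert np.allclose(db.values, expect, atol=1e-12)

    def test_amplitude_rescaling_cancels(self, rng):
        data = rng.normal(size=(2, 1, int(4 * FS)))
        db1 = timefreq.db_normalize(timefreq.morlet_tfr(_epochs(data)), (-0.1, 0.0))
        db2 = timefreq.db_normalize(timefreq.morlet_tfr(_epochs(3.0 * data)), (-0.1, 0.0))
        assert np.allclose(np.nan_to_num(db1.values), np.nan_to_num(db2.values), atol=1e-9)

    def test_nonpositive_baseline_rejected(self):
        vals = np.zeros((1, 1, 1, 10))
        tf = timefreq.TimeFrequencyMap(
            values=vals, freqs=np.array([1.0]), times=np.arange(10) * 0.05 - 0.25,
            channels=("a",), alignment="feedback",
        )
        with pytest.raises(ValueError):
            timefreq.db_normalize(tf, (-0.25, -0.05))


class TestBandAverage:
    @staticmethod
    def _map(vals, channels=("P3", "Pz", "P4")):
        n_t = vals.shape[-1]
        return timefreq.TimeFrequencyMap(
            values=vals, freqs=np.arange(1.0, 31.0),
            times=np.arange(n_t) * 0.05, channels=channels, alignment="feedback",
            kind="db",
        )

    def test_constant_map_gives_constant_series(self):
        tf = self._map(np.full((4, 3, 30, 10), 2.5))
        out = timefreq.band_average(tf, electrode_groups={"parietal": ("P3", "Pz", "P4")})
        assert np.allclose(out["value"], 2.5)

    def test_delta_band_covers_four_inclusive_bins(self):
        vals = np.zeros((1, 1, 30, 4))
        vals[0, 0, :, :] = np.arange(1, 31)[:, None]  # value = frequency
        tf = self._map(vals, channels=("Pz",))
        out = timefreq.band_average(tf, electrode_groups={"Pz": ("Pz",)})
        by = out.groupby("band")["value"].mean()
        assert by["delta"] == pytest.approx(np.mean([1, 2, 3, 4]))
        assert by["theta"] == pytest.approx(np.mean([4, 5, 6, 7, 8]))  # shared 4 Hz edge
        assert by["beta"] == pytest.approx(np.mean(np.arange(13, 31)))

    def test_matches_explicit_loop_oracle(self, rng):
        vals = rng.normal(size=(3, 3, 30, 8))
        tf = self._map(vals)
        out = timefreq.band_average(tf, electrode_groups={"parietal": ("P3", "Pz", "P4")})
        sel = out[(out.band == "alpha") & (out.group == "parietal")].sort_values("time_ms")
        freqs = np.arange(1, 31)
        fsel = (freqs >= 8) & (freqs <= 13)
        for j, (_, row) in enumerate(sel.iterrows()):
            acc = [
                vals[tr, ch, k, j]
                for tr in range(3)
                for ch in range(3)
                for k in np.flatnonzero(fsel)
            ]
            assert row["value"] == pytest.approx(np.mean(acc), abs=1e-12)

    def test_band_and_trial_averaging_commute(self, rng):
        data = rng.normal(size=(6, 3, int(4 * FS)))
        tf = timefreq.db_normalize(timefreq.morlet_tfr(
            _epochs(data)), (-0.1, 0.0))
        groups = {"parietal": ("ch0", "ch1", "ch2")}
        direct = timefreq.band_average(tf, electrode_groups=groups)
        via_mean = timefreq.band_average(timefreq.average_trials(tf), electrode_groups=groups)
        assert np.allclose(
            direct["value"].to_numpy(), via_mean["value"].to_numpy(), atol=1e-9, equal_nan=True
        )

    def test_unknown_electrode_rejected(self, rng):
        tf = self._map(rng.normal(size=(1, 3, 30, 4)))
        with pytest.raises(ValueError):
            timefreq.band_average(tf, electrode_groups={"x": ("Cz",)})
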