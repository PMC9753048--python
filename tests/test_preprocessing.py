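import numpy as np
import pytest

import semdecode as sd
from helpers import brute_force_bins


def make_recording(signal, rate=2000.0):
    ids = tuple(f"ch{i}" for i in range(signal.shape[0]))
    return sd.Recording(np.asarray(signal, float), rate=rate, channel_ids=ids)


class TestCommonAverageReference:
    def test_zero_mean_columns(self):
        rng = np.random.default_rng(0)
        rec = make_recording(rng.standard_normal((5, 1000)))
        out = sd.common_average_reference(rec)
        assert np.abs(out.signal.mean(axis=0)).max() < 1e-10

    def test_antisymmetric_pair_unchanged(self):
        x = np.sin(np.linspace(0, 10, 500))
        rec = make_recording(np.vstack([x, -x]))
        out = sd.common_average_reference(rec)
        np.testing.assert_allclose(out.signal, rec.signal, atol=1e-12)

    def test_common_mode_invariance(self):
        rng = np.random.default_rng(1)
        sig = rng.standard_normal((4, 300))
        ref = sd.common_average_reference(make_recording(sig))
        offset = sd.common_average_reference(make_recording(sig + 17.5))
        np.testing.assert_allclose(offset.signal, ref.signal, atol=1e-10)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="2 channels"):
            sd.common_average_reference(make_recording(np.zeros((1, 100))))


class TestExtractHGP:
    RATE = 2000.0

    def test_inband_tone_envelope_equals_amplitude(self):
        t = np.arange(int(4 * self.RATE)) / self.RATE
        rec = make_recording(3.0 * np.sin(2 * np.pi * 100 * t)[None, :])
        env = sd.extract_hgp(rec)
        mid = slice(1000, -1000)
        np.testing.assert_allclose(env.signal[0, mid], 3.0, rtol=0.02)
        assert (env.signal >= 0).all()

    def test_out_of_band_tone_suppressed(self):
        t = np.arange(int(4 * self.RATE)) / self.RATE
        rec = make_recording(np.sin(2 * np.pi * 10 * t)[None, :])
        env = sd.extract_hgp(rec)
        assert env.signal[0, 1000:-1000].max() < 0.01

    def test_amplitude_step_tracked(self):
        t = np.arange(int(4 * self.RATE)) / self.RATE
        tone = np.sin(2 * np.pi * 100 * t)
        tone[len(tone) // 2:] *= 2.0
        env = sd.extract_hgp(make_recording(tone[None, :])).signal[0]
        pre = env[2000: len(t) // 2 - 500].mean()
        post = env[len(t) // 2 + 500: -2000].mean()
        assert post / pre == pytest.approx(2.0, rel=0.03)

    def test_rate_too_low_rejected(self):
        rec = make_recording(np.zeros((1, 100)), rate=250.0)
        with pytest.raises(ValueError, match="too low"):
            sd.extract_hgp(rec)


class TestEpochAndBin:
    def test_constant_envelope(self, config):
        rec = make_recording(np.full((2, 20000), 3.0))
        events = sd.EventList([2.0, 5.0], ["w01", "w02"], ["abstract", "concrete"])
        binned = sd.epoch_and_bin(rec, events, config)
        assert binned.power.shape == (2, 2, 10)
        np.testing.assert_allclose(binned.power, 3.0)

    def test_ramp_bin_mean(self, config):
        """A 0->1 ramp across one bin averages to ~0.5."""
        rate = 2000.0
        sig = np.zeros((1, 20000))
        start = int(2.0 * rate)  # bin 2 starts at onset 0 ms
        sig[0, start:start + 500] = np.linspace(0, 1, 500)
        events = sd.EventList([2.0], ["w01"], ["abstract"])
        binned = sd.epoch_and_bin(make_recording(sig), events, config)
        assert binned.power[0, 0, 2] == pytest.approx(0.5, abs=0.01)

    def test_brute_force_oracle(self, config):
        rng = np.random.default_rng(3)
        rate = 400.0  # keeps bin width an integer sample count
        sig = rng.lognormal(size=(3, 6000))
        onsets = [2.0, 5.5, 9.25]
        events = sd.EventList(onsets, ["w1", "w2", "w3"],
                              ["abstract", "concrete", "abstract"])
        binned = sd.epoch_and_bin(make_recording(sig, rate=rate), events, config)
        expected = brute_force_bins(sig, rate, onsets, config.epoch_start_ms,
                                    config.bin_width_ms, config.n_bins)
        np.testing.assert_allclose(binned.power, expected, rtol=1e-12)

    def test_epoch_outside_recording_names_trial(self, config):
        rec = make_recording(np.zeros((1, 7000)))
        events = sd.EventList([1.0, 3.0], ["w1", "w2"], ["abstract", "concrete"])
        with pytest.raises(ValueError, match="trial 1"):
            sd.epoch_and_bin(rec, events, config)


class TestBaselineZscore:
    def _binned(self, power, config):
        n = power.shape[0]
        cats = np.asarray(["abstract", "concrete"] * (n // 2 + 1), dtype=object)[:n]
        ids = tuple(f"c{i}" for i in range(power.shape[1]))
        return sd.BinnedPower(power, config.bin_edges_ms, cats, ids)

    def test_degenerate_baseline_rejected(self, config):
        binned = self._binned(np.ones((4, 2, 10)), config)
        with pytest.raises(ValueError, match="zero baseline variance"):
            sd.baseline_zscore(binned, [0, 1, 2, 3], config)

    def test_mean_power_maps_to_zero(self, config):
        """Baseline bins {1, 3} give mu = 2 (population sigma = 1); an
        analysis power of 2 becomes z = 0."""
        power = np.ones((2, 1, 10))
        power[0, 0, :2] = 1.0
        power[1, 0, :2] = 3.0
        power[:, :, 2:] = 2.0
        feats = sd.baseline_zscore(self._binned(power, config), [0, 1], config)
        np.testing.assert_allclose(feats.baseline_mean, [2.0])
        np.testing.assert_allclose(feats.baseline_sd, [1.0])
        np.testing.assert_allclose(feats.z, 0.0)

    def test_fold_recompute_oracle(self, random_binned, config):
        """Removing the held-out trial changes mu and sigma; the fold's
        tensor matches a from-scratch pooled-baseline recomputation."""
        held_out = 3
        train = [t for t in range(random_binned.n_trials) if t != held_out]
        feats = sd.baseline_zscore(random_binned, train, config)
        all_feats = sd.baseline_zscore(random_binned, range(random_binned.n_trials), config)
        assert not np.allclose(feats.baseline_mean, all_feats.baseline_mean)

        base = random_binned.power[train][:, :, :2]
        for c in range(base.shape[1]):
            pooled = base[:, c, :].ravel()
            assert feats.baseline_mean[c] == pytest.approx(pooled.mean(), rel=1e-12)
            assert feats.baseline_sd[c] == pytest.approx(pooled.std(), rel=1e-12)
        expected = (random_binned.power[:, :, 2:8] - feats.baseline_mean[None, :, None]) \
            / feats.baseline_sd[None, :, None]
        np.testing.assert_allclose(feats.z, expected, rtol=1e-12)

    def test_no_leakage_from_held_out_trial(self, random_binned, config):
        """Perturbing the held-out trial's baseline bins never changes
        the training-trial statistics."""
        held_out = 0
        train = list(range(1, random_binned.n_trials))
        ref = sd.baseline_zscore(random_binned, train, config)
        perturbed = random_binned.subset(np.ones(random_binned.n_trials, dtype=bool))
        perturbed.power[held_out, :, :2] *= 100.0
        alt = sd.baseline_zscore(perturbed, train, config)
        np.testing.assert_array_equal(alt.baseline_mean, ref.baseline_mean)
        np.testing.assert_array_equal(alt.baseline_sd, ref.baseline_sd)
        np.testing.assert_array_equal(alt.z[1:], ref.z[1:])


class TestRejectTrials:
    def _epochs(self, envelope, raw=None):
        n = envelope.shape[0]
        cats = np.asarray(["abstract", "concrete"] * (n // 2), dtype=object)[:n]
        return sd.TrialEpochs(envelope=envelope, rate=2000.0, epoch_start_ms=-500.0,
                              channel_ids=tuple(f"c{i}" for i in range(envelope.shape[1])),
                              categories=cats, kept=np.ones(n, dtype=bool), raw=raw)

    def test_clean_trials_kept(self):
        rng = np.random.default_rng(0)
        epochs = self._epochs(np.abs(rng.standard_normal((20, 3, 100))))
        assert sd.reject_trials(epochs, k=5.0).kept.all()

    def test_contaminated_trial_flagged(self):
        rng = np.random.default_rng(1)
        env = np.abs(rng.standard_normal((20, 3, 100)))
        env[7] *= 10.0
        kept = sd.reject_trials(self._epochs(env), k=5.0).kept
        assert not kept[7]
        assert kept.sum() == 19

    def test_infinite_k_is_identity(self):
        rng = np.random.default_rng(2)
        env = np.abs(rng.standard_normal((10, 2, 50)))
        env[3] *= 50.0
        assert sd.reject_trials(self._epochs(env), k=np.inf).kept.all()

    def test_all_rejected_is_error(self):
        env = np.abs(np.random.default_rng(3).standard_normal((4, 2, 50)))
        epochs = self._epochs(env)
        epochs.kept[:] = False
        with pytest.raises(ValueError, match="all trials"):
            sd.reject_trials(epochs, k=5.0)


class TestGyralTimecourse:
    def _electrodes(self, regions):
        import pandas as pd

        return sd.ElectrodeTable(pd.DataFrame({
            "channel_id": [f"c{i}" for i in range(len(regions))],
            "region": regions, "hemisphere": "left", "dominant": True}))

    def test_constant_envelope_flat_with_p_one(self):
        env = np.full((8, 2, 200), 4.0)
        cats = np.asarray(["abstract", "concrete"] * 4, dtype=object)
        epochs = sd.TrialEpochs(env, 2000.0, -500.0, ("c0", "c1"), cats,
                                np.ones(8, dtype=bool))
        df = sd.gyral_timecourse(epochs, self._electrodes(["IFG", "IFG"]))
        np.testing.assert_allclose(df["mean"], 4.0)
        np.testing.assert_allclose(df["p"], 1.0)

    def test_injection_recovery(self, effect_preprocessed):
        """Abstract-dominant IFG windows are flagged inside the injected
        250-1250 ms interval, not in the pre-stimulus baseline."""
        _, epochs, electrodes = effect_preprocessed
        df = sd.gyral_timecourse(epochs, electrodes, window_ms=25.0)
        ifg = df[(df["region"] == "IFG") & (df["category"] == "abstract")]
        inside = ifg[(ifg["time_ms"] > 300) & (ifg["time_ms"] < 1200)]
        baseline = ifg[ifg["time_ms"] < 0]
        assert (inside["p"] < 0.05).mean() > 0.9
        assert (baseline["p"] < 0.05).mean() < 0.3
        # abstract mean exceeds concrete mean inside the window
        conc = df[(df["region"] == "IFG") & (df["category"] == "concrete")]
        conc_inside = conc[(conc["time_ms"] > 300) & (conc["time_ms"] < 1200)]
        assert inside["mean"].mean() > conc_inside["mean"].mean()

    def test_empty_region_skipped_with_warning(self):
        import pandas as pd

        env = np.abs(np.random.default_rng(0).standard_normal((4, 1, 100)))
        cats = np.asarray(["abstract", "concrete"] * 2, dtype=object)
        epochs = sd.TrialEpochs(env, 2000.0, -500.0, ("c0",), cats,
                                np.ones(4, dtype=bool))
        electrodes = sd.ElectrodeTable(pd.DataFrame({
            "channel_id": ["c0", "zz"], "region": ["IFG", "SM1"],
            "hemisphere": "left", "dominant": True}))
        with pytest.warns(UserWarning, match="SM1"):
            df = sd.gyral_timecourse(epochs, electrodes)
        assert set(df["region"]) == {"IFG"}
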