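"""Feature quantification: baseline, FRN peak-to-peak, P3, Morlet power,
band averages, repeated-measures ANOVA."""

import numpy as np
import pandas as pd
import pytest

from twostep_eeg.eeg_sim import (ComponentSpec, EEGGenConfig, EpochSet,
                                 generate_epochs)
from twostep_eeg.features import (_ms_to_idx, _rm_anova_sums,
                                  band_window_average, baseline_correct,
                                  cell_anova, frn_peak_to_peak,
                                  lowpass_filter, morlet_power,
                                  p3_mean_amplitude, reject_artifacts,
                                  trial_features)

SRATE = 512.0
TIMES = (np.arange(int(2.5 * SRATE)) / SRATE - 1.0) * 1000.0


def _bump(center_ms, width_ms, amp):
    return amp * np.exp(-0.5 * ((TIMES - center_ms) / width_ms) ** 2)


def _epochs(data, meta=None):
    n = data.shape[0]
    meta = meta if meta is not None else pd.DataFrame({"i": range(n)})
    return EpochSet(data, SRATE, -1.0, ("FCz", "Pz"), meta)


class TestBaseline:
    def test_constant_offset_removed_and_idempotent(self):
        data = np.full((2, 2, len(TIMES)), 7.0)
        ep = baseline_correct(_epochs(data))
        m = (TIMES >= -200) & (TIMES <= 0)
        np.testing.assert_allclose(ep.data[:, :, m], 0.0, atol=1e-12)
        np.testing.assert_allclose(ep.data, -0.0, atol=1e-12)
        again = baseline_correct(ep)
        np.testing.assert_allclose(again.data, ep.data, atol=1e-12)

    def test_shifts_whole_epoch(self):
        base = np.zeros((1, 2, len(TIMES)))
        base[0, 0] = _bump(300, 30, 4.0)
        shifted = base + 7.0
        a = baseline_correct(_epochs(base))
        b = baseline_correct(_epochs(shifted))
        np.testing.assert_allclose(a.data, b.data, atol=1e-10)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            baseline_correct(_epochs(np.zeros((1, 2, len(TIMES)))),
                             window=(-100, -100.5))


class TestFRN:
    def test_hand_constructed_waveform(self):
        """+5 uV at 180 ms, -3 uV at 260 ms, +4 uV at 380 ms ->
        p2p = -3 - (5 + 4)/2 = -7.5 uV."""
        w = _bump(180, 12, 5.0) + _bump(260, 12, -3.0) + _bump(380, 12, 4.0)
        m = frn_peak_to_peak(w, TIMES)
        assert m.p2p == pytest.approx(-7.5, abs=0.01)
        assert not m.fallback
        assert abs(m.latency_frn_ms - 260) < 3
        assert abs(m.latency_pre_ms - 180) < 3
        assert abs(m.latency_post_ms - 380) < 3

    def test_flat_waveform_flagged_zero(self):
        m = frn_peak_to_peak(np.zeros_like(TIMES), TIMES)
        assert m.p2p == 0.0
        assert m.fallback

    def test_rising_ramp_widens_to_cap(self):
        """A monotone rising ramp has no local minimum (fallback to the
        window start) and its succeeding flank maximum keeps sitting on
        the window edge, so widening runs to the 300 ms cap."""
        w = TIMES / 1000.0
        m = frn_peak_to_peak(w, TIMES)
        assert m.fallback
        assert m.latency_frn_ms == pytest.approx(200.0, abs=2)
        assert m.latency_post_ms - m.latency_frn_ms == \
            pytest.approx(300.0, abs=2)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal(len(TIMES))
        w = lowpass_filter(w, SRATE)
        a = frn_peak_to_peak(w, TIMES)
        b = frn_peak_to_peak(w + 13.7, TIMES)
        assert b.p2p == pytest.approx(a.p2p, abs=1e-10)
        assert b.latency_frn_ms == a.latency_frn_ms

    def test_most_negative_local_peak_wins(self):
        w = _bump(220, 8, -2.0) + _bump(320, 8, -5.0)
        m = frn_peak_to_peak(w, TIMES)
        assert abs(m.latency_frn_ms - 320) < 3


class TestP3:
    def test_constant(self):
        assert p3_mean_amplitude(np.full(len(TIMES), 2.0), TIMES) == \
            pytest.approx(2.0)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(len(TIMES))
        b = rng.standard_normal(len(TIMES))
        assert p3_mean_amplitude(a + b, TIMES) == pytest.approx(
            p3_mean_amplitude(a, TIMES) + p3_mean_amplitude(b, TIMES))


class TestMorlet:
    def test_pure_tone_peaks_at_nearest_bin(self):
        data = np.zeros((3, 2, len(TIMES)))
        data[:, 0] = np.sin(2 * np.pi * 6.0 * TIMES / 1000.0)
        tfr, raw = morlet_power(_epochs(data), channel="FCz",
                                return_raw=True)
        assert len(tfr.freqs) == 50
        assert tfr.freqs[0] == pytest.approx(1.0)
        assert tfr.freqs[-1] == pytest.approx(50.0)
        mid = (TIMES > 200) & (TIMES < 800)
        prof = raw[0][:, mid].mean(axis=1)
        assert np.argmax(prof) == np.argmin(np.abs(tfr.freqs - 6.0))

    def test_stationary_noise_trial_average_db_near_zero(self):
        """For noise whose statistics equal the baseline's, the dB of the
        trial-averaged power is ~0 across the epoch interior.  (The mean
        of single-trial dB sits ~-2.5 dB lower: the Jensen offset of
        averaging log power.)"""
        rng = np.random.default_rng(2)
        data = rng.standard_normal((80, 2, len(TIMES)))
        tfr, raw = morlet_power(_epochs(data), channel="Pz",
                                return_raw=True)
        t = TIMES
        b = (t >= -300) & (t <= -200)
        base = raw[:, :, b].mean(axis=(0, 2))
        avg_db = 10 * np.log10(raw.mean(axis=0) / base[:, None])
        interior = ~tfr.edge_mask
        vals = [avg_db[f, interior[f]].mean()
                for f in range(20, 50) if interior[f].any()]
        assert abs(np.mean(vals)) < 0.5
        single = [tfr.power_db[:, f, interior[f]].mean()
                  for f in range(20, 50) if interior[f].any()]
        assert np.mean(single) < -1.0

    def test_matches_mne_oracle(self):
        """dB time-frequency power agrees with mne's Morlet implementation
        (n_cycles = 4 matches sigma = 4 / (2 pi f)) away from the edges,
        for frequencies whose mne wavelet fits inside the epoch."""
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(3)
        n = len(TIMES)
        data = rng.standard_normal((6, 2, n)) * 5
        data[:, 0] += _bump(300, 80, 4.0) * \
            np.cos(2 * np.pi * 6 * (TIMES - 300) / 1000.0)
        ep = _epochs(data)
        freqs = np.logspace(0, np.log10(50), 50)
        tfr = morlet_power(ep, channel="FCz")

        fsel = freqs >= 5.0
        out = mne.time_frequency.tfr_array_morlet(
            data[:, :1] * 1e-6, SRATE, freqs[fsel], n_cycles=4.0,
            output="power", zero_mean=False, verbose="error")[:, 0]
        t = TIMES
        b_lo, b_hi = _ms_to_idx(t, -300.0), _ms_to_idx(t, -200.0)
        base = out[:, :, b_lo:b_hi + 1].mean(axis=(0, 2))
        mne_db = 10 * np.log10(out / base[None, :, None])
        tsel = (t >= 0) & (t <= 700)
        diff = (tfr.power_db[:, fsel][:, :, tsel] - mne_db[:, :, tsel])
        assert np.max(np.abs(diff)) < 0.05

    def test_power_nonnegative_and_db_monotone(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((4, 2, len(TIMES)))
        tfr, raw = morlet_power(_epochs(data), channel="FCz",
                                return_raw=True)
        assert (raw >= 0).all()
        # dB is a monotone transform of power within each frequency (the
        # baseline is per-frequency)
        for f in (0, 25, 49):
            p = raw[0, f]
            db = tfr.power_db[0, f]
            i = np.argsort(p)
            assert (np.diff(db[i]) >= -1e-12).all()


class TestBandAverage:
    def _tfr(self, fill=3.0):
        data = np.zeros((2, 2, len(TIMES)))
        tfr = morlet_power(_epochs(data + 1e-6), channel="FCz")
        tfr.power_db[:] = fill
        return tfr

    def test_constant_field(self):
        tfr = self._tfr(3.0)
        vals = band_window_average(tfr, (4, 8), (200, 400))
        np.testing.assert_allclose(vals, 3.0)

    def test_band_selection_bounds(self):
        tfr = self._tfr(0.0)
        fmask = (tfr.freqs >= 4) & (tfr.freqs <= 8)
        tfr.power_db[:, fmask, :] = 5.0
        theta = band_window_average(tfr, (4, 8), (200, 400))
        np.testing.assert_allclose(theta, 5.0)
        delta = band_window_average(tfr, (1, 4), (300, 500))
        assert delta.max() < 5.0

    def test_empty_selection_rejected(self):
        tfr = self._tfr()
        with pytest.raises(ValueError):
            band_window_average(tfr, (60, 70), (200, 400))

    def test_injected_theta_burst_separates_bands(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal((40, 2, len(TIMES))) * 3
        burst = base.copy()
        burst[:, 0] += 4 * _bump(300, 60, 1.0) * \
            np.cos(2 * np.pi * 6 * (TIMES - 300) / 1000.0)
        t_base = morlet_power(_epochs(base), "FCz")
        t_burst = morlet_power(_epochs(burst), "FCz")
        theta_gain = band_window_average(t_burst, (4, 8), (200, 400)).mean() \
            - band_window_average(t_base, (4, 8), (200, 400)).mean()
        delta_gain = band_window_average(t_burst, (1, 4), (300, 500)).mean() \
            - band_window_average(t_base, (1, 4), (300, 500)).mean()
        assert theta_gain > 1.0
        assert abs(delta_gain) < 0.5 * theta_gain


class TestTrialFeatures:
    def test_row_count_and_metadata(self, sim_df):
        trials = sim_df.head(40)
        ep, _ = generate_epochs(trials, seed=0)
        ep = baseline_correct(reject_artifacts(ep))
        feats = trial_features(ep)
        assert len(feats) == ep.n_trials
        pd.testing.assert_series_equal(feats["condition"],
                                       ep.trial_meta["condition"],
                                       check_names=False)
        assert {"frn_p2p", "p3_mean", "theta_db", "delta_db"} <= \
            set(feats.columns)

    def test_measurement_is_deterministic(self, sim_df):
        ep, _ = generate_epochs(sim_df.head(20), seed=0)
        a = trial_features(ep)
        b = trial_features(ep)
        pd.testing.assert_frame_equal(a, b)


def _brute_force_f(cells, effect):
    """Independent 2x2x2 within-subject F by explicit cell-mean sums of
    squares (enumeration over the eight cells)."""
    n = cells.shape[0]
    y = cells.reshape(n, 2, 2, 2)
    signs = {0: None, 1: None, 2: None}
    contrast = np.ones((2, 2, 2))
    for ax in effect:
        sgn = np.array([1.0, -1.0]).reshape(
            [2 if a == ax else 1 for a in range(3)])
        contrast = contrast * sgn
    per_subj = (y * contrast).sum(axis=(1, 2, 3)) / 8.0
    ss_eff = 8.0 * n * per_subj.mean() ** 2
    ss_err = 8.0 * np.sum((per_subj - per_subj.mean()) ** 2)
    if ss_eff < 1e-12:
        return 0.0
    return (ss_eff / 1.0) / (ss_err / (n - 1))


class TestCellAnova:
    def _features(self, cells, factors=("condition", "expectancy",
                                        "valence")):
        levels = [("predictable", "random"), ("expected", "unexpected"),
                  ("win", "loss")]
        rows = []
        for s in range(cells.shape[0]):
            k = 0
            for a in levels[0]:
                for b in levels[1]:
                    for c in levels[2]:
                        rows.append({"subject": s, "condition": a,
                                     "expectancy": b, "valence": c,
                                     "y": cells[s, k]})
                        k += 1
        return pd.DataFrame(rows)

    def test_identical_cells_give_zero_f(self):
        cells = np.tile(np.arange(8, dtype=float), (5, 1))
        cells = np.tile(cells[0], (5, 1)) * 0 + 2.0
        tab = cell_anova(self._features(cells), "y")
        assert (tab["F"] == 0.0).all()
        assert (tab["p"] == 1.0).all()

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(6)
        cells = rng.normal(size=(7, 8))
        tab = cell_anova(self._features(cells), "y").set_index("effect")
        mapping = {"condition": (0,), "expectancy": (1,), "valence": (2,),
                   "condition x expectancy": (0, 1),
                   "condition x valence": (0, 2),
                   "expectancy x valence": (1, 2),
                   "condition x expectancy x valence": (0, 1, 2)}
        for name, eff in mapping.items():
            want = _brute_force_f(cells, eff)
            assert tab.loc[name, "F"] == pytest.approx(want, rel=1e-9), name

    def test_matches_statsmodels_anova_rm(self):
        from statsmodels.stats.anova import AnovaRM
        rng = np.random.default_rng(7)
        cells = rng.normal(size=(9, 8))
        feats = self._features(cells)
        tab = cell_anova(feats, "y").set_index("effect")
        res = AnovaRM(feats, depvar="y", subject="subject",
                      within=["condition", "expectancy", "valence"]
                      ).fit().anova_table
        for name in res.index:
            ours = " x ".join(name.split(":"))
            assert tab.loc[ours, "F"] == pytest.approx(
                res.loc[name, "F Value"], rel=1e-8)
            assert tab.loc[ours, "p"] == pytest.approx(
                res.loc[name, "Pr > F"], abs=1e-10)

    def test_hand_checkable_two_subject_dataset(self):
        # integer cell means; effects computable by hand from the +/- 1
        # contrast sums
        cells = np.array([[4, 2, 3, 1, 2, 0, 1, -1],
                          [5, 3, 4, 2, 1, -1, 0, -2]], dtype=float)
        tab = cell_anova(self._features(cells), "y").set_index("effect")
        for name, eff in {"condition": (0,),
                          "condition x expectancy": (0, 1)}.items():
            assert tab.loc[name, "F"] == pytest.approx(
                _brute_force_f(cells, eff), rel=1e-9)

    def test_incomplete_subject_dropped_with_warning(self):
        cells = np.random.default_rng(8).normal(size=(4, 8))
        feats = self._features(cells)
        feats = feats[~((feats["subject"] == 0)
                        & (feats["valence"] == "win"))]
        with pytest.warns(UserWarning, match="missing"):
            tab = cell_anova(feats, "y")
        assert (tab["df_den"] == 2).all()


def test_ms_to_idx_rounds_half_up():
    times = np.array([0.0, 1.0, 2.0, 3.0])
    assert _ms_to_idx(times, 1.5) == 2
    assert _ms_to_idx(times, 1.4) == 1
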