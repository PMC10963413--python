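"""EEG chain: notch/band-pass filters, artifact removal, Welch band
powers, ratio indices."""

import numpy as np
import pytest
from scipy import signal as sps

from mwload import eeg, synthio
from mwload.config import SynthConfig
from mwload.types import Recording

FS = 500.0


def _rec(x, fs=FS, labels=None):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = labels or [f"ch{i}" for i in range(x.shape[0])]
    return Recording("eeg", fs, labels, x)


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestNotch:
    def test_60hz_tone_suppressed(self):
        t = np.arange(int(10 * FS)) / FS
        tone = np.sin(2 * np.pi * 60 * t)
        out = eeg.notch_filter(_rec(tone))
        assert _rms(out.samples[0, 500:-500]) <= 0.01 * _rms(tone)

    def test_passband_tone_preserved(self):
        t = np.arange(int(10 * FS)) / FS
        tone = np.sin(2 * np.pi * 10 * t)
        out = eeg.notch_filter(_rec(tone))
        assert _rms(out.samples[0, 500:-500]) == pytest.approx(
            _rms(tone[500:-500]), rel=0.05
        )

    def test_zero_in_zero_out(self):
        out = eeg.notch_filter(_rec(np.zeros(5000)))
        assert np.allclose(out.samples, 0.0)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            eeg.notch_filter(_rec(np.zeros(500), fs=100.0))


class TestBandpass:
    def test_drift_attenuated(self):
        t = np.arange(int(40 * FS)) / FS
        drift = np.sin(2 * np.pi * 0.1 * t)
        out = eeg.bandpass_filter(_rec(drift))
        atten_db = 20 * np.log10(
            _rms(drift) / max(_rms(out.samples[0, 2000:-2000]), 1e-30)
        )
        assert atten_db >= 20

    def test_10hz_tone_preserved(self):
        t = np.arange(int(10 * FS)) / FS
        tone = np.sin(2 * np.pi * 10 * t)
        out = eeg.bandpass_filter(_rec(tone))
        assert _rms(out.samples[0, 500:-500]) == pytest.approx(
            _rms(tone[500:-500]), rel=0.05
        )

    def test_dc_removed(self):
        out = eeg.bandpass_filter(_rec(np.full(5000, 7.0)))
        assert abs(out.samples.mean()) < 1e-3


class TestOcularRemoval:
    def _mixture(self, k=2.0, seed=0):
        rng = np.random.default_rng(seed)
        n = int(20 * FS)
        clean = rng.normal(0, 1.0, size=(4, n))
        eog_sig = np.cumsum(rng.normal(0, 1, size=(2, n)), axis=1)
        eog_sig -= eog_sig.mean(axis=1, keepdims=True)
        eog_sig /= eog_sig.std(axis=1, keepdims=True)
        contaminated = clean + k * eog_sig[0] + 0.5 * k * eog_sig[1]
        return _rec(contaminated), _rec(eog_sig, labels=["h", "v"])

    def test_regression_removes_contamination(self):
        rec, eog_ref = self._mixture()
        out = eeg.remove_ocular_artifacts(rec, eog_ref, method="regression")
        for c in range(out.n_channels):
            for e in range(2):
                r = np.corrcoef(out.samples[c], eog_ref.samples[e])[0, 1]
                assert abs(r) < 0.2

    def test_zero_eog_is_identity(self):
        rng = np.random.default_rng(1)
        rec = _rec(rng.normal(size=(3, 2000)))
        eog_ref = _rec(np.zeros((2, 2000)), labels=["h", "v"])
        out = eeg.remove_ocular_artifacts(rec, eog_ref)
        assert np.allclose(out.samples, rec.samples, atol=1e-9)

    def test_ica_threshold_one_keeps_everything(self):
        rec, eog_ref = self._mixture(seed=2)
        out = eeg.remove_ocular_artifacts(
            rec, eog_ref, method="ica", corr_threshold=1.0
        )
        # nothing removed: reconstruction equals input up to ICA tolerance
        assert np.allclose(out.samples, rec.samples, atol=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            eeg.remove_ocular_artifacts(
                _rec(np.zeros((2, 100))), _rec(np.zeros((2, 99)), labels=["h", "v"])
            )


class TestAsr:
    def test_calibration_identical_data_preserved(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, size=(4, int(30 * FS)))
        rec = _rec(x)
        out = eeg.asr_clean(rec, (0, 15), cutoff_sd=20)
        assert np.allclose(out.samples, x, atol=0.5)

    def test_burst_suppressed_clean_preserved(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, size=(6, int(30 * FS)))
        rec_clean = x.copy()
        i0, i1 = int(20 * FS), int(22 * FS)
        x[:3, i0:i1] += rng.normal(0, 50, size=(3, i1 - i0))
        out = eeg.asr_clean(_rec(x), (0, 15), cutoff_sd=5)
        var_before = x[:3, i0:i1].var()
        var_after = out.samples[:3, i0:i1].var()
        assert var_after <= var_before / 10
        clean_seg = slice(int(5 * FS), int(15 * FS))
        assert np.allclose(
            out.samples[:, clean_seg], rec_clean[:, clean_seg], atol=0.5
        )

    def test_infinite_cutoff_identity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(3, int(20 * FS)))
        out = eeg.asr_clean(_rec(x), (0, 12), cutoff_sd=np.inf)
        assert np.allclose(out.samples, x, atol=1e-8)

    def test_short_calibration_rejected(self):
        with pytest.raises(ValueError):
            eeg.asr_clean(_rec(np.zeros((2, 10000))), (0, 5))


class TestWelchBandpower:
    def test_alpha_tone_lands_in_alpha(self):
        t = np.arange(int(20 * FS)) / FS
        tone = np.sin(2 * np.pi * 10 * t)
        bp = eeg.welch_bandpower(_rec(tone))
        total = bp.power[0].sum()
        assert bp.band("alpha")[0].sum() >= 0.9 * total

    def test_two_tone_balance(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 6 * t) + np.sin(2 * np.pi * 20 * t)
        bp = eeg.welch_bandpower(_rec(x))
        theta = bp.band("theta").mean()
        beta = bp.band("beta").mean()
        assert theta == pytest.approx(beta, rel=0.1)

    def test_zero_signal_zero_power(self):
        bp = eeg.welch_bandpower(_rec(np.zeros(int(10 * FS))))
        assert np.allclose(bp.power, 0.0)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            eeg.welch_bandpower(
                _rec(np.zeros(int(4 * FS))), bands={"bad": (100.0, 300.0)}
            )

    def test_band_power_sum_bounded_by_total(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=int(20 * FS))
        rec = eeg.bandpass_filter(_rec(x))
        bp = eeg.welch_bandpower(rec)
        total = eeg.welch_bandpower(rec, bands={"all": (1.0, 59.0)})
        assert (
            bp.power.sum(axis=1) <= total.power[:, 0, :] * 1.02 + 1e-12
        ).all()


class TestRatioFeatures:
    def _bp_from(self, theta, alpha, beta):
        power = np.zeros((1, 5, 1))
        names = ["delta", "theta", "alpha", "beta", "gamma"]
        power[0, 1, 0], power[0, 2, 0], power[0, 3, 0] = theta, alpha, beta
        return eeg.BandPowerSeries(["ch0"], names, power, np.array([0.0]), 2.0, 1.0)

    def test_unit_powers(self):
        r = eeg.ratio_features(self._bp_from(1, 1, 1))
        assert r["engagement"][0, 0] == pytest.approx(0.5)
        assert r["theta_alpha"][0, 0] == pytest.approx(1.0)
        assert r["theta_beta"][0, 0] == pytest.approx(1.0)
        assert r["ta_ba"][0, 0] == pytest.approx(1.0)

    def test_engagement_beta_dominant(self):
        r = eeg.ratio_features(self._bp_from(1, 1, 2))
        assert r["engagement"][0, 0] == pytest.approx(1.0)

    def test_zero_denominator_missing(self):
        r = eeg.ratio_features(self._bp_from(0, 0, 1))
        assert np.isnan(r["engagement"][0, 0])

    def test_tone_ratios_match_integrated_powers(self):
        t = np.arange(int(20 * FS)) / FS
        tone = np.sin(2 * np.pi * 10 * t)
        bp = eeg.welch_bandpower(_rec(tone))
        r = eeg.ratio_features(bp)
        theta = bp.band("theta").mean()
        alpha = bp.band("alpha").mean()
        beta = bp.band("beta").mean()
        assert r["theta_alpha"].mean() == pytest.approx(theta / alpha, rel=0.2)
        assert r["theta_alpha"].mean() < 0.01
        # engagement approx beta/alpha when theta << alpha
        assert r["engagement"].mean() == pytest.approx(
            beta / (alpha + theta), rel=0.05
        )

    def test_missing_band_rejected(self):
        bp = eeg.BandPowerSeries(
            ["c"], ["delta"], np.ones((1, 1, 1)), np.array([0.0]), 2.0, 1.0
        )
        with pytest.raises(ValueError):
            eeg.ratio_features(bp)


class TestRecoveryAndBookkeeping:
    def test_alpha_condition_ratio_recovered(self):
        cfg = SynthConfig()
        design = synthio.build_block_design("s", "SituationAwareness", 1, cfg)
        truth = synthio.make_ground_truth(design, cfg, seed=3)
        for g, b in zip(truth, design):
            g.band_power_scale = {
                "delta": 1, "theta": 1, "beta": 1, "gamma": 1,
                "alpha": 2.0 if b.condition == "easy" else 1.0,
            }
        rec = synthio.simulate_eeg(design, truth, seed=5)
        x = eeg.bandpass_filter(eeg.notch_filter(rec))
        bp = eeg.welch_bandpower(x)
        alpha = bp.band("alpha")
        means = {"easy": [], "hard": []}
        for b in design:
            sel = (bp.window_times_s >= b.t_start_s) & (
                bp.window_times_s < b.t_end_s
            )
            means[b.condition].append(alpha[:, sel].mean())
        ratio = np.mean(means["easy"]) / np.mean(means["hard"])
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_line_component_visible_then_removed(self, wm_session):
        raw = wm_session.recordings["eeg"]
        f, psd = sps.welch(raw.samples[0], fs=FS, nperseg=8192)
        peak = psd[np.argmin(abs(f - 60))]
        background = np.median(psd[(f > 48) & (f < 58)])
        assert 10 * np.log10(peak / background) >= 40
        notched = eeg.notch_filter(raw)
        f2, psd2 = sps.welch(notched.samples[0], fs=FS, nperseg=8192)
        assert psd2[np.argmin(abs(f2 - 60))] < background

    def test_288_eeg_measures(self, wm_table):
        sub = wm_table[wm_table.modality == "eeg"]
        assert sub["measure_name"].nunique() == 288
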