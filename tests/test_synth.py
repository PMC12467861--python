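"""Synthetic gait generator: taxonomy, determinism, noise and structure."""

import numpy as np
import pytest
from scipy.signal import periodogram

from gaitintent.modes import (
    MODE_CODES,
    STEADY_CODES,
    ModeLabel,
    transition_endpoints,
)
from gaitintent.synth import (
    MUSCLES,
    SimConfig,
    default_config,
    generate_dataset,
    generate_trial,
    inject_awgn,
    oracle_window_features,
    read_recording,
    write_recording,
)


class TestModeTaxonomy:
    def test_thirteen_codes_five_steady(self):
        assert len(MODE_CODES) == 13
        assert len(set(MODE_CODES)) == 13
        assert sum(not ModeLabel(c).is_transition for c in MODE_CODES) == 5

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="unknown locomotion mode"):
            ModeLabel("JUMP")

    @pytest.mark.parametrize("code,expected", [
        ("RD-LW", ("RD", "LW")),
        ("LW-SA", ("LW", "SA")),
        ("LW", ("LW", "LW")),
    ])
    def test_transition_endpoints(self, code, expected):
        assert transition_endpoints(code) == expected


class TestGenerateTrial:
    def test_identical_seed_bit_identical(self, sim_config):
        seq = [("LW", 1.0), ("LW-SA", 1.0), ("SA", 1.0)]
        a = generate_trial(sim_config, seq, seed=5)
        b = generate_trial(sim_config, seq, seed=5)
        assert np.array_equal(a.semg, b.semg)
        assert np.array_equal(a.imu, b.imu)
        assert [l.code for l in a.window_labels] == [l.code for l in b.window_labels]

    def test_all_terms_zero_gives_silent_semg(self):
        zero_tonic = {c: np.zeros(len(MUSCLES)) for c in STEADY_CODES}
        zero_bursts = {c: [[] for _ in MUSCLES] for c in STEADY_CODES}
        kin = default_config().kinematics
        cfg = SimConfig(
            powerline_amp=0.0,
            drift_amp=0.0,
            artifact_level=0.0,
            tonic=zero_tonic,
            bursts=zero_bursts,
            kinematics=kin,
        )
        rec = generate_trial(cfg, [("LW", 1.0)], seed=3)
        assert np.all(rec.semg == 0.0)

    def test_ten_second_trial_has_100_windows(self, sim_config):
        rec = generate_trial(sim_config, [("LW", 10.0)], seed=1)
        assert len(rec.window_labels) == 100
        assert all(l.code == "LW" for l in rec.window_labels)
        assert rec.semg.shape == (6, 10_000)
        assert rec.imu.shape == (18, 2_000)

    def test_unknown_mode_in_sequence_errors(self, sim_config):
        with pytest.raises(ValueError):
            generate_trial(sim_config, [("SPRINT", 1.0)], seed=0)

    def test_nonpositive_duration_errors(self, sim_config):
        with pytest.raises(ValueError, match="positive"):
            generate_trial(sim_config, [("LW", -1.0)], seed=0)

    def test_all_samples_finite(self, sim_config):
        rec = generate_trial(sim_config, [("RD", 1.0), ("RD-LW", 1.0)], seed=8)
        assert np.all(np.isfinite(rec.semg))
        assert np.all(np.isfinite(rec.imu))


class TestInjectAwgn:
    def test_none_and_inf_are_identity(self, sim_config):
        rec = generate_trial(sim_config, [("SA", 1.0)], seed=2)
        for level in (None, np.inf):
            out = inject_awgn(rec, level, seed=4)
            assert np.array_equal(out.semg, rec.semg)

    def test_snr_zero_noise_power_matches_signal_power(self, sim_config):
        rec = generate_trial(sim_config, [("LW", 10.0)], seed=2)
        noisy = inject_awgn(rec, 0.0, seed=9)
        for ch in range(rec.semg.shape[0]):
            p_sig = np.mean(rec.semg[ch] ** 2)
            p_noise = np.mean((noisy.semg[ch] - rec.semg[ch]) ** 2)
            assert p_noise == pytest.approx(p_sig, rel=0.05)

    def test_snr_10db_empirical(self, sim_config):
        rec = generate_trial(sim_config, [("LW", 10.0)], seed=2)
        noisy = inject_awgn(rec, 10.0, seed=9)
        for ch in range(rec.semg.shape[0]):
            p_sig = np.mean(rec.semg[ch] ** 2)
            p_noise = np.mean((noisy.semg[ch] - rec.semg[ch]) ** 2)
            snr = 10 * np.log10(p_sig / p_noise)
            assert abs(snr - 10.0) < 0.5

    def test_zero_power_channel_errors(self, sim_config):
        rec = generate_trial(sim_config, [("LW", 1.0)], seed=2)
        rec.semg[:] = 0.0
        with pytest.raises(ValueError, match="zero power"):
            inject_awgn(rec, 10.0, seed=0)

    def test_labels_unchanged(self, sim_config):
        rec = generate_trial(sim_config, [("SD", 2.0)], seed=6)
        noisy = inject_awgn(rec, 5.0, seed=1)
        assert [l.code for l in noisy.window_labels] == [
            l.code for l in rec.window_labels
        ]


class TestGenerateDataset:
    def test_coverage_all_13_modes(self, sim_config):
        recs = generate_dataset(sim_config, trials_per_mode=1, seed=0)
        seen = {l.code for r in recs for l in r.window_labels}
        assert seen == set(MODE_CODES)

    def test_transition_trials_embed_steady_phases(self, sim_config):
        recs = generate_dataset(sim_config, trials_per_mode=1, seed=0)
        for rec in recs:
            code = rec.meta["primary_mode"]
            if ModeLabel(code).is_transition:
                a, b = transition_endpoints(code)
                codes = [l.code for l in rec.window_labels]
                assert codes[0] == a and codes[-1] == b and code in codes

    def test_seeds_change_values_not_label_multiset(self, sim_config):
        r1 = generate_dataset(sim_config, trials_per_mode=2, seed=1)
        r2 = generate_dataset(sim_config, trials_per_mode=2, seed=2)
        assert not np.array_equal(r1[0].semg, r2[0].semg)
        lab1 = sorted(l.code for r in r1 for l in r.window_labels)
        lab2 = sorted(l.code for r in r2 for l in r.window_labels)
        assert lab1 == lab2

    def test_label_histogram_reproducible(self, sim_config):
        from collections import Counter

        c1 = Counter(
            l.code
            for r in generate_dataset(sim_config, trials_per_mode=1, seed=3)
            for l in r.window_labels
        )
        c2 = Counter(
            l.code
            for r in generate_dataset(sim_config, trials_per_mode=1, seed=3)
            for l in r.window_labels
        )
        assert c1 == c2

    def test_trials_per_mode_validated(self, sim_config):
        with pytest.raises(ValueError):
            generate_dataset(sim_config, trials_per_mode=0, seed=0)


class TestSignalStructure:
    def test_semg_power_concentrated_in_band(self):
        cfg = default_config(powerline_amp=0.0, drift_amp=0.0, artifact_level=0.0)
        rec = generate_trial(cfg, [("LW", 10.0)], seed=1)
        for ch in range(6):
            f, P = periodogram(rec.semg[ch], fs=cfg.fs_semg)
            frac = P[(f >= 20) & (f <= 250)].sum() / P.sum()
            assert frac >= 0.95

    def test_oracle_nearest_centroid_separability(self, sim_config):
        """Simulator design bound: modes are separable by construction."""
        from sklearn.neighbors import NearestCentroid
        from sklearn.preprocessing import StandardScaler

        X, y = [], []
        for code in MODE_CODES:
            f = oracle_window_features(sim_config, code, 2.0)
            X.append(f)
            y += [code] * f.shape[0]
        X = np.vstack(X)
        y = np.array(y)
        Xs = StandardScaler().fit_transform(X)
        pred = NearestCentroid().fit(Xs, y).predict(Xs)
        assert np.mean(pred == y) > 0.90


class TestRecordingIO:
    def test_round_trip(self, sim_config, tmp_path):
        rec = generate_trial(sim_config, [("RA", 1.0), ("RA-LW", 1.0)], seed=12)
        write_recording(rec, tmp_path, "t0")
        back = read_recording(tmp_path, "t0")
        np.testing.assert_allclose(back.semg, rec.semg, atol=1e-12)
        np.testing.assert_allclose(back.imu, rec.imu, atol=1e-12)
        assert [l.code for l in back.window_labels] == [
            l.code for l in rec.window_labels
        ]
        assert back.fs_semg == rec.fs_semg
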