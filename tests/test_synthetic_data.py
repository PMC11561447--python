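import json
import math

import numpy as np
import pandas as pd
import pytest

from kdscreen import keystroke_features as kf
from kdscreen import stats as kst
from kdscreen import synthetic_data as sd


class TestCalibrateCopula:
    def test_zero(self):
        assert sd.calibrate_copula(0.0) == pytest.approx(0.0)

    def test_unit_boundary(self):
        assert sd.calibrate_copula(1.0) == pytest.approx(1.0)

    def test_closed_form_value(self):
        # 2 sin(pi * 0.733 / 6)
        assert sd.calibrate_copula(0.733) == pytest.approx(2 * math.sin(math.pi * 0.733 / 6))
        assert sd.calibrate_copula(0.733) == pytest.approx(0.7489, abs=1e-4)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            sd.calibrate_copula(1.5)

    def test_matrix_version_psd(self):
        rho = sd.calibrate_copula(sd.default_target_spearman())
        assert np.linalg.eigvalsh(rho).min() >= -1e-10
        assert np.allclose(np.diag(rho), 1.0)


class TestNearestPsd:
    def test_already_psd_untouched(self):
        m = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert np.allclose(sd.nearest_psd_correlation(m), m)

    def test_repairs_indefinite(self):
        m = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed = sd.nearest_psd_correlation(m)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-12
        assert np.allclose(np.diag(fixed), 1.0)


class TestGenerateCohort:
    def test_group_sizes(self):
        cohort = sd.generate_cohort(sd.CohortConfig(seed=0), latent=np.eye(4))
        assert len(cohort) == 111
        assert (cohort["group"] == "HC").sum() == 64
        assert (cohort["group"] == "MCI").sum() == 47

    def test_determinism(self):
        c1 = sd.generate_cohort(sd.CohortConfig(seed=7), latent=np.eye(4))
        c2 = sd.generate_cohort(sd.CohortConfig(seed=7), latent=np.eye(4))
        pd.testing.assert_frame_equal(c1, c2)

    def test_marginal_constraints(self):
        cohort = sd.generate_cohort(sd.CohortConfig(seed=3), latent=np.eye(4))
        assert cohort["moca_k"].between(0, 30).all()
        assert (cohort["moca_k"] == cohort["moca_k"].round()).all()
        assert cohort["cbt_accuracy"].between(0, 1).all()
        assert (cohort["mean_ht_ms"] >= 1).all()
        assert (cohort["mean_ft_ms"] >= 1).all()

    def test_mci_ft_mean_monte_carlo(self):
        n = 10**4
        config = sd.CohortConfig(
            hc=sd.default_hc_params(2), mci=sd.default_mci_params(n), seed=21
        )
        cohort = sd.generate_cohort(config, latent=np.eye(4))
        ft = cohort.loc[cohort["group"] == "MCI", "mean_ft_ms"]
        assert ft.mean() == pytest.approx(1351.51, abs=3 * 242.75 / math.sqrt(n))

    def test_non_psd_latent_rejected(self):
        bad = np.array(
            [[1, 0.9, -0.9, 0], [0.9, 1, 0.9, 0], [-0.9, 0.9, 1, 0], [0, 0, 0, 1.0]]
        )
        with pytest.raises(ValueError, match="positive semi-definite"):
            sd.generate_cohort(sd.CohortConfig(seed=0), latent=bad)


class TestPooledCalibration:
    def test_pooled_targets_recovered(self):
        n = 20000
        hc = sd.default_hc_params(round(n * 64 / 111))
        mci = sd.default_mci_params(n - hc.n)
        config = sd.CohortConfig(hc=hc, mci=mci, seed=17)
        cohort = sd.generate_cohort(config)
        r, _ = kst.correlation_matrix(cohort)
        target = sd.default_target_spearman()
        assert np.abs(r.to_numpy() - target).max() < 0.02

    def test_within_mode_uses_identity(self):
        config = sd.CohortConfig(seed=0)
        config.copula.mode = "within"
        latent = sd.latent_correlation(config)
        expected = sd.calibrate_copula(sd.default_target_spearman())
        assert np.allclose(latent, expected)


class TestEventStream:
    def _record(self, ht=150.0, ft=600.0, pid="P0000"):
        return {"participant_id": pid, "mean_ht_ms": ht, "mean_ft_ms": ft}

    def test_degenerate_noise_recovers_latent(self, rng):
        stream = sd.StreamConfig(
            sessions_mean=2, sessions_dispersion=0, presses_mean=30, presses_dispersion=0,
            within_participant_cv=0.0, ht_outlier_rate=0.0, ft_outlier_rate=0.0,
        )
        sessions = sd.generate_event_stream(self._record(), stream, rng)
        for s in sessions:
            parsed, _ = kf.pair_events(
                [
                    kf.RawKeyEvent(e["t"], "press" if e["action"] == "down" else "release", e["key"])
                    for e in sorted(s["events"], key=lambda e: e["t"])
                ]
            )
            ts = kf.TypingSession(s["session_id"], s["participant_id"], parsed, len(parsed))
            for ht in kf.compute_hold_times(ts):
                assert ht == pytest.approx(150.0, abs=0.01)
            for ft in kf.compute_flight_times(ts):
                assert ft == pytest.approx(600.0, abs=0.01)

    def test_count_conservation(self, rng):
        stream = sd.StreamConfig(
            sessions_mean=10, sessions_dispersion=0, presses_mean=50, presses_dispersion=0
        )
        sessions = sd.generate_event_stream(self._record(), stream, rng)
        assert len(sessions) == 10
        for s in sessions:
            downs = sum(e["action"] == "down" for e in s["events"])
            ups = sum(e["action"] == "up" for e in s["events"])
            assert downs == ups == 50

    def test_outlier_rate_binomial(self, rng):
        stream = sd.StreamConfig(
            sessions_mean=1, sessions_dispersion=0, presses_mean=10**4, presses_dispersion=0,
            within_participant_cv=0.2, ht_outlier_rate=0.05, ft_outlier_rate=0.0,
        )
        sessions = sd.generate_event_stream(self._record(), stream, rng)
        events = [
            kf.RawKeyEvent(e["t"], "press" if e["action"] == "down" else "release", e["key"])
            for e in sorted(sessions[0]["events"], key=lambda e: e["t"])
        ]
        strokes, _ = kf.pair_events(events)
        hts = [k.hold_time for k in strokes]
        frac = sum(h > 700 for h in hts) / len(hts)
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_nonpositive_latent_rejected(self, rng):
        with pytest.raises(ValueError):
            sd.generate_event_stream(self._record(ht=0.0), sd.StreamConfig(), rng)

    def test_seed_determinism_byte_identical(self, tmp_path, small_config):
        cohort = sd.generate_cohort(small_config, latent=np.eye(4))
        for name in ("a.json", "b.json"):
            sessions = list(sd.generate_cohort_streams(cohort, small_config.stream, seed=5))
            sd.write_event_log(sessions, tmp_path / name)
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_ndjson_round_trip(self, tmp_path, rng):
        stream = sd.StreamConfig(sessions_mean=3, sessions_dispersion=0, presses_mean=45,
                                 presses_dispersion=0)
        sessions = sd.generate_event_stream(self._record(), stream, rng)
        path = tmp_path / "events.ndjson"
        sd.write_event_log(sessions, path, ndjson=True)
        parsed, report = kf.parse_event_log(path)
        assert len(parsed) == 3
        assert report.n_malformed_records == 0


class TestEndToEndRecovery:
    def test_uncontaminated_round_trip_within_2se(self, tmp_path):
        config = sd.CohortConfig(
            hc=sd.default_hc_params(6),
            mci=sd.default_mci_params(5),
            stream=sd.StreamConfig(
                sessions_mean=8, sessions_dispersion=0, presses_mean=100, presses_dispersion=0,
                within_participant_cv=0.3, ht_outlier_rate=0.0, ft_outlier_rate=0.0,
            ),
            seed=31,
        )
        cohort = sd.generate_cohort(config, latent=np.eye(4))
        sessions = list(sd.generate_cohort_streams(cohort, config.stream, config.seed))
        path = tmp_path / "events.json"
        sd.write_event_log(sessions, path)
        parsed, _ = kf.parse_event_log(path)
        feats = {f.participant_id: f for f in kf.extract_participant_features(parsed)}
        zs = []
        for _, row in cohort.iterrows():
            f = feats[row["participant_id"]]
            n = f.n_keystrokes
            for extracted, latent in ((f.mean_ht, row["mean_ht_ms"]), (f.mean_ft, row["mean_ft_ms"])):
                se = config.stream.within_participant_cv * latent / math.sqrt(n)
                zs.append(abs(extracted - latent) / se)
        # each individual deviation is a ~N(0,1) draw; with 22 of them the
        # extreme can exceed 2 SE, so bound the extreme loosely and the
        # average tightly (mean |z| of standard normals is ~0.8)
        assert max(zs) < 4.0
        assert np.mean(zs) < 1.5

    def test_filtering_improves_contaminated_recovery(self, tmp_path):
        config = sd.CohortConfig(
            hc=sd.default_hc_params(4),
            mci=sd.default_mci_params(3),
            stream=sd.StreamConfig(
                sessions_mean=10, sessions_dispersion=0, presses_mean=120, presses_dispersion=0,
                within_participant_cv=0.3, ht_outlier_rate=0.05, ft_outlier_rate=0.05,
            ),
            seed=13,
        )
        cohort = sd.generate_cohort(config, latent=np.eye(4))
        sessions = list(sd.generate_cohort_streams(cohort, config.stream, config.seed))
        path = tmp_path / "events.json"
        sd.write_event_log(sessions, path)
        parsed, _ = kf.parse_event_log(path)
        truth = cohort.set_index("participant_id")
        err_filtered = err_raw = 0.0
        for pid, group in kf.sessions_by_participant(parsed).items():
            filt = kf.aggregate_participant(pid, group)
            raw = kf.aggregate_participant(pid, group, ht_max_ms=np.inf, ft_max_ms=np.inf)
            err_filtered += abs(filt.mean_ht - truth.loc[pid, "mean_ht_ms"])
            err_filtered += abs(filt.mean_ft - truth.loc[pid, "mean_ft_ms"])
            err_raw += abs(raw.mean_ht - truth.loc[pid, "mean_ht_ms"])
            err_raw += abs(raw.mean_ft - truth.loc[pid, "mean_ft_ms"])
        assert err_filtered < err_raw

    def test_session_retention_near_design_target(self):
        # default press-count distribution is tuned so ~78% of sessions
        # survive the >40-press filter
        config = sd.CohortConfig(
            hc=sd.default_hc_params(30), mci=sd.default_mci_params(20), seed=2
        )
        cohort = sd.generate_cohort(config, latent=np.eye(4))
        sessions = list(sd.generate_cohort_streams(cohort, config.stream, config.seed))
        parsed = [
            kf.TypingSession(s["session_id"], s["participant_id"], [],
                             n_presses=sum(e["action"] == "down" for e in s["events"]))
            for s in sessions
        ]
        _, frac = kf.filter_sessions(parsed)
        assert frac == pytest.approx(0.776, abs=0.03)


class TestConfigSerialization:
    def test_round_trip(self):
        config = sd.CohortConfig(seed=42)
        config.copula.mode = "within"
        d = config.to_dict()
        json.dumps(d)  # must be JSON-serializable
        back = sd.CohortConfig.from_dict(d)
        assert back.seed == 42
        assert back.copula.mode == "within"
        assert back.hc.n == 64
        assert np.allclose(back.copula.target_spearman, config.copula.target_spearman)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            sd.StreamConfig(ht_outlier_rate=1.0)

    def test_invalid_group_params(self):
        with pytest.raises(ValueError):
            sd.default_hc_params(0)
        with pytest.raises(ValueError):
            sd.GroupParams(
                n=5, label="HC", ht_mean=100, ht_sd=-1, ft_mean=600, ft_sd=100,
                moca_mean=25, moca_sd=2, mmse_mean=26, mmse_sd=1, cbt_mean=0.7,
                cbt_sd=0.05, age_mean=75, age_sd=7, education_mean=6, education_sd=4,
                sex_fraction_male=0.5,
            )
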