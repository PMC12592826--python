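"""Synthetic-night generator: stage chains, event processes, determinism."""
import numpy as np
import pytest

import naaglm as na
from naaglm.types import ConfigurationError

from conftest import RECOVERY_STAGE_RATES, all_light_hypnogram

L = na.StageCode.LIGHT


def identity_transitions():
    return {a: {b: 1.0 if a is b else 0.0 for b in na.StageCode} for a in na.StageCode}


class TestHypnogram:
    def test_absorbing_chain_stays_in_start_stage(self):
        cfg = na.SimConfig(
            duration_s=3600.0, start_stage=L, transitions=identity_transitions()
        )
        hyp = na.simulate_hypnogram(cfg, seed=0)
        assert all(s is L for s in hyp.stages)

    def test_epoch_count_from_duration(self):
        hyp = na.simulate_hypnogram(na.SimConfig(duration_s=28_800.0), seed=0)
        assert hyp.n_epochs == 960

    def test_non_stochastic_matrix_rejected(self):
        bad = identity_transitions()
        bad[L][L] = 0.7
        with pytest.raises(ConfigurationError):
            na.simulate_hypnogram(na.SimConfig(transitions=bad), seed=0)

    def test_occupancy_matches_stationary_distribution(self):
        # long-run epoch occupancy vs eigen-analysis of the embedded chain
        cfg = na.SimConfig(duration_s=28_800.0)
        target = na.stationary_occupancy(cfg)
        counts = {s: 0 for s in na.StageCode}
        n_epochs = 0
        burn = 240  # discard 2 h: the fixed WAKE start biases early epochs
        for seed in range(500):
            hyp = na.simulate_hypnogram(cfg, seed=seed)
            for s in hyp.stages[burn:]:
                counts[s] += 1
            n_epochs += hyp.n_epochs - burn
        for s in na.StageCode:
            frac = counts[s] / n_epochs
            # dwell correlation inflates the naive binomial SE; bound by
            # 3 SE with an effective sample size of one per mean dwell
            n_eff = n_epochs / max(cfg.dwell_epochs[s], 1.0)
            se = np.sqrt(target[s] * (1 - target[s]) / n_eff)
            assert abs(frac - target[s]) < 3.5 * se + 0.005


class TestEventIntervals:
    def test_zero_rates_give_no_events(self):
        hyp = all_light_hypnogram(2.0)
        cfg = na.SimConfig(
            sdb_rate_per_h={s: 0.0 for s in na.StageCode},
            arousal_rate_per_h={s: 0.0 for s in na.StageCode},
        )
        assert na.simulate_event_intervals(hyp, cfg, seed=0) == []

    def test_negative_rate_rejected(self):
        rates = {s: 0.0 for s in na.StageCode}
        rates[L] = -1.0
        cfg = na.SimConfig(sdb_rate_per_h=rates)
        with pytest.raises(ConfigurationError):
            na.simulate_event_intervals(all_light_hypnogram(), cfg, seed=0)

    def test_poisson_mean_count_in_light(self):
        # SDB only in LIGHT at 30/h: mean onset count ~ 30 x hours(LIGHT)
        hours = 2.0
        hyp = all_light_hypnogram(hours)
        rates = {s: 0.0 for s in na.StageCode}
        rates[L] = 30.0
        cfg = na.SimConfig(
            sdb_rate_per_h=rates,
            arousal_rate_per_h={s: 0.0 for s in na.StageCode},
            sdb_duration_log_sd=0.1,
            sdb_duration_median_s=5.0,  # short events: merging is negligible
        )
        n_nights = 400
        counts = [
            len(na.simulate_event_intervals(hyp, cfg, seed=s)) for s in range(n_nights)
        ]
        expected = 30.0 * hours
        se = np.sqrt(expected / n_nights)
        assert abs(np.mean(counts) - expected) < 3.0 * se + 0.5

    def test_same_kind_intervals_disjoint_after_merging(self):
        hyp = all_light_hypnogram(4.0)
        cfg = na.SimConfig()
        events = na.simulate_event_intervals(hyp, cfg, seed=5)
        for kind in na.EventKind:
            same = sorted((e for e in events if e.kind is kind), key=lambda e: e.start)
            for a, b in zip(same, same[1:]):
                assert b.start > a.end

    def test_fixed_seed_reproducible(self):
        hyp = all_light_hypnogram(2.0)
        cfg = na.SimConfig()
        a = na.simulate_event_intervals(hyp, cfg, seed=7)
        b = na.simulate_event_intervals(hyp, cfg, seed=7)
        assert a == b


class TestNAATrain:
    def test_binomial_mean_event_count(self):
        # flat rate 0.001/bin over 28,800 bins: mean count 28.8
        hyp = all_light_hypnogram(8.0)
        tm = na.TrueModel({s: np.log(0.001) for s in na.StageCode})
        counts = [
            len(na.simulate_naa_events(tm, hyp, [], seed=s)) for s in range(300)
        ]
        se = np.sqrt(28.8 / 300)  # binomial variance ~ Poisson at small p
        assert abs(np.mean(counts) - 28.8) < 3.0 * se

    def test_sdb_multiplier_doubles_rate(self):
        hyp = all_light_hypnogram(8.0)
        covered = [na.EventInterval(0.0, hyp.duration, na.EventKind.OSA)]
        tm = na.TrueModel({s: np.log(0.001) for s in na.StageCode},
                          beta_sdb=np.log(2.0))
        n_cov = sum(len(na.simulate_naa_events(tm, hyp, covered, seed=s))
                    for s in range(150))
        n_base = sum(len(na.simulate_naa_events(tm, hyp, [], seed=s))
                     for s in range(150))
        ratio = n_cov / n_base
        assert 1.8 < ratio < 2.2

    def test_hard_refractory_enforces_minimum_spacing(self):
        hyp = all_light_hypnogram(8.0)
        tm = na.TrueModel(
            {s: np.log(0.02) for s in na.StageCode},
            history_curve=na.hard_refractory(10.0),
        )
        train = na.simulate_naa_events(tm, hyp, [], seed=3)
        assert len(train) > 10
        assert np.min(np.diff(train.onsets)) >= 10.0

    def test_fixed_seed_bit_identical(self, sim_config, recovery_model):
        a = na.simulate_night(sim_config, recovery_model, seed=11)
        b = na.simulate_night(sim_config, recovery_model, seed=11)
        assert np.array_equal(a.train.onsets, b.train.onsets)
        assert np.array_equal(a.rr.rr.rr, b.rr.rr.rr)
        assert a.hypnogram.stages == b.hypnogram.stages


class TestRRSeries:
    def test_no_events_gives_quiet_series(self, sim_config):
        train = na.NAAEventTrain(np.array([]), recording_span=1800.0)
        sim = na.simulate_rr_series(train, sim_config, seed=0)
        det = na.AvalancheDetector().detect(sim.rr)
        assert len(det) == 0
        assert np.allclose(sim.rr.rr, 1.0, atol=0.15)

    def test_single_event_recovered_at_onset(self, sim_config):
        train = na.NAAEventTrain(np.array([600.0]), recording_span=1800.0)
        sim = na.simulate_rr_series(train, sim_config, seed=0)
        det = na.AvalancheDetector().detect(sim.rr)
        assert len(det) == 1
        assert abs(det.onsets[0] - sim.embedded_onsets[0]) < 1.5 * sim_config.baseline_rr_s

    def test_too_close_events_skipped_with_warning(self, sim_config):
        train = na.NAAEventTrain(np.array([600.0, 602.0]), recording_span=1200.0)
        with pytest.warns(UserWarning, match="skipped"):
            sim = na.simulate_rr_series(train, sim_config, seed=0)
        assert sim.n_skipped == 1
        assert len(sim.embedded_onsets) == 1

    def test_shallow_depth_rejected_in_config(self):
        with pytest.raises(ConfigurationError):
            na.SimConfig(naa_depth_fraction=0.25)


class TestECG:
    def test_clean_beats_produce_local_maxima_at_beat_times(self):
        rr = na.RRSeries(np.arange(1.0, 11.0), np.ones(10))
        sim = na.simulate_ecg(rr, sample_rate=256.0, seed=0)
        x, fs = sim.ecg.samples, 256.0
        for bt in rr.beat_time:
            i = int(round(bt * fs))
            w = x[i - 3 : i + 4]
            assert np.argmax(w) in (2, 3, 4)  # peak within +-1 sample

    def test_noise_with_fixed_seed_is_reproducible(self):
        rr = na.RRSeries(np.arange(1.0, 11.0), np.ones(10))
        a = na.simulate_ecg(rr, 256.0, seed=5, noise_sd=0.1)
        b = na.simulate_ecg(rr, 256.0, seed=5, noise_sd=0.1)
        assert np.array_equal(a.ecg.samples, b.ecg.samples)

    def test_interval_shorter_than_template_rejected(self):
        rr = na.RRSeries(np.array([1.0, 1.04]), np.array([1.0, 0.04]))
        with pytest.raises(ValueError, match="template"):
            na.simulate_ecg(rr, 256.0)

    def test_low_sample_rate_rejected(self):
        rr = na.RRSeries(np.arange(1.0, 11.0), np.ones(10))
        with pytest.raises(ConfigurationError):
            na.simulate_ecg(rr, sample_rate=64.0)


class TestStageRateConvergence:
    def test_stage_rates_recover_truth_across_nights(self):
        # generator + detector-free route: rates from the simulated train
        cfg = na.SimConfig(duration_s=14_400.0)
        tm = na.TrueModel.from_rates_per_hour(RECOVERY_STAGE_RATES)
        totals = {s: [0, 0.0] for s in na.StageCode}
        for seed in range(200):
            hyp = na.simulate_hypnogram(cfg, seed=seed)
            train = na.simulate_naa_events(tm, hyp, [], seed=seed + 10_000)
            for s, (cnt, hrs) in na.stage_counts(train, hyp).items():
                totals[s][0] += cnt
                totals[s][1] += hrs
        for s, want in RECOVERY_STAGE_RATES.items():
            cnt, hrs = totals[s]
            rate = cnt / hrs
            se = np.sqrt(cnt) / hrs
            assert abs(rate - want) < 3.0 * se + 0.05
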