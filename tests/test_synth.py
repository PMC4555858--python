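"""Synthetic generators: season statistics, call round-trips, response pairs."""

import numpy as np
import pytest
from scipy import stats as spstats

from rivalcall import acoustics, synth
from rivalcall.errors import InvalidConfigError


class TestSeason:
    def test_saturated_strength_gap_always_wins(self):
        config = synth.ColonyConfig(
            n_males=2, strength=(0.0, 10.0), n_interactions=50, steepness=10.0, seed=1
        )
        records = synth.simulate_season(config)
        assert len(records) == 50
        assert all(r.winner_id == "M01" for r in records)

    def test_zero_interactions(self):
        config = synth.ColonyConfig(
            n_males=3, strength=(0.0, 0.0, 0.0), n_interactions=0, seed=1
        )
        assert synth.simulate_season(config) == []

    def test_equal_strength_win_rates_near_half(self):
        config = synth.ColonyConfig(
            n_males=20, strength=(0.0,) * 20, n_interactions=2000, seed=9
        )
        records = synth.simulate_season(config)
        wins = {m: 0 for m in config.male_ids()}
        bouts = {m: 0 for m in config.male_ids()}
        for r in records:
            wins[r.winner_id] += 1
            bouts[r.winner_id] += 1
            bouts[r.loser_id] += 1
        for m in config.male_ids():
            se = 0.5 / np.sqrt(bouts[m])
            assert abs(wins[m] / bouts[m] - 0.5) < 3 * se

    def test_win_probability_matches_logistic(self):
        # two males, fixed strength gap: empirical win rate within binomial error
        delta, steep, n = 0.8, 1.0, 10_000
        config = synth.ColonyConfig(
            n_males=2, strength=(0.0, delta), n_interactions=n, steepness=steep, seed=3
        )
        records = synth.simulate_season(config)
        p_hat = np.mean([r.winner_id == "M01" for r in records])
        p_true = synth.logistic(steep * delta)
        assert abs(p_hat - p_true) < 3 * np.sqrt(p_true * (1 - p_true) / n)

    def test_vocalization_rates(self):
        config = synth.ColonyConfig(
            n_males=10, strength=(0.0,) * 10, n_interactions=4000, seed=4
        )
        records = synth.simulate_season(config)
        winner_rate = np.mean([r.winner_vocalized for r in records])
        loser_rate = np.mean([r.loser_vocalized for r in records])
        assert winner_rate == pytest.approx(0.95, abs=0.02)
        assert loser_rate == pytest.approx(0.29, abs=0.03)

    def test_deterministic_with_seed(self):
        config = synth.ColonyConfig(
            n_males=5, strength=(0, 1, 2, 3, 4), n_interactions=100, seed=77
        )
        assert synth.simulate_season(config) == synth.simulate_season(config)

    def test_chronological_order(self):
        config = synth.ColonyConfig(
            n_males=5, strength=(0,) * 5, n_interactions=200, seed=2
        )
        dates = [r.date for r in synth.simulate_season(config)]
        assert dates == sorted(dates)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_males=1, strength=(0.0,), n_interactions=10),
            dict(n_males=2, strength=(0.0, 1.0), n_interactions=-1),
            dict(n_males=2, strength=(0.0, 1.0), n_interactions=10, steepness=0.0),
            dict(n_males=3, strength=(0.0, 1.0), n_interactions=10),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            synth.ColonyConfig(seed=0, **kwargs)


class TestSimulateCall:
    def test_deterministic_with_seed(self, medium_signature):
        a = synth.simulate_call(medium_signature, sample_rate=16000.0, seed=5)
        b = synth.simulate_call(medium_signature, sample_rate=16000.0, seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_round_trip_average_male(self, medium_call, medium_features):
        f = medium_features
        assert f.n_pulses == 14
        assert f.pulse_rate == pytest.approx(1.7, abs=0.01)
        # the observed group-mean Q25 used as the generator target
        assert abs(f.q25 - 643.0) <= acoustics.fft_bin_width(medium_call)

    def test_round_trip_signature_grid(self):
        """Feature extraction inverts the generator across 12 signatures:
        pulse count exact, rate within 1 %, Q25 within one FFT bin,
        centroid within 5 %."""
        rng = np.random.default_rng(21)
        cases = [
            (float(r), int(n))
            for r, n in zip(rng.uniform(1.0, 2.8, 12), rng.integers(5, 16, 12))
        ]
        for k, (rate, n_pulses) in enumerate(cases):
            sig = synth.CallSignature(
                male_id="G",
                pulse_rate=rate,
                n_pulses=n_pulses,
                centroid_target=1700.0,
                q25_target=643.0,
                jitter=0.0,
            )
            call = synth.simulate_call(sig, sample_rate=16000.0, seed=100 + k)
            f = acoustics.extract_features(call)
            assert f.n_pulses == n_pulses
            assert f.pulse_rate == pytest.approx(rate, rel=0.01)
            assert abs(f.q25 - 643.0) <= acoustics.fft_bin_width(call)
            assert f.centroid == pytest.approx(1700.0, rel=0.05)

    def test_nyquist_guard(self, medium_signature):
        with pytest.raises(InvalidConfigError):
            synth.simulate_call(medium_signature, sample_rate=3000.0, seed=0)

    def test_unattainable_spectral_target(self):
        sig = synth.CallSignature(
            male_id="X", pulse_rate=1.7, n_pulses=5,
            centroid_target=7500.0, q25_target=7000.0, jitter=0.0,
        )
        with pytest.raises(InvalidConfigError):
            synth.simulate_call(sig, sample_rate=16000.0, seed=0)

    def test_signature_validation(self):
        with pytest.raises(InvalidConfigError):
            synth.CallSignature("X", pulse_rate=1.7, n_pulses=2,
                                centroid_target=1700.0, q25_target=600.0)
        with pytest.raises(InvalidConfigError):
            synth.CallSignature("X", pulse_rate=1.7, n_pulses=5,
                                centroid_target=600.0, q25_target=1700.0)
        with pytest.raises(InvalidConfigError):
            synth.CallSignature("X", pulse_rate=-1.0, n_pulses=5,
                                centroid_target=1700.0, q25_target=600.0)

    def test_jitter_spreads_calls(self):
        sig = synth.CallSignature(
            male_id="J", pulse_rate=1.7, n_pulses=8,
            centroid_target=1700.0, q25_target=643.0, jitter=0.10,
        )
        rates = []
        for seed in range(6):
            f = acoustics.extract_features(
                synth.simulate_call(sig, sample_rate=16000.0, seed=seed)
            )
            rates.append(f.pulse_rate)
        assert np.std(rates) / np.mean(rates) > 0.02  # jitter visibly expressed


class TestColonySignatures:
    def test_bounds_respected(self):
        sigs = synth.simulate_colony_signatures(16, seed=0)
        assert len(sigs) == 16
        for s in sigs:
            assert 0.94 <= s.pulse_rate <= 2.84
            assert 263.0 <= s.q25_target <= 781.0
            assert 1574.0 <= s.centroid_target <= 1902.0
            assert s.q25_target < s.centroid_target


class TestSimulateResponses:
    def test_null_effect_centred(self):
        a, b, _ = synth.simulate_responses(0.0, 10, 1.0, seed=1)
        diffs = (a.to_numpy() - b.to_numpy()).mean(axis=0)
        se = 1.0 * np.sqrt(2.0 / 10)
        assert np.all(np.abs(diffs) < 3 * se)

    def test_large_effect_orders_all_pairs(self):
        a, b, _ = synth.simulate_responses(-5.0, 8, 1e-9, seed=2)
        assert np.all(a.to_numpy() > b.to_numpy())

    def test_latencies_censored_at_window(self):
        a, b, censored = synth.simulate_responses(100.0, 20, 5.0, seed=3)
        lat = b[["latency_orient", "latency_posture", "latency_vocalize", "latency_move"]]
        assert lat.to_numpy().max() <= synth.RESPONSE_WINDOW_S
        assert censored.any()  # the shift pushed latencies into the window limit

    def test_negative_noise_rejected(self):
        with pytest.raises(InvalidConfigError):
            synth.simulate_responses(0.0, 5, -1.0, seed=0)

    def test_wilcoxon_power_matches_enumeration_oracle(self):
        """Rejection rate of the signed-rank test at a calibrated effect agrees
        with the power computed from the exact null distribution."""
        n, effect, sd = 10, 1.1, 1.0
        # exact null distribution of W+ by enumeration over sign patterns
        from itertools import product

        ranks = np.arange(1, n + 1)
        dist = np.array([np.sum(ranks[list(signs)]) for signs in
                         [[i for i, s in enumerate(p) if s] for p in
                          product([0, 1], repeat=n)]])
        total = n * (n + 1) / 2
        # two-sided alpha=0.05 critical value
        alphas = [
            (w, (np.mean(dist <= w) + np.mean(dist >= total - w)))
            for w in range(int(total // 2) + 1)
        ]
        crit = max(w for w, a in alphas if a <= 0.05)
        # oracle power: Monte Carlo of W+ under the shifted alternative
        rng = np.random.default_rng(17)
        rejections = 0
        m = 4000
        for _ in range(m):
            d = rng.normal(effect, sd * np.sqrt(2), size=n)
            w_plus = np.sum(spstats.rankdata(np.abs(d))[d > 0])
            w = min(w_plus, total - w_plus)
            rejections += w <= crit
        oracle_power = rejections / m
        # package path: Wilcoxon on simulated paired responses
        from rivalcall.playback import compare_conditions

        hits = 0
        reps = 500
        for seed in range(reps):
            a, b, _ = synth.simulate_responses(effect, n, sd, seed=seed)
            # use a non-censored measure so the shift is exactly Gaussian
            _, p = compare_conditions(a["distance_moved"], b["distance_moved"])
            hits += p < 0.05
        assert hits / reps == pytest.approx(oracle_power, abs=0.05)
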