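"""Stimulus modifications, series construction and response scoring."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from rivalcall import acoustics, playback, synth
from rivalcall.errors import InfeasibleTargetError, InvalidConfigError
from rivalcall.playback import (
    StimulusSpec,
    alpha_distance_test,
    build_series,
    compare_conditions,
    modify_pulse_count,
    modify_pulse_rate,
    response_pca,
    seven_signal_configurations,
    shift_q25,
)


class TestModifyPulseRate:
    @pytest.mark.parametrize("target", [1.0, 3.0])
    def test_remeasured_rate_hits_target(self, medium_call, target):
        modified = modify_pulse_rate(medium_call, target)
        f = acoustics.extract_features(modified)
        assert f.pulse_rate == pytest.approx(target, rel=0.01)
        assert f.n_pulses == 14  # pulse count conserved

    def test_identity_target_keeps_pulses_verbatim(self, medium_call, medium_features):
        modified = modify_pulse_rate(medium_call, medium_features.pulse_rate)
        f = acoustics.extract_features(modified)
        assert f.n_pulses == medium_features.n_pulses
        assert f.pulse_rate == pytest.approx(medium_features.pulse_rate, rel=0.005)

    def test_overlapping_target_rejected(self, medium_call):
        with pytest.raises(InfeasibleTargetError):
            modify_pulse_rate(medium_call, 9.0)  # pulses would collide

    def test_negative_target_rejected(self, medium_call):
        with pytest.raises(InvalidConfigError):
            modify_pulse_rate(medium_call, -1.0)


class TestModifyPulseCount:
    @pytest.mark.parametrize("target", [7, 21])
    def test_remeasured_count_exact_and_rate_preserved(
        self, medium_call, medium_features, target
    ):
        modified = modify_pulse_count(medium_call, target)
        f = acoustics.extract_features(modified)
        assert f.n_pulses == target
        assert f.pulse_rate == pytest.approx(medium_features.pulse_rate, rel=0.02)

    def test_identity_target_bitwise(self, medium_call):
        modified = modify_pulse_count(medium_call, 14)
        assert np.array_equal(modified.samples, medium_call.samples)

    def test_down_up_round_trip_restores_count_not_waveform(self, medium_call):
        seven = modify_pulse_count(medium_call, 7)
        back = modify_pulse_count(seven, 14)
        f = acoustics.extract_features(back)
        assert f.n_pulses == 14
        # lossy: deleted pulses are rebuilt from the final pulse
        assert back.samples.size != medium_call.samples.size or not np.array_equal(
            back.samples, medium_call.samples
        )

    def test_invalid_target_rejected(self, medium_call):
        with pytest.raises(InvalidConfigError):
            modify_pulse_count(medium_call, 0)


class TestShiftQ25:
    @pytest.mark.parametrize("target", [536.0, 804.0])
    def test_remeasured_q25_within_one_bin(self, medium_call, target):
        modified = shift_q25(medium_call, target)
        f = acoustics.extract_features(modified)
        assert abs(f.q25 - target) <= acoustics.fft_bin_width(modified)

    def test_temporal_features_preserved(self, medium_call, medium_features):
        modified = shift_q25(medium_call, 536.0)
        f = acoustics.extract_features(modified)
        assert f.n_pulses == medium_features.n_pulses
        assert f.pulse_rate == pytest.approx(medium_features.pulse_rate, rel=0.01)
        assert f.duration == pytest.approx(medium_features.duration, rel=0.01)

    def test_identity_target_leaves_spectrum(self, medium_call, medium_features):
        modified = shift_q25(medium_call, medium_features.q25)
        f = acoustics.extract_features(modified)
        assert abs(f.q25 - medium_features.q25) <= acoustics.fft_bin_width(modified)

    def test_target_outside_band_rejected(self, medium_call):
        with pytest.raises(InvalidConfigError):
            shift_q25(medium_call, 30000.0)


class TestBuildSeries:
    def test_natural_series_composition(self, medium_signature):
        calls = [
            synth.simulate_call(medium_signature, sample_rate=16000.0, seed=s)
            for s in (1, 2, 3)
        ]
        spec = StimulusSpec(kind="natural_series", repetitions=3)
        series = build_series(calls, spec)
        expected = sum(c.samples.size for c in calls) + 2 * int(3.0 * 16000)
        assert series.samples.size == expected  # 3 renditions, 3.000 s gaps

    def test_modified_series_two_repetitions(self, medium_call_16k):
        spec = StimulusSpec(kind="mod_pulse_rate", target_pulse_rate=3.0, repetitions=2)
        series = build_series([medium_call_16k], spec)
        expected = 2 * medium_call_16k.samples.size + int(3.0 * 16000)
        assert series.samples.size == expected

    def test_rendered_level_is_spec_level(self, medium_call_16k):
        spec = StimulusSpec(kind="mod_q25", target_q25=536.0, repetitions=2)
        series = build_series([medium_call_16k], spec)
        assert acoustics.peak_level(series) == pytest.approx(116.0, abs=0.01)

    def test_wrong_call_count_rejected(self, medium_call_16k):
        with pytest.raises(InvalidConfigError):
            build_series([medium_call_16k], StimulusSpec(kind="natural_series"))

    def test_seven_distinct_configurations(self):
        specs = seven_signal_configurations()
        assert len(specs) == 7
        assert len(set(specs)) == 7
        rates = {s.target_pulse_rate for s in specs if s.kind == "mod_pulse_rate"}
        counts = {s.target_n_pulses for s in specs if s.kind == "mod_pulse_count"}
        q25s = {s.target_q25 for s in specs if s.kind == "mod_q25"}
        assert rates == {1.0, 1.7, 3.0}
        assert counts == {7, 21}
        assert q25s == {536.0, 804.0}

    def test_spec_validation(self):
        with pytest.raises(InvalidConfigError):
            StimulusSpec(kind="mod_pulse_rate")  # missing target
        with pytest.raises(InvalidConfigError):
            StimulusSpec(kind="natural_series", target_q25=600.0)  # stray target
        with pytest.raises(InvalidConfigError):
            StimulusSpec(kind="natural_series", repetitions=5)


class TestResponsePCA:
    def test_two_correlated_blocks(self):
        """Blocks of 4 and 2 perfectly correlated standardized measures yield
        two retained components explaining 66.7 % and 33.3 %."""
        rng = np.random.default_rng(0)
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        X = pd.DataFrame(
            {
                "latency_orient": a,
                "latency_posture": a * 2 + 1,
                "latency_vocalize": -a,
                "latency_move": a * 0.5,
                "n_calls": b,
                "distance_moved": -3 * b,
            }
        )
        pcs = response_pca(X)
        assert pcs.n_retained == 2
        assert pcs.variance_explained[0] == pytest.approx(100 * 4 / 6, abs=0.5)
        assert pcs.variance_explained[1] == pytest.approx(100 * 2 / 6, abs=0.5)

    def test_rotation_preserves_retained_variance(self):
        rng = np.random.default_rng(1)
        latent = rng.normal(size=(80, 2))
        X = pd.DataFrame(
            latent @ rng.normal(size=(2, 6)) + 0.3 * rng.normal(size=(80, 6)),
            columns=playback.RESPONSE_MEASURES,
        )
        pcs = response_pca(X)
        unrotated_var = np.sum(np.sort(pcs.eigenvalues)[::-1][: pcs.n_retained])
        rotated_var = np.sum((pcs.loadings.to_numpy() ** 2).sum(axis=0))
        assert rotated_var == pytest.approx(unrotated_var, abs=1e-9)

    def test_rotation_preserves_reproduced_correlation(self):
        """Varimax is orthogonal: the reproduced correlation matrix L L^T of
        the retained subspace is unchanged by the rotation."""
        rng = np.random.default_rng(2)
        latent = rng.normal(size=(90, 2))
        X = pd.DataFrame(
            latent @ rng.normal(size=(2, 6)) + 0.4 * rng.normal(size=(90, 6)),
            columns=playback.RESPONSE_MEASURES,
        )
        pcs = response_pca(X)
        # unrotated loadings recomputed independently from the correlation matrix
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(corr)
        order = np.argsort(eigvals)[::-1][: pcs.n_retained]
        L0 = eigvecs[:, order] * np.sqrt(eigvals[order])
        L1 = pcs.loadings.to_numpy()
        assert np.allclose(L1 @ L1.T, L0 @ L0.T, atol=1e-9)

    def test_single_factor_recovered(self):
        """One dominant latent factor: PC1 loadings match generator weights."""
        rng = np.random.default_rng(3)
        weights = np.array([0.2, 0.7, 0.9, 0.8, -0.75, -0.9])
        factor = rng.normal(size=300)
        X = pd.DataFrame(
            np.outer(factor, weights) + 0.3 * rng.normal(size=(300, 6)),
            columns=playback.RESPONSE_MEASURES,
        )
        pcs = response_pca(X)
        pc1 = pcs.loadings["PC1"].to_numpy()
        r = np.corrcoef(np.abs(pc1), np.abs(weights))[0, 1]
        assert r >= 0.95

    def test_aggression_sign_convention(self):
        """Strong responders (more calls, approach) get negative PC1 scores."""
        rng = np.random.default_rng(4)
        aggression = rng.normal(size=120)
        X = pd.DataFrame(
            {
                "latency_orient": -0.2 * aggression + rng.normal(size=120),
                "latency_posture": -0.7 * aggression + 0.3 * rng.normal(size=120),
                "latency_vocalize": -0.9 * aggression + 0.3 * rng.normal(size=120),
                "n_calls": 0.9 * aggression + 0.3 * rng.normal(size=120),
                "latency_move": -0.8 * aggression + 0.3 * rng.normal(size=120),
                "distance_moved": 0.75 * aggression + 0.3 * rng.normal(size=120),
            }
        )
        pcs = response_pca(X)
        assert pcs.loadings.loc["n_calls", "PC1"] < 0
        # high-aggression trials score negative
        r = np.corrcoef(aggression, pcs.scores[:, 0])[0, 1]
        assert r < -0.9

    def test_constant_measure_dropped(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(50, 6)), columns=playback.RESPONSE_MEASURES)
        X["n_calls"] = 3.0
        pcs = response_pca(X)
        assert pcs.dropped_measures == ["n_calls"]
        assert "n_calls" not in pcs.loadings.index


def _enumerated_two_sided_p(d):
    """Exact two-sided signed-rank p by full enumeration over sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    dist = np.zeros(1 << n)
    for i, pattern in enumerate(product([0, 1], repeat=n)):
        dist[i] = ranks[np.array(pattern, dtype=bool)].sum()
    p_low = np.mean(dist <= w_obs)
    p_high = np.mean(dist >= w_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


class TestCompareConditions:
    def test_all_positive_differences_n10(self):
        a = np.arange(10, dtype=float) + 1.0
        b = a - np.linspace(0.5, 1.4, 10)
        _, p = compare_conditions(a, b)
        assert p == pytest.approx(2.0 / 1024.0)

    def test_identical_scores_give_p_one(self):
        a = np.arange(6, dtype=float)
        stat, p = compare_conditions(a, a.copy())
        assert p == 1.0

    @pytest.mark.parametrize("n", range(5, 13))
    def test_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        _, p = compare_conditions(a, b)
        assert p == pytest.approx(_enumerated_two_sided_p(a - b), abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(30)
        a = rng.normal(0.4, 1, size=40)
        b = rng.normal(0.0, 1, size=40)
        _, p = compare_conditions(a, b)
        assert 0.0 < p < 1.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InvalidConfigError):
            compare_conditions([1.0, 2.0], [2.0, 1.0])

    def test_synthetic_dominance_effect_power(self):
        """A 1.5-pooled-s.d. condition effect at n = 10 is detected in the
        majority of replicate experiments."""
        hits = 0
        reps = 60
        for seed in range(reps):
            a, b, _ = synth.simulate_responses(1.5, 10, 1.0, seed=seed)
            both = pd.concat([a, b], ignore_index=True)
            pcs = response_pca(both)
            _, p = compare_conditions(pcs.scores[:10, 0], pcs.scores[10:, 0])
            hits += p < 0.05
        assert hits / reps >= 0.5


class TestAlphaDistanceTest:
    @staticmethod
    def _scores(effect_at_10m, n_males=5, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for m in range(n_males):
            for d in (40.0, 30.0, 20.0, 10.0):
                score = rng.normal(0, 0.3)
                if d == 10.0:
                    score -= effect_at_10m
                rows.append({"male_id": f"M{m}", "distance_m": d, "score": score})
        return pd.DataFrame(rows)

    def test_flat_scores_give_p_one(self):
        df = self._scores(0.0)
        df["score"] = 1.0
        _, p = alpha_distance_test(df, seed=1)
        assert p == 1.0

    def test_close_range_effect_detected(self):
        hits = 0
        for seed in range(20):
            df = self._scores(2.0, seed=seed)
            _, p = alpha_distance_test(df, n_permutations=300, seed=seed)
            hits += p < 0.05
        assert hits >= 12  # majority of seeds

    def test_minimum_p_bound(self):
        df = self._scores(5.0, seed=3)
        _, p = alpha_distance_test(df, n_permutations=50, seed=3)
        assert p >= 1.0 / 51.0

    def test_incomplete_block_excluded(self):
        df = self._scores(1.0, seed=4)
        df = df.drop(index=df.index[0])  # male 0 misses the 40 m trial
        stat, p = alpha_distance_test(df, seed=4)
        assert np.isfinite(stat)
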