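"""TFCE, the chance baseline, the sign-flip group test, and binning."""

import numpy as np
import pytest

from megrwa.containers import GroupStatMap
from megrwa.group_stats import (
    bin_significance,
    group_rank_test,
    spatiotemporal_edges,
    subject_null_epsilon,
    tfce,
)
from megrwa.searchlight import searchlight_rdms, sensor_adjacency
from oracles import brute_force_tfce


def _chain_adjacency(n):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return adj


class TestTFCE:
    def test_zero_map_stays_zero(self):
        adj = _chain_adjacency(4)
        assert not tfce(np.zeros((4, 6)), adj).any()

    def test_isolated_peak_matches_analytic_limit(self):
        """A single supra-threshold point of height h0 integrates to
        h0^(H+1)/(H+1) = h0^3/3 at H=2, up to dh discretization."""
        adj = _chain_adjacency(5)
        m = np.zeros((5, 5))
        h0 = 1.7
        m[2, 2] = h0
        out = tfce(m, adj, E=0.5, H=2.0, n_steps=400)
        assert out[2, 2] == pytest.approx(h0**3 / 3, rel=0.01)
        assert out.sum() == pytest.approx(out[2, 2])

    def test_1d_toy_map_matches_brute_force(self):
        adj = np.zeros((1, 1), dtype=bool)
        m = np.array([[0.0, 2.0, 2.0, 0.0, 1.0]])
        fast = tfce(m, adj, n_steps=500)
        brute = brute_force_tfce(m, adj, n_steps=500)
        assert np.allclose(fast, brute, rtol=1e-10, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_maps_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        adj = sensor_adjacency(__import__("megrwa").generate_sensor_layout(10), 3)
        m = rng.normal(size=(10, 20))
        fast = tfce(m, adj, n_steps=100)
        brute = brute_force_tfce(m, adj, n_steps=100)
        assert np.allclose(fast, brute, rtol=1e-9, atol=1e-12)

    def test_monotone_in_the_input(self, rng):
        adj = _chain_adjacency(6)
        m = rng.normal(size=(6, 10))
        bigger = m + 0.5 * rng.random(m.shape)
        h_max = bigger.max()
        a = tfce(m, adj, h_max=h_max)
        b = tfce(bigger, adj, h_max=h_max)
        assert (b >= a - 1e-12).all()

    def test_asymmetric_adjacency_rejected(self):
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = True
        with pytest.raises(ValueError, match="symmetric"):
            spatiotemporal_edges(adj, 4)


def _tiny_neural(rng, n_sensors=3, n_times=4, n_stim=10):
    from megrwa.containers import NeuralRDMSeries

    n_pairs = n_stim * (n_stim - 1) // 2
    return NeuralRDMSeries(
        rdms=rng.random((n_sensors, n_times, n_pairs)),
        sensor_ids=np.array([f"S{i}" for i in range(n_sensors)]),
        times=np.arange(n_times) / 400.0,
        stimulus_ids=np.array([f"s{i}" for i in range(n_stim)]),
    )


def _tiny_models(rng, n_stim=10):
    from megrwa.containers import ModelRDM

    out = []
    for name in ("a", "b", "c"):
        m = np.zeros((n_stim, n_stim))
        iu = np.triu_indices(n_stim, k=1)
        m[iu] = rng.random(len(iu[0]))
        out.append(ModelRDM(name, m + m.T))
    return out


class TestNullEpsilon:
    def test_identity_relabeling_reproduces_observed(self, rng):
        from megrwa.group_stats import _pair_permutation_index

        idx = _pair_permutation_index(10, np.arange(10))
        assert np.array_equal(idx, np.arange(45))

    def test_observed_far_exceeds_null_for_planted_signal(self, rng, model_rdms):
        from megrwa.containers import NeuralRDMSeries, upper_triangle
        from megrwa.rwa import searchlight_rwa
        from megrwa.synthetic import mixture_rdm

        y = upper_triangle(mixture_rdm(model_rdms, np.array([1.0, 0, 0])))
        neural = NeuralRDMSeries(
            rdms=np.tile(y, (1, 1, 1)),
            sensor_ids=np.array(["S0"]),
            times=np.array([0.0]),
            stimulus_ids=model_rdms[0].stimulus_ids,
        )
        obs = searchlight_rwa(neural, model_rdms).epsilon[0, 0, 0]
        null_mean, null_sd = subject_null_epsilon(neural, model_rdms, n_null=50, seed=1)
        assert obs > null_mean[0, 0, 0] + 10 * null_sd[0, 0, 0]

    def test_pure_noise_epsilon_within_null_band(self, rng):
        neural = _tiny_neural(rng, n_sensors=4, n_times=5)
        models = _tiny_models(rng)
        from megrwa.rwa import searchlight_rwa

        obs = searchlight_rwa(neural, models).epsilon
        null_mean, null_sd = subject_null_epsilon(neural, models, n_null=200, seed=2)
        z = (obs - null_mean) / np.where(null_sd > 0, null_sd, 1.0)
        assert (np.abs(z) <= 2.5).mean() > 0.9

    def test_minimum_null_iterations_enforced(self, rng):
        with pytest.raises(ValueError):
            subject_null_epsilon(_tiny_neural(rng), _tiny_models(rng), n_null=5)


class TestGroupRankTest:
    def test_all_zero_maps_nothing_significant(self):
        maps = [np.zeros((4, 6, 2)) for _ in range(5)]
        stats = group_rank_test(maps, _chain_adjacency(4), n_permutations=200, seed=0)
        assert not stats.significant().any()
        assert stats.exhaustive  # 2^5 = 32 <= 200

    def test_planted_location_detected_and_sign_reversal_kills_it(self, rng):
        n_subj, shape = 8, (6, 10, 1)
        maps = [0.1 * rng.normal(size=shape) for _ in range(n_subj)]
        for m in maps:
            m[2, 4:7, 0] += 2.0  # strong consistent positive effect
        adj = _chain_adjacency(6)
        stats = group_rank_test(maps, adj, n_permutations=1000, seed=1)
        assert stats.significant()[0, 2, 5]
        flipped = group_rank_test([-m for m in maps], adj, n_permutations=1000, seed=1)
        assert not flipped.significant().any()

    def test_seed_determinism(self, rng):
        maps = [rng.normal(size=(4, 8, 2)) for _ in range(12)]
        adj = _chain_adjacency(4)
        a = group_rank_test(maps, adj, n_permutations=300, seed=42)
        b = group_rank_test(maps, adj, n_permutations=300, seed=42)
        assert np.array_equal(a.z, b.z)
        assert np.array_equal(a.p_corrected, b.p_corrected)
        assert not a.exhaustive  # 2^12 > 300

    def test_p_values_valid_and_one_tailed(self, rng):
        maps = [rng.normal(size=(3, 5, 1)) for _ in range(6)]
        stats = group_rank_test(maps, _chain_adjacency(3), n_permutations=500, seed=3)
        assert ((stats.p_corrected >= 1 / stats.n_permutations) & (stats.p_corrected <= 1)).all()


class TestBinSignificance:
    def _stats(self, sig_mask, times):
        p = np.where(sig_mask, 0.01, 0.5)
        return GroupStatMap(
            z=np.where(sig_mask, 3.0, 0.0),
            p_corrected=p,
            model_names=["m"],
            sensor_ids=np.array(["S0", "S1"]),
            times=times,
        )

    def test_fully_significant_bin_retained(self):
        times = np.arange(0.100, 0.150, 1 / 400.0)
        sig = np.zeros((1, 2, len(times)), dtype=bool)
        sig[0, 0, :] = True
        binned = bin_significance(self._stats(sig, times))
        assert binned.sensors("m", 0).tolist() == ["S0"]

    def test_single_missing_sample_excludes_sensor(self):
        times = np.arange(0.100, 0.150, 1 / 400.0)
        sig = np.ones((1, 2, len(times)), dtype=bool)
        sig[0, 1, 3] = False
        binned = bin_significance(self._stats(sig, times))
        assert binned.sensors("m", 0).tolist() == ["S0"]

    def test_empty_map_all_bins_empty(self):
        times = np.arange(0.0, 0.2, 1 / 400.0)
        sig = np.zeros((1, 2, len(times)), dtype=bool)
        binned = bin_significance(self._stats(sig, times))
        for b in range(len(binned.bins)):
            assert len(binned.sensors("m", b)) == 0
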