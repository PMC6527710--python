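"""Synthetic stimulus/MEG generator: determinism, structure, planted geometry."""

import numpy as np
import pytest

from megrwa.containers import upper_triangle
from megrwa.features import correlation_distance_matrix, model_intercorrelation
from megrwa.preprocessing import average_pseudo_trials
from megrwa.rwa import relative_weights
from megrwa.searchlight import searchlight_rdms, spatial_neighbors
from megrwa.synthetic import (
    PlantedEffect,
    PlantedSignalSpec,
    SyntheticStimulusSpec,
    exact_mixture_patterns,
    generate_meg_dataset,
    generate_sensor_layout,
    generate_stimuli,
    mixture_rdm,
    planted_correlation_factor,
    presentation_design,
)


class TestStimuli:
    def test_default_design_counts(self, stimulus_set):
        assert stimulus_set.n_stimuli == 30
        assert stimulus_set.masks.shape[0] == 30
        counts = np.bincount(stimulus_set.labels)
        assert (counts == 5).all() and len(counts) == 6

    def test_every_mask_nonempty(self, stimulus_set):
        assert stimulus_set.masks.reshape(30, -1).any(axis=1).all()

    def test_zero_jitter_single_category_identical_images(self):
        spec = SyntheticStimulusSpec(n_categories=1, n_per_category=2, jitter=0.0, seed=3)
        st = generate_stimuli(spec)
        assert np.array_equal(st.images[0], st.images[1])
        assert np.array_equal(st.masks[0], st.masks[1])

    def test_seed_determinism_bit_identical(self):
        a = generate_stimuli(SyntheticStimulusSpec(seed=7))
        b = generate_stimuli(SyntheticStimulusSpec(seed=7))
        assert np.array_equal(a.images, b.images)
        assert np.array_equal(a.masks, b.masks)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="image_size"):
            SyntheticStimulusSpec(image_size=16)

    def test_collinearity_is_tunable(self, model_rdms):
        """Decoupled mode removes the category-shape/spectral association;
        the collinear default keeps all pairwise rank correlations positive."""
        from megrwa.features import compute_model_rdms

        rho_coll = model_intercorrelation(model_rdms)
        off = rho_coll[np.triu_indices(3, k=1)]
        assert (off > 0).all()
        decoupled = generate_stimuli(SyntheticStimulusSpec(seed=1, collinear=False))
        rho_dec = model_intercorrelation(compute_model_rdms(decoupled))
        assert np.abs(rho_dec[np.triu_indices(3, k=1)]).max() < np.max(off)


class TestSensorLayout:
    def test_102_unique_positions(self):
        layout = generate_sensor_layout(102)
        assert layout.n_sensors == 102
        assert len(np.unique(layout.positions, axis=0)) == 102

    def test_two_sensors_distinct(self):
        layout = generate_sensor_layout(2)
        assert not np.allclose(layout.positions[0], layout.positions[1])

    def test_all_pairwise_distances_positive(self):
        pos = generate_sensor_layout(50).positions
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        assert (d[np.triu_indices(50, k=1)] > 0).all()

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            generate_sensor_layout(1)


class TestPresentationDesign:
    def test_8_runs_3_blocks_gives_24_presentations(self):
        order = presentation_design(30, n_runs=8, n_blocks_per_run=3, seed=0)
        assert (np.bincount(order) == 24).all()

    def test_each_block_is_a_permutation(self):
        order = presentation_design(12, n_runs=2, n_blocks_per_run=3, seed=1)
        for b in order.reshape(6, 12):
            assert sorted(b) == list(range(12))


class TestPlantedFactor:
    def test_factor_reconstructs_similarity(self, model_rdms):
        for rdm in model_rdms:
            L, distortion = planted_correlation_factor(rdm)
            assert np.allclose(np.linalg.norm(L, axis=1), 1.0)
            assert distortion < 0.25
            C = L @ L.T
            assert np.allclose(np.diag(C), 1.0)

    def test_exact_embedding_matches_mixture(self, model_rdms):
        w = np.array([0.5, 0.3, 0.2])
        P, D = exact_mixture_patterns(model_rdms, w, 210)
        emp = correlation_distance_matrix(P)
        assert np.abs(emp - D).max() < 1e-10
        assert np.abs(mixture_rdm(model_rdms, w) - D).max() < 1e-12

    def test_embedding_needs_enough_features(self, model_rdms):
        with pytest.raises(ValueError, match="n_features"):
            exact_mixture_patterns(model_rdms, np.ones(3), 10)


def _small_plant(layout, weights, noise_sd, n_subjects=2, seed=5, trials=6):
    group = np.argsort(layout.positions[:, 1])[:8]
    return PlantedSignalSpec(
        sensor_layout=layout,
        plants=[PlantedEffect(group, (0.1, 0.15), np.asarray(weights))],
        noise_sd=noise_sd,
        n_subjects=n_subjects,
        n_trials_per_stimulus=trials,
        sfreq=400.0,
        epoch_window=(-0.1, 0.3),
        seed=seed,
    )


class TestMEGDataset:
    def test_mismatched_rdm_size_rejected(self, stimulus_set, model_rdms, layout20):
        from megrwa.containers import ModelRDM

        bad = ModelRDM("x", np.zeros((4, 4)))
        spec = _small_plant(layout20, [1, 0, 0], 1.0)
        with pytest.raises(ValueError, match="stimuli"):
            generate_meg_dataset(stimulus_set, [bad] * 3, spec)

    def test_seed_determinism(self, stimulus_set, model_rdms, layout20):
        spec = _small_plant(layout20, [1, 0, 0], 0.5, n_subjects=1)
        a = generate_meg_dataset(stimulus_set, model_rdms, spec)[0]
        b = generate_meg_dataset(stimulus_set, model_rdms, spec)[0]
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.trial_stimulus_id, b.trial_stimulus_id)

    def test_single_model_noiseless_plant_recovers_geometry(
        self, stimulus_set, model_rdms, layout20
    ):
        """With w = (1, 0, 0) and no noise, the searchlight RDM at the plant
        center matches the (variance-equalized) model-1 geometry at high
        rank correlation."""
        from scipy.stats import spearmanr

        spec = _small_plant(layout20, [1.0, 0.0, 0.0], noise_sd=0.0, n_subjects=1, trials=1)
        data = generate_meg_dataset(stimulus_set, model_rdms, spec)[0]
        pseudo = average_pseudo_trials(data, stimulus_order=stimulus_set.stimulus_ids)
        neural = searchlight_rdms(pseudo, k=8, r=10)
        group = np.argsort(layout20.positions[:, 1])[:8]
        center = group[0]
        t_idx = spec.time_indices((0.1, 0.15))
        t_mid = int(t_idx.mean())
        target = upper_triangle(mixture_rdm(model_rdms, np.array([1.0, 0, 0])))
        rho = spearmanr(neural.rdms[center, t_mid], target).statistic
        assert rho > 0.7

    def test_null_weights_give_pure_noise(self, stimulus_set, model_rdms, layout20):
        spec = PlantedSignalSpec(
            sensor_layout=layout20,
            plants=[],
            noise_sd=1.0,
            n_subjects=1,
            n_trials_per_stimulus=4,
            epoch_window=(-0.05, 0.05),
            seed=9,
        )
        data = generate_meg_dataset(stimulus_set, model_rdms, spec)[0]
        # white noise: mean ~ 0, variance ~ noise_sd^2
        assert abs(data.data.mean()) < 0.01
        assert data.data.var() == pytest.approx(1.0, rel=0.05)

    def test_weighted_plant_recovers_epsilon_ordering(
        self, stimulus_set, model_rdms, layout20
    ):
        """Planted w = (0.5, 0.3, 0.2) with moderate noise: the group-mean
        relative weights inside the plant preserve the planted ordering.
        Oracle: the mixture geometry is constructed directly."""
        spec = _small_plant(layout20, [0.5, 0.3, 0.2], noise_sd=0.5, n_subjects=4, trials=8)
        datasets = generate_meg_dataset(stimulus_set, model_rdms, spec)
        group = np.argsort(layout20.positions[:, 1])[:8]
        t_idx = spec.time_indices((0.1, 0.15))
        eps_sum = np.zeros(3)
        for data in datasets:
            pseudo = average_pseudo_trials(data, stimulus_order=stimulus_set.stimulus_ids)
            neural = searchlight_rdms(pseudo, k=8, r=10)
            y = neural.rdms[group[0], int(t_idx.mean())]
            X = np.column_stack([m.vector for m in model_rdms])
            eps_sum += relative_weights(y, X).epsilon
        assert np.argsort(eps_sum)[::-1].tolist() == [0, 1, 2]

    def test_plant_outside_epoch_rejected(self, layout20):
        with pytest.raises(ValueError, match="window"):
            PlantedSignalSpec(
                sensor_layout=layout20,
                plants=[PlantedEffect(np.array([0]), (0.5, 0.6), np.ones(3))],
                epoch_window=(-0.1, 0.3),
            )
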