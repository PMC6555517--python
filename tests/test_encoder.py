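"""Encoder layer: structure, plasticity, activation rules, persistence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cstm import encoder as E

from conftest import make_stream


def brute_force_counts(layer):
    """Enumeration oracle for synapse counts: walk the arrays."""
    prox = int(np.prod(layer.proximal.shape))
    distal = int(np.prod(layer.distal.shape))
    units = layer.proximal.shape[0] * layer.proximal.shape[1]
    return units, prox, distal


class TestStructure:
    def test_counts_match_enumeration_on_small_config(self, small_encoder_config):
        layer = E.EncoderLayer(small_encoder_config, seed=0)
        units, prox, distal = brute_force_counts(layer)
        cfg = small_encoder_config
        assert units == cfg.n_units_total == 9 * 25
        assert prox == cfg.n_proximal_synapses == 9 * 25 * 10
        assert distal == cfg.n_distal_synapses == 9 * 25 * 8 * 6

    def test_degenerate_single_unit_layer(self):
        cfg = E.EncoderConfig(
            grid_shape=(1, 1), unit_shape=(1, 1), afferent_inputs=1,
            lateral_rf=(1, 1), linked_fraction=0.0, potential_per_dendrite=1,
            sparsity=0.0, proximal_activation_pct=1.0,
        )
        layer = E.EncoderLayer(cfg, seed=0)
        assert cfg.n_units_total == 1
        assert cfg.n_proximal_synapses == 1
        assert cfg.n_distal_synapses == 0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):  # min active would be zero
            E.EncoderConfig(unit_shape=(5, 5), lateral_rf=(3, 3), sparsity=0.99)
        with pytest.raises(ValueError):  # RF bigger than the grid
            E.EncoderConfig(grid_shape=(3, 3), lateral_rf=(9, 9), unit_shape=(15, 15))

    def test_potential_targets_are_valid_unit_indices(self, small_encoder_config):
        layer = E.EncoderLayer(small_encoder_config, seed=2)
        U = small_encoder_config.units_per_column
        assert layer.targets.min() >= 0 and layer.targets.max() < U
        # distinct within each dendrite
        s = np.sort(layer.targets, axis=-1)
        assert not (s[..., 1:] == s[..., :-1]).any()

    def test_sample_distinct_is_uniform_without_replacement(self):
        rng = np.random.default_rng(0)
        draws = E.sample_distinct(rng, 10, (4000,), 3)
        s = np.sort(draws, axis=-1)
        assert not (s[:, 1:] == s[:, :-1]).any()
        counts = np.bincount(draws.reshape(-1), minlength=10)
        assert counts.min() > 0.8 * counts.mean()


class TestImputation:
    def test_fully_determined_vector_untouched(self, small_encoder_config):
        layer = E.EncoderLayer(small_encoder_config, seed=0)
        x = np.linspace(0, 1, layer.afferent_idx.shape[0] * layer.afferent_idx.shape[1])
        x = x.reshape(layer.afferent_idx.shape)
        out = layer.impute_undetermined(x, np.zeros_like(x, bool), layer.rng, learn=False)
        assert np.array_equal(out, x)

    def test_collapsed_margin_fills_exact_value(self, small_encoder_config):
        layer = E.EncoderLayer(small_encoder_config, seed=0)
        layer.margin_min[:] = 0.2
        layer.margin_max[:] = 0.2
        x = np.zeros(layer.margin_min.shape)
        out = layer.impute_undetermined(x, np.ones_like(x, bool), layer.rng, learn=False)
        assert np.allclose(out, 0.2)

    def test_uniform_draws_between_margins(self, small_encoder_config):
        layer = E.EncoderLayer(small_encoder_config, seed=0)
        layer.margin_min[:] = 0.0
        layer.margin_max[:] = 1.0
        rng = np.random.default_rng(0)
        draws = [
            layer.impute_undetermined(
                np.zeros(layer.margin_min.shape),
                np.ones(layer.margin_min.shape, bool),
                rng,
                learn=False,
            )[0, 0]
            for _ in range(10_000)
        ]
        assert abs(np.mean(draws) - 0.5) < 0.02

    def test_margins_learn_running_min_max(self, small_encoder_config):
        layer = E.EncoderLayer(small_encoder_config, seed=0)
        shape = layer.margin_min.shape
        for v in (0.4, 0.9, 0.1):
            layer.impute_undetermined(
                np.full(shape, v), np.zeros(shape, bool), layer.rng, learn=True
            )
        assert np.allclose(layer.margin_min, 0.1)
        assert np.allclose(layer.margin_max, 0.9)


class TestProximalPlasticity:
    def test_zero_learning_rate_no_change(self, small_encoder_config):
        layer = E.EncoderLayer(small_encoder_config, seed=1)
        before = layer.proximal.copy()
        x = np.random.default_rng(0).random(layer.margin_min.shape)
        d = np.linalg.norm(layer.proximal - x[:, None, :], axis=2)
        layer.ssom_update(x, d, 0.0, 1.0)
        assert np.array_equal(layer.proximal, before)

    def test_unit_learning_rate_snaps_bmu_to_input(self):
        cfg = E.EncoderConfig(
            grid_shape=(1, 1), unit_shape=(1, 1), afferent_inputs=3,
            lateral_rf=(1, 1), linked_fraction=0.0, potential_per_dendrite=1,
            sparsity=0.0, proximal_activation_pct=1.0,
        )
        layer = E.EncoderLayer(cfg, seed=0)
        x = np.array([[0.3, 0.6, 0.9]])
        d = np.linalg.norm(layer.proximal - x[:, None, :], axis=2)
        layer.ssom_update(x, d, 1.0, 0.0)
        assert np.allclose(layer.proximal[0, 0], x[0])

    def test_half_learning_rate_halves_bmu_distance(self, small_encoder_config):
        layer = E.EncoderLayer(small_encoder_config, seed=3)
        x = np.random.default_rng(1).random(layer.margin_min.shape)
        d = np.linalg.norm(layer.proximal - x[:, None, :], axis=2)
        bmu = np.argmin(d, axis=1)
        before = d[np.arange(len(bmu)), bmu].copy()
        layer.ssom_update(x, d, 0.5, 0.0)  # radius 0: isolated BMU update
        d2 = np.linalg.norm(layer.proximal - x[:, None, :], axis=2)
        after = d2[np.arange(len(bmu)), bmu]
        assert np.allclose(after, 0.5 * before)


class TestDistalPlasticity:
    def _two_column_layer(self):
        cfg = E.EncoderConfig(
            grid_shape=(1, 2), unit_shape=(2, 2), afferent_inputs=2,
            lateral_rf=(1, 2), linked_fraction=1.0, potential_per_dendrite=2,
            sparsity=0.75, proximal_activation_pct=0.5,
            enable_random_behaviour=False, distal_normalization_period=10**9,
        )
        return E.EncoderLayer(cfg, seed=0)

    def test_sequential_firing_strengthens(self):
        layer = self._two_column_layer()
        # the dendrite of unit (0,0) in column 0 that links to column 1
        l_idx = int(np.flatnonzero(layer.linked[0] == 1)[0])
        prev = np.zeros((2, 4), bool)
        prev[1, layer.targets[0, 0, l_idx, 0]] = True
        cur = np.zeros((2, 4), bool)
        cur[0, 0] = True
        _, prev_mask = layer.compute_distal_support(prev)
        layer.dsom_update(cur, np.zeros(2, bool), prev_mask)
        assert layer.distal[0, 0, l_idx, 0] == pytest.approx(layer.config.delta_plus)

    def test_simultaneous_firing_weakens_with_floor(self):
        layer = self._two_column_layer()
        l_idx = int(np.flatnonzero(layer.linked[0] == 1)[0])
        layer.distal[0, 0, l_idx, 0] = 0.002
        cur = np.zeros((2, 4), bool)
        cur[0, 0] = True
        cur[1, layer.targets[0, 0, l_idx, 0]] = True
        _, prev_mask = layer.compute_distal_support(None)
        layer.dsom_update(cur, np.zeros(2, bool), prev_mask)
        # w -> max(0, w - delta_minus): 0.002 - 0.005 floors at zero
        assert layer.distal[0, 0, l_idx, 0] == 0.0
        assert layer.distal.min() >= 0.0

    def test_dendrite_rescaled_to_unit_sum(self):
        distal = np.array([[0.9, 0.6]], dtype=np.float32)
        E.normalize_dendrites(distal)
        assert np.allclose(distal, [[0.6, 0.4]])
        under = np.array([[0.3, 0.2]], dtype=np.float32)
        E.normalize_dendrites(under)
        assert np.allclose(under, [[0.3, 0.2]])  # sum <= 1 untouched

    def test_stdp_asymmetry_direction(self):
        """A->B ordering strengthens B's synapses onto A, not the reverse."""
        layer = self._two_column_layer()
        l01 = int(np.flatnonzero(layer.linked[0] == 1)[0])  # col0 dendrites to col1
        l10 = int(np.flatnonzero(layer.linked[1] == 0)[0])  # col1 dendrites to col0
        a = np.zeros((2, 4), bool)
        a[0, layer.targets[1, 0, l10, 0]] = True  # unit in col 0 ("A")
        b = np.zeros((2, 4), bool)
        b[1, 0] = True  # unit 0 in col 1 ("B")
        _, mask = layer.compute_distal_support(a)
        layer.dsom_update(b, np.zeros(2, bool), mask)
        onto_a = layer.distal[1, 0, l10, 0]
        onto_b = layer.distal[0].sum()
        assert onto_a > 0 and onto_b == 0


class TestDistalSupport:
    def test_no_previous_activity_no_support(self, small_encoder_config):
        layer = E.EncoderLayer(small_encoder_config, seed=0)
        support, _ = layer.compute_distal_support(None)
        assert not support.any()

    def test_single_and_double_dendrite_counts(self):
        cfg = E.EncoderConfig(
            grid_shape=(1, 2), unit_shape=(2, 2), afferent_inputs=2,
            lateral_rf=(1, 2), linked_fraction=1.0, potential_per_dendrite=2,
            sparsity=0.75, proximal_activation_pct=0.5,
            enable_random_behaviour=False,
        )
        layer = E.EncoderLayer(cfg, seed=0)
        thr = 100 * cfg.distal_synaptic_threshold
        prev = np.zeros((2, 4), bool)
        # make both of unit (0,0)'s dendrites point at active targets
        prev[layer.linked[0, 0], layer.targets[0, 0, 0, 0]] = True
        layer.distal[0, 0, 0, 0] = thr * 1.1
        support, _ = layer.compute_distal_support(prev)
        assert support[0, 0] == 1
        prev[layer.linked[0, 1], layer.targets[0, 0, 1, 1]] = True
        layer.distal[0, 0, 1, 1] = thr * 1.1
        support, _ = layer.compute_distal_support(prev)
        assert support[0, 0] == 2
        # weights at or below the threshold do not activate a dendrite
        layer.distal[0, 0, 1, 1] = thr
        support, _ = layer.compute_distal_support(prev)
        assert support[0, 0] == 1


class TestActivationRules:
    def test_no_support_gives_massive_firing(self):
        updated = np.full(25, np.inf)
        excited = np.arange(5, 10)
        active, mfe = E.select_active(updated, excited, 1)
        assert mfe and np.array_equal(active, excited)

    def test_supported_units_give_sparse_firing(self):
        updated = np.full(25, np.inf)
        updated[7] = 0.3
        updated[9] = 0.5
        excited = np.array([5, 6, 7, 8, 9])
        active, mfe = E.select_active(updated, excited, 2)
        assert not mfe and np.array_equal(active, [7, 9])

    def test_single_unit_column_always_active(self):
        active, mfe = E.select_active(np.array([np.inf]), np.array([0]), 1)
        assert np.array_equal(active, [0]) and not mfe

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_active_count_is_min_or_full_cluster(self, seed):
        rng = np.random.default_rng(seed)
        U, Ecount, m = 25, 5, 2
        distances = rng.random(U)
        support = rng.integers(0, 3, U)
        updated = np.where(support > 0, distances / np.maximum(support, 1), np.inf)
        excited = E.choose_excited(distances, Ecount, rng if seed % 2 else None)
        active, mfe = E.select_active(updated, excited, m, rng if seed % 2 else None)
        assert len(active) == (Ecount if mfe else m)
        assert set(active) <= set(excited.tolist())

    def test_choose_excited_deterministic_ranking(self):
        d = np.array([0.5, 0.1, 0.9, 0.1, 0.3])
        assert list(E.choose_excited(d, 3)) == [1, 3, 4]  # stable index tie-break

    def test_choose_excited_stochastic_prefers_near_units(self):
        d = np.array([0.01, 1.0, 1.0, 1.0, 1.0, 1.0])
        rng = np.random.default_rng(0)
        hits = sum(0 in E.choose_excited(d, 2, rng) for _ in range(200))
        assert hits > 190


class TestStepAndModes:
    def test_first_frame_is_all_mfe(self, small_encoder_config):
        layer = E.EncoderLayer(small_encoder_config, seed=0)
        act = layer.step(np.random.default_rng(0).random((5, 128)))
        assert act.mfe.all()
        assert (act.counts == small_encoder_config.excited_count).all()

    def test_frame_shape_mismatch_rejected(self, small_encoder_config):
        layer = E.EncoderLayer(small_encoder_config, seed=0)
        with pytest.raises(ValueError):
            layer.step(np.zeros((5, 64)))

    def test_inference_identical_runs_and_weight_purity(self, small_encoder_config):
        layer = E.EncoderLayer(small_encoder_config, seed=4)
        stream = make_stream(np.random.default_rng(2).random((20, 5, 128)))
        before = layer.weight_checksum()
        acts1 = layer.infer(stream, seed=11)
        acts2 = layer.infer(stream, seed=11)
        assert layer.weight_checksum() == before
        for a, b in zip(acts1, acts2):
            assert np.array_equal(a.active_mask, b.active_mask)
            assert np.array_equal(a.mfe, b.mfe)

    def test_training_schedule_shape_and_decay(self, small_encoder_config):
        sched = E.TrainingSchedule()
        records = sched.passes((15, 15))
        assert len(records) == 4 * 4 + 4
        for s in range(4):
            lrs = [r["learning_rate"] for r in records if r["stage"] == s]
            assert all(a > b for a, b in zip(lrs, lrs[1:]))
        stage_initials = [
            next(r["learning_rate"] for r in records if r["stage"] == s) for s in range(4)
        ]
        assert all(a > b for a, b in zip(stage_initials, stage_initials[1:]))
        fixed = [r for r in records if r["stage"] == 4]
        assert len({r["learning_rate"] for r in fixed}) == 1

    def test_train_log_one_record_per_pass(self, small_encoder_config):
        layer = E.EncoderLayer(small_encoder_config, seed=0)
        stream = make_stream(np.random.default_rng(3).random((6, 5, 128)))
        log = layer.train(stream)
        sched = small_encoder_config.schedule
        assert len(log) == sched.n_stages * sched.passes_per_stage + sched.final_passes

    def test_sequence_learned_then_violated(self, small_encoder_config):
        """A repeated deterministic cycle becomes predictable (sparse firing);
        replaying it in a shuffled order re-elicits massive firing."""
        layer = E.EncoderLayer(small_encoder_config, seed=3)
        cycle = np.random.default_rng(0).random((4, 5, 128)) * 0.8 + 0.2
        stream = make_stream(np.tile(cycle, (10, 1, 1)))
        layer.train(stream)
        replay = layer.infer(make_stream(np.tile(cycle, (2, 1, 1))), seed=0)
        assert not any(a.mfe.any() for a in replay[1:])
        permuted = layer.infer(make_stream(np.tile(cycle[[2, 0, 3, 1]], (2, 1, 1))), seed=0)
        assert any(a.mfe.any() for a in permuted)


class TestPersistence:
    def test_roundtrip_preserves_inference(self, small_encoder_config, tmp_path):
        layer = E.EncoderLayer(small_encoder_config, seed=5)
        stream = make_stream(np.random.default_rng(4).random((8, 5, 128)))
        layer.train(stream)
        E.save_model(tmp_path / "m.h5", layer)
        back = E.load_model(tmp_path / "m.h5")
        assert np.array_equal(back.proximal, layer.proximal)
        assert np.array_equal(back.distal, layer.distal)
        a1 = layer.infer(stream, seed=1)
        a2 = back.infer(stream, seed=1)
        for x, y in zip(a1, a2):
            assert np.array_equal(x.active_mask, y.active_mask)

    def test_corrupted_file_rejected(self, tmp_path):
        import h5py

        with h5py.File(tmp_path / "bad.h5", "w") as fh:
            fh.attrs["format"] = "something-else"
        with pytest.raises(ValueError):
            E.load_model(tmp_path / "bad.h5")
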