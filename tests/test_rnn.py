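"""Modular STSP network: masks, dynamics, task encoding, gradients."""

import numpy as np
import pandas as pd
import pytest

from flexwm import rnn
from flexwm.rnn import network as net
from flexwm.rnn.train import population_vector, train as train_network

FAST_EPOCHS = {
    "sample1": 100, "isi1": 40, "sample2": 100, "retro_cue": 40, "delay1": 100,
    "task_cue": 40, "delay2": 200, "option1": 80, "option2": 80, "test": 120,
}


def tiny_config(**kw):
    base = dict(
        units_per_module=20, batch_per_condition=8, epochs_ms=FAST_EPOCHS,
        grace_ms=20, max_iter=5,
    )
    base.update(kw)
    return rnn.network_config("desk", **base)


class TestMasks:
    @pytest.mark.parametrize("scale,U", [("tiny", 20), ("desk", 60)])
    def test_module_and_ei_counts(self, scale, U):
        cfg = tiny_config(units_per_module=U)
        assert cfg.n_units == 3 * U
        assert cfg.n_exc_per_module == int(0.8 * U)

    def test_full_scale_counts(self):
        cfg = rnn.network_config("full")
        assert cfg.units_per_module == 200
        assert cfg.n_exc_per_module == 160
        assert cfg.n_units == 600

    def test_connectivity_topology(self):
        cfg = tiny_config(units_per_module=40)
        params = net.init_params(cfg, seed=3)
        conn, sign = params.conn_mask, params.sign
        U, nE = 40, 32
        mods = [slice(m * U, (m + 1) * U) for m in range(3)]
        # no module-1 <-> module-3 direct connections
        assert conn[mods[0], mods[2]].sum() == 0
        assert conn[mods[2], mods[0]].sum() == 0
        # inhibitory units never project outside their module
        inh = np.where(sign < 0)[0]
        for i in inh:
            m = i // U
            outside = np.ones(cfg.n_units, bool)
            outside[mods[m]] = False
            assert conn[i, outside].sum() == 0
        # exactly half of each module's E units send to each neighbor
        for src, dst in [(0, 1), (1, 0), (1, 2), (2, 1)]:
            senders = [
                e for e in range(mods[src].start, mods[src].start + nE)
                if conn[e, mods[dst]].sum() > 0
            ]
            assert len(senders) == nE // 2

    def test_no_self_connections(self):
        params = net.init_params(tiny_config(), seed=0)
        assert np.all(np.diag(params.conn_mask) == 0)

    def test_dale_sign_of_effective_weights(self):
        params = net.init_params(tiny_config(), seed=1)
        _, W_rec, _ = params.effective()
        exc = params.sign > 0
        assert np.all(W_rec[exc, :] >= 0)
        assert np.all(W_rec[~exc, :] <= 0)

    def test_input_output_routing(self):
        cfg = tiny_config()
        params = net.init_params(cfg, seed=2)
        W_in, _, W_out = params.effective()
        U, nE = cfg.units_per_module, cfg.n_exc_per_module
        assert np.all(W_in[:, nE:] == 0)  # inputs only to module-1 E units
        assert np.all(W_out[: 2 * U, :] == 0)  # outputs only from module 3
        assert np.all(W_out[2 * U + nE :, :] == 0)  # and only its E units


class TestTaskEncoding:
    def test_batch_shapes_and_bump_peak(self):
        cfg = tiny_config()
        rng = np.random.default_rng(0)
        trials = rnn.sample_trials(cfg, 8, rng)
        batch = rnn.encode_batch(trials, cfg, rng, input_noise=False)
        assert batch.inputs.shape[1] == len(trials)
        assert len(trials) == 8 * len(cfg.conditions)
        a, b = batch.epochs["sample1"]
        first = np.where(
            trials["cued_order"] == "first",
            trials["orientation"],
            trials["uncued_orientation"],
        ).astype(float)
        prefs = np.arange(cfg.n_tuned_in) * 180.0 / cfg.n_tuned_in
        from flexwm import circ

        for i in range(len(trials)):
            peak_unit = np.argmax(batch.inputs[a, i, : cfg.n_tuned_in])
            assert circ.distance(prefs[peak_unit], first[i]) <= 90 / cfg.n_tuned_in + 1e-9

    def test_rnn2_maintenance_category_target_is_zero(self):
        cfg = tiny_config(output_mode="rnn2")
        rng = np.random.default_rng(1)
        trials = rnn.sample_trials(cfg, 10, rng)
        batch = rnn.encode_batch(trials, cfg, rng)
        m = batch.loss_mask
        maint = (trials["task"] == "maintenance").to_numpy()
        assert np.all(batch.targets[np.ix_(m, maint, [0, 1])] == 0)
        cat = ~maint
        assert np.all(batch.targets[np.ix_(m, cat, [0, 1])].max(axis=2) == 1)

    def test_rnn1_options_span_categories(self):
        cfg = tiny_config(output_mode="rnn1", rule_mode="flexible")
        rng = np.random.default_rng(2)
        trials = rnn.sample_trials(cfg, 30, rng)
        from flexwm import task_design as td

        cat_trials = trials[trials["task"] == "categorization"]
        for _, row in cat_trials.iterrows():
            rule = cfg.rules[row["rule"]]
            c1 = td.assign_category(row["option1"], rule)
            c2 = td.assign_category(row["option2"], rule)
            assert c1 != c2
            correct = (row["option1"], row["option2"])[row["correct_choice"]]
            assert td.assign_category(correct, rule) == row["category"]
        maint = trials[trials["task"] == "maintenance"]
        for _, row in maint.iterrows():
            correct = (row["option1"], row["option2"])[row["correct_choice"]]
            assert correct == row["orientation"]

    def test_off_grid_orientation_rejected(self):
        cfg = tiny_config()
        rng = np.random.default_rng(3)
        trials = rnn.sample_trials(cfg, 4, rng)
        trials.loc[0, "orientation"] = 5.0  # not on the 9-deg grid
        with pytest.raises(ValueError):
            rnn.encode_batch(trials, cfg, rng)

    def test_grace_period_excluded(self):
        cfg = tiny_config(grace_ms=40)
        rng = np.random.default_rng(4)
        batch = rnn.encode_batch(rnn.sample_trials(cfg, 4, rng), cfg, rng)
        a, b = batch.epochs["test"]
        grace_steps = int(40 / (cfg.dt * 1000))
        assert not batch.loss_mask[:a].any()
        assert not batch.loss_mask[a : a + grace_steps].any()
        assert batch.loss_mask[a + grace_steps : b].all()


class TestDynamics:
    def test_determinism_without_noise(self):
        cfg = tiny_config(noise_sd=0.0)
        params = net.init_params(cfg, seed=5)
        rng = np.random.default_rng(5)
        batch = rnn.encode_batch(rnn.sample_trials(cfg, 6, rng), cfg, rng, input_noise=False)
        H1, Y1, _ = rnn.simulate(params, batch.inputs, noise_on=False)
        H2, Y2, _ = rnn.simulate(params, batch.inputs, noise_on=False)
        assert np.array_equal(H1, H2) and np.array_equal(Y1, Y2)

    def test_activity_nonnegative_and_stsp_bounded(self):
        cfg = tiny_config()
        params = net.init_params(cfg, seed=6)
        rng = np.random.default_rng(6)
        batch = rnn.encode_batch(rnn.sample_trials(cfg, 10, rng), cfg, rng)
        H, _, st = rnn.simulate(params, batch.inputs, noise_on=True, seed=1)
        assert np.all(H >= 0)
        assert np.all((st["U"] >= 0) & (st["U"] <= 1))
        assert np.all((st["X"] >= 0) & (st["X"] <= 1))

    def test_zero_input_stays_at_baseline(self):
        cfg = tiny_config(noise_sd=0.0)
        params = net.init_params(cfg, seed=7)
        inputs = np.zeros((50, 3, cfg.n_inputs), dtype=np.float32)
        H, _, _ = rnn.simulate(params, inputs, noise_on=False)
        assert np.all(np.isfinite(H))
        assert H[-1].mean() < 1.0  # no runaway excitation from rest


class TestLoss:
    def test_closed_forms(self):
        T, B, K = 10, 4, 3
        mask = np.zeros(T, bool)
        mask[6:] = True
        y = np.random.default_rng(0).normal(size=(T, B, K))
        assert rnn.loss_mse(y, y.copy(), mask) == 0.0
        off = y.copy()
        off[mask] += 0.5
        assert rnn.loss_mse(off, y, mask) == pytest.approx(0.25)
        grace_only = y.copy()
        grace_only[~mask] += 9.0
        assert rnn.loss_mse(grace_only, y, mask) == 0.0

    def test_spike_penalty_zero_contributes_nothing(self):
        cfg = tiny_config(noise_sd=0.0, spike_penalty=0.0)
        params = net.init_params(cfg, seed=8)
        rng = np.random.default_rng(8)
        batch = rnn.encode_batch(rnn.sample_trials(cfg, 4, rng), cfg, rng, input_noise=False)
        _, y, st = rnn.simulate(params, batch.inputs, noise_on=False, cache=True)
        g0 = net.backward(params, st, y, batch.targets, batch.loss_mask)
        cfg2 = tiny_config(noise_sd=0.0, spike_penalty=0.1)
        params2 = net.init_params(cfg2, seed=8)
        _, y2, st2 = rnn.simulate(params2, batch.inputs, noise_on=False, cache=True)
        g1 = net.backward(params2, st2, y2, batch.targets, batch.loss_mask)
        assert not np.allclose(g0["w_rec"], g1["w_rec"])  # penalty changes grads
        assert rnn.loss_mse(y, batch.targets, batch.loss_mask) == rnn.loss_mse(
            y2, batch.targets, batch.loss_mask
        )


class TestGradients:
    def test_bptt_matches_finite_differences(self):
        cfg = tiny_config(units_per_module=10, batch_per_condition=2, noise_sd=0.0)
        params = net.init_params(cfg, seed=0)
        for k, v in params.trainable().items():
            setattr(params, k, v.astype(np.float64))
        rng = np.random.default_rng(0)
        batch = rnn.encode_batch(rnn.sample_trials(cfg, 2, rng), cfg, rng, input_noise=False)
        inputs = batch.inputs.astype(np.float64)
        targets = batch.targets.astype(np.float64)

        def loss():
            _, y, st = rnn.simulate(params, inputs, noise_on=False, cache=True)
            return rnn.loss_mse(y, targets, batch.loss_mask), y, st

        _, y, st = loss()
        g = net.backward(params, st, y, targets, batch.loss_mask)
        eps = 1e-6
        checked = 0
        for name in ("w_rec", "w_in", "w_out", "b_rec", "b_out"):
            arr = getattr(params, name)
            for _ in range(5):
                ix = tuple(rng.integers(s) for s in arr.shape)
                old = arr[ix]
                if name.startswith("w") and abs(old) < 1e-6:
                    continue  # |.|-kink: subgradient differs from central diff
                arr[ix] = old + eps
                lp, _, _ = loss()
                arr[ix] = old - eps
                lm, _, _ = loss()
                arr[ix] = old
                num = (lp - lm) / (2 * eps)
                if abs(num) + abs(g[name][ix]) > 1e-9:
                    assert g[name][ix] == pytest.approx(num, rel=1e-3, abs=1e-9)
                    checked += 1
        assert checked >= 10

    def test_training_step_preserves_masks_and_dale(self):
        cfg = tiny_config(max_iter=3)
        params, res = train_network(cfg, seed=4)
        _, W_rec, _ = params.effective()
        assert np.all(W_rec[params.conn_mask == 0] == 0)
        exc = params.sign > 0
        assert np.all(W_rec[exc, :] >= 0) and np.all(W_rec[~exc, :] <= 0)
        assert res.n_iter == 3 and res.success is False


class TestEvaluation:
    def test_exact_targets_give_perfect_accuracy(self):
        cfg = tiny_config(output_mode="rnn2")
        rng = np.random.default_rng(9)
        batch = rnn.encode_batch(rnn.sample_trials(cfg, 6, rng), cfg, rng)
        acc = rnn.evaluate_accuracy(batch.targets, batch, cfg)
        assert all(v == 1.0 for v in acc.values())

    def test_tied_choice_counts_incorrect(self):
        cfg = tiny_config(output_mode="rnn1")
        rng = np.random.default_rng(10)
        batch = rnn.encode_batch(rnn.sample_trials(cfg, 5, rng), cfg, rng)
        outputs = np.zeros_like(batch.targets)  # all ties
        acc = rnn.evaluate_accuracy(outputs, batch, cfg)
        assert all(v == 0.0 for v in acc.values())

    def test_random_outputs_near_chance_choice(self):
        cfg = tiny_config(output_mode="rnn1")
        rng = np.random.default_rng(11)
        batch = rnn.encode_batch(rnn.sample_trials(cfg, 200, rng), cfg, rng)
        outputs = rng.normal(size=batch.targets.shape).astype(np.float32)
        acc = rnn.evaluate_accuracy(outputs, batch, cfg)
        for v in acc.values():
            assert 0.35 <= v <= 0.65

    def test_population_vector_roundtrip(self):
        from flexwm.rnn.task import input_tuning

        grid = np.arange(20) * 9.0
        rates = input_tuning(grid, 15, 9.0)
        est = population_vector(rates)
        from flexwm import circ

        assert np.all(circ.distance(est, grid) < 1.0)


class TestAnalysis:
    def test_rdm_properties_and_duplicate_conditions(self):
        cfg = tiny_config(noise_sd=0.0)
        params = net.init_params(cfg, seed=12)
        rng = np.random.default_rng(12)
        trials = rnn.sample_trials(cfg, 40, rng)
        batch = rnn.encode_batch(trials, cfg, rng, input_noise=True)
        H, _, _ = rnn.simulate(params, batch.inputs, noise_on=False, seed=0)
        rdms = rnn.rnn_rdm(H, trials, module=0, config=cfg)
        for rdm in rdms.values():
            assert np.allclose(rdm.matrix, rdm.matrix.T)
            assert np.allclose(np.diag(rdm.matrix), 0)

    def test_decode_units_shuffled_labels_chance(self):
        cfg = tiny_config(noise_sd=0.0)
        params = net.init_params(cfg, seed=13)
        rng = np.random.default_rng(13)
        trials = rnn.sample_trials(cfg, 60, rng)
        batch = rnn.encode_batch(trials, cfg, rng)
        H, _, _ = rnn.simulate(params, batch.inputs, noise_on=False, seed=0)
        a, b = batch.epochs["sample2"]
        labels = rng.permutation(np.where(trials["orientation"] < 90, 0, 1))
        accs = [
            rnn.decode_units(H, labels, 0, range(a, b), cfg, seed=s) for s in range(4)
        ]
        assert abs(np.mean(accs) - 0.5) < 0.12

    def test_module_bounds_checked(self):
        cfg = tiny_config()
        with pytest.raises(IndexError):
            rnn.decode_units(np.zeros((5, 4, cfg.n_units)), np.zeros(4), 3, 0, cfg)
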