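"""Training loop (Adam on the masked-MSE objective) and batch accuracy.

Training minimizes the test-period mean squared error in block-
interleaved batches (equal trials per task condition, condition block
order randomized per iteration) and stops as soon as the last training
batch reaches the accuracy criterion (90%) on all tasks, or at the
iteration cap, in which case the run is reported as failed rather than
raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import circ
from .config import GRID_STEP, NetworkConfig
from .network import NetworkParams, backward, init_params, loss_mse, simulate
from .task import TaskBatch, encode_batch, sample_trials


@dataclass
class TrainingResult:
    success: bool
    n_iter: int
    accuracies: dict
    loss_history: list = field(repr=False, default_factory=list)
    seed: int = 0


def population_vector(rates: np.ndarray, n_units: int | None = None) -> np.ndarray:
    """Decode orientations (deg) from tuned-unit rates by vector averaging
    on the doubled-angle circle.  ``rates``: (n_trials, n_units)."""
    n = rates.shape[1] if n_units is None else n_units
    prefs = np.arange(n) * 180.0 / n
    ang = 2 * np.deg2rad(prefs)
    s = rates @ np.sin(ang)
    c = rates @ np.cos(ang)
    return np.rad2deg(np.arctan2(s, c)) / 2.0 % 180.0


def evaluate_accuracy(outputs: np.ndarray, batch: TaskBatch, config: NetworkConfig) -> dict:
    """Per-condition (and, for RNN2, per-output) batch accuracies.

    Choice/category accuracy takes the larger of the two units' means
    over the masked test period (exact ties count as incorrect); RNN2
    stimulus accuracy requires the population-vector estimate from the
    15 tuned output units to fall within one grid step (9 deg) of the
    cued orientation.
    """
    m = batch.loss_mask
    mean_out = outputs[m].mean(axis=0)  # (B, n_out)
    trials = batch.trials
    acc = {}
    if config.output_mode == "rnn1":
        pred = np.where(mean_out[:, 0] > mean_out[:, 1], 0,
                        np.where(mean_out[:, 1] > mean_out[:, 0], 1, -1))
        correct = pred == trials["correct_choice"].to_numpy()
        for cond in config.conditions:
            sel = _condition_mask(trials, cond)
            acc[f"{cond}/choice"] = float(correct[sel].mean())
    else:
        est = population_vector(mean_out[:, 2:], config.n_tuned_in)
        stim_ok = circ.distance(est, trials["orientation"].to_numpy()) <= GRID_STEP + 1e-6
        cat_pred = np.where(mean_out[:, 0] > mean_out[:, 1], 1,
                            np.where(mean_out[:, 1] > mean_out[:, 0], 2, -1))
        for cond in config.conditions:
            sel = _condition_mask(trials, cond)
            acc[f"{cond}/stimulus"] = float(stim_ok[sel].mean())
            if cond != "maintenance":
                cat_ok = cat_pred[sel] == trials.loc[sel, "category"].to_numpy()
                acc[f"{cond}/category"] = float(cat_ok.mean())
    return acc


def _condition_mask(trials, cond: str) -> np.ndarray:
    if cond == "maintenance":
        return (trials["task"] == "maintenance").to_numpy()
    rule = cond.split("-")[1]
    return ((trials["task"] == "categorization") & (trials["rule"] == rule)).to_numpy()


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            p -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(p.dtype)


def _clip_grads(grads: dict, max_norm: float):
    total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


def train(
    config: NetworkConfig,
    seed: int | None = None,
    callback=None,
) -> tuple[NetworkParams, TrainingResult]:
    """Train a network to the all-task accuracy criterion.

    Deterministic given ``seed``.  Non-convergence at ``max_iter`` is
    reported via ``TrainingResult.success = False``.
    """
    seed = config.seed if seed is None else seed
    params = init_params(config, seed)
    opt = _Adam(params.trainable(), config.learning_rate)
    master = np.random.default_rng(seed)
    losses = []
    acc = {}
    for it in range(1, config.max_iter + 1):
        it_rng = np.random.default_rng(int(master.integers(2**31 - 1)))
        trials = sample_trials(config, config.batch_per_condition, it_rng)
        batch = encode_batch(trials, config, it_rng)
        _, outputs, states = simulate(
            params, batch.inputs, noise_on=True,
            seed=int(it_rng.integers(2**31 - 1)), cache=True,
        )
        loss = loss_mse(outputs, batch.targets, batch.loss_mask)
        losses.append(loss)
        acc = evaluate_accuracy(outputs, batch, config)
        if callback is not None:
            callback(it, loss, acc)
        if all(a >= config.accuracy_criterion for a in acc.values()):
            return params, TrainingResult(True, it, acc, losses, seed)
        grads = backward(params, states, outputs, batch.targets, batch.loss_mask)
        _clip_grads(grads, config.grad_clip)
        opt.step(params.trainable(), grads)
    return params, TrainingResult(False, config.max_iter, acc, losses, seed)
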