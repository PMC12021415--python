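"""Trial sampling and input/target encoding for the network tasks.

Stimuli come from a 20-orientation grid spanning [0, 180) degrees and
are presented as Gaussian bumps over 15 orientation-tuned input units
(a ring receptive field); both samples pass through the same receptive
field sequentially.  Retro-cue (which sample to keep) and task cue
(maintain / categorize under rule X) arrive through 5 dedicated cue
units.  Choice networks (RNN1) additionally see two sequential probe
options before the test window: in maintenance one option is the cued
sample and the other a random different orientation; in categorization
one option comes from the cued sample's category (not necessarily the
same angle) and the other from the opposite category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .. import circ, task_design
from .config import GRID_STEP, N_GRID, NetworkConfig, epoch_steps

GRID = np.arange(N_GRID) * GRID_STEP  # 0, 9, ..., 171 degrees


def input_tuning(thetas, n_units: int, sigma: float) -> np.ndarray:
    """Gaussian ring bumps: (n_thetas, n_units), peak 1 at the preferred."""
    prefs = np.arange(n_units) * 180.0 / n_units
    d = circ.distance(np.asarray(thetas, float)[:, None], prefs[None, :])
    return np.exp(-0.5 * (d / sigma) ** 2)


@dataclass
class TaskBatch:
    """Encoded batch: inputs/targets (time x trial x unit) plus metadata."""

    inputs: np.ndarray
    targets: np.ndarray
    loss_mask: np.ndarray  # (time,) bool: test period minus grace
    trials: pd.DataFrame
    epochs: dict = field(default_factory=dict)


def sample_trials(
    config: NetworkConfig,
    n_per_condition: int | None = None,
    rng: np.random.Generator | None = None,
    orientations: np.ndarray | None = None,
) -> pd.DataFrame:
    """Random trial specifications, ``n_per_condition`` per task condition."""
    rng = rng or np.random.default_rng(config.seed)
    if n_per_condition is None:
        n_per_condition = config.batch_per_condition
    grid = GRID if orientations is None else np.asarray(orientations, float)
    rows = []
    conditions = list(config.conditions)
    # task block order randomized, trials blocked by condition
    for cond in [conditions[i] for i in rng.permutation(len(conditions))]:
        task = "maintenance" if cond == "maintenance" else "categorization"
        rule_name = cond.split("-")[1] if task == "categorization" else "n/a"
        for _ in range(n_per_condition):
            cued = grid[rng.integers(len(grid))]
            others = grid[grid != cued]
            uncued = others[rng.integers(len(others))]
            cued_order = "first" if rng.random() < 0.5 else "second"
            row = {
                "task": task,
                "rule": rule_name,
                "orientation": cued,
                "uncued_orientation": uncued,
                "cued_order": cued_order,
                "category": 0,
                "option1": np.nan,
                "option2": np.nan,
                "correct_choice": -1,
            }
            if task == "categorization":
                rule = config.rules[rule_name]
                cat = task_design.assign_category(cued, rule)
                row["category"] = cat
                if config.output_mode == "rnn1":
                    labels = task_design.category_labels(grid, rule)
                    same = grid[labels == cat]
                    other = grid[labels != cat]
                    correct = same[rng.integers(len(same))]
                    wrong = other[rng.integers(len(other))]
            if config.output_mode == "rnn1":
                if task == "maintenance":
                    correct, wrong = cued, others[rng.integers(len(others))]
                if rng.random() < 0.5:
                    row["option1"], row["option2"], row["correct_choice"] = correct, wrong, 0
                else:
                    row["option1"], row["option2"], row["correct_choice"] = wrong, correct, 1
            rows.append(row)
    return pd.DataFrame(rows)


def encode_batch(
    trials: pd.DataFrame,
    config: NetworkConfig,
    rng: np.random.Generator | None = None,
    input_noise: bool = True,
) -> TaskBatch:
    """Encode trial specs into input and target tensors."""
    grid_ok = np.isin(circ.wrap(trials["orientation"]), circ.wrap(GRID))
    if not grid_ok.all():
        bad = trials.loc[~grid_ok, "orientation"].unique()
        raise ValueError(f"orientations off the {N_GRID}-value grid: {bad}")
    rng = rng or np.random.default_rng(config.seed)
    ep = epoch_steps(config)
    T, B = ep["_total"], len(trials)
    n_in, n_out = config.n_inputs, config.n_outputs
    inputs = np.zeros((T, B, n_in), dtype=np.float32)
    targets = np.zeros((T, B, n_out), dtype=np.float32)

    cued = trials["orientation"].to_numpy(float)
    uncued = trials["uncued_orientation"].to_numpy(float)
    first = np.where(trials["cued_order"] == "first", cued, uncued)
    second = np.where(trials["cued_order"] == "first", uncued, cued)

    def put_bump(epoch, thetas):
        a, b = ep[epoch]
        inputs[a:b, :, : config.n_tuned_in] = input_tuning(
            thetas, config.n_tuned_in, config.input_sigma
        )[None, :, :]

    put_bump("sample1", first)
    put_bump("sample2", second)

    a, b = ep["retro_cue"]
    retro_idx = config.n_tuned_in + (trials["cued_order"] == "second").to_numpy().astype(int)
    inputs[a:b, np.arange(B), retro_idx] = 1.0

    a, b = ep["task_cue"]
    cue_base = config.n_tuned_in + config.n_retro_cue
    rule_slot = {"n/a": 0, "A": 1, "B": 2}
    task_idx = cue_base + trials["rule"].map(rule_slot).to_numpy()
    inputs[a:b, np.arange(B), task_idx] = 1.0

    if config.output_mode == "rnn1":
        put_bump("option1", trials["option1"].to_numpy(float))
        put_bump("option2", trials["option2"].to_numpy(float))

    ta, tb = ep["test"]
    if config.output_mode == "rnn1":
        targets[ta:tb, np.arange(B), trials["correct_choice"].to_numpy()] = 1.0
    else:
        is_cat = (trials["task"] == "categorization").to_numpy()
        cat_unit = np.where(trials["category"].to_numpy() == 1, 0, 1)
        rows = np.where(is_cat)[0]
        targets[ta:tb, rows, cat_unit[rows]] = 1.0
        targets[ta:tb, :, 2:] = input_tuning(
            cued, config.n_tuned_in, config.input_sigma
        )[None, :, :]

    if input_noise and config.input_noise_sd > 0:
        inputs += rng.normal(0.0, config.input_noise_sd, size=inputs.shape).astype(np.float32)

    grace = int(round(config.grace_ms / (config.dt * 1000.0)))
    loss_mask = np.zeros(T, dtype=bool)
    loss_mask[ta + grace : tb] = True
    return TaskBatch(inputs=inputs, targets=targets, loss_mask=loss_mask,
                     trials=trials.reset_index(drop=True), epochs=ep)
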