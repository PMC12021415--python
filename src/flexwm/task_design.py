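"""Trial-list and timeline generation for the flexible working-memory task.

Two delayed-estimation/categorization designs are supported:

* Experiment 1 ("flexible rule"): maintenance trials interleaved with
  categorization trials whose rule (A or B, with orthogonal boundary
  pairs) switches block by block.
* Experiment 2 ("fixed rule"): a single categorization rule throughout,
  with twice as many categorization as maintenance trials.

Orientations live on the 180-degree circle.  The standard sample sets are
30 orientations in 6-degree steps starting at 5 deg (Experiment 1) or
4 deg (Experiment 2 and two Experiment-1 participants); rule boundaries
are chosen so that no sample orientation ever falls on a boundary and
each rule splits the sample set 15/15.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import circ


class DesignError(ValueError):
    """Raised when a requested design cannot be counterbalanced."""


class InvalidOrientationSetError(ValueError):
    """Raised when a requested orientation grid collapses under mod-180."""


class BoundaryAmbiguityError(ValueError):
    """Raised when an orientation lies exactly on a categorization boundary."""


class TimingError(ValueError):
    """Raised for event timings outside the task schedule."""


# Fixed event schedule (seconds): two samples, retro-cue, task cue,
# 8-s memory delay, response window.  ITI varies in {3, 5, 7} s.
EVENT_SCHEDULE = (
    ("sample1", 0.75),
    ("isi", 0.5),
    ("sample2", 0.75),
    ("interval", 0.5),
    ("retro_cue", 0.5),
    ("delay1", 1.5),
    ("task_cue", 0.5),
    ("delay2", 8.0),
    ("response", 2.0),
)
ITI_CHOICES = (3.0, 5.0, 7.0)
TRIALS_PER_BLOCK = 9
CATEGORIZATION_PER_BLOCK = 6
MAINTENANCE_PER_BLOCK = 3
BLOCKS_PER_RUN = 2


@dataclass(frozen=True)
class OrientationSet:
    """An arithmetic grid of sample orientations on the 180-deg circle."""

    start: float
    step: float
    count: int
    values: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.count


@dataclass(frozen=True)
class CategorizationRule:
    """A pair of orthogonal category boundaries on the orientation circle.

    Category 1 is the counter-clockwise arc from ``boundary1`` to
    ``boundary2``; category 2 is the complementary arc.
    """

    name: str
    boundary1: float
    boundary2: float

    def __post_init__(self) -> None:
        if not np.isclose(circ.distance(self.boundary1, self.boundary2), 90.0):
            raise ValueError(
                f"rule {self.name!r}: boundaries must be orthogonal (90 deg apart), "
                f"got {self.boundary1} / {self.boundary2}"
            )


RULE_A = CategorizationRule("A", 20.0, 110.0)
RULE_B = CategorizationRule("B", 65.0, 155.0)
#: Fixed-rule variants used in the single-rule design (half the cohort each).
RULE_FIXED_1 = CategorizationRule("fixed", 19.0, 109.0)
RULE_FIXED_2 = CategorizationRule("fixed", 67.0, 157.0)


def sample_orientations(start: float, step: float, count: int) -> OrientationSet:
    """Build an arithmetic orientation grid, e.g. ``(5, 6, 30)`` -> 5..179.

    Raises
    ------
    InvalidOrientationSetError
        If any two grid values coincide after mod-180 reduction.
    """
    if step <= 0:
        raise InvalidOrientationSetError("step must be positive")
    if start < 0:
        raise InvalidOrientationSetError("start must be >= 0")
    values = circ.wrap(start + step * np.arange(count, dtype=float))
    if len(np.unique(values)) != count:
        raise InvalidOrientationSetError(
            f"grid (start={start}, step={step}, count={count}) has duplicate "
            "orientations after mod-180 reduction"
        )
    return OrientationSet(start=start, step=step, count=count, values=values)


def assign_category(theta: float, rule: CategorizationRule) -> int:
    """Category label (1 or 2) of an orientation under a boundary rule.

    Label 1 covers the counter-clockwise arc (boundary1, boundary2).
    """
    t = circ.wrap(theta)
    d1 = circ.wrap(t - rule.boundary1)
    if d1 == 0.0 or circ.wrap(t - rule.boundary2) == 0.0:
        raise BoundaryAmbiguityError(
            f"orientation {theta} deg lies on a boundary of rule {rule.name!r}"
        )
    return 1 if d1 < 90.0 else 2


def category_labels(thetas: np.ndarray, rule: CategorizationRule) -> np.ndarray:
    """Vectorized :func:`assign_category` over an orientation array."""
    return np.array([assign_category(t, rule) for t in np.asarray(thetas).ravel()])


def distance_to_boundary(theta: float, rule: CategorizationRule) -> float:
    """Minimum circular distance from ``theta`` to either boundary, in [0, 45]."""
    return float(
        min(circ.distance(theta, rule.boundary1), circ.distance(theta, rule.boundary2))
    )


def trial_timeline(trial_row=None, iti: float = 5.0) -> pd.DataFrame:
    """Event timeline (name, onset, duration) for one trial.

    The fixed events sum to 15 s; with the equiprobable {3, 5, 7} s ITI the
    expected trial length is 20 s.
    """
    if iti not in ITI_CHOICES:
        raise TimingError(f"iti must be one of {ITI_CHOICES}, got {iti}")
    events = list(EVENT_SCHEDULE) + [("iti", float(iti))]
    onsets = np.concatenate([[0.0], np.cumsum([d for _, d in events])[:-1]])
    return pd.DataFrame(
        {
            "name": [n for n, _ in events],
            "onset": onsets,
            "duration": [d for _, d in events],
        }
    )


def _balanced_draw(rng: np.random.Generator, choices, n: int) -> np.ndarray:
    """n values with each choice appearing exactly n/len(choices) times, shuffled."""
    k = len(choices)
    if n % k:
        raise DesignError(f"cannot balance {n} trials over {k} levels")
    arr = np.repeat(np.asarray(choices), n // k)
    rng.shuffle(arr)
    return arr


def _condition_pool(
    rng: np.random.Generator,
    orientations: np.ndarray,
    n_trials: int,
    task: str,
    rule_name: str,
) -> pd.DataFrame:
    """Counterbalanced trial pool for one condition (task x rule)."""
    n_ori = len(orientations)
    if n_trials % n_ori:
        raise DesignError(
            f"{n_trials} trials not divisible by {n_ori} orientations"
        )
    ori = np.repeat(orientations, n_trials // n_ori)
    rng.shuffle(ori)
    # Uncued sample: uniform over the grid excluding the cued orientation.
    uncued = np.empty(n_trials)
    for i, o in enumerate(ori):
        others = orientations[orientations != o]
        uncued[i] = others[rng.integers(len(others))]
    pool = pd.DataFrame(
        {
            "orientation": ori,
            "uncued_orientation": uncued,
            "task": task,
            "rule": rule_name,
            "cued_order": _balanced_draw(rng, ["first", "second"], n_trials),
            "iti": _balanced_draw(rng, ITI_CHOICES, n_trials),
        }
    )
    return pool


def generate_design(
    experiment: int,
    orientation_set: OrientationSet | None = None,
    seed: int = 0,
    trials_per_condition: int = 90,
    fixed_rule: CategorizationRule = RULE_FIXED_1,
) -> pd.DataFrame:
    """Generate a counterbalanced trial table.

    Experiment 1 yields equal trial counts for maintenance,
    categorization-A and categorization-B (default 90 each); Experiment 2
    yields maintenance : categorization = 1 : 2 under a single fixed rule.
    Blocks hold 6 categorization + 3 maintenance trials; runs hold 2 blocks.
    Deterministic given ``seed``.
    """
    if experiment not in (1, 2):
        raise DesignError(f"experiment must be 1 or 2, got {experiment}")
    if orientation_set is None:
        # The 4-178 deg grid is the default for both experiments: it is the
        # only 6-deg grid of the two standard variants on which neither
        # rule boundary coincides with a sample orientation (65 deg sits on
        # the 5-179 grid), so both rules split it cleanly 15/15.
        orientation_set = sample_orientations(4, 6, 30)
    rng = np.random.default_rng(seed)
    n = trials_per_condition
    if n % MAINTENANCE_PER_BLOCK:
        raise DesignError("trials_per_condition must be divisible by 3")

    if experiment == 1:
        pools = {
            "maintenance": _condition_pool(rng, orientation_set.values, n, "maintenance", "n/a"),
            "A": _condition_pool(rng, orientation_set.values, n, "categorization", "A"),
            "B": _condition_pool(rng, orientation_set.values, n, "categorization", "B"),
        }
        n_blocks = 3 * n // TRIALS_PER_BLOCK
        # Equal numbers of rule-A and rule-B blocks, in seeded random order.
        block_rules = _balanced_draw(rng, ["A", "B"], n_blocks)
    else:
        pools = {
            "maintenance": _condition_pool(rng, orientation_set.values, n, "maintenance", "n/a"),
            "fixed": _condition_pool(
                rng, orientation_set.values, 2 * n, "categorization", "fixed"
            ),
        }
        n_blocks = 3 * n // TRIALS_PER_BLOCK
        block_rules = np.repeat("fixed", n_blocks)

    cursors = {k: 0 for k in pools}
    rows = []
    for b, rule_name in enumerate(block_rules):
        cat = pools[rule_name].iloc[
            cursors[rule_name] : cursors[rule_name] + CATEGORIZATION_PER_BLOCK
        ]
        cursors[rule_name] += CATEGORIZATION_PER_BLOCK
        mnt = pools["maintenance"].iloc[
            cursors["maintenance"] : cursors["maintenance"] + MAINTENANCE_PER_BLOCK
        ]
        cursors["maintenance"] += MAINTENANCE_PER_BLOCK
        block = pd.concat([cat, mnt], ignore_index=True)
        block = block.iloc[rng.permutation(len(block))].reset_index(drop=True)
        block["block_id"] = b
        block["run_id"] = b // BLOCKS_PER_RUN
        rows.append(block)

    table = pd.concat(rows, ignore_index=True)
    table.insert(0, "trial_id", np.arange(len(table)))

    rules = {"A": RULE_A, "B": RULE_B, "fixed": fixed_rule}
    label = np.full(len(table), "n/a", dtype=object)
    for rn, rule in rules.items():
        mask = table["rule"] == rn
        if mask.any():
            label[mask.to_numpy()] = [
                str(assign_category(t, rule)) for t in table.loc[mask, "orientation"]
            ]
    table["category_label"] = label
    table.attrs["orientation_set"] = orientation_set
    table.attrs["rules"] = rules
    table.attrs["seed"] = seed
    table.attrs["experiment"] = experiment
    return table
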