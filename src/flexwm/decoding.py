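"""Linear SVM decoding of orientation bins and of category.

Orientation decoding groups the 30 sample orientations into four
45-degree bins (cardinal: centered 90 and 180 deg; oblique: 45 and
135 deg), runs one two-way linear SVM per pairing under leave-one-run-out
cross-validation with balanced training sets, and averages the two
accuracies.  Category decoding is two-way with leave-one-trial-out
cross-validation, either with the true rule's labels or with the
orthogonal ("opposite") rule's labels; the abstract category index is
the difference of the two accuracies and isolates stimulus-independent
category information (chance 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from . import circ, task_design
from .synthetic_bold import BoldDataset

BIN_CENTERS = (45.0, 90.0, 135.0, 180.0)
CARDINAL = (90.0, 180.0)
OBLIQUE = (45.0, 135.0)
DEFAULT_C = 1.0


class DecodingError(ValueError):
    """Raised when a decoding problem is degenerate (empty class, tie bin)."""


def _make_svm():
    return SVC(kernel="linear", C=DEFAULT_C)


def bin_orientation(theta: float) -> float:
    """Nearest 45-deg bin center on the 180-deg circle (the 180 bin wraps)."""
    d = circ.distance(theta, np.asarray(BIN_CENTERS))
    best = np.min(d)
    if np.sum(np.isclose(d, best)) > 1:
        raise DecodingError(f"orientation {theta} deg is equidistant from two bin centers")
    return BIN_CENTERS[int(np.argmin(d))]


def bin_labels(thetas) -> np.ndarray:
    return np.array([bin_orientation(t) for t in np.asarray(thetas).ravel()])


def _balanced_indices(rng, labels, classes):
    """Subsample the larger class to the smaller one; returns indices."""
    idx = [np.where(labels == c)[0] for c in classes]
    n = min(len(i) for i in idx)
    if n == 0:
        raise DecodingError("empty class in training fold")
    keep = [rng.choice(i, size=n, replace=False) for i in idx]
    return np.concatenate(keep)


def _pair_accuracy_loro(X, y, runs, pair, rng):
    """Leave-one-run-out two-way SVM accuracy for one bin pairing."""
    sel = np.isin(y, pair)
    Xs, ys, rs = X[sel], y[sel], runs[sel]
    correct, total = 0, 0
    for run in np.unique(rs):
        test = rs == run
        train = ~test
        tr = np.where(train)[0]
        tr = tr[np.isin(ys[tr], pair)]
        keep = _balanced_indices(rng, ys[tr], pair)
        clf = _make_svm().fit(Xs[tr[keep]], ys[tr[keep]])
        pred = clf.predict(Xs[test])
        correct += int(np.sum(pred == ys[test]))
        total += int(test.sum())
    if total == 0:
        raise DecodingError("no test trials")
    return correct / total


def decode_bins(
    dataset: BoldDataset,
    condition: str,
    time_point: int,
    seed: int = 0,
) -> float:
    """Orientation-bin decoding accuracy for one condition at one TR.

    Mean of the cardinal and oblique two-way classifier accuracies; for
    the categorization condition, accuracies are computed per rule and
    averaged.
    """
    rng = np.random.default_rng(seed)
    trials = dataset.trials
    if trials["run_id"].nunique() < 2:
        raise DecodingError("need >= 2 runs")
    X_all = dataset.signal[:, :, time_point].T
    bins = bin_labels(trials["orientation"].to_numpy())

    if condition == "categorization":
        groups = [
            (trials["task"] == "categorization") & (trials["rule"] == r)
            for r in trials.loc[trials["task"] == "categorization", "rule"].unique()
        ]
    else:
        groups = [trials["task"] == condition]

    accs = []
    for g in groups:
        m = g.to_numpy()
        X, y, runs = X_all[m], bins[m], trials["run_id"].to_numpy()[m]
        acc_c = _pair_accuracy_loro(X, y, runs, CARDINAL, rng)
        acc_o = _pair_accuracy_loro(X, y, runs, OBLIQUE, rng)
        accs.append(0.5 * (acc_c + acc_o))
    return float(np.mean(accs))


def orthogonal_rule(rule: task_design.CategorizationRule) -> task_design.CategorizationRule:
    """The control rule used for opposite-rule decoding.

    Rule A and Rule B are each other's controls.  For a fixed rule, the
    other fixed-rule variant is used; otherwise the boundaries are
    rotated 45 deg.
    """
    if rule.name == "A":
        return task_design.RULE_B
    if rule.name == "B":
        return task_design.RULE_A
    if np.isclose(circ.wrap(rule.boundary1), circ.wrap(task_design.RULE_FIXED_1.boundary1)):
        return task_design.RULE_FIXED_2
    if np.isclose(circ.wrap(rule.boundary1), circ.wrap(task_design.RULE_FIXED_2.boundary1)):
        return task_design.RULE_FIXED_1
    return task_design.CategorizationRule(
        rule.name, circ.wrap(rule.boundary1 + 45.0), circ.wrap(rule.boundary2 + 45.0)
    )


def _loto_accuracy(X, y):
    """Leave-one-trial-out two-way SVM accuracy."""
    classes = np.unique(y)
    if len(classes) != 2 or min(np.bincount(np.searchsorted(classes, y))) < 2:
        raise DecodingError("need >= 2 trials in each of two categories")
    n = len(y)
    correct = 0
    for i in range(n):
        train = np.ones(n, bool)
        train[i] = False
        clf = _make_svm().fit(X[train], y[train])
        correct += int(clf.predict(X[i : i + 1])[0] == y[i])
    return correct / n


def decode_category(
    dataset: BoldDataset,
    rule_labels: str = "true",
    time_point: int = 12,
    seed: int = 0,
) -> float:
    """Category decoding accuracy on categorization trials at one TR.

    ``rule_labels`` "true" uses each trial's own rule; "opposite" labels
    the same trials with the orthogonal rule.  Flexible-rule designs are
    decoded per rule (90 trials each) and averaged; fixed-rule designs
    split the categorization trials into random halves of equal size and
    average (leave-one-trial-out cross-validation throughout).
    """
    if rule_labels not in ("true", "opposite"):
        raise ValueError("rule_labels must be 'true' or 'opposite'")
    rng = np.random.default_rng(seed)
    trials = dataset.trials
    rules = trials.attrs.get("rules", {"A": task_design.RULE_A, "B": task_design.RULE_B})
    X_all = dataset.signal[:, :, time_point].T
    cat = (trials["task"] == "categorization").to_numpy()

    accs = []
    rule_names = trials.loc[cat, "rule"].unique()
    for rn in rule_names:
        m = cat & (trials["rule"] == rn).to_numpy()
        rule = rules[rn]
        lab_rule = rule if rule_labels == "true" else orthogonal_rule(rule)
        ori = trials.loc[m, "orientation"].to_numpy()
        y = task_design.category_labels(ori, lab_rule)
        X = X_all[m]
        if len(rule_names) == 1:
            # fixed rule: random halves of equal size, decoded separately
            perm = rng.permutation(len(y))
            half = len(y) // 2
            for part in (perm[:half], perm[half : 2 * half]):
                accs.append(_loto_accuracy(X[part], y[part]))
        else:
            accs.append(_loto_accuracy(X, y))
    return float(np.mean(accs))


def abstract_category_index(acc_true, acc_opposite):
    """True-rule minus opposite-rule category decoding accuracy (chance 0)."""
    a, b = np.asarray(acc_true, float), np.asarray(acc_opposite, float)
    if a.shape != b.shape:
        raise ValueError("accuracy arrays must have matching shapes")
    return a - b


def decode_category_timecourse(
    dataset: BoldDataset, time_points, seed: int = 0
) -> pd.DataFrame:
    """Abstract-category-index table over time points."""
    rows = []
    for tp in time_points:
        at = decode_category(dataset, "true", tp, seed)
        ao = decode_category(dataset, "opposite", tp, seed)
        rows.append(
            {
                "subject": dataset.subject_id,
                "time_point": tp,
                "acc_true": at,
                "acc_opposite": ao,
                "abstract_index": at - ao,
            }
        )
    return pd.DataFrame(rows)
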