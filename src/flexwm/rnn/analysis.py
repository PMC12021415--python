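"""Population decoding and RDM construction on frozen-network activity.

Activity is obtained by feeding fresh task batches through a trained
network with recurrent noise off (input noise stays on, so nominally
identical trials still vary).  Decoders are linear SVMs with five-fold
cross-validation, run separately per module and time point; stimulus
decoding uses the same cardinal/oblique 45-degree binning as the fMRI
analyses, and the abstract category index is again the true-rule minus
opposite-rule decoding accuracy.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .. import task_design
from ..decoding import CARDINAL, OBLIQUE, DEFAULT_C, bin_labels, orthogonal_rule
from ..rsa import RDM, pairwise_condition_rdm
from .config import NetworkConfig, epoch_steps


def _module_units(config: NetworkConfig, module: int) -> slice:
    if not 0 <= module < config.n_modules:
        raise IndexError(f"module must be in [0, {config.n_modules})")
    U = config.units_per_module
    return slice(module * U, (module + 1) * U)


def critical_window(config: NetworkConfig, ms: int = 250) -> np.ndarray:
    """Step indices of the decoding summary window: the final ``ms`` of
    the main (post-task-cue) delay."""
    a, b = epoch_steps(config)["delay2"]
    k = int(round(ms / (config.dt * 1000.0)))
    return np.arange(b - k, b)


def delay_window(config: NetworkConfig) -> np.ndarray:
    """Step indices of the whole post-task-cue delay."""
    a, b = epoch_steps(config)["delay2"]
    return np.arange(a, b)


def decode_units(
    activity: np.ndarray,
    labels: np.ndarray,
    module: int,
    time_point,
    config: NetworkConfig,
    seed: int = 0,
    n_folds: int = 5,
    n_sample_units: int | None = None,
    feature_noise_sd: float = 0.0,
    n_draws: int = 1,
) -> float:
    """Two-way linear SVM accuracy on one module's activity.

    ``activity``: (time, trials, units); ``time_point`` may be an int or
    an iterable of steps (features averaged over them).  Five
    stratified folds (80/20 train/test).

    With ``n_sample_units`` and/or ``feature_noise_sd`` the decoder sees
    a measurement-limited view of the module — a random unit subsample
    plus additive Gaussian noise scaled by the pooled feature sd,
    averaged over ``n_draws`` seeded draws.  Noise-free readouts of
    small trained networks saturate at 1.0 in every condition, where
    differences between conditions are unmeasurable; the limited
    readout emulates the subsampled, noisy view imaging gives of a
    region and keeps accuracy in its sensitive range.
    """
    sl = _module_units(config, module)
    tp = np.atleast_1d(time_point)
    X_full = activity[tp][:, :, sl].mean(axis=0)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    rng = np.random.default_rng(seed)
    accs = []
    for draw in range(n_draws):
        X = X_full
        if n_sample_units is not None and n_sample_units < X.shape[1]:
            keep = rng.choice(X.shape[1], size=n_sample_units, replace=False)
            X = X[:, keep]
        if feature_noise_sd > 0:
            X = X + rng.normal(0.0, feature_noise_sd * X_full.std(), size=X.shape)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + draw)
        correct = total = 0
        for tr, te in skf.split(X, y):
            clf = SVC(kernel="linear", C=DEFAULT_C).fit(X[tr], y[tr])
            correct += int(np.sum(clf.predict(X[te]) == y[te]))
            total += len(te)
        accs.append(correct / total)
    return float(np.mean(accs))


def stimulus_decoding(
    activity: np.ndarray,
    orientations: np.ndarray,
    module: int,
    time_point,
    config: NetworkConfig,
    seed: int = 0,
    **probe_kwargs,
) -> float:
    """Orientation-bin decoding: mean of the cardinal and oblique
    two-way accuracies (45-degree bins, as in the fMRI analyses)."""
    bins = bin_labels(orientations)
    accs = []
    for pair in (CARDINAL, OBLIQUE):
        sel = np.isin(bins, pair)
        accs.append(
            decode_units(activity[:, sel], bins[sel], module, time_point, config,
                         seed, **probe_kwargs)
        )
    return float(np.mean(accs))


def category_decoding(
    activity: np.ndarray,
    trials,
    module: int,
    time_point,
    config: NetworkConfig,
    seed: int = 0,
    rule_labels: str = "true",
    **probe_kwargs,
) -> float:
    """Two-way category decoding on categorization trials, per rule then
    averaged; "opposite" labels the trials with the orthogonal rule."""
    accs = []
    for rn, rule in config.rules.items():
        sel = ((trials["task"] == "categorization") & (trials["rule"] == rn)).to_numpy()
        lab_rule = rule if rule_labels == "true" else orthogonal_rule(rule)
        y = task_design.category_labels(trials.loc[sel, "orientation"].to_numpy(), lab_rule)
        accs.append(decode_units(activity[:, sel], y, module, time_point, config,
                                 seed, **probe_kwargs))
    return float(np.mean(accs))


def abstract_category_index_units(
    activity: np.ndarray, trials, module: int, time_point, config: NetworkConfig,
    seed: int = 0, **probe_kwargs,
) -> float:
    """True-rule minus opposite-rule category decoding accuracy."""
    t = category_decoding(activity, trials, module, time_point, config, seed, "true",
                          **probe_kwargs)
    o = category_decoding(activity, trials, module, time_point, config, seed, "opposite",
                          **probe_kwargs)
    return t - o


def rnn_rdm(
    activity: np.ndarray,
    trials,
    module: int,
    config: NetworkConfig,
    window: np.ndarray | None = None,
) -> dict[str, RDM]:
    """Per-task orientation RDMs from one module's delay activity.

    Pearson correlation distances between trials, averaged within each
    orientation pair and across the window's time steps.
    """
    if window is None:
        window = delay_window(config)
    sl = _module_units(config, module)
    out = {}
    for task in ("maintenance", "categorization"):
        for rn in (["n/a"] if task == "maintenance" else list(config.rules)):
            sel = ((trials["task"] == task) & (trials["rule"] == rn)).to_numpy()
            if not sel.any():
                continue
            ori = trials.loc[sel, "orientation"].to_numpy(float)
            mats = []
            for t in window:
                m, conds = pairwise_condition_rdm(activity[t][sel][:, sl], ori)
                mats.append(m)
            name = task if task == "maintenance" else f"{task}-{rn}"
            out[name] = RDM(np.mean(mats, axis=0), conds, task=name)
    return out
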