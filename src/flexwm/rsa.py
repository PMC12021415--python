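"""Representational similarity analysis with model-RDM regression.

Neural representational dissimilarity matrices (RDMs) are 30 x 30
Pearson-correlation distances (1 - r) between orientation conditions
within each task, averaged over delay time points and over trial pairs.
Three model RDMs decompose them: a graded stimulus model (dissimilarity
grows with circular orientation distance), a discrete stimulus model
(all different orientations equidistant), and an abstract category model
(0 within category, 1 between).  Their contributions are estimated with
a linear mixed-effects model over subjects (random intercept per
subject, fit on off-diagonal entries).

RDMs can be aligned by stimulus (rows sorted 1-180 deg) or by category
(rows rotated so the first 15 conditions share a category), which makes
RDMs from different categorization rules commensurable and allows
comparison against network RDMs via Kendall's tau-b.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sp_stats

from . import circ, task_design
from .synthetic_bold import BoldDataset


class RdmError(ValueError):
    """Raised for degenerate RDM construction or comparison inputs."""


@dataclass
class RDM:
    """A condition x condition dissimilarity matrix with its row order."""

    matrix: np.ndarray
    orientations: np.ndarray
    task: str = ""
    alignment: str = "stimulus"
    kind: str = "neural"

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.orientations):
            raise RdmError("matrix must be square and match the condition list")
        if not np.allclose(m, m.T, atol=1e-10):
            raise RdmError("RDM must be symmetric")

    def offdiag(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries, row-major."""
        iu = np.triu_indices(self.matrix.shape[0], k=1)
        return self.matrix[iu]


def pairwise_condition_rdm(
    patterns: np.ndarray, condition_ids: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Average trial-pair correlation distances within condition pairs.

    ``patterns``: (n_trials, n_features) for one time point.  Returns the
    condition x condition matrix (diagonal forced to 0) and the sorted
    unique condition ids defining row order.
    """
    conds = np.unique(condition_ids)
    with np.errstate(invalid="ignore"):
        d = 1.0 - np.corrcoef(patterns)
    if not np.all(np.isfinite(d)):
        raise RdmError("zero-variance pattern encountered")
    out = np.zeros((len(conds), len(conds)))
    idx = [np.where(condition_ids == c)[0] for c in conds]
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            out[i, j] = out[j, i] = d[np.ix_(idx[i], idx[j])].mean()
    return out, conds


def neural_rdm(
    dataset: BoldDataset,
    epoch_time_points,
    task: str,
    rule: str | None = None,
) -> RDM:
    """Orientation RDM for one task (optionally one rule), delay-averaged."""
    trials = dataset.trials
    sel = (trials["task"] == task).to_numpy()
    if rule is not None:
        sel &= (trials["rule"] == rule).to_numpy()
    if not sel.any():
        raise RdmError(f"no trials for task={task!r}, rule={rule!r}")
    ori = trials.loc[sel, "orientation"].to_numpy(dtype=float)
    counts = pd.Series(ori).value_counts()
    if (counts < 2).any():
        missing = sorted(counts[counts < 2].index)
        raise RdmError(f"orientations with < 2 trials: {missing}")
    mats = []
    for tp in epoch_time_points:
        m, conds = pairwise_condition_rdm(dataset.signal[:, sel, tp].T, ori)
        mats.append(m)
    return RDM(
        matrix=np.mean(mats, axis=0),
        orientations=conds,
        task=task if rule is None else f"{task}-{rule}",
    )


def align_rdm(rdm: RDM, by: str = "stimulus", rule: task_design.CategorizationRule | None = None) -> RDM:
    """Reorder an RDM by stimulus (ascending orientation) or by category.

    Category alignment orders conditions counter-clockwise from the
    rule's first boundary, so the first half of the rows share one
    category and the second half the other (e.g. rule boundaries
    20/110 deg on the 4-178 deg grid give 22-106 then 112-16 deg).
    A pure permutation: the off-diagonal multiset is unchanged; idempotent.
    """
    if by == "stimulus":
        order = np.argsort(rdm.orientations)
    elif by == "category":
        if rule is None:
            raise RdmError("category alignment requires a rule")
        order = np.argsort(circ.wrap(rdm.orientations - rule.boundary1))
    else:
        raise RdmError(f"unknown alignment {by!r}")
    return replace(
        rdm,
        matrix=rdm.matrix[np.ix_(order, order)],
        orientations=rdm.orientations[order],
        alignment=by,
    )


def average_rdms(rdms: list[RDM]) -> RDM:
    """Elementwise mean of equally-shaped, identically-aligned RDMs."""
    if len({r.matrix.shape for r in rdms}) != 1:
        raise RdmError("RDMs must share a shape")
    return replace(rdms[0], matrix=np.mean([r.matrix for r in rdms], axis=0))


def model_rdms(
    rule: task_design.CategorizationRule,
    orientation_set: task_design.OrientationSet,
    graded_form: str = "linear",
) -> dict[str, RDM]:
    """The graded-stimulus, discrete-stimulus and abstract-category models.

    ``graded_form``: "linear" (circular distance / 90) or "cos"
    ((1 - cos 2*distance)/2); both normalized to [0, 1].
    """
    ori = np.sort(orientation_set.values)
    d = circ.distance(ori[None, :], ori[:, None])
    if graded_form == "linear":
        graded = d / 90.0
    elif graded_form == "cos":
        graded = (1.0 - np.cos(2 * np.deg2rad(d))) / 2.0
    else:
        raise ValueError(f"unknown graded_form {graded_form!r}")
    discrete = 1.0 - np.eye(len(ori))
    labels = task_design.category_labels(ori, rule)
    category = (labels[None, :] != labels[:, None]).astype(float)
    return {
        "graded_stimulus": RDM(graded, ori, kind="graded_stimulus"),
        "discrete_stimulus": RDM(discrete, ori, kind="discrete_stimulus"),
        "abstract_category": RDM(category, ori, kind="abstract_category"),
    }


def fit_lmem(subject_rdms: list[RDM], models: dict[str, RDM]) -> pd.DataFrame:
    """Mixed-effects regression of neural RDMs on the three model RDMs.

    Off-diagonal entries of every subject's RDM are stacked and regressed
    on the model predictors with a random intercept per subject.  The
    discrete-stimulus model is constant over off-diagonal cells, so it
    doubles as the fixed intercept and no separate intercept is added.
    Returns one row per model with the fixed-effect coefficient and its
    p-value.
    """
    if len(subject_rdms) < 3:
        raise RdmError("need >= 3 subjects")
    names = list(models)
    X = np.column_stack([models[n].offdiag() for n in names])
    cond = np.linalg.cond(X)
    if cond > 1e8:
        warnings.warn(f"model predictors poorly conditioned (cond={cond:.2e})")
    frames = []
    for s, rdm in enumerate(subject_rdms):
        df = pd.DataFrame(X, columns=names)
        df["y"] = rdm.offdiag()
        df["subject"] = s
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    formula = "y ~ 0 + " + " + ".join(names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm(formula, data, groups=data["subject"]).fit(reml=True)
    rows = [
        {"model": n, "coef": fit.params[n], "p_value": fit.pvalues[n], "se": fit.bse[n]}
        for n in names
    ]
    return pd.DataFrame(rows)


def restrict_rdm(rdm: RDM, keep_idx: np.ndarray) -> RDM:
    """Sub-RDM over a subset of conditions (order preserved)."""
    keep_idx = np.asarray(keep_idx)
    return replace(
        rdm,
        matrix=rdm.matrix[np.ix_(keep_idx, keep_idx)],
        orientations=rdm.orientations[keep_idx],
    )


def match_conditions(rdm_a: RDM, rdm_b: RDM, tol: float = 4.5) -> tuple[RDM, RDM]:
    """Restrict two RDMs to nearest-orientation condition pairs.

    Different stimulus grids (e.g. a 6-deg human grid and a 9-deg
    network grid) rarely share exact orientations; each condition of the
    smaller set is greedily matched to its nearest unmatched counterpart
    within ``tol`` degrees (circular), and both RDMs are restricted to
    the matched pairs.
    """
    a, b = rdm_a.orientations, rdm_b.orientations
    if len(a) > len(b):
        rb, ra = match_conditions(rdm_b, rdm_a, tol)
        return ra, rb
    d = circ.distance(a[:, None], b[None, :])
    used_b: set[int] = set()
    ia, ib = [], []
    for i in np.argsort(d.min(axis=1)):
        order = np.argsort(d[i])
        for j in order:
            if d[i, j] > tol:
                break
            if j not in used_b:
                ia.append(i)
                ib.append(int(j))
                used_b.add(int(j))
                break
    if not ia:
        raise RdmError("no overlapping conditions within tolerance")
    order = np.argsort([a[i] for i in ia])
    ia = np.asarray(ia)[order]
    ib = np.asarray(ib)[order]
    return restrict_rdm(rdm_a, ia), restrict_rdm(rdm_b, ib)


def rdm_similarity(subject_rdms: list[RDM], reference: RDM) -> tuple[np.ndarray, float]:
    """Kendall tau-b of each subject's RDM with a reference RDM, plus a
    one-sided (greater-than-zero) Wilcoxon signed-rank group p-value."""
    ref = reference.offdiag()
    if len(ref) != len(subject_rdms[0].offdiag()):
        raise RdmError("no matching condition set between RDMs")
    taus = np.array(
        [sp_stats.kendalltau(r.offdiag(), ref).statistic for r in subject_rdms]
    )
    p = float(sp_stats.wilcoxon(taus, alternative="greater").pvalue)
    return taus, p


def compare_networks(
    taus_a: np.ndarray, taus_b: np.ndarray, n_iter: int = 1000, seed: int = 0
) -> dict:
    """Sign-flip permutation test on z-transformed tau differences (a - b)."""
    from .stats import sign_flip_test

    za, zb = np.arctanh(np.asarray(taus_a)), np.arctanh(np.asarray(taus_b))
    res = sign_flip_test(za - zb, n_iter=n_iter, seed=seed)
    return {"mean_z_diff": float(np.mean(za - zb)), "p_value": res.p_value, "n_iter": n_iter}


def compare_rdms(
    subject_rdms: list[RDM],
    network_rdm: RDM,
    other_network_rdm: RDM | None = None,
    n_iter: int = 1000,
    seed: int = 0,
) -> dict:
    """Human-network RDM comparison (Kendall tau-b per subject, group
    signed-rank p; optional network-vs-network sign-flip contrast)."""
    taus, p_group = rdm_similarity(subject_rdms, network_rdm)
    out = {"tau": taus, "mean_tau": float(np.mean(taus)), "p_group": p_group}
    if other_network_rdm is not None:
        taus2, _ = rdm_similarity(subject_rdms, other_network_rdm)
        out["contrast"] = compare_networks(taus, taus2, n_iter=n_iter, seed=seed)
    return out
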