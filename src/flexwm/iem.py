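"""Inverted encoding model (IEM) for population orientation reconstruction.

The forward model expresses each voxel's response as a weighted sum of
nine hypothesized orientation channels (half-wave-rectified sinusoids
raised to the eighth power, centers 20 deg apart starting at 1 deg).
Training data B1 (voxels x trials) and hypothesized channel responses
C1 (channels x trials) give the least-squares weight estimate

    W_hat = B1 C1' (C1 C1')^-1

which is inverted on held-out data B2 to estimate channel responses

    C2_hat = (W_hat' W_hat)^-1 W_hat' B2.

The procedure is repeated for 20 one-degree shifts of the channel
centers so the responses tile all 180 integer orientations; per-trial
responses are recentered on the cued orientation and averaged by
condition under leave-one-run-out cross-validation, each TR separately.

Reconstruction strength is summarized by the representational fidelity:
each channel response r(theta) is projected onto the cued-orientation
vector after doubling angles to the full circle, and the projections
are averaged:  fidelity = mean_theta r(theta) * cos(2 theta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import circ
from .synthetic_bold import BoldDataset

BASE_CENTERS = np.arange(1.0, 180.0, 20.0)  # 1, 21, ..., 161
N_SHIFTS = 20
DEFAULT_EXPONENT = 8
RCOND = 1e-10

#: relative-orientation axis of a recentered reconstruction (deg)
RELATIVE_AXIS = np.arange(180) - 90


class RankError(np.linalg.LinAlgError):
    """Raised when a design or weight matrix is numerically rank-deficient."""


@dataclass
class Reconstruction:
    """Recentered 180-point channel response for one condition/time point."""

    response: np.ndarray  # (180,), indexed by RELATIVE_AXIS
    condition: str = ""
    time_point: float = np.nan

    def __post_init__(self):
        if self.response.shape != (180,):
            raise ValueError("reconstruction must have 180 channels")


def basis_response(theta, center, exponent: int = DEFAULT_EXPONENT):
    """Channel tuning max(0, cos(theta - center))**exponent with the
    difference wrapped into [-90, 90] degrees before rectification."""
    d = circ.signed_diff(theta, center)
    c = np.cos(np.deg2rad(d))
    # exact zero at +/-90 deg (the rectification point), where floating
    # cosine leaves a ~1e-17 residue
    c = np.where(np.abs(d) >= 90.0 - 1e-9, 0.0, c)
    return np.maximum(0.0, c) ** exponent


def design_matrix(thetas, centers, exponent: int = DEFAULT_EXPONENT) -> np.ndarray:
    """Hypothesized channel responses C1 (channels x trials), peak 1."""
    thetas = np.asarray(thetas, dtype=float)
    return basis_response(thetas[None, :], np.asarray(centers, dtype=float)[:, None], exponent)


def _solve_gram(gram: np.ndarray, rhs: np.ndarray, what: str) -> np.ndarray:
    """Solve gram @ x = rhs, raising RankError below the condition threshold."""
    s = np.linalg.svd(gram, compute_uv=False)
    if s[-1] <= RCOND * s[0]:
        deficient = int(np.sum(s <= RCOND * s[0]))
        raise RankError(
            f"{what} is rank-deficient ({deficient} near-null direction(s); "
            f"condition number {s[0] / max(s[-1], 1e-300):.2e})"
        )
    return np.linalg.solve(gram, rhs)


def estimate_weights(B1: np.ndarray, C1: np.ndarray) -> np.ndarray:
    """Least-squares weight estimate W_hat = B1 C1' (C1 C1')^-1 (voxels x channels)."""
    if B1.shape[1] != C1.shape[1]:
        raise ValueError("B1 and C1 must have the same number of trials")
    sol = _solve_gram(C1 @ C1.T, C1 @ B1.T, "C1 C1'")
    return sol.T


def invert_weights(W_hat: np.ndarray, B2: np.ndarray) -> np.ndarray:
    """Estimated channel responses C2_hat = (W'W)^-1 W' B2 (channels x trials)."""
    if W_hat.shape[0] != B2.shape[0]:
        raise ValueError("W_hat and B2 must have the same number of voxels")
    return _solve_gram(W_hat.T @ W_hat, W_hat.T @ B2, "W_hat' W_hat")


def _check_runs(trials: pd.DataFrame):
    runs = trials["run_id"].unique()
    if len(runs) < 2:
        raise ValueError("leave-one-run-out cross-validation needs >= 2 runs")
    return runs


def reconstruct_trials(
    dataset: BoldDataset,
    time_point: int,
    scheme: str = "all-condition",
    exponent: int = DEFAULT_EXPONENT,
    orientations: np.ndarray | None = None,
) -> np.ndarray:
    """Per-trial recentered 180-channel responses at one TR.

    ``scheme`` "all-condition" trains on all trials of the training runs;
    "within-condition" trains separately per task condition.  Returns an
    (n_trials, 180) array indexed by :data:`RELATIVE_AXIS`.
    """
    if scheme not in ("all-condition", "within-condition"):
        raise ValueError(f"unknown scheme {scheme!r}")
    trials = dataset.trials
    runs = _check_runs(trials)
    B = dataset.signal[:, :, time_point]
    if orientations is None:
        orientations = trials["orientation"].to_numpy(dtype=float)
    ori = np.asarray(orientations, dtype=float)
    tasks = trials["task"].to_numpy()
    run_ids = trials["run_id"].to_numpy()

    full = np.zeros((len(trials), 180))
    for run in runs:
        test = run_ids == run
        train = ~test
        groups = (
            [np.ones(len(trials), bool)]
            if scheme == "all-condition"
            else [tasks == t for t in np.unique(tasks)]
        )
        for g in groups:
            tr = train & g
            te = test & g
            if not te.any():
                continue
            for shift in range(N_SHIFTS):
                centers = BASE_CENTERS + shift
                C1 = design_matrix(ori[tr], centers, exponent)
                W = estimate_weights(B[:, tr], C1)
                C2 = invert_weights(W, B[:, te])  # (9, n_test)
                idx = (centers.astype(int)) % 180
                full[np.ix_(np.where(te)[0], idx)] = C2.T
    # Recenter: response at relative angle d = full[trial, (theta + d) mod 180].
    rel = np.empty_like(full)
    for i, th in enumerate(ori):
        rel[i] = full[i, (int(round(th)) + RELATIVE_AXIS) % 180]
    return rel


def _condition_of(trials: pd.DataFrame) -> np.ndarray:
    """Collapse rules: 'maintenance' or 'categorization'."""
    return trials["task"].to_numpy()


def run_iem(
    dataset: BoldDataset,
    scheme: str = "all-condition",
    time_point: int = 12,
    **kwargs,
) -> dict[str, Reconstruction]:
    """Condition-averaged recentered reconstructions at one TR.

    Categorization trials are averaged across rules (they share the
    'categorization' task label).
    """
    rel = reconstruct_trials(dataset, time_point, scheme, **kwargs)
    cond = _condition_of(dataset.trials)
    out = {}
    for c in np.unique(cond):
        out[str(c)] = Reconstruction(
            response=rel[cond == c].mean(axis=0), condition=str(c), time_point=time_point
        )
    return out


def fidelity(recon) -> float:
    """Mean projection of the recentered response onto the cued direction
    after angle doubling: mean_theta r(theta) cos(2 theta).

    Exactly 0 for a flat response; invariant to additive offsets; linear
    in the response amplitude.
    """
    r = recon.response if isinstance(recon, Reconstruction) else np.asarray(recon, float)
    if r.shape[-1] != 180:
        raise ValueError("expected a 180-channel reconstruction")
    # de-meaning first makes the additive-offset invariance exact in
    # floating point (cos(2 theta) sums to zero over the uniform grid)
    r = r - r.mean(axis=-1, keepdims=True)
    return float(np.mean(r * np.cos(2 * np.deg2rad(RELATIVE_AXIS)), axis=-1))


def fidelity_timecourse(
    dataset: BoldDataset,
    scheme: str = "all-condition",
    time_points=None,
    **kwargs,
) -> pd.DataFrame:
    """Long-format fidelity table (subject, condition, time_point, fidelity)."""
    if time_points is None:
        time_points = range(dataset.n_trs)
    rows = []
    for tp in time_points:
        for cond, rec in run_iem(dataset, scheme, tp, **kwargs).items():
            rows.append(
                {
                    "subject": dataset.subject_id,
                    "condition": cond,
                    "time_point": tp,
                    "fidelity": fidelity(rec),
                }
            )
    return pd.DataFrame(rows)


def demean_conditions(dataset: BoldDataset) -> BoldDataset:
    """Remove the mean voxel pattern of each task condition per time point.

    Idempotent; eliminates fidelity differences driven purely by uniform
    additive task offsets.
    """
    sig = dataset.signal.copy()
    tasks = dataset.trials["task"].to_numpy()
    for t in np.unique(tasks):
        m = tasks == t
        sig[:, m, :] -= sig[:, m, :].mean(axis=1, keepdims=True)
    return BoldDataset(
        signal=sig,
        trials=dataset.trials,
        subject_id=dataset.subject_id,
        tr=dataset.tr,
        ground_truth=dataset.ground_truth,
    )
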