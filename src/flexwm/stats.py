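"""Group-level inference utilities: sign-flip permutation tests,
Benjamini-Hochberg FDR, analysis-epoch averaging, and across-subject
brain-behavior correlation.

The sign-flip test builds a null distribution by randomly assigning
+1/-1 to each subject's value and averaging, repeated ``n_iter`` times
(10,000 by default); the p-value uses add-one smoothing so it is never
zero and never below 1/(n_iter+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EpochDefinition:
    """Analysis epochs on the 20-point trial grid (TR = 1 s, times 0-19 s)."""

    early: tuple = (5, 6, 7, 8, 9, 10)   # 5-10 s
    late: tuple = (11, 12, 13, 14, 15, 16)  # 11-16 s


EPOCHS = EpochDefinition()


@dataclass
class PermutationResult:
    observed: float
    p_value: float
    n_iter: int
    seed: int
    null: np.ndarray = field(repr=False, default=None)


def sign_flip_test(
    sample,
    n_iter: int = 10000,
    seed: int = 0,
    sided: str = "two",
) -> PermutationResult:
    """Sign-flip permutation test of a zero group mean.

    ``sample`` holds one value per subject (or one paired difference per
    subject).  ``sided``: "two" (default), "greater", or "less".
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 subjects")
    obs = float(x.mean())
    if np.all(x == 0):
        warnings.warn("all-zero sample: sign-flip test is degenerate, p = 1")
        return PermutationResult(obs, 1.0, n_iter, seed, np.zeros(n_iter))
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_iter, x.size))
    null = flips @ x / x.size
    if sided == "two":
        k = np.sum(np.abs(null) >= abs(obs))
    elif sided == "greater":
        k = np.sum(null >= obs)
    elif sided == "less":
        k = np.sum(null <= obs)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    p = (k + 1) / (n_iter + 1)
    return PermutationResult(obs, float(p), n_iter, seed, null)


def fdr_correct(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up correction.

    Returns (rejected boolean array, adjusted p-values).
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p <= q, p.copy()
    rej, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return rej, p_adj


def epoch_average(series, time_points, epoch) -> float:
    """Mean of a per-time-point series over an epoch's time points.

    ``epoch`` is an iterable of time points (or "early"/"late" for the
    standard analysis epochs).
    """
    if isinstance(epoch, str):
        epoch = getattr(EPOCHS, epoch)
    series = np.asarray(series, dtype=float)
    tps = np.asarray(time_points)
    idx = []
    for t in epoch:
        hit = np.where(tps == t)[0]
        if hit.size == 0:
            raise ValueError(f"time point {t} missing from series")
        idx.append(hit[0])
    return float(series[np.asarray(idx)].mean())


def behavior_correlation(
    fidelity_per_subject,
    accuracy_per_subject,
    n_iter: int = 10000,
    seed: int = 0,
) -> dict:
    """Pearson correlation between representational strength and behavior,
    with a permutation p-value from shuffling the subject pairing."""
    x = np.asarray(fidelity_per_subject, dtype=float).ravel()
    y = np.asarray(accuracy_per_subject, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples of >= 3 subjects")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        null[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
    p = float((np.sum(np.abs(null) >= abs(r)) + 1) / (n_iter + 1))
    return {"r": r, "p_value": p, "n_iter": n_iter, "seed": seed}
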