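"""Synthetic multi-voxel BOLD generator with known ground truth.

Emulates the statistical structure the downstream analyses assume:
orientation-tuned voxel populations, task- and epoch-dependent tuning
gain, an optional stimulus-independent category signal carried on a
voxel-space axis orthogonal to the tuning subspace, hemodynamic
smoothing at TR = 1 s, run structure for cross-validation, and a
behavioral accuracy per subject linked to representational strength.

Region presets mirror the qualitative profiles of the study's regions of
interest: an "EVC-like" region where late-delay stimulus gain is higher
for maintenance than categorization, an "IPS-like" region with equal
gains, and an "sPCS-like" region with the reverse late-delay pattern.

The neural gain windows are placed ~6 s earlier than the corresponding
BOLD analysis epochs (early 5-10 s, late 11-16 s) so that, after
convolution with the canonical hemodynamic response (peak ~6 s), the
injected effects surface in the epochs where the analyses measure them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from . import circ, task_design

N_CHANNELS = 9  # minimum voxel count for encoding-model estimability

#: neural-drive windows (seconds within the trial) feeding each analysis epoch
NEURAL_WINDOWS = {"early": (0.0, 5.0), "late": (5.0, 11.0)}

TR = 1.0
N_TRS = 20
FINE_DT = 0.25


@dataclass(frozen=True)
class RegionProfile:
    """Generative gains of a synthetic region.

    ``stimulus_gain`` and ``category_gain`` map (task, epoch) to a
    nonnegative scalar; ``epoch`` is "early" or "late".  The category
    signal is only injected after the task cue, i.e. in the late window,
    and only on categorization trials; early category entries exist for
    interface symmetry but are inert.
    """

    name: str
    stimulus_gain: dict
    category_gain: dict
    baseline: float = 0.0
    noise_sd: float = 8.0

    def __post_init__(self):
        for m in (self.stimulus_gain, self.category_gain):
            for v in m.values():
                if not np.isfinite(v) or v < 0:
                    raise ValueError("gains must be finite and nonnegative")


def _profile(name, stim, cat=0.0, noise_sd=8.0):
    m, c = stim
    sg = {
        ("maintenance", "early"): 1.0,
        ("categorization", "early"): 1.0,
        ("maintenance", "late"): m,
        ("categorization", "late"): c,
    }
    cg = {
        ("maintenance", "early"): 0.0,
        ("categorization", "early"): 0.0,
        ("maintenance", "late"): 0.0,
        ("categorization", "late"): cat,
    }
    return RegionProfile(name=name, stimulus_gain=sg, category_gain=cg, noise_sd=noise_sd)


def region_profile(name: str, noise_sd: float = 8.0, category_gain: float = 0.0) -> RegionProfile:
    """Named presets: ``EVC-like``, ``IPS-like``, ``sPCS-like``."""
    presets = {
        "EVC-like": (1.0, 0.5),   # maintenance > categorization late stimulus gain
        "IPS-like": (0.8, 0.8),
        "sPCS-like": (0.3, 1.0),  # categorization > maintenance late stimulus gain
    }
    if name not in presets:
        raise KeyError(f"unknown region profile {name!r}; options: {sorted(presets)}")
    return _profile(name, presets[name], cat=category_gain, noise_sd=noise_sd)


@dataclass(frozen=True)
class VoxelPopulation:
    """Ground-truth voxel population: tuning plus per-rule category axes."""

    n_voxels: int
    preferred: np.ndarray = field(repr=False)
    tuning_exponent: float
    category_axes: dict = field(repr=False)  # rule name -> unit voxel vector
    profile: RegionProfile
    seed: int

    def tuning(self, thetas) -> np.ndarray:
        """Voxel tuning pattern(s) for orientation(s): (n_voxels, n_thetas)."""
        thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
        d = circ.signed_diff(thetas[None, :], self.preferred[:, None])
        resp = np.maximum(0.0, np.cos(np.deg2rad(d))) ** self.tuning_exponent
        return resp


@dataclass
class BoldDataset:
    """Voxels x trials x time synthetic BOLD with its trial table."""

    signal: np.ndarray  # (n_voxels, n_trials, n_trs)
    trials: pd.DataFrame
    subject_id: str = "sub-00"
    tr: float = TR
    ground_truth: VoxelPopulation | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if self.signal.shape[1] != len(self.trials):
            raise ValueError("signal/trials shape mismatch")
        if self.trials["run_id"].nunique() < 2:
            raise ValueError("need >= 2 runs for cross-validation")

    @property
    def n_voxels(self):
        return self.signal.shape[0]

    @property
    def n_trials(self):
        return self.signal.shape[1]

    @property
    def n_trs(self):
        return self.signal.shape[2]


def double_gamma_hrf(dt: float = FINE_DT, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak 6 s, undershoot 16 s,
    undershoot ratio 1/6), normalized to unit peak."""
    t = np.arange(0, duration, dt)
    h = sp_stats.gamma.pdf(t, 6.0) - sp_stats.gamma.pdf(t, 16.0) / 6.0
    return h / h.max()


def make_population(
    n_voxels: int,
    profile: RegionProfile,
    seed: int = 0,
    tuning_exponent: float = 8.0,
    rules: dict | None = None,
) -> VoxelPopulation:
    """Construct a deterministic voxel population.

    Preferred orientations are spread evenly over [0, 180) (uniform
    coverage); per-rule category axes are random unit vectors projected
    out of the stimulus-tuning subspace and orthogonalized across rules.
    """
    if n_voxels < N_CHANNELS:
        raise ValueError(
            f"n_voxels={n_voxels} is below the {N_CHANNELS}-channel minimum"
        )
    rng = np.random.default_rng(seed)
    preferred = circ.wrap(np.arange(n_voxels) * 180.0 / n_voxels + rng.uniform(0, 180))
    pop = VoxelPopulation(
        n_voxels=n_voxels,
        preferred=preferred,
        tuning_exponent=tuning_exponent,
        category_axes={},
        profile=profile,
        seed=seed,
    )
    # Basis of the stimulus subspace: tuning patterns over a fine grid.
    T = pop.tuning(np.arange(0.0, 180.0, 2.0))
    Q, _ = np.linalg.qr(T)
    axes = {}
    prev = []
    if rules is None:
        rules = {"A": task_design.RULE_A, "B": task_design.RULE_B}
    for name in rules:
        v = rng.standard_normal(n_voxels)
        v -= Q @ (Q.T @ v)
        for p in prev:
            v -= (p @ v) * p
        v /= np.linalg.norm(v)
        axes[name] = v
        prev.append(v)
    return replace(pop, category_axes=axes)


def _drive_envelopes(trials: pd.DataFrame, profile: RegionProfile, fine_t: np.ndarray):
    """Per-trial stimulus- and category-drive envelopes on the fine grid."""
    n = len(trials)
    env_stim = np.zeros((n, fine_t.size))
    env_cat = np.zeros((n, fine_t.size))
    for epoch, (t0, t1) in NEURAL_WINDOWS.items():
        w = (fine_t >= t0) & (fine_t < t1)
        for task in ("maintenance", "categorization"):
            rows = (trials["task"] == task).to_numpy()
            env_stim[np.ix_(rows, w)] = profile.stimulus_gain[(task, epoch)]
            if epoch == "late":
                env_cat[np.ix_(rows, w)] = profile.category_gain[(task, epoch)]
    return env_stim, env_cat


def simulate_bold(
    pop: VoxelPopulation,
    design: pd.DataFrame,
    seed: int = 0,
    noise_sd: float | None = None,
) -> BoldDataset:
    """Simulate a BOLD dataset for a trial table.

    Per trial, a neural time course (stimulus-tuned drive scaled by the
    profile's task x epoch gain, plus a signed category-axis drive after
    the task cue on categorization trials, plus i.i.d. Gaussian noise) is
    convolved with the canonical double-gamma HRF and sampled at TR = 1 s
    on a 20-point grid (0-19 s).
    """
    rng = np.random.default_rng(seed)
    profile = pop.profile
    if noise_sd is None:
        noise_sd = profile.noise_sd
    fine_t = np.arange(0.0, N_TRS * TR, FINE_DT)
    env_stim, env_cat = _drive_envelopes(design, profile, fine_t)

    tuning = pop.tuning(design["orientation"].to_numpy())  # (V, n)
    # Signed category drive: +axis for category 1, -axis for category 2.
    cat_pattern = np.zeros_like(tuning)
    for rule_name, axis in pop.category_axes.items():
        rows = (design["rule"] == rule_name).to_numpy()
        if not rows.any():
            continue
        sign = np.where(design.loc[rows, "category_label"].to_numpy() == "1", 1.0, -1.0)
        cat_pattern[:, rows] = axis[:, None] * sign[None, :]

    neural = (
        tuning[:, :, None] * env_stim[None, :, :]
        + cat_pattern[:, :, None] * env_cat[None, :, :]
    )
    if noise_sd > 0:
        neural = neural + rng.normal(0.0, noise_sd, size=neural.shape)

    hrf = double_gamma_hrf(FINE_DT)
    bold_fine = sp_signal.fftconvolve(neural, hrf[None, None, :], axes=2)[..., : fine_t.size]
    step = int(round(TR / FINE_DT))
    bold = bold_fine[:, :, ::step] + profile.baseline
    return BoldDataset(signal=np.ascontiguousarray(bold), trials=design, ground_truth=pop)


@dataclass(frozen=True)
class SubjectBehavior:
    """Behavioral accuracy per task for one subject."""

    accuracy: dict  # task -> proportion in [0, 1]

    def __post_init__(self):
        for v in self.accuracy.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("accuracy must lie in [0, 1]")


def simulate_cohort(
    n_subjects: int,
    profile: RegionProfile,
    coupling: float = 0.6,
    seed: int = 0,
    n_voxels: int = 120,
    experiment: int = 1,
    trials_per_condition: int = 90,
    gain_jitter_sd: float = 0.3,
    base_accuracy: float = 0.815,
    accuracy_spread: float = 0.06,
) -> list[tuple[BoldDataset, SubjectBehavior]]:
    """Simulate a cohort with gain-linked behavior.

    Each subject's stimulus gains are jittered multiplicatively
    (lognormal, sd ``gain_jitter_sd`` on the log scale) around the
    profile.  Behavioral accuracy is a monotone function of the
    subject's true late-epoch stimulus gain plus independent noise:
    ``coupling`` = 0 gives independence, ``coupling`` = 1 with the noise
    term weighted ``sqrt(1 - coupling**2)`` = 0 gives a rank-perfect
    association.
    """
    if n_subjects < 3:
        raise ValueError("need >= 3 subjects")
    rng = np.random.default_rng(seed)
    jit = np.exp(rng.normal(0.0, gain_jitter_sd, size=n_subjects))
    eps = rng.normal(0.0, 1.0, size=n_subjects)
    z = (np.log(jit) - np.mean(np.log(jit))) / (np.std(np.log(jit)) + 1e-12)
    latent = coupling * z + np.sqrt(max(0.0, 1.0 - coupling**2)) * eps

    out = []
    for s in range(n_subjects):
        sg = {k: v * jit[s] for k, v in profile.stimulus_gain.items()}
        prof_s = RegionProfile(
            name=profile.name,
            stimulus_gain=sg,
            category_gain=dict(profile.category_gain),
            baseline=profile.baseline,
            noise_sd=profile.noise_sd,
        )
        sub_seed = int(rng.integers(2**31 - 1))
        design = task_design.generate_design(
            experiment, seed=sub_seed, trials_per_condition=trials_per_condition
        )
        pop = make_population(n_voxels, prof_s, seed=sub_seed)
        ds = simulate_bold(pop, design, seed=sub_seed + 1)
        ds.subject_id = f"sub-{s:02d}"
        acc = float(np.clip(base_accuracy + accuracy_spread * latent[s], 0.0, 1.0))
        beh = SubjectBehavior(accuracy={"maintenance": acc, "categorization": acc})
        out.append((ds, beh))
    return out
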