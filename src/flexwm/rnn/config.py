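"""Configuration of the modular STSP recurrent networks.

The architecture follows the study design: three hidden modules in a
chain (posterior -> middle -> anterior), each split 80/20 into
excitatory and inhibitory units; only module-1 excitatory units receive
input, only module-3 excitatory units drive the output; between-module
connections are excitatory-only, restricted to adjacent modules, and
carried by a random half of each module's excitatory units; inhibitory
connectivity is strictly local.

Model time runs at dt = 10 ms (full preset; the desk/micro presets use
20 ms) with a 100 ms membrane time constant.  Trial epochs are
compressed relative to the scanner schedule (the event order is
preserved): samples 250 ms with 100 ms gaps, retro-cue 100 ms, short
delay 300 ms, task cue 100 ms, main delay 1000 ms at full scale
(600 ms in the desk/micro presets), two 200 ms probe options (choice
networks only), 500 ms test window with a 50 ms grace period.
Short-term synaptic plasticity uses the standard
utilization/resource formulation with facilitating (tau_x 200 ms,
tau_u 1500 ms, U 0.15) and depressing (tau_x 1500 ms, tau_u 200 ms,
U 0.45) synapse groups on alternating excitatory units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .. import task_design

#: grid of 20 orientations evenly spanning [0, 180) degrees
N_GRID = 20
GRID_STEP = 180.0 / N_GRID  # 9 degrees


@dataclass(frozen=True)
class NetworkConfig:
    output_mode: str = "rnn2"          # "rnn1" (choice) or "rnn2" (category+stimulus)
    rule_mode: str = "flexible"        # "flexible" (rules A & B) or "fixed"
    n_modules: int = 3
    units_per_module: int = 200
    exc_frac: float = 0.8
    n_tuned_in: int = 15
    n_retro_cue: int = 2
    n_task_cue: int = 3
    p_inter: float = 0.5               # fraction of E units sending between modules
    noise_sd: float = 0.01             # recurrent noise (training)
    input_noise_sd: float = 0.01
    dt: float = 0.010                  # s
    tau: float = 0.100                 # membrane time constant, s
    input_sigma: float = GRID_STEP     # tuning width of input/output bumps, deg
    # STSP constants (seconds): facilitating / depressing halves
    stsp_fac: tuple = (0.200, 1.500, 0.15)   # (tau_x, tau_u, U)
    stsp_dep: tuple = (1.500, 0.200, 0.45)
    # trial epochs, ms
    epochs_ms: dict = field(
        default_factory=lambda: {
            "sample1": 250,
            "isi1": 100,
            "sample2": 250,
            "retro_cue": 100,
            "delay1": 300,
            "task_cue": 100,
            "delay2": 1000,
            "option1": 200,
            "option2": 200,
            "test": 500,
        }
    )
    grace_ms: int = 50
    # initialization
    init_radius: float = 1.2       # rest-state spectral radius of W_rec
    w_in_scale: float = 1.5
    # training
    batch_per_condition: int = 300
    max_iter: int = 10000
    learning_rate: float = 0.01
    grad_clip: float = 0.5
    spike_penalty: float = 0.0
    accuracy_criterion: float = 0.90
    fixed_rule: str = "A"
    seed: int = 0

    def __post_init__(self):
        n_exc = self.units_per_module * self.exc_frac
        if abs(n_exc - round(n_exc)) > 1e-9:
            raise ValueError("units_per_module must divide evenly into the E/I split")
        if self.output_mode not in ("rnn1", "rnn2"):
            raise ValueError("output_mode must be 'rnn1' or 'rnn2'")
        if self.rule_mode not in ("flexible", "fixed"):
            raise ValueError("rule_mode must be 'flexible' or 'fixed'")

    @property
    def n_units(self) -> int:
        return self.n_modules * self.units_per_module

    @property
    def n_exc_per_module(self) -> int:
        return round(self.units_per_module * self.exc_frac)

    @property
    def n_inputs(self) -> int:
        return self.n_tuned_in + self.n_retro_cue + self.n_task_cue

    @property
    def n_outputs(self) -> int:
        return 2 if self.output_mode == "rnn1" else 2 + self.n_tuned_in

    @property
    def alpha(self) -> float:
        return self.dt / self.tau

    @property
    def rules(self) -> dict:
        if self.rule_mode == "flexible":
            return {"A": task_design.RULE_A, "B": task_design.RULE_B}
        rule = {"A": task_design.RULE_A, "B": task_design.RULE_B}[self.fixed_rule]
        return {self.fixed_rule: rule}

    @property
    def conditions(self) -> list:
        return ["maintenance"] + [f"categorization-{r}" for r in self.rules]


def epoch_steps(config: NetworkConfig) -> dict:
    """Ordered (start, stop) step ranges per epoch for this output mode."""
    names = list(config.epochs_ms)
    if config.output_mode == "rnn2":
        names = [n for n in names if not n.startswith("option")]
    out, t = {}, 0
    step_ms = config.dt * 1000.0
    for n in names:
        k = int(round(config.epochs_ms[n] / step_ms))
        out[n] = (t, t + k)
        t += k
    out["_total"] = t
    return out


def _compressed_epochs():
    """CPU-scale trial schedule: same event order, shorter main delay.

    The 600 ms delay is still six membrane time constants, so rate decay
    alone cannot bridge it and maintenance must be learned.
    """
    return {
        "sample1": 250, "isi1": 100, "sample2": 250, "retro_cue": 100,
        "delay1": 300, "task_cue": 100, "delay2": 600,
        "option1": 200, "option2": 200, "test": 500,
    }


_PRESETS = {
    # full scale mirrors the printed hyperparameters
    "full": {},
    # desk scale: fits single-CPU training runs (minutes per network)
    "desk": {
        "units_per_module": 60, "max_iter": 3000, "batch_per_condition": 64,
        "dt": 0.020, "input_sigma": 15.0, "epochs_ms": _compressed_epochs(),
    },
    # micro scale for multi-seed directional sweeps
    "micro": {
        "units_per_module": 40, "max_iter": 2500, "batch_per_condition": 64,
        "dt": 0.020, "input_sigma": 15.0, "epochs_ms": _compressed_epochs(),
    },
}


def network_config(preset: str = "desk", **overrides) -> NetworkConfig:
    """Named presets: "full", "desk" (default), "micro"."""
    if preset not in _PRESETS:
        raise KeyError(f"unknown preset {preset!r}; options: {sorted(_PRESETS)}")
    kw = dict(_PRESETS[preset])
    kw.update(overrides)
    return NetworkConfig(**kw)
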