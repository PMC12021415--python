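import numpy as np
import pytest

from flexwm import synthetic_bold as sb
from flexwm import task_design as td


@pytest.fixture(scope="session")
def small_design():
    """90-trial flexible-rule design (30 per condition, 5 runs)."""
    return td.generate_design(1, seed=7, trials_per_condition=30)


@pytest.fixture(scope="session")
def noiseless_dataset(small_design):
    """Zero-noise dataset with equal gains: every analysis oracle holds exactly."""
    prof = sb.region_profile("IPS-like", noise_sd=0.0)
    pop = sb.make_population(60, prof, seed=11)
    return sb.simulate_bold(pop, small_design, seed=12)


@pytest.fixture(scope="session")
def noisy_dataset(small_design):
    prof = sb.region_profile("sPCS-like", noise_sd=1.0)
    pop = sb.make_population(60, prof, seed=21)
    return sb.simulate_bold(pop, small_design, seed=22)


@pytest.fixture(scope="session")
def grid30():
    return td.sample_orientations(4, 6, 30)


@pytest.fixture(scope="session")
def rdm_dataset():
    """Two trials per orientation per condition, mild noise: RDM-ready."""
    design = td.generate_design(1, seed=17, trials_per_condition=60)
    prof = sb.region_profile("IPS-like", noise_sd=0.2)
    pop = sb.make_population(60, prof, seed=17)
    return sb.simulate_bold(pop, design, seed=18)
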