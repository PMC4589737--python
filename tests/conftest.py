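import numpy as np
import pytest

from multihill import (
    DoseResponseDataset,
    HillPhase,
    MultiphasicModel,
    simulate_curve,
)

NINE_POINT_GRID = np.logspace(-2.0, 2.0, 9)


@pytest.fixture
def mono_model():
    return MultiphasicModel([HillPhase(ec50=1.0, h=1.5, e_inf=0.1)])


@pytest.fixture
def biphasic_2i_model():
    return MultiphasicModel(
        [HillPhase(ec50=0.01, h=2.0, e_inf=0.5), HillPhase(ec50=10.0, h=2.0, e_inf=0.1)]
    )


@pytest.fixture
def hormetic_model():
    return MultiphasicModel(
        [HillPhase(ec50=0.01, h=2.0, e_inf=1.4), HillPhase(ec50=10.0, h=2.0, e_inf=0.05)]
    )


@pytest.fixture
def noisy_mono_dataset(mono_model):
    return simulate_curve(
        mono_model, NINE_POINT_GRID, n_replicates=3, sigma=0.05, seed=42
    )


def random_model(rng, n_phases=None, allow_stimulatory=True):
    """A random valid model spanning several decades, for property checks."""
    if n_phases is None:
        n_phases = int(rng.integers(1, 4))
    phases = []
    lec = rng.uniform(-3.0, 1.0)
    for i in range(n_phases):
        role_stim = allow_stimulatory and i == 0 and n_phases > 1 and rng.random() < 0.5
        e_inf = rng.uniform(1.1, 1.6) if role_stim else rng.uniform(0.0, 0.6)
        phases.append(
            HillPhase(ec50=10.0**lec, h=rng.uniform(0.5, 4.0), e_inf=e_inf)
        )
        lec += rng.uniform(1.0, 2.0)
    return MultiphasicModel(phases, baseline_scale=1.0)


def random_dataset(rng, p=7, n_rep=3):
    conc = np.logspace(-2, 2, p)
    effects = rng.uniform(0.0, 1.3, size=(p, n_rep))
    return DoseResponseDataset(concentrations=conc, effects=effects)
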