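"""Synthetic dose-response data: single curves, whole screens, reference shapes.

The generator draws curves from known multiphasic models and adds
Gaussian measurement noise with a per-concentration standard deviation,
matching the noise model the weighted objective assumes.  Effects are
truncated at zero from below (a viability readout cannot be negative),
which slightly biases noise near complete inhibition.  Screens mix the
four searched phase classes in chosen proportions and ship a truth
table so classification accuracy can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    ConfigLabel,
    HillPhase,
    MultiphasicModel,
    PhaseRole,
    eval_model,
    make_configuration,
)
from .objective import DoseResponseDataset
from .selection import CLASS_LABELS

__all__ = [
    "ScreenRanges",
    "DEFAULT_CONCENTRATIONS",
    "simulate_curve",
    "simulate_screen",
    "reference_shapes",
]

#: default tested grid: 11 concentrations spanning 5 decades, half-decade
#: steps — wide enough that three phases separated by 1.5 decades all
#: complete their transitions inside the window
DEFAULT_CONCENTRATIONS = np.logspace(-3.0, 2.0, 11)


@dataclass(frozen=True)
class ScreenRanges:
    """Parameter ranges for screen simulation.

    EC50s are drawn uniformly in log10 space inside the interior of the
    tested range (``edge_margin`` decades from each end, so every
    transition is actually observable) with at least ``min_separation``
    decades between consecutive phases, keeping generated phases
    visually distinct.  The
    terminal (highest-EC50) inhibitory phase draws its asymptote from
    ``inhibitory_e_inf``; intermediate inhibitory phases use
    ``intermediate_e_inf`` so the plateau between inhibitory
    transitions actually shows.  Stimulatory asymptotes give hormetic
    peaks clearly above baseline.
    """

    h: tuple[float, float] = (0.5, 4.0)
    inhibitory_e_inf: tuple[float, float] = (0.0, 0.4)
    intermediate_e_inf: tuple[float, float] = (0.35, 0.65)
    stimulatory_e_inf: tuple[float, float] = (1.2, 1.6)
    min_separation: float = 1.5
    edge_margin: float = 0.5


def simulate_curve(
    model: MultiphasicModel,
    concentrations=DEFAULT_CONCENTRATIONS,
    n_replicates: int = 3,
    sigma: float = 0.05,
    seed: int = 0,
    sigma_known: bool = False,
    title: str = "",
    unit: str = "uM",
) -> DoseResponseDataset:
    """Noisy replicate measurements of a known model.

    Gaussian noise of sd ``sigma`` is added independently to every cell
    and truncated at 0 from below; ``sigma=0`` returns the exact curve.
    With ``sigma_known=True`` the true sigma is stored on the dataset
    (so weighting does not need to estimate it from replicates).  The
    generating model is recorded on the dataset for recovery tests.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    conc = np.asarray(concentrations, dtype=float)
    truth = eval_model(model, conc)
    rng = np.random.default_rng(seed)
    effects = truth[:, None] + rng.normal(0.0, sigma, size=(conc.size, n_replicates))
    effects = np.clip(effects, 0.0, None) if sigma > 0 else np.tile(
        truth[:, None], (1, n_replicates)
    )
    ds = DoseResponseDataset(
        concentrations=conc,
        effects=effects,
        sigma=np.full(conc.size, sigma) if (sigma_known and sigma > 0) else None,
        unit=unit,
        title=title,
        generating_model=model,
    )
    return ds


def draw_model(
    label: ConfigLabel | str,
    rng: np.random.Generator,
    concentrations=DEFAULT_CONCENTRATIONS,
    ranges: ScreenRanges = ScreenRanges(),
) -> MultiphasicModel:
    """Draw one random model of the given class within the screen ranges."""
    config = make_configuration(label)
    conc = np.asarray(concentrations, dtype=float)
    pos = conc[conc > 0]
    lo = np.log10(pos.min()) + ranges.edge_margin
    hi = np.log10(pos.max()) - ranges.edge_margin
    k = config.n_phases
    sep = ranges.min_separation
    if hi - lo < sep * (k - 1):
        raise ValueError(
            f"usable range of {hi - lo:.2f} decades cannot hold {k} phases "
            f"separated by {sep} decades"
        )
    lecs = []
    prev = None
    for i in range(k):
        low = lo if prev is None else prev + sep
        high = hi - sep * (k - 1 - i)
        lec = float(rng.uniform(low, high))
        lecs.append(lec)
        prev = lec
    inh_slots = [i for i, r in enumerate(config.roles) if r is PhaseRole.INHIBITORY]
    phases = []
    for i, role in enumerate(config.roles):
        h = float(rng.uniform(*ranges.h))
        if role is PhaseRole.STIMULATORY:
            e_inf = float(rng.uniform(*ranges.stimulatory_e_inf))
        elif i == inh_slots[-1]:
            e_inf = float(rng.uniform(*ranges.inhibitory_e_inf))
        else:
            e_inf = float(rng.uniform(*ranges.intermediate_e_inf))
        phases.append(HillPhase(ec50=10.0 ** lecs[i], h=h, e_inf=e_inf))
    return MultiphasicModel(phases)


def _allocate_counts(n_curves: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n_curves into exact class counts."""
    props = np.asarray(proportions, dtype=float)
    raw = props * n_curves
    counts = np.floor(raw).astype(int)
    rem = n_curves - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in order[:rem]:
        counts[i] += 1
    return counts.tolist()


def simulate_screen(
    n_curves: int,
    proportions: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    concentrations=DEFAULT_CONCENTRATIONS,
    n_replicates: int = 3,
    sigma: float = 0.05,
    ranges: ScreenRanges = ScreenRanges(),
    seed: int = 0,
    exact_counts: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A simulated screen of dose-response curves with known classes.

    ``proportions`` orders the classes as HILL_1I, BIPHASIC_2I,
    BIPHASIC_1S1I, TRIPHASIC_1S2I and must sum to 1.  Class labels are
    drawn multinomially, or allocated exactly (largest remainder, then
    shuffled) with ``exact_counts=True``.  Returns a long-format table
    (``curve_id, concentration, replicate_id, effect``) ready for batch
    fitting, plus a truth table (``curve_id, label, phase_class,
    parameters``) for scoring.
    """
    props = np.asarray(proportions, dtype=float)
    if props.size != 4 or not np.isclose(props.sum(), 1.0):
        raise ValueError("proportions must be 4 values summing to 1")
    labels_pool = list(ConfigLabel)
    rng = np.random.default_rng(seed)
    if exact_counts:
        counts = _allocate_counts(n_curves, props)
        labels = [lab for lab, c in zip(labels_pool, counts) for _ in range(c)]
        rng.shuffle(labels)
    else:
        idx = rng.choice(len(labels_pool), size=n_curves, p=props)
        labels = [labels_pool[i] for i in idx]

    long_rows = []
    truth_rows = []
    conc = np.asarray(concentrations, dtype=float)
    for idx, label in enumerate(labels):
        cid = f"curve{idx:04d}"
        model = draw_model(label, rng, conc, ranges)
        curve_seed = int(rng.integers(0, 2**31 - 1))
        ds = simulate_curve(
            model, conc, n_replicates=n_replicates, sigma=sigma, seed=curve_seed
        )
        for j, c in enumerate(conc):
            for r in range(n_replicates):
                long_rows.append((cid, c, r + 1, ds.effects[j, r]))
        params = "|".join(
            f"{p.role.value[0]}:ec50={p.ec50:.6g},h={p.h:.4g},e_inf={p.e_inf:.4g}"
            for p in model.phases
        )
        truth_rows.append((cid, label.value, CLASS_LABELS[label], params))
    long_df = pd.DataFrame(
        long_rows, columns=["curve_id", "concentration", "replicate_id", "effect"]
    )
    truth_df = pd.DataFrame(
        truth_rows, columns=["curve_id", "label", "phase_class", "parameters"]
    )
    return long_df, truth_df


def reference_shapes() -> dict[str, MultiphasicModel]:
    """Canonical fixture models, one per qualitative multiphasic shape:
    two inhibitory phases with an intermediate plateau; a hormetic rise
    before inhibition; both combined; and a five-phase curve (two
    stimulatory + three inhibitory) showing the model's generality."""
    return {
        "two_inhibitory": MultiphasicModel(
            [
                HillPhase(ec50=1e-2, h=2.0, e_inf=0.5),
                HillPhase(ec50=1e1, h=2.0, e_inf=0.1),
            ]
        ),
        "stimulatory_inhibitory": MultiphasicModel(
            [
                HillPhase(ec50=3e-2, h=2.0, e_inf=1.4),
                HillPhase(ec50=3e0, h=2.0, e_inf=0.05),
            ]
        ),
        "stimulatory_two_inhibitory": MultiphasicModel(
            [
                HillPhase(ec50=3e-3, h=2.0, e_inf=1.3),
                HillPhase(ec50=3e-1, h=2.0, e_inf=0.5),
                HillPhase(ec50=3e1, h=2.0, e_inf=0.1),
            ]
        ),
        "five_phase": MultiphasicModel(
            [
                HillPhase(ec50=1e-4, h=2.0, e_inf=1.3),
                HillPhase(ec50=1e-2, h=3.0, e_inf=0.45),
                HillPhase(ec50=1e0, h=3.0, e_inf=1.35),
                HillPhase(ec50=1e2, h=3.0, e_inf=0.5),
                HillPhase(ec50=1e4, h=3.0, e_inf=0.05),
            ]
        ),
    }
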