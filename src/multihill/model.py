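"""Multiphasic dose-response model built from independent Hill phases.

A dose-response curve is modelled as the product of one or more Hill
terms, each describing a single underlying dose-dependent process
("phase").  On the normalized response scale (baseline = 1, complete
inhibition = 0) a phase with midpoint ``ec50``, slope ``h`` and
asymptote ``e_inf`` contributes

    E_i(C) = e_inf + (1 - e_inf) / (1 + (C / ec50)^h)

and the full model is ``E(C) = baseline_scale * prod_i E_i(C)``, the
Bliss-independence composition of the phases: processes that converge
independently on the same phenotype multiply on the fractional-response
scale.  A phase is *inhibitory* when ``e_inf < 1``, *stimulatory*
(hormetic) when ``e_inf > 1``, and an *identity* phase (``e_inf = 1``)
contributes a constant factor of 1, which is how simpler models are
embedded in the richest parameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np

__all__ = [
    "PhaseRole",
    "HillPhase",
    "MultiphasicModel",
    "ConfigLabel",
    "PhaseConfiguration",
    "eval_phase",
    "eval_model",
    "make_configuration",
]


class PhaseRole(str, Enum):
    """Role of a phase, determined by where its asymptote sits relative to baseline."""

    INHIBITORY = "inhibitory"
    STIMULATORY = "stimulatory"
    IDENTITY = "identity"


# sort order for ec50 ties: stimulatory phases come first
_ROLE_RANK = {PhaseRole.STIMULATORY: 0, PhaseRole.IDENTITY: 1, PhaseRole.INHIBITORY: 2}


@dataclass(frozen=True)
class HillPhase:
    """One Hill term: midpoint ``ec50`` (> 0, data units), slope ``h`` (> 0),
    asymptote ``e_inf`` (>= 0, dimensionless, baseline = 1)."""

    ec50: float
    h: float
    e_inf: float

    def __post_init__(self) -> None:
        for name in ("ec50", "h", "e_inf"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"{name} must be a finite number, got {v!r}")
        if self.ec50 <= 0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if self.h <= 0:
            raise ValueError(f"h must be > 0, got {self.h}")
        if self.e_inf < 0:
            raise ValueError(f"e_inf must be >= 0, got {self.e_inf}")

    @property
    def role(self) -> PhaseRole:
        if self.e_inf == 1.0:
            return PhaseRole.IDENTITY
        return PhaseRole.STIMULATORY if self.e_inf > 1.0 else PhaseRole.INHIBITORY

    def __call__(self, c):
        return eval_phase(self, c)


def eval_phase(phase: HillPhase, c):
    """Evaluate a single Hill phase at concentration(s) ``c`` (>= 0).

    Returns exactly 1 at c = 0 (the zero-dose limit, avoiding the 0^h
    ambiguity) and tends to ``e_inf`` as c grows.
    """
    arr = np.asarray(c, dtype=float)
    if np.any(arr < 0):
        raise ValueError("concentrations must be nonnegative")
    with np.errstate(over="ignore"):
        ratio = np.where(arr > 0, (arr / phase.ec50) ** phase.h, 0.0)
    out = phase.e_inf + (1.0 - phase.e_inf) / (1.0 + ratio)
    if np.ndim(c) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class MultiphasicModel:
    """Ordered product of Hill phases with an optional baseline factor.

    Phases are stored sorted by ascending ec50 (stimulatory first on
    ties) so that "the first inhibitory phase" has a stable meaning in
    reports.  ``baseline_scale`` is a positive factor applied to the
    whole product; it absorbs modest control-normalization error and is
    1 on perfectly normalized data, so ``E(0) = baseline_scale``.
    """

    phases: tuple[HillPhase, ...]
    baseline_scale: float = 1.0

    def __init__(self, phases: Iterable[HillPhase], baseline_scale: float = 1.0):
        phases = tuple(sorted(phases, key=lambda p: (p.ec50, _ROLE_RANK[p.role])))
        if not phases:
            raise ValueError("a model needs at least one phase")
        if not (math.isfinite(baseline_scale) and baseline_scale > 0):
            raise ValueError(f"baseline_scale must be > 0, got {baseline_scale}")
        object.__setattr__(self, "phases", phases)
        object.__setattr__(self, "baseline_scale", float(baseline_scale))

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def __call__(self, c):
        return eval_model(self, c)


def eval_model(model: MultiphasicModel, c):
    """Evaluate the full model: baseline_scale times the product of all phases."""
    arr = np.asarray(c, dtype=float)
    out = np.full(arr.shape, model.baseline_scale, dtype=float)
    for phase in model.phases:
        out = out * eval_phase(phase, arr)
    if np.ndim(c) == 0:
        return float(out)
    return out


class ConfigLabel(str, Enum):
    """The four candidate phase configurations searched by the automated procedure."""

    HILL_1I = "HILL_1I"
    BIPHASIC_2I = "BIPHASIC_2I"
    BIPHASIC_1S1I = "BIPHASIC_1S1I"
    TRIPHASIC_1S2I = "TRIPHASIC_1S2I"


_CONFIG_ROLES: dict[ConfigLabel, tuple[PhaseRole, ...]] = {
    ConfigLabel.HILL_1I: (PhaseRole.INHIBITORY,),
    ConfigLabel.BIPHASIC_2I: (PhaseRole.INHIBITORY, PhaseRole.INHIBITORY),
    ConfigLabel.BIPHASIC_1S1I: (PhaseRole.STIMULATORY, PhaseRole.INHIBITORY),
    ConfigLabel.TRIPHASIC_1S2I: (
        PhaseRole.STIMULATORY,
        PhaseRole.INHIBITORY,
        PhaseRole.INHIBITORY,
    ),
}


@dataclass(frozen=True)
class PhaseConfiguration:
    """A candidate model structure: how many phases, their roles, and
    whether the baseline factor is free.  Each phase contributes 3 free
    parameters (ec50, h, e_inf); a free baseline adds one more."""

    label: ConfigLabel
    roles: tuple[PhaseRole, ...]
    baseline_free: bool = False

    @property
    def n_phases(self) -> int:
        return len(self.roles)

    @property
    def n_free_params(self) -> int:
        return 3 * self.n_phases + (1 if self.baseline_free else 0)


def make_configuration(
    label: ConfigLabel | str, baseline_free: bool = False
) -> PhaseConfiguration:
    """Return the phase configuration for one of the four searched labels."""
    try:
        label = ConfigLabel(label)
    except ValueError as exc:
        raise ValueError(
            f"unknown configuration label {label!r}; expected one of "
            f"{[l.value for l in ConfigLabel]}"
        ) from exc
    return PhaseConfiguration(
        label=label, roles=_CONFIG_ROLES[label], baseline_free=baseline_free
    )
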