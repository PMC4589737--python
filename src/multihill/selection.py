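"""Automated model selection over the four candidate configurations.

The procedure fits, in order, the monophasic Hill model, the two
inhibitory-process model, the stimulatory + inhibitory model and the
triphasic (one stimulatory + two inhibitory) model, then ranks the four
candidates by BIC (AIC optionally) and proposes the lowest-scoring one.
BIC's stronger complexity penalty makes the procedure conservative:
simpler models win unless an extra phase buys a real improvement in F.

Reduced models are the richest parameterization with surplus phases
fixed to the identity (ec50 = h = e_inf = 1, a constant factor of 1);
operationally each configuration is fitted in its own free-parameter
space, and each richer candidate is additionally warm-started from the
best simpler fit with its extra phases placed near identity, which
keeps the nested-F property (richer candidates never fit worse) in
practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fitters import (
    FitResult,
    FitSettings,
    _log_range,
    _logit,
    fit,
    pack_parameters,
)
from .model import (
    ConfigLabel,
    MultiphasicModel,
    PhaseConfiguration,
    PhaseRole,
    make_configuration,
)
from .objective import DoseResponseDataset

__all__ = ["SelectionReport", "select_model", "classify", "CANDIDATE_ORDER", "CLASS_LABELS"]

#: the order in which candidates are attempted
CANDIDATE_ORDER = (
    ConfigLabel.HILL_1I,
    ConfigLabel.BIPHASIC_2I,
    ConfigLabel.BIPHASIC_1S1I,
    ConfigLabel.TRIPHASIC_1S2I,
)

CLASS_LABELS = {
    ConfigLabel.HILL_1I: "monophasic",
    ConfigLabel.BIPHASIC_2I: "biphasic_two_inhibitory",
    ConfigLabel.BIPHASIC_1S1I: "biphasic_stimulatory",
    ConfigLabel.TRIPHASIC_1S2I: "triphasic",
}

# sigmoid coordinate for a phase parked (numerically) at the identity
_NEAR_IDENTITY_U = 13.0


@dataclass(frozen=True)
class SelectionReport:
    """The four candidate fits, their ranking, and the winner."""

    candidates: dict[ConfigLabel, Optional[FitResult]]
    ranking: tuple[ConfigLabel, ...]
    best: ConfigLabel
    ranking_criterion: str
    flags: dict[ConfigLabel, tuple[str, ...]]

    @property
    def best_fit(self) -> FitResult:
        return self.candidates[self.best]


def _near_identity_phase(role: PhaseRole, log_ec50: float) -> tuple[float, float, float]:
    """(log10 ec50, ln h, u) for a phase whose factor is ~1 everywhere."""
    u = _NEAR_IDENTITY_U if role is PhaseRole.INHIBITORY else -_NEAR_IDENTITY_U
    return (log_ec50, 0.0, u)


def _warm_start(
    simpler: FitResult,
    target: PhaseConfiguration,
    dataset: DoseResponseDataset,
    settings: FitSettings,
) -> Optional[np.ndarray]:
    """Embed a simpler fitted model into a richer configuration's
    parameter space, parking the extra phases near the identity."""
    lo, hi = _log_range(dataset)
    src = simpler.configuration
    have = {PhaseRole.STIMULATORY: [], PhaseRole.INHIBITORY: []}
    for ph in simpler.model.phases:
        if ph.role in have:
            have[ph.role].append(ph)
    need = {
        r: sum(rr is r for rr in target.roles) - len(have[r])
        for r in (PhaseRole.STIMULATORY, PhaseRole.INHIBITORY)
    }
    if any(n < 0 for n in need.values()):
        return None
    lecs = [np.log10(ph.ec50) for ph in simpler.model.phases]
    # extra stimulatory phase sits below the existing phases, extra
    # inhibitory ones above, preserving the role/ec50 ordering
    fill = dict(have)
    for _ in range(need[PhaseRole.STIMULATORY]):
        fill[PhaseRole.STIMULATORY] = [None] + fill[PhaseRole.STIMULATORY]
    theta = np.empty(target.n_free_params)
    stim_iter = iter(fill[PhaseRole.STIMULATORY])
    inh_pool = list(have[PhaseRole.INHIBITORY])
    lo_anchor = min(lecs) - 1.0 if lecs else lo
    hi_anchor = max(lecs) + 1.5 if lecs else hi
    for i, role in enumerate(target.roles):
        if role is PhaseRole.STIMULATORY:
            ph = next(stim_iter, None)
            if ph is None:
                theta[3 * i : 3 * i + 3] = _near_identity_phase(
                    role, max(lo - 5.0, lo_anchor)
                )
                continue
        else:
            ph = inh_pool.pop(0) if inh_pool else None
            if ph is None:
                theta[3 * i : 3 * i + 3] = _near_identity_phase(
                    role, min(hi + 5.0, hi_anchor)
                )
                continue
        one = MultiphasicModel([ph])
        cfg_one = PhaseConfiguration(label=src.label, roles=(role,))
        theta[3 * i : 3 * i + 3] = pack_parameters(one, cfg_one, settings)[:3]
    if target.baseline_free:
        if src.baseline_free:
            theta[-1] = pack_parameters(simpler.model, src, settings)[-1]
        else:
            theta[-1] = _logit((1.0 - 0.5) / 1.5)  # baseline_scale = 1
    return theta


def _degeneracy_flags(
    result: FitResult,
    dataset: DoseResponseDataset,
    simpler: list[FitResult],
) -> tuple[str, ...]:
    """Spot candidates that converged to something effectively simpler:
    a phase parked at the identity, a phase pushed far outside the
    tested range, or (e.g. a mutually cancelling stimulatory/inhibitory
    pair) a fitted curve indistinguishable from a simpler candidate's
    on the tested grid."""
    lo, hi = _log_range(dataset)
    flags = []
    for i, ph in enumerate(result.model.phases):
        if abs(ph.e_inf - 1.0) < 1e-3:
            flags.append(f"phase{i + 1}_near_identity")
        lec = np.log10(ph.ec50)
        if lec < lo - 3.0 or lec > hi + 3.0:
            flags.append(f"phase{i + 1}_ec50_outside_tested_range")
    grid = np.logspace(lo, hi, 101)
    pred = result.model(grid)
    for other in simpler:
        if np.max(np.abs(pred - other.model(grid))) < 1e-3:
            flags.append(f"curve_matches_{other.configuration.label.value}")
            break
    if flags:
        flags.append("effectively_simpler")
    return tuple(flags)


def select_model(
    dataset: DoseResponseDataset,
    settings: Optional[FitSettings] = None,
    weighting: str = "sd",
    criterion: str = "bic",
    baseline_free: bool = False,
) -> SelectionReport:
    """Fit all four candidate configurations and rank them.

    Ranking is by ascending BIC (or AIC); exact ties break toward fewer
    free parameters, then toward the earlier candidate in the search
    order.  A candidate whose fit raises is excluded from the ranking
    with a warning; if all four fail a RuntimeError is raised.
    """
    if criterion not in ("bic", "aic"):
        raise ValueError(f"criterion must be 'bic' or 'aic', got {criterion!r}")
    settings = settings if settings is not None else FitSettings()

    candidates: dict[ConfigLabel, Optional[FitResult]] = {}
    flags: dict[ConfigLabel, tuple[str, ...]] = {}
    for label in CANDIDATE_ORDER:
        config = make_configuration(label, baseline_free=baseline_free)
        warm: list[np.ndarray] = []
        for src_label in CANDIDATE_ORDER:
            if src_label is label:
                break
            src = candidates.get(src_label)
            if src is None:
                continue
            th = _warm_start(src, config, dataset, settings)
            if th is not None:
                warm.append(th)
        try:
            result = fit(
                dataset, config, settings, weighting=weighting, extra_starts=warm
            )
        except Exception as exc:  # failure isolation: keep ranking the rest
            warnings.warn(f"candidate {label.value} failed to fit: {exc}", stacklevel=2)
            candidates[label] = None
            flags[label] = ("fit_failed",)
            continue
        candidates[label] = result
        simpler = [
            candidates[l]
            for l in CANDIDATE_ORDER
            if candidates.get(l) is not None
            and candidates[l].configuration.n_free_params
            < config.n_free_params
        ]
        flags[label] = _degeneracy_flags(result, dataset, simpler)

    fitted = [lab for lab in CANDIDATE_ORDER if candidates[lab] is not None]
    if not fitted:
        raise RuntimeError("all four candidate fits failed")

    def score(lab: ConfigLabel) -> float:
        st = candidates[lab].stats
        return st.bic if criterion == "bic" else st.aic

    order_idx = {lab: i for i, lab in enumerate(CANDIDATE_ORDER)}
    ranking = tuple(
        sorted(
            fitted,
            key=lambda lab: (
                score(lab),
                candidates[lab].configuration.n_free_params,
                order_idx[lab],
            ),
        )
    )
    return SelectionReport(
        candidates=candidates,
        ranking=ranking,
        best=ranking[0],
        ranking_criterion=criterion,
        flags=flags,
    )


def classify(report: SelectionReport) -> str:
    """Map the winning configuration to its phase-class label."""
    return CLASS_LABELS[report.best]
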