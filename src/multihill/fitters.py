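"""Parameter estimation: multi-start minimization of F with three optimizers.

Three optimizers are available, all minimizing the same objective F:

* ``simplex`` — derivative-free Nelder-Mead downhill simplex on the
  transformed parameters;
* ``simplex_constrained`` — the same simplex plus a soft penalty that
  keeps consecutive phases well separated in log-concentration space
  (no overlap of processes);
* ``trust_region`` — trust-region-reflective bounded least squares on
  the sqrt-weight-scaled residual vector, whose implicit objective
  equals F exactly since F is a sum of squares.

Because the multiphasic F surface is multimodal, every fit runs from a
deterministic list of starts: log-EC50s placed at quantiles of the
tested log-concentration range (ordered and separated for multi-phase
configurations), Hill slopes at 1, asymptotes seeded from the data, and
seeded jitter across the remaining starts.

Internally ec50 is parameterized as log10(ec50) and h as log(h) so
positivity needs no hard bounds; asymptotes are mapped through a
sigmoid into [0, 1) for inhibitory phases and (1, e_inf_max] for
stimulatory ones, which keeps every iterate in the interpretable
regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize as _opt

from .model import (
    HillPhase,
    MultiphasicModel,
    PhaseConfiguration,
    PhaseRole,
    eval_model,
)
from .objective import (
    DoseResponseDataset,
    FitStatistics,
    ensure_sigma,
    fit_statistics,
    objective_f,
)

__all__ = [
    "FitSettings",
    "FitResult",
    "initial_guesses",
    "fit",
    "separation_penalty",
    "pack_parameters",
    "unpack_parameters",
]

_U_LIM = 14.0  # bound on the sigmoid coordinate for asymptotes/baseline
_LNH_LO, _LNH_HI = np.log(0.05), np.log(20.0)
_PENALTY_SCALE = 1e6
_BASELINE_LO, _BASELINE_HI = 0.5, 2.0


@dataclass
class FitSettings:
    """Optimizer choice, multi-start count, tolerances and seeds."""

    optimizer: str = "trust_region"
    n_starts: int = 10
    max_iter: int = 2000
    tol_f: float = 1e-8
    tol_x: float = 1e-8
    separation_delta: float = 0.5
    seed: int = 0
    e_inf_max: float = 5.0

    def __post_init__(self) -> None:
        if self.optimizer not in ("simplex", "simplex_constrained", "trust_region"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.n_starts < 1 or self.separation_delta < 0:
            raise ValueError("n_starts >= 1 and separation_delta >= 0 required")
        if self.tol_f <= 0 or self.tol_x <= 0:
            raise ValueError("tolerances must be positive")
        if self.e_inf_max <= 1:
            raise ValueError("e_inf_max must exceed 1")


@dataclass(frozen=True)
class FitResult:
    """Best model found for one configuration, with its statistics."""

    model: MultiphasicModel
    configuration: PhaseConfiguration
    stats: FitStatistics
    converged: bool
    n_evals: int
    start_index: int


def _sigmoid(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-u))


def _logit(x: float) -> float:
    x = min(max(x, 1e-12), 1.0 - 1e-12)
    return float(np.log(x / (1.0 - x)))


def unpack_parameters(
    theta: np.ndarray, configuration: PhaseConfiguration, settings: FitSettings
) -> MultiphasicModel:
    """Map a free-parameter vector to a model.

    Layout: per phase (log10 ec50, ln h, u) with e_inf = sigmoid(u) for
    inhibitory phases and 1 + (e_inf_max - 1)·sigmoid(u) for stimulatory
    ones; a trailing coordinate maps to baseline_scale in [0.5, 2] when
    the baseline is free.
    """
    theta = np.asarray(theta, dtype=float)
    phases = []
    for i, role in enumerate(configuration.roles):
        lec, lnh, u = theta[3 * i : 3 * i + 3]
        if role is PhaseRole.STIMULATORY:
            e_inf = 1.0 + (settings.e_inf_max - 1.0) * float(_sigmoid(u))
        else:
            e_inf = float(_sigmoid(u))
        phases.append(HillPhase(ec50=10.0**lec, h=float(np.exp(lnh)), e_inf=e_inf))
    baseline = 1.0
    if configuration.baseline_free:
        baseline = _BASELINE_LO + (_BASELINE_HI - _BASELINE_LO) * float(
            _sigmoid(theta[-1])
        )
    return MultiphasicModel(phases, baseline_scale=baseline)


def pack_parameters(
    model: MultiphasicModel, configuration: PhaseConfiguration, settings: FitSettings
) -> np.ndarray:
    """Inverse of :func:`unpack_parameters`, matching phases to role slots
    by role and ascending ec50."""
    by_role: dict[PhaseRole, list[HillPhase]] = {r: [] for r in PhaseRole}
    for ph in model.phases:
        by_role[ph.role].append(ph)
    theta = np.empty(configuration.n_free_params)
    for i, role in enumerate(configuration.roles):
        pool = by_role[role] or by_role[PhaseRole.IDENTITY]
        if not pool:
            raise ValueError(f"model has no phase to fill {role.value} slot {i}")
        ph = pool.pop(0)
        if role is PhaseRole.STIMULATORY:
            u = _logit((ph.e_inf - 1.0) / (settings.e_inf_max - 1.0))
        else:
            u = _logit(min(ph.e_inf, 1.0 - 1e-9))
        theta[3 * i : 3 * i + 3] = (
            np.log10(ph.ec50),
            np.clip(np.log(ph.h), _LNH_LO, _LNH_HI),
            np.clip(u, -_U_LIM, _U_LIM),
        )
    if configuration.baseline_free:
        frac = (model.baseline_scale - _BASELINE_LO) / (_BASELINE_HI - _BASELINE_LO)
        theta[-1] = np.clip(_logit(frac), -_U_LIM, _U_LIM)
    return theta


def _log_range(dataset: DoseResponseDataset) -> tuple[float, float]:
    pos = dataset.concentrations[dataset.concentrations > 0]
    if pos.size < 2:
        raise ValueError("need at least two positive concentrations")
    return float(np.log10(pos.min())), float(np.log10(pos.max()))


def _bounds(
    dataset: DoseResponseDataset, configuration: PhaseConfiguration, settings: FitSettings
) -> tuple[np.ndarray, np.ndarray]:
    lo_c, hi_c = _log_range(dataset)
    lb, ub = [], []
    for _ in configuration.roles:
        lb += [lo_c - 6.0, _LNH_LO, -_U_LIM]
        ub += [hi_c + 6.0, _LNH_HI, _U_LIM]
    if configuration.baseline_free:
        lb.append(-_U_LIM)
        ub.append(_U_LIM)
    return np.asarray(lb), np.asarray(ub)


def initial_guesses(
    dataset: DoseResponseDataset,
    configuration: PhaseConfiguration,
    settings: FitSettings,
) -> list[np.ndarray]:
    """Deterministic multi-start list (length ``n_starts``).

    Start 0 is the plain data-driven guess; later starts jitter it with
    a generator seeded from ``settings.seed``, keeping log-EC50s inside
    the tested range and in ascending order.
    """
    if dataset.n_concentrations < 3:
        raise ValueError("need at least 3 concentrations to fit")
    lo, hi = _log_range(dataset)
    rng = np.random.default_rng(settings.seed)
    k = configuration.n_phases
    mean_eff = np.nanmean(dataset.effects, axis=1)
    m_hi = float(np.clip(mean_eff[-1], 1e-3, 0.95))
    m_max = float(np.nanmax(mean_eff))

    base_lec = lo + (hi - lo) * (np.arange(1, k + 1) / (k + 1))
    n_inh = sum(r is PhaseRole.INHIBITORY for r in configuration.roles)
    e_inh = m_hi ** (1.0 / max(n_inh, 1))
    e_stim = float(np.clip(max(m_max, 1.2), 1.05, settings.e_inf_max - 1e-3))

    base = np.empty(configuration.n_free_params)
    for i, role in enumerate(configuration.roles):
        if role is PhaseRole.STIMULATORY:
            u = _logit((e_stim - 1.0) / (settings.e_inf_max - 1.0))
        else:
            u = _logit(e_inh)
        base[3 * i : 3 * i + 3] = (base_lec[i], 0.0, u)
    if configuration.baseline_free:
        base[-1] = _logit((1.0 - _BASELINE_LO) / (_BASELINE_HI - _BASELINE_LO))

    starts = [base.copy()]
    for _ in range(settings.n_starts - 1):
        th = base.copy()
        lec = base_lec + rng.normal(0.0, 0.4, size=k)
        lec = np.clip(np.sort(lec), lo, hi)
        # keep strict ascending order after clipping, staying inside [lo, hi]
        for i in range(k - 2, -1, -1):
            lec[i] = min(lec[i], lec[i + 1] - 1e-3)
        for i in range(k):
            th[3 * i] = lec[i]
            th[3 * i + 1] = np.clip(rng.normal(0.0, 0.3), _LNH_LO, _LNH_HI)
            th[3 * i + 2] = np.clip(
                base[3 * i + 2] + rng.normal(0.0, 0.75), -_U_LIM, _U_LIM
            )
        if configuration.baseline_free:
            th[-1] = np.clip(base[-1] + rng.normal(0.0, 0.3), -_U_LIM, _U_LIM)
        starts.append(th)
    return starts


def separation_penalty(model: MultiphasicModel, settings: FitSettings) -> float:
    """Soft non-overlap constraint: zero when consecutive phases (by
    ec50) are at least ``separation_delta`` decades apart, otherwise a
    quadratic in the violation, scaled to dominate F near violation."""
    if model.n_phases < 2:
        return 0.0
    lecs = np.log10([p.ec50 for p in model.phases])
    gaps = np.diff(lecs)
    viol = np.maximum(0.0, settings.separation_delta - gaps)
    return float(_PENALTY_SCALE * np.sum(viol**2))


def fit(
    dataset: DoseResponseDataset,
    configuration: PhaseConfiguration,
    settings: Optional[FitSettings] = None,
    weighting: str = "sd",
    extra_starts: Optional[Sequence[np.ndarray]] = None,
) -> FitResult:
    """Fit one configuration by multi-start minimization of F.

    Returns the best result over all starts (plus any ``extra_starts``,
    e.g. warm starts from a simpler model).  If no start converges the
    best attempt is still returned with ``converged=False``.
    """
    settings = settings if settings is not None else FitSettings()
    if weighting == "sd":
        w = ensure_sigma(dataset)
    else:
        w = np.ones(dataset.n_concentrations)
    # when sd weighting had no replicate scatter to work with, the
    # weights are effectively unit and scores must profile the variance
    stats_weighting = (
        "unit" if (weighting == "sd" and dataset.sigma_fallback_unit) else weighting
    )

    mask = np.isfinite(dataset.effects)
    conc = dataset.concentrations
    effects = dataset.effects
    w_col = w[:, None]

    def residuals(theta: np.ndarray) -> np.ndarray:
        m = unpack_parameters(theta, configuration, settings)
        pred = eval_model(m, conc)
        r = (effects - pred[:, None]) / w_col
        return r[mask]

    def f_of(theta: np.ndarray) -> float:
        r = residuals(theta)
        return float(np.dot(r, r))

    penalized = settings.optimizer == "simplex_constrained"

    def nm_objective(theta: np.ndarray) -> float:
        val = f_of(theta)
        if penalized:
            m = unpack_parameters(theta, configuration, settings)
            val += separation_penalty(m, settings)
        return val

    starts = initial_guesses(dataset, configuration, settings)
    if extra_starts is not None:
        starts = starts + [np.asarray(t, dtype=float) for t in extra_starts]
    lb, ub = _bounds(dataset, configuration, settings)

    best_f = np.inf
    best_theta = None
    best_idx = -1
    best_ok = False
    n_evals = 0
    for idx, theta0 in enumerate(starts):
        t0 = np.clip(theta0, lb + 1e-9, ub - 1e-9)
        if settings.optimizer == "trust_region":
            res = _opt.least_squares(
                residuals,
                t0,
                bounds=(lb, ub),
                method="trf",
                xtol=settings.tol_x,
                ftol=settings.tol_f,
                gtol=1e-12,
                max_nfev=settings.max_iter,
            )
            theta, ok, nfev = res.x, res.status > 0, res.nfev
        else:
            res = _opt.minimize(
                nm_objective,
                t0,
                method="Nelder-Mead",
                options=dict(
                    maxiter=settings.max_iter,
                    maxfev=4 * settings.max_iter,
                    fatol=settings.tol_f,
                    xatol=settings.tol_x,
                ),
            )
            theta, ok, nfev = res.x, bool(res.success), res.nfev
        n_evals += int(nfev)
        f_val = f_of(theta)
        if f_val < best_f:
            best_f, best_theta, best_idx, best_ok = f_val, theta, idx, ok

    model = unpack_parameters(best_theta, configuration, settings)
    f_final = objective_f(model, dataset, weighting)  # self-consistency
    stats = fit_statistics(
        f_final, dataset.n_obs, configuration.n_free_params, stats_weighting
    )
    return FitResult(
        model=model,
        configuration=configuration,
        stats=stats,
        converged=best_ok,
        n_evals=n_evals,
        start_index=best_idx,
    )
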