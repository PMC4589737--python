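"""Weighted least-squares objective, goodness of fit and information criteria.

The fitting objective is

    F = sum_j sum_i ( E_exp,i(c_j) - E(c_j) )^2 / w_j^2

summed over the p concentrations j and the replicates i measured at
each, skipping missing cells.  With ``sd`` weighting w_j is the
per-concentration standard deviation sigma_j, so that for Gaussian
observational noise minimizing F is a maximum-likelihood estimate and F
at the optimum is a chi-square statistic; with ``unit`` weighting w_j = 1,
the recommended fallback when replicates are too few to estimate sigma.

Candidate models are ranked on the constants-dropped Gaussian scores
AIC = F + 2k and BIC = F + k ln N, where k counts free parameters and N
counts non-missing observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as _stats

from .model import MultiphasicModel, eval_model

__all__ = [
    "DoseResponseDataset",
    "FitStatistics",
    "compute_sigma",
    "objective_f",
    "information_criteria",
    "goodness_of_fit",
    "fit_statistics",
]

#: recognized response-scale tags for raw input data
SCALE_TAGS = ("one_to_zero", "hundred_to_zero", "zero_to_one", "zero_to_hundred")

# per-concentration variances estimated from very few replicates have
# heavy-tailed inverses (2 degrees of freedom for triplicates); shrink them
# toward the pooled variance with this many prior degrees of freedom
SIGMA_PRIOR_DOF = 4.0


@dataclass
class DoseResponseDataset:
    """Dose-response measurements on the canonical normalized scale.

    ``concentrations`` is a strictly increasing vector of p nonnegative
    concentrations; ``effects`` is the p x n replicate matrix with NaN
    for missing cells, normalized so the zero-dose response is 1 and
    complete inhibition is 0.  ``sigma`` may be supplied (known noise)
    or left None to be estimated from replicate scatter.
    """

    concentrations: np.ndarray
    effects: np.ndarray
    sigma: Optional[np.ndarray] = None
    unit: str = ""
    title: str = ""
    scale_tag: str = "one_to_zero"
    generating_model: Optional[MultiphasicModel] = None
    #: set when sd weighting had to fall back to unit weights (no usable
    #: replicate scatter); scores then use the profiled-variance forms
    sigma_fallback_unit: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float).ravel()
        e = np.asarray(self.effects, dtype=float)
        if e.ndim == 1:
            e = e[:, None]
        if e.ndim != 2 or e.shape[0] != c.size:
            raise ValueError(
                f"effects must be p x n with p = len(concentrations); "
                f"got {e.shape} for p = {c.size}"
            )
        if np.any(c < 0) or np.any(~np.isfinite(c)):
            raise ValueError("concentrations must be finite and nonnegative")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        bad = ~np.isfinite(e).any(axis=1)
        if bad.any():
            raise ValueError(
                f"every concentration needs at least one non-missing effect; "
                f"rows {np.nonzero(bad)[0].tolist()} are all missing"
            )
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        self.concentrations = c
        self.effects = e
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float).ravel()
            if s.size != c.size or np.any(s <= 0):
                raise ValueError("sigma must be positive with one entry per concentration")
            self.sigma = s

    @property
    def n_concentrations(self) -> int:
        return int(self.concentrations.size)

    @property
    def n_replicates(self) -> int:
        return int(self.effects.shape[1])

    @property
    def n_obs(self) -> int:
        """Number of non-missing observations N."""
        return int(np.isfinite(self.effects).sum())


def compute_sigma(
    dataset: DoseResponseDataset, prior_dof: float = SIGMA_PRIOR_DOF
) -> tuple[np.ndarray, bool]:
    """Per-concentration dispersion estimates and a unit-weighting advisory.

    Returns ``(sigma, unit_recommended)``.  Each concentration with at
    least two replicates gets its sample standard deviation; because a
    triplicate sd carries only 2 degrees of freedom (its inverse square
    has no finite mean), the per-concentration variances are moderated
    toward the pooled variance in empirical-Bayes fashion,

        sigma_j^2 = (nu_j s_j^2 + nu_0 s_0^2) / (nu_j + nu_0),

    with nu_j = n_j - 1, prior ``prior_dof`` nu_0 and pooled variance
    s_0^2 the dof-weighted mean of the s_j^2.  Concentrations without a
    usable sd (fewer than 2 replicates, or identical replicates) get
    the pooled value.  When no concentration yields a usable sd the
    weights are unity and ``unit_recommended`` is True; it is also True
    when most concentrations lack replication.  Homoscedastic data
    (equal s_j) pass through unchanged.
    """
    e = dataset.effects
    p = dataset.n_concentrations
    counts = np.isfinite(e).sum(axis=1)
    sds = np.full(p, np.nan)
    for j in range(p):
        vals = e[j][np.isfinite(e[j])]
        if vals.size >= 2:
            sds[j] = np.std(vals, ddof=1)
    # sds of numerically identical replicates come out at float-epsilon
    # level rather than exactly zero; treat those as degenerate too
    usable = np.isfinite(sds) & (sds > 1e-12)
    unit_recommended = bool((counts < 2).sum() > p / 2)
    if not usable.any():
        return np.ones(p), True
    dofs = (counts - 1).astype(float)
    pooled_var = float(
        np.sum(dofs[usable] * sds[usable] ** 2) / np.sum(dofs[usable])
    )
    var = np.where(usable, sds**2, pooled_var)
    nu = np.where(usable, dofs, 0.0)
    var = (nu * var + prior_dof * pooled_var) / (nu + prior_dof)
    return np.sqrt(var), unit_recommended


def ensure_sigma(dataset: DoseResponseDataset) -> np.ndarray:
    """Estimate and cache per-concentration sigma on the dataset."""
    if dataset.sigma is None:
        sigma, _ = compute_sigma(dataset)
        dataset.sigma = sigma
        dataset.sigma_fallback_unit = bool(np.all(sigma == 1.0))
    return dataset.sigma


def _weights(dataset: DoseResponseDataset, weighting: str) -> np.ndarray:
    if weighting == "unit":
        return np.ones(dataset.n_concentrations)
    if weighting == "sd":
        return ensure_sigma(dataset)
    raise ValueError(f"weighting must be 'sd' or 'unit', got {weighting!r}")


def objective_f(
    model: MultiphasicModel, dataset: DoseResponseDataset, weighting: str = "sd"
) -> float:
    """The weighted sum-of-squares objective F; 0 iff the model interpolates
    every non-missing observation exactly."""
    w = _weights(dataset, weighting)
    pred = eval_model(model, dataset.concentrations)
    resid = (dataset.effects - pred[:, None]) / w[:, None]
    return float(np.nansum(resid**2))


def information_criteria(f_value: float, n_obs: int, k_params: int) -> tuple[float, float]:
    """(AIC, BIC) = (F + 2k, F + k ln N), Gaussian constants dropped.

    This is the known-sigma form: it presumes F is built from
    sigma-standardized residuals (sd weighting), so that F itself is the
    -2 log-likelihood core.
    """
    if n_obs < 1 or k_params < 1:
        raise ValueError("need n_obs >= 1 and k_params >= 1")
    return f_value + 2.0 * k_params, f_value + k_params * float(np.log(n_obs))


# variance floor (normalized-effect scale) for the profiled unit-weight
# likelihood: keeps exactly-interpolating fits comparable instead of -inf
_RSS_VAR_FLOOR = 1e-12


def unit_information_criteria(
    f_value: float, n_obs: int, k_params: int
) -> tuple[float, float]:
    """(AIC, BIC) under unit weighting, where the noise variance is unknown.

    The Gaussian likelihood profiled over the common variance gives
    -2 log L = N ln(RSS / N) up to constants, so the scores are
    ``N ln(RSS/N) + 2k`` and ``N ln(RSS/N) + k ln N`` — the standard
    least-squares forms.  RSS/N is floored at 1e-12 (an effect-scale sd
    of 1e-6, far below any assay's precision) so that candidates which
    interpolate the data exactly tie on the fit term and the parameter
    penalty decides.
    """
    if n_obs < 1 or k_params < 1:
        raise ValueError("need n_obs >= 1 and k_params >= 1")
    core = n_obs * float(np.log(max(f_value / n_obs, _RSS_VAR_FLOOR)))
    return core + 2.0 * k_params, core + k_params * float(np.log(n_obs))


def goodness_of_fit(
    f_value: float, n_obs: int, k_params: int, weighting: str = "sd"
) -> Optional[float]:
    """Upper-tail chi-square probability of F at N - k degrees of freedom.

    Only meaningful under sd weighting (F is then a chi-square statistic
    for correctly estimated noise); returns None under unit weighting or
    when no degrees of freedom remain.
    """
    if weighting == "unit":
        return None
    dof = n_obs - k_params
    if dof <= 0:
        warnings.warn(
            "goodness of fit unavailable: no residual degrees of freedom",
            stacklevel=2,
        )
        return None
    return float(_stats.chi2.sf(f_value, dof))


@dataclass(frozen=True)
class FitStatistics:
    """Objective value and derived scores for one fitted candidate."""

    f_value: float
    n_obs: int
    k_params: int
    gof_p: Optional[float]
    aic: float
    bic: float


def fit_statistics(
    f_value: float, n_obs: int, k_params: int, weighting: str = "sd"
) -> FitStatistics:
    if weighting == "unit":
        aic, bic = unit_information_criteria(f_value, n_obs, k_params)
    else:
        aic, bic = information_criteria(f_value, n_obs, k_params)
    gof = goodness_of_fit(f_value, n_obs, k_params, weighting)
    return FitStatistics(
        f_value=f_value, n_obs=n_obs, k_params=k_params, gof_p=gof, aic=aic, bic=bic
    )
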