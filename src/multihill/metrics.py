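"""Model-derived summaries: interpolated effects, effective concentrations, AUC."""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy import optimize as _opt

from .model import MultiphasicModel, eval_model

__all__ = ["effect_at", "effective_concentration", "auc"]

_DEFAULT_WINDOW_DECADES = 6.0


def effect_at(
    model: MultiphasicModel,
    concentrations,
    tested_range: Optional[tuple[float, float]] = None,
):
    """Model effects at arbitrary concentrations (interpolation or
    extrapolation).  If ``tested_range = (c_lo, c_hi)`` is given, a
    warning flags any concentration outside it as extrapolated."""
    arr = np.asarray(concentrations, dtype=float)
    if tested_range is not None:
        c_lo, c_hi = tested_range
        outside = (arr < c_lo) | (arr > c_hi)
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} concentration(s) outside the tested range "
                f"[{c_lo:g}, {c_hi:g}]: extrapolating",
                stacklevel=2,
            )
    return eval_model(model, concentrations)


def _default_window(model: MultiphasicModel) -> tuple[float, float]:
    ecs = [p.ec50 for p in model.phases]
    return (
        min(ecs) * 10.0**-_DEFAULT_WINDOW_DECADES,
        max(ecs) * 10.0**_DEFAULT_WINDOW_DECADES,
    )


def effective_concentration(
    model: MultiphasicModel,
    level: float,
    window: Optional[tuple[float, float]] = None,
    n_grid: int = 1000,
) -> np.ndarray:
    """All concentrations at which the model reaches a given fraction of
    its effect span.

    The target effect is span-relative: with baseline ``b`` (the model
    at zero dose) and floor ``E_floor`` (the model at the window's upper
    edge), the equation solved is ``E(c) = b - level * (b - E_floor)``.
    For a plain Hill curve this reduces to the textbook ECx — e.g.
    ``level=0.5`` returns the ec50 parameter.  Multiphasic curves may
    cross the target more than once; every crossing inside ``window``
    is located by a sign-change scan on an ``n_grid``-point log grid
    refined by bisection, and returned in ascending order.  The
    smallest is the primary ECx.  An empty array (with a warning) means
    no crossing exists in the window.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if window is None:
        window = _default_window(model)
    c_lo, c_hi = window
    if not 0.0 < c_lo < c_hi:
        raise ValueError("window must satisfy 0 < c_lo < c_hi")

    baseline = model.baseline_scale
    floor = eval_model(model, c_hi)
    target = baseline - level * (baseline - floor)

    grid = np.logspace(np.log10(c_lo), np.log10(c_hi), n_grid)
    g = eval_model(model, grid) - target
    roots = [float(grid[i]) for i in np.nonzero(g == 0.0)[0]]
    sign_change = np.nonzero(g[:-1] * g[1:] < 0)[0]
    for i in sign_change:
        root = _opt.brentq(
            lambda c: eval_model(model, c) - target,
            grid[i],
            grid[i + 1],
            rtol=1e-9,
            maxiter=200,
        )
        roots.append(float(root))
    roots = np.array(sorted(set(roots)))
    if roots.size == 0:
        warnings.warn(
            f"no concentration in [{c_lo:g}, {c_hi:g}] reaches the "
            f"{100 * level:g}% effect level",
            stacklevel=2,
        )
    return roots


def auc(
    model: MultiphasicModel,
    c_min: float,
    c_max: float,
    normalize: bool = False,
    n_points: int = 2001,
) -> float:
    """Area under the modelled curve over log10 concentration.

    Composite-trapezoid integral of ``E`` against log10(c) on
    ``[c_min, c_max]`` (both > 0).  With ``normalize=True`` the area is
    divided by the log-interval width, giving a mean effect on [0, ~1]
    that is comparable across concentration ranges.
    """
    if not 0.0 < c_min < c_max:
        raise ValueError("need 0 < c_min < c_max")
    u = np.linspace(np.log10(c_min), np.log10(c_max), n_points)
    y = eval_model(model, 10.0**u)
    area = float(np.trapezoid(y, u))
    if normalize:
        area /= u[-1] - u[0]
    return area
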