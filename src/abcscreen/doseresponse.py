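"""Four-parameter log-logistic viability fits, IC50 and dose planning.

The viability curve is the standard LL.4 model

    f(x; b, c, d, e) = c + (d - c) / (1 + exp(b * (log x - log e)))

with slope ``b``, lower asymptote ``c``, upper asymptote ``d`` and
inflection dose ``e`` (ug/mL).  The IC50 is defined as the absolute
50%-viability crossing of the fitted curve (for ``c = 0, d = 1`` it
coincides with ``e``) and sets the maximum exposure concentration of
the signal-disruption assay; when no crossing exists on the tested
range, the maximum concentration falls back to the highest soluble
concentration, subject to a vehicle-fraction cap (1% for PBS, 0.1% for
DMSO).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import ParameterError, PlanningError

__all__ = [
    "DoseResponseFit",
    "ConcentrationPlan",
    "VEHICLE_CAPS",
    "ll4",
    "fit_4pl",
    "estimate_ic50",
    "ic50_closed_form",
    "max_concentration",
]

#: Maximum tolerated vehicle volume fraction in the medium.
VEHICLE_CAPS = {"PBS": 0.01, "DMSO": 0.001}


@dataclass(frozen=True)
class DoseResponseFit:
    b: float
    c: float
    d: float
    e: float
    residual_sd: float
    converged: bool

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return ll4(x, self.b, self.c, self.d, self.e)


@dataclass(frozen=True)
class ConcentrationPlan:
    """Maximum test concentration for one chemical and its provenance."""

    chemical: str
    max_concentration: float
    source: str  # "ic50" or "solubility_cap"
    vehicle_cap_ok: bool


def ll4(x: np.ndarray | float, b: float, c: float, d: float, e: float) -> np.ndarray | float:
    """Four-parameter log-logistic response at dose ``x`` (> 0)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        out = c + (d - c) / (1.0 + np.exp(b * (np.log(x) - np.log(e))))
    return out if out.ndim else float(out)


def _residuals(theta: np.ndarray, logx: np.ndarray, y: np.ndarray) -> np.ndarray:
    b, c, d, loge = theta
    with np.errstate(over="ignore"):
        return c + (d - c) / (1.0 + np.exp(b * (logx - loge))) - y


def fit_4pl(doses: np.ndarray, viabilities: np.ndarray) -> DoseResponseFit:
    """Least-squares LL.4 fit over a fixed deterministic multi-start grid.

    Starts span both slope signs, several slope magnitudes and
    inflection doses across the tested range; the lowest-SSE solution
    wins and is canonicalized to ``d >= c`` (the model is invariant
    under swapping the asymptotes and negating the slope).
    """
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(viabilities, dtype=float)
    if doses.shape != y.shape:
        raise ParameterError("doses and viabilities must have equal length")
    if np.any(doses <= 0):
        raise ParameterError("doses must be positive")
    if np.unique(doses).size < 4:
        raise ParameterError("need at least 4 distinct positive doses")
    logx = np.log(doses)

    lo, hi = float(np.min(y)), float(np.max(y))
    e_grid = np.exp(np.linspace(logx.min(), logx.max(), 5))
    best = None
    for b0 in (-4.0, -1.0, 1.0, 4.0):
        for e0 in e_grid:
            x0 = np.array([b0, lo, hi, np.log(e0)])
            try:
                sol = least_squares(_residuals, x0, args=(logx, y), method="lm", max_nfev=2000)
            except Exception:  # singular start; keep scanning
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            sse = float(np.sum(sol.fun**2))
            if best is None or sse < best[0] - 1e-12:
                best = (sse, sol)
    if best is None:
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, np.nan, converged=False)
    sse, sol = best
    b, c, d, loge = sol.x
    if d < c:  # canonical orientation
        b, c, d = -b, d, c
    dof = max(y.size - 4, 1)
    return DoseResponseFit(
        b=float(b),
        c=float(c),
        d=float(d),
        e=float(np.exp(loge)),
        residual_sd=float(np.sqrt(sse / dof)),
        converged=bool(sol.success),
    )


def ic50_closed_form(fit: DoseResponseFit) -> float | None:
    """Analytic 50%-viability crossing, if it exists."""
    c, d, b, e = fit.c, fit.d, fit.b, fit.e
    if not (min(c, d) < 0.5 < max(c, d)):
        return None
    ratio = (d - c) / (0.5 - c) - 1.0
    if ratio <= 0:
        return None
    return float(e * ratio ** (1.0 / b))


def estimate_ic50(
    fit: DoseResponseFit, dose_range: tuple[float, float], rel_tol: float = 1e-6
) -> float | None:
    """Smallest dose in ``dose_range`` where fitted viability is 50%.

    Solved by bisection on log dose to the given relative tolerance;
    returns ``None`` when the fitted curve never crosses 0.5 on the
    range (not estimable).
    """
    if not fit.converged:
        raise ParameterError("cannot estimate IC50 from a non-converged fit")
    lo, hi = dose_range
    if not 0 < lo < hi:
        raise ParameterError("dose_range must satisfy 0 < lo < hi")

    def half(logx: float) -> float:
        return float(ll4(np.exp(logx), fit.b, fit.c, fit.d, fit.e)) - 0.5

    flo, fhi = half(np.log(lo)), half(np.log(hi))
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        return None
    root = brentq(half, np.log(lo), np.log(hi), xtol=rel_tol / 2, rtol=8.9e-16)
    return float(np.exp(root))


def max_concentration(
    chemical: str,
    ic50: float | None,
    solubility_limit: float | None,
    vehicle: str,
    vehicle_fraction_at_top: float,
) -> ConcentrationPlan:
    """Maximum test concentration: the IC50 when estimable, else the solubility cap.

    ``vehicle_cap_ok`` is False when delivering the top dose requires a
    vehicle fraction above 1% (PBS) or 0.1% (DMSO).
    """
    if vehicle not in VEHICLE_CAPS:
        raise ParameterError(f"vehicle must be one of {sorted(VEHICLE_CAPS)}")
    if ic50 is not None:
        source, top = "ic50", float(ic50)
    elif solubility_limit is not None:
        source, top = "solubility_cap", float(solubility_limit)
    else:
        raise PlanningError(f"{chemical}: neither IC50 nor solubility cap available")
    return ConcentrationPlan(
        chemical=chemical,
        max_concentration=top,
        source=source,
        vehicle_cap_ok=vehicle_fraction_at_top <= VEHICLE_CAPS[vehicle],
    )
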