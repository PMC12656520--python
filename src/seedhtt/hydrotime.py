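"""Hydrotime model of germination at a fixed temperature.

Each seed carries its own base water potential Ψb; germination of fraction g
requires accumulating hydrotime θH (MPa·h) above that threshold:

    θH = (Ψ − Ψb(g)) · t(g)

With Ψb normally distributed over the lot (median Ψb(50), s.d. σΨb), the
model linearizes on the probit scale: regressing probit(g) against
x = Ψ − θH/t(g) gives a line with slope 1/σΨb and intercept −Ψb(50)/σΨb.
θH itself is not linear in the regression, so it is estimated by a nested
search — a coarse log-spaced grid refined by bounded minimization — choosing
the θH that maximizes the probit R² ("best fit").
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .errors import BoundaryWarning, InsufficientDataError, NonIdentifiableError
from .germdata import PercentileTimes
from .thermaltime import FitDiagnostics

#: search interval for θH (MPa·h); brackets reported crop values by >10×
THETA_H_BOUNDS: tuple[float, float] = (0.1, 500.0)
_GRID_POINTS = 60
_REL_TOL = 1e-4


@dataclass
class HydrotimeFit:
    """Hydrotime parameters at one temperature."""

    temperature: float  # °C
    theta_H: float  # MPa·h
    psi_b50: float  # MPa
    sigma_psib: float  # MPa
    predicted_G: float  # %
    observed_G: float  # %
    reference_psi: float  # MPa at which predicted/observed G are reported
    diagnostics: FitDiagnostics


def probit_design(g_obs, psi, t_g, theta_H: float) -> tuple[np.ndarray, np.ndarray]:
    """Regression vectors for the probit linearization at a candidate θH.

    y = probit(g), x = Ψ − θH/t(g). Fractions at 0 or 1 must already be
    excluded (or smoothed) by the caller; t(g) must be positive.
    """
    g_obs = np.asarray(g_obs, dtype=float)
    psi = np.asarray(psi, dtype=float)
    t_g = np.asarray(t_g, dtype=float)
    ok = (g_obs > 0) & (g_obs < 1) & (t_g > 0) & ~np.isnan(t_g)
    if not ok.any():
        raise InsufficientDataError("no usable (g, Ψ, t(g)) points for probit design")
    x = psi[ok] - theta_H / t_g[ok]
    y = norm.ppf(g_obs[ok])
    return x, y


def _probit_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS of y on x; returns (R², slope, intercept)."""
    b, a = np.polyfit(x, y, 1)
    resid = y - (a + b * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    return r2, b, a


def _collect_points(
    percentiles: list[PercentileTimes], *, smoothing: bool = False
):
    g, psi, t = [], [], []
    for p in percentiles:
        mask = p.defined()
        frac = p.g_levels[mask]
        if smoothing:
            # (count + 0.5)/(n + 1)-style shrink applied on the fraction scale
            frac = (frac + 0.5 / 100) / (1 + 1.0 / 100)
        g.extend(frac)
        psi.extend([p.treatment.water_potential] * int(mask.sum()))
        t.extend(p.t_g[mask])
    return np.asarray(g), np.asarray(psi), np.asarray(t)


def fit_hydrotime(
    percentiles: list[PercentileTimes],
    *,
    theta_bounds: tuple[float, float] = THETA_H_BOUNDS,
    reference_psi: float | None = None,
    smoothing: bool = False,
) -> HydrotimeFit:
    """Grid + refined search over θH maximizing the probit regression R².

    ``percentiles`` must share a temperature and span >= 2 water potentials
    with germination, contributing >= 4 usable (g, Ψ, t(g)) points. Ψb(50) and
    σΨb come from the winning regression line; predicted G is the normal-model
    fraction 100·Φ((Ψ_ref − Ψb50)/σΨb) at the declared reference Ψ (default:
    the highest Ψ with data), observed G the pooled final percentage there.
    """
    temps = {p.treatment.temperature for p in percentiles}
    if len(temps) != 1:
        raise InsufficientDataError(
            f"hydrotime fit needs a single temperature, got {sorted(temps)}"
        )
    temperature = temps.pop()

    usable = [p for p in percentiles if p.defined().any()]
    psis = sorted({p.treatment.water_potential for p in usable})
    g, psi, t = _collect_points(usable, smoothing=smoothing)
    if len(psis) < 2 or g.size < 4:
        raise InsufficientDataError(
            f"hydrotime fit at T={temperature} °C needs >= 2 water potentials "
            f"and >= 4 points; got {len(psis)} Ψ levels, {g.size} points"
        )

    def neg_r2_log(log_theta: float) -> float:
        x, y = probit_design(g, psi, t, math.exp(log_theta))
        return -_probit_r2(x, y)[0]

    lo, hi = math.log(theta_bounds[0]), math.log(theta_bounds[1])
    grid = np.linspace(lo, hi, _GRID_POINTS)
    vals = np.array([neg_r2_log(lt) for lt in grid])
    k = int(np.argmin(vals))
    if k in (0, _GRID_POINTS - 1):
        warnings.warn(
            f"θH optimum at search boundary ({math.exp(grid[k]):.3g} MPa·h)",
            BoundaryWarning,
        )
    bl = grid[max(k - 1, 0)]
    bh = grid[min(k + 1, _GRID_POINTS - 1)]
    res = minimize_scalar(
        neg_r2_log, bounds=(bl, bh), method="bounded",
        options={"xatol": _REL_TOL / 10},
    )
    theta_H = float(math.exp(res.x))

    x, y = probit_design(g, psi, t, theta_H)
    r2, slope, intercept = _probit_r2(x, y)
    if slope <= 0:
        raise NonIdentifiableError(
            f"probit slope non-positive at T={temperature} °C: model not identifiable"
        )
    sigma = 1.0 / slope
    psi_b50 = -intercept / slope

    # percent-scale RMSE between model-implied and observed fractions
    pred_pct = 100.0 * norm.cdf(intercept + slope * x)
    obs_pct = 100.0 * norm.cdf(y)
    rmse = float(np.sqrt(np.mean((pred_pct - obs_pct) ** 2)))

    ref = max(psis) if reference_psi is None else float(reference_psi)
    predicted_G = 100.0 * float(norm.cdf((ref - psi_b50) / sigma))
    obs_candidates = [
        p.final_fraction for p in usable if p.treatment.water_potential == ref
    ]
    observed_G = 100.0 * obs_candidates[0] if obs_candidates else float("nan")

    return HydrotimeFit(
        temperature=temperature,
        theta_H=theta_H,
        psi_b50=psi_b50,
        sigma_psib=sigma,
        predicted_G=predicted_G,
        observed_G=observed_G,
        reference_psi=ref,
        diagnostics=FitDiagnostics(
            r_squared=max(0.0, min(1.0, r2)), rmse=rmse, n_obs=int(g.size)
        ),
    )


def germinable_fraction(fit: HydrotimeFit, psi: float) -> float:
    """Fraction of the lot whose base water potential lies below ``psi``."""
    return float(norm.cdf((psi - fit.psi_b50) / fit.sigma_psib))
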