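"""Thermal-time model of germination.

At a fixed water potential, the time t(g) for subpopulation fraction g to
germinate shortens linearly with temperature above a base temperature Tb:

    θT(g) = (T − Tb) · t(g)        GR(g) = 1/t(g) = (T − Tb) / θT(g)

θT(g) is the thermal-time constant (°C·h). Fitting is on the rate scale,
where the model is the straight line GR = a + b·T with Tb = −a/b and
θT = 1/b; the slope must be positive for the model to be identifiable. The
linear form only holds below the optimum temperature, so supra-optimal
temperatures are excluded by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, NonIdentifiableError
from .germdata import PercentileTimes

#: temperature at which the headline GR(50) is reported (°C)
DEFAULT_REFERENCE_TEMPERATURE = 25.0


@dataclass
class FitDiagnostics:
    """Goodness-of-fit bundle shared by all fitters."""

    r_squared: float
    rmse: float
    n_obs: int
    sem: float | None = None


@dataclass
class ThermalTimeFit:
    """Thermal-time parameters at one water potential."""

    water_potential: float  # MPa
    theta_T50: float  # °C·h
    Tb: float  # °C
    GR50: float  # h⁻¹ at reference_temperature
    reference_temperature: float
    temperatures_used: list[float]
    g: float
    diagnostics: FitDiagnostics


def _suboptimal_mask(temps: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Keep temperatures up to and including the one with maximal rate."""
    t_opt = temps[int(np.argmax(rates))]
    return temps <= t_opt


def fit_thermal_time(
    percentiles: list[PercentileTimes],
    g: float = 0.5,
    *,
    suboptimal_only: bool = True,
    fixed_Tb: float | None = None,
    reference_temperature: float = DEFAULT_REFERENCE_TEMPERATURE,
) -> ThermalTimeFit:
    """Least-squares fit of GR(g) = (T − Tb)/θT(g) across temperatures.

    ``percentiles`` must share a water potential and span >= 3 temperatures
    with a defined t(g). With ``fixed_Tb`` the slope alone is estimated by
    regression through the origin on (T − Tb). R² is computed on the rate
    scale; RMSE on back-predicted t(g) in hours.
    """
    psis = {p.treatment.water_potential for p in percentiles}
    if len(psis) != 1:
        raise InsufficientDataError(
            f"thermal-time fit needs a single water potential, got {sorted(psis)}"
        )
    psi = psis.pop()

    temps, times = [], []
    for p in percentiles:
        gi = np.flatnonzero(np.isclose(p.g_levels, g))
        if gi.size == 0:
            continue
        t = p.t_g[int(gi[0])]
        if not math.isnan(t):
            temps.append(p.treatment.temperature)
            times.append(t)
    temps = np.asarray(temps, dtype=float)
    times = np.asarray(times, dtype=float)
    rates = 1.0 / times

    if suboptimal_only and temps.size:
        keep = _suboptimal_mask(temps, rates)
        temps, times, rates = temps[keep], times[keep], rates[keep]

    if temps.size < 3:
        raise InsufficientDataError(
            f"thermal-time fit at Ψ={psi} MPa needs >= 3 usable temperatures, "
            f"got {temps.size}"
        )

    if fixed_Tb is None:
        b, a = np.polyfit(temps, rates, 1)
        se_b = _slope_se(temps, rates, a, b)
        if b <= 0:
            raise NonIdentifiableError(
                f"thermal-time slope is non-positive (b={b:.3g}) at Ψ={psi} MPa"
            )
        Tb = -a / b
    else:
        Tb = float(fixed_Tb)
        x = temps - Tb
        b = float(np.dot(x, rates) / np.dot(x, x))
        if b <= 0:
            raise NonIdentifiableError("thermal-time slope is non-positive")
        resid = rates - b * x
        dof = max(temps.size - 1, 1)
        se_b = math.sqrt(float(resid @ resid) / dof / float(x @ x))
        a = -b * Tb
    theta = 1.0 / b

    pred_rates = a + b * temps
    ss_res = float(np.sum((rates - pred_rates) ** 2))
    ss_tot = float(np.sum((rates - rates.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    # back-predicted times; undefined where predicted rate is non-positive
    with np.errstate(divide="ignore"):
        pred_t = np.where(pred_rates > 0, 1.0 / pred_rates, np.nan)
    ok = ~np.isnan(pred_t)
    rmse_t = float(np.sqrt(np.mean((times[ok] - pred_t[ok]) ** 2))) if ok.any() else float("nan")
    sem_theta = se_b / b**2 if se_b is not None else None

    return ThermalTimeFit(
        water_potential=psi,
        theta_T50=theta,
        Tb=Tb,
        GR50=max(reference_temperature - Tb, 0.0) / theta,
        reference_temperature=reference_temperature,
        temperatures_used=[float(t) for t in temps],
        g=g,
        diagnostics=FitDiagnostics(
            r_squared=max(0.0, min(1.0, r2)), rmse=rmse_t, n_obs=int(temps.size),
            sem=sem_theta,
        ),
    )


def _slope_se(x: np.ndarray, y: np.ndarray, a: float, b: float) -> float:
    resid = y - (a + b * x)
    dof = max(x.size - 2, 1)
    sxx = float(np.sum((x - x.mean()) ** 2))
    return math.sqrt(float(resid @ resid) / dof / sxx) if sxx > 0 else float("nan")


def predict_t(fit: ThermalTimeFit, temperature: float) -> float:
    """Predicted t(g) = θT/(T − Tb) in hours; inf when T <= Tb (no germination)."""
    if temperature <= fit.Tb:
        return float("inf")
    return fit.theta_T50 / (temperature - fit.Tb)
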