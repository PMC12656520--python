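"""Hydrothermal-time (HTT) model over the full temperature × water-potential grid.

Germination of fraction g requires joint accumulation of thermal and hydro
time above both thresholds:

    θHT = (Ψ − Ψb(g)) · (T − Tb) · t(g)        [MPa·°C·h]

With Ψb ~ Normal(Ψb(50), σΨb), all observed germination fractions across
temperatures and water potentials linearize on the probit scale:

    probit(g) = (Ψ − θHT/((T − Tb)·t(g)) − Ψb(50)) / σΨb

The regression is linear given (θHT, Tb), so those two are estimated by an
outer search — a grid over Tb crossed with a log-spaced grid over θHT,
refined by coordinate descent — maximizing the probit R²; Ψb(50) and σΨb fall
out of the winning regression line. The standard error of θHT is obtained by
a nonparametric bootstrap over replicate dishes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .errors import BoundaryWarning, InsufficientDataError, NonIdentifiableError
from .germdata import (
    GerminationTimeCourse,
    PercentileTimes,
    exclude_non_germinating,
    percentiles_by_treatment,
    truncate_plateau,
)
from .hydrotime import _probit_r2
from .thermaltime import FitDiagnostics

#: search interval for θHT (MPa·°C·h); brackets reported crop values by >10×
THETA_HT_BOUNDS: tuple[float, float] = (1.0, 50_000.0)
TB_GRID_STEP = 0.5
_THETA_GRID_POINTS = 50
_REL_TOL = 1e-4
_MAX_SWEEPS = 30


@dataclass
class HydrothermalFit:
    """Whole-grid HTT parameters for one seed lot."""

    theta_HT: float  # MPa·°C·h
    Tb: float  # °C
    psi_b50: float  # MPa
    sigma_psib: float  # MPa
    temp_range_used: tuple[float, float]  # °C
    diagnostics: FitDiagnostics  # sem = bootstrap s.e. of θHT (None if skipped)


def htt_time(theta_HT: float, Tb: float, psi_b_g: float, T: float, psi: float) -> float:
    """t(g) = θHT / ((Ψ − Ψb(g))(T − Tb)); inf when either threshold binds."""
    if T <= Tb or psi <= psi_b_g:
        return float("inf")
    return theta_HT / ((psi - psi_b_g) * (T - Tb))


def _collect_points(percentiles: list[PercentileTimes]):
    g, T, psi, t = [], [], [], []
    for p in percentiles:
        mask = p.defined() & (p.g_levels > 0) & (p.g_levels < 1)
        n = int(mask.sum())
        g.extend(p.g_levels[mask])
        T.extend([p.treatment.temperature] * n)
        psi.extend([p.treatment.water_potential] * n)
        t.extend(p.t_g[mask])
    return (np.asarray(g), np.asarray(T), np.asarray(psi), np.asarray(t))


def _r2_at(g, T, psi, t, theta: float, Tb: float):
    keep = T > Tb
    if keep.sum() < 4:
        return -np.inf, np.nan, np.nan
    x = psi[keep] - theta / ((T[keep] - Tb) * t[keep])
    y = norm.ppf(g[keep])
    if np.unique(x).size < 2:
        return -np.inf, np.nan, np.nan
    return _probit_r2(x, y)


def fit_htt(
    percentiles: list[PercentileTimes],
    *,
    fixed_Tb: float | None = None,
    temp_window: tuple[float, float] | None = None,
    theta_bounds: tuple[float, float] = THETA_HT_BOUNDS,
    tb_step: float = TB_GRID_STEP,
    start: tuple[float, float] | None = None,
) -> HydrothermalFit:
    """Nested probit fit of the HTT model across the whole T × Ψ design.

    All reachable percentile observations at every (T, Ψ) enter the
    regression. Tb is searched on a ``tb_step`` grid within [0, min(T) − 1]
    unless ``fixed_Tb`` pins it; ``temp_window`` optionally restricts the
    temperatures used (the "poor germination outside this range" workflow).
    ``start`` warm-starts the coordinate descent, skipping the coarse grids
    (used by the bootstrap).
    """
    if temp_window is not None:
        lo, hi = temp_window
        percentiles = [
            p for p in percentiles if lo <= p.treatment.temperature <= hi
        ]
    usable = [p for p in percentiles if p.defined().any()]
    temps = sorted({p.treatment.temperature for p in usable})
    psis = sorted({p.treatment.water_potential for p in usable})
    if len(temps) < 3 or len(psis) < 2:
        raise InsufficientDataError(
            f"HTT fit needs >= 3 temperatures and >= 2 water potentials with "
            f"germination; got {len(temps)} and {len(psis)}"
        )
    g, T, psi, t = _collect_points(usable)

    log_lo, log_hi = math.log(theta_bounds[0]), math.log(theta_bounds[1])
    tb_max = min(temps) - 1.0

    def refine_theta(Tb: float, lo: float, hi: float) -> float:
        res = minimize_scalar(
            lambda lt: -_r2_at(g, T, psi, t, math.exp(lt), Tb)[0],
            bounds=(lo, hi), method="bounded", options={"xatol": _REL_TOL / 10},
        )
        return float(res.x)

    def refine_tb(log_theta: float, lo: float, hi: float) -> float:
        theta = math.exp(log_theta)
        res = minimize_scalar(
            lambda tb: -_r2_at(g, T, psi, t, theta, tb)[0],
            bounds=(lo, hi), method="bounded", options={"xatol": _REL_TOL},
        )
        return float(res.x)

    if start is not None:
        log_theta, Tb = math.log(start[0]), float(start[1])
    elif fixed_Tb is not None:
        Tb = float(fixed_Tb)
        grid = np.linspace(log_lo, log_hi, _THETA_GRID_POINTS)
        vals = [-_r2_at(g, T, psi, t, math.exp(lt), Tb)[0] for lt in grid]
        k = int(np.argmin(vals))
        log_theta = grid[k]
    else:
        tb_grid = np.arange(0.0, tb_max + 1e-9, tb_step)
        if tb_grid.size == 0:
            tb_grid = np.array([0.0])
        theta_grid = np.linspace(log_lo, log_hi, _THETA_GRID_POINTS)
        best = (np.inf, theta_grid[0], tb_grid[0])
        for tb in tb_grid:
            for lt in theta_grid:
                v = -_r2_at(g, T, psi, t, math.exp(lt), tb)[0]
                if v < best[0]:
                    best = (v, lt, tb)
        _, log_theta, Tb = best
        if math.isinf(best[0]):
            raise NonIdentifiableError("no (θHT, Tb) candidate yields a usable regression")

    theta_span = (log_hi - log_lo) / (_THETA_GRID_POINTS - 1)
    prev = (log_theta, Tb)
    for _ in range(_MAX_SWEEPS):
        log_theta = refine_theta(
            Tb,
            max(log_lo, log_theta - theta_span),
            min(log_hi, log_theta + theta_span),
        )
        if fixed_Tb is None:
            Tb = refine_tb(
                log_theta, max(0.0, Tb - tb_step), min(tb_max, Tb + tb_step)
            )
        d_theta = abs(log_theta - prev[0])
        d_tb = abs(Tb - prev[1])
        prev = (log_theta, Tb)
        if d_theta < _REL_TOL / 10 and d_tb < _REL_TOL:
            break

    theta_HT = math.exp(log_theta)
    if (
        theta_HT < theta_bounds[0] * 1.01
        or theta_HT > theta_bounds[1] * 0.99
        or (fixed_Tb is None and tb_max > 0 and Tb > tb_max - 1e-6)
    ):
        warnings.warn(
            f"HTT optimum near a search boundary (θHT={theta_HT:.4g}, Tb={Tb:.3g})",
            BoundaryWarning,
        )

    r2, slope, intercept = _r2_at(g, T, psi, t, theta_HT, Tb)
    if not np.isfinite(slope) or slope <= 0:
        raise NonIdentifiableError("probit slope non-positive: HTT model not identifiable")
    sigma = 1.0 / slope
    psi_b50 = -intercept / slope

    keep = T > Tb
    x = psi[keep] - theta_HT / ((T[keep] - Tb) * t[keep])
    pred_pct = 100.0 * norm.cdf(intercept + slope * x)
    obs_pct = 100.0 * g[keep]
    rmse = float(np.sqrt(np.mean((pred_pct - obs_pct) ** 2)))

    return HydrothermalFit(
        theta_HT=theta_HT,
        Tb=Tb,
        psi_b50=psi_b50,
        sigma_psib=sigma,
        temp_range_used=(min(temps), max(temps)),
        diagnostics=FitDiagnostics(
            r_squared=max(0.0, min(1.0, r2)), rmse=rmse, n_obs=int(g.size), sem=None
        ),
    )


def bootstrap_sem(
    courses: list[GerminationTimeCourse],
    fit: HydrothermalFit,
    *,
    n_boot: int = 200,
    seed: int = 0,
    g_levels=None,
    basis: str = "sown",
    temp_window: tuple[float, float] | None = None,
    fixed_Tb: float | None = None,
) -> tuple[float, np.ndarray]:
    """Nonparametric bootstrap s.e. of θHT over replicate dishes.

    Replicates are resampled with replacement within each treatment; each
    resample is re-truncated, re-pooled and refitted with a warm start at the
    point estimate. Returns (sem, bootstrap θHT draws); failed refits are
    dropped.
    """
    from .germdata import DEFAULT_G_LEVELS

    if g_levels is None:
        g_levels = DEFAULT_G_LEVELS
    rng = np.random.default_rng(seed)
    groups: dict = {}
    for tc in courses:
        groups.setdefault(tc.treatment, []).append(tc)
    draws = []
    for _ in range(n_boot):
        sample = []
        for reps in groups.values():
            idx = rng.integers(0, len(reps), size=len(reps))
            sample.extend(reps[i] for i in idx)
        try:
            sample = [truncate_plateau(tc) for tc in sample]
            sample = exclude_non_germinating(sample)
            pcts = percentiles_by_treatment(sample, g_levels, basis=basis)
            bfit = fit_htt(
                pcts,
                temp_window=temp_window,
                fixed_Tb=fixed_Tb,
                start=(fit.theta_HT, fit.Tb),
            )
            draws.append(bfit.theta_HT)
        except (InsufficientDataError, NonIdentifiableError):
            continue
    draws = np.asarray(draws)
    sem = float(draws.std(ddof=1)) if draws.size > 1 else float("nan")
    return sem, draws


def predict_time_course(fit: HydrothermalFit, T: float, psi: float, times) -> np.ndarray:
    """Cumulative germinated fraction g(t) = Φ((Ψ − θHT/((T−Tb)t) − Ψb50)/σΨb)."""
    times = np.asarray(times, dtype=float)
    if T <= fit.Tb:
        return np.zeros_like(times)
    with np.errstate(divide="ignore"):
        arg = (psi - fit.theta_HT / ((T - fit.Tb) * times) - fit.psi_b50) / fit.sigma_psib
    return norm.cdf(arg)


def equivalent_theta_H(fit: HydrothermalFit, T: float) -> float:
    """Hydrotime constant implied at a fixed temperature: θH = θHT/(T − Tb)."""
    if T <= fit.Tb:
        return float("inf")
    return fit.theta_HT / (T - fit.Tb)
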