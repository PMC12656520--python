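"""Synthetic germination-trial generator and parameter-recovery harness.

The generator embodies the population-threshold generative model: each seed
draws its own base water potential Ψb ~ Normal(Ψb(50), σΨb); at temperature T
and water potential Ψ it germinates at

    t = θHT / ((Ψ − Ψb) · (T − Tb))      when Ψ > Ψb and T > Tb, else never.

Dishes are scored on a fixed interval (a seed is first observed germinated at
the census following its true germination time, i.e. times are discretized
upward), and the trial ends at a census horizon after which ungerminated
seeds are right-censored. The default design mirrors a standard constant-
temperature Petri-dish trial: temperatures 10–45 °C in 5 °C steps, water
potentials 0 to −1.2 MPa imposed with PEG-6000, 4 replicate dishes of 50
seeds, scoring every 8 h for 7 days (168 h).

``exact_percentiles`` produces the noiseless quantile curves of the same
model (no sampling, no discretization) for oracle checks, and
``recovery_suite`` runs generator → pipeline → fit repeatedly to measure
bias, RMSE and coverage of the fitted parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DataError, SeedHTTError
from .germdata import (
    DEFAULT_G_LEVELS,
    GerminationTimeCourse,
    PercentileTimes,
    Treatment,
    exclude_non_germinating,
    percentiles_by_treatment,
    truncate_plateau,
)
from .hydrothermaltime import HydrothermalFit, fit_htt

#: the full experimental grid the generator emulates by default
DEFAULT_TEMPERATURES: tuple[float, ...] = (10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0)
DEFAULT_WATER_POTENTIALS: tuple[float, ...] = (0.0, -0.2, -0.4, -0.6, -0.8, -1.0, -1.2)


@dataclass
class SyntheticTrialConfig:
    """Generative parameters for one synthetic trial."""

    true_theta_HT: float = 500.0  # MPa·°C·h
    true_Tb: float = 10.0  # °C
    true_psi_b50: float = -0.6  # MPa
    true_sigma_psib: float = 0.2  # MPa
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    water_potentials: tuple[float, ...] = DEFAULT_WATER_POTENTIALS
    n_seeds: int = 50  # per dish
    n_reps: int = 4
    scoring_interval: float = 8.0  # h
    census_end: float = 168.0  # h
    rng_seed: int = 0
    cultivar: str = "synthetic"
    overdispersion: float = 0.0  # s.d. of an optional dish-level Ψb50 shift

    def __post_init__(self) -> None:
        for name in ("true_theta_HT", "true_sigma_psib", "scoring_interval", "census_end"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be > 0")
        n_intervals = self.census_end / self.scoring_interval
        if abs(n_intervals - round(n_intervals)) > 1e-9:
            raise DataError("scoring_interval must divide census_end")
        if any(p > 0 for p in self.water_potentials):
            raise DataError("water potentials must be <= 0 MPa")


def _dish_rng(cfg: SyntheticTrialConfig, ti: int, pi: int, rep: int) -> np.random.Generator:
    # per-dish substream keyed by grid position, so adding replicates or
    # grid points never reshuffles the draws of earlier dishes
    ss = np.random.SeedSequence(entropy=cfg.rng_seed, spawn_key=(ti, pi, rep))
    return np.random.default_rng(ss)


def simulate_trial(cfg: SyntheticTrialConfig) -> list[GerminationTimeCourse]:
    """Generate one trial: a time course per (temperature, Ψ, replicate) dish."""
    times = np.arange(
        cfg.scoring_interval, cfg.census_end + cfg.scoring_interval / 2, cfg.scoring_interval
    )
    out: list[GerminationTimeCourse] = []
    for ti, T in enumerate(cfg.temperatures):
        for pi, psi in enumerate(cfg.water_potentials):
            for rep in range(cfg.n_reps):
                rng = _dish_rng(cfg, ti, pi, rep)
                psi_b50 = cfg.true_psi_b50
                if cfg.overdispersion > 0:
                    psi_b50 = psi_b50 + rng.normal(0.0, cfg.overdispersion)
                psi_b = rng.normal(psi_b50, cfg.true_sigma_psib, size=cfg.n_seeds)
                if T > cfg.true_Tb:
                    drive = (psi - psi_b) * (T - cfg.true_Tb)
                    with np.errstate(divide="ignore"):
                        t_germ = np.where(drive > 0, cfg.true_theta_HT / drive, np.inf)
                else:
                    t_germ = np.full(cfg.n_seeds, np.inf)
                # first census at/after the true time; censored past the horizon
                t_obs = np.ceil(t_germ / cfg.scoring_interval) * cfg.scoring_interval
                counts = (t_obs[None, :] <= times[:, None]).sum(axis=1)
                out.append(
                    GerminationTimeCourse(
                        treatment=Treatment(cfg.cultivar, float(T), float(psi)),
                        replicate=rep + 1,
                        n_sown=cfg.n_seeds,
                        times=times.copy(),
                        cum_germinated=counts.astype(float),
                    )
                )
    return out


def exact_percentiles(
    theta_HT: float,
    Tb: float,
    psi_b50: float,
    sigma_psib: float,
    temperatures,
    water_potentials,
    g_levels=DEFAULT_G_LEVELS,
    *,
    cultivar: str = "synthetic",
    census_end: float | None = None,
) -> list[PercentileTimes]:
    """Noiseless percentile times straight from the model quantiles.

    The seed at population quantile g has Ψb(g) = Ψb50 + σΨb·probit(g) and
    germinates at t(g) = θHT/((Ψ − Ψb(g))(T − Tb)). Optionally censors t(g)
    beyond ``census_end`` (undefined, as in a real trial).
    """
    g_levels = np.asarray(g_levels, dtype=float)
    out = []
    for T in temperatures:
        for psi in water_potentials:
            psi_b_g = psi_b50 + sigma_psib * norm.ppf(g_levels)
            if T > Tb:
                drive = (psi - psi_b_g) * (T - Tb)
                with np.errstate(divide="ignore"):
                    t_g = np.where(drive > 0, theta_HT / drive, np.nan)
            else:
                t_g = np.full(g_levels.shape, np.nan)
            if census_end is not None:
                t_g = np.where(t_g <= census_end, t_g, np.nan)
            out.append(
                PercentileTimes(
                    treatment=Treatment(cultivar, float(T), float(psi)),
                    g_levels=g_levels,
                    t_g=t_g,
                    final_fraction=float(norm.cdf((psi - psi_b50) / sigma_psib)),
                )
            )
    return out


@dataclass
class RecoveryReport:
    """Parameter-recovery summary over repeated simulated trials."""

    runs: pd.DataFrame  # one row per run: fitted parameters or failure note
    bias: dict[str, float]
    rmse: dict[str, float]
    coverage: float  # fraction of successful runs with all params in tolerance
    tolerances: dict[str, float]
    n_runs: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise DataError("coverage must lie in [0, 1]")


#: recovery tolerances: |θ̂HT/θHT − 1|, |T̂b − Tb|, |Ψ̂b50 − Ψb50|, |σ̂ − σ|
DEFAULT_TOLERANCES: dict[str, float] = {
    "theta_HT_rel": 0.15,
    "Tb_abs": 1.5,
    "psi_b50_abs": 0.05,
    "sigma_psib_abs": 0.05,
}


def run_pipeline_fit(
    courses: list[GerminationTimeCourse],
    g_levels=DEFAULT_G_LEVELS,
    *,
    basis: str = "sown",
    **fit_kwargs,
) -> HydrothermalFit:
    """Standard pipeline: truncate → exclude zero-germination → pool → HTT fit."""
    courses = [truncate_plateau(tc) for tc in courses]
    courses = exclude_non_germinating(courses)
    pcts = percentiles_by_treatment(courses, g_levels, basis=basis)
    return fit_htt(pcts, **fit_kwargs)


def recovery_suite(
    cfg: SyntheticTrialConfig,
    n_runs: int = 20,
    tolerances: dict[str, float] | None = None,
    *,
    g_levels=DEFAULT_G_LEVELS,
    fit_marginals: bool = False,
) -> RecoveryReport:
    """Repeated simulate → fit cycles measuring recovery of the HTT parameters.

    Run r uses rng_seed + r, so the whole suite is reproducible from the
    config seed. Fitter failures are recorded per run, never fatal.
    """
    if n_runs < 1:
        raise DataError("n_runs must be >= 1")
    tol = dict(DEFAULT_TOLERANCES if tolerances is None else tolerances)
    truth = {
        "theta_HT": cfg.true_theta_HT,
        "Tb": cfg.true_Tb,
        "psi_b50": cfg.true_psi_b50,
        "sigma_psib": cfg.true_sigma_psib,
    }
    rows = []
    for r in range(n_runs):
        run_cfg = SyntheticTrialConfig(
            **{
                **cfg.__dict__,
                "rng_seed": int(cfg.rng_seed + r) % (2**31),
            }
        )
        row: dict = {"run": r, "seed": run_cfg.rng_seed, "ok": False, "error": ""}
        try:
            courses = simulate_trial(run_cfg)
            fit = run_pipeline_fit(courses, g_levels)
            row.update(
                ok=True,
                theta_HT=fit.theta_HT,
                Tb=fit.Tb,
                psi_b50=fit.psi_b50,
                sigma_psib=fit.sigma_psib,
                r_squared=fit.diagnostics.r_squared,
            )
            row["within_tol"] = (
                abs(fit.theta_HT / truth["theta_HT"] - 1) <= tol["theta_HT_rel"]
                and abs(fit.Tb - truth["Tb"]) <= tol["Tb_abs"]
                and abs(fit.psi_b50 - truth["psi_b50"]) <= tol["psi_b50_abs"]
                and abs(fit.sigma_psib - truth["sigma_psib"]) <= tol["sigma_psib_abs"]
            )
            if fit_marginals:
                row["n_marginal_fits"] = _count_marginal_fits(courses, g_levels)
        except SeedHTTError as exc:
            row["error"] = str(exc)
            row["within_tol"] = False
        rows.append(row)
    runs = pd.DataFrame(rows)
    ok = runs[runs["ok"]]
    bias, rmse = {}, {}
    for key, true_val in truth.items():
        if len(ok):
            err = ok[key].to_numpy() - true_val
            bias[key] = float(err.mean())
            rmse[key] = float(np.sqrt((err**2).mean()))
        else:
            bias[key] = rmse[key] = float("nan")
    coverage = float(runs["within_tol"].mean()) if len(runs) else 0.0
    return RecoveryReport(
        runs=runs, bias=bias, rmse=rmse, coverage=coverage,
        tolerances=tol, n_runs=n_runs,
    )


def _count_marginal_fits(courses, g_levels) -> int:
    """Fit TT per water potential and HT per temperature; count successes."""
    from .hydrotime import fit_hydrotime
    from .thermaltime import fit_thermal_time

    courses = [truncate_plateau(tc) for tc in courses]
    courses = exclude_non_germinating(courses)
    pcts = percentiles_by_treatment(courses, g_levels)
    n = 0
    for psi in sorted({p.treatment.water_potential for p in pcts}):
        subset = [p for p in pcts if p.treatment.water_potential == psi]
        try:
            fit_thermal_time(subset)
            n += 1
        except SeedHTTError:
            pass
    for T in sorted({p.treatment.temperature for p in pcts}):
        subset = [p for p in pcts if p.treatment.temperature == T]
        try:
            fit_hydrotime(subset)
            n += 1
        except SeedHTTError:
            pass
    return n
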