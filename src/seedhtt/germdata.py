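"""Data model for germination trials.

A trial scores, every few hours, how many seeds in a dish have produced a
radicle. The raw observable is the cumulative germinated count over scoring
times for one (cultivar, temperature, water potential, replicate) cell. This
module reads and writes that tabular format, applies the standard
pre-analysis rules (plateau truncation, exclusion of treatments with no
germinants), pools replicates, and interpolates the pooled cumulative curve
to per-subpopulation germination times t(g) and rates GR(g) = 1/t(g) — the
quantities every threshold model downstream consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

#: default subpopulation fractions at which germination times are computed
DEFAULT_G_LEVELS: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)

#: columns a counts table must provide
COUNTS_SCHEMA: tuple[str, ...] = (
    "cultivar",
    "temperature_C",
    "water_potential_MPa",
    "replicate",
    "n_sown",
    "time_h",
    "cum_germinated",
)


@dataclass(frozen=True)
class Treatment:
    """One experimental condition: cultivar at a temperature and water potential."""

    cultivar: str
    temperature: float  # °C
    water_potential: float  # MPa, <= 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature):
            raise DataError(f"temperature must be finite, got {self.temperature}")
        if self.water_potential > 0:
            raise DataError(
                f"water potential must be <= 0 MPa, got {self.water_potential}"
            )


@dataclass
class GerminationTimeCourse:
    """Cumulative germinated counts over scoring times for one dish."""

    treatment: Treatment
    replicate: int
    n_sown: int
    times: np.ndarray  # hours since imbibition, strictly increasing, > 0
    cum_germinated: np.ndarray  # aligned with times, non-decreasing
    non_germinating: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cum_germinated = np.asarray(self.cum_germinated, dtype=float)
        if self.times.shape != self.cum_germinated.shape:
            raise DataError("times and cum_germinated must have equal length")
        if self.times.size == 0:
            raise DataError("empty time course")
        if np.any(self.times <= 0):
            raise DataError("scoring times must be > 0 h")
        if np.any(np.diff(self.times) <= 0):
            raise DataError("scoring times must be strictly increasing")
        if np.any(np.diff(self.cum_germinated) < 0):
            bad = int(np.flatnonzero(np.diff(self.cum_germinated) < 0)[0]) + 1
            raise DataError(
                f"cumulative count decreases at observation {bad} "
                f"(t={self.times[bad]} h) for {self.treatment}, "
                f"replicate {self.replicate}"
            )
        if np.any(self.cum_germinated < 0) or np.any(self.cum_germinated > self.n_sown):
            raise DataError("cumulative counts must lie in [0, n_sown]")


@dataclass
class PercentileTimes:
    """Times and rates to reach subpopulation fractions g on a pooled curve.

    ``t_g`` holds NaN where a fraction is never reached within the census
    (flagged, never silently zero); ``gr_g`` is the elementwise reciprocal.
    ``final_fraction`` is the pooled end-of-census germinated fraction on the
    same basis as the percentiles.
    """

    treatment: Treatment
    g_levels: np.ndarray
    t_g: np.ndarray
    gr_g: np.ndarray = field(init=False)
    final_fraction: float = float("nan")
    basis: str = "sown"

    def __post_init__(self) -> None:
        self.g_levels = np.asarray(self.g_levels, dtype=float)
        self.t_g = np.asarray(self.t_g, dtype=float)
        with np.errstate(divide="ignore"):
            self.gr_g = np.where(np.isnan(self.t_g), np.nan, 1.0 / self.t_g)

    def defined(self) -> np.ndarray:
        """Boolean mask of fractions actually reached."""
        return ~np.isnan(self.t_g)


# ---------------------------------------------------------------------------
# reading / writing


def read_counts(path, *, delimiter: str = ",") -> list[GerminationTimeCourse]:
    """Read a counts table into one time course per (treatment, replicate).

    The file must provide the columns in :data:`COUNTS_SCHEMA`; rows are
    sorted by time within each dish and validated (non-decreasing counts).
    """
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in COUNTS_SCHEMA if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    out: list[GerminationTimeCourse] = []
    keys = ["cultivar", "temperature_C", "water_potential_MPa", "replicate"]
    for (cult, temp, psi, rep), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_h")
        n_sown = grp["n_sown"].unique()
        if len(n_sown) != 1:
            raise DataError(
                f"n_sown varies within dish ({cult}, {temp} °C, {psi} MPa, rep {rep})"
            )
        out.append(
            GerminationTimeCourse(
                treatment=Treatment(str(cult), float(temp), float(psi)),
                replicate=int(rep),
                n_sown=int(n_sown[0]),
                times=grp["time_h"].to_numpy(dtype=float),
                cum_germinated=grp["cum_germinated"].to_numpy(dtype=float),
            )
        )
    return out


def write_counts(courses: list[GerminationTimeCourse], path, *, delimiter: str = ",") -> None:
    """Write time courses back to the tabular schema read by :func:`read_counts`."""
    rows = []
    for tc in courses:
        for t, c in zip(tc.times, tc.cum_germinated):
            rows.append(
                {
                    "cultivar": tc.treatment.cultivar,
                    "temperature_C": tc.treatment.temperature,
                    "water_potential_MPa": tc.treatment.water_potential,
                    "replicate": tc.replicate,
                    "n_sown": tc.n_sown,
                    "time_h": t,
                    "cum_germinated": int(c),
                }
            )
    pd.DataFrame(rows, columns=list(COUNTS_SCHEMA)).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# pre-analysis rules


def truncate_plateau(tc: GerminationTimeCourse) -> GerminationTimeCourse:
    """Drop trailing observations after germination stops increasing.

    Observations with no further increase during the rest of the test are
    removed, keeping the first time the maximum count is reached. A course
    with no germinants at all is collapsed to its final observation and
    flagged ``non_germinating``.
    """
    counts = tc.cum_germinated
    if counts.max() == 0:
        return replace(
            tc,
            times=tc.times[-1:],
            cum_germinated=counts[-1:],
            non_germinating=True,
        )
    last = int(np.flatnonzero(counts == counts.max())[0])
    return replace(
        tc,
        times=tc.times[: last + 1],
        cum_germinated=counts[: last + 1],
        non_germinating=False,
    )


def final_germination(tc: GerminationTimeCourse) -> float:
    """Final germination percentage: 100 · max(count) / seeds sown."""
    if tc.n_sown == 0:
        raise DataError("n_sown is zero")
    return 100.0 * float(tc.cum_germinated.max()) / tc.n_sown


def exclude_non_germinating(
    courses: list[GerminationTimeCourse], *, min_germinated: int = 1
) -> list[GerminationTimeCourse]:
    """Drop treatments whose pooled germinant count is below ``min_germinated``.

    The default removes exactly the zero-germination treatments (the standard
    rule for temperatures or potentials at which nothing germinates); the
    threshold is configurable upward.
    """
    totals: dict[Treatment, float] = {}
    for tc in courses:
        totals[tc.treatment] = totals.get(tc.treatment, 0.0) + float(tc.cum_germinated.max())
    return [tc for tc in courses if totals[tc.treatment] >= min_germinated]


# ---------------------------------------------------------------------------
# pooling and interpolation


def pool_replicates(
    courses: list[GerminationTimeCourse],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pool replicate dishes of one treatment into (times, pooled counts, n_sown).

    Counts are summed on the union time grid; each replicate's cumulative
    count is carried forward between its own scoring times (and is 0 before
    its first observation). Pooling is count-weighted by construction, never
    an average of replicate percentages.
    """
    if not courses:
        raise DataError("no time courses to pool")
    tr = courses[0].treatment
    if any(tc.treatment != tr for tc in courses):
        raise DataError("pool_replicates requires a single treatment")
    grid = np.unique(np.concatenate([tc.times for tc in courses]))
    pooled = np.zeros_like(grid)
    for tc in courses:
        idx = np.searchsorted(tc.times, grid, side="right") - 1
        vals = np.where(idx >= 0, tc.cum_germinated[np.clip(idx, 0, None)], 0.0)
        pooled += vals
    return grid, pooled, int(sum(tc.n_sown for tc in courses))


def time_to_fraction(
    times: np.ndarray, fractions: np.ndarray, g: float
) -> float:
    """Hours for the cumulative-fraction curve to first reach fraction ``g``.

    Linear interpolation between the bracketing scoring times; NaN (undefined,
    flagged by the caller) when the curve never reaches ``g``. No
    extrapolation before the first or after the last scoring time.
    """
    if not 0.0 < g < 1.0:
        raise DataError(f"g must be in (0, 1), got {g}")
    times = np.asarray(times, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    reached = np.flatnonzero(fractions >= g)
    if reached.size == 0:
        return float("nan")
    i = int(reached[0])
    if fractions[i] == g:
        return float(times[i])
    if i == 0:  # already above g at the first census: no extrapolation
        return float("nan")
    t0, t1 = times[i - 1], times[i]
    f0, f1 = fractions[i - 1], fractions[i]
    return float(t0 + (g - f0) * (t1 - t0) / (f1 - f0))


def percentile_times(
    courses: list[GerminationTimeCourse],
    g_levels: tuple[float, ...] | np.ndarray = DEFAULT_G_LEVELS,
    *,
    basis: str = "sown",
) -> PercentileTimes:
    """Interpolate the pooled curve of one treatment to t(g) at each level.

    ``basis`` selects the denominator of the cumulative fraction: seeds sown
    (default, the whole-lot subpopulation convention used by population
    threshold models) or the final germinated count of the treatment.
    """
    if basis not in ("sown", "final"):
        raise SchemaError(f"basis must be 'sown' or 'final', got {basis!r}")
    grid, pooled, n_sown = pool_replicates(courses)
    final_frac_sown = float(pooled[-1] / n_sown) if n_sown else float("nan")
    denom = n_sown if basis == "sown" else pooled[-1]
    if denom == 0:
        t_g = np.full(len(g_levels), np.nan)
    else:
        frac = pooled / denom
        t_g = np.array([time_to_fraction(grid, frac, g) for g in g_levels])
    return PercentileTimes(
        treatment=courses[0].treatment,
        g_levels=np.asarray(g_levels, dtype=float),
        t_g=t_g,
        final_fraction=final_frac_sown if basis == "sown" else 1.0,
        basis=basis,
    )


def percentiles_by_treatment(
    courses: list[GerminationTimeCourse],
    g_levels: tuple[float, ...] | np.ndarray = DEFAULT_G_LEVELS,
    *,
    basis: str = "sown",
) -> list[PercentileTimes]:
    """Group courses by treatment and compute :func:`percentile_times` for each."""
    groups: dict[Treatment, list[GerminationTimeCourse]] = {}
    for tc in courses:
        groups.setdefault(tc.treatment, []).append(tc)
    return [
        percentile_times(grp, g_levels, basis=basis) for grp in groups.values()
    ]


def percentiles_to_frame(percentiles: list[PercentileTimes]) -> pd.DataFrame:
    """Tidy table of percentile germination times (one row per treatment × g)."""
    rows = []
    for p in percentiles:
        for g, t, gr in zip(p.g_levels, p.t_g, p.gr_g):
            rows.append(
                {
                    "cultivar": p.treatment.cultivar,
                    "temperature_C": p.treatment.temperature,
                    "water_potential_MPa": p.treatment.water_potential,
                    "g": g,
                    "t_g_h": t,
                    "gr_g_per_h": gr,
                    "defined": not math.isnan(t),
                    "basis": p.basis,
                }
            )
    return pd.DataFrame(rows)
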