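# Methods and numerical decisions

This document records the modelling assumptions and numerical choices made in
`seedhtt`, in enough detail that the results of any fit can be reproduced and
audited.

## 1. Data model

The unit of raw data is a **germination time course**: one Petri dish
(replicate) of `n_sown` seeds under one treatment (cultivar, temperature `T`
in °C, water potential `Ψ` in MPa, with `Ψ ≤ 0`), scored at a strictly
increasing set of census times (hours) as cumulative germinated counts.
Validation rejects decreasing counts, counts above `n_sown`, and
non-positive or non-increasing times, naming the offending row.

Preprocessing pipeline, in order:

1. **Plateau truncation.** Only censuses up to the first time the maximum
   count is reached are kept; trailing flat observations carry no timing
   information and would otherwise distort interpolation. A dish with zero
   germination throughout is flagged `non_germinating`.
2. **Exclusion of non-germinating treatments.** Treatments whose pooled
   final count falls below a threshold (default 1 germinant) are excluded
   from model fitting; exclusions are listed in the run manifest. A model of
   germination *timing* has no observations in such cells.
3. **Replicate pooling.** Replicates of a treatment are merged on the union
   of their census grids (counts carried forward between a dish's own
   censuses) and pooled by **summing counts**, i.e. count-weighted, not by
   averaging replicate percentages. Dishes with unequal `n_sown` therefore
   contribute proportionally to their size.
4. **Percentile times.** `t(g)` is obtained by linear interpolation of the
   pooled cumulative fraction against time, taking the earliest crossing.
   No extrapolation: if fraction `g` is never reached, or is already
   exceeded at the first census (so the crossing time is unidentified),
   `t(g)` is NaN and that point is simply absent from the fits. The default
   percentile grid is the deciles `g = 0.1 … 0.9`.

**Fraction basis.** Percentiles are computed on a **sown-seed basis** by
default (`g` = fraction of seeds sown), with a `final` basis (fraction of
seeds that eventually germinated) available as an option. The sown basis is
the one consistent with the population-threshold interpretation: the normal
distribution of `Ψb` itself explains why a fraction of the sown population
never germinates at a given `Ψ`, so renormalising to the germinated subset
would double-count that mechanism.

## 2. The three models

All three treat percentile `g` of the seed population as requiring a fixed
accumulated "time" before germination; differences lie in which environmental
factor drives accumulation and where the population variation sits.

### Thermal time (`fit_thermal_time`)

`θT(g) = (T − Tb) · t(g)` in the sub-optimal range, i.e.
`GR(g) = 1/t(g) = (T − Tb)/θT(g)`, linear in `T`. The fit is an ordinary
least-squares regression of `GR(g)` on `T` (one fit per `g`, typically
`g = 0.5`), giving `Tb = −a/b` and `θT = 1/b` from intercept `a` and slope
`b`. Requirements and conventions:

- ≥ 3 temperatures with defined `t(g)`; a non-positive slope means the rate
  does not increase with temperature and raises `NonIdentifiableError` —
  there is no base temperature to extrapolate to.
- **Sub-optimal masking:** by default only temperatures up to the
  temperature of maximum `GR` enter the regression, since the linear model
  holds only below the optimum. Supra-optimal data are reported but not fit.
- `fixed_Tb` mode regresses `GR` on `(T − Tb)` through the origin.
- `sem(θT) = se(b)/b²` by the delta method.
- **GR(50) at a reference temperature** (default 25 °C) is reported so that
  rates are comparable across fits whose temperature ranges differ; the raw
  per-temperature rates remain in the percentile tables.

### Hydrotime (`fit_hydrotime`)

At a single temperature, `θH = (Ψ − Ψb(g)) · t(g)` with
`Ψb(g) ~ Normal(Ψb(50), σΨb)`. Estimation is nested: for a candidate `θH`,
`probit(g)` is regressed on `Ψ − θH/t(g)`; the R² of that regression scores
the candidate. `Ψb(50) = −intercept/slope`, `σΨb = 1/slope`.

- Candidate grid: 60 logarithmically spaced points on `θH ∈ [0.1, 500]`
  MPa·h, followed by bounded scalar minimisation (golden/Brent) around the
  best grid point to relative tolerance 1e-4. The log grid reflects the
  scale-parameter nature of `θH`; the bounds comfortably cover germination
  on hour-to-week timescales, and a solution at either bound raises a
  `BoundaryWarning` rather than being silently accepted.
- Inputs must share one temperature (mixed temperatures are an error — that
  is the hydrothermal model's job), with ≥ 2 water potentials and ≥ 4
  defined `(g, Ψ, t)` points; fractions outside (0, 1) are dropped before
  the probit transform.
- Predicted final germination at a **reference Ψ** (default: the highest Ψ
  present) is `100·Φ((Ψref − Ψb(50))/σΨb)`, reported next to the observed
  final percentage at that Ψ.

### Hydrothermal time (`fit_htt`)

`θHT = (Ψ − Ψb(g)) · (T − Tb) · t(g)`, fitted jointly over the whole
`T × Ψ` grid. For candidate `(θHT, Tb)` the probit regression above is run
on all defined points with `T > Tb`; R² scores the pair.

- **Tb is estimated jointly** with `θHT` by default rather than imported
  from the thermal-time fit: the two sub-models make different assumptions
  (thermal time conditions on non-limiting water; hydrothermal time uses
  all `Ψ` levels), and fixing `Tb` from one inside the other would hide
  disagreement between them. `fixed_Tb` remains available for the
  conditional fit.
- Coarse search: 50 log-spaced `θHT` points on `[1, 50000]` MPa·°C·h
  crossed with a `Tb` grid from 0 °C to (lowest observed `T` − 1) in 0.5 °C
  steps. Refinement: coordinate descent alternating bounded 1-D
  minimisations in `log θHT` and `Tb` (relative tolerance 1e-4, at most 30
  sweeps, exiting when neither coordinate moves). Boundary solutions raise
  `BoundaryWarning`.
- Requirements: ≥ 3 temperatures and ≥ 2 water potentials after the
  optional `temp_window` restriction (used to confine the fit to the
  sub-optimal range when supra-optimal temperatures are present).
- `equivalent_theta_H(fit, T) = θHT/(T − Tb)` recovers the implied
  single-temperature hydrotime constant; `predict_time_course` gives
  `G(t) = Φ((Ψ − θHT/((T−Tb)t) − Ψb(50))/σΨb)`, zero at or below `Tb`.

### Goodness-of-fit units

Two RMSE conventions exist in this literature, and the package keeps them
deliberately distinct (and records which is which in the run manifest):

- Thermal time: R² on the **rate scale** (the scale of the regression), but
  RMSE in **hours** on back-predicted `t(g)` — timing error in natural units.
- Hydrotime and hydrothermal time: RMSE in **percentage points** between
  observed cumulative germination and the model's `100·Φ(·)` prediction at
  the observed `(T, Ψ, t)` points. R² is that of the probit regression.

## 3. PEG-6000 osmoticum calibration

Water potential of PEG-6000 solutions follows the Michel–Kaufmann
polynomial, with `C` in g/L and `T` in °C, in bars (converted to MPa by
dividing by 10):

```
Ψ[bar] = −1.18e−2·C − 1.18e−4·C² + 2.67e−4·C·T + 8.39e−7·C²·T
```

The inverse (concentration needed for a target `Ψ` at a given `T`) has no
closed form and is obtained by `brentq` root bracketing on
`C ∈ [0, 600] g/L` with `xtol = 1e-10`; `Ψ` is monotone decreasing in `C`
over this range at the supported temperatures, so the root is unique. 600
g/L is far beyond any concentration used in germination assays.

## 4. Synthetic trial generator (`simulate`)

The generator emulates a **thermal-gradient germination assay**: a factorial
of constant temperatures × PEG-imposed water potentials, replicate Petri
dishes of `n_seeds` each, scored on a fixed interval up to a final census.
The generative model *is* the hydrothermal-time model:

1. Each seed draws `Ψb ~ Normal(Ψb(50), σΨb)` independently.
2. Its germination time is `t = θHT / ((Ψ − Ψb)(T − Tb))`; seeds with
   `Ψ ≤ Ψb` or `T ≤ Tb` never germinate.
3. Times are **discretised up** to the next scoring census (an observer
   records a seed at the first census after emergence) and right-censored
   at the end of the trial.

Defaults (study-scale conditions, not tuning knobs): `θHT = 500 MPa·°C·h`,
`Tb = 10 °C`, `Ψb(50) = −0.6 MPa`, `σΨb = 0.2 MPa`; temperatures 10–45 °C in
5 °C steps; `Ψ` from 0 to −1.2 MPa; 4 dishes × 50 seeds; scored every 8 h
for 168 h (one week). The config validates that the interval divides the
census length, `Ψ ≤ 0`, and positivity of sizes.

What the generator deliberately does **not** emulate: dormancy or viability
loss, ageing, fungal loss of seeds, oxygen limitation at low `Ψ`,
temperature-dependent `Ψb` shifts (the usual explanation of supra-optimal
slowdown), or observer miscounts. It is the exact null model of the fitter,
which is what makes it usable as an oracle: any estimation error is
attributable to sampling, discretisation, censoring, and the pipeline — not
model misspecification.

**Reproducibility.** Dish-level RNG streams come from
`np.random.SeedSequence(entropy=seed, spawn_key=(temp_index, psi_index,
replicate))`, so output is identical across runs for a given seed and —
importantly — adding replicates or treatments leaves existing dishes'
draws unchanged. All derived integer seeds are reduced mod 2³¹.

**Recovery suite.** `recovery_suite(cfg, n_runs)` simulates and refits
`n_runs` independent trials (run `r` reseeded as `(seed + r) mod 2³¹`),
reporting bias, RMSE and coverage of the hydrothermal parameters against
tolerances `{θHT: 15% rel, Tb: 1.5 °C, Ψb(50): 0.05 MPa, σΨb: 0.05 MPa}` —
roughly the precision a 4×50-seed design supports. Failed refits are
recorded per-run, not silently dropped. Coverage is judged on the four
hydrothermal parameters, since they generate the data; marginal TT/HT fits
can be computed per run but are diagnostics, not coverage criteria.

**Bootstrap standard error.** `bootstrap_sem` resamples replicates *within*
each treatment with replacement (the dish is the independent unit),
re-truncates, re-pools and refits each resample, **warm-starting** the
coordinate descent at the point estimate (the resampled optimum is near the
original, so the coarse grid would be wasted effort). Default `B = 200`;
resamples whose refit fails are dropped and counted; `sem` is the standard
deviation (ddof = 1) of the successful `θHT` draws.

## 5. Multivariate module

- **PCA** on the correlation matrix (variables standardised with
  `ddof = 1`), eigendecomposition via `scipy.linalg.eigh`. Loadings are
  `eigvec·√λ` (equal to the correlation between variable and component
  score); contributions are `100·eigvec²` (summing to 100 per component);
  `cos² = loading²`. **Sign convention:** each component is flipped so its
  largest-|loading| variable is positive — eigenvectors are sign-arbitrary
  and a deterministic convention keeps outputs reproducible. Supplementary
  variables are projected as correlations with the scores and do not enter
  the decomposition. A zero-variance active column is an error naming the
  column (its correlation is undefined).
- **Clustering on components (HCPC-style):** Ward linkage
  (`scipy.cluster.hierarchy`) on the retained PC scores (retention by count
  or by cumulative-variance fraction), cut at `k` clusters. Labels are
  relabelled canonically (by size descending, ties by first member) so they
  are invariant to row order up to the partition.
- **Trait correlations:** Pearson `r` with p-values; `n < 10` flagged
  `low_power`, constant columns flagged `undefined` rather than erroring.

## 6. Problem sizes and runtime

The package's own defaults are sized so that a full simulate–fit round trip
(8×5 grid, 4×50 seeds) fits comfortably in interactive use: the HTT coarse
grid is 50×~`n_Tb` regressions of a few hundred points each, and the
bootstrap at `B = 200` re-runs only the warm-started refinement. These are
package choices about default problem size, not guarantees about any
particular machine.

## 7. Known limitations

- The thermal-time fitter models only the sub-optimal range; supra-optimal
  behaviour (ceiling temperatures, `Ψb(g)` shifting upward with `T`) is not
  modelled, only avoidable via masking/`temp_window`.
- `t(g)` interpolation is linear between censuses; with coarse scoring
  intervals this discretisation is a real (if small) error source, and it
  is the dominant one for large dishes.
- The probit regression treats interpolated `t(g)` points as exact
  observations; percentile estimates from small dishes are noisy in a way
  the OLS weighting ignores.
- `σΨb` is assumed constant across temperatures in the joint model.
- The bootstrap resamples dishes, so designs with a single replicate per
  treatment cannot produce a meaningful standard error.
- The published PEG-concentration tables this calibration is usually checked
  against contain a handful of entries that differ from the polynomial
  itself by up to ~0.22 g/L; the package reproduces the polynomial, not the
  typos.
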