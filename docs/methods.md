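# Methods

## The problem

Groundfish survey series record, for every tow, where it fished (position,
depth), the bottom temperature, and how many individuals of a target
species came up in the net; for a subsample of individuals they record
length, weight, sex and maturity stage. `trawlniche` turns those three
tables into the standard habitat-preference and life-history summaries
used for data-poor bycatch species such as small deep-water sharks:
catch-weighted niche indices, maturity ogives, allometric length-weight
fits, diet composition, subgroup habitat envelopes, and a survey
abundance index.

## Catch-weighted niche statistics

All niche statistics compare two distributions over the same tows: the
*unweighted* distribution of an environmental variable over every station
fished (the available habitat), and the *catch-weighted* distribution in
which each station counts once per individual caught there (the occupied
habitat). Null tows therefore shape the unweighted distribution and
contribute nothing to the weighted one.

* **Thermal bias (TB, °C)** — median catch-weighted temperature minus the
  median station temperature. Positive TB = the species concentrates in
  water warmer than the survey average (warm-water affinity). TB is
  defined through medians; a mean-based restatement sometimes circulates
  but the median form is what this package computes.
* **Steno index (°C)** — width of the 5th–95th percentile interval of the
  catch-weighted temperature. Small = stenothermal, large = eurythermal.
  No classification threshold exists for "small", so the package reports
  the raw index and only labels the *sign* of TB.
* **Occupancy intervals** — weighted or unweighted quantile pairs for
  temperature or depth. The default pair is (0.05, 0.95), i.e. a "90%
  range"; (0.10, 0.90) is selectable because both conventions appear in
  survey reports. The pair used is always recorded in the output.

**Quantile convention.** Weighted quantiles use linear interpolation on
the expanded per-individual vector: for integer catch weights the result
is exactly `numpy`'s linear-interpolation quantile of the vector in which
each station value is repeated `catch` times (position
`h = (W−1)p + 1` on total weight `W`, generalized to fractional weights
by interpolating cumulative-weight positions). The expanded vector is the
natural estimand because the statistics are statements about individuals
("90% of the sharks"), not stations. Consequence worth knowing: at a
support point `x`, `Q(F(x))` lies between `x` and the next support value
(interpolation looks rightward), so quantile and CDF are inverses only up
to that sandwich.

Stations with a missing temperature are excluded from both weighted and
unweighted temperature statistics — never imputed — and the exclusion
count is reported. TB and Steno pool both seasonal surveys across all
years by default; occupancy intervals are usually more informative per
season, and a season filter is available everywhere.

The seasonal temperature comparison is a two-group one-way ANOVA
(`scipy.stats.f_oneway`); with two groups F is identically the square of
the pooled-variance t statistic, which the tests verify to 1e−10.

## Life history

**Maturity ogive.** Binary maturity (default: stages 3–7 mature on the
7-point elasmobranch scale, an overridable named scheme) is regressed on
total length with a Bernoulli-logit GLM maximized in-package by
Newton–Raphson with step-halving: accepted steps never decrease the
likelihood, convergence is a score norm below 1e−8 (cap 100 iterations),
and the coefficient covariance is the inverse observed information at the
optimum. `L50 = −β0/β1` and `L95 = (ln 19 − β0)/β1`. Initialization is
`β0 = logit(overall mature fraction), β1 = 0` — deterministic and
tie-free. Quasi-separation (diverging coefficients, or every fitted
probability pinned at 0/1) marks the fit unconverged with a separation
flag; predictions from unconverged fits raise rather than mislead.
The implementation is cross-checked against `statsmodels.Logit` in the
test suite but does not depend on it.

L50 uncertainty is a nonparametric percentile bootstrap (records
resampled with replacement; refits that fail are dropped and counted,
with >50% failures aborting). The bootstrap is the primary method because
survey ogives are routinely published without uncertainty and the
bootstrap makes the fewest assumptions; a delta-method interval is
provided as a cross-check.

**Length-weight.** The allometric power law `W = a·TL^b` is fitted as OLS
of `ln W` on `ln TL`; `log_a` is reported on the natural-log scale and r²
on the log-log scale. The reference coefficients used throughout the
synthetic model, `log_a = −5.73` and `b = 3.06`, are read as natural-log
parameters (`a = e^−5.73 ≈ 0.00324 g·cm⁻³·⁰⁶`): this yields ≈650 g for a
54 cm female, consistent with observed mature-female weights, whereas a
base-10 reading yields sub-gram weights.

## Ecology summaries

**Diet.** Vacuity = % of all stomachs empty. Frequency of occurrence uses
*non-empty* stomachs as the denominator — with 27 stomachs of which 19%
are empty, the printed occurrence percentages (50/41/18/14/5) are
integer-consistent with counts out of 22 non-empty stomachs and not with
counts out of 27. Weight percent is the category's share of total content
mass, summing to 100 when every gram is categorized; occurrence may sum
past 100 through co-occurrence. All-empty collections return vacuity with
occurrence/weight undefined (`None`), not zero.

**Envelopes.** A subgroup envelope aggregates at the individual level:
each selected shark inherits its station's depth/temperature/position,
and a tow with k selected sharks contributes k times to the mean, because
the ranges being mimicked are phrased over individuals caught. The
critical-habitat construction intersects the depth and temperature
intervals of the late-pregnancy female envelope (stages 5–6 by default)
and the ≤20 cm juvenile envelope; a disjoint intersection is a result
("disjoint"), not an error.

**Abundance.** The annual index is mean catch per tow per (year, season),
null tows included — the simplest effort-normalized index when tow effort
is treated as uniform. Raw totals and tow counts are emitted alongside so
any alternative normalization can be recomputed, and an OLS trend of the
index on year carries a 95% t-interval on its slope.

## The synthetic survey generator

The generator exists so every stage is testable end to end with known
truth; its defaults are the package's reference study conditions.

* **Stations**: two seasonal surveys per year over 11 years
  (2010–2020), 5,300 tows per season by default (~10.6k total);
  depths uniform on 18–550 m (spring) and 23–1359 m (autumn); positions
  uniform in a box south-west of Iceland (62–65.5 °N, 28–14 °W,
  west-negative).
* **Thermal field**: `independent` mode (default) draws bottom
  temperature N(μ_T = 5.69, σ_T = 2.5) °C independently of depth;
  `depth_linked` mode declines linearly with depth plus a seasonal offset
  and noise, for exercising depth analyses (no closed forms there).
* **Catches**: `Poisson(A·exp(−(T−c)²/2σ_c²))` with c = 7.2507 °C,
  σ_c = 0.6567 °C, A = 5. In independent mode the catch-weighted
  temperature is then the normalized product of two Gaussians —
  N(7.150, 0.6352²) — so TB = 7.150 − 5.69 = 1.46 °C and
  Steno = 3.2897 × 0.6352 = 2.09 °C exactly, and the mean catch per tow
  is `A·σ_c/√(σ_T²+σ_c²)·exp(−(c−μ_T)²/2(σ_T²+σ_c²)) = 1.058`. These
  closed forms are the oracles for the niche stack.
* **Subsampling**: at most 20 individuals per tow are sexed and measured;
  at most 5 of those are weighed and staged — the measuring protocol the
  analyses must survive.
* **Biology**: sex ratio 0.5; lengths truncated-Normal, females
  N(41, 10²) on [13, 66] cm, males on [13, 62] cm (observed ranges);
  lengths recorded to 0.1 cm and downstream biology generated from the
  recorded value. Maturity is Bernoulli with logit
  `β0 + β1·TL` (β0 = −12.5, β1 = 0.25, so L50 = 50 cm); stage is drawn
  uniformly within 3–7 (mature) or 1–2 (immature) — stage microstructure
  is cosmetic since only the binary cut is analyzed. Weight is
  `exp(−5.73 + 3.06·ln TL + ε)`, ε ~ N(0, 0.11²); with the female length
  distribution this σ gives an expected log-scale r² of 0.981.
* **Stomachs**: empty w.p. 0.185; otherwise independent per-category
  presence (teleost 0.50, crustacean 0.41, cephalopod 0.18, echinoderm
  0.05, unidentified 0.14) with lognormal masses whose scales put teleosts
  near 80% of content mass. A non-empty stomach drawing no category gets
  an unidentified trace so flags stay consistent.
* **Seeding**: one global seed spawns fixed per-operation
  `numpy.random.SeedSequence` streams, so tables regenerate independently
  and identically across runs and platforms.

What the generator does **not** emulate: spatial autocorrelation or any
real bathymetry, depth–sex segregation, tow standardization (every tow is
one unit of effort), multi-species interactions, measurement error in
temperature, or seasonal differences in staging protocol (real spring
surveys often skip maturity staging; the generator stages both seasons).
Passing tests therefore demonstrate the estimators are correct under the
stated model, not that the model captures every feature of real surveys.

## Numerical choices and degenerate inputs

* Weighted statistics require at least one strictly positive weight;
  all-zero catch raises a no-catch error rather than returning NaN.
* Tied support values in the ECDF are merged; the final cumulative weight
  is clamped to exactly 1.
* Ogive fitting requires ≥2 records of each maturity class and
  non-constant lengths; the length-weight fit requires ≥3 strictly
  positive pairs.
* Row-level validation never drops data silently: rejected + accepted =
  read, per-rule tallies in every report. Depth/temperature outside the
  observed survey extremes (18–1359 m, −1–11 °C) are warnings;
  only logically impossible values (negative counts, nonpositive lengths,
  content in an "empty" stomach) reject rows.
* Report output is deterministic for fixed seed and config: sorted JSON
  keys, no timestamps.

## Problem sizes

The test suite and the acceptance script run the niche indices on a
40,000-station survey (~42,000 individuals; seconds on one CPU), ogive
recovery on 100 replicates at n = 582 females, bootstrap coverage with
199 resamples per replicate, and length-weight fits on ~38,000 weighed
individuals. These sizes put Monte-Carlo error comfortably inside the
closed-form tolerances while keeping a full run under a minute.

## Known limitations

* The unweighted station median ignores whether a tow successfully
  recorded temperature; if missingness correlates with habitat the TB
  estimate inherits that bias (the exclusion count is reported so users
  can judge).
* The index of abundance assumes uniform tow effort; surveys with
  variable swept area need an effort column this schema does not carry.
* `depth_linked` mode has no closed-form oracles; its tests are
  regression-level (slope recovery), not exact.
* The critical-habitat intersection is a descriptive envelope overlap,
  not a habitat-suitability model; it inherits all the caveats of
  min/max ranges under subsampling.
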