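# trawlniche

Catch-weighted environmental-niche and life-history statistics for
bottom-trawl survey data.

Groundfish survey series are often the only systematic observations of
non-commercial deep-water bycatch species — small sharks in particular.
`trawlniche` turns three per-tow tables (stations, measured specimens,
stomachs) into the summaries used to characterize such a species'
habitat preferences and productivity:

* **Thermal bias** `TB = median_w(T) − median(T)`: the median
  catch-weighted bottom temperature (each station counted once per
  individual caught there) minus the median temperature of *all* fished
  stations, null tows included. `TB > 0` → warm-water affinity.
* **Steno index** `= Q_w(0.95) − Q_w(0.05)`: the width of the central
  90% of the catch-weighted temperature distribution; small values mean
  a stenothermal species with a narrow tolerance window.
* **Occupancy intervals** from weighted/unweighted CDFs of temperature
  and depth — "90% of the catch came from 315–546 m"-style ranges.
* **Maturity ogives**: maximum-likelihood logistic regression of binary
  maturity on total length (in-package Newton/IRLS with step-halving and
  separation detection), `L50 = −β0/β1`, nonparametric bootstrap CI.
* **Length-weight**: the allometric power law `W = a·TL^b` fitted as OLS
  of `ln W` on `ln TL`.
* **Diet**: vacuity, frequency of occurrence (non-empty denominator),
  weight percent per prey category.
* **Habitat envelopes** of subgroups (juveniles ≤ 20 cm, late-pregnancy
  females) and their intersection as a critical-habitat window.
* **Annual abundance index**: mean catch per tow per (year, season) with
  an OLS trend.

A synthetic survey generator with known parameters — Normal station
thermal field, Poisson catches under a Gaussian thermal response,
protocol-faithful subsampling caps (≤20 measured, ≤5 staged per tow) —
makes every stage testable end to end; in the default thermal mode the
niche indices have closed-form expectations. See `docs/methods.md` for
the model and its assumptions.

## Worked example

Simulate a survey (2,000 tows per season), then run the analyses:

```sh
trawlniche simulate --seed 42 --n-stations 2000 --out-dir demo
trawlniche niche demo/stations.csv
```

```json
{
  "classification": "warmwater",
  "interval": [6.094891959307896, 8.219052024430711],
  "interval_unweighted": [1.6001351319009203, 9.727961000323091],
  "n_missing": 0,
  "n_stations": 4000,
  "percentiles": [0.05, 0.95],
  "season": null,
  "steno": 2.1241600651228154,
  "tb": 1.5204609962093407,
  "total_catch": 4146.0,
  "variable": "temperature"
}
```

The 4,146 individuals came from stations spanning 1.6–9.7 °C, yet 90% of
them were caught within a 2.12 °C window (`steno`) centred 1.52 °C warmer
than the habitat median (`tb`) — a stenothermal warm-water species. The
generating truth here is TB = 1.46 and Steno = 2.09 (closed form); a
4,000-station survey recovers them to within sampling error.

```sh
trawlniche ogive demo/specimens.csv --n-boot 200
```

```json
{
  "beta0": -11.851329538975827,
  "beta1": 0.23482088876482582,
  "converged": true,
  "l50": 50.46965626147931,
  "l50_ci": [49.77001058982445, 51.13813582891551],
  "l95": 63.0087408150486,
  "n_mature": 394,
  "n_used": 1888,
  "scheme": "stage3plus",
  "separation": false,
  "sex": "female"
}
```

Of 1,888 staged females, 394 were mature (stages 3–7); the fitted ogive
puts the length at 50% maturity at 50.5 cm (95% bootstrap CI
49.8–51.1), against a generating L50 of 50 cm.

```sh
trawlniche lw demo/specimens.csv
```

```json
{
  "b": 3.0586901072230037,
  "log_a": -5.7268215751172535,
  "n_used": 3734,
  "r2": 0.9797486086148091,
  "resid_sd": 0.10961777780563806
}
```

`ln W = −5.73 + 3.06·ln TL` with log-scale r² ≈ 0.98 — near-isometric
growth (b ≈ 3), recovered from 3,734 weighed individuals against
generating values (−5.73, 3.06).

Other subcommands: `validate`, `diet`, `envelope`, `abundance`, and
`run` (full pipeline from a YAML config, writing `report.json` plus the
resolved config for exact re-runs). The same functionality is available
as a library (`trawlniche.thermal_bias`, `trawlniche.MaturityOgive`,
`trawlniche.LengthWeightModel`, …); the two fitted models follow the
scikit-learn estimator API and compose with its pipelines.

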