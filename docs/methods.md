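# Methods

## Operational heat-wave definition

The package analyzes daily maximum temperature (Tmax) in the 91-day
April–June pre-monsoon window, the season in which Indian heat waves
concentrate. A heat wave is a maximal run of ≥ 3 consecutive days with
`Tmax ≥ T_eff`, where the effective threshold is

    T_eff = max(Q90 of baseline AMJ Tmax, fixed zone cutoff),

the cutoffs being 40 °C (plains zones: Northwest, North Central,
Northeast, Interior Peninsula), 37 °C (West and East Coast) and 30 °C
(Hilly). Several conventions here are deliberate choices where the
operational literature leaves room:

- **Inclusive exceedance** (`≥`, not `>`): IMD-style definitions are
  "equal or exceed".
- **Pooled percentile**: `Q90` is taken over all AMJ days of the
  baseline pooled together (not per calendar day), with linear
  interpolation — the single-number reading of "90th percentile of the
  baseline period". The baseline window defaults to 1950–2010 but is
  configurable; with observed-style records starting in 1981 the
  practical default is all available pre-2011 years.
- **Window clipping before the length test**: a run straddling Jun 30
  counts only its AMJ days; 5 hot days ending Jul 5 contribute no spell.
- **Missing data**: a missing (NaN) day terminates a run; a season with
  more than 9 missing AMJ days (10%) is excluded from period means.

Per season, *frequency* is the spell count (zero allowed), *duration*
the arithmetic mean of spell lengths, and *intensity* the mean of
per-spell peak Tmax — "the maximum temperature sustained". The mean
spell-day temperature is retained on each spell (`mean_tmax`) but not
used in headline statistics.

## City extraction

A city's series is the nearest grid cell in squared-degree distance
(ties to the lower latitude index, then longitude index). Nearest-cell
rather than bilinear interpolation preserves threshold-exceedance
counts, which smoothing would bias low; the choice is recorded in each
series' provenance string.

## Period aggregation and ensembles

Analysis periods are HIST 1981–2020 (historical forcing) and D1
2021–2046, D2 2047–2072, D3 2073–2098 (SSP2-4.5 or SSP5-8.5). Over a
period:

- **duration** and **intensity** average only over seasons with at
  least one spell — a mean spell length over spell-free seasons is
  meaningless — and are undefined (`None`) when no season had one;
- **frequency** averages over all retained seasons, zeros included,
  because it is a count.

Ensemble members are processed independently and their period
statistics averaged without weights ("compute then combine");
detecting on an ensemble-mean field would smear exactly the extremes
under study. Undefined member values are left out of the mean.

Zone summaries are Student-t 95% confidence intervals across the
cities of a zone, treating cities as independent units; with a single
city the interval is undefined and flagged. Percent change is
`100·(future − baseline)/baseline`; a city with no baseline activity
yields a `new_occurrence` flag instead of a percentage and is excluded
from *both* terms of the zone-level change, so the compared means cover
the same city set.

## Hazard index

For one period × scenario cohort, each city contributes
`delta_duration` (ensemble future duration minus historical duration,
days; zero when undefined) and `excess_intensity` (ensemble intensity
minus `T_eff`, °C; zero when undefined). Each component is min–max
normalized across the cohort (a constant component maps to 0.5 for
everyone), and the score is their equal-weight mean, classed at
0.25/0.5/0.75 into low/moderate/high/very_high. Design choices:

- Equal weights, because no principled weighting between duration and
  intensity intensification is available; the index is a ranking, not
  a physical quantity.
- Frequency is excluded: sub-spell counts are already subsumed in the
  duration statistic.
- Normalization is within a period/scenario cohort, never across
  periods, so scores are comparable only within one panel.

The construction is monotone in each component and invariant under
affine rescaling of a component across the cohort (both are tested).

## Mortality

The national rate for a year is `10⁶·Σ deaths / Σ population` over
states — a pooled rate, not a mean of state rates, so small states do
not dominate. Populations are interpolated linearly between census
years and held flat outside; with a single census the denominator is
constant. The decadal change compares mean annual national rates of
1981–1999 vs 2000–2019. Which census vintage underlies published
figures is generally unstated; the pooled-denominator convention is
explicit here and overridable by supplying annual population tables.

## Synthetic data

The generator emulates the structure of the real inputs, not their
physics. Daily Tmax per cell is

    climatology(doy) + trend·t + AR(1) anomaly,

with a per-zone cosine annual cycle peaking at day 135 (mid-May),
per-scenario linear trends (defaults 0.15 / 0.35 / 0.60 °C per decade
for historical / SSP2-4.5 / SSP5-8.5 — central values for South-Asian
warming rates), AR(1) anomalies with lag-1 correlation 0.7 and
stationary standard deviation 1.5 °C (typical day-to-day persistence
and spread of daily Tmax anomalies). Both a 1° "observed-like" and a
0.25° "model-like" resolution are supported; default ensemble size is
13 members differing only in noise seed.

Injected spells hold a **uniform** level of (zone cutoff + exceedance)
for their whole length, and injection caps the background 0.5 °C below
the zone cutoff everywhere. Since `T_eff ≥ cutoff > background`, every
injected spell is either recovered whole (its level reaches `T_eff`)
or invisible whole — never truncated — so duration, frequency, and
intensity have closed-form ground truth wherever the baseline
percentile lands. Spell schedules are validated (inside the AMJ
window, ≥ 3 days, separated by at least one sub-threshold day).

What the generator does **not** emulate: monsoon dynamics and their
interannual modes, spatial correlation between cells, humidity, any
bias-correction artifacts, and the real spatial layout of the seven
zones. Passing tests therefore demonstrate the correctness of the
statistical machinery on data with the right marginal structure, not
skill on real IMD or CMIP6 fields.

The mortality generator fixes the decadal national rate ratio exactly
by scaling second-window deaths around the target mean with a zero-mean
perturbation; synthetic death counts are real-valued expected counts.

## Numerical choices and problem sizes

- Percentiles use numpy's linear-interpolation definition, matching
  the sort-and-index oracle used in tests.
- Kelvin inputs are detected by a median above 200 and converted; no
  Earth surface Tmax is ambiguous under this rule.
- All randomness flows through `numpy.random.default_rng` with integer
  seeds; identical seeds give bit-identical grids, and the pipeline's
  CSV/JSON outputs are byte-identical across reruns.
- Verification runs use desk-scale sizes chosen to exercise every code
  path: 2×2–3×3 grids, 26-year periods, 13-member ensembles for
  recovery checks, 5 000 random exceedance patterns against the
  brute-force run enumerator, 10 000 Gaussian replicates for interval
  coverage, and a two-member two-scenario study for the end-to-end
  determinism check.

## Limitations

- The hazard index is relative to its cohort; adding or removing a
  city changes everyone's score.
- Humidity is absent from both detection and mortality; heat-index
  style definitions would need a second variable.
- No spatial interpolation of characteristics between cities, no
  regridding between resolutions, and no trend testing over time —
  period contrasts only.
- Mortality is not attributed to detected spells; the two analyses
  share only the reporting period.
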