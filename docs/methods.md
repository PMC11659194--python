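# Methods

## Data model

The unit of analysis is the dissemination area (DA), the finest Canadian
census geography with public demographic data (~400–700 residents,
roughly 19 households per postal code). A `DATable` is one census year of
DA rows: environmental values, demographic percentages on the 0–100
scale, and population counts. DA identifiers are opaque strings (DAUIDs
carry meaningful leading zeros). Percentages are kept on the 0–100 scale
so regression slopes read directly in percentage points.

Missing data are never imputed: a DA missing either variable of a
combination is excluded from that combination's classification and from
its regressions, with the count logged. Silent imputation would distort
spot proportions, which are reported per combination over the DAs
actually classified.

Two census years are aligned on the intersection of DA id sets. Within-
year metrics (classes, spots, regressions) always use each year's full
table; only between-year spatial comparisons are restricted to common
DAs. DA boundary harmonization between censuses is out of scope — the
design avoids it because every assessment metric is computed within one
year at a time.

## Exposure quantities

**Humidex.** Apparent temperature H = T + 0.5555·(e − 10), with vapor
pressure (hPa) e = 6.11·exp(5417.7530·(1/273.16 − 1/T_dew)), T_dew in
kelvins (T + 273.15). The constants are the Environment Canada form. H
equals T exactly when e = 10 hPa, approaches T − 5.555 in the dry limit,
and is strictly increasing in dew point. A dew point above the air
temperature is physically suspect and triggers a warning, not an error.
Naming note: the heat input is called `air_temp` even though some data
sources label the Humidex input "surface temperature"; the two names
circulate for the same raster input and the calculation is identical.
The index does not capture multi-day heat-event duration.

**Accessibility.** Minimum Euclidean distance from a point (postal code)
to any park or water-body feature, with points inside a polygon at
distance 0 (being in a park counts as full access). All geometry must
already be projected to planar meters; the library does no CRS handling,
keeping it dependency-light and deterministic. Whether a water body is
publicly accessible is not modelled. Road-network and transit
accessibility are deliberate non-goals.

**Aggregation.** Postal-code values are averaged (unweighted arithmetic
mean, missing skipped) into their parent DA; with near-constant
households per postal code this approximates population weighting.

**Population-weighted group means.** Σ(vᵢ·wᵢ)/Σwᵢ with wᵢ = group % ×
DA population / 100, over DAs with all three quantities present.

## Classification

**Breaks.** `QUARTILE` cutpoints are the 25th/50th/75th percentiles
(linear interpolation) of the DA values, giving near-equal class sizes
(differing by at most 1 on tie-free data) regardless of skew.
`EVEN_BREAKS` cutpoints sit at min + k·(max−min)/4, ranking absolute
performance. Quartiles are computed over DA values, not person-weighted —
this is what makes class sizes equal in DA count. Bins are
left-open/right-closed (a value exactly on a cutpoint goes to the lower
bin; the lowest bin is closed below): deterministic and order-
independent under ties. For LOW_IS_GOOD variables the bin order is
reversed so the highest (worst) values get class 1. A variable with all
values identical cannot be classified (error); fewer than 4 distinct
values warns and proceeds with merged classes.

**Rule sets are data.** Each combination's sour/risky/sweet cells are
explicit ordered class pairs validated for pairwise disjointness;
everything else is MEDIUM, so the 16-cell table is total by
construction. Symmetric entries are stored explicitly rather than
auto-symmetrized, keeping asymmetric rules (the walkability×NO2 risky
cell (4, 1)) representable. The six shipped rule sets widen the sour
corner to {(1,1),(1,2),(2,1)} where the burdens compound (heat×NO2, and
both park-access pairs) and widen the sweet corner to
{(4,4),(3,4),(4,3)} where one benefit amplifies the other (vegetation
pairs, walkability×park access). Custom pairs load from config; three-
variable combinations are out of scope.

**Spot codes.** SOUR=1, RISKY=2, MEDIUM=3, SWEET=4 — ordinal from worst
to best. The full 1–4 coding is used in regressions even for
combinations with no risky cells, so slopes are comparable across
combinations; the interval between codes does not represent equal health-
impact differences, which is why the slope is read as a relative metric.

## Inequity metrics

Per spot category, a group's DA percentages are summarized by n, mean,
median, quartiles and Tukey whiskers (most extreme values inside
q1 − 1.5·IQR and q3 + 1.5·IQR). Empty categories are reported as absent,
never as zeros.

The regression is simple OLS of group percentage (y) on spot code (x);
slope = cov(x,y)/var(x), with the usual two-sided t-test on the slope.
This orientation — demographics on spots, not the reverse — is what
gives coefficients in percentage points per category step. Significance
is p ≤ 0.05; a p-value exactly on the boundary is counted significant
and logged. *Inequity* = significant negative slope for a group flagged
vulnerable. Which groups count as vulnerable is a normative judgement,
so it is configuration (default: all supplied groups), never hard-coded.
Regressions run over classified DAs with the group observed; at least 3
points and at least two distinct codes are required (else an explicit
error). No multiple-testing correction is applied by default, keeping
each cell's test interpretable on its own; a Benjamini–Hochberg option
exists and outputs record which was used. Ordinal-logit alternatives and
spatial-error models are out of scope.

The risky-exclusion sensitivity refits after dropping RISKY DAs; on
combinations without risky cells it is bit-identical to the full fit
(verified by test).

## Change taxonomy

The verdict is a pure function of the two years' (inequity flag, slope):
improved when inequity disappears, or eases (slope strictly up) while
persisting; worsened for the mirror image; none when inequity is absent
in both years. An exact slope tie with inequity in both years yields
*none* (only strict movement counts as change) and is logged. A flip
from significant-negative to significant-positive is classified improved
(inequity → no inequity) and logged as noteworthy. The taxonomy is total
over {inequity, none}² × {up, down, tie} and antisymmetric under year
swap. Two time points cannot show whether change was monotonic through
the decade.

## Synthetic-city generator

The generator reproduces the statistical structure the analysis assumes,
with defaults chosen once to mirror a mid-sized Canadian metro's urban
descriptives:

| variable | family | default | rationale |
|---|---|---|---|
| no2 | log-normal | median 13 ppb, σ=0.40 | right-skewed, ~4–30 ppb |
| walkability | gamma | shape 2, scale 1.2 | skewed index near 0 |
| ndvi | scaled beta | a=4, b=3 on [0.03, 0.64] | bounded vegetation index |
| heat | normal | 26.3 ± 0.7 °C | ~3 °C July spread |
| park_distance | exponential | scale 350 m | 0 to >2 km |

Cross-variable dependence comes from a Gaussian copula targeting a
Spearman matrix (Pearson ρ = 2·sin(π·ρₛ/6)), so marginal families are
preserved exactly; the matrix is validated positive semi-definite. The
default correlations encode urban-density structure (NO2 with
walkability +0.5, with NDVI −0.5, etc.). DA populations are uniform on
400–700.

Inequity is planted *on the realized spot code*: the table is classified
first, then group % = baseline + β·code + N(0, σ²), clipped to [0, 100].
The ground truth is therefore exactly the estimand of the spot
regression, giving a sharp recovery test; clipping of more than 5% of
DAs warns because it attenuates the recoverable slope, and the shipped
group defaults keep expected values well inside the bounds. Percentages
are clipped, not renormalized across groups — census groups overlap
anyway, so simulated groups are independent by design. Year B reuses
year A's environmental draw under configurable additive/multiplicative
drift (rank-preserving for positive multipliers) and re-plants
demographics with year-B betas and fresh noise, so between-year verdicts
reflect planted parameter changes, not resampled geography. A scenario-
bank configuration exercises every change verdict: slope easing and
deepening within persistent inequity at low noise (robust across seeds),
plus significance gained/lost at high noise.

What the generator does **not** emulate: spatial autocorrelation, street
networks, realistic inter-group correlation, DA boundary changes.
Passing recovery tests therefore demonstrates estimator correctness
under the model's own assumptions, not robustness to spatial confounding
in real data.

Recovery under the standard conditions (β = −3, noise sd 2, 400 DAs,
500 replicates) is checked for mean-estimate bias within ±0.15 and 95%
CI coverage within [0.92, 0.98]; these sizes keep the whole suite and
the acceptance script to seconds while leaving Monte-Carlo error well
below the bounds.

## Numerical and I/O choices

Percentile computation uses linear interpolation throughout (breaks,
descriptive quartiles). OLS uses the closed-form simple-regression path
(`scipy.stats.linregress`), cross-checked in tests against a full OLS
fit; a constant response short-circuits to slope 0, p 1. Pipeline CSV
outputs carry 6 significant digits, making reruns byte-identical across
platforms; the JSON manifest records the configuration hash, seed and
library versions needed to reproduce a run. All pipeline outputs are
sorted (by combination/da_id or group/combination), so results are
invariant to input row order. Seeds derived internally stay below 2³¹.

## Known limitations

- Spot labels are relative to the region and year being analyzed (class
  breaks are recomputed per table); they are not absolute health
  thresholds, and cross-region comparisons of slopes are not meaningful.
- The OLS slope summarizes a monotone trend in one number; strongly
  non-linear group distributions across the four categories are better
  read from the per-spot descriptive statistics alongside it.
- Statistical significance is computed per cell without spatial
  dependence adjustments; with spatially clustered residuals the
  nominal p-values are optimistic.
- Even-break classes can be highly unbalanced on skewed variables; that
  is intentional (absolute performance) but makes some category
  statistics rest on few DAs.
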