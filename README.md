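# sweetspots

Cumulative two-variable environmental exposure classification and
distributional-inequity analysis for census dissemination areas (DAs).

## The problem

Urban environmental quality is a mixture of burdens (traffic-related NO2,
summer heat stress) and benefits (walkability, vegetation coverage, access
to parks and water bodies) that overlap in space and interact in their
health effects: walking through polluted air raises pollutant intake,
vegetation tempers both heat and air pollution, and heat is more dangerous
where cool refuges are out of reach. Single-variable exposure assessments
miss these interactions, and they miss the neighbourhoods where burdens
pile up on the same — often structurally marginalized — residents.

`sweetspots` implements a two-dimensional cumulative-exposure assessment
and the equity metrics built on top of it, for analysts working with
DA-level (or any small-area) tables across one or two census years.

## The method

**Classes.** Each environmental variable is discretized into performance
classes 1–4 (1 = most unfavorable to health, 4 = most favorable), either
by *quartiles* of the DA values (equal DA counts per class, robust to
skew) or by *even breaks* of the observed range (absolute performance).
The favorable direction of each variable (low NO2 good, high walkability
good, …) is declared in a variable registry.

**Spots.** For a pair of variables, each DA's class pair (c₁, c₂) maps to
a spot category under a combination-specific rule set encoding the health
synergy or trade-off:

| category | meaning | code |
|---|---|---|
| SWEET | both variables favorable | 4 |
| MEDIUM | neither extreme | 3 |
| RISKY | a benefit undermined/amplified into harm by a co-located burden (e.g. walkable but polluted) | 2 |
| SOUR | both unfavorable | 1 |

Six validated rule sets ship by default (walkability×NO2, heat×NO2,
NDVI×NO2, NDVI×heat, walkability×park access, heat×park access); custom
rule sets load from YAML/JSON.

**Inequity metric.** For each demographic group *g* and combination, the
package fits the simple OLS regression

&nbsp;&nbsp;&nbsp;&nbsp;pctᵍ(DA) = β₀ + β₁ · code(DA) + ε

of the group's DA-level percentage on the ordinal spot code. A
significant (p ≤ 0.05, two-sided) negative β₁ for a vulnerable group is
recorded as *distributional inequity*: the group is concentrated toward
sour/risky spots. β₁ is a relative, within-region summary — not a causal
model. A sensitivity variant refits after dropping RISKY DAs.

**Change between years.** Cells are compared across two census years:
*improved* when inequity disappears or the slope eases toward zero while
inequity persists; *worsened* for the mirror cases; *none* otherwise.

**Supporting quantities** computed by the package: Humidex apparent
temperature H = T + 0.5555·(e − 10) with vapor pressure e from the dew
point; Euclidean nearest-distance accessibility to park/water polygons;
postal-code→DA mean aggregation; population-weighted group exposure means.

A seeded synthetic-city generator (Gaussian-copula-correlated skewed
exposures, planted spot-code↔percentage slopes) makes every stage
testable without any data download.

## Worked example

```python
import sweetspots as sw

city = sw.simulate_city(sw.default_sim_config(seed=1))   # 400 synthetic DAs
rules = next(r for r in sw.builtin_rulesets() if r.name == "walkability_no2")
assignment = sw.classify_table(city, rules)              # quartile method

for cat, pct in sw.spot_proportions(assignment).items():
    print(f"{cat.name:<7} {pct:5.2f} %")
fit = sw.fit_spot_regression(assignment, city, "visible_minority")
print(f"slope = {fit.slope:+.2f}, p = {fit.p_value:.4f}, inequity = {fit.inequity}")
```

prints

```
SOUR     1.25 %
RISKY   12.00 %
MEDIUM  85.75 %
SWEET    1.00 %
slope = -2.42, p = 0.0115, inequity = True
```

Read: 1.25% of DAs are unfavorable on both walkability and NO2, and 12%
are walkable-but-polluted risky spots. The visible-minority percentage
falls by 2.4 points per one-step improvement in spot category
(significant at p ≈ 0.01), so the generator's planted inequity (−3 points
per step, plus noise) is detected and estimated.

The same analysis runs from the shell:

```sh
sweetspots simulate --seed 1 --n-das 400 --out sim/
sweetspots run --table-a sim/synthetic_2006.csv --year-a 2006 \
               --table-b sim/synthetic_2016.csv --year-b 2016 --out results/
```

which writes spot assignments, per-DA sweet/sour count tables, category
proportions, per-spot descriptive statistics, the inequity grid, the
two-year change grid, and a reproducibility manifest. Real DA tables in
the same CSV layout (a `da_id` column, registry-declared environmental
columns, percentage columns, optional `population`) drop straight in.

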