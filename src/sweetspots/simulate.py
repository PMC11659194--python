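"""Synthetic two-year DA tables with planted distributional inequity.

The generator reproduces the statistical structure the analysis assumes,
not any particular city's geography: right-skewed pollutant
concentrations (log-normal NO2), a bounded vegetation index (scaled-beta
NDVI), a right-skewed built-environment index (gamma walkability), nearly
normal July apparent temperature with a narrow range, and exponential
distances to the nearest park or water body.  Cross-variable dependence
is imposed through a Gaussian copula with a target Spearman rank
correlation matrix, so each marginal family is preserved exactly.

Demographic inequity is planted directly on the estimand: after
classifying the synthetic DAs under a rule set, a group's percentage is
set to ``baseline + beta * spot_code`` plus Gaussian noise (clipped to
[0, 100]).  The ground-truth beta is therefore exactly the slope the
equity regression estimates, which gives a sharp parameter-recovery test.
Fields are spatially unstructured (no autocorrelation): recovery results
here show estimator correctness, not robustness to spatial confounding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import (
    DATable,
    UsageError,
    ValidationError,
    VariableRegistry,
    YearPair,
    align_years,
    default_registry,
)
from .spots import BreakMethod, RuleSet, builtin_rulesets, classify_table

logger = logging.getLogger("sweetspots")

__all__ = [
    "EnvDist",
    "GroupPlan",
    "SimConfig",
    "default_sim_config",
    "scenario_bank_config",
    "simulate_city",
    "plant_inequity",
    "simulate_year_pair",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class EnvDist:
    """One environmental variable's marginal distribution family."""

    family: str
    params: dict

    def frozen(self):
        p = self.params
        if self.family == "lognormal":
            return stats.lognorm(s=p["sigma"], scale=p["median"])
        if self.family == "normal":
            return stats.norm(loc=p["mean"], scale=p["sd"])
        if self.family == "beta":
            return stats.beta(p["a"], p["b"], loc=p["lo"], scale=p["hi"] - p["lo"])
        if self.family == "gamma":
            return stats.gamma(p["shape"], scale=p["scale"])
        if self.family == "exponential":
            return stats.expon(scale=p["scale"])
        raise UsageError(f"unknown distribution family {self.family!r}")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        return self.frozen().ppf(u)

    @property
    def support(self) -> tuple[float, float]:
        lo, hi = self.frozen().support()
        return float(lo), float(hi)


@dataclass(frozen=True)
class GroupPlan:
    """Planted linear relation between spot code and a group's percentage.

    ``beta`` is in percentage points per one-step spot-code increase (a
    negative beta plants inequity); ``beta_year_b`` overrides it in the
    second simulated year so every change verdict can be exercised.
    """

    beta: float
    baseline: float
    noise_sd: float
    combination: str = "walkability_no2"
    beta_year_b: float | None = None
    vulnerable: bool = True

    def beta_for_year_b(self) -> float:
        return self.beta if self.beta_year_b is None else self.beta_year_b


@dataclass
class SimConfig:
    """Everything needed to generate a reproducible synthetic year pair."""

    n_das: int = 400
    seed: int = 0
    year_a: int = 2006
    year_b: int = 2016
    env: dict[str, EnvDist] = field(default_factory=dict)
    rank_corr: pd.DataFrame | None = None
    groups: dict[str, GroupPlan] = field(default_factory=dict)
    year_b_shift: dict[str, tuple[float, float]] = field(default_factory=dict)
    break_method: BreakMethod = BreakMethod.QUARTILE
    registry: VariableRegistry = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        if self.n_das < 16:
            raise ValidationError("SimConfig.n_das must be >= 16")
        for name, plan in self.groups.items():
            if plan.noise_sd < 0:
                raise ValidationError(f"group {name!r}: noise_sd must be >= 0")
            for beta in (plan.beta, plan.beta_for_year_b()):
                for code in (1, 4):
                    expected = plan.baseline + beta * code
                    if not (0.0 <= expected <= 100.0):
                        raise ValidationError(
                            f"group {name!r}: baseline {plan.baseline} with beta "
                            f"{beta} puts the expected percentage at {expected} "
                            "for some spot code; keep baseline + code*beta in [0, 100]"
                        )


def _default_env() -> dict[str, EnvDist]:
    # Families and rough scales follow the study region's descriptives:
    # NO2 roughly 4-30 ppb and right-skewed; walkability index right-skewed
    # near zero; NDVI within [0.03, 0.64]; July apparent temperature with a
    # ~3 degC spread around 26 degC; park/water distance 0 to >2 km.
    return {
        "no2": EnvDist("lognormal", {"sigma": 0.40, "median": 13.0}),
        "walkability": EnvDist("gamma", {"shape": 2.0, "scale": 1.2}),
        "ndvi": EnvDist("beta", {"a": 4.0, "b": 3.0, "lo": 0.03, "hi": 0.64}),
        "heat": EnvDist("normal", {"mean": 26.3, "sd": 0.7}),
        "park_distance": EnvDist("exponential", {"scale": 350.0}),
    }


_DEFAULT_VARS = ["no2", "walkability", "ndvi", "heat", "park_distance"]


def _default_rank_corr() -> pd.DataFrame:
    # Urban-density-driven dependence: NO2 tracks walkability and heat,
    # opposes greenery; green DAs sit nearer parks and run cooler.
    r = pd.DataFrame(np.eye(5), index=_DEFAULT_VARS, columns=_DEFAULT_VARS)

    def set_(a: str, b: str, v: float) -> None:
        r.loc[a, b] = v
        r.loc[b, a] = v

    set_("no2", "walkability", 0.50)
    set_("no2", "ndvi", -0.50)
    set_("no2", "heat", 0.30)
    set_("no2", "park_distance", 0.20)
    set_("walkability", "ndvi", -0.40)
    set_("walkability", "heat", 0.25)
    set_("walkability", "park_distance", -0.25)
    set_("ndvi", "heat", -0.35)
    set_("ndvi", "park_distance", -0.30)
    set_("heat", "park_distance", 0.15)
    return r


def _default_year_b_shift() -> dict[str, tuple[float, float]]:
    # (additive, multiplicative) drift applied to year A values.  Pollution
    # fell over the decade, walkability and greenery access rose slightly,
    # July heat crept up.
    return {
        "no2": (0.0, 0.78),
        "walkability": (0.3, 1.0),
        "ndvi": (-0.01, 1.0),
        "heat": (0.3, 1.0),
        "park_distance": (0.0, 0.92),
    }


def default_sim_config(seed: int = 0, n_das: int = 400) -> SimConfig:
    """The standard synthetic city: three clustered vulnerable groups with
    modest planted inequity over the default six combinations' variables."""
    return SimConfig(
        n_das=n_das,
        seed=seed,
        env=_default_env(),
        rank_corr=_default_rank_corr(),
        groups={
            "visible_minority": GroupPlan(
                beta=-3.0, baseline=55.0, noise_sd=8.0, combination="walkability_no2"
            ),
            "lico": GroupPlan(
                beta=-2.0, baseline=22.0, noise_sd=5.0, combination="walkability_no2"
            ),
            "recent_immigrant": GroupPlan(
                beta=-1.0, baseline=12.0, noise_sd=3.0, combination="heat_no2"
            ),
        },
        year_b_shift=_default_year_b_shift(),
    )


def scenario_bank_config(seed: int = 0, n_das: int = 400) -> SimConfig:
    """A year pair engineered to exercise every change verdict.

    Two cells move within persistent inequity (slope easing vs deepening,
    low noise so significance is essentially certain at n=400), one group
    is never disadvantaged (NONE), and two high-noise cells gain or lose
    statistical significance outright.
    """
    cfg = default_sim_config(seed=seed, n_das=n_das)
    return replace(
        cfg,
        groups={
            "easing": GroupPlan(
                beta=-6.0, beta_year_b=-3.0, baseline=60.0, noise_sd=6.0
            ),
            "deepening": GroupPlan(
                beta=-3.0, beta_year_b=-6.0, baseline=60.0, noise_sd=6.0
            ),
            "advantaged": GroupPlan(
                beta=2.0, beta_year_b=2.0, baseline=20.0, noise_sd=6.0
            ),
            "faded": GroupPlan(
                beta=-5.0, beta_year_b=0.0, baseline=55.0, noise_sd=20.0
            ),
            "emerged": GroupPlan(
                beta=0.0, beta_year_b=-5.0, baseline=55.0, noise_sd=20.0
            ),
        },
    )


def _copula_sample(
    rng: np.random.Generator, rank_corr: pd.DataFrame, variables: list[str], n: int
) -> pd.DataFrame:
    """Uniform marginals with the requested Spearman correlation, via a
    Gaussian copula (Pearson rho = 2 sin(pi * rho_s / 6))."""
    rs = rank_corr.loc[variables, variables].to_numpy(dtype=float)
    if not np.allclose(rs, rs.T):
        raise UsageError("rank correlation matrix must be symmetric")
    pearson = 2.0 * np.sin(np.pi * rs / 6.0)
    np.fill_diagonal(pearson, 1.0)
    eigvals = np.linalg.eigvalsh(pearson)
    if eigvals.min() < -1e-8:
        raise UsageError(
            "rank correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.3g})"
        )
    # tiny jitter so Cholesky succeeds on a boundary-PSD matrix
    chol = np.linalg.cholesky(pearson + 1e-10 * np.eye(len(variables)))
    z = rng.standard_normal((n, len(variables))) @ chol.T
    return pd.DataFrame(special.ndtr(z), columns=variables)


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, _MAX_SEED, size=n)]


def simulate_city(
    config: SimConfig, seed: int | None = None, year: int | None = None
) -> DATable:
    """Generate one synthetic census year: correlated environmental
    variables, DA populations, and planted demographic percentages.

    Fully deterministic given ``(config, seed)``.  Populations are drawn
    uniformly on 400-700 residents, the typical DA size.
    """
    if not config.env:
        raise UsageError("SimConfig.env is empty; nothing to simulate")
    seed = config.seed if seed is None else seed
    year = config.year_a if year is None else year
    env_seed, pop_seed, plant_seed = _child_seeds(seed, 3)
    rng = np.random.default_rng(env_seed)
    variables = list(config.env)
    rank_corr = (
        config.rank_corr
        if config.rank_corr is not None
        else pd.DataFrame(
            np.eye(len(variables)), index=variables, columns=variables
        )
    )
    u = _copula_sample(rng, rank_corr, variables, config.n_das)
    df = pd.DataFrame(
        {v: config.env[v].ppf(u[v].to_numpy()) for v in variables}
    )
    df["population"] = np.random.default_rng(pop_seed).integers(
        400, 701, size=config.n_das
    )
    df.index = pd.Index([f"DA{i:05d}" for i in range(config.n_das)], name="da_id")
    table = DATable(df, year=year, registry=config.registry, demo_groups=[])
    table.provenance = {"seed": seed, "year": year, "planted": {}}
    rulesets = {r.name: r for r in builtin_rulesets()}
    plant_seeds = _child_seeds(plant_seed, max(len(config.groups), 1))
    for (gname, plan), gseed in zip(config.groups.items(), plant_seeds):
        beta = plan.beta if year == config.year_a else plan.beta_for_year_b()
        table = plant_inequity(
            table,
            rulesets[plan.combination],
            gname,
            beta=beta,
            baseline=plan.baseline,
            noise_sd=plan.noise_sd,
            seed=gseed,
            method=config.break_method,
        )
    return table


def plant_inequity(
    table: DATable,
    rules: RuleSet,
    group: str,
    beta: float,
    baseline: float,
    noise_sd: float,
    seed: int,
    method: BreakMethod = BreakMethod.QUARTILE,
) -> DATable:
    """Set a group's DA percentages to ``baseline + beta*code`` plus noise.

    The table is classified under ``rules`` first, so the ground truth is
    exactly the slope the equity regression estimates.  DAs that cannot be
    classified get a missing percentage.  Values are clipped to [0, 100];
    clipping of more than 5% of DAs attenuates recovery and triggers a
    warning.  The planted parameters are recorded in the table's
    provenance for round-tripping into recovery tests.
    """
    assignment = classify_table(table, rules, method)
    codes = assignment.codes.reindex(table.da_ids)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(codes)) if noise_sd > 0 else 0.0
    raw = baseline + beta * codes.to_numpy(dtype=float) + noise
    clipped = np.clip(raw, 0.0, 100.0)
    n_clipped = int(np.sum(clipped != raw))
    if n_clipped > 0.05 * len(codes):
        warnings.warn(
            f"plant_inequity({group!r}): clipping affected {n_clipped} of "
            f"{len(codes)} DAs; the recovered slope will be attenuated",
            stacklevel=2,
        )
    out = table.copy()
    out.df[group] = clipped
    if group not in out.demo_groups:
        out.demo_groups.append(group)
    out.provenance.setdefault("planted", {})[group] = {
        "beta": beta,
        "baseline": baseline,
        "noise_sd": noise_sd,
        "seed": seed,
        "combination": rules.name,
        "method": BreakMethod(method).value,
    }
    out._validate()
    return out


def simulate_year_pair(config: SimConfig) -> YearPair:
    """Two aligned synthetic census years sharing one set of DA ids.

    Year B environmental values are the year A values under the configured
    additive/multiplicative drift (rank-preserving for positive
    multipliers), and its demographics are re-planted with the year B
    betas and fresh noise, so between-year verdicts reflect the planted
    beta changes rather than resampled geography.
    """
    seed_a, seed_b = _child_seeds(config.seed, 2)
    table_a = simulate_city(config, seed=seed_a, year=config.year_a)

    drifted = table_a.df[list(config.env) + ["population"]].copy()
    for var, (add, mult) in config.year_b_shift.items():
        if var in drifted.columns:
            drifted[var] = drifted[var] * mult + add
    table_b = DATable(
        drifted, year=config.year_b, registry=config.registry, demo_groups=[]
    )
    table_b.provenance = {"seed": seed_b, "year": config.year_b, "planted": {}}
    rulesets = {r.name: r for r in builtin_rulesets()}
    for gname, gseed in zip(
        config.groups, _child_seeds(seed_b, max(len(config.groups), 1))
    ):
        plan = config.groups[gname]
        table_b = plant_inequity(
            table_b,
            rulesets[plan.combination],
            gname,
            beta=plan.beta_for_year_b(),
            baseline=plan.baseline,
            noise_sd=plan.noise_sd,
            seed=gseed,
            method=config.break_method,
        )
    return align_years(table_a, table_b)
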