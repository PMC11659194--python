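"""One-call orchestration of the full analysis, plus output writers.

`run_analysis` reads one or two census-year tables, classifies every
configured combination, and writes the complete output bundle: per-DA
spot assignments, the per-DA spot-count (heat-map) table, category
proportions, per-spot descriptive statistics per group, the inequity
regression grid, and — when two years are given — the change-verdict
grid.  A JSON manifest captures the configuration hash, seed and library
versions so a run can be reproduced byte-for-byte in its numeric fields.

Numeric CSV fields are written with 6 significant digits so diffs are
stable across platforms.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .change import change_frame, change_matrix
from .core import (
    DATable,
    SweetspotsError,
    UsageError,
    VariableRegistry,
    align_years,
    default_registry,
    read_da_table,
    write_da_table,
)
from .equity import grid_frame, inequity_matrix
from .simulate import SimConfig, default_sim_config, scenario_bank_config, simulate_year_pair
from .spots import (
    BreakMethod,
    builtin_rulesets,
    classify_table,
    count_spots,
    rulesets_from_config,
    spot_proportions,
)
from .equity import describe_by_spot

logger = logging.getLogger("sweetspots")

__all__ = ["RunConfig", "load_run_config", "run_analysis", "simulate_bundle"]

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Configuration for a full analysis run."""

    table_a: str
    year_a: int
    outdir: str
    table_b: str | None = None
    year_b: int | None = None
    registry_path: str | None = None
    ruleset_path: str | None = None
    combinations: list[str] | None = None
    method: BreakMethod = BreakMethod.QUARTILE
    groups: list[str] | None = None
    vulnerable: list[str] | None = None
    exclude_risky: bool = False
    p_adjust: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        self.method = BreakMethod(self.method)
        if (self.table_b is None) != (self.year_b is None):
            raise UsageError("table_b and year_b must be given together")

    def digest(self) -> str:
        payload = {k: (v.value if isinstance(v, BreakMethod) else v) for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SweetspotsError(f"{path}: expected a mapping of run options")
    return RunConfig(**raw)


def _stage(name: str):
    """Decorator naming the pipeline stage in any error it raises."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except SweetspotsError as exc:
                raise SweetspotsError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def _write_year_outputs(
    table: DATable,
    config: RunConfig,
    outdir: Path,
    rulesets,
) -> dict[str, Path]:
    year = table.year
    out: dict[str, Path] = {}

    assignments = [
        _stage("classify")(classify_table)(table, rules, config.method)
        for rules in rulesets
    ]

    spots = pd.concat(
        [a.frame.assign(combination=a.combination) for a in assignments]
    ).reset_index()
    spots = spots[
        ["da_id", "combination", "class_first", "class_second", "category", "code"]
    ].sort_values(["combination", "da_id"])
    out[f"spots_{year}"] = outdir / f"spots_{year}.csv"
    spots.to_csv(out[f"spots_{year}"], index=False)

    counts = count_spots(assignments).sort_index()
    out[f"spot_counts_{year}"] = outdir / f"spot_counts_{year}.csv"
    counts.to_csv(out[f"spot_counts_{year}"])

    prop_rows = []
    for a in assignments:
        props = _stage("proportions")(spot_proportions)(a)
        for cat, pct in props.items():
            prop_rows.append(
                {
                    "combination": a.combination,
                    "category": cat.name,
                    "percentage": pct,
                    "n_classified": a.n_classified,
                }
            )
    out[f"spot_proportions_{year}"] = outdir / f"spot_proportions_{year}.csv"
    pd.DataFrame(prop_rows).to_csv(
        out[f"spot_proportions_{year}"], index=False, float_format=_FLOAT_FMT
    )

    groups = config.groups if config.groups is not None else list(table.demo_groups)
    stat_rows = []
    for a in assignments:
        for g in groups:
            for cat, s in _stage("describe")(describe_by_spot)(a, table, g).items():
                stat_rows.append(
                    {
                        "combination": a.combination,
                        "group": g,
                        "category": cat.name,
                        "n": s.n,
                        "mean": s.mean,
                        "median": s.median,
                        "q1": s.q1,
                        "q3": s.q3,
                        "whisker_low": s.whisker_low,
                        "whisker_high": s.whisker_high,
                    }
                )
    out[f"group_stats_{year}"] = outdir / f"group_stats_{year}.csv"
    pd.DataFrame(stat_rows).to_csv(
        out[f"group_stats_{year}"], index=False, float_format=_FLOAT_FMT
    )

    grid = _stage("equity")(inequity_matrix)(
        assignments,
        table,
        groups,
        vulnerable=config.vulnerable,
        exclude_risky=config.exclude_risky,
        p_adjust=config.p_adjust,
    )
    out[f"inequity_{year}"] = outdir / f"inequity_{year}.csv"
    grid_frame(grid, p_adjust=config.p_adjust).to_csv(
        out[f"inequity_{year}"], index=False, float_format=_FLOAT_FMT
    )
    out[f"_grid_{year}"] = grid  # in-memory, for the change stage
    return out


def run_analysis(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline and return the paths of every written output."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = (
        VariableRegistry.from_config(config.registry_path)
        if config.registry_path
        else default_registry()
    )
    rulesets = (
        rulesets_from_config(config.ruleset_path)
        if config.ruleset_path
        else builtin_rulesets()
    )
    if config.combinations is not None:
        keep = set(config.combinations)
        unknown = keep - {r.name for r in rulesets}
        if unknown:
            raise UsageError(f"unknown combinations requested: {sorted(unknown)}")
        rulesets = tuple(r for r in rulesets if r.name in keep)

    table_a = _stage("read")(read_da_table)(
        config.table_a, config.year_a, registry, demo_columns=config.groups
    )
    outputs = _write_year_outputs(table_a, config, outdir, rulesets)

    if config.table_b is not None:
        table_b = _stage("read")(read_da_table)(
            config.table_b, config.year_b, registry, demo_columns=config.groups
        )
        _stage("align")(align_years)(table_a, table_b)
        outputs_b = _write_year_outputs(table_b, config, outdir, rulesets)
        grid_a = outputs.pop(f"_grid_{table_a.year}")
        grid_b = outputs_b.pop(f"_grid_{table_b.year}")
        outputs.update(outputs_b)
        changes = _stage("change")(change_matrix)(grid_a, grid_b)
        outputs["change"] = outdir / "change.csv"
        change_frame(changes).to_csv(
            outputs["change"], index=False, float_format=_FLOAT_FMT
        )
    else:
        outputs.pop(f"_grid_{table_a.year}", None)

    manifest = {
        "package": "sweetspots",
        "version": __version__,
        "config": {
            k: (v.value if isinstance(v, BreakMethod) else v)
            for k, v in asdict(config).items()
        },
        "config_sha256": config.digest(),
        "seed": config.seed,
        "library_versions": _library_versions(),
        "outputs": {k: str(v) for k, v in outputs.items() if not k.startswith("_")},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = manifest_path
    return {k: v for k, v in outputs.items() if not k.startswith("_")}


def _library_versions() -> dict[str, str]:
    import numpy
    import scipy
    import statsmodels

    return {
        "numpy": numpy.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def simulate_bundle(
    sim_config: SimConfig, outdir: str | Path, scenario_bank: bool = False
) -> dict[str, Path]:
    """Write a seeded synthetic year pair plus its ground-truth sidecar.

    The tables use the same CSV dialect `read_da_table` expects, so the
    bundle feeds straight back into `run_analysis`; the sidecar records
    the planted betas for recovery checks.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pair = simulate_year_pair(sim_config)
    paths = {
        "table_a": outdir / f"synthetic_{pair.table_a.year}.csv",
        "table_b": outdir / f"synthetic_{pair.table_b.year}.csv",
        "truth": outdir / "synthetic_truth.json",
    }
    write_da_table(pair.table_a, paths["table_a"])
    write_da_table(pair.table_b, paths["table_b"])
    truth = {
        "seed": sim_config.seed,
        "n_das": sim_config.n_das,
        "scenario_bank": scenario_bank,
        "groups": {
            name: {
                "beta_year_a": plan.beta,
                "beta_year_b": plan.beta_for_year_b(),
                "baseline": plan.baseline,
                "noise_sd": plan.noise_sd,
                "combination": plan.combination,
            }
            for name, plan in sim_config.groups.items()
        },
        "provenance_year_a": pair.table_a.provenance.get("planted", {}),
        "provenance_year_b": pair.table_b.provenance.get("planted", {}),
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return paths
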