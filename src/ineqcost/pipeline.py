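"""End-to-end orchestration: simulate or load inputs, cost, aggregate,
compare, and write every table the analysis reports.

A run is driven by one :class:`~ineqcost.config.PipelineConfig` and writes a
self-contained output directory: the costed episodes, the activity table
(episode counts and rates by quintile and admission type), the inequality
table (gaps by quintile and sex with the comparator row), survival curves,
expected/cumulative cost profiles, the lifetime-cost summary, a run log
recording every assumption applied (dropped episodes, missing fraction,
inflation factor, life-table conventions, seed), and an echo of the config —
so the run is reproducible from the directory alone. Same config and seed
produce a byte-identical directory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .cohort_aggregation import (
    GroupCostSummary,
    aggregate,
    aggregate_population,
    assign_quintiles,
    rate_ratio,
)
from .config import PipelineConfig, save_config
from .episode_costing import CostingConfig, cost_episodes, filter_groupable
from .inequality_costing import InequalityCostResult, compute_inequality
from .io import QUINTILES
from .life_table import survival_table
from .lifetime_costs import lifetime_summary
from .synthetic_data import write_dataset


@dataclass
class PipelineResult:
    """Everything a run computed, plus where it was written."""

    out_dir: Path
    costing: CostingConfig
    dropped_count: int
    summary: GroupCostSummary
    pop_cells: pd.DataFrame
    inequality: InequalityCostResult
    survival: pd.DataFrame
    cost_profile: pd.DataFrame
    lifetime: pd.DataFrame
    activity_table: pd.DataFrame
    inequality_table: pd.DataFrame


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage from one config and write the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.simulate is not None:
        paths = write_dataset(cfg.simulate, out / "data")
    else:
        paths = {role: Path(p) for role, p in cfg.inputs.items()}
    episodes = io.read_episodes(paths["episodes"])
    tariffs = io.read_tariffs(paths["tariffs"])
    pop = io.read_population(paths["population"])
    deaths = io.read_deaths(paths["deaths"])
    areas = io.read_areas(paths["areas"])

    kept, dropped, pi = filter_groupable(episodes)
    costing = CostingConfig(missing_fraction=pi)
    costed = cost_episodes(kept, tariffs)

    lookup = assign_quintiles(areas)
    summary = aggregate(costed, lookup, pop, inflation_factor=costing.inflation_factor)
    pop_cells = aggregate_population(pop, lookup)
    inequality = compute_inequality(summary, pop_cells)
    survival = survival_table(deaths, pop, lookup, cfg.life_table)
    profile, lifetime = lifetime_summary(survival, summary, cfg.life_table)

    activity = activity_table(summary)
    ineq_table = inequality_table(inequality)

    io.write_episodes(costed.drop(columns=["cost_pence"]), out / "kept_episodes.csv")
    costed.to_csv(out / "costed_episodes.csv", index=False)
    summary.cells.to_csv(out / "summary_cells.csv", index=False)
    summary.quintile_margins.to_csv(out / "quintile_margins.csv", index=False)
    pop_cells.to_csv(out / "population_cells.csv", index=False)
    inequality.per_cell.to_csv(out / "inequality.csv", index=False)
    survival.to_csv(out / "survival_curves.csv", index=False)
    profile.to_csv(out / "expected_costs.csv", index=False)
    lifetime.to_csv(out / "lifetime_costs.csv", index=False)
    activity.to_csv(out / "activity_table.csv", index=False)
    ineq_table.to_csv(out / "inequality_table.csv", index=False)
    (out / "activity_table.txt").write_text(format_activity_table(activity))
    (out / "inequality_table.txt").write_text(
        format_inequality_table(ineq_table, inequality)
    )

    log = {
        "episodes_total": int(len(episodes)),
        "episodes_dropped": int(dropped),
        "missing_fraction": float(pi),
        "inflation_factor": float(costing.inflation_factor),
        "q_convention": cfg.life_table.q_convention,
        "max_age": int(cfg.life_table.max_age),
        "survival_weighting": cfg.life_table.survival_weighting,
        "seed": None if cfg.simulate is None else int(cfg.simulate.seed),
        "rate_excess_pct": {
            stratum: float(rate_ratio(summary, "Q1", "Q5", stratum))
            for stratum in ("elective", "emergency", "all")
        },
        "inequality_grand_total": float(inequality.grand_total),
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
    save_config(cfg, out / "config.yaml")

    return PipelineResult(
        out_dir=out,
        costing=costing,
        dropped_count=dropped,
        summary=summary,
        pop_cells=pop_cells,
        inequality=inequality,
        survival=survival,
        cost_profile=profile,
        lifetime=lifetime,
        activity_table=activity,
        inequality_table=ineq_table,
    )


def activity_table(summary: GroupCostSummary) -> pd.DataFrame:
    """Episode counts and crude rates by quintile and admission type.

    Six rows (Q1..Q5 then Overall); rates are rounded to integer episodes
    per 100 000 at this presentation layer only.
    """
    m = summary.quintile_margins
    wide = m.pivot(index="quintile", columns="admission_type", values=["episode_count", "rate_per_100k"])
    rows = []
    for q in list(QUINTILES) + ["Overall"]:
        rows.append(
            {
                "quintile": q,
                "elective_total": int(wide.loc[q, ("episode_count", "elective")]),
                "elective_rate": int(round(wide.loc[q, ("rate_per_100k", "elective")])),
                "emergency_total": int(wide.loc[q, ("episode_count", "emergency")]),
                "emergency_rate": int(round(wide.loc[q, ("rate_per_100k", "emergency")])),
                "all_total": int(wide.loc[q, ("episode_count", "all")]),
                "all_rate": int(round(wide.loc[q, ("rate_per_100k", "all")])),
            }
        )
    return pd.DataFrame(rows)


def inequality_table(result: InequalityCostResult) -> pd.DataFrame:
    """Gap by quintile x sex in whole GBP, quintile-ordered, plus Overall."""
    cell = result.per_cell.pivot(index="quintile", columns="sex", values="gap")
    rows = []
    for q in [q for q in QUINTILES if q in cell.index]:
        f, m = cell.loc[q, "female"], cell.loc[q, "male"]
        rows.append(
            {"quintile": q, "female": round(f), "male": round(m), "total": round(f + m)}
        )
    rows.append(
        {
            "quintile": "Overall",
            "female": round(result.sex_totals["female"]),
            "male": round(result.sex_totals["male"]),
            "total": round(result.grand_total),
        }
    )
    return pd.DataFrame(rows)


def _fmt(n) -> str:
    return f"{n:,}"


def format_activity_table(table: pd.DataFrame) -> str:
    """Plain-text activity report (counts and rates per 100 000)."""
    lines = [
        "Number and rate of hospital episodes by admission type",
        "",
        f"{'Quintile':<20}{'Elective':>14}{'Rate':>9}{'Emergency':>14}{'Rate':>9}{'All':>14}{'Rate':>9}",
    ]
    for _, r in table.iterrows():
        label = _quintile_label(r["quintile"])
        lines.append(
            f"{label:<20}{_fmt(r['elective_total']):>14}{_fmt(r['elective_rate']):>9}"
            f"{_fmt(r['emergency_total']):>14}{_fmt(r['emergency_rate']):>9}"
            f"{_fmt(r['all_total']):>14}{_fmt(r['all_rate']):>9}"
        )
    lines.append("")
    lines.append("Rates are episodes per 100,000 residents.")
    return "\n".join(lines) + "\n"


def format_inequality_table(
    table: pd.DataFrame, result: InequalityCostResult | None = None
) -> str:
    """Plain-text inequality report; the comparator row prints dashes."""
    ref = result.reference if result is not None else "Q5"
    lines = [
        "Estimated cost of social inequality (GBP)",
        "",
        f"{'Quintile':<22}{'Female':>18}{'Male':>18}{'Total':>18}",
    ]
    for _, r in table.iterrows():
        label = _quintile_label(r["quintile"])
        if r["quintile"] == ref:
            lines.append(f"{label + '*':<22}{'-':>18}{'-':>18}{'-':>18}")
        else:
            lines.append(
                f"{label:<22}{_fmt(r['female']):>18}{_fmt(r['male']):>18}{_fmt(r['total']):>18}"
            )
    if result is not None:
        obs = result.per_cell[result.per_cell["quintile"] == ref]
        if len(obs) and "observed_cost" in obs.columns:
            f = round(float(obs.loc[obs["sex"] == "female", "observed_cost"].sum()))
            m = round(float(obs.loc[obs["sex"] == "male", "observed_cost"].sum()))
            lines.append("")
            lines.append(
                f"* Comparator group - costs in this group are {_fmt(f)}, {_fmt(m)} "
                f"and {_fmt(f + m)} for women, men and total, respectively."
            )
    return "\n".join(lines) + "\n"


def _quintile_label(q: str) -> str:
    return {"Q1": "Q1 (most deprived)", "Q5": "Q5 (most affluent)"}.get(q, q)
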