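"""Deprivation quintiles and per-cell aggregation of costed episodes.

Areas are ranked by the index of multiple deprivation (rank 1 = most
deprived) and cut into fifths *of areas* (not of population): Q1 holds the
most deprived fifth, Q5 the least deprived. When the number of areas is not
divisible by 5 the remainder areas go to the more-deprived quintiles first,
deterministically.

Costed episodes are then reduced to cells of deprivation quintile x sex x
single-year age (0-84, 85+) x admission type, carrying episode counts, cost
totals (exact integer pence), rates per 100 000 residents and the average
annual cost per head c(g,a,s) used by the counterfactual and lifetime-cost
stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ADMISSION_TYPES, AGE_OPEN, QUINTILES, SEXES

RATE_BASE = 100_000

STRATA = ADMISSION_TYPES + ("all",)


class AggregationError(ValueError):
    """Raised when inputs violate the aggregation contract."""


def quintile_group_sizes(n_areas: int) -> list[int]:
    """Sizes of the five rank-ordered groups; remainder to Q1 side first."""
    base, rem = divmod(n_areas, 5)
    return [base + (1 if i < rem else 0) for i in range(5)]


def assign_quintiles(areas: pd.DataFrame) -> pd.DataFrame:
    """Attach a deprivation quintile to each area from its IMD rank.

    Parameters
    ----------
    areas:
        DataFrame with columns ``area_id`` and ``imd_rank`` (distinct
        positive integers; rank 1 = most deprived).

    Returns
    -------
    DataFrame with columns ``area_id``, ``imd_rank``, ``quintile`` where
    quintiles partition the areas into 5 groups whose sizes differ by at
    most 1 and rank order agrees with quintile order.
    """
    ranks = areas["imd_rank"]
    if (ranks <= 0).any():
        raise AggregationError("imd_rank values must be positive integers")
    dup = ranks[ranks.duplicated(keep=False)].unique()
    if len(dup):
        raise AggregationError(f"duplicate imd_rank values: {sorted(map(int, dup))}")
    out = areas.sort_values("imd_rank", kind="mergesort").reset_index(drop=True)
    sizes = quintile_group_sizes(len(out))
    labels = np.repeat(list(QUINTILES), sizes)
    out = out.assign(quintile=labels)
    return out[["area_id", "imd_rank", "quintile"]]


def aggregate_population(pop: pd.DataFrame, lookup: pd.DataFrame) -> pd.DataFrame:
    """Collapse the area-level population to N(quintile, age, sex).

    Returns the full quintile x sex x age grid (zeros where empty) with an
    integer ``population`` column. Total population is conserved exactly.
    """
    merged = pop.merge(lookup[["area_id", "quintile"]], on="area_id", how="left")
    if merged["quintile"].isna().any():
        bad = merged.loc[merged["quintile"].isna(), "area_id"].unique()[:10]
        raise AggregationError(f"population rows reference unknown areas: {list(bad)}")
    cells = (
        merged.groupby(["quintile", "sex", "age"], observed=True)["population"]
        .sum()
        .reindex(_grid_index(), fill_value=0)
        .reset_index()
    )
    cells["population"] = cells["population"].astype(np.int64)
    return cells


def _grid_index() -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [list(QUINTILES), list(SEXES), range(AGE_OPEN + 1)],
        names=["quintile", "sex", "age"],
    )


@dataclass(frozen=True)
class GroupCostSummary:
    """Per-cell totals, rates and average annual costs.

    ``cells`` has one row per (quintile, sex, age, admission_type) with
    admission_type in {elective, emergency, all}; ``all`` rows are the exact
    sum of the two strata. Columns: ``episode_count``, ``total_cost_pence``
    (raw), ``inflated_cost_pence`` (after the missing-data uplift),
    ``population``, ``rate_per_100k`` and ``avg_cost_per_head`` (GBP; the
    quantity c(g,a,s), NaN where the population is zero).
    """

    cells: pd.DataFrame
    quintile_margins: pd.DataFrame
    inflation_factor: float

    def quintile_rates(self, stratum: str = "all") -> pd.Series:
        """Episode rate per 100 000 by quintile plus 'Overall'."""
        m = self.quintile_margins
        sel = m[m["admission_type"] == stratum]
        return sel.set_index("quintile")["rate_per_100k"]

    def avg_cost_profile(self, quintile: str, stratum: str = "all") -> pd.DataFrame:
        """c(g,a,s) for one quintile: rows (sex, age), column avg_cost_per_head."""
        c = self.cells
        sel = c[(c["quintile"] == quintile) & (c["admission_type"] == stratum)]
        return sel[["sex", "age", "population", "avg_cost_per_head"]].reset_index(drop=True)


def aggregate(
    costed: pd.DataFrame,
    lookup: pd.DataFrame,
    pop: pd.DataFrame,
    inflation_factor: float = 1.0,
) -> GroupCostSummary:
    """Reduce costed episodes to the quintile x sex x age x stratum summary.

    Every episode must carry age, sex and area_id (run ``filter_groupable``
    first) and every area_id must exist in ``lookup``. The inflation factor
    multiplies cost totals only, never populations or counts.
    """
    pop_cells = aggregate_population(pop, lookup)

    ep = costed.merge(lookup[["area_id", "quintile"]], on="area_id", how="left")
    if ep["quintile"].isna().any():
        bad = ep.loc[ep["quintile"].isna(), "area_id"].unique()[:10]
        raise AggregationError(
            f"episodes reference area_ids missing from the lookup: {list(bad)}"
        )
    ep = ep.assign(age=ep["age"].astype(np.int64))

    by_type = (
        ep.groupby(["quintile", "sex", "age", "admission_type"], observed=True)
        .agg(episode_count=("cost_pence", "size"), total_cost_pence=("cost_pence", "sum"))
        .reset_index()
    )
    full = pd.MultiIndex.from_product(
        [list(QUINTILES), list(SEXES), range(AGE_OPEN + 1), list(ADMISSION_TYPES)],
        names=["quintile", "sex", "age", "admission_type"],
    )
    by_type = (
        by_type.set_index(["quintile", "sex", "age", "admission_type"])
        .reindex(full, fill_value=0)
        .reset_index()
    )
    combined = (
        by_type.groupby(["quintile", "sex", "age"], observed=True)[
            ["episode_count", "total_cost_pence"]
        ]
        .sum()
        .reset_index()
        .assign(admission_type="all")
    )
    cells = pd.concat([by_type, combined], ignore_index=True)
    cells = cells.merge(pop_cells, on=["quintile", "sex", "age"], how="left")

    orphan = cells[(cells["population"] == 0) & (cells["episode_count"] > 0)]
    if len(orphan):
        keys = orphan[["quintile", "sex", "age"]].drop_duplicates().to_records(index=False)
        raise AggregationError(f"episodes in cells with zero population: {list(keys)[:10]}")

    cells["inflated_cost_pence"] = cells["total_cost_pence"] * inflation_factor
    with np.errstate(divide="ignore", invalid="ignore"):
        cells["rate_per_100k"] = np.where(
            cells["population"] > 0,
            cells["episode_count"] / cells["population"] * RATE_BASE,
            0.0,
        )
        cells["avg_cost_per_head"] = np.where(
            cells["population"] > 0,
            cells["inflated_cost_pence"] / cells["population"] / 100.0,
            np.nan,
        )

    margins = _quintile_margins(cells)
    return GroupCostSummary(cells=cells, quintile_margins=margins, inflation_factor=inflation_factor)


def _quintile_margins(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-quintile (and Overall) totals and crude rates per stratum."""
    rows = []
    for scope, frame in [("quintile", cells), ("Overall", cells.assign(quintile="Overall"))]:
        g = (
            frame.groupby(["quintile", "admission_type"], observed=True)
            .agg(
                episode_count=("episode_count", "sum"),
                total_cost_pence=("total_cost_pence", "sum"),
                inflated_cost_pence=("inflated_cost_pence", "sum"),
            )
            .reset_index()
        )
        pop_by_q = (
            frame[frame["admission_type"] == "all"]
            .groupby("quintile", observed=True)["population"]
            .sum()
        )
        g["population"] = g["quintile"].map(pop_by_q)
        rows.append(g)
    margins = pd.concat(rows, ignore_index=True)
    margins["rate_per_100k"] = np.where(
        margins["population"] > 0,
        margins["episode_count"] / margins["population"] * RATE_BASE,
        0.0,
    )
    order = {q: i for i, q in enumerate(list(QUINTILES) + ["Overall"])}
    margins = margins.sort_values(
        ["quintile", "admission_type"], key=lambda s: s.map(order) if s.name == "quintile" else s
    ).reset_index(drop=True)
    return margins


def rate_ratio(summary: GroupCostSummary, g_num: str, g_den: str, stratum: str = "all") -> float:
    """Percentage excess of one quintile's crude rate over another's.

    Returns 100 * (rate_num / rate_den - 1); round to integer percent only
    at presentation.
    """
    rates = summary.quintile_rates(stratum)
    return rate_excess_pct(rates[g_num], rates[g_den])


def rate_excess_pct(rate_num: float, rate_den: float) -> float:
    """100 * (rate_num/rate_den - 1); errors on a zero denominator."""
    if rate_den == 0:
        raise AggregationError("rate ratio undefined: denominator rate is zero")
    return 100.0 * (rate_num / rate_den - 1.0)


def standardised_rates(summary: GroupCostSummary, stratum: str = "all") -> pd.Series:
    """Directly age/sex-standardised episode rates per 100 000 by quintile.

    Each quintile's cell-level rates are averaged with the *national*
    population as the weight, removing the quintiles' different demographic
    structures from the comparison (crude rates fold them in). Cells where a
    quintile has no residents are excluded from that quintile's average.
    """
    cells = summary.cells
    sel = cells[cells["admission_type"] == stratum].copy()
    national = (
        sel.groupby(["sex", "age"], observed=True)["population"].sum().rename("weight")
    )
    sel = sel.merge(national, on=["sex", "age"])
    sel = sel[sel["population"] > 0]
    num = (sel["rate_per_100k"] * sel["weight"]).groupby(sel["quintile"]).sum()
    den = sel.groupby("quintile")["weight"].sum()
    return (num / den).reindex(list(QUINTILES))
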