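"""The counterfactual cost of inequality.

Observed cost per quintile and sex is compared with the cost had every
quintile experienced the least-deprived quintile's age/sex-specific average
costs at its own demography:

    counterfactual(g, s) = sum_a N(g, a, s) * cbar(Q5, a, s)
    gap(g, s)            = observed(g, s) - counterfactual(g, s)

The reference quintile's gap is zero by construction. Gaps may be negative
(a quintile cheaper than the reference at its demography) and are never
clamped. Both sides of the comparison use inflated (missing-data-corrected)
costs, so they are on the same basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort_aggregation import GroupCostSummary
from .io import QUINTILES, SEXES


class InequalityError(ValueError):
    """Raised on grid mismatches or missing reference cells."""


def observed_costs(summary: GroupCostSummary, stratum: str = "all") -> pd.DataFrame:
    """Observed (inflated) cost in GBP per quintile x sex.

    Computed as sum_a N(g,a,s) * cbar(g,a,s), which equals the inflated cell
    cost total by the definition of cbar; using the identical expression on
    both sides of the comparison makes the reference quintile's gap exactly
    zero in floating point, not merely close.
    """
    c = summary.cells
    sel = c[c["admission_type"] == stratum].copy()
    contrib = sel["population"] * sel["avg_cost_per_head"].fillna(0.0)
    out = (
        sel.assign(observed_cost=contrib)
        .groupby(["quintile", "sex"], observed=True)["observed_cost"]
        .sum()
        .reset_index()
    )
    return out


def counterfactual_costs(
    pop_cells: pd.DataFrame,
    summary: GroupCostSummary,
    reference: str = "Q5",
    stratum: str = "all",
) -> pd.DataFrame:
    """Cost each quintile's population at the reference quintile's cbar.

    ``pop_cells`` is the N(quintile, age, sex) table. Errors if the
    reference profile is undefined (zero reference population) in any cell
    where some quintile has people.
    """
    ref = summary.avg_cost_profile(reference, stratum).rename(
        columns={"avg_cost_per_head": "ref_cost"}
    )[["sex", "age", "ref_cost"]]
    merged = pop_cells.merge(ref, on=["sex", "age"], how="left")
    bad = merged[(merged["population"] > 0) & (merged["ref_cost"].isna())]
    if len(bad):
        cells = bad[["sex", "age"]].drop_duplicates().to_records(index=False)
        raise InequalityError(
            f"reference quintile {reference} has no cost profile for populated cells: {list(cells)[:10]}"
        )
    merged["ref_cost"] = merged["ref_cost"].fillna(0.0)
    out = (
        merged.assign(counterfactual_cost=merged["population"] * merged["ref_cost"])
        .groupby(["quintile", "sex"], observed=True)["counterfactual_cost"]
        .sum()
        .reset_index()
    )
    return out


@dataclass(frozen=True)
class InequalityCostResult:
    """Observed-minus-counterfactual gaps with all margins, in GBP.

    ``per_cell`` has one row per quintile x sex with observed,
    counterfactual and gap columns; ``quintile_totals`` and ``sex_totals``
    both sum to ``grand_total`` exactly.
    """

    per_cell: pd.DataFrame
    quintile_totals: pd.Series
    sex_totals: pd.Series
    grand_total: float
    reference: str = "Q5"


def summarise_gaps(per_cell: pd.DataFrame, reference: str = "Q5") -> InequalityCostResult:
    """Build the result (margins included) from a per-(quintile, sex) table.

    ``per_cell`` must contain ``quintile``, ``sex`` and ``gap`` columns; any
    observed/counterfactual columns are carried through. Usable directly on
    published gap tables as well as on pipeline output.
    """
    q_order = [q for q in QUINTILES if q in set(per_cell["quintile"])]
    quintile_totals = (
        per_cell.groupby("quintile", observed=True)["gap"].sum().reindex(q_order)
    )
    sex_totals = per_cell.groupby("sex", observed=True)["gap"].sum().reindex(list(SEXES))
    return InequalityCostResult(
        per_cell=per_cell.reset_index(drop=True),
        quintile_totals=quintile_totals,
        sex_totals=sex_totals,
        grand_total=float(per_cell["gap"].sum()),
        reference=reference,
    )


def inequality_gap(
    observed: pd.DataFrame, counterfactual: pd.DataFrame, reference: str = "Q5"
) -> InequalityCostResult:
    """Element-wise observed minus counterfactual with margins.

    Both inputs must cover the same (quintile, sex) grid.
    """
    obs = observed.set_index(["quintile", "sex"])["observed_cost"]
    cf = counterfactual.set_index(["quintile", "sex"])["counterfactual_cost"]
    if not obs.index.sort_values().equals(cf.index.sort_values()):
        raise InequalityError("observed and counterfactual are on different (quintile, sex) grids")
    per_cell = pd.DataFrame(
        {"observed_cost": obs, "counterfactual_cost": cf.reindex(obs.index)}
    ).reset_index()
    per_cell["gap"] = per_cell["observed_cost"] - per_cell["counterfactual_cost"]
    return summarise_gaps(per_cell, reference=reference)


def compute_inequality(
    summary: GroupCostSummary,
    pop_cells: pd.DataFrame,
    reference: str = "Q5",
    stratum: str = "all",
) -> InequalityCostResult:
    """End-to-end: observed and counterfactual costs, then the gap table."""
    obs = observed_costs(summary, stratum)
    cf = counterfactual_costs(pop_cells, summary, reference, stratum)
    return inequality_gap(obs, cf, reference=reference)
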