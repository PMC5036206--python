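"""Per-episode tariff costing and the missing-data exclusion rule.

Each finished consultant episode is costed from the national reference-cost
tariff for its HRG code:

    cost = unit_cost + max(0, length_of_stay - trim_point) * excess_per_diem

i.e. stays beyond the trim point attract a per-diem excess-bed-day
supplement. No local price (market-forces-factor) adjustment is applied:
the analysis targets variation in resource use, not in local prices.

Episodes missing any of age, sex or area of residence cannot be assigned to
an analysis cell and are dropped; group cost totals are then inflated by the
dropped fraction pi (factor 1 + pi), under the assumption that missing data
are equally distributed across patient groups and HRGs. The uplift applies
to cost totals only, never to populations or episode counts.

Costs are carried as exact integer pence through aggregation so that table
checks are bit-exact; division to averages happens last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class TariffLookupError(KeyError):
    """An episode's HRG code is absent from the reference-cost table."""


def _tariff_pence(tariffs: pd.DataFrame) -> pd.DataFrame:
    t = tariffs[["hrg_code", "unit_cost", "trim_point", "excess_per_diem"]].copy()
    if t["hrg_code"].duplicated().any():
        dup = t.loc[t["hrg_code"].duplicated(), "hrg_code"].tolist()
        raise ValueError(f"duplicate hrg_code in tariff table: {dup}")
    if (t[["unit_cost", "trim_point", "excess_per_diem"]] < 0).any().any():
        raise ValueError("tariff table has negative unit_cost/trim_point/excess_per_diem")
    t["unit_pence"] = np.round(t["unit_cost"] * 100).astype(np.int64)
    t["excess_pence"] = np.round(t["excess_per_diem"] * 100).astype(np.int64)
    return t.set_index("hrg_code")


def episode_cost_pence(length_of_stay, unit_pence, trim_point, excess_pence):
    """Exact tariff cost in pence; vectorised over numpy arrays."""
    excess_days = np.maximum(0, np.asarray(length_of_stay) - np.asarray(trim_point))
    return np.asarray(unit_pence) + excess_days * np.asarray(excess_pence)


def cost_episode(episode: pd.Series | dict, tariffs: pd.DataFrame) -> pd.Series:
    """Cost a single episode; returns the record with ``cost_pence`` added."""
    e = pd.Series(episode).copy()
    t = _tariff_pence(tariffs)
    code = e["hrg_code"]
    if code not in t.index:
        raise TariffLookupError(f"hrg_code {code!r} not found in the tariff table")
    row = t.loc[code]
    e["cost_pence"] = int(
        episode_cost_pence(e["length_of_stay"], row["unit_pence"], row["trim_point"], row["excess_pence"])
    )
    return e


def cost_episodes(episodes: pd.DataFrame, tariffs: pd.DataFrame) -> pd.DataFrame:
    """Attach ``cost_pence`` to every episode (vectorised tariff join).

    Raises :class:`TariffLookupError` naming the offending codes if any
    episode's HRG is missing from the table — never a silent zero cost.
    """
    t = _tariff_pence(tariffs)
    out = episodes.copy()
    if len(out) == 0:
        out["cost_pence"] = np.array([], dtype=np.int64)
        return out
    known = out["hrg_code"].isin(t.index)
    if not known.all():
        bad = sorted(out.loc[~known, "hrg_code"].unique())
        raise TariffLookupError(f"hrg_code(s) not found in the tariff table: {bad}")
    idx = t.index.get_indexer(out["hrg_code"])
    out["cost_pence"] = episode_cost_pence(
        out["length_of_stay"].to_numpy(),
        t["unit_pence"].to_numpy()[idx],
        t["trim_point"].to_numpy()[idx],
        t["excess_pence"].to_numpy()[idx],
    ).astype(np.int64)
    return out


def filter_groupable(episodes: pd.DataFrame) -> tuple[pd.DataFrame, int, float]:
    """Drop episodes that cannot be assigned to an age/sex/area cell.

    Returns ``(kept, dropped_count, missing_fraction)`` where kept contains
    exactly the episodes with age, sex and area_id all present and
    ``missing_fraction = dropped / total`` (0 for empty input).
    """
    if len(episodes) == 0:
        return episodes.copy(), 0, 0.0
    complete = (
        episodes["age"].notna() & episodes["sex"].notna() & episodes["area_id"].notna()
    )
    kept = episodes[complete].reset_index(drop=True)
    dropped = int((~complete).sum())
    return kept, dropped, dropped / len(episodes)


@dataclass(frozen=True)
class CostingConfig:
    """The missing-data fraction pi and its cost uplift factor 1 + pi."""

    missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_fraction < 1:
            raise ValueError(f"missing_fraction must be in [0, 1); got {self.missing_fraction}")

    @property
    def inflation_factor(self) -> float:
        return 1.0 + self.missing_fraction


def inflate_group_totals(totals, cfg: CostingConfig):
    """Multiply cost totals by (1 + pi). Linear, so group sums commute."""
    return totals * cfg.inflation_factor
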