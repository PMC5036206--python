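"""Period life tables: banded death counts to single-year survival curves.

Death counts arrive in 5-year bands (0-4 ... 80-84, 85+) per area, sex and
deprivation quintile; populations arrive by single year of age. Rates are
pooled within quintile (sum of deaths over sum of person-years, never a mean
of area-level rates), expanded piecewise-constant to single years of age,
and chained into survival curves:

    S(0) = 1,   S(a+1) = S(a) * (1 - q(a))

with q(a) the annual death probability. By default q(a) = m(a), the central
death rate used directly; the actuarial conversion q = m / (1 + m/2) is
available as an option. Ages beyond the open 85+ band keep the 85+ rate
(rates in old age are assumed constant, not to keep rising), and the curve
is closed at ``max_age`` (default 110).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import LifeTableOptions
from .io import AGE_OPEN, BAND_STARTS, QUINTILES, SEXES, band_of_age


class LifeTableError(ValueError):
    """Raised on inconsistent death/population inputs."""


def mortality_rates(
    deaths: pd.DataFrame, pop: pd.DataFrame, lookup: pd.DataFrame
) -> pd.DataFrame:
    """Pooled death rates m = sum(D) / sum(N) per quintile x sex x band.

    ``deaths`` is area-level with columns area_id, sex, band_start, deaths;
    ``pop`` is area-level by single year of age. Bands where both deaths and
    population are zero get rate 0 with a warning; deaths exceeding
    population are a validation error.
    """
    d = deaths.merge(lookup[["area_id", "quintile"]], on="area_id", how="left")
    if d["quintile"].isna().any():
        bad = d.loc[d["quintile"].isna(), "area_id"].unique()[:10]
        raise LifeTableError(f"deaths reference unknown areas: {list(bad)}")
    d_cells = (
        d.groupby(["quintile", "sex", "band_start"], observed=True)["deaths"].sum()
    )

    p = pop.merge(lookup[["area_id", "quintile"]], on="area_id", how="left")
    if p["quintile"].isna().any():
        bad = p.loc[p["quintile"].isna(), "area_id"].unique()[:10]
        raise LifeTableError(f"population rows reference unknown areas: {list(bad)}")
    p = p.assign(band_start=p["age"].astype(int).map(band_of_age))
    p_cells = p.groupby(["quintile", "sex", "band_start"], observed=True)["population"].sum()

    grid = pd.MultiIndex.from_product(
        [list(QUINTILES), list(SEXES), list(BAND_STARTS)],
        names=["quintile", "sex", "band_start"],
    )
    out = pd.DataFrame(
        {
            "deaths": d_cells.reindex(grid, fill_value=0),
            "population": p_cells.reindex(grid, fill_value=0),
        }
    ).reset_index()

    over = out[out["deaths"] > out["population"]]
    if len(over):
        keys = over[["quintile", "sex", "band_start"]].to_records(index=False)
        raise LifeTableError(f"death counts exceed population in bands: {list(keys)[:10]}")
    empty = (out["population"] == 0) & (out["deaths"] == 0)
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} band(s) have zero population and zero deaths; rate set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        out["rate"] = np.where(out["population"] > 0, out["deaths"] / out["population"], 0.0)
    return out


def expand_bands(band_rates: pd.DataFrame, max_age: int = 110) -> np.ndarray:
    """Piecewise-constant expansion of banded rates to single years 0..max_age.

    ``band_rates`` needs columns ``band_start`` and ``rate``; the last band
    is open-ended and its rate is held constant through ``max_age``. If a
    ``band_end`` column is present, bands must tile the age axis exactly
    (start 0, end_i + 1 = start_{i+1}); without it, each band is taken to
    run to the next band's start.
    """
    b = band_rates.sort_values("band_start").reset_index(drop=True)
    starts = b["band_start"].to_numpy()
    if len(starts) == 0:
        raise LifeTableError("no bands supplied")
    if starts[0] != 0:
        raise LifeTableError(f"bands must start at age 0; first band starts at {starts[0]}")
    if (np.diff(starts) <= 0).any() or len(np.unique(starts)) != len(starts):
        raise LifeTableError("overlapping bands: duplicate band_start values")
    if "band_end" in b.columns:
        ends = b["band_end"].to_numpy()
        expected_next = ends[:-1] + 1
        if (expected_next != starts[1:]).any():
            raise LifeTableError("bands have gaps or overlaps: band_end + 1 must equal the next band_start")
    rates = b["rate"].to_numpy(dtype=float)
    ages = np.arange(max_age + 1)
    idx = np.searchsorted(starts, ages, side="right") - 1
    return rates[idx]


def death_probabilities(rates_by_age: np.ndarray, q_convention: str = "central") -> np.ndarray:
    """Annual death probability q(a) from the central rate m(a)."""
    m = np.asarray(rates_by_age, dtype=float)
    if (m < 0).any() or (m > 1).any():
        raise LifeTableError("single-year rates must lie in [0, 1]")
    if q_convention == "central":
        q = m
    elif q_convention == "actuarial":
        q = m / (1.0 + m / 2.0)
    else:
        raise LifeTableError(f"unknown q_convention {q_convention!r}")
    return np.clip(q, 0.0, 1.0)


def survival_curve(rates_by_age: np.ndarray, q_convention: str = "central") -> np.ndarray:
    """S(a) for a = 0..max_age from single-year rates (len max_age + 1)."""
    q = death_probabilities(rates_by_age, q_convention)
    s = np.ones(len(q))
    s[1:] = np.cumprod(1.0 - q)[:-1]
    return s


def survival_table(
    deaths: pd.DataFrame,
    pop: pd.DataFrame,
    lookup: pd.DataFrame,
    options: LifeTableOptions | None = None,
) -> pd.DataFrame:
    """Survival curves per quintile x sex: columns quintile, sex, age, survival."""
    opts = options or LifeTableOptions()
    rates = mortality_rates(deaths, pop, lookup)
    frames = []
    for (quintile, sex), grp in rates.groupby(["quintile", "sex"], observed=True):
        by_age = expand_bands(grp[["band_start", "rate"]], opts.max_age)
        s = survival_curve(by_age, opts.q_convention)
        frames.append(
            pd.DataFrame(
                {"quintile": quintile, "sex": sex, "age": np.arange(opts.max_age + 1), "survival": s}
            )
        )
    return pd.concat(frames, ignore_index=True)
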