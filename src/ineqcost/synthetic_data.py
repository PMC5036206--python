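"""Synthetic small-area populations, hospital episodes, tariffs and deaths.

The generator stands in for the restricted whole-population inputs the
analysis was designed around: small census areas of ~1 500 residents ranked
by deprivation, an episode file with one row per finished consultant episode
(FCE), a reference-cost tariff catalogue, mid-year populations by single year
of age (0-84, 85+), and death counts in 5-year bands.

Statistical structure emulated:

* **Mortality** is Gompertz in age, lower for women, and scaled by a
  deprivation hazard gradient that ramps log-linearly from Q5 (factor 1) to
  Q1 (factor = ``mortality_gradient``).
* **Age structure** is the stationary population implied by each quintile's
  own hazard, so more-deprived areas have fewer residents surviving to old
  age — the population and mortality files are internally consistent.
* **Admission rates** are U-shaped in age (high in infancy, minimum near 10,
  rising steeply in old age), multiplied for women aged 20-40 by a
  reproductive-age factor, and scaled by separate elective and emergency
  deprivation gradients (emergency steeper). Per-cell episode counts are
  Poisson.
* **Missingness**: a fraction ``missing_rate`` of episodes has one of age,
  sex or area blanked, uniformly at random across cells.

Every random stream derives from the master seed via a fixed integer label,
so regenerating with the same config is bit-identical and the missingness
stream never perturbs the episodes themselves.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_aggregation import assign_quintiles, quintile_group_sizes
from .config import SimulationConfig, save_config
from .io import (
    ADMISSION_TYPES,
    AGE_OPEN,
    QUINTILES,
    SEXES,
    band_of_age,
    write_areas,
    write_deaths,
    write_episodes,
    write_population,
    write_tariffs,
)

# fixed stream labels: adding a generator must never renumber existing ones
STREAM_AREAS = 11
STREAM_POPULATION = 12
STREAM_TARIFFS = 13
STREAM_EPISODES = 14
STREAM_MISSING = 15
STREAM_MORTALITY = 16

FEMALE_HAZARD_FACTOR = 0.55
YEAR_LABEL = "2011/12"
N_HRG = 20
MAX_AGE = 110  # closes the open 85+ group inside the generator

# admission-rate curve r(a) = child*exp(-a/5) + old*exp(growth*(a-85)),
# calibrated so national crude rates land near ~22k elective / ~15k
# emergency episodes per 100k residents
RATE_CURVES = {
    "elective": (0.12, 0.50, 0.028),
    "emergency": (0.14, 0.50, 0.045),
}
REPRO_AGES = (20, 40)  # inclusive band for the female reproductive-age factor


def _rng(cfg: SimulationConfig, label: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, label])


def quintile_factor(quintile: str, gradient: float) -> float:
    """Log-linear ramp: Q5 -> 1, Q1 -> gradient."""
    idx = QUINTILES.index(quintile)  # 0 for Q1 .. 4 for Q5
    return float(gradient ** ((4 - idx) / 4))


def gompertz_hazard(ages: np.ndarray, cfg: SimulationConfig, sex: str, hazard_factor: float = 1.0) -> np.ndarray:
    h = cfg.gompertz_intercept * np.exp(cfg.gompertz_slope * np.asarray(ages, dtype=float))
    if sex == "female":
        h = h * FEMALE_HAZARD_FACTOR
    return h * hazard_factor


def annual_death_prob(ages: np.ndarray, cfg: SimulationConfig, sex: str, hazard_factor: float = 1.0) -> np.ndarray:
    """q(a) = 1 - exp(-h(a)): always in [0, 1)."""
    return 1.0 - np.exp(-gompertz_hazard(ages, cfg, sex, hazard_factor))


def analytic_survival(cfg: SimulationConfig, sex: str, hazard_factor: float = 1.0, max_age: int = MAX_AGE) -> np.ndarray:
    """S(a) for a = 0..max_age under the generator's single-year hazard."""
    q = annual_death_prob(np.arange(max_age + 1), cfg, sex, hazard_factor)
    s = np.ones(max_age + 1)
    s[1:] = np.cumprod(1.0 - q)[:-1]
    return s


def open_interval_death_prob(cfg: SimulationConfig, sex: str, hazard_factor: float = 1.0) -> float:
    """Survivorship-weighted annual death probability over ages 85..max.

    This is the probability applied to the pooled 85+ population cell, so
    the deaths file is consistent with the stationary age mix inside the
    open interval.
    """
    s = analytic_survival(cfg, sex, hazard_factor)
    q = annual_death_prob(np.arange(MAX_AGE + 1), cfg, sex, hazard_factor)
    w = s[AGE_OPEN:]
    return float((w * q[AGE_OPEN:]).sum() / w.sum())


def _population_shares(cfg: SimulationConfig, quintile: str) -> pd.DataFrame:
    """Expected share of an area's residents per (sex, age 0-84, 85+) cell.

    Shares follow each quintile's own stationary population (survivorship
    under its hazard), with the 85+ cell pooling the tail, and equal numbers
    of male and female births.
    """
    factor = quintile_factor(quintile, cfg.mortality_gradient)
    frames = []
    for sex in SEXES:
        s = analytic_survival(cfg, sex, factor)
        w = np.empty(AGE_OPEN + 1)
        w[:AGE_OPEN] = s[:AGE_OPEN]
        w[AGE_OPEN] = s[AGE_OPEN:].sum()
        frames.append(pd.DataFrame({"sex": sex, "age": np.arange(AGE_OPEN + 1), "weight": w}))
    out = pd.concat(frames, ignore_index=True)
    out["share"] = out["weight"] / out["weight"].sum()
    return out[["sex", "age", "share"]]


def simulate_areas(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate areas with distinct IMD ranks and their resident populations.

    Returns ``(areas, population)``: areas has columns ``area_id`` and
    ``imd_rank`` (a random permutation of 1..n_areas); population has one
    row per area x sex x age cell with Poisson-sampled counts whose mean is
    ``mean_area_pop`` times the quintile's stationary age-structure share.
    """
    rng = _rng(cfg, STREAM_AREAS)
    area_ids = np.array([f"A{i:06d}" for i in range(1, cfg.n_areas + 1)])
    ranks = rng.permutation(cfg.n_areas) + 1
    areas = pd.DataFrame({"area_id": area_ids, "imd_rank": ranks})

    lookup = assign_quintiles(areas)
    shares = {q: _population_shares(cfg, q) for q in QUINTILES}

    rng_pop = _rng(cfg, STREAM_POPULATION)
    blocks = []
    for quintile in QUINTILES:
        ids = lookup.loc[lookup["quintile"] == quintile, "area_id"].to_numpy()
        sh = shares[quintile]
        lam = cfg.mean_area_pop * sh["share"].to_numpy()
        counts = rng_pop.poisson(np.broadcast_to(lam, (len(ids), len(lam))))
        blocks.append(
            pd.DataFrame(
                {
                    "area_id": np.repeat(ids, len(lam)),
                    "sex": np.tile(sh["sex"].to_numpy(), len(ids)),
                    "age": np.tile(sh["age"].to_numpy(), len(ids)),
                    "population": counts.ravel(),
                }
            )
        )
    pop = pd.concat(blocks, ignore_index=True)
    pop["age"] = pop["age"].astype("Int64")
    return areas, pop


def simulate_tariffs(cfg: SimulationConfig) -> pd.DataFrame:
    """A pseudo-HRG catalogue of N_HRG codes with gamma-distributed unit costs.

    Columns beyond the costing contract (``mean_los``, ``weight``) drive the
    generator's length-of-stay and case-mix draws and are written to the
    tariff file for transparency; the costing stage ignores them.
    """
    rng = _rng(cfg, STREAM_TARIFFS)
    unit_cost = np.round(rng.gamma(cfg.tariff_shape, cfg.tariff_mean / cfg.tariff_shape, N_HRG), 2)
    trim_point = rng.integers(5, 31, N_HRG)
    excess_per_diem = np.round(rng.gamma(2.0, 100.0, N_HRG), 2)
    weight = rng.dirichlet(np.full(N_HRG, 5.0))
    return pd.DataFrame(
        {
            "hrg_code": [f"HRG{i:02d}" for i in range(1, N_HRG + 1)],
            "unit_cost": unit_cost,
            "trim_point": trim_point,
            "excess_per_diem": excess_per_diem,
            "mean_los": trim_point / 2.0,  # exercises the excess-bed-day path
            "weight": weight,
        }
    )


def baseline_episode_rate(ages: np.ndarray, sex: str, admission_type: str, cfg: SimulationConfig) -> np.ndarray:
    """Expected episodes per person-year before the deprivation gradient."""
    child, old, growth = RATE_CURVES[admission_type]
    a = np.asarray(ages, dtype=float)
    r = child * np.exp(-a / 5.0) + old * np.exp(growth * (a - 85.0))
    if sex == "female":
        repro = (a >= REPRO_AGES[0]) & (a <= REPRO_AGES[1])
        r = np.where(repro, r * cfg.female_repro_multiplier, r)
    return r


def expected_cell_rate(ages, sex: str, admission_type: str, quintile: str, cfg: SimulationConfig) -> np.ndarray:
    gradient = (
        cfg.rate_gradient_elective if admission_type == "elective" else cfg.rate_gradient_emergency
    )
    return baseline_episode_rate(ages, sex, admission_type, cfg) * quintile_factor(quintile, gradient)


def simulate_episodes(
    areas: pd.DataFrame,
    pop: pd.DataFrame,
    cfg: SimulationConfig,
    tariffs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per finished consultant episode, Poisson per population cell.

    Each episode carries an HRG code drawn from the catalogue's case-mix
    weights and a geometric length of stay with the HRG's mean, so a share
    of stays exceeds the trim point. A fraction ``missing_rate`` of episodes
    then has age, sex or area blanked (field chosen uniformly), independent
    of the cell — matching the downstream assumption that missing data are
    equally distributed across patient groups.
    """
    if tariffs is None:
        tariffs = simulate_tariffs(cfg)
    lookup = assign_quintiles(areas)
    cells = pop.merge(lookup[["area_id", "quintile"]], on="area_id", how="left")
    cells = cells[cells["population"] > 0].reset_index(drop=True)

    rng = _rng(cfg, STREAM_EPISODES)
    parts = []
    for adm in ADMISSION_TYPES:
        lam = np.zeros(len(cells))
        for sex in SEXES:
            for q in QUINTILES:
                m = (cells["sex"] == sex).to_numpy() & (cells["quintile"] == q).to_numpy()
                if m.any():
                    lam[m] = expected_cell_rate(
                        cells.loc[m, "age"].to_numpy(dtype=float), sex, adm, q, cfg
                    )
        counts = rng.poisson(lam * cells["population"].to_numpy())
        idx = np.repeat(np.arange(len(cells)), counts)
        parts.append(
            pd.DataFrame(
                {
                    "age": cells["age"].to_numpy()[idx],
                    "sex": cells["sex"].to_numpy()[idx],
                    "area_id": cells["area_id"].to_numpy()[idx],
                    "admission_type": adm,
                }
            )
        )
    ep = pd.concat(parts, ignore_index=True)
    n = len(ep)

    hrg_idx = rng.choice(N_HRG, size=n, p=tariffs["weight"].to_numpy())
    ep["hrg_code"] = tariffs["hrg_code"].to_numpy()[hrg_idx]
    mean_los = tariffs["mean_los"].to_numpy()[hrg_idx]
    # geometric on {0,1,...} with the HRG's mean
    ep["length_of_stay"] = (rng.geometric(1.0 / (1.0 + mean_los)) - 1).astype(np.int64) if n else np.array([], dtype=np.int64)
    ep["year"] = YEAR_LABEL
    ep.insert(0, "episode_id", np.arange(1, n + 1))
    ep["age"] = ep["age"].astype("Int64")
    ep["sex"] = ep["sex"].astype(object)
    ep["area_id"] = ep["area_id"].astype(object)

    rng_miss = _rng(cfg, STREAM_MISSING)
    if cfg.missing_rate > 0 and n:
        blank = rng_miss.random(n) < cfg.missing_rate
        which = rng_miss.integers(0, 3, n)
        ep.loc[blank & (which == 0), "age"] = pd.NA
        ep.loc[blank & (which == 1), "sex"] = pd.NA
        ep.loc[blank & (which == 2), "area_id"] = pd.NA
    return ep


def simulate_mortality(areas: pd.DataFrame, pop: pd.DataFrame, cfg: SimulationConfig) -> pd.DataFrame:
    """Binomial death counts per area x sex x 5-year band.

    Single-year cells die with the quintile-scaled Gompertz probability and
    are then pooled to bands; the open 85+ cell uses the survivorship-
    weighted probability over ages 85..110.
    """
    lookup = assign_quintiles(areas)
    cells = pop.merge(lookup[["area_id", "quintile"]], on="area_id", how="left").copy()
    q_prob = np.zeros(len(cells))
    for sex in SEXES:
        for quintile in QUINTILES:
            factor = quintile_factor(quintile, cfg.mortality_gradient)
            m = (cells["sex"] == sex).to_numpy() & (cells["quintile"] == quintile).to_numpy()
            if not m.any():
                continue
            ages = cells.loc[m, "age"].to_numpy(dtype=float)
            p = annual_death_prob(ages, cfg, sex, factor)
            open_mask = ages >= AGE_OPEN
            if open_mask.any():
                p[open_mask] = open_interval_death_prob(cfg, sex, factor)
            q_prob[m] = p

    rng = _rng(cfg, STREAM_MORTALITY)
    cells["deaths"] = rng.binomial(cells["population"].to_numpy(), q_prob)
    cells["band_start"] = cells["age"].astype(int).map(band_of_age)
    out = (
        cells.groupby(["area_id", "sex", "band_start"], observed=True)["deaths"]
        .sum()
        .reset_index()
    )
    return out


@dataclass
class GroundTruth:
    """Expectation-level quantities realised by a simulated dataset.

    All fields are deterministic functions of the config, so regenerating
    with the same seed reproduces the file bit-identically. Rate ratios are
    *crude* expected Q1/Q5 ratios — they fold in the quintiles' different
    age structures and therefore differ slightly from the configured per-cell
    gradients, exactly as the analysis pipeline will see them.
    """

    config: dict
    quintile_sizes: list[int]
    expected_population: float
    expected_rates_per_100k: dict  # admission_type -> {quintile: rate}
    expected_rate_ratio: dict  # admission_type -> expected crude Q1/Q5 ratio
    configured_rate_gradients: dict  # admission_type -> per-cell Q1/Q5 gradient
    mortality_hazard_factors: dict  # quintile -> hazard factor vs Q5
    expected_cell_counts: pd.DataFrame  # quintile,sex,age,admission_type,expected_count
    expected_band_death_prob: pd.DataFrame  # quintile,sex,band_start,prob
    expected_survival: pd.DataFrame  # quintile,sex,age,survival (band convention)

    def scalars(self) -> dict:
        return {
            "config": self.config,
            "quintile_sizes": self.quintile_sizes,
            "expected_population": self.expected_population,
            "expected_rates_per_100k": self.expected_rates_per_100k,
            "expected_rate_ratio": self.expected_rate_ratio,
            "configured_rate_gradients": self.configured_rate_gradients,
            "mortality_hazard_factors": self.mortality_hazard_factors,
        }


def ground_truth(cfg: SimulationConfig, max_age: int = MAX_AGE) -> GroundTruth:
    """Compute the generator's expectations for recovery tests.

    ``expected_survival`` applies the same convention the life-table stage
    uses — banded rates expanded piecewise-constant to single years — to the
    generator's *expected* death counts, so an estimate from a large
    simulated dataset should match it up to Monte-Carlo error alone.
    """
    sizes = quintile_group_sizes(cfg.n_areas)
    ages = np.arange(AGE_OPEN + 1)

    cell_rows = []
    rates = {adm: {} for adm in ADMISSION_TYPES}
    band_rows = []
    surv_rows = []
    for qi, quintile in enumerate(QUINTILES):
        shares = _population_shares(cfg, quintile)
        q_pop = sizes[qi] * cfg.mean_area_pop
        pop_by_cell = shares.set_index(["sex", "age"])["share"] * q_pop
        for adm in ADMISSION_TYPES:
            total = 0.0
            for sex in SEXES:
                n_cell = pop_by_cell.loc[sex].to_numpy()
                lam = expected_cell_rate(ages, sex, adm, quintile, cfg) * n_cell
                total += lam.sum()
                cell_rows.append(
                    pd.DataFrame(
                        {
                            "quintile": quintile,
                            "sex": sex,
                            "age": ages,
                            "admission_type": adm,
                            "expected_count": lam,
                        }
                    )
                )
            rates[adm][quintile] = total / q_pop * 100_000

        factor = quintile_factor(quintile, cfg.mortality_gradient)
        for sex in SEXES:
            n_cell = pop_by_cell.loc[sex]
            q_single = annual_death_prob(ages.astype(float), cfg, sex, factor)
            q_single[AGE_OPEN] = open_interval_death_prob(cfg, sex, factor)
            band = pd.DataFrame(
                {
                    "band_start": [band_of_age(int(a)) for a in ages],
                    "w": n_cell.to_numpy(),
                    "wq": n_cell.to_numpy() * q_single,
                }
            ).groupby("band_start").sum()
            band_prob = (band["wq"] / band["w"]).rename("prob").reset_index()
            band_rows.append(band_prob.assign(quintile=quintile, sex=sex))

            # band-convention survival: piecewise-constant single-year rates
            per_age = band_prob.set_index("band_start")["prob"]
            q_expand = np.array([per_age[band_of_age(min(a, AGE_OPEN))] for a in range(max_age + 1)])
            s = np.ones(max_age + 1)
            s[1:] = np.cumprod(1.0 - q_expand)[:-1]
            surv_rows.append(
                pd.DataFrame(
                    {"quintile": quintile, "sex": sex, "age": np.arange(max_age + 1), "survival": s}
                )
            )

    all_rates = {
        "all": {
            q: rates["elective"][q] + rates["emergency"][q] for q in QUINTILES
        }
    }
    rates.update(all_rates)
    ratio = {adm: rates[adm]["Q1"] / rates[adm]["Q5"] for adm in list(ADMISSION_TYPES) + ["all"]}

    return GroundTruth(
        config=cfg.to_dict(),
        quintile_sizes=sizes,
        expected_population=cfg.n_areas * cfg.mean_area_pop,
        expected_rates_per_100k=rates,
        expected_rate_ratio=ratio,
        configured_rate_gradients={
            "elective": cfg.rate_gradient_elective,
            "emergency": cfg.rate_gradient_emergency,
        },
        mortality_hazard_factors={
            q: quintile_factor(q, cfg.mortality_gradient) for q in QUINTILES
        },
        expected_cell_counts=pd.concat(cell_rows, ignore_index=True),
        expected_band_death_prob=pd.concat(band_rows, ignore_index=True)[
            ["quintile", "sex", "band_start", "prob"]
        ],
        expected_survival=pd.concat(surv_rows, ignore_index=True),
    )


def write_dataset(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the five input files plus ground truth and config.

    Returns a mapping of role -> path. Same config (including seed) writes
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    areas, pop = simulate_areas(cfg)
    tariffs = simulate_tariffs(cfg)
    episodes = simulate_episodes(areas, pop, cfg, tariffs)
    deaths = simulate_mortality(areas, pop, cfg)
    gt = ground_truth(cfg)

    paths = {
        "areas": out / "areas.csv",
        "population": out / "population.csv",
        "tariffs": out / "tariffs.csv",
        "episodes": out / "episodes.csv",
        "deaths": out / "deaths.csv",
        "ground_truth": out / "ground_truth.json",
        "ground_truth_cells": out / "ground_truth_cells.csv",
        "ground_truth_survival": out / "ground_truth_survival.csv",
        "config": out / "config.yaml",
    }
    write_areas(areas, paths["areas"])
    write_population(pop, paths["population"])
    write_tariffs(tariffs, paths["tariffs"])
    write_episodes(episodes, paths["episodes"])
    write_deaths(deaths, paths["deaths"])
    paths["ground_truth"].write_text(json.dumps(gt.scalars(), indent=2, sort_keys=True))
    gt.expected_cell_counts.to_csv(paths["ground_truth_cells"], index=False)
    gt.expected_survival.to_csv(paths["ground_truth_survival"], index=False)
    save_config(cfg, paths["config"])
    return paths
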