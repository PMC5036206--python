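import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ineqcost as iq
from ineqcost.life_table import LifeTableError, death_probabilities
from ineqcost.io import BAND_STARTS


def _toy_inputs(deaths_by_area, pop_by_area):
    """Three one-band areas in one quintile-span rank range."""
    areas = pd.DataFrame({"area_id": ["A1", "A2", "A3", "A4", "A5"], "imd_rank": [1, 2, 3, 4, 5]})
    lookup = iq.assign_quintiles(areas)
    deaths = pd.DataFrame(
        {
            "area_id": list(deaths_by_area),
            "sex": "male",
            "band_start": 0,
            "deaths": list(deaths_by_area.values()),
        }
    )
    pop = pd.DataFrame(
        {
            "area_id": list(pop_by_area),
            "sex": "male",
            "age": 2,
            "population": list(pop_by_area.values()),
        }
    )
    return deaths, pop, lookup


def test_rate_is_direct_division():
    deaths, pop, lookup = _toy_inputs({"A1": 10}, {"A1": 1000})
    with pytest.warns(UserWarning):
        rates = iq.mortality_rates(deaths, pop, lookup)
    cell = rates[
        (rates["quintile"] == "Q1") & (rates["band_start"] == 0) & (rates["sex"] == "male")
    ]
    assert cell["rate"].item() == pytest.approx(0.01)


def test_rates_pool_counts_not_area_rates():
    """Aggregation is sum(D)/sum(N), not the mean of per-area rates: with
    areas (1/10, 10/1000, 5/100) pooled m = 16/1110, not mean(0.1, 0.01, 0.05)."""
    # put all three areas in one quintile by giving them adjacent ranks
    areas = pd.DataFrame({"area_id": [f"A{i}" for i in range(1, 16)], "imd_rank": range(1, 16)})
    lookup = iq.assign_quintiles(areas)  # A1..A3 -> Q1
    deaths = pd.DataFrame(
        {"area_id": ["A1", "A2", "A3"], "sex": "male", "band_start": 0, "deaths": [1, 10, 5]}
    )
    pop = pd.DataFrame(
        {"area_id": ["A1", "A2", "A3"], "sex": "male", "age": 0, "population": [10, 1000, 100]}
    )
    with pytest.warns(UserWarning):
        rates = iq.mortality_rates(deaths, pop, lookup)
    q1 = rates[
        (rates["quintile"] == "Q1") & (rates["band_start"] == 0) & (rates["sex"] == "male")
    ]
    assert q1["rate"].item() == pytest.approx(16 / 1110)
    assert q1["rate"].item() != pytest.approx(np.mean([0.1, 0.01, 0.05]))


def test_deaths_exceeding_population_is_an_error():
    deaths, pop, lookup = _toy_inputs({"A1": 20}, {"A1": 10})
    with pytest.raises(LifeTableError, match="exceed"):
        iq.mortality_rates(deaths, pop, lookup)


def test_empty_bands_warn_and_rate_zero():
    deaths, pop, lookup = _toy_inputs({"A1": 0}, {"A1": 0})
    with pytest.warns(UserWarning, match="zero population"):
        rates = iq.mortality_rates(deaths, pop, lookup)
    assert (rates["rate"] == 0).all()


def test_expand_bands_is_piecewise_constant():
    bands = pd.DataFrame({"band_start": [0, 5], "rate": [0.002, 0.01]})
    by_age = iq.expand_bands(bands, max_age=12)
    np.testing.assert_allclose(by_age[:5], 0.002)
    np.testing.assert_allclose(by_age[5:], 0.01)


def test_open_band_rate_held_to_max_age():
    bands = pd.DataFrame({"band_start": list(BAND_STARTS), "rate": [0.001] * 17 + [0.15]})
    by_age = iq.expand_bands(bands, max_age=110)
    np.testing.assert_allclose(by_age[85:], 0.15)
    assert len(by_age) == 111


def test_single_open_band_gives_constant_hazard():
    bands = pd.DataFrame({"band_start": [0], "rate": [0.03]})
    np.testing.assert_allclose(iq.expand_bands(bands, max_age=50), 0.03)


def test_band_gaps_and_overlaps_are_errors():
    with pytest.raises(LifeTableError, match="start at age 0"):
        iq.expand_bands(pd.DataFrame({"band_start": [5, 10], "rate": [0.1, 0.1]}))
    with pytest.raises(LifeTableError, match="overlap"):
        iq.expand_bands(pd.DataFrame({"band_start": [0, 0, 5], "rate": [0.1, 0.2, 0.1]}))
    with pytest.raises(LifeTableError, match="gaps or overlaps"):
        iq.expand_bands(
            pd.DataFrame({"band_start": [0, 10], "band_end": [4, 14], "rate": [0.1, 0.1]})
        )


def test_zero_hazard_means_certain_survival():
    s = iq.survival_curve(np.zeros(51))
    np.testing.assert_array_equal(s, np.ones(51))


def test_unit_hazard_at_birth_is_absorbing():
    m = np.zeros(10)
    m[0] = 1.0
    s = iq.survival_curve(m)
    assert s[0] == 1.0
    np.testing.assert_array_equal(s[1:], 0.0)


def test_constant_hazard_gives_geometric_survival():
    s = iq.survival_curve(np.full(111, 0.01))
    np.testing.assert_allclose(s, 0.99 ** np.arange(111), rtol=1e-14)


def test_actuarial_conversion():
    q = death_probabilities(np.array([0.1]), q_convention="actuarial")
    assert q[0] == pytest.approx(0.1 / 1.05)


def test_rates_outside_unit_interval_are_rejected():
    with pytest.raises(LifeTableError):
        iq.survival_curve(np.array([0.5, 1.2]))


@given(
    m=st.lists(st.floats(min_value=0, max_value=0.5), min_size=5, max_size=30),
    bump_at=st.integers(min_value=0, max_value=4),
    bump=st.floats(min_value=0.01, max_value=0.4),
)
def test_raising_any_hazard_weakly_lowers_later_survival(m, bump_at, bump):
    m = np.asarray(m)
    s0 = iq.survival_curve(m)
    m2 = m.copy()
    m2[bump_at] = min(1.0, m2[bump_at] + bump)
    s1 = iq.survival_curve(m2)
    assert (s1[bump_at + 1 :] <= s0[bump_at + 1 :] + 1e-15).all()
    np.testing.assert_array_equal(s1[: bump_at + 1], s0[: bump_at + 1])


def test_survival_table_is_monotone_and_anchored(tiny_data):
    surv = iq.survival_table(tiny_data["deaths"], tiny_data["pop"], tiny_data["lookup"])
    for _, grp in surv.groupby(["quintile", "sex"]):
        s = grp.sort_values("age")["survival"].to_numpy()
        assert s[0] == 1.0
        assert (np.diff(s) <= 1e-15).all()
        assert (s >= 0).all()


def test_estimated_survival_matches_generator_expectation(recovery_run):
    """At decade ages the estimated curves sit within 3 Monte-Carlo standard
    errors of the generator's expected (band-convention) survival.

    The standard error comes from the delta method: S(a) is a product of
    (1 - m_b) factors over bands b, each m_b a binomial proportion on the
    band's population, so Var(log S) = sum over bands of
    k_b^2 * m_b * (1 - m_b) / (N_b * (1 - m_b)^2) with k_b the years the
    band contributes before age a.
    """
    gt = recovery_run["ground_truth"]
    est = recovery_run["survival"].set_index(["quintile", "sex", "age"])["survival"]
    exp_s = gt.expected_survival.set_index(["quintile", "sex", "age"])["survival"]
    exp_m = gt.expected_band_death_prob.set_index(["quintile", "sex", "band_start"])["prob"]

    pop_band = recovery_run["pop_cells"].copy()
    pop_band["band_start"] = pop_band["age"].astype(int).map(lambda a: 85 if a >= 85 else (a // 5) * 5)
    n_band = pop_band.groupby(["quintile", "sex", "band_start"])["population"].sum()

    for q in ["Q1", "Q3", "Q5"]:
        for sex in ["female", "male"]:
            for age in range(10, 101, 10):
                var_log_s = 0.0
                for b in BAND_STARTS:
                    k = min(max(age - b, 0), 110 - b + 1 if b == 85 else 5)
                    if k == 0:
                        continue
                    m = exp_m[(q, sex, b)]
                    n = max(float(n_band[(q, sex, b)]), 1.0)
                    var_log_s += k**2 * m * (1 - m) / (n * (1 - m) ** 2)
                s = exp_s[(q, sex, age)]
                se = s * np.sqrt(var_log_s)
                assert abs(est[(q, sex, age)] - s) <= 3 * se, (q, sex, age)


def test_q1_survival_at_or_below_q5(recovery_run):
    wide = recovery_run["survival"].pivot_table(
        index=["sex", "age"], columns="quintile", values="survival"
    )
    # expectation-level dominance; allow sampling jitter at very old ages
    assert (wide["Q1"] <= wide["Q5"] + 0.01).all()
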