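"""Published national aggregates for NHS England inpatient activity, 2011/12.

These are the whole-population totals by deprivation quintile that the
underlying restricted data (HES episode-level records linked to ONS
populations and IMD 2010 ranks) reduce to. The raw record-level inputs are
not publicly releasable, but the published aggregates let the reporting and
formula layer be exercised against real national numbers: rate additivity,
quintile rate excesses, inequality-gap margins and the missing-data
fraction.

All rates are crude episodes per 100 000 residents; costs are GBP.
"""

from __future__ import annotations

import pandas as pd

# Number and rate of finished consultant episodes by admission type and
# deprivation quintile (Q1 = most deprived), England 2011/12.
EPISODE_ACTIVITY = pd.DataFrame(
    [
        # quintile, elective_total, elective_rate, emergency_total, emergency_rate
        ("Q1", 2_481_014, 23_727, 2_055_481, 19_658),
        ("Q2", 2_355_297, 22_338, 1_706_833, 16_188),
        ("Q3", 2_310_208, 21_811, 1_546_013, 14_596),
        ("Q4", 2_235_779, 21_254, 1_390_347, 13_217),
        ("Q5", 2_095_137, 19_804, 1_216_063, 11_495),
        ("Overall", 11_477_435, 21_783, 7_914_736, 15_021),
    ],
    columns=["quintile", "elective_total", "elective_rate", "emergency_total", "emergency_rate"],
)

# All-episode totals and rates printed alongside the stratum columns.
ALL_EPISODE_ACTIVITY = pd.DataFrame(
    [
        ("Q1", 4_536_495, 43_385),
        ("Q2", 4_062_130, 38_526),
        ("Q3", 3_856_220, 36_408),
        ("Q4", 3_626_126, 34_472),
        ("Q5", 3_311_200, 31_298),
        ("Overall", 19_392_171, 36_804),
    ],
    columns=["quintile", "all_total", "all_rate"],
)

# Estimated cost of social inequality: observed minus counterfactual cost in
# GBP per quintile and sex, against the least-deprived quintile's age/sex
# cost profile. Q5 is the comparator (gap zero by construction).
INEQUALITY_GAPS = pd.DataFrame(
    [
        ("Q1", "female", 1_127_006_663),
        ("Q1", "male", 1_065_236_932),
        ("Q2", "female", 706_629_004),
        ("Q2", "male", 671_287_893),
        ("Q3", "female", 410_841_645),
        ("Q3", "male", 405_654_922),
        ("Q4", "female", 198_794_943),
        ("Q4", "male", 190_121_699),
        ("Q5", "female", 0),
        ("Q5", "male", 0),
    ],
    columns=["quintile", "sex", "gap"],
)

# Observed cost in the comparator (least deprived) quintile, GBP.
COMPARATOR_OBSERVED = {"female": 2_608_800_295, "male": 2_208_982_887, "total": 4_817_783_181}

# Episode file before the missing-data exclusion: total records and records
# lacking age, sex or area of residence.
EPISODES_BEFORE_EXCLUSION = 18_808_903
EPISODES_UNGROUPABLE = 1_659_295

# Average annual inpatient cost per resident, GBP, most vs least deprived
# quintile.
AVG_ANNUAL_COST_PER_RESIDENT = {"Q1": 597, "Q5": 455}
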