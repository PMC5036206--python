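"""Survival-weighted expected annual costs and cumulative lifetime costs.

For each deprivation quintile g and sex s the expected annual cost at age a
weights the average annual cost per head by the probability of being alive
to incur it:

    E(g,a,s) = S(g,a,s) * cbar(g,a,s)

and the cumulative expected cost is the running sum C(g,a,s) =
sum_{a' <= a} E(g,a',s); the expected lifetime cost L(g,s) is the value of C
at the terminal age. Average costs beyond age 84 are frozen at the 85+ cell
(the underlying data are truncated there); survival and costs are held at
their observed-year levels with no discounting. By default the survival
weight is the start-of-year survivorship S(a); a mid-year weight
(S(a) + S(a+1)) / 2 is available as an option, treating survivorship beyond
the terminal age as zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort_aggregation import GroupCostSummary
from .config import LifeTableOptions
from .io import AGE_OPEN


class LifetimeCostError(ValueError):
    """Raised on age-grid mismatches."""


def extend_cost_profile(cbar: np.ndarray, max_age: int) -> np.ndarray:
    """Extend a cost-per-head profile on ages 0..85 to 0..max_age.

    Ages above the open 85+ group keep the 85+ value.
    """
    cbar = np.asarray(cbar, dtype=float)
    if len(cbar) != AGE_OPEN + 1:
        raise LifetimeCostError(
            f"cost profile must cover ages 0..{AGE_OPEN} ({AGE_OPEN + 1} values); got {len(cbar)}"
        )
    out = np.empty(max_age + 1)
    out[: AGE_OPEN + 1] = cbar
    out[AGE_OPEN + 1 :] = cbar[AGE_OPEN]
    return out


def expected_annual(
    survival: np.ndarray, cbar: np.ndarray, weighting: str = "start"
) -> np.ndarray:
    """E(a) = survival weight at age a times cbar(a), element-wise."""
    s = np.asarray(survival, dtype=float)
    c = np.asarray(cbar, dtype=float)
    if s.shape != c.shape:
        raise LifetimeCostError(
            f"survival and cost profiles are on different age grids: {s.shape} vs {c.shape}"
        )
    if weighting == "start":
        w = s
    elif weighting == "midyear":
        w = (s + np.append(s[1:], 0.0)) / 2.0
    else:
        raise LifetimeCostError(f"unknown survival weighting {weighting!r}")
    return w * c


def cumulative_lifetime(expected: np.ndarray) -> tuple[np.ndarray, float]:
    """Running sum C(a) of expected annual costs and the lifetime total L."""
    e = np.asarray(expected, dtype=float)
    if (e < 0).any():
        raise LifetimeCostError("expected annual costs must be nonnegative")
    c = np.cumsum(e)
    return c, float(c[-1]) if len(c) else 0.0


def lifetime_summary(
    survival: pd.DataFrame,
    summary: GroupCostSummary,
    options: LifeTableOptions | None = None,
    stratum: str = "all",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expected/cumulative cost profiles and lifetime costs per quintile x sex.

    Returns ``(profile, lifetime)``: profile has one row per quintile x sex
    x age with ``avg_cost``, ``survival``, ``expected_cost`` and
    ``cumulative_cost`` columns; lifetime has one row per quintile x sex
    with ``lifetime_cost``. Ages with no resident population contribute zero
    cost.
    """
    opts = options or LifeTableOptions()
    prof_frames = []
    life_rows = []
    for (quintile, sex), grp in survival.groupby(["quintile", "sex"], observed=True):
        grp = grp.sort_values("age")
        s = grp["survival"].to_numpy()
        if len(s) != opts.max_age + 1:
            raise LifetimeCostError(
                f"survival curve for {quintile}/{sex} has {len(s)} ages; expected {opts.max_age + 1}"
            )
        cprof = summary.avg_cost_profile(quintile, stratum)
        cbar85 = (
            cprof[cprof["sex"] == sex]
            .sort_values("age")["avg_cost_per_head"]
            .to_numpy()
        )
        cbar = extend_cost_profile(np.nan_to_num(cbar85, nan=0.0), opts.max_age)
        e = expected_annual(s, cbar, opts.survival_weighting)
        c, total = cumulative_lifetime(e)
        prof_frames.append(
            pd.DataFrame(
                {
                    "quintile": quintile,
                    "sex": sex,
                    "age": np.arange(opts.max_age + 1),
                    "avg_cost": cbar,
                    "survival": s,
                    "expected_cost": e,
                    "cumulative_cost": c,
                }
            )
        )
        life_rows.append({"quintile": quintile, "sex": sex, "lifetime_cost": total})
    return pd.concat(prof_frames, ignore_index=True), pd.DataFrame(life_rows)
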