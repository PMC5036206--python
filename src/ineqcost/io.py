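"""Reading and writing the pipeline's delimited-text files.

All inputs and outputs are headered CSV. Conventions shared across the
package:

* **Age** is recorded in single years 0-84 plus the open group ``"85+"``.
  In memory the open group is coded as the integer 85 (nullable ``Int64``;
  missing ages are ``<NA>``); on disk it is written as the string ``85+``.
* **Sex** is ``female`` / ``male``; **admission type** is ``elective`` /
  ``emergency``.
* **Deprivation quintiles** run ``Q1`` (most deprived) to ``Q5`` (least
  deprived).
* **Mortality bands** are the 5-year bands ``0-4`` ... ``80-84`` plus
  ``85+``, identified by their lower bound (85 for the open band).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

AGE_OPEN = 85
SEXES = ("female", "male")
QUINTILES = ("Q1", "Q2", "Q3", "Q4", "Q5")
ADMISSION_TYPES = ("elective", "emergency")
BAND_STARTS = tuple(range(0, 85, 5)) + (AGE_OPEN,)

EPISODE_COLUMNS = [
    "episode_id", "age", "sex", "area_id", "admission_type",
    "hrg_code", "length_of_stay", "year",
]


def band_label(start: int) -> str:
    return "85+" if start == AGE_OPEN else f"{start}-{start + 4}"


def band_of_age(age: int) -> int:
    """Lower bound of the 5-year band containing ``age`` (85 for 85+)."""
    return AGE_OPEN if age >= AGE_OPEN else (age // 5) * 5


def _format_age(age) -> str:
    if pd.isna(age):
        return ""
    age = int(age)
    return "85+" if age >= AGE_OPEN else str(age)


def _parse_age(value):
    if pd.isna(value) or value == "":
        return pd.NA
    if isinstance(value, str) and value.strip() == "85+":
        return AGE_OPEN
    return int(value)


def write_areas(df: pd.DataFrame, path: str | Path) -> None:
    df[["area_id", "imd_rank"]].to_csv(path, index=False)


def read_areas(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"area_id": str, "imd_rank": np.int64})


def write_population(df: pd.DataFrame, path: str | Path) -> None:
    out = df[["area_id", "sex", "age", "population"]].copy()
    out["age"] = out["age"].map(_format_age)
    out.to_csv(path, index=False)


def read_population(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"area_id": str, "sex": str, "age": str, "population": np.int64})
    df["age"] = df["age"].map(_parse_age).astype("Int64")
    return df


def write_episodes(df: pd.DataFrame, path: str | Path) -> None:
    out = df[EPISODE_COLUMNS].copy()
    out["age"] = out["age"].map(_format_age)
    for col in ("sex", "area_id"):
        out[col] = out[col].fillna("")
    out.to_csv(path, index=False)


def read_episodes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "episode_id": np.int64, "age": str, "sex": str, "area_id": str,
            "admission_type": str, "hrg_code": str, "length_of_stay": np.int64,
            "year": str,
        },
        keep_default_na=False,
    )
    df["age"] = df["age"].map(_parse_age).astype("Int64")
    for col in ("sex", "area_id"):
        df[col] = df[col].replace("", pd.NA)
    return df


def write_tariffs(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.2f")


def read_tariffs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"hrg_code": str})


def write_deaths(df: pd.DataFrame, path: str | Path) -> None:
    out = df[["area_id", "sex", "band_start", "deaths"]].copy()
    out.insert(3, "band", out["band_start"].map(band_label))
    out.to_csv(path, index=False)


def read_deaths(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"area_id": str, "sex": str, "band_start": np.int64, "deaths": np.int64}
    )
    return df[["area_id", "sex", "band_start", "deaths"]]
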