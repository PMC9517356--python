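"""Reading, validating, filtering and writing MBDS-like episode tables.

The episode table emulates the layout of a minimum basic data set (MBDS)
hospital-discharge registry: one main diagnosis plus up to 19 secondary
ICD-10 diagnoses per hospitalization, alongside age, sex, in-hospital death
and length of stay.

Two CSV layouts are supported:

* ``wide`` — one row per episode with columns ``episode_id, age, sex, death,
  length_of_stay, obstetric_flag, year, dx_main, dx_sec_01..dx_sec_19``;
* ``long`` — an episode header CSV (same columns minus the dx ones) plus a
  diagnoses CSV with columns ``episode_id, position, code``.

Rows missing any of age, sex or death are rejected (never imputed) and
reported; empty diagnosis cells are skipped.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import EmptyCohortError, MalformedCodeError, ValidationError
from .mapping import normalize_code

logger = logging.getLogger(__name__)

MAX_DIAGNOSES = 20  # 1 main + 19 secondary, the MBDS slot layout

WIDE_DX_COLS = ["dx_main"] + [f"dx_sec_{i:02d}" for i in range(1, 20)]
WIDE_HEADER_COLS = [
    "episode_id", "age", "sex", "death", "length_of_stay",
    "obstetric_flag", "year",
]

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}


@dataclass(frozen=True)
class EpisodeRecord:
    """One hospitalization episode."""

    episode_id: str
    age: int
    sex: str  # "male" | "female"
    death: bool
    length_of_stay: int
    diagnoses: tuple[str, ...]  # first entry = main diagnosis
    obstetric_flag: bool = False
    year: int | None = None
    mdc_label: str | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError(f"{self.episode_id}: negative age")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"{self.episode_id}: sex must be male/female")
        if self.length_of_stay < 0:
            raise ValidationError(f"{self.episode_id}: negative length of stay")
        if not self.diagnoses:
            raise ValidationError(f"{self.episode_id}: no diagnoses")
        if len(self.diagnoses) > MAX_DIAGNOSES:
            warnings.warn(
                f"{self.episode_id}: {len(self.diagnoses)} diagnoses exceed the "
                f"{MAX_DIAGNOSES}-slot MBDS layout; keeping the first {MAX_DIAGNOSES}",
                stacklevel=2,
            )
            object.__setattr__(self, "diagnoses", self.diagnoses[:MAX_DIAGNOSES])
        for code in self.diagnoses:
            normalize_code(code)  # raises MalformedCodeError


def median_low(values: Iterable[float]) -> float:
    """Sample median; for even n the lower of the two middle order statistics."""
    v = np.sort(np.asarray(list(values)))
    if v.size == 0:
        raise EmptyCohortError("median of empty sample")
    return float(v[(v.size - 1) // 2])


@dataclass
class Cohort:
    """A list of episodes plus headline summary statistics."""

    episodes: list[EpisodeRecord]
    rejections: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.episode_id for e in self.episodes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate episode_id in cohort")

    def __len__(self) -> int:
        return len(self.episodes)

    @property
    def median_age(self) -> float:
        return median_low(e.age for e in self.episodes)

    @property
    def mortality_rate(self) -> float:
        if not self.episodes:
            raise EmptyCohortError("empty cohort")
        return sum(e.death for e in self.episodes) / len(self.episodes)

    def to_frame(self) -> pd.DataFrame:
        """Header fields as a DataFrame (diagnoses as a list column)."""
        return pd.DataFrame(
            {
                "episode_id": [e.episode_id for e in self.episodes],
                "age": [e.age for e in self.episodes],
                "sex": [e.sex for e in self.episodes],
                "death": [e.death for e in self.episodes],
                "length_of_stay": [e.length_of_stay for e in self.episodes],
                "obstetric_flag": [e.obstetric_flag for e in self.episodes],
                "year": [e.year for e in self.episodes],
                "diagnoses": [list(e.diagnoses) for e in self.episodes],
            }
        )


def _parse_bool(value, what: str):
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE and s != "":
        return False
    raise ValidationError(f"cannot parse {what} value {value!r}")


def _parse_sex(value) -> str:
    s = str(value).strip().lower()
    if s in ("male", "m", "1"):
        return "male"
    if s in ("female", "f", "2", "0"):
        return "female"
    raise ValidationError(f"cannot parse sex value {value!r}")


def _row_episode(row: pd.Series, diagnoses: list[str]) -> EpisodeRecord:
    for fld in ("age", "sex", "death"):
        if fld not in row or pd.isna(row[fld]) or str(row[fld]).strip() == "":
            raise ValidationError(f"missing {fld}")
    los = row.get("length_of_stay")
    year = row.get("year")
    obst = row.get("obstetric_flag")
    return EpisodeRecord(
        episode_id=str(row["episode_id"]),
        age=int(float(row["age"])),
        sex=_parse_sex(row["sex"]),
        death=_parse_bool(row["death"], "death"),
        length_of_stay=0 if pd.isna(los) else int(float(los)),
        diagnoses=tuple(diagnoses),
        obstetric_flag=False if obst is None or pd.isna(obst) else _parse_bool(obst, "obstetric_flag"),
        year=None if year is None or pd.isna(year) else int(float(year)),
    )


def read_episodes(path: str | Path, layout: str = "wide") -> Cohort:
    """Read an episode table; invalid rows are rejected with a per-row report.

    ``layout="long"`` expects ``path`` to be the episode header CSV and a
    sibling diagnoses CSV named by replacing ``episodes`` with ``diagnoses``
    (or ``<stem>_diagnoses.csv``).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if layout == "wide":
        df = pd.read_csv(path, dtype=str)
        dx_lists = {}
        for _, row in df.iterrows():
            codes = [
                str(row[c]).strip()
                for c in WIDE_DX_COLS
                if c in df.columns and not pd.isna(row[c]) and str(row[c]).strip() != ""
            ]
            dx_lists[row["episode_id"]] = codes
        headers = df
    elif layout == "long":
        headers = pd.read_csv(path, dtype=str)
        if "episodes" in path.name:
            dx_path = path.with_name(path.name.replace("episodes", "diagnoses"))
        else:
            dx_path = path.with_name(path.stem + "_diagnoses.csv")
        if not dx_path.exists():
            raise IOError(f"no diagnoses file alongside {path} (expected {dx_path})")
        dx = pd.read_csv(dx_path, dtype=str)
        dx["position"] = dx["position"].astype(int)
        dx = dx.sort_values(["episode_id", "position"])
        dx_lists = {
            eid: [c for c in grp["code"].tolist() if str(c).strip() != ""]
            for eid, grp in dx.groupby("episode_id", sort=False)
        }
    else:
        raise ValidationError(f"unknown layout {layout!r}")

    episodes: list[EpisodeRecord] = []
    rejections: list[dict] = []
    for i, (_, row) in enumerate(headers.iterrows()):
        eid = str(row.get("episode_id", f"row{i}"))
        try:
            ep = _row_episode(row, dx_lists.get(row["episode_id"], []))
            episodes.append(ep)
        except (ValidationError, MalformedCodeError) as exc:
            rejections.append({"episode_id": eid, "row": i, "reason": str(exc)})
    if not episodes:
        raise EmptyCohortError(f"{path}: no valid rows")
    if rejections:
        logger.info("rejected %d of %d rows", len(rejections), len(headers))
    return Cohort(episodes=episodes, rejections=rejections)


def filter_cohort(cohort: Cohort, min_age: int = 19) -> Cohort:
    """Keep adult, non-obstetric episodes (age >= min_age, obstetric_flag false).

    The default ``min_age=19`` encodes a cohort of patients over 18 years of
    age; pass 18 for an inclusive-18 reading. Idempotent.
    """
    if not cohort.episodes:
        raise EmptyCohortError("empty cohort")
    kept = [e for e in cohort.episodes if e.age >= min_age and not e.obstetric_flag]
    if not kept:
        raise EmptyCohortError("all episodes excluded by the adult/non-obstetric filter")
    return Cohort(episodes=kept, rejections=list(cohort.rejections))


def infer_obstetric_flag(cohort: Cohort) -> Cohort:
    """Convenience: set obstetric_flag where any diagnosis is in ICD-10 chapter O.

    The canonical exclusion is by admission type; this helper approximates it
    from the codes when no admission-type field is available.
    """
    episodes = []
    for e in cohort.episodes:
        if any(normalize_code(c).startswith("O") for c in e.diagnoses):
            episodes.append(replace(e, obstetric_flag=True))
        else:
            episodes.append(e)
    return Cohort(episodes=episodes, rejections=list(cohort.rejections))


def write_episodes(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the wide CSV layout."""
    rows = []
    for e in cohort.episodes:
        row = {
            "episode_id": e.episode_id,
            "age": e.age,
            "sex": e.sex,
            "death": int(e.death),
            "length_of_stay": e.length_of_stay,
            "obstetric_flag": int(e.obstetric_flag),
            "year": "" if e.year is None else e.year,
        }
        for col, code in zip(WIDE_DX_COLS, e.diagnoses):
            row[col] = code
        rows.append(row)
    pd.DataFrame(rows, columns=WIDE_HEADER_COLS + WIDE_DX_COLS).to_csv(path, index=False)


def write_table(result: pd.DataFrame, path: str | Path) -> None:
    """Write a pipeline result table as CSV with >= 6 significant digits.

    Floats survive a read round trip to 1e-9; integers bitwise.
    """
    if not isinstance(result, pd.DataFrame):
        raise ValidationError("write_table expects a DataFrame")
    result.to_csv(path, index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
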