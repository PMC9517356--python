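"""Comorbidity index scores and quartile strata.

Three indices per episode, all integer-valued:

* ``cci`` — Charlson comorbidity index, the weighted sum of the 17 Charlson
  category flags (weights 1/2/3/6);
* ``eci`` — Elixhauser comorbidity index, the unweighted count of Elixhauser
  category flags (each comorbidity contributes 1);
* ``wci`` — van Walraven comorbidity index, the sum of van Walraven's
  mortality-derived weights over the Elixhauser flags (weights range -7..12,
  so the score can be negative).

Each index is then cut into four quartile strata of its score distribution;
because the scores are small integers with heavy ties, tied scores always
share one stratum and the strata are deliberately unequal in size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateStrataError, EmptyCohortError, ValidationError
from .mapping import ComorbidityMap, ComorbidityProfile

INDEX_NAMES = ("cci", "eci", "wci")


@dataclass(frozen=True)
class ScoreSet:
    """The three comorbidity scores for one episode."""

    episode_id: str
    cci: int
    eci: int
    wci: int


def quantile(values, q: float, convention: str = "stata") -> float:
    """Empirical quantile under a fixed, documented convention.

    ``"stata"`` is the summarize/detail convention of classical statistical
    software: with n·q non-integer the ceil-th order statistic, with n·q
    integer the average of the two adjacent order statistics. ``"linear"``
    is linear interpolation of order statistics (numpy default).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise EmptyCohortError("quantile of empty sample")
    if convention == "linear":
        return float(np.quantile(v, q))
    if convention != "stata":
        raise ValidationError(f"unknown quantile convention {convention!r}")
    h = n * q
    if abs(h - round(h)) < 1e-12:
        i = int(round(h))
        if i <= 0:
            return float(v[0])
        if i >= n:
            return float(v[-1])
        return float((v[i - 1] + v[i]) / 2.0)
    i = math.ceil(h)
    return float(v[min(max(i, 1), n) - 1])


def compute_scores(
    charlson_profile: ComorbidityProfile,
    elixhauser_profile: ComorbidityProfile,
    charlson_map: ComorbidityMap,
    elixhauser_map: ComorbidityMap,
) -> ScoreSet:
    """CCI/ECI/WCI from one episode's post-hierarchy profiles."""
    if charlson_profile.episode_id != elixhauser_profile.episode_id:
        raise ValidationError(
            f"episode_id mismatch: {charlson_profile.episode_id!r} vs "
            f"{elixhauser_profile.episode_id!r}"
        )
    if charlson_profile.scheme != "charlson" or elixhauser_profile.scheme != "elixhauser":
        raise ValidationError("profile schemes do not match maps")
    cf = np.asarray(charlson_profile.flags, dtype=bool)
    ef = np.asarray(elixhauser_profile.flags, dtype=bool)
    cci = int(charlson_map.weights("charlson")[cf].sum())
    eci = int(ef.sum())
    wci = int(elixhauser_map.weights("vw")[ef].sum())
    return ScoreSet(episode_id=charlson_profile.episode_id, cci=cci, eci=eci, wci=wci)


def scores_from_frames(
    charlson_flags: pd.DataFrame,
    elixhauser_flags: pd.DataFrame,
    charlson_map: ComorbidityMap,
    elixhauser_map: ComorbidityMap,
) -> pd.DataFrame:
    """Vectorized scoring over aligned boolean flag frames.

    Returns a DataFrame indexed by episode_id with columns cci, eci, wci.
    """
    if not charlson_flags.index.equals(elixhauser_flags.index):
        raise ValidationError("flag frames are not aligned on episode_id")
    cm = charlson_flags.to_numpy(dtype=bool)
    em = elixhauser_flags.to_numpy(dtype=bool)
    return pd.DataFrame(
        {
            "cci": cm @ charlson_map.weights("charlson"),
            "eci": em.sum(axis=1).astype(int),
            "wci": em @ elixhauser_map.weights("vw"),
        },
        index=charlson_flags.index,
    )


@dataclass
class StrataAssignment:
    """Quartile strata for one index: cutpoints, per-episode stratum, table."""

    index_name: str
    cutpoints: tuple[float, float, float]
    strata: np.ndarray  # int in 1..4 per episode
    interval_table: pd.DataFrame  # stratum, score_min, score_max, n, percent


def assign_strata(
    scores,
    index_name: str = "score",
    cutpoints: tuple[float, float, float] | None = None,
    convention: str = "stata",
) -> StrataAssignment:
    """Cut scores into 4 strata at the quartiles of their distribution.

    The scores are small integers with heavy ties, so equal scores must
    share one stratum and exact quarters are impossible. When ``cutpoints``
    is omitted, each *distinct* score is assigned the quartile containing
    the midpoint of its rank range (the rank-midpoint rule): a score whose
    observations span cumulative fractions (F_lo, F_hi) goes to stratum
    ``1 + #{q in {.25,.5,.75} : (F_lo+F_hi)/2 >= q}``. Any stratum left
    empty by a dominant tie group is closed up by renumbering. The reported
    ``cutpoints`` are the empirical 25/50/75th percentiles for reference.

    Explicit cutpoints (e.g. transcribed from a published strata table) are
    applied verbatim under a left-closed threshold rule:
    ``stratum = 1 + #{c : score >= c}``.
    """
    s = np.asarray(scores)
    if s.size == 0:
        raise EmptyCohortError("no scores")
    if cutpoints is None:
        if s.size < 4:
            raise ValidationError("need n >= 4 for empirical quartiles")
        uniq, counts = np.unique(s, return_counts=True)
        if uniq.size < 2:
            raise DegenerateStrataError(f"{index_name}: all scores identical")
        cum = np.cumsum(counts)
        f_hi = cum / s.size
        f_lo = (cum - counts) / s.size
        mid = (f_lo + f_hi) / 2.0
        level = 1 + (mid >= 0.25).astype(int) + (mid >= 0.50).astype(int) + (
            mid >= 0.75
        ).astype(int)
        # close up empty strata so the categorical coding stays full rank
        occupied = np.unique(level)
        relabel = {lv: k + 1 for k, lv in enumerate(occupied)}
        level = np.array([relabel[lv] for lv in level])
        strata = level[np.searchsorted(uniq, s)]
        cutpoints = tuple(quantile(s, q, convention) for q in (0.25, 0.50, 0.75))
        c1, c2, c3 = cutpoints
    else:
        c1, c2, c3 = cutpoints
        if not (c1 <= c2 <= c3):
            raise ValidationError("cutpoints must be non-decreasing")
        strata = 1 + (s >= c1).astype(int) + (s >= c2).astype(int) + (s >= c3).astype(int)
    if np.unique(strata).size < 2:
        raise DegenerateStrataError(
            f"{index_name}: quartile cutpoints give a single stratum"
        )
    rows = []
    n = s.size
    for k in (1, 2, 3, 4):
        sel = strata == k
        rows.append(
            {
                "stratum": k,
                "score_min": float(s[sel].min()) if sel.any() else np.nan,
                "score_max": float(s[sel].max()) if sel.any() else np.nan,
                "n": int(sel.sum()),
                "percent": 100.0 * sel.sum() / n,
            }
        )
    table = pd.DataFrame(rows)
    return StrataAssignment(
        index_name=index_name,
        cutpoints=(float(c1), float(c2), float(c3)),
        strata=strata,
        interval_table=table,
    )


def _med_iqr(values, convention: str) -> tuple[float, float, float]:
    return (
        quantile(values, 0.50, convention),
        quantile(values, 0.25, convention),
        quantile(values, 0.75, convention),
    )


def summarize_cohort(cohort, scores: pd.DataFrame, convention: str = "stata") -> pd.DataFrame:
    """Descriptive summary: n, median (IQR) of age/LOS/scores, deaths.

    ``scores`` is the frame from :func:`scores_from_frames`, aligned with the
    cohort.
    """
    if not cohort.episodes:
        raise EmptyCohortError("empty cohort")
    if len(scores) != len(cohort.episodes):
        raise ValidationError("scores not aligned with cohort")
    ages = [e.age for e in cohort.episodes]
    los = [e.length_of_stay for e in cohort.episodes]
    deaths = sum(e.death for e in cohort.episodes)
    n = len(cohort.episodes)
    males = sum(e.sex == "male" for e in cohort.episodes)
    rows = [("n", n, "", "")]
    for name, vals in (
        ("age", ages),
        ("length_of_stay", los),
        ("cci", scores["cci"]),
        ("eci", scores["eci"]),
        ("wci", scores["wci"]),
    ):
        med, lo, hi = _med_iqr(vals, convention)
        rows.append((f"{name}_median", med, lo, hi))
    rows.append(("male_percent", 100.0 * males / n, "", ""))
    rows.append(("death_count", deaths, "", ""))
    rows.append(("death_percent", 100.0 * deaths / n, "", ""))
    return pd.DataFrame(rows, columns=["variable", "value", "iqr_low", "iqr_high"])
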