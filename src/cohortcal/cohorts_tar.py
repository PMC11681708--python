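"""New-user design restrictions and time-at-risk (TAR) construction.

TAR intervals are inclusive integer-day intervals starting the day after
index.  The on-treatment TAR extends through an era of inferred persistent
exposure — successive administrations no more than `persistence_window`
days apart — plus a surveillance tail after the last administration of the
era, right-censored at observation end and at the first censoring-drug
exposure.  The intention-to-treat TAR runs to observation end and is never
right-censored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class TimeAtRisk:
    """One person's at-risk interval [tar_start_day, tar_end_day], inclusive.

    An empty interval (end = start - 1) is legal and yields 0 days at risk.
    """

    person_id: int
    tar_start_day: int
    tar_end_day: int

    @property
    def days_at_risk(self) -> int:
        return max(0, self.tar_end_day - self.tar_start_day + 1)


def build_on_treatment_tar(index_day: int, obs_end_day: int,
                           administrations: Sequence[int],
                           censor_days: Iterable[int] = (),
                           persistence_window: int = 90,
                           surveillance: int = 90,
                           person_id: int = -1) -> TimeAtRisk:
    """On-treatment TAR for a single person.

    The exposure era is the maximal run of administrations starting at
    index with successive gaps <= persistence_window; the TAR ends at the
    era's last administration plus `surveillance` days, capped at
    observation end and at the first censoring-drug exposure day.
    """
    admins = np.asarray(sorted(administrations))
    if admins.size == 0:
        raise ValueError("not a new user: administrations are empty")
    if admins[0] != index_day:
        raise ValueError("first administration must fall on the index day")
    gaps = np.diff(admins)
    breaks = np.nonzero(gaps > persistence_window)[0]
    last_era_day = int(admins[breaks[0]] if breaks.size else admins[-1])
    tar_end = min(last_era_day + surveillance, obs_end_day)
    censor_days = list(censor_days)
    if censor_days:
        tar_end = min(tar_end, min(censor_days))
    return TimeAtRisk(person_id=person_id, tar_start_day=index_day + 1,
                      tar_end_day=tar_end)


def build_itt_tar(index_day: int, obs_end_day: int,
                  person_id: int = -1) -> TimeAtRisk:
    """Intention-to-treat TAR: day after index to observation end."""
    return TimeAtRisk(person_id=person_id, tar_start_day=index_day + 1,
                      tar_end_day=obs_end_day)


def build_tar_table(persons: pd.DataFrame, administrations: pd.DataFrame,
                    censor_exposures: pd.DataFrame, kind: str = "on_treatment",
                    persistence_window: int = 90, surveillance: int = 90,
                    ) -> pd.DataFrame:
    """Vectorized TAR construction for a whole PersonTable.

    Returns columns person_id, tar_start_day, tar_end_day, days_at_risk.
    Persons without administrations are not new users and are excluded
    from the on-treatment table.
    """
    if kind not in ("on_treatment", "itt"):
        raise ValueError(f"unknown TAR kind {kind!r}")
    pid = persons["person_id"].to_numpy()
    start = persons["index_day"].to_numpy() + 1
    if kind == "itt":
        end = persons["obs_end_day"].to_numpy()
        tar = pd.DataFrame({"person_id": pid, "tar_start_day": start,
                            "tar_end_day": end})
    else:
        a = administrations.sort_values(["person_id", "day"])
        ap = a["person_id"].to_numpy()
        ad = a["day"].to_numpy()
        new_person = np.r_[True, ap[1:] != ap[:-1]] if len(ad) else np.array([], bool)
        gap = np.r_[0, np.diff(ad)] if len(ad) else np.array([], np.int64)
        gap[new_person] = 0
        # the era runs until the first gap > window, restarting per person
        broken = (pd.Series(gap > persistence_window)
                  .groupby(ap).cummax().to_numpy()
                  if len(ad) else np.array([], bool))
        in_era = ~broken
        era = pd.DataFrame({"person_id": ap[in_era], "day": ad[in_era]})
        last_era = era.groupby("person_id", sort=False)["day"].max()
        tar = persons[["person_id", "index_day", "obs_end_day"]].merge(
            last_era.rename("last_era_day"), left_on="person_id",
            right_index=True, how="inner")
        end = np.minimum(tar["last_era_day"].to_numpy() + surveillance,
                         tar["obs_end_day"].to_numpy())
        if len(censor_exposures):
            first_censor = censor_exposures.groupby("person_id")["day"].min()
            cmap = tar["person_id"].map(first_censor)
            end = np.where(cmap.notna(), np.minimum(end, cmap.fillna(np.inf)), end)
        tar = pd.DataFrame({"person_id": tar["person_id"].to_numpy(),
                            "tar_start_day": tar["index_day"].to_numpy() + 1,
                            "tar_end_day": end.astype(np.int64)})
    tar["days_at_risk"] = np.maximum(
        0, tar["tar_end_day"] - tar["tar_start_day"] + 1)
    return tar.reset_index(drop=True)


def apply_design_restrictions(persons: pd.DataFrame, outcomes: pd.DataFrame,
                              tar: pd.DataFrame,
                              outcome_id: int = 0,
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequential design restrictions with an attrition table.

    1. restrict to calendar time when both arms were observed (index-day
       range intersection of the two arms);
    2. exclude persons with a pre-index event of the outcome of interest
       (event_day <= index_day);
    3. exclude persons with zero days at risk.

    Returns (retained persons, attrition table with per-step counts).
    """
    steps = []

    def _record(step: str, df: pd.DataFrame) -> None:
        steps.append({"step": step,
                      "n_target": int((df["arm"] == "target").sum()),
                      "n_comparator": int((df["arm"] == "comparator").sum())})

    kept = persons.copy()
    _record("initial", kept)
    if len(kept):
        ranges = kept.groupby("arm")["index_day"].agg(["min", "max"])
        if {"target", "comparator"} <= set(ranges.index):
            lo = ranges["min"].max()
            hi = ranges["max"].min()
            kept = kept[(kept["index_day"] >= lo) & (kept["index_day"] <= hi)]
    _record("calendar_overlap", kept)

    ev = outcomes[outcomes["outcome_id"] == outcome_id]
    prior = kept.merge(ev, on="person_id", how="left")
    has_prior = prior["event_day"].notna() & (
        prior["event_day"] <= prior["index_day"])
    kept = kept[~kept["person_id"].isin(prior.loc[has_prior, "person_id"])]
    _record("no_prior_outcome", kept)

    dar = kept["person_id"].map(tar.set_index("person_id")["days_at_risk"])
    kept = kept[dar.fillna(0).to_numpy() > 0]
    _record("nonzero_time_at_risk", kept)

    attrition = pd.DataFrame(steps)
    return kept.reset_index(drop=True), attrition


def person_years(tar: pd.DataFrame) -> float:
    """Total person-years represented by a TAR table."""
    return float(tar["days_at_risk"].sum() / DAYS_PER_YEAR)
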