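"""Epoch-level ENMO classification and daily/subject composition building.

Upstream raw-signal processing (autocalibration, ENMO computation, non-wear
detection, sleep-window detection) is assumed done: the input is a 5-second
epoch table with ENMO in milli-g plus wear and sleep flags.  This module
applies intensity cutpoints to waking epochs, aggregates midnight-to-midnight
days into 4-part behaviour-minute compositions, applies the wear-time
validity rules (>=16 h/day; >=3 school days and >=1 weekend day per subject;
wear present in every 15-minute period of the 24-h cycle), and averages a
subject's valid days into one composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import DAY_MINUTES, Composition, close

__all__ = [
    "CutpointSet",
    "ValidityCriteria",
    "classify_epochs",
    "aggregate_daily",
    "filter_valid_days",
    "subject_composition",
]

BEHAVIOURS = ("mvpa", "lpa", "sb", "sleep")
MINUTE_COLS = ("mvpa_min", "lpa_min", "sb_min", "sleep_min")


@dataclass(frozen=True)
class CutpointSet:
    """ENMO intensity cutpoints in milli-g.

    Intervals are half-open so every value is classified: SB [0, 36),
    LPA [36, 201), MVPA [201, inf).  The published thresholds print LPA as
    36-200 and MVPA as >= 201; the half-open convention preserves both
    printed boundary behaviours while covering the (200, 201) gap that a
    continuous ENMO value could fall into.
    """

    sb_upper_mg: float = 36.0
    mvpa_lower_mg: float = 201.0

    def __post_init__(self) -> None:
        if not (0 < self.sb_upper_mg < self.mvpa_lower_mg):
            raise ValueError("need 0 < sb_upper_mg < mvpa_lower_mg")


@dataclass(frozen=True)
class ValidityCriteria:
    min_wear_hours: float = 16.0
    min_school_days: int = 3
    min_weekend_days: int = 1
    coverage_bin_minutes: int = 15
    coverage_scope: str = "week"  # "week": bins pooled over days; "day": each day

    def __post_init__(self) -> None:
        if min(self.min_wear_hours, self.min_school_days,
               self.min_weekend_days, self.coverage_bin_minutes) <= 0:
            raise ValueError("all criteria must be positive")


def classify_epochs(epochs: pd.DataFrame, cuts: CutpointSet | None = None) -> pd.DataFrame:
    """Label each epoch sleep/SB/LPA/MVPA.

    The sleep flag dominates ENMO: an epoch inside the sleep window is sleep
    regardless of movement.
    """
    cuts = cuts or CutpointSet()
    enmo = epochs["enmo_mg"].to_numpy(dtype=float)
    if np.any(enmo < 0):
        raise ValueError("negative enmo_mg values present")
    out = epochs.copy()
    behaviour = np.where(
        enmo < cuts.sb_upper_mg, "sb",
        np.where(enmo < cuts.mvpa_lower_mg, "lpa", "mvpa"),
    )
    asleep = epochs["asleep"].to_numpy(dtype=bool)
    behaviour = np.where(asleep, "sleep", behaviour)
    out["behaviour"] = behaviour
    return out


def aggregate_daily(
    labelled: pd.DataFrame,
    min_wear_hours_for_closure: float = 16.0,
    coverage_bin_minutes: int = 15,
) -> pd.DataFrame:
    """Aggregate labelled epochs into per-day behaviour minutes.

    Each calendar day runs midnight to midnight.  Minutes are epoch counts
    x epoch length; non-worn waking epochs contribute nothing.  Days with at
    least ``min_wear_hours_for_closure`` hours of wear are proportionally
    re-closed to 1440 minutes; shorter days keep their raw minutes (they are
    dropped later by the validity filter).  A per-day boolean wear-coverage
    vector over 15-minute bins is attached for the coverage rule.
    """
    if labelled.empty:
        return pd.DataFrame(columns=["subject_id", "date", "day_type",
                                     *MINUTE_COLS, "wear_hours", "wear_bins"])
    df = labelled.reset_index(drop=True).copy()
    ts = pd.to_datetime(df["timestamp"])
    df["date"] = ts.dt.date
    minute_of_day = ts.dt.hour * 60 + ts.dt.minute
    df["bin"] = (minute_of_day // coverage_bin_minutes).to_numpy()
    epoch_min = _epoch_minutes(ts, df)
    df["worn"] = df["wear"].astype(bool) | df["asleep"].astype(bool)
    n_bins = int(np.ceil(1440 / coverage_bin_minutes))

    rows = []
    for (sid, date), day in df.groupby(["subject_id", "date"], sort=True):
        obs = day[day["worn"]]
        if obs.empty:
            continue  # zero observed epochs: skip the day entirely
        counts = obs["behaviour"].value_counts()
        minutes = np.array([counts.get(b, 0) for b in BEHAVIOURS], float) * epoch_min
        wear_hours = float(day["wear"].astype(bool).sum()) * epoch_min / 60.0
        total = minutes.sum()
        if wear_hours >= min_wear_hours_for_closure and total > 0:
            minutes = minutes * (DAY_MINUTES / total)
        bins = np.zeros(n_bins, dtype=bool)
        bins[np.unique(obs["bin"].to_numpy())] = True
        day_type = day["day_type"].iloc[0] if "day_type" in day else "school"
        rows.append({
            "subject_id": sid, "date": date, "day_type": day_type,
            **dict(zip(MINUTE_COLS, minutes)),
            "wear_hours": wear_hours, "wear_bins": bins,
        })
    return pd.DataFrame(rows)


def _epoch_minutes(ts: pd.Series, df: pd.DataFrame) -> float:
    if len(ts) < 2:
        return 5.0 / 60.0
    step = ts.diff().dropna().dt.total_seconds()
    step = step[step > 0]
    return (float(step.mode().iloc[0]) if len(step) else 5.0) / 60.0


def filter_valid_days(
    days: pd.DataFrame, criteria: ValidityCriteria | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply day- and subject-level wear validity rules.

    Returns ``(retained_days, verdicts)``.  ``verdicts`` has one row per
    subject with ``valid`` and a semicolon-joined ``reasons`` field drawn from
    {insufficient_wear_all_days, insufficient_school_days,
    insufficient_weekend_days, coverage_gap}.
    """
    criteria = criteria or ValidityCriteria()
    if days.empty:
        return days, pd.DataFrame(columns=["subject_id", "valid", "reasons"])
    days = days.copy()
    days["day_valid"] = days["wear_hours"] >= criteria.min_wear_hours

    verdicts = []
    keep_subjects = []
    for sid, sub in days.groupby("subject_id", sort=True):
        valid_days = sub[sub["day_valid"]]
        reasons = []
        if valid_days.empty:
            reasons.append("insufficient_wear_all_days")
        n_school = int((valid_days["day_type"] == "school").sum())
        n_weekend = int((valid_days["day_type"] == "weekend").sum())
        if n_school < criteria.min_school_days:
            reasons.append("insufficient_school_days")
        if n_weekend < criteria.min_weekend_days:
            reasons.append("insufficient_weekend_days")
        if not _coverage_ok(valid_days, criteria):
            reasons.append("coverage_gap")
        valid = not reasons
        verdicts.append({
            "subject_id": sid,
            "valid": valid,
            "n_valid_school_days": n_school,
            "n_valid_weekend_days": n_weekend,
            "reasons": ";".join(reasons),
        })
        if valid:
            keep_subjects.append(sid)
    retained = days[days["subject_id"].isin(keep_subjects) & days["day_valid"]]
    return retained.drop(columns=["day_valid"]), pd.DataFrame(verdicts)


def _coverage_ok(valid_days: pd.DataFrame, criteria: ValidityCriteria) -> bool:
    if valid_days.empty:
        return False
    if "wear_bins" not in valid_days.columns or valid_days["wear_bins"].isna().any():
        return True  # no epoch-level information: rule cannot be evaluated
    stacked = np.vstack(valid_days["wear_bins"].to_numpy())
    if criteria.coverage_scope == "day":
        return bool(stacked.all())
    return bool(stacked.any(axis=0).all())


def subject_composition(valid_days: pd.DataFrame) -> Composition:
    """Arithmetic mean of daily behaviour minutes across valid days, re-closed."""
    if valid_days.empty:
        raise ValueError("no valid days to average")
    mean_minutes = valid_days[list(MINUTE_COLS)].to_numpy(dtype=float).mean(axis=0)
    return close(mean_minutes, total=DAY_MINUTES)


def subject_compositions_table(valid_days: pd.DataFrame) -> pd.DataFrame:
    """One closed composition row per subject (pipeline convenience)."""
    rows = []
    for sid, sub in valid_days.groupby("subject_id", sort=True):
        comp = subject_composition(sub)
        rows.append({"subject_id": sid, **dict(zip(MINUTE_COLS, comp.values)),
                     "n_valid_days": len(sub)})
    return pd.DataFrame(rows)
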