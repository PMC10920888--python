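"""Per-trajectory outcomes: followers, mortality, hospital utilization,
diverging-pair ratio tables and critical events.

A patient *follows* a trajectory in an age group if their diagnosis
events cover at least half (inclusive) of the trajectory's tuples up to
that age group and they were hospitalized in that age group.  The
trajectory's mortality in an age group combines the member diagnoses'
in-hospital mortalities m_i as the exactly-one-death probability
M = sum_i m_i prod_{j != i} (1 - m_j).  Critical events are diverging
trajectory pairs whose outcome ratios (diagnoses, hospital days, stays,
mortality) separate by more than a threshold in some age group after the
split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._icd import SENTINEL

OUTCOME_MEASURES = ("mean_dx", "mean_days", "mean_stays", "mortality")


class OutcomeData:
    """Pre-indexed events + stays for fast follower/outcome queries.

    ``min_stay_days`` sets the floor for a same-day stay (1 by default:
    an admission counts as one hospital day).
    """

    def __init__(self, events: pd.DataFrame, stays: pd.DataFrame,
                 min_stay_days: int = 1):
        self.events = events
        self.min_stay_days = min_stay_days
        ev = events[["patient_id", "code", "age_group"]].drop_duplicates()
        self.tuples_by_patient = {
            pid: frozenset(zip(grp["code"], grp["age_group"]))
            for pid, grp in ev.groupby("patient_id")
        }
        self.patients_by_layer = {
            layer: frozenset(grp["patient_id"])
            for layer, grp in ev.groupby("age_group")
        }
        self.patients_by_tuple = {
            (code, layer): frozenset(grp["patient_id"])
            for (code, layer), grp in ev.groupby(["code", "age_group"])
        }
        st = stays.copy()
        st["days"] = st["days"].clip(lower=min_stay_days)
        agg = st.groupby(["patient_id", "age_group"]).agg(
            n_stays=("days", "size"),
            total_days=("days", "sum"),
            died=("death", "any"),
        )
        ndx = (
            ev[ev["code"] != SENTINEL]
            .groupby(["patient_id", "age_group"])["code"]
            .nunique()
            .rename("n_dx")
        )
        self.patient_layer = agg.join(ndx).fillna({"n_dx": 0})
        self.deaths_by_layer = {
            layer: frozenset(grp.index.get_level_values(0))
            for layer, grp in self.patient_layer[self.patient_layer["died"]]
            .groupby(level="age_group")
        }


def followers(trajectory, data: OutcomeData, age_group: int) -> frozenset:
    """Patients holding >= 50% (inclusive) of the trajectory's tuples up
    to ``age_group``, hospitalized in that age group."""
    need = frozenset(t for t in trajectory.tuples if t[1] <= age_group)
    if not need:
        return frozenset()
    half = len(need) / 2
    out = []
    for pid in data.patients_by_layer.get(age_group, ()):
        held = len(data.tuples_by_patient[pid] & need)
        if held >= half:
            out.append(pid)
    return frozenset(out)


def diagnosis_mortality(data: OutcomeData, code: str, age_group: int):
    """In-hospital mortality of one diagnosis in one age group: deaths
    among patients carrying the code there, as a fraction.  ``None`` when
    no patient carries the code (excluded from M upstream)."""
    carriers = data.patients_by_tuple.get((code, age_group), frozenset())
    if not carriers:
        return None
    deaths = data.deaths_by_layer.get(age_group, frozenset())
    return len(carriers & deaths) / len(carriers)


def trajectory_mortality(m_list) -> float:
    """Exactly-one-death probability M = sum_i m_i prod_{j!=i} (1-m_j)."""
    m = np.asarray(list(m_list), dtype=float)
    if m.size == 0:
        return 0.0
    if ((m < 0) | (m > 1)).any():
        raise ValueError("mortalities must lie in [0, 1]")
    total = 0.0
    for i in range(m.size):
        total += m[i] * np.prod(np.delete(1.0 - m, i))
    return float(total)


def hospitalization_stats(trajectory, data: OutcomeData, age_group: int,
                          follower_set=None, per_stay=False):
    """Mean hospital days, stays and distinct diagnoses of the
    trajectory's followers in an age group.

    Means are ``nan`` (reported missing, never 0) when there is no
    follower.  ``per_stay`` divides the diagnosis count by the number of
    stays instead of counting per age group.
    """
    fol = followers(trajectory, data, age_group) if follower_set is None \
        else follower_set
    if not fol:
        return float("nan"), float("nan"), float("nan")
    sub = data.patient_layer.loc[
        [(p, age_group) for p in sorted(fol)
         if (p, age_group) in data.patient_layer.index]
    ]
    if sub.empty:
        return float("nan"), float("nan"), float("nan")
    dx = sub["n_dx"] / sub["n_stays"] if per_stay else sub["n_dx"]
    return (
        float(sub["total_days"].mean()),
        float(sub["n_stays"].mean()),
        float(dx.mean()),
    )


def compute_outcomes(trajectories, data: OutcomeData,
                     per_stay=False) -> pd.DataFrame:
    """Outcome summary: one row per trajectory x age group in its span."""
    rows = []
    for t in trajectories:
        for g in range(t.alpha_min, t.alpha_max + 1):
            fol = followers(t, data, g)
            codes_here = sorted(c for c, a in t.tuples if a == g)
            ms = {}
            for code in codes_here:
                m = diagnosis_mortality(data, code, g)
                if m is None:
                    warnings.warn(
                        f"{t.id}: no carriers of {code} in age group {g}; "
                        "excluded from M", stacklevel=2)
                else:
                    ms[code] = m
            days, stays_, dx = hospitalization_stats(
                t, data, g, follower_set=fol, per_stay=per_stay)
            rows.append({
                "trajectory_id": t.id,
                "age_group": g,
                "n_followers": len(fol),
                "mortality": trajectory_mortality(ms.values()) if ms
                else float("nan"),
                "mean_days": days,
                "mean_stays": stays_,
                "mean_dx": dx,
                "m_by_code": ms,
            })
    return pd.DataFrame(rows, columns=[
        "trajectory_id", "age_group", "n_followers", "mortality",
        "mean_days", "mean_stays", "mean_dx", "m_by_code",
    ])


def diverging_ratios(x_id, y_id, outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per-age-group ratios (first vs second trajectory) of the outcome
    measures; branch order is fixed by trajectory id.  A zero or missing
    denominator yields a missing ratio."""
    if x_id > y_id:
        x_id, y_id = y_id, x_id
    ox = outcomes[outcomes["trajectory_id"] == x_id].set_index("age_group")
    oy = outcomes[outcomes["trajectory_id"] == y_id].set_index("age_group")
    idx = ox.index.intersection(oy.index)
    rows = []
    for g in sorted(idx):
        row = {"age_group": int(g)}
        for col in OUTCOME_MEASURES:
            num, den = ox.at[g, col], oy.at[g, col]
            row[f"ratio_{col}"] = (
                num / den if np.isfinite(num) and np.isfinite(den) and den != 0
                else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["age_group"] + [f"ratio_{c}" for c in OUTCOME_MEASURES]
    )


@dataclass(frozen=True)
class CriticalEvent:
    """A diverging pair with its split layer and post-split outcome
    ratios; ``flagged`` marks a ratio beyond the threshold."""

    x_id: str
    y_id: str
    split_layer: int
    ratios: pd.DataFrame
    flagged: bool


def split_layer_of(rel, traj_by_id) -> int:
    """Highest layer of the shared tuples at the pair's common start
    (the overlap that makes the pair diverging)."""
    x, y = traj_by_id[rel.x_id], traj_by_id[rel.y_id]
    start_overlap = (
        (x.at_layer(x.alpha_min) & y.at_layer(x.alpha_min))
        | (x.at_layer(y.alpha_min) & y.at_layer(y.alpha_min))
    )
    return max(a for _, a in start_overlap)


def detect_critical_events(relations, outcomes: pd.DataFrame, trajectories,
                           threshold: float = 1.5):
    """One :class:`CriticalEvent` per diverging pair; flagged when any
    post-split outcome ratio is >= threshold or <= 1/threshold."""
    traj_by_id = {t.id: t for t in trajectories}
    events = []
    for rel in relations:
        if "diverging" not in rel.labels:
            continue
        split = split_layer_of(rel, traj_by_id)
        ratios = diverging_ratios(rel.x_id, rel.y_id, outcomes)
        post = ratios[ratios["age_group"] > split]
        vals = post[[f"ratio_{c}" for c in OUTCOME_MEASURES]].to_numpy()
        vals = vals[np.isfinite(vals)]
        flagged = bool(
            len(vals) and ((vals >= threshold) | (vals <= 1 / threshold)).any()
        )
        events.append(CriticalEvent(rel.x_id, rel.y_id, split, ratios, flagged))
    return events
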