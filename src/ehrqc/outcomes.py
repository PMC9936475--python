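"""Outcome operationalization: in-hospital mortality, acute inpatient
events, and the discharge-disposition feasibility audit.

EHR extracts only reliably capture deaths occurring during a hospitalization,
and even those are recorded at day resolution with timestamps frequently
absent — so a death recorded one day before or after the visit end is
expected clock skew, while larger offsets signal either data errors (death
well before discharge) or unreliable out-of-hospital reporting (death well
after). Acute events during a stay are confounded by sites that re-record a
patient's medical history every day; an event coded on every single day of
the stay is carried-forward history, not a new event.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class MortalityCall:
    person_id: str
    delta_days: int | None   # death_date - macrovisit end; None if no death
    call: str                # in_hospital | not_in_hospital |
                             # excluded_data_error | no_death
    within_28d: bool


def classify_mortality(death_date, macrovisit_start, macrovisit_end,
                       person_id: str = "",
                       subsequent_visit: bool = False,
                       tolerance_days: int = 1,
                       horizon_days: int = 28) -> MortalityCall:
    """Classify one patient's death record against their macrovisit.

    With the default one-day tolerance: |delta| <= 1 -> ``in_hospital``
    (day-resolution clock skew in either direction); delta <= -2 ->
    ``excluded_data_error`` (death well before discharge is a data error);
    delta >= +2 -> ``not_in_hospital`` (late out-of-hospital reports are not
    systematically available and must not count as in-hospital mortality).
    A death with any subsequent visit on record is a billing artifact ->
    ``excluded_data_error``. ``within_28d`` is true when the death date is
    within ``horizon_days`` of the macrovisit start.
    """
    if death_date is None or pd.isna(death_date):
        return MortalityCall(person_id, None, "no_death", False)
    delta = int((death_date - macrovisit_end).days)
    within = death_date <= macrovisit_start + pd.Timedelta(days=horizon_days)
    if subsequent_visit:
        call = "excluded_data_error"
    elif abs(delta) <= tolerance_days:
        call = "in_hospital"
    elif delta < 0:
        call = "excluded_data_error"
    else:
        call = "not_in_hospital"
    return MortalityCall(person_id, delta, call, bool(within))


def mortality_calls(cohort: pd.DataFrame, deaths: pd.DataFrame,
                    visits: pd.DataFrame,
                    tolerance_days: int = 1,
                    horizon_days: int = 28) -> pd.DataFrame:
    """Mortality call per included cohort patient.

    A patient has a subsequent visit when any visit of theirs starts strictly
    after the death date (billing artifacts); such deaths are excluded.
    """
    inc = cohort[cohort["included"]]
    dd = deaths.drop_duplicates("person_id").set_index("person_id")[
        "death_date"]
    later = visits.merge(dd.rename("death_date_"), left_on="person_id",
                         right_index=True)
    artifact = set(later.loc[later["start_date"] > later["death_date_"],
                             "person_id"])
    rows = []
    for row in inc.itertuples():
        call = classify_mortality(
            dd.get(row.person_id), row.macrovisit_start, row.macrovisit_end,
            person_id=row.person_id,
            subsequent_visit=row.person_id in artifact,
            tolerance_days=tolerance_days, horizon_days=horizon_days)
        rows.append({"person_id": row.person_id, "site_id": row.site_id,
                     "delta_days": call.delta_days, "call": call.call,
                     "within_28d": call.within_28d})
    return pd.DataFrame(rows)


def death_delta_distribution(calls: pd.DataFrame) -> pd.DataFrame:
    """Histogram of (death date - visit end) day offsets among patients who
    died, excluding billing-artifact deaths, with an asymmetry summary
    (mass at delta >= +2 vs delta <= -2)."""
    # keep data-error early deaths (the histogram's left tail) but drop
    # subsequent-visit artifacts, whose delta is not meaningful
    died = calls[calls["delta_days"].notna()].copy()
    artifact = died["call"].eq("excluded_data_error") & (died["delta_days"] > -2)
    died = died[~artifact]
    hist = (died.groupby("delta_days").size().rename("n")
            .reset_index().sort_values("delta_days").reset_index(drop=True))
    hist["delta_days"] = hist["delta_days"].astype(int)
    late = int(hist.loc[hist["delta_days"] >= 2, "n"].sum())
    early = int(hist.loc[hist["delta_days"] <= -2, "n"].sum())
    hist.attrs["asymmetry"] = {"late": late, "early": early}
    return hist


def classify_acute_event(condition_dates: pd.Series | list,
                         macrovisit_start, macrovisit_end,
                         treatment_start=None) -> dict:
    """Classify one (person, event concept set) against a stay.

    ``condition_dates`` are the dates of matching codes; only those within
    the macrovisit are considered (day-level semantics: duplicates within a
    day collapse). Rules, in order:

    - matching codes on *every* day of the stay -> ``carried_forward``
      (re-recorded medical history, not a new event);
    - first occurrence before ``treatment_start`` -> ``pre_treatment_excluded``;
    - any occurrence on/after ``treatment_start`` (or any occurrence when no
      treatment date is given) -> ``acute_post_treatment``;
    - no occurrence -> ``absent``.

    Returns dict with ``call``, ``events_per_day`` (#days with >=1 code /
    stay length) and ``first_date``.
    """
    dates = pd.to_datetime(pd.Series(list(condition_dates))).dt.normalize()
    dates = dates[(dates >= macrovisit_start) & (dates <= macrovisit_end)]
    days_with = dates.drop_duplicates()
    length = (macrovisit_end - macrovisit_start).days + 1
    events_per_day = len(days_with) / length
    if len(days_with) == 0:
        return {"call": "absent", "events_per_day": 0.0, "first_date": None}
    first = days_with.min()
    if len(days_with) == length:
        call = "carried_forward"
    elif treatment_start is not None and pd.notna(treatment_start) \
            and first < treatment_start:
        call = "pre_treatment_excluded"
    else:
        call = "acute_post_treatment"
    return {"call": call, "events_per_day": events_per_day,
            "first_date": first}


def acute_event_calls(bundle_conditions: pd.DataFrame, cohort: pd.DataFrame,
                      event_set: set[int], event_name: str,
                      treatment_starts: pd.Series | None = None
                      ) -> pd.DataFrame:
    """Acute-event call per included patient for one event concept set."""
    inc = cohort[cohort["included"]]
    rows = bundle_conditions[bundle_conditions["concept_id"].isin(event_set)]
    by_person = {pid: grp["date"] for pid, grp in rows.groupby("person_id")}
    out = []
    for row in inc.itertuples():
        t0 = (treatment_starts.get(row.person_id)
              if treatment_starts is not None else None)
        res = classify_acute_event(
            by_person.get(row.person_id, []), row.macrovisit_start,
            row.macrovisit_end, treatment_start=t0)
        out.append({"person_id": row.person_id, "event": event_name, **res})
    return pd.DataFrame(out)


def disposition_audit(visits: pd.DataFrame, top_k: int = 10
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Audit discharge-disposition reporting.

    Returns (top_table, site_availability): the ``top_k`` most frequent
    dispositions across all sites (no padding when fewer exist), and the
    per-site availability rate of the field among inpatient rows, flagging
    sites with zero reporting (some source CDMs lack the field entirely).
    """
    inpt = visits[visits["visit_kind"] == "inpatient"]
    present = inpt[inpt["discharge_disposition"].notna()]
    top = (present.groupby("discharge_disposition").size().rename("count")
           .sort_values(ascending=False).head(top_k).reset_index())
    n = inpt.groupby("site_id").size().rename("n_inpatient")
    got = present.groupby("site_id").size().rename("n_with_disposition")
    avail = pd.concat([n, got], axis=1).fillna(0)
    avail["n_with_disposition"] = avail["n_with_disposition"].astype(int)
    avail["availability_pct"] = (100.0 * avail["n_with_disposition"]
                                 / avail["n_inpatient"])
    avail["zero_reporting"] = avail["n_with_disposition"] == 0
    return top, avail.reset_index()
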