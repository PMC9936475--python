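"""Macrovisit construction and hospitalized-cohort selection.

A *macrovisit* merges the overlapping inpatient and emergency visit rows of
one patient into a single contiguous hospital care episode, compensating for
the fragmented way different source systems record a stay. Cohort selection
then applies the study's inclusion rules — adult, non-missing demographics,
a first qualifying hospitalization of at least two days anchored near the
index COVID-positive date — recording every rule outcome per patient so the
attrition cascade is auditable.
"""

from __future__ import annotations

import pandas as pd

from .tables import EHRBundle

#: inclusion rules, in the order the attrition table reports them
COHORT_RULES = (
    "nonmissing_age", "nonmissing_sex", "index_on_or_after_2020",
    "index_in_window", "age_18_plus", "has_qualifying_macrovisit",
    "stay_2_days_plus",
)


def build_macrovisits(visits: pd.DataFrame,
                      merge_gap_days: int = 0) -> pd.DataFrame:
    """Merge inpatient/emergency visit rows into macrovisits per person.

    Two visits merge when the later one starts no more than
    ``merge_gap_days`` days after the earlier one ends; at the default 0
    this merges only overlapping or same-day-abutting intervals (closed
    intervals sharing a day), so visits on consecutive days remain distinct
    episodes. An absent end date is treated as end = start.

    Returns one row per macrovisit: ``person_id``, ``site_id``,
    ``macrovisit_id``, ``start_date``, ``end_date``, ``length_days``,
    ``visit_ids`` (comma-joined constituents).
    """
    v = visits[visits["visit_kind"].isin(["inpatient", "emergency"])].copy()
    if v.empty:
        return pd.DataFrame(columns=["person_id", "site_id", "macrovisit_id",
                                     "start_date", "end_date", "length_days",
                                     "visit_ids"])
    v["end_date"] = v["end_date"].fillna(v["start_date"])
    # flagged-not-dropped upstream; here reversed visits are normalized
    swap = v["end_date"] < v["start_date"]
    v.loc[swap, ["start_date", "end_date"]] = (
        v.loc[swap, ["end_date", "start_date"]].to_numpy())
    v = v.sort_values(["person_id", "start_date", "end_date", "visit_id"])

    out = []
    gap = pd.Timedelta(days=merge_gap_days)
    for pid, grp in v.groupby("person_id", sort=True):
        cur_start = cur_end = None
        cur_ids: list[str] = []
        site = grp["site_id"].iloc[0]
        k = 0

        def flush():
            nonlocal k
            out.append({
                "person_id": pid, "site_id": site,
                "macrovisit_id": f"{pid}-M{k}",
                "start_date": cur_start, "end_date": cur_end,
                "length_days": (cur_end - cur_start).days + 1,
                "visit_ids": ",".join(cur_ids),
            })
            k += 1

        for row in grp.itertuples():
            if cur_start is None:
                cur_start, cur_end, cur_ids = (row.start_date, row.end_date,
                                               [row.visit_id])
            elif row.start_date <= cur_end + gap:
                cur_end = max(cur_end, row.end_date)
                cur_ids.append(row.visit_id)
            else:
                flush()
                cur_start, cur_end, cur_ids = (row.start_date, row.end_date,
                                               [row.visit_id])
        if cur_start is not None:
            flush()
    return pd.DataFrame(out)


def select_cohort(bundle: EHRBundle, macrovisits: pd.DataFrame,
                  index_events: pd.Series,
                  window: tuple[str, str] = ("2020-03-01", "2021-09-01"),
                  admission_window_days: int = 14,
                  min_stay_days: int = 2) -> pd.DataFrame:
    """Apply the study inclusion rules and return one row per person.

    ``index_events`` maps person_id -> first COVID-positive date (any
    per-person source is accepted; phenotype derivation is upstream). The
    qualifying hospitalization is the first macrovisit starting within
    ``admission_window_days`` of the index date. Output columns: person_id,
    site_id, index_date, macrovisit fields, age_at_index, sex, one boolean
    column per rule in :data:`COHORT_RULES`, and ``included``. Only the first
    qualifying hospitalization per person is evaluated.
    """
    w0, w1 = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    tol = pd.Timedelta(days=admission_window_days)
    person = bundle.person.set_index("person_id")
    mv = macrovisits.sort_values(["person_id", "start_date"])
    mv_by_person = dict(tuple(mv.groupby("person_id", sort=False)))

    rows = []
    for pid, idx_date in index_events.sort_index().items():
        if pid not in person.index:
            continue
        idx_date = pd.Timestamp(idx_date)
        p = person.loc[pid]
        flags = {}
        flags["nonmissing_age"] = pd.notna(p["birth_year"])
        flags["nonmissing_sex"] = pd.notna(p["sex"])
        flags["index_on_or_after_2020"] = idx_date >= pd.Timestamp("2020-01-01")
        flags["index_in_window"] = w0 <= idx_date <= w1
        age = (int(idx_date.year - p["birth_year"])
               if flags["nonmissing_age"] else None)
        flags["age_18_plus"] = age is not None and age >= 18

        cand = mv_by_person.get(pid)
        chosen = None
        if cand is not None:
            ok = cand[(cand["start_date"] >= idx_date - tol)
                      & (cand["start_date"] <= idx_date + tol)]
            if len(ok):
                chosen = ok.iloc[0]
        flags["has_qualifying_macrovisit"] = chosen is not None
        flags["stay_2_days_plus"] = (chosen is not None
                                     and chosen["length_days"] >= min_stay_days)
        rows.append({
            "person_id": pid, "site_id": p["site_id"],
            "index_date": idx_date, "age_at_index": age, "sex": p["sex"],
            "macrovisit_id": None if chosen is None else chosen["macrovisit_id"],
            "macrovisit_start": None if chosen is None else chosen["start_date"],
            "macrovisit_end": None if chosen is None else chosen["end_date"],
            "length_days": None if chosen is None else int(chosen["length_days"]),
            **flags,
            "included": all(flags.values()),
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["macrovisit_start"] = pd.to_datetime(df["macrovisit_start"])
        df["macrovisit_end"] = pd.to_datetime(df["macrovisit_end"])
    return df


def attrition_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Sequential attrition: rows remaining after each rule is added."""
    remaining = cohort
    out = [{"rule": "assessed", "n_remaining": len(cohort), "n_excluded": 0}]
    for rule in COHORT_RULES:
        nxt = remaining[remaining[rule]]
        out.append({"rule": rule, "n_remaining": len(nxt),
                    "n_excluded": len(remaining) - len(nxt)})
        remaining = nxt
    return pd.DataFrame(out)
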