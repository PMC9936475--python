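"""Ingredient roll-up and drug-era reconstruction from dirty exposure rows.

Raw inpatient drug exposures arrive under wildly different documentation
paradigms: per-day duplicated single-day rows (order + administration), open
intervals with no end date, multi-day sub-intervals, and occasional reversed
start/end pairs. A *drug era* is the consolidated continuous interval of
exposure to one ingredient. The cleaning rules applied here, in order:

1. discard rows with end < start (erroneous reversed intervals), logged;
2. treat an absent end date as a single-day exposure (end = start);
3. deduplicate identical (start, end) pairs per person;
4. sort by start and merge intervals that overlap, abut, or are separated
   by an uncovered gap of at most ``gap_days``.

``gap_days`` defaults to 0: consecutive-day exposures are one continuous
course, but the 30-day outpatient persistence window used by stock OMOP era
derivation is deliberately NOT the default — it over-merges short inpatient
courses. Exposure days per era are counted on closed intervals
(end - start + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .tables import EHRBundle


def descendants_of_ingredient(concept_ancestor: pd.DataFrame,
                              ingredient_id: int) -> set[int]:
    """Transitive closure of descendants, including the ingredient itself."""
    children: dict[int, list[int]] = {}
    for a, b in zip(concept_ancestor["ancestor_id"],
                    concept_ancestor["descendant_id"]):
        children.setdefault(int(a), []).append(int(b))
    seen = {int(ingredient_id)}
    stack = [int(ingredient_id)]
    while stack:
        node = stack.pop()
        for ch in children.get(node, ()):
            if ch not in seen:
                seen.add(ch)
                stack.append(ch)
    return seen


def concept_distribution(rows: pd.DataFrame, descendant_set: set[int],
                         concept: pd.DataFrame) -> pd.DataFrame:
    """Count exposure rows per concept name within one ingredient's
    descendant set, descending, with percentages."""
    sel = rows[rows["concept_id"].isin(descendant_set)]
    if sel.empty:
        return pd.DataFrame(columns=["concept_id", "name", "count", "percent"])
    counts = (sel.groupby("concept_id").size()
              .sort_values(ascending=False).rename("count").reset_index())
    names = concept.set_index("concept_id")["name"]
    counts["name"] = counts["concept_id"].map(names)
    counts["percent"] = 100.0 * counts["count"] / counts["count"].sum()
    return counts[["concept_id", "name", "count", "percent"]]


@dataclass
class CleaningLog:
    rows_in: int = 0
    reversed_dropped: int = 0
    open_closed: int = 0
    duplicates_removed: int = 0
    eras_out: int = 0
    extra: dict = field(default_factory=dict)


def build_drug_eras(rows: pd.DataFrame,
                    gap_days: int = 0) -> tuple[pd.DataFrame, CleaningLog]:
    """Consolidate exposure rows (already filtered to one ingredient's
    descendant set) into drug eras per person.

    Returns (eras, log). Era columns: ``person_id``, ``site_id``,
    ``start_date``, ``end_date``, ``exposure_days``, ``n_source_rows``,
    ``any_claim_inferred``. Deterministic and order-invariant in the input
    rows; total exposure days equal the size of the union of the retained
    rows' day sets whenever ``gap_days`` is 0.
    """
    log = CleaningLog(rows_in=len(rows))
    cols = ["person_id", "site_id", "start_date", "end_date",
            "exposure_days", "n_source_rows", "any_claim_inferred"]
    if rows.empty:
        return pd.DataFrame(columns=cols), log
    r = rows.copy()

    # rule 1: reversed intervals are erroneous -> discard, log
    reversed_mask = r["end_date"].notna() & (r["end_date"] < r["start_date"])
    log.reversed_dropped = int(reversed_mask.sum())
    r = r[~reversed_mask]

    # rule 2: open intervals are single-day exposures
    open_mask = r["end_date"].isna()
    log.open_closed = int(open_mask.sum())
    r = r.copy()
    r.loc[open_mask, "end_date"] = r.loc[open_mask, "start_date"]

    # rule 3: deduplicate identical (person, start, end)
    claim = (r.get("drug_type_label").astype("string").str.contains(
        "claim", case=False, na=False) if "drug_type_label" in r else
        pd.Series(False, index=r.index))
    r = r.assign(claim_row=claim)
    before = len(r)
    agg = (r.groupby(["person_id", "start_date", "end_date"], as_index=False)
           .agg(site_id=("site_id", "first"), nrows=("person_id", "size"),
                claim_row=("claim_row", "any")))
    log.duplicates_removed = before - len(agg)

    # rule 4: sort and merge
    agg = agg.sort_values(["person_id", "start_date", "end_date"])
    gap = pd.Timedelta(days=gap_days + 1)  # uncovered gap <= gap_days merges
    out = []
    for pid, grp in agg.groupby("person_id", sort=True):
        cur = None
        for row in grp.itertuples():
            if cur is None:
                cur = [pid, row.site_id, row.start_date, row.end_date,
                       int(row.nrows), bool(row.claim_row)]
            elif row.start_date <= cur[3] + gap:
                cur[3] = max(cur[3], row.end_date)
                cur[4] += int(row.nrows)
                cur[5] = cur[5] or bool(row.claim_row)
            else:
                out.append(cur)
                cur = [pid, row.site_id, row.start_date, row.end_date,
                       int(row.nrows), bool(row.claim_row)]
        if cur is not None:
            out.append(cur)
    eras = pd.DataFrame(out, columns=["person_id", "site_id", "start_date",
                                      "end_date", "n_source_rows",
                                      "any_claim_inferred"])
    eras["exposure_days"] = (eras["end_date"]
                             - eras["start_date"]).dt.days + 1
    eras = eras[cols]
    log.eras_out = len(eras)
    return eras, log


def ingredient_eras(bundle: EHRBundle, ingredient_id: int,
                    gap_days: int = 0) -> tuple[pd.DataFrame, CleaningLog]:
    """Roll exposures up to one ingredient's descendant set and build eras."""
    desc = descendants_of_ingredient(bundle.concept_ancestor, ingredient_id)
    rows = bundle.drug_exposure[bundle.drug_exposure["concept_id"].isin(desc)]
    return build_drug_eras(rows, gap_days=gap_days)


def first_era_per_person(eras: pd.DataFrame) -> pd.DataFrame:
    return (eras.sort_values(["person_id", "start_date"])
            .drop_duplicates("person_id"))


def initiated_within(eras: pd.DataFrame, cohort: pd.DataFrame,
                     days: int = 2) -> pd.Series:
    """Predicate: person's first era starts within ``days`` of admission.

    Exposed for study-specific treatment definitions (treatment initiated
    early in the stay), not hard-coded into era construction.
    """
    first = first_era_per_person(eras).set_index("person_id")
    adm = cohort.set_index("person_id")["macrovisit_start"]
    joined = first.join(adm, how="inner")
    ok = ((joined["start_date"] >= joined["macrovisit_start"])
          & (joined["start_date"]
             <= joined["macrovisit_start"] + pd.Timedelta(days=days)))
    return ok


def duration_distribution(eras: pd.DataFrame, cohort: pd.DataFrame,
                          deaths: pd.DataFrame,
                          terminal_filter: str = "none") -> pd.DataFrame:
    """Histogram of per-patient first-era durations.

    ``terminal_filter='drop_if_ends_at_discharge_or_death'`` removes
    patients whose era end coincides with the macrovisit end or the death
    date — treatment courses cut short by discharge or death rather than
    completed.
    """
    first = first_era_per_person(eras)
    info = cohort.set_index("person_id")
    if terminal_filter == "drop_if_ends_at_discharge_or_death":
        dd = deaths.drop_duplicates("person_id").set_index("person_id")[
            "death_date"]
        keep = []
        for row in first.itertuples():
            end = row.end_date
            mv_end = (info.loc[row.person_id, "macrovisit_end"]
                      if row.person_id in info.index else None)
            death = dd.get(row.person_id)
            terminal = ((mv_end is not None and pd.notna(mv_end)
                         and end == mv_end)
                        or (death is not None and pd.notna(death)
                            and end == death))
            keep.append(not terminal)
        first = first[pd.Series(keep, index=first.index)]
    elif terminal_filter != "none":
        raise ValueError(f"unknown terminal_filter {terminal_filter!r}")
    hist = (first.groupby("exposure_days").size().rename("n_patients")
            .reset_index().sort_values("exposure_days"))
    hist["percent"] = 100.0 * hist["n_patients"] / hist["n_patients"].sum()
    return hist.reset_index(drop=True)


def claim_inferred_breakdown(rows: pd.DataFrame,
                             eras: pd.DataFrame) -> pd.DataFrame:
    """site x drug_type_label counts of source rows backing single-day eras.

    Rows with an absent label are counted under ``missing``. Reversed rows
    never back an era and are ignored.
    """
    single = eras[eras["exposure_days"] == 1]
    if single.empty:
        return pd.DataFrame(columns=["site_id", "drug_type_label", "count"])
    r = rows.copy()
    rev = r["end_date"].notna() & (r["end_date"] < r["start_date"])
    r = r[~rev]
    r["end_date"] = r["end_date"].fillna(r["start_date"])
    m = r.merge(single[["person_id", "start_date", "end_date"]]
                .rename(columns={"start_date": "era_start",
                                 "end_date": "era_end"}),
                on="person_id")
    m = m[(m["start_date"] >= m["era_start"]) & (m["end_date"] <= m["era_end"])]
    m["drug_type_label"] = m["drug_type_label"].fillna("missing")
    out = (m.groupby(["site_id", "drug_type_label"]).size().rename("count")
           .reset_index().sort_values("count", ascending=False)
           .reset_index(drop=True))
    return out
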