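"""EHR continuity: prior-history depth, baseline covariates, and group
comparison via standardized mean differences.

Multi-site EHR extracts contain no enrollment spans: a patient with no
visits before their admission may be healthy, may receive care elsewhere
(EHR discontinuity), or may lack access to care — and their documented
comorbidity burden is biased downward accordingly. History depth is measured
as months between the earliest recorded visit of any kind and admission,
right-capped both by the extract's lookback floor and at 24 months, giving
three analysis groups: no history, 1-23 months, and 24+ months.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .tables import EHRBundle

#: average Gregorian month length used for month arithmetic (configurable)
DAYS_PER_MONTH = 30.4375

HISTORY_GROUPS = ("none", "under_24", "cap_24plus")


def months_prior_history(visits: pd.DataFrame, cohort: pd.DataFrame,
                         lookback_floor: str | pd.Timestamp = "2018-01-01",
                         cap_months: int = 24,
                         days_per_month: float = DAYS_PER_MONTH
                         ) -> pd.DataFrame:
    """Per-patient months of prior history and history group.

    months = floor(days between the earliest visit start (on/after the
    lookback floor, strictly before the macrovisit start) and the macrovisit
    start / ``days_per_month``), capped at ``cap_months``. A patient with no
    prior visit is group ``none``; a prior visit under one month still
    counts as history (group ``under_24`` with months 0).
    """
    floor = pd.Timestamp(lookback_floor)
    inc = cohort[cohort["included"]]
    v = visits[visits["start_date"] >= floor]
    earliest = (v.merge(inc[["person_id", "macrovisit_start"]],
                        on="person_id")
                .query("start_date < macrovisit_start")
                .groupby("person_id")["start_date"].min())
    out = []
    for row in inc.itertuples():
        e = earliest.get(row.person_id)
        if e is None or pd.isna(e):
            months, group, e = 0, "none", None
        else:
            days = (row.macrovisit_start - e).days
            months = min(int(days // days_per_month), cap_months)
            group = "cap_24plus" if months >= cap_months else "under_24"
        out.append({"person_id": row.person_id, "site_id": row.site_id,
                    "months_prior_history": months, "history_group": group,
                    "earliest_visit_date": e})
    df = pd.DataFrame(out)
    df["earliest_visit_date"] = pd.to_datetime(df["earliest_visit_date"])
    return df


def baseline_covariates(bundle: EHRBundle, cohort: pd.DataFrame,
                        concept_sets: dict[str, set[int]],
                        med_sets: dict[str, set[int]] | None = None,
                        med_lookback_days: int | None = 365,
                        ventilation_set_name: str = "ventilation_ecmo",
                        admission_days: int = 2) -> pd.DataFrame:
    """Per-patient binary baseline indicators from concept sets.

    A comorbidity indicator is true iff at least one matching condition code
    is dated strictly before the macrovisit start. Prior-medication
    indicators use drug exposure rows within ``med_lookback_days`` before
    admission (``None`` = any time before). ``ventilated_on_admission`` is
    true iff a code from the ventilation concept set falls within the first
    ``admission_days`` days of the macrovisit; ``in_hospital_mortality``
    requires a death date within one day of the macrovisit end.
    """
    inc = cohort[cohort["included"]]
    info = inc.set_index("person_id")
    conds = bundle.condition_occurrence.merge(
        inc[["person_id", "macrovisit_start", "macrovisit_end"]],
        on="person_id")
    out = pd.DataFrame(index=info.index)
    out["site_id"] = info["site_id"]
    out["age_at_index"] = info["age_at_index"]
    out["sex"] = info["sex"]

    before = conds[conds["date"] < conds["macrovisit_start"]]
    for name, ids in concept_sets.items():
        if name == ventilation_set_name:
            continue
        hit = set(before.loc[before["concept_id"].isin(ids), "person_id"])
        out[name] = out.index.isin(hit)

    if med_sets:
        d = bundle.drug_exposure.merge(
            inc[["person_id", "macrovisit_start"]], on="person_id")
        d = d[d["start_date"] < d["macrovisit_start"]]
        if med_lookback_days is not None:
            lo = d["macrovisit_start"] - pd.Timedelta(days=med_lookback_days)
            d = d[d["start_date"] >= lo]
        for name, ids in med_sets.items():
            hit = set(d.loc[d["concept_id"].isin(ids), "person_id"])
            out[f"prior_{name}"] = out.index.isin(hit)

    vent_ids = concept_sets.get(ventilation_set_name, set())
    lim = conds["macrovisit_start"] + pd.Timedelta(days=admission_days)
    vent_rows = conds[conds["concept_id"].isin(vent_ids)
                      & (conds["date"] >= conds["macrovisit_start"])
                      & (conds["date"] <= lim)]
    out["ventilated_on_admission"] = out.index.isin(set(vent_rows["person_id"]))

    dd = bundle.death.drop_duplicates("person_id").set_index("person_id")[
        "death_date"]
    joined = info.join(dd, how="left")
    delta = (joined["death_date"] - joined["macrovisit_end"]).dt.days
    out["in_hospital_mortality"] = delta.abs().le(1).fillna(False).to_numpy()
    return out.reset_index()


def smd(a, b, kind: str = "binary") -> float:
    """Standardized mean difference between two group summaries.

    binary: ``a``/``b`` are prevalences p; SMD =
    (p_a - p_b) / sqrt((p_a(1-p_a) + p_b(1-p_b)) / 2).
    continuous: ``a``/``b`` are (mean, sd); SMD =
    (m_a - m_b) / sqrt((s_a^2 + s_b^2)/2).
    |SMD| < 0.1 is conventionally negligible. Identical groups give 0
    (including degenerate zero-variance cases).
    """
    if kind == "binary":
        pa, pb = float(a), float(b)
        num = pa - pb
        den = math.sqrt((pa * (1 - pa) + pb * (1 - pb)) / 2.0)
    elif kind == "continuous":
        (ma, sa), (mb, sb) = a, b
        num = float(ma) - float(mb)
        den = math.sqrt((float(sa) ** 2 + float(sb) ** 2) / 2.0)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if den == 0.0:
        return 0.0
    return num / den


def smd_table(covariates: pd.DataFrame, groups: pd.Series,
              group_a: str, group_b: str) -> pd.DataFrame:
    """SMD per covariate column between two history groups.

    Boolean columns are treated as binary prevalences, numeric columns as
    continuous (mean, sd). ``negligible`` flags |SMD| < 0.1.
    """
    ga = covariates[groups.reindex(covariates.index) == group_a]
    gb = covariates[groups.reindex(covariates.index) == group_b]
    out = []
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == bool:
            val = smd(ga[col].mean(), gb[col].mean(), "binary")
        elif pd.api.types.is_numeric_dtype(s):
            val = smd((ga[col].mean(), ga[col].std(ddof=1)),
                      (gb[col].mean(), gb[col].std(ddof=1)), "continuous")
        else:
            continue
        out.append({"covariate": col, "smd": val,
                    "negligible": abs(val) < 0.1})
    return pd.DataFrame(out)


def history_table(covariates: pd.DataFrame, groups: pd.Series,
                  suppress_below: int = 20) -> pd.DataFrame:
    """Stratified baseline table with per-covariate p-values.

    Binary covariates are summarized as n (%) per group and tested with the
    chi-square test of independence; continuous covariates as median (IQR)
    and tested with Kruskal-Wallis. Cell counts below ``suppress_below``
    are rendered ``"<{suppress_below}"``. With a single non-empty group,
    p-values are omitted.
    """
    g = groups.reindex(covariates.index)
    levels = [lv for lv in HISTORY_GROUPS if (g == lv).any()]
    if not levels:
        levels = sorted(g.dropna().unique())
    multi = len(levels) >= 2
    out = []
    for col in covariates.columns:
        s = covariates[col]
        rec = {"covariate": col}
        pval = None
        if s.dtype == bool:
            counts = []
            for lv in levels:
                sub = s[g == lv]
                n = int(sub.sum())
                total = len(sub)
                cell = (f"<{suppress_below}" if 0 < n < suppress_below
                        else str(n))
                pct = 100.0 * n / total if total else float("nan")
                rec[lv] = f"{cell} ({pct:.1f}%)"
                counts.append([n, total - n])
            if multi:
                tab = np.array(counts).T
                tab = tab[:, tab.sum(axis=0) > 0]
                if tab.shape[1] >= 2 and (tab.sum(axis=1) > 0).all():
                    pval = float(stats.chi2_contingency(tab)[1])
        elif pd.api.types.is_numeric_dtype(s):
            samples = []
            for lv in levels:
                sub = pd.to_numeric(s[g == lv], errors="coerce").dropna()
                if len(sub):
                    q1, med, q3 = sub.quantile([0.25, 0.5, 0.75])
                    rec[lv] = f"{med:g} ({q1:g}, {q3:g})"
                    samples.append(sub.to_numpy())
                else:
                    rec[lv] = ""
            if multi and len(samples) >= 2:
                try:
                    pval = float(stats.kruskal(*samples)[1])
                except ValueError:  # all values identical
                    pval = 1.0
        else:
            continue
        rec["p_value"] = pval if multi else None
        out.append(rec)
    return pd.DataFrame(out)


def no_history_heatmap(cohort: pd.DataFrame,
                       continuity: pd.DataFrame) -> pd.DataFrame:
    """site x pandemic-month matrix of the fraction of patients with no
    prior history. Empty site-months are NaN (no data), not zero."""
    inc = cohort[cohort["included"]].copy()
    inc["month"] = inc["macrovisit_start"].dt.strftime("%Y-%m")
    m = inc.merge(continuity[["person_id", "history_group"]], on="person_id")
    n = m.groupby(["site_id", "month"]).size()
    none = (m[m["history_group"] == "none"]
            .groupby(["site_id", "month"]).size())
    frac = (none.reindex(n.index, fill_value=0) / n).rename("frac_no_history")
    return frac.unstack("month")
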