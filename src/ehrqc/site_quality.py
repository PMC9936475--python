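"""Per-site completeness profiling, temporal missingness, and exclusion rules.

A multi-site extract is only as usable as its worst contributors: sites vary
in which vitals and labs they capture at all, and in how capture drifts over
calendar time. This module computes the per-site completeness matrix
(% of cohort patients with at least one value during hospitalization),
clusters sites on those vectors, and applies the screening rules: drop sites
whose mean missingness across key vitals exceeds 70%, whose overall missing
proportion or temporal variance exceeds two standard deviations of the
global value, or whose dates were shifted by more than a week before
submission.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .tables import EHRBundle

#: key vitals screened by the 70%-missingness rule
KEY_VITALS = ("SpO2", "respiration_rate", "body_temperature", "heart_rate",
              "BMI")

DEFAULT_THRESHOLDS = {"vitals_missing_max": 0.70, "sd_mult": 2.0,
                      "max_shift_days": 7}


def _cohort_measurements(bundle: EHRBundle, cohort: pd.DataFrame,
                         variables: list[str]) -> pd.DataFrame:
    """Measurement rows of included patients dated within their macrovisit."""
    inc = cohort[cohort["included"]]
    m = bundle.measurement
    m = m[m["variable"].isin(variables)]
    merged = m.merge(
        inc[["person_id", "macrovisit_start", "macrovisit_end"]],
        on="person_id", how="inner")
    in_window = ((merged["date"] >= merged["macrovisit_start"])
                 & (merged["date"] <= merged["macrovisit_end"]))
    return merged[in_window]


def completeness_matrix(bundle: EHRBundle, cohort: pd.DataFrame,
                        variables: list[str]) -> pd.DataFrame:
    """site x variable matrix of completeness percentages.

    A cell is 100 x (#included patients at the site with >=1 value of the
    variable during their macrovisit) / (#included patients at the site).
    """
    inc = cohort[cohort["included"]]
    rows = _cohort_measurements(bundle, cohort, variables)
    n_per_site = inc.groupby("site_id")["person_id"].nunique()
    have = (rows.drop_duplicates(["person_id", "variable"])
            .groupby(["site_id", "variable"])["person_id"].nunique()
            .unstack(fill_value=0))
    mat = have.reindex(index=n_per_site.index, columns=variables,
                       fill_value=0)
    return 100.0 * mat.div(n_per_site, axis=0)


def temporal_missingness(bundle: EHRBundle, cohort: pd.DataFrame,
                         variables: list[str]) -> pd.DataFrame:
    """(site, pandemic month) x variable matrix of missing fractions.

    Pandemic month is the calendar month of the macrovisit start; a cell is
    the fraction of that month's cohort patients at the site with no value
    of the variable during their stay. Empty site-months are absent rather
    than zero.
    """
    inc = cohort[cohort["included"]].copy()
    inc["month"] = inc["macrovisit_start"].dt.strftime("%Y-%m")
    rows = _cohort_measurements(bundle, cohort, variables)
    have = (rows.drop_duplicates(["person_id", "variable"])
            .merge(inc[["person_id", "month"]], on="person_id"))
    n = inc.groupby(["site_id", "month"])["person_id"].nunique()
    got = (have.groupby(["site_id", "month", "variable"])["person_id"]
           .nunique().unstack(fill_value=0))
    got = got.reindex(index=n.index, columns=variables, fill_value=0)
    frac_missing = 1.0 - got.div(n, axis=0)
    return frac_missing


@dataclass
class SiteClustering:
    labels: dict[str, int]          # site_id -> cluster label (1..k)
    retained_sites: list[str]       # members of the higher-completeness cluster
    linkage_matrix: np.ndarray
    site_order: list[str]


def cluster_sites(matrix: pd.DataFrame, k: int = 2,
                  metric: str = "euclidean",
                  method: str = "average") -> SiteClustering:
    """Agglomerative clustering of sites on their completeness vectors.

    Cutting at ``k`` clusters, the retained cluster is the one with the
    highest mean completeness across its member sites.
    """
    sites = list(matrix.index)
    if len(sites) < 2:
        return SiteClustering(labels={s: 1 for s in sites},
                              retained_sites=sites,
                              linkage_matrix=np.empty((0, 4)),
                              site_order=sites)
    X = matrix.to_numpy(dtype=float)
    Z = linkage(pdist(X, metric=metric), method=method)
    labs = fcluster(Z, t=min(k, len(sites)), criterion="maxclust")
    means = {}
    for lab in np.unique(labs):
        means[lab] = float(X[labs == lab].mean())
    best = max(sorted(means), key=lambda lab: means[lab])
    retained = [s for s, lab in zip(sites, labs) if lab == best]
    return SiteClustering(labels=dict(zip(sites, (int(x) for x in labs))),
                          retained_sites=retained, linkage_matrix=Z,
                          site_order=sites)


def apply_exclusion_rules(matrix: pd.DataFrame,
                          temporal: pd.DataFrame,
                          site_meta: pd.DataFrame,
                          thresholds: dict | None = None,
                          clustering: SiteClustering | None = None,
                          key_vitals: tuple[str, ...] = KEY_VITALS
                          ) -> pd.DataFrame:
    """Build per-site quality profiles with exclusion flags and reasons.

    Rules (a site is excluded iff at least one fires):

    - ``vitals_below_threshold``: mean missingness across the key vitals
      exceeds ``vitals_missing_max`` (default 0.70);
    - ``missing_gt_2sd``: the site's mean missing proportion (over all
      matrix variables) exceeds the global mean by more than ``sd_mult``
      population standard deviations;
    - ``temporal_var_gt_2sd``: likewise for the site's temporal variance —
      the variance across pandemic months of its monthly missing fraction,
      averaged over variables;
    - ``date_shift_gt_7d``: the site shifted dates by more than
      ``max_shift_days`` before submission;
    - ``cluster_dropout``: site falls outside the retained top-level cluster
      (only when a clustering is supplied).

    Global means/SDs are computed once over all profiled sites, before any
    exclusion (no iterative re-screening). If all sites are identical the
    SD is zero and rules (a)/(b) exclude nobody.
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    sites = list(matrix.index)
    missing = 1.0 - matrix / 100.0
    mean_missing = missing.mean(axis=1)
    vit = [v for v in key_vitals if v in matrix.columns]
    vitals_missing = missing[vit].mean(axis=1) if vit else pd.Series(
        0.0, index=matrix.index)

    # per-site temporal variance: variance over months per variable, then
    # averaged over variables; sites with a single month get variance 0
    if len(temporal):
        tvar = (temporal.groupby(level="site_id")
                .var(ddof=0).mean(axis=1).reindex(sites).fillna(0.0))
    else:
        tvar = pd.Series(0.0, index=pd.Index(sites, name="site_id"))

    g_mean, g_sd = float(mean_missing.mean()), float(mean_missing.std(ddof=0))
    t_mean, t_sd = float(tvar.mean()), float(tvar.std(ddof=0))
    shift = (site_meta.set_index("site_id")["max_date_shift_days"]
             .reindex(sites).fillna(0))

    out = []
    for s in sites:
        reasons = []
        if vitals_missing[s] > th["vitals_missing_max"]:
            reasons.append("vitals_below_threshold")
        if g_sd > 0 and mean_missing[s] > g_mean + th["sd_mult"] * g_sd:
            reasons.append("missing_gt_2sd")
        if t_sd > 0 and tvar[s] > t_mean + th["sd_mult"] * t_sd:
            reasons.append("temporal_var_gt_2sd")
        if shift[s] > th["max_shift_days"]:
            reasons.append("date_shift_gt_7d")
        if clustering is not None and s not in clustering.retained_sites:
            reasons.append("cluster_dropout")
        out.append({
            "site_id": s,
            "mean_missing": float(mean_missing[s]),
            "vitals_missing": float(vitals_missing[s]),
            "temporal_variance": float(tvar[s]),
            "max_date_shift_days": int(shift[s]),
            "excluded": bool(reasons),
            "reasons": "|".join(reasons),
        })
    return pd.DataFrame(out)


def patient_missingness_table(bundle: EHRBundle, cohort: pd.DataFrame,
                              variables: list[str],
                              window: str = "whole_visit",
                              admission_days: int = 2) -> pd.DataFrame:
    """Per-variable missingness and summary of per-patient first values.

    ``window`` is either ``whole_visit`` (any record during the macrovisit)
    or ``admission`` (within ``admission_days`` of the macrovisit start).
    The representative per-patient value is the first one in the window;
    reported as median (q1, q3).
    """
    if window not in ("whole_visit", "admission"):
        raise ValueError(f"unknown window {window!r}")
    inc = cohort[cohort["included"]]
    n_total = len(inc)
    rows = _cohort_measurements(bundle, cohort, variables)
    if window == "admission":
        lim = rows["macrovisit_start"] + pd.Timedelta(days=admission_days)
        rows = rows[rows["date"] <= lim]
    first = (rows.sort_values(["person_id", "variable", "date"])
             .drop_duplicates(["person_id", "variable"]))
    out = []
    for var in variables:
        vals = first.loc[first["variable"] == var, "value"]
        n_non = len(vals)
        q = vals.quantile([0.25, 0.5, 0.75]) if n_non else None
        out.append({
            "variable": var,
            "n_nonmissing": n_non,
            "n_missing": n_total - n_non,
            "pct_missing": (100.0 * (n_total - n_non) / n_total
                            if n_total else float("nan")),
            "median": None if q is None else float(q.loc[0.5]),
            "q1": None if q is None else float(q.loc[0.25]),
            "q3": None if q is None else float(q.loc[0.75]),
        })
    return pd.DataFrame(out)
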