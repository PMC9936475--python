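"""Synthetic multi-site EHR generator with planted, configurable pathologies.

Emulates the data-quality failure modes documented for large federated
COVID-19 EHR repositories, so that every curation stage can be exercised and
its estimates checked against planted ground truth without access to
restricted data:

* heterogeneous per-site variable capture, with calendar-month modulation;
* two drug documentation paradigms — per-day duplicated single-day rows
  (some with absent end dates sharing the start) and multi-day sub-intervals,
  optionally containing a reversed start/end pair;
* claim-inferred truncation of treatment courses to a single day,
  concentrated on one designated site;
* variable prior-history depth with a hard lookback floor, and comorbidity /
  prior-medication prevalences that rise with available history;
* death dates offset from the visit end date, with a small excess of late
  recordings and rare post-death "billing artifact" visits;
* discharge-disposition reporting restricted to a subset of source CDMs.

Every random draw flows from ``SimConfig.seed`` through per-site
``numpy.random.SeedSequence`` spawns, so a config fully determines the bundle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .tables import EHRBundle, MEASUREMENT_VARIABLES, coerce_table

# ---------------------------------------------------------------------------
# Toy concept vocabulary
# ---------------------------------------------------------------------------

REMDESIVIR = 100
DEXAMETHASONE = 200

CONCEPTS = [
    (100, "remdesivir", "ingredient"),
    (101, "remdesivir 100 MG Injection", "clinical_drug"),
    (102, "remdesivir Injection", "clinical_drug"),
    (103, "20 ML remdesivir 5 MG/ML Injection", "branded_drug"),
    (200, "dexamethasone", "ingredient"),
    (201, "dexamethasone 2 MG Oral Tablet", "clinical_drug"),
    (202, "dexamethasone 0.5 MG Oral Tablet", "clinical_drug"),
    (301, "hypertension", "other"),
    (302, "diabetes", "other"),
    (303, "coronary artery disease", "other"),
    (304, "congestive heart failure", "other"),
    (305, "COPD", "other"),
    (306, "cerebrovascular disease", "other"),
    (307, "chronic kidney disease", "other"),
    (308, "cardiac arrhythmia", "other"),
    (309, "tobacco smoking", "other"),
    (310, "malignancy", "other"),
    (410, "lisinopril", "ingredient"),
    (420, "losartan", "ingredient"),
    (430, "atorvastatin", "ingredient"),
    (501, "invasive mechanical ventilation", "other"),
    (502, "ECMO", "other"),
    (601, "myocardial infarction", "other"),
    (700, "COVID-19", "other"),
]

# direct edges; ingredients also carry self-loops (added in concept_tables)
ANCESTOR_EDGES = [
    (100, 101), (100, 102), (102, 103),
    (200, 201), (200, 202),
]

#: Concept-set config usable with the continuity / outcomes modules.
DEFAULT_CONCEPT_SETS: dict[str, set[int]] = {
    "hypertension": {301}, "diabetes": {302}, "CAD": {303}, "CHF": {304},
    "COPD": {305}, "cerebrovascular": {306}, "CKD": {307},
    "arrhythmia": {308}, "smoking": {309}, "malignancy": {310},
    "ventilation_ecmo": {501, 502}, "MI": {601},
}

DEFAULT_MED_SETS: dict[str, set[int]] = {
    "ACEI": {410}, "ARB": {420}, "statin": {430},
}

# remdesivir rows are coded at these levels with roughly the observed mix:
# overwhelmingly at the bare ingredient, the rest at clinical/branded drugs.
_REM_CONCEPT_MIX = {100: 0.885, 101: 0.105, 102: 0.0080, 103: 0.0013}
_DEX_CONCEPT_MIX = {200: 0.41, 201: 0.35, 202: 0.24}


def concept_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    concept = pd.DataFrame(CONCEPTS, columns=["concept_id", "name", "level"])
    ingredients = concept.loc[concept["level"] == "ingredient", "concept_id"]
    edges = ANCESTOR_EDGES + [(i, i) for i in ingredients]
    ancestor = pd.DataFrame(edges, columns=["ancestor_id", "descendant_id"])
    return (coerce_table("concept", concept),
            coerce_table("concept_ancestor", ancestor))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _lognorm_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    # quartile-matched log-normal
    return float(np.log(median)), float(np.log(q3 / q1) / (2 * 0.6744898))


#: value model per measurement variable: ("lognorm", mu, sigma) or
#: ("norm", mean, sd); medians/IQRs follow typical hospitalized-COVID labs.
VALUE_MODELS: dict[str, tuple] = {
    "BMI": ("lognorm", *_lognorm_params(29, 25, 35)),
    "creatinine": ("lognorm", *_lognorm_params(0.94, 0.73, 1.40)),
    "bilirubin": ("lognorm", *_lognorm_params(0.50, 0.37, 0.70)),
    "PaO2": ("lognorm", *_lognorm_params(79, 71, 90)),
    "FiO2": ("lognorm", *_lognorm_params(0.69, 0.52, 0.83)),
    "body_temperature": ("norm", 36.8, 0.35),
    "WBC": ("lognorm", *_lognorm_params(7.8, 5.6, 10.7)),
    "ferritin": ("lognorm", *_lognorm_params(555, 270, 1116)),
    "CRP": ("lognorm", *_lognorm_params(52, 23, 98)),
    "IL-6": ("lognorm", *_lognorm_params(34.5, 32.6, 34.9)),
    "SpO2": ("norm", 95.0, 1.8),
    "respiration_rate": ("norm", 19.5, 2.2),
    "heart_rate": ("norm", 86.0, 14.0),
}

#: default probability that a hospitalized patient has >=1 recorded value,
#: per variable — the observed non-missing fractions in the study population.
DEFAULT_CAPTURE: dict[str, float] = {
    "BMI": 0.762, "creatinine": 0.428, "bilirubin": 0.194, "PaO2": 0.011,
    "FiO2": 0.024, "body_temperature": 0.876, "WBC": 0.346,
    "ferritin": 0.018, "CRP": 0.032, "IL-6": 0.0005, "SpO2": 0.898,
    "respiration_rate": 0.898, "heart_rate": 0.90,
}

#: prevalence (no-history, 1-23mo, 24+mo) — documented-comorbidity gradients
#: steepen with available history, the signature of EHR discontinuity.
DEFAULT_COMORBIDITY_PREVALENCE: dict[str, tuple[float, float, float]] = {
    "hypertension": (0.45, 0.59, 0.74),
    "diabetes": (0.33, 0.36, 0.45),
    "CAD": (0.11, 0.19, 0.30),
    "CHF": (0.13, 0.21, 0.30),
    "COPD": (0.074, 0.12, 0.18),
    "cerebrovascular": (0.068, 0.12, 0.19),
    "CKD": (0.13, 0.22, 0.35),
    "arrhythmia": (0.29, 0.35, 0.47),
    "smoking": (0.061, 0.12, 0.12),
    "malignancy": (0.059, 0.16, 0.21),
}

DEFAULT_MED_PREVALENCE: dict[str, tuple[float, float, float]] = {
    "ACEI": (0.039, 0.15, 0.25),
    "ARB": (0.031, 0.11, 0.19),
    "statin": (0.066, 0.26, 0.45),
}

HISTORY_GROUPS = ("none", "under_24", "cap_24plus")

DISPOSITIONS = ["Discharged home", "Skilled nursing facility",
                "Home health service", "Rehabilitation facility",
                "Hospice", "Left against medical advice"]
_DISPO_PROBS = [0.70, 0.12, 0.08, 0.05, 0.03, 0.02]


class SimConfig(BaseModel):
    """Full specification of one synthetic multi-site extract."""

    n_sites: int = 4
    patients_per_site: int = 500
    seed: int = 0

    cohort_start: str = "2020-03-01"
    cohort_end: str = "2021-09-01"
    lookback_floor: str = "2018-01-01"

    # measurement capture
    capture: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_CAPTURE))
    site_capture: dict[str, dict[str, float]] = Field(default_factory=dict)
    temporal_multipliers: dict[str, dict[str, float]] = Field(default_factory=dict)

    # drug documentation
    default_paradigm: str = "mixed"  # daily_duplicated | multiday_interval | mixed
    site_paradigm: dict[str, str] = Field(default_factory=dict)
    p_reversed: float = 0.10
    p_open: float = 0.25
    treated_fraction: float = 0.5
    course_days: dict[int, float] = Field(default_factory=lambda: {5: 0.8, 10: 0.2})
    single_day_claim_fraction: float = 0.55
    claim_site: Optional[str] = None  # defaults to the first site
    claim_site_share: float = 0.73
    dexamethasone_fraction: float = 0.3

    # history / continuity
    history_weights: tuple[float, float, float] = (0.288, 0.225, 0.487)
    no_history_overrides: dict[str, dict[str, float]] = Field(default_factory=dict)
    comorbidity_prevalence: dict[str, tuple[float, float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCE))
    med_prevalence: dict[str, tuple[float, float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_MED_PREVALENCE))

    # outcomes
    ventilation_prob: tuple[float, float, float] = (0.19, 0.091, 0.088)
    death_prob: tuple[float, float, float] = (0.14, 0.11, 0.11)
    death_offset_probs: dict[int, float] = Field(default_factory=lambda: {
        -2: 0.004, -1: 0.05, 0: 0.80, 1: 0.09, 2: 0.035, 3: 0.013,
        4: 0.005, 5: 0.003})
    p_subsequent_visit: float = 0.02
    p_carried_forward_mi: float = 0.05
    p_acute_mi: float = 0.05

    # demographics / visits
    p_missing_sex: float = 0.01
    p_missing_birth_year: float = 0.005
    p_under18: float = 0.02
    female_prob: tuple[float, float, float] = (0.39, 0.50, 0.53)
    p_one_day_stay: float = 0.05
    p_split_visit: float = 0.30
    p_ed_visit: float = 0.20

    date_shift: dict[str, int] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.n_sites < 1 or self.patients_per_site < 1:
            raise ValueError("n_sites and patients_per_site must be >= 1")
        probs = [self.p_reversed, self.p_open, self.treated_fraction,
                 self.single_day_claim_fraction, self.claim_site_share,
                 self.p_missing_sex, self.p_under18, *self.history_weights]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.history_weights) - 1.0) > 1e-9:
            raise ValueError("history_weights must sum to 1")
        if abs(sum(self.death_offset_probs.values()) - 1.0) > 1e-9:
            raise ValueError("death_offset_probs must sum to 1")
        if self.default_paradigm not in ("daily_duplicated",
                                         "multiday_interval", "mixed"):
            raise ValueError(f"unknown paradigm {self.default_paradigm!r}")
        return self

    def site_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_sites)]

    def capture_for(self, site: str, var: str) -> float:
        return float(self.site_capture.get(site, {}).get(
            var, self.capture.get(var, 0.0)))


@dataclass
class GroundTruth:
    """Planted quantities, recorded before documentation corruption."""

    patients: pd.DataFrame       # one row per person, see generate_bundle
    site_capture: pd.DataFrame   # site_id x variable base capture probability
    config: SimConfig


# ---------------------------------------------------------------------------
# Drug documentation corruption
# ---------------------------------------------------------------------------

def corrupt_drug_documentation(
    true_courses: list[tuple[pd.Timestamp, pd.Timestamp]],
    paradigm: str,
    seed_or_rng,
    p_reversed: float = 0.10,
    p_open: float = 0.25,
    max_duplicates: int = 2,
) -> list[tuple[pd.Timestamp, Optional[pd.Timestamp]]]:
    """Render true exposure courses as dirty raw rows under one paradigm.

    ``daily_duplicated`` emits one bounded (d, d) row per covered day plus
    0-``max_duplicates`` duplicate rows, each either bounded or open (end
    absent) sharing the same start date. ``multiday_interval`` splits the course into 1-3
    contiguous sub-intervals sharing boundary days, optionally injecting a
    reversed (end < start) copy of a covered pair and a duplicate open row.
    ``mixed`` picks one of the two per course.

    The dirty rows always cover exactly the course's day set once the
    standard cleaning rules (drop reversed, open -> single day, dedupe,
    merge) are applied, so era reconstruction round-trips to the truth.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    if paradigm not in ("daily_duplicated", "multiday_interval", "mixed"):
        raise ValueError(f"unknown paradigm {paradigm!r}")
    day = pd.Timedelta(days=1)
    rows: list[tuple[pd.Timestamp, Optional[pd.Timestamp]]] = []
    for start, end in true_courses:
        if end < start:
            raise ValueError("true courses must have start <= end")
        par = paradigm
        if par == "mixed":
            par = ("daily_duplicated" if rng.random() < 0.5
                   else "multiday_interval")
        if par == "daily_duplicated":
            d = start
            while d <= end:
                rows.append((d, d))
                n_dup = (int(rng.integers(0, max_duplicates + 1))
                         if max_duplicates else 0)
                for _ in range(n_dup):
                    rows.append((d, None) if rng.random() < p_open else (d, d))
                d = d + day
        else:
            n_days = (end - start).days + 1
            n_sub = int(rng.integers(1, min(3, n_days) + 1))
            # boundary days shared between consecutive sub-intervals
            if n_sub > 1:
                cuts = np.sort(rng.choice(np.arange(1, n_days), size=n_sub - 1,
                                          replace=False))
            else:
                cuts = np.array([], dtype=int)
            bounds = [0, *cuts.tolist(), n_days - 1]
            subs = [(start + bounds[i] * day, start + bounds[i + 1] * day)
                    for i in range(n_sub)]
            rows.extend(subs)
            two_day = [(s, e) for s, e in subs if e > s]
            if two_day and rng.random() < p_reversed:
                s, _ = two_day[int(rng.integers(len(two_day)))]
                rows.append((s + day, s))  # reversed pair over covered days
            if rng.random() < p_open:
                s, _ = subs[int(rng.integers(len(subs)))]
                rows.append((s, None))
    return rows


# ---------------------------------------------------------------------------
# Bundle generation
# ---------------------------------------------------------------------------

def _sample_values(rng: np.random.Generator, var: str, n: int) -> np.ndarray:
    kind, a, b = VALUE_MODELS[var]
    if kind == "lognorm":
        v = np.exp(rng.normal(a, b, size=n))
    else:
        v = rng.normal(a, b, size=n)
    if var == "FiO2":
        v = np.clip(v, 0.21, 1.0)
    if var == "SpO2":
        v = np.clip(v, 50.0, 100.0)
    return v


def _choice(rng, items, probs, size):
    probs = np.asarray(probs, dtype=float)
    return rng.choice(np.asarray(items, dtype=object), size=size,
                      p=probs / probs.sum())


def generate_bundle(config: SimConfig) -> tuple[EHRBundle, GroundTruth]:
    """Generate one multi-site bundle plus its planted ground truth.

    ``GroundTruth.patients`` has one row per person with: ``person_id``,
    ``site_id``, ``index_date``, ``admission_date``, ``discharge_date``,
    ``age``, ``history_group``, ``months_history``, ``earliest_visit_date``,
    ``treated``, ``course_start``, ``course_end``, ``truncated``, ``died``,
    ``death_offset``, ``subsequent_visit``, ``ventilated``,
    ``carried_forward_mi`` and the per-patient comorbidity indicator columns.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    site_seeds = root.spawn(cfg.n_sites + 1)
    day = pd.Timedelta(days=1)
    start = pd.Timestamp(cfg.cohort_start)
    end = pd.Timestamp(cfg.cohort_end)
    floor = pd.Timestamp(cfg.lookback_floor)
    window_days = (end - start).days

    site_ids = cfg.site_ids()
    claim_site = cfg.claim_site or site_ids[0]
    sites_df = pd.DataFrame({
        "site_id": site_ids,
        "source_cdm": [("OMOP", "PCORnet", "ACT", "TriNetX")[i % 4]
                       for i in range(cfg.n_sites)],
        "max_date_shift_days": [abs(cfg.date_shift.get(s, 0))
                                for s in site_ids],
    })

    persons, visits, drugs, meas, conds, deaths = [], [], [], [], [], []
    gt_rows = []
    offsets = sorted(cfg.death_offset_probs)
    offset_p = [cfg.death_offset_probs[o] for o in offsets]
    group_idx = {g: i for i, g in enumerate(HISTORY_GROUPS)}

    for si, site in enumerate(site_ids):
        rng = np.random.default_rng(site_seeds[si])
        n = cfg.patients_per_site
        cdm = sites_df.loc[si, "source_cdm"]
        reports_dispo = cdm == "OMOP"
        paradigm = cfg.site_paradigm.get(site, cfg.default_paradigm)
        shift = int(cfg.date_shift.get(site, 0)) * day

        pids = [f"{site}-P{j:05d}" for j in range(n)]
        admit = start + pd.to_timedelta(
            rng.integers(0, window_days, size=n), unit="D")
        admit_month = admit.strftime("%Y-%m")

        groups = _choice(rng, HISTORY_GROUPS, cfg.history_weights, n)
        overrides = cfg.no_history_overrides.get(site, {})
        if overrides:
            for j in range(n):
                p_none = overrides.get(admit_month[j])
                if p_none is not None:
                    if rng.random() < p_none:
                        groups[j] = "none"
                    else:
                        groups[j] = ("under_24" if rng.random() < 0.4
                                     else "cap_24plus")
        gi = np.array([group_idx[g] for g in groups])

        age_mu = np.array([59.0, 60.0, 65.0])[gi]
        age = np.clip(np.round(rng.normal(age_mu, 16.0, size=n)), 18, 99)
        under18 = rng.random(n) < cfg.p_under18
        age[under18] = rng.integers(10, 18, size=int(under18.sum()))
        birth_year = admit.year.to_numpy() - age.astype(int)
        miss_by = rng.random(n) < cfg.p_missing_birth_year
        p_f = np.array(cfg.female_prob)[gi]
        sex = np.where(rng.random(n) < p_f, "female", "male").astype(object)
        sex[rng.random(n) < cfg.p_missing_sex] = None
        race = _choice(rng, ["White", "Black or African American", "Asian",
                             "Other/Unknown", None],
                       [0.50, 0.22, 0.035, 0.215, 0.03], n)
        ethnicity = _choice(rng, ["Not Hispanic or Latino",
                                  "Hispanic or Latino", "Unknown"],
                            [0.74, 0.19, 0.07], n)

        index_date = admit - pd.to_timedelta(
            rng.integers(0, 3, size=n), unit="D")
        one_day = rng.random(n) < cfg.p_one_day_stay
        length = np.where(one_day, 1, 3 + rng.poisson(5.0, size=n))
        discharge = admit + pd.to_timedelta(length - 1, unit="D")

        for j in range(n):
            persons.append((pids[j], site,
                            None if miss_by[j] else int(birth_year[j]),
                            sex[j], race[j], ethnicity[j]))
            a, dsc, L = admit[j], discharge[j], int(length[j])

            # index COVID diagnosis
            conds.append((pids[j], site, 700, index_date[j] + shift))

            # hospitalization visit rows, sometimes split / with an ED visit
            vn = 0
            if L >= 4 and rng.random() < cfg.p_split_visit:
                k = int(rng.integers(1, L - 1))
                for s_, e_ in ((a, a + k * day), (a + k * day, dsc)):
                    visits.append((f"{pids[j]}-V{vn}", pids[j], site,
                                   "inpatient", s_ + shift, e_ + shift, None))
                    vn += 1
            else:
                visits.append((f"{pids[j]}-V{vn}", pids[j], site, "inpatient",
                               a + shift, dsc + shift, None))
                vn += 1
            if rng.random() < cfg.p_ed_visit:
                visits.append((f"{pids[j]}-V{vn}", pids[j], site, "emergency",
                               a + shift, a + shift, None))
                vn += 1

            # prior history visits
            g = groups[j]
            max_back = (a - floor).days
            earliest = None
            months = 0
            if g == "under_24":
                back = int(rng.integers(31, min(729, max_back) + 1))
                earliest = a - back * day
                months = int((back) // 30.4375)
                for _ in range(int(rng.integers(0, 3))):
                    d_ = earliest + int(rng.integers(0, back)) * day
                    visits.append((f"{pids[j]}-V{vn}", pids[j], site,
                                   "outpatient", d_ + shift, d_ + shift,
                                   None))
                    vn += 1
            elif g == "cap_24plus":
                back = int(rng.integers(731, max_back + 1))
                earliest = a - back * day
                months = 24
            if earliest is not None:
                visits.append((f"{pids[j]}-V{vn}", pids[j], site,
                               "outpatient", earliest + shift,
                               earliest + shift, None))
                vn += 1

            # comorbidities & prior medications (dated before admission)
            gt_com = {}
            for name, prev in cfg.comorbidity_prevalence.items():
                has = rng.random() < prev[group_idx[g]]
                gt_com[name] = bool(has)
                if has:
                    cid = next(iter(DEFAULT_CONCEPT_SETS[name]))
                    back_ = int(rng.integers(1, min(365, max(2, max_back))))
                    conds.append((pids[j], site, cid, a - back_ * day + shift))
            for name, prev in cfg.med_prevalence.items():
                if rng.random() < prev[group_idx[g]]:
                    cid = next(iter(DEFAULT_MED_SETS[name]))
                    back_ = int(rng.integers(31, 365))
                    d_ = a - back_ * day
                    drugs.append((pids[j], site, cid, d_ + shift, d_ + shift,
                                  "EHR"))

            # ventilation on admission
            vent = rng.random() < cfg.ventilation_prob[group_idx[g]]
            if vent:
                cid = 502 if rng.random() < 0.1 else 501
                conds.append((pids[j], site, cid,
                              a + int(rng.integers(0, 2)) * day + shift))

            # acute vs carried-forward MI codes
            cf_mi = rng.random() < cfg.p_carried_forward_mi
            acute_day = -1
            if cf_mi:
                for t in range(L):
                    conds.append((pids[j], site, 601, a + t * day + shift))
            elif rng.random() < cfg.p_acute_mi:
                acute_day = int(rng.integers(0, L))
                conds.append((pids[j], site, 601,
                              a + acute_day * day + shift))

            # death
            died = rng.random() < cfg.death_prob[group_idx[g]]
            offset = 0
            subsequent = False
            if died:
                offset = int(rng.choice(offsets, p=offset_p))
                dd = dsc + offset * day
                deaths.append((pids[j], site, dd + shift))
                if rng.random() < cfg.p_subsequent_visit:
                    subsequent = True
                    d_ = dd + 30 * day
                    visits.append((f"{pids[j]}-V{vn}", pids[j], site,
                                   "outpatient", d_ + shift, d_ + shift,
                                   None))
                    vn += 1

            # discharge disposition on the last inpatient row
            if reports_dispo and rng.random() < 0.85:
                dispo = ("Expired" if died and offset <= 1 else
                         str(_choice(rng, DISPOSITIONS, _DISPO_PROBS, 1)[0]))
                for vi in range(len(visits) - 1, -1, -1):
                    row = visits[vi]
                    if row[1] == pids[j] and row[3] == "inpatient":
                        visits[vi] = row[:6] + (dispo,)
                        break

            # remdesivir course (true, pre-corruption); only stays that can
            # hold a full course are treated, so single-day eras below come
            # solely from the claim-truncation artifact
            treated = L >= 5 and rng.random() < cfg.treated_fraction
            c_start = c_end = None
            if treated:
                durs = sorted(cfg.course_days)
                dp = np.array([cfg.course_days[d_] for d_ in durs])
                dur = int(rng.choice(durs, p=dp / dp.sum()))
                off0 = int(rng.integers(0, 3))
                if off0 + dur > L:
                    dur = 5 if L >= 5 + off0 else L - off0
                c_start = a + off0 * day
                c_end = c_start + (dur - 1) * day

            gt_rows.append({
                "person_id": pids[j], "site_id": site,
                "index_date": index_date[j], "admission_date": a,
                "discharge_date": dsc, "length_days": L,
                "age": int(age[j]),
                "missing_sex": sex[j] is None,
                "missing_birth_year": bool(miss_by[j]),
                "history_group": g, "months_history": months,
                "earliest_visit_date": earliest,
                "treated": bool(treated), "course_start": c_start,
                "course_end": c_end, "truncated": False,
                "paradigm": paradigm,
                "died": bool(died), "death_offset": offset if died else None,
                "subsequent_visit": subsequent, "ventilated": bool(vent),
                "carried_forward_mi": bool(cf_mi),
                "acute_mi_day": acute_day,
                **gt_com,
            })

        # measurements, vectorized per variable
        months_mult = cfg.temporal_multipliers.get(site, {})
        for var in MEASUREMENT_VARIABLES:
            p = cfg.capture_for(site, var)
            if months_mult:
                mult = np.array([months_mult.get(m, 1.0)
                                 for m in admit_month])
                p_eff = np.clip(p * mult, 0.0, 1.0)
            else:
                p_eff = p
            captured = np.flatnonzero(rng.random(n) < p_eff)
            if captured.size == 0:
                continue
            n_rows = rng.integers(1, 3, size=captured.size)
            idx = np.repeat(captured, n_rows)
            frac = rng.random(idx.size)
            dates = (admit[idx]
                     + pd.to_timedelta(
                         np.floor(frac * length[idx]).astype(int), unit="D"))
            vals = _sample_values(rng, var, idx.size)
            for pid_i, d_, v_ in zip(idx, dates, vals):
                meas.append((pids[pid_i], site, var, float(v_), d_ + shift))

    # --- claim truncation, allocated across sites with a designated share ---
    gt = pd.DataFrame(gt_rows)
    rng_claim = np.random.default_rng(site_seeds[-1])
    treated_idx = gt.index[gt["treated"]].to_numpy()
    total_t = int(round(cfg.single_day_claim_fraction * treated_idx.size))
    des_pool = gt.index[gt["treated"] & (gt["site_id"] == claim_site)].to_numpy()
    oth_pool = gt.index[gt["treated"] & (gt["site_id"] != claim_site)].to_numpy()
    n_des = min(int(round(cfg.claim_site_share * total_t)), des_pool.size)
    n_oth = min(total_t - n_des, oth_pool.size)
    chosen = np.concatenate([
        rng_claim.choice(des_pool, size=n_des, replace=False),
        rng_claim.choice(oth_pool, size=n_oth, replace=False),
    ]) if total_t else np.array([], dtype=int)
    gt.loc[chosen, "truncated"] = True
    gt.loc[chosen, "course_end"] = gt.loc[chosen, "course_start"]

    # --- render drug rows through the documentation paradigms ---
    rem_ids = np.array(sorted(_REM_CONCEPT_MIX))
    rem_p = np.array([_REM_CONCEPT_MIX[i] for i in rem_ids], dtype=float)
    rem_p /= rem_p.sum()
    dex_ids = np.array(sorted(_DEX_CONCEPT_MIX))
    dex_p = np.array([_DEX_CONCEPT_MIX[i] for i in dex_ids], dtype=float)
    dex_p /= dex_p.sum()
    shift_by_site = {s: int(cfg.date_shift.get(s, 0)) for s in site_ids}
    for row in gt.itertuples():
        if not row.treated:
            continue
        sh = shift_by_site[row.site_id] * day
        if row.truncated:
            raw = [(row.course_start, row.course_start),
                   (row.course_start, None)]
            label = "Inferred from claim"
        else:
            raw = corrupt_drug_documentation(
                [(row.course_start, row.course_end)], row.paradigm,
                rng_claim, cfg.p_reversed, cfg.p_open)
            label = "EHR" if rng_claim.random() < 0.95 else None
        for s_, e_ in raw:
            cid = int(rng_claim.choice(rem_ids, p=rem_p))
            drugs.append((row.person_id, row.site_id, cid, s_ + sh,
                          None if e_ is None else e_ + sh, label))
        if rng_claim.random() < cfg.dexamethasone_fraction:
            d0 = row.admission_date + int(rng_claim.integers(0, 3)) * day
            d1 = min(d0 + int(rng_claim.integers(2, 9)) * day,
                     row.discharge_date)
            if d1 >= d0:
                cid = int(rng_claim.choice(dex_ids, p=dex_p))
                drugs.append((row.person_id, row.site_id, cid, d0 + sh,
                              d1 + sh, "EHR"))

    concept, ancestor = concept_tables()
    bundle = EHRBundle(
        person=coerce_table("person", pd.DataFrame(
            persons, columns=["person_id", "site_id", "birth_year", "sex",
                              "race", "ethnicity"])),
        visit_occurrence=coerce_table("visit_occurrence", pd.DataFrame(
            visits, columns=["visit_id", "person_id", "site_id", "visit_kind",
                             "start_date", "end_date",
                             "discharge_disposition"])),
        drug_exposure=coerce_table("drug_exposure", pd.DataFrame(
            drugs, columns=["person_id", "site_id", "concept_id",
                            "start_date", "end_date", "drug_type_label"])),
        measurement=coerce_table("measurement", pd.DataFrame(
            meas, columns=["person_id", "site_id", "variable", "value",
                           "date"])),
        condition_occurrence=coerce_table("condition_occurrence", pd.DataFrame(
            conds, columns=["person_id", "site_id", "concept_id", "date"])),
        death=coerce_table("death", pd.DataFrame(
            deaths, columns=["person_id", "site_id", "death_date"])),
        concept=concept,
        concept_ancestor=ancestor,
        site=coerce_table("site", sites_df),
        provenance={"dialect_version": "1.0", "generator_seed": cfg.seed},
    )
    site_capture = pd.DataFrame(
        [{"site_id": s, **{v: cfg.capture_for(s, v)
                           for v in MEASUREMENT_VARIABLES}}
         for s in site_ids])
    gt["index_date"] = pd.to_datetime(gt["index_date"])
    return bundle, GroundTruth(patients=gt, site_capture=site_capture,
                               config=cfg)


def index_events(gt: GroundTruth) -> pd.Series:
    """Per-person first COVID-positive date from the planted ground truth."""
    return gt.patients.set_index("person_id")["index_date"]
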