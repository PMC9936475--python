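import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ehrqc import (build_drug_eras, claim_inferred_breakdown,
                   concept_distribution, descendants_of_ingredient,
                   duration_distribution)
from ehrqc.tables import coerce_table

D = pd.Timestamp


def _rows(triples, pid="P1", site="S01", label="EHR"):
    return coerce_table("drug_exposure", pd.DataFrame(
        [{"person_id": p if isinstance(p, str) else pid, "site_id": site,
          "concept_id": 100, "start_date": s, "end_date": e,
          "drug_type_label": label}
         for p, s, e in triples]))


# ---------------------------------------------------------------- hierarchy

def test_descendants_trivial_and_chain():
    anc = pd.DataFrame({"ancestor_id": [1, 1, 2], "descendant_id": [1, 2, 3]})
    assert descendants_of_ingredient(anc, 3) == {3}
    assert descendants_of_ingredient(anc, 1) == {1, 2, 3}


def test_descendants_match_reachability_on_random_dags():
    rng = np.random.default_rng(8)
    for _ in range(30):
        n = int(rng.integers(3, 15))
        edges = [(int(a), int(b)) for a in range(n) for b in range(a + 1, n)
                 if rng.random() < 0.3]
        anc = pd.DataFrame(edges or [(0, 0)],
                           columns=["ancestor_id", "descendant_id"])
        g = nx.DiGraph(edges)
        g.add_nodes_from(range(n))
        for root in range(n):
            assert (descendants_of_ingredient(anc, root)
                    == nx.descendants(g, root) | {root})


def test_concept_distribution_counts():
    concept = pd.DataFrame({"concept_id": [100, 101, 102],
                            "name": ["a", "b", "c"],
                            "level": ["ingredient"] * 3})
    rows = pd.DataFrame({
        "concept_id": [100] * 885 + [101] * 100 + [102] * 15,
        "person_id": "P", "site_id": "S",
    })
    dist = concept_distribution(rows, {100, 101, 102}, concept)
    assert list(dist["count"]) == [885, 100, 15]
    assert list(dist["percent"]) == [88.5, 10.0, 1.5]
    assert dist["percent"].sum() == pytest.approx(100.0)

    empty = concept_distribution(rows.iloc[:0], {100}, concept)
    assert empty.empty


# ---------------------------------------------------------------- eras

def test_daily_duplicated_worked_example():
    """Duplicated single-day rows (some open-ended) spanning 2020-12-31
    through 2021-01-04 consolidate into one era of 5 exposure days."""
    triples = []
    for d in pd.date_range("2020-12-31", "2021-01-04"):
        triples += [("P1", d, d), ("P1", d, d), ("P1", d, None)]
    eras, log = build_drug_eras(_rows(triples))
    assert len(eras) == 1
    assert int(eras["exposure_days"].iloc[0]) == 5
    assert log.duplicates_removed == 10
    assert log.open_closed == 5


def test_reversed_interval_worked_example():
    """Rows 23->24, 24->23 (reversed), 24->27 Nov 2020: the reversed row is
    discarded and one 5-day era remains."""
    eras, log = build_drug_eras(_rows([
        ("P1", D("2020-11-23"), D("2020-11-24")),
        ("P1", D("2020-11-24"), D("2020-11-23")),
        ("P1", D("2020-11-24"), D("2020-11-27")),
    ]))
    assert log.reversed_dropped == 1
    assert len(eras) == 1
    assert eras["start_date"].iloc[0] == D("2020-11-23")
    assert eras["end_date"].iloc[0] == D("2020-11-27")
    assert int(eras["exposure_days"].iloc[0]) == 5


def _random_dirty(rng, n_sets):
    base = D("2020-06-01")
    rows = []
    for i in range(n_sets):
        for _ in range(int(rng.integers(1, 9))):
            s = int(rng.integers(0, 30))
            r = rng.random()
            if r < 0.15:
                e = s - int(rng.integers(1, 5))  # reversed
            elif r < 0.45:
                e = None                         # open
            else:
                e = s + int(rng.integers(0, 6))
            rows.append({"person_id": f"P{i:04d}", "site_id": "S01",
                         "concept_id": 100,
                         "start_date": base + pd.Timedelta(days=s),
                         "end_date": (None if e is None
                                      else base + pd.Timedelta(days=e)),
                         "drug_type_label": "EHR"})
    return coerce_table("drug_exposure", pd.DataFrame(rows))


def _day_union(df):
    """Brute-force day sets per person after rules 1-2."""
    out = {}
    for row in df.itertuples():
        e = row.end_date
        if pd.isna(e):
            e = row.start_date
        if e < row.start_date:
            continue
        days = out.setdefault(row.person_id, set())
        d = row.start_date
        while d <= e:
            days.add(d)
            d += pd.Timedelta(days=1)
    return out


def test_era_day_coverage_equals_union_oracle():
    """Random dirty row sets: era day coverage equals the brute-force union
    of retained rows' day sets (gap 0)."""
    df = _random_dirty(np.random.default_rng(3), 300)
    eras, _ = build_drug_eras(df)
    truth = _day_union(df)
    got = {}
    for row in eras.itertuples():
        days = got.setdefault(row.person_id, set())
        d = row.start_date
        while d <= row.end_date:
            days.add(d)
            d += pd.Timedelta(days=1)
    assert got == truth
    # total covered days conserved
    assert int(eras["exposure_days"].sum()) == sum(
        len(v) for v in truth.values())


def test_era_building_order_invariant_and_idempotent():
    df = _random_dirty(np.random.default_rng(5), 50)
    eras1, _ = build_drug_eras(df)
    shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
    eras2, _ = build_drug_eras(shuffled)
    key = ["person_id", "start_date", "end_date", "exposure_days"]
    pd.testing.assert_frame_equal(
        eras1[key].sort_values(key).reset_index(drop=True),
        eras2[key].sort_values(key).reset_index(drop=True))
    again, log = build_drug_eras(
        eras1.assign(concept_id=100, drug_type_label="EHR"))
    assert log.reversed_dropped == 0 and log.duplicates_removed == 0
    pd.testing.assert_frame_equal(
        again[key].reset_index(drop=True),
        eras1[key].sort_values(key).reset_index(drop=True))


def test_era_count_monotone_in_gap():
    df = _random_dirty(np.random.default_rng(6), 80)
    counts = [len(build_drug_eras(df, gap_days=g)[0]) for g in (0, 3, 30)]
    assert counts[0] >= counts[1] >= counts[2]


def test_same_start_bounded_plus_unbounded_collapse():
    """A single bounded one-day interval plus an unbounded row sharing the
    start date collapse through the open-interval and dedup rules alone."""
    eras, log = build_drug_eras(_rows([("P1", D("2021-03-01"),
                                        D("2021-03-01")),
                                       ("P1", D("2021-03-01"), None)]))
    assert len(eras) == 1
    assert int(eras["exposure_days"].iloc[0]) == 1
    assert log.duplicates_removed == 1


# ---------------------------------------------------------------- durations

def _cohort_for(pid, start, end):
    return pd.DataFrame([{
        "person_id": pid, "site_id": "S01", "included": True,
        "macrovisit_start": start, "macrovisit_end": end}])


def test_duration_histogram_of_clean_courses():
    triples = []
    for i in range(20):
        s = D("2020-06-01") + pd.Timedelta(days=3 * i)
        triples.append((f"Q{i}", s, s + pd.Timedelta(days=4)))
    eras, _ = build_drug_eras(_rows(triples))
    hist = duration_distribution(eras, pd.DataFrame(
        columns=["person_id", "macrovisit_end"]).assign(included=True),
        pd.DataFrame(columns=["person_id", "death_date"]))
    assert list(hist["exposure_days"]) == [5]
    assert hist["n_patients"].iloc[0] == 20


def test_terminal_filter_drops_era_ending_at_death():
    eras, _ = build_drug_eras(_rows([("P1", D("2020-06-01"),
                                      D("2020-06-05"))]))
    cohort = _cohort_for("P1", D("2020-05-30"), D("2020-06-10"))
    deaths = coerce_table("death", pd.DataFrame(
        [{"person_id": "P1", "site_id": "S01",
          "death_date": D("2020-06-05")}]))
    kept = duration_distribution(eras, cohort, deaths,
                                 "drop_if_ends_at_discharge_or_death")
    assert kept.empty or kept["n_patients"].sum() == 0
    unfiltered = duration_distribution(eras, cohort, deaths)
    assert unfiltered["n_patients"].sum() == 1


def test_terminal_filter_drops_era_ending_at_discharge():
    eras, _ = build_drug_eras(_rows([("P1", D("2020-06-01"),
                                      D("2020-06-10"))]))
    cohort = _cohort_for("P1", D("2020-05-30"), D("2020-06-10"))
    deaths = coerce_table("death", pd.DataFrame(
        columns=["person_id", "site_id", "death_date"]))
    kept = duration_distribution(eras, cohort, deaths,
                                 "drop_if_ends_at_discharge_or_death")
    assert kept.empty or kept["n_patients"].sum() == 0


# ---------------------------------------------------------------- claims

def test_claim_breakdown_empty_without_single_day_eras():
    rows = _rows([("P1", D("2020-06-01"), D("2020-06-05"))])
    eras, _ = build_drug_eras(rows)
    assert claim_inferred_breakdown(rows, eras).empty


def test_claim_breakdown_concentration_and_missing_label():
    rows = []
    for i in range(73):
        rows.append({"person_id": f"A{i}", "site_id": "BIG",
                     "concept_id": 100, "start_date": D("2020-06-01"),
                     "end_date": D("2020-06-01"),
                     "drug_type_label": "Inferred from claim"})
    for i in range(27):
        rows.append({"person_id": f"B{i}", "site_id": f"S{i % 10}",
                     "concept_id": 100, "start_date": D("2020-06-01"),
                     "end_date": None, "drug_type_label": None})
    df = coerce_table("drug_exposure", pd.DataFrame(rows))
    eras, _ = build_drug_eras(df)
    tab = claim_inferred_breakdown(df, eras)
    big = tab[tab["site_id"] == "BIG"]
    assert big["count"].sum() == 73
    assert (big["drug_type_label"] == "Inferred from claim").all()
    assert tab.loc[tab["drug_type_label"] == "missing", "count"].sum() == 27
    assert tab["count"].sum() == 100
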