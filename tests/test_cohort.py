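import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from abxallergy import (
    build_cohort,
    case_windows,
    exposure_duration,
    simulate_cohort,
    split_train_test,
)
from abxallergy.errors import ValidationError
from abxallergy.synthetic_ehr import EHRBundle, GeneratorConfig

PROC = pd.Timestamp("2020-03-01")


def _bundle(exposure_offsets, settings=None, supplies=None):
    settings = settings or ["inpatient_admin"] * len(exposure_offsets)
    supplies = supplies or [0] * len(exposure_offsets)
    b = EHRBundle.empty()
    b.procedures = pd.DataFrame(
        [{"patient_id": "P1", "procedure_id": "P1-0", "procedure_date": PROC,
          "procedure_type": "pacemaker"}]
    )
    b.exposures = pd.DataFrame(
        [
            {"patient_id": "P1", "procedure_id": "P1-0", "drug_name": "cefazolin",
             "drug_class": "cephalosporin", "setting": s,
             "date": PROC + pd.Timedelta(days=o), "days_supply": d}
            for o, s, d in zip(exposure_offsets, settings, supplies)
        ]
    )
    b.truth = pd.DataFrame([{"procedure_id": "P1-0", "event_type": "none",
                             "event_day_offset": None, "culprit_class": None,
                             "severity": None, "exposure_gt_24h": None}])
    return b


@pytest.mark.parametrize(
    "offsets,expected",
    [([-1], True), ([0], True), ([1], True), ([2], False), ([-2], False)],
)
def test_inclusion_rule_within_one_day(offsets, expected):
    cohort = build_cohort(_bundle(offsets))
    assert bool(cohort["included"].iloc[0]) is expected


def test_exposure_duration_distinct_days():
    exp = _bundle([0, 1, 2, 3]).exposures
    assert exposure_duration(exp, PROC) == 4


def test_exposure_duration_union_of_admin_and_fill():
    """Admin on day 0 plus a 7-day fill from day 1 covers days 0..7."""
    exp = _bundle([0, 1], settings=["inpatient_admin", "outpatient_fill"],
                  supplies=[0, 7]).exposures
    assert exposure_duration(exp, PROC) == 8


def test_exposure_duration_overlap_counted_once():
    exp = _bundle([0, 0, 1], settings=["inpatient_admin", "outpatient_fill",
                                       "inpatient_admin"],
                  supplies=[0, 3, 0]).exposures
    assert exposure_duration(exp, PROC) == 3  # days 0,1,2


def test_exposure_duration_no_exposures():
    assert exposure_duration(EHRBundle.empty().exposures, PROC) == 0


def test_negative_days_supply_rejected():
    b = _bundle([1], settings=["outpatient_fill"], supplies=[-2])
    with pytest.raises(ValidationError, match="days_supply"):
        build_cohort(b)


def test_invalid_procedure_date_excluded_not_fatal():
    b = _bundle([0])
    b.procedures["procedure_date"] = b.procedures["procedure_date"].astype(object)
    b.procedures.loc[0, "procedure_date"] = "not-a-date"
    cohort = build_cohort(b)
    assert not cohort["included"].iloc[0]


@pytest.mark.parametrize(
    "last_day,expected_end",
    [(5, 15), (40, 45), (-1, 9), (35, 45), (36, 45)],
)
def test_attribution_window_ten_days_after_last_exposure(last_day, expected_end):
    cohort = pd.DataFrame(
        [{"procedure_id": "c", "patient_id": "p", "procedure_date": PROC,
          "included": True, "exposure_days": 1, "last_exposure_day": last_day,
          "antibiotic_classes": frozenset()}]
    )
    w = case_windows(cohort).iloc[0]
    assert w["attribution_end"] == PROC + pd.Timedelta(days=expected_end)
    assert w["extraction_start"] == PROC
    assert w["extraction_end"] == PROC + pd.Timedelta(days=45)


def test_window_nesting_invariant(small_cohort, small_windows):
    w = small_windows
    assert (w["extraction_start"] <= w["attribution_end"]).all()
    assert (w["attribution_end"] <= w["extraction_end"]).all()
    assert len(w) == int(small_cohort["included"].sum())


def test_last_exposure_before_minus_one_rejected():
    cohort = pd.DataFrame(
        [{"procedure_id": "c", "patient_id": "p", "procedure_date": PROC,
          "included": True, "exposure_days": 1, "last_exposure_day": -3,
          "antibiotic_classes": frozenset()}]
    )
    with pytest.raises(ValidationError):
        case_windows(cohort)


def _toy_cohort(n_patients, procs_per_patient=1):
    rows = []
    for i in range(n_patients):
        for k in range(procs_per_patient):
            rows.append({"procedure_id": f"P{i}-{k}", "patient_id": f"P{i}",
                         "included": True})
    return pd.DataFrame(rows)


def test_split_even_and_reproducible():
    cohort = _toy_cohort(10)
    a = split_train_test(cohort, seed=5)
    b = split_train_test(cohort, seed=5)
    assert a == b
    assert len(a[0]) == len(a[1]) == 5
    assert set(a[0]) | set(a[1]) == set(cohort["procedure_id"])
    assert not set(a[0]) & set(a[1])


def test_split_keeps_patients_together():
    cohort = _toy_cohort(11, procs_per_patient=2)
    train, test = split_train_test(cohort, seed=1)
    patients_train = {i.rsplit("-", 1)[0] for i in train}
    patients_test = {i.rsplit("-", 1)[0] for i in test}
    assert not patients_train & patients_test


def test_split_near_equal_on_large_simulated_cohort():
    """Mix of single- and double-procedure patients still splits within 1."""
    rng = np.random.default_rng(0)
    rows = []
    for i in range(4001):
        for k in range(2 if rng.random() < 0.05 else 1):
            rows.append({"procedure_id": f"P{i}-{k}", "patient_id": f"P{i}",
                         "included": True})
    cohort = pd.DataFrame(rows)
    train, test = split_train_test(cohort, seed=9)
    assert abs(len(train) - len(test)) <= 1
    assert len(train) + len(test) == len(cohort)


@given(
    days=st.lists(st.integers(min_value=-1, max_value=45), max_size=15),
    extra=st.integers(min_value=-1, max_value=45),
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_duration_monotone_when_exposure_added(days, extra):
    """Adding an exposure day can never shorten the computed duration."""
    before = exposure_duration(_bundle(days).exposures if days else
                               pd.DataFrame(columns=["setting", "date", "days_supply"]),
                               PROC)
    after = exposure_duration(_bundle(days + [extra]).exposures, PROC)
    assert after >= before
    assert after <= 47  # days -1..45 inclusive


def test_simulated_inclusion_fraction_matches_configured_rate():
    cfg = GeneratorConfig(n_patients=3000, seed=21)
    cohort = build_cohort(simulate_cohort(cfg))
    frac = cohort["included"].mean()
    se = np.sqrt(0.96 * 0.04 / len(cohort))
    assert abs(frac - 0.96) < 3 * se
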