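import pandas as pd
import pytest

from abxallergy import FEATURE_COLUMNS, assemble_feature_matrix, default_lexicon, load_phecode_map
from abxallergy.errors import IntegrityError, ValidationError
from abxallergy.features import (
    art_flags,
    consult_flags,
    keyword_flag,
    map_icd_to_phecode,
    medication_flags,
    new_allergy_code_flag,
    note_matches,
    prior_year_allergy_flag,
)
from conftest import make_window

PROC = pd.Timestamp("2020-01-01")
WINDOW = make_window(PROC)


def _art(entries):
    return pd.DataFrame(
        [{"patient_id": "p", "entry_date": PROC + pd.Timedelta(days=d),
          "drug_name": "cefazolin", "entry_kind": kind, "reaction_text": "hives"}
         for d, kind in entries]
    )


def test_art_flags_observed_in_window():
    assert art_flags(_art([(3, "observed")]), WINDOW) == (0, 1)


def test_art_flags_outside_window():
    assert art_flags(_art([(50, "historical"), (-2, "observed")]), WINDOW) == (0, 0)


def test_art_flags_unknown_kind_rejected():
    with pytest.raises(ValidationError):
        art_flags(_art([(3, "rumoured")]), WINDOW)


def _codes(entries):
    return pd.DataFrame(
        [{"patient_id": "p", "date": PROC + pd.Timedelta(days=d), "icd10_code": c}
         for d, c in entries]
    )


def test_phecode_prefix_match():
    pmap = load_phecode_map()
    flags = map_icd_to_phecode(_codes([(4, "L50.0")]), pmap, WINDOW)
    assert flags["phecode_urticaria"] == 1
    assert sum(flags.values()) == 1


def test_phecode_longest_prefix_wins_once():
    pmap = pd.DataFrame(
        {"icd10_prefix": ["T36", "T36.0X5"],
         "phecode_label": ["ae_nonspecific_drug", "ae_antibiotic_penicillin"]}
    )
    flags = map_icd_to_phecode(_codes([(2, "T36.0X5A")]), pmap, WINDOW)
    assert flags["phecode_ae_antibiotic_penicillin"] == 1
    assert flags["phecode_ae_nonspecific_drug"] == 0


def test_phecode_window_bound():
    pmap = load_phecode_map()
    flags = map_icd_to_phecode(_codes([(46, "L50.0")]), pmap, WINDOW)
    assert sum(flags.values()) == 0


def test_new_allergy_code_no_history():
    assert new_allergy_code_flag(_codes([(10, "Z88.0")]), PROC) == 1


def test_new_allergy_code_suppressed_by_carried_forward_history():
    assert new_allergy_code_flag(_codes([(10, "Z88.0"), (-30, "Z88.0")]), PROC) == 0


def test_new_allergy_code_day_zero_counts_as_history():
    """The history interval is closed at the procedure day itself."""
    assert new_allergy_code_flag(_codes([(0, "Z88.0"), (10, "Z88.1")]), PROC) == 0


def _notes(texts, day=5):
    return pd.DataFrame(
        [{"patient_id": "p", "date": PROC + pd.Timedelta(days=day),
          "note_id": f"n{i}", "text": t} for i, t in enumerate(texts)]
    )


def test_keyword_symptom_and_medication_in_one_note():
    lex = default_lexicon()
    assert keyword_flag(_notes(["developed hives after cefazolin dose"]), lex, WINDOW) == 1


def test_keyword_negated_symptom_does_not_flag():
    lex = default_lexicon()
    assert keyword_flag(_notes(["denies hives; tolerated vancomycin"]), lex, WINDOW) == 0


def test_keyword_requires_cooccurrence_within_single_note():
    lex = default_lexicon()
    split_across = _notes(["patient noted hives today", "continues cefazolin"])
    together = _notes(["patient noted hives today while on cefazolin"])
    assert keyword_flag(split_across, lex, WINDOW) == 0
    assert keyword_flag(together, lex, WINDOW) == 1


def test_keyword_negation_scope_is_sentence_bounded():
    lex = default_lexicon()
    # negation in a previous sentence does not reach the symptom
    assert note_matches("no fevers reported. hives after cefazolin.", lex)


def test_keyword_multiword_term():
    lex = default_lexicon()
    assert note_matches("shortness of breath after vancomycin infusion", lex)


def _meds(entries):
    return pd.DataFrame(
        [{"patient_id": "p", "date": PROC + pd.Timedelta(days=d),
          "med_class": cls, "route": route} for d, cls, route in entries]
    )


def test_medication_flags_single_class():
    flags = medication_flags(_meds([(2, "antihistamine", "po")]), WINDOW)
    assert flags == (1, 0, 0, 0)


def test_medication_same_day_combination():
    flags = medication_flags(
        _meds([(2, "antihistamine", "po"), (2, "corticosteroid", "iv")]), WINDOW
    )
    assert flags == (1, 1, 1, 0)


def test_medication_different_days_not_combined():
    flags = medication_flags(
        _meds([(2, "antihistamine", "po"), (9, "corticosteroid", "po")]), WINDOW
    )
    assert flags == (1, 1, 0, 0)


def test_epinephrine_requires_iv_route():
    assert medication_flags(_meds([(3, "epinephrine_iv", "iv")]), WINDOW)[3] == 1
    assert medication_flags(_meds([(3, "epinephrine_iv", "im")]), WINDOW)[3] == 0


def test_unknown_med_class_rejected():
    with pytest.raises(ValidationError):
        medication_flags(_meds([(2, "leeches", "po")]), WINDOW)


def test_consult_and_prior_year_flags():
    consults = pd.DataFrame(
        [{"patient_id": "p", "date": PROC + pd.Timedelta(days=4), "specialty": "allergy"}]
    )
    assert consult_flags(consults, WINDOW) == (1, 0)
    assert prior_year_allergy_flag(_art([(-100, "historical")]), PROC) == 1
    assert prior_year_allergy_flag(_art([(-400, "historical")]), PROC) == 0
    assert prior_year_allergy_flag(_art([(3, "historical")]), PROC) == 0


# ---------------------------------------------------------------------------
# assembled matrix properties


def test_matrix_shape_and_column_order(small_features, small_cohort):
    assert list(small_features.columns) == FEATURE_COLUMNS
    assert len(small_features) == int(small_cohort["included"].sum())
    assert small_features.isin([0, 1]).all().all()


def test_combo_flags_equal_and_of_components(small_features):
    f = small_features
    assert (f["combo_art_keyword"] == (f["art_observed"] & f["keyword_note"])).all()
    med_any = f["antihistamine"] | f["corticosteroid"] | f["epinephrine_iv"]
    assert (f["combo_art_medication"] == (f["art_observed"] & med_any)).all()
    assert (
        f["combo_art_phecode_ae"]
        == (f["art_observed"] & f["phecode_ae_antibiotic_penicillin"])
    ).all()


def test_extraction_is_idempotent(small_bundle, small_cohort, small_windows, small_features):
    again = assemble_feature_matrix(small_bundle, small_cohort, small_windows)
    pd.testing.assert_frame_equal(small_features, again)


def test_missing_window_is_integrity_error(small_bundle, small_cohort, small_windows):
    with pytest.raises(IntegrityError):
        assemble_feature_matrix(small_bundle, small_cohort, small_windows.iloc[1:])


def test_records_outside_window_cannot_set_flags(small_bundle, small_cohort, small_windows):
    """Shifting every non-procedure record past day 45 clears all flags
    except history-based ones (window confinement)."""
    import copy

    b = copy.copy(small_bundle)
    shift = pd.Timedelta(days=4000)
    b.art = small_bundle.art.assign(entry_date=small_bundle.art["entry_date"] + shift)
    b.diagnoses = small_bundle.diagnoses.assign(date=small_bundle.diagnoses["date"] + shift)
    b.med_admins = small_bundle.med_admins.assign(date=small_bundle.med_admins["date"] + shift)
    b.notes = small_bundle.notes.assign(date=small_bundle.notes["date"] + shift)
    b.consults = small_bundle.consults.assign(date=small_bundle.consults["date"] + shift)
    f = assemble_feature_matrix(b, small_cohort, small_windows)
    window_cols = [c for c in FEATURE_COLUMNS
                   if c not in ("prior_year_antibiotic_allergy", "new_allergy_icd")]
    assert (f[window_cols] == 0).all().all()


def test_all_empty_bundle_yields_all_zero_rows(small_cohort, small_windows):
    from abxallergy.synthetic_ehr import EHRBundle

    empty = EHRBundle.empty()
    empty.procedures = pd.DataFrame(
        {"patient_id": small_cohort["patient_id"],
         "procedure_id": small_cohort["procedure_id"],
         "procedure_date": small_cohort["procedure_date"],
         "procedure_type": "pacemaker"}
    )
    f = assemble_feature_matrix(empty, small_cohort, small_windows)
    assert (f == 0).all().all()
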