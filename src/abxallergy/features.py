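"""Candidate detection variables extracted per case within its windows.

Each included procedure gets a binary feature vector built from five EHR
sources, all restricted to the case's extraction window (procedure date
through day +45, boundaries inclusive):

* allergy-module (ART) entries — observed and historical flags;
* diagnosis codes mapped to eight allergy/skin phenotype groupings
  (PheCodes) by longest-prefix ICD-10 match;
* a new-allergy code flag (an allergy-status code in the 45 days after
  the procedure with none in the prior year — carried-forward history
  suppresses the flag);
* clinical notes — a keyword flag requiring a non-negated symptom term
  and a medication term co-occurring *within one note*;
* rescue medications (antihistamine, corticosteroid, same-day
  combination, intravenous epinephrine) and allergy/dermatology consults;
* three prespecified composites: observed ART flag AND note keyword,
  observed ART AND anti-allergy medication, observed ART AND the
  antibiotic/penicillin adverse-event PheCode.

Consult flags reproduce candidate variables that lacked discriminative
value in the development cohort; they are extracted but excluded from the
shipped final model.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging
import re

import pandas as pd
import yaml

from .errors import IntegrityError, ValidationError
from .synthetic_ehr import EHRBundle

logger = logging.getLogger(__name__)

#: Fixed, documented column order of the feature matrix.
FEATURE_COLUMNS = [
    "art_historical", "art_observed", "keyword_note", "antihistamine",
    "corticosteroid", "antihistamine_with_steroid", "epinephrine_iv",
    "new_allergy_icd", "phecode_contact_dermatitis", "phecode_anaphylaxis",
    "phecode_urticaria", "phecode_allergies_other",
    "phecode_ae_antibiotic_penicillin", "phecode_ae_nonspecific_drug",
    "phecode_rash_skin_erupt", "phecode_symptoms_skin",
    "consult_allergy", "consult_dermatology",
    "combo_art_keyword", "combo_art_medication", "combo_art_phecode_ae",
    "prior_year_antibiotic_allergy",
]

PHECODE_LABELS = [
    "contact_dermatitis", "anaphylactic_shock_nos", "urticaria",
    "allergies_other", "ae_antibiotic_penicillin", "ae_nonspecific_drug",
    "rash_skin_erupt", "symptoms_affecting_skin",
]

#: flag-column name per phenotype label
PHECODE_FLAG = {
    "contact_dermatitis": "phecode_contact_dermatitis",
    "anaphylactic_shock_nos": "phecode_anaphylaxis",
    "urticaria": "phecode_urticaria",
    "allergies_other": "phecode_allergies_other",
    "ae_antibiotic_penicillin": "phecode_ae_antibiotic_penicillin",
    "ae_nonspecific_drug": "phecode_ae_nonspecific_drug",
    "rash_skin_erupt": "phecode_rash_skin_erupt",
    "symptoms_affecting_skin": "phecode_symptoms_skin",
}

#: ICD-10 prefixes counted as allergy-status codes for the new-allergy
#: flag (drug-allergy status, Z88*).
ALLERGY_ICD_PREFIXES = ("Z88",)

VALID_MED_CLASSES = {"antihistamine", "corticosteroid", "epinephrine_iv", "other"}


@dataclasses.dataclass
class KeywordLexicon:
    """Terms driving the clinical-note keyword flag.

    Multi-word terms match as contiguous token runs.  A symptom mention is
    negated when a negation trigger occurs within ``negation_scope_tokens``
    tokens before it in the same sentence.
    """

    symptom_terms: list
    medication_terms: list
    negation_triggers: list
    negation_scope_tokens: int = 5

    def __post_init__(self):
        for field in ("symptom_terms", "medication_terms", "negation_triggers"):
            vals = [str(t).lower().strip() for t in getattr(self, field)]
            if not vals:
                raise ValidationError(f"lexicon {field} must be nonempty")
            setattr(self, field, sorted(set(vals)))


def load_lexicon(path) -> KeywordLexicon:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return KeywordLexicon(**raw)


def default_lexicon() -> KeywordLexicon:
    """The documented default lexicon shipped with the package."""
    ref = importlib.resources.files("abxallergy") / "data" / "lexicon.yaml"
    return KeywordLexicon(**yaml.safe_load(ref.read_text()))


def load_phecode_map(path=None) -> pd.DataFrame:
    """ICD-10 prefix -> phenotype-label map (longest prefix wins).

    Ships as a minimal editable CSV covering only the eight study labels;
    full phenome-wide maps are out of scope.
    """
    if path is None:
        ref = importlib.resources.files("abxallergy") / "data" / "phecode_map.csv"
        with importlib.resources.as_file(ref) as p:
            pmap = pd.read_csv(p, dtype=str)
    else:
        pmap = pd.read_csv(path, dtype=str)
    if set(pmap.columns) != {"icd10_prefix", "phecode_label"}:
        raise ValidationError("phecode map needs icd10_prefix,phecode_label columns")
    bad = set(pmap["phecode_label"]) - set(PHECODE_LABELS)
    if bad:
        raise ValidationError(f"unknown phecode labels: {sorted(bad)}")
    if pmap["icd10_prefix"].duplicated().any():
        raise ValidationError("duplicate prefixes in phecode map")
    return pmap


# ---------------------------------------------------------------------------
# note text matching

_SENTENCE_SPLIT = re.compile(r"[.;!?\n]+")
_TOKEN = re.compile(r"[a-z0-9]+")


def _match_term_positions(tokens: list, term: str) -> list:
    """Start indices where a (possibly multi-word) term matches."""
    words = term.split()
    n = len(words)
    return [
        i for i in range(len(tokens) - n + 1) if tokens[i:i + n] == words
    ]


def note_matches(text: str, lexicon: KeywordLexicon) -> bool:
    """True when the note holds a non-negated symptom term AND a med term."""
    text = str(text).lower()
    has_symptom = False
    has_medication = False
    for sentence in _SENTENCE_SPLIT.split(text):
        tokens = _TOKEN.findall(sentence)
        if not tokens:
            continue
        if not has_medication:
            for term in lexicon.medication_terms:
                if _match_term_positions(tokens, term):
                    has_medication = True
                    break
        if not has_symptom:
            neg_positions = set()
            for trig in lexicon.negation_triggers:
                for i in _match_term_positions(tokens, trig):
                    neg_positions.add(i)
            for term in lexicon.symptom_terms:
                for i in _match_term_positions(tokens, term):
                    scope = range(
                        max(0, i - lexicon.negation_scope_tokens), i
                    )
                    if not any(j in neg_positions for j in scope):
                        has_symptom = True
                        break
                if has_symptom:
                    break
        if has_symptom and has_medication:
            return True
    return has_symptom and has_medication


# ---------------------------------------------------------------------------
# per-source flag extractors (window: mapping with extraction_start /
# extraction_end / attribution_end timestamps)


def _win(window, key):
    if isinstance(window, dict):
        return pd.Timestamp(window[key])
    return pd.Timestamp(getattr(window, key, None) or window[key])


def art_flags(art_entries: pd.DataFrame, window) -> tuple:
    """(historical, observed) allergy-module flags inside the window."""
    if len(art_entries) == 0:
        return (0, 0)
    kinds = set(art_entries["entry_kind"].unique())
    if not kinds <= {"observed", "historical"}:
        raise ValidationError(f"unknown ART entry_kind: {sorted(kinds - {'observed', 'historical'})}")
    lo, hi = _win(window, "extraction_start"), _win(window, "extraction_end")
    dates = pd.to_datetime(art_entries["entry_date"])
    inside = (dates >= lo) & (dates <= hi)
    hist = int((inside & (art_entries["entry_kind"] == "historical")).any())
    obs = int((inside & (art_entries["entry_kind"] == "observed")).any())
    return (hist, obs)


def map_icd_to_phecode(codes: pd.DataFrame, pmap: pd.DataFrame, window) -> dict:
    """Eight phenotype flags from in-window diagnosis codes.

    Each code is assigned the label of its longest matching prefix;
    unmapped codes are ignored (counted in debug logs only).
    """
    flags = {PHECODE_FLAG[lab]: 0 for lab in PHECODE_LABELS}
    if len(codes) == 0:
        return flags
    lo, hi = _win(window, "extraction_start"), _win(window, "extraction_end")
    dates = pd.to_datetime(codes["date"])
    sub = codes[(dates >= lo) & (dates <= hi)]
    prefixes = sorted(
        zip(pmap["icd10_prefix"], pmap["phecode_label"]),
        key=lambda t: -len(t[0]),
    )
    unmapped = 0
    for code in sub["icd10_code"].astype(str):
        for prefix, label in prefixes:  # longest prefix first
            if code.startswith(prefix):
                flags[PHECODE_FLAG[label]] = 1
                break
        else:
            unmapped += 1
    if unmapped:
        logger.debug("%d in-window codes had no phecode mapping", unmapped)
    return flags


def new_allergy_code_flag(codes: pd.DataFrame, procedure_date,
                          lookback_days: int = 365) -> int:
    """1 iff an allergy-status code appears in (procedure, procedure+45]
    with none in [procedure-lookback, procedure].

    The history interval is closed on the procedure day: a code dated day
    0 counts as carried-forward history, not as a new allergy.
    """
    if len(codes) == 0:
        return 0
    proc = pd.Timestamp(procedure_date)
    dates = pd.to_datetime(codes["date"])
    is_allergy = codes["icd10_code"].astype(str).str.startswith(ALLERGY_ICD_PREFIXES)
    new = is_allergy & (dates > proc) & (dates <= proc + pd.Timedelta(days=45))
    prior = is_allergy & (dates >= proc - pd.Timedelta(days=lookback_days)) & (dates <= proc)
    return int(new.any() and not prior.any())


def keyword_flag(notes: pd.DataFrame, lexicon: KeywordLexicon, window) -> int:
    """1 iff some in-window note satisfies the co-occurrence rule."""
    if len(notes) == 0:
        return 0
    lo, hi = _win(window, "extraction_start"), _win(window, "extraction_end")
    dates = pd.to_datetime(notes["date"])
    sub = notes[(dates >= lo) & (dates <= hi)]
    return int(any(note_matches(t, lexicon) for t in sub["text"]))


def medication_flags(med_admins: pd.DataFrame, window) -> tuple:
    """(antihistamine, corticosteroid, same-day combo, IV epinephrine)."""
    if len(med_admins) == 0:
        return (0, 0, 0, 0)
    bad = set(med_admins["med_class"].unique()) - VALID_MED_CLASSES
    if bad:
        raise ValidationError(f"unknown med_class values: {sorted(bad)}")
    lo, hi = _win(window, "extraction_start"), _win(window, "extraction_end")
    dates = pd.to_datetime(med_admins["date"])
    sub = med_admins[(dates >= lo) & (dates <= hi)]
    sub_dates = pd.to_datetime(sub["date"]).dt.normalize()
    anti_days = set(sub_dates[sub["med_class"] == "antihistamine"])
    ster_days = set(sub_dates[sub["med_class"] == "corticosteroid"])
    epi = int(
        ((sub["med_class"] == "epinephrine_iv") & (sub["route"] == "iv")).any()
    )
    return (
        int(bool(anti_days)),
        int(bool(ster_days)),
        int(bool(anti_days & ster_days)),
        epi,
    )


def consult_flags(consults: pd.DataFrame, window) -> tuple:
    """(allergy, dermatology) consult flags inside the window."""
    if len(consults) == 0:
        return (0, 0)
    lo, hi = _win(window, "extraction_start"), _win(window, "extraction_end")
    dates = pd.to_datetime(consults["date"])
    sub = consults[(dates >= lo) & (dates <= hi)]
    return (
        int((sub["specialty"] == "allergy").any()),
        int((sub["specialty"] == "dermatology").any()),
    )


def prior_year_allergy_flag(art_entries: pd.DataFrame, procedure_date,
                            lookback_days: int = 365) -> int:
    """Allergy-module entry in the year before the procedure (covariate)."""
    if len(art_entries) == 0:
        return 0
    proc = pd.Timestamp(procedure_date)
    dates = pd.to_datetime(art_entries["entry_date"])
    prior = (dates >= proc - pd.Timedelta(days=lookback_days)) & (dates < proc)
    return int(prior.any())


# ---------------------------------------------------------------------------


def assemble_feature_matrix(
    bundle: EHRBundle,
    cohort: pd.DataFrame,
    windows: pd.DataFrame,
    lexicon: KeywordLexicon | None = None,
    pmap: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One feature row per included case, in ``FEATURE_COLUMNS`` order.

    Re-running on the same bundle is idempotent.  A missing window for an
    included case is an integrity error.
    """
    lexicon = lexicon or default_lexicon()
    pmap = load_phecode_map() if pmap is None else pmap

    win_by_case = windows.set_index("procedure_id")
    included = cohort[cohort["included"]]

    def by_patient(df: pd.DataFrame) -> dict:
        if len(df) == 0:
            return {}
        return {k: g for k, g in df.groupby("patient_id", sort=False)}

    # score notes once; per-case work is then just a window check
    notes = bundle.notes.copy()
    if len(notes):
        notes["_match"] = [note_matches(t, lexicon) for t in notes["text"]]
    art_g = by_patient(bundle.art)
    dx_g = by_patient(bundle.diagnoses)
    med_g = by_patient(bundle.med_admins)
    note_g = by_patient(notes)
    cons_g = by_patient(bundle.consults)
    empty = {
        name: pd.DataFrame(columns=df.columns)
        for name, df in (
            ("art", bundle.art), ("dx", bundle.diagnoses),
            ("med", bundle.med_admins), ("notes", notes),
            ("cons", bundle.consults),
        )
    }

    rows = []
    for r in included.itertuples():
        if r.procedure_id not in win_by_case.index:
            raise IntegrityError(f"no window for included case {r.procedure_id}")
        w = win_by_case.loc[r.procedure_id]
        art = art_g.get(r.patient_id, empty["art"])
        dx = dx_g.get(r.patient_id, empty["dx"])
        med = med_g.get(r.patient_id, empty["med"])
        pnotes = note_g.get(r.patient_id, empty["notes"])
        cons = cons_g.get(r.patient_id, empty["cons"])

        hist, obs = art_flags(art, w)
        anti, ster, combo_med, epi = medication_flags(med, w)
        phe = map_icd_to_phecode(dx, pmap, w)
        if len(pnotes):
            dates = pd.to_datetime(pnotes["date"])
            kw = int(
                (
                    pnotes["_match"]
                    & (dates >= _win(w, "extraction_start"))
                    & (dates <= _win(w, "extraction_end"))
                ).any()
            )
        else:
            kw = 0
        row = {
            "procedure_id": r.procedure_id,
            "art_historical": hist,
            "art_observed": obs,
            "keyword_note": kw,
            "antihistamine": anti,
            "corticosteroid": ster,
            "antihistamine_with_steroid": combo_med,
            "epinephrine_iv": epi,
            "new_allergy_icd": new_allergy_code_flag(dx, r.procedure_date),
            **phe,
        }
        ca, cd = consult_flags(cons, w)
        row["consult_allergy"] = ca
        row["consult_dermatology"] = cd
        row["combo_art_keyword"] = obs & kw
        row["combo_art_medication"] = obs & (anti | ster | epi)
        row["combo_art_phecode_ae"] = obs & phe["phecode_ae_antibiotic_penicillin"]
        row["prior_year_antibiotic_allergy"] = prior_year_allergy_flag(
            art, r.procedure_date
        )
        rows.append(row)

    out = pd.DataFrame(rows, columns=["procedure_id"] + FEATURE_COLUMNS)
    return out.set_index("procedure_id")
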