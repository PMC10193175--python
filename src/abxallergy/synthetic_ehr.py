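"""Linked synthetic EHR tables with a latent allergic-event process.

Real periprocedural surveillance data live in closed health-system data
warehouses, so this generator emulates the relevant slice of an EHR for a
CIED-procedure cohort: procedures, antibiotic exposures (inpatient
administrations and outpatient fills), ICD-10 diagnoses, allergy-module
(ART) entries, medication administrations, free-text notes and consults —
plus a generator-only ``truth`` table holding the latent event behind each
procedure.

The event model, per procedure with periprocedural antibiotic exposure:

* an allergic-type reaction occurs with probability ``p_allergic_event``
  (default 0.6%), a non-immune adverse reaction with ``p_adverse_event``,
  something else with ``p_other_event``;
* an allergic event day is drawn within the attribution window
  [0, min(last exposure day + 10, 45)] (day 0 = procedure date);
* each detection channel (observed/historical allergy-module entry,
  keyword-bearing note, rescue medications, new allergy code, diagnosis
  phenotype codes, consults) fires with P(flag | allergic) for allergic
  cases and a background rate otherwise.

Defaults encode the development cohort: P(flag | allergic) from the
adjudicated training review sample (e.g. 60/96 = 62.5% for an observed
allergy-module entry) and background rates derived so the implied cohort
marginal matches the cohort-level detection rates (0.3% observed ART,
8.7% keyword notes, ...).  The enriched review sample's *negative* column
rates are deliberately not matched — those negatives were coverage-sampled
and over-represent flagged charts.

Dates live on an integer day axis anchored at each procedure and are
rendered as ISO-8601 calendar dates on output, which removes any
timezone/clock ambiguity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .reference import ANTIBIOTIC_CLASSES, SEVERITY_REFERENCE

logger = logging.getLogger(__name__)

PROCEDURE_TYPES = ["pacemaker", "icd", "biv_icd", "watchman"]

CLASS_DRUGS = {
    "cephalosporin": ["cefazolin", "cephalexin", "ceftriaxone"],
    "vancomycin": ["vancomycin"],
    "tetracycline": ["doxycycline", "minocycline"],
    "penicillin": ["amoxicillin", "ampicillin", "nafcillin"],
    "sulfa": ["sulfamethoxazole", "trimethoprim"],
    "clindamycin": ["clindamycin"],
    "daptomycin": ["daptomycin"],
    "fluoroquinolone": ["ciprofloxacin", "levofloxacin"],
    "carbapenem": ["meropenem", "ertapenem"],
    "macrolide": ["azithromycin", "erythromycin"],
}

#: ICD-10 exemplars emitted per diagnosis-phenotype channel.  Kept disjoint
#: from the new-allergy-code channel (Z88*) so each extracted flag stays
#: calibrated to its own configured rate.
PHECODE_CHANNEL_CODES = {
    "phecode_contact_dermatitis": ["L23.9", "L24.9"],
    "phecode_anaphylaxis": ["T78.2XXA"],
    "phecode_urticaria": ["L50.0", "L50.9"],
    "phecode_allergies_other": ["T78.40XA", "Z91.09"],
    "phecode_ae_antibiotic_penicillin": ["T36.0X5A", "T36.95XA"],
    "phecode_ae_nonspecific_drug": ["T50.905A"],
    "phecode_rash_skin_erupt": ["R21"],
    "phecode_symptoms_skin": ["R23.8", "L29.9"],
}

NEW_ALLERGY_CODES = ["Z88.0", "Z88.1", "Z88.8"]
DISTRACTOR_CODES = ["I10", "E11.9", "I50.9", "Z95.0"]

SYMPTOM_WORDS = ["rash", "hives", "urticaria", "pruritus", "swelling", "flushing"]
REACTION_TEXTS = ["hives", "rash", "pruritus", "angioedema", "anaphylaxis"]

# --- development-cohort calibration ------------------------------------
# P(channel fires | allergic event): adjudicated allergic reviewees (n=96).
P_GIVEN_ALLERGIC = {
    "art_observed": 60 / 96,
    "art_historical": 23 / 96,
    "keyword_note": 51 / 96,
    "antihistamine": 35 / 96,
    "corticosteroid": 25 / 96,
    "epinephrine_iv": 1 / 96,
    "new_allergy_icd": 40 / 96,
    "phecode_contact_dermatitis": 7 / 96,
    "phecode_anaphylaxis": 1 / 96,
    "phecode_urticaria": 13 / 96,
    "phecode_allergies_other": 2 / 96,
    "phecode_ae_antibiotic_penicillin": 19 / 96,
    "phecode_ae_nonspecific_drug": 0.0,
    "phecode_rash_skin_erupt": 17 / 96,
    "phecode_symptoms_skin": 0.10,     # not tabulated in the source; chosen
    "consult_allergy": 0.08,           # chosen (rejected-variable channels)
    "consult_dermatology": 0.05,       # chosen
    "prior_year_antibiotic_allergy": 4 / 96,
}

# Cohort-level detection rates (training cohort, n=17 350).
COHORT_DETECTION_RATE = {
    "art_observed": 48 / 17350,
    "art_historical": 83 / 17350,
    "keyword_note": 1510 / 17350,
    "antihistamine": 500 / 17350,
    "corticosteroid": 352 / 17350,
    "epinephrine_iv": 94 / 17350,
    "new_allergy_icd": 229 / 17350,
    "phecode_contact_dermatitis": 18 / 17350,
    "phecode_anaphylaxis": 3 / 17350,
    "phecode_urticaria": 25 / 17350,
    "phecode_allergies_other": 18 / 17350,
    "phecode_ae_antibiotic_penicillin": 39 / 17350,
    "phecode_ae_nonspecific_drug": 7 / 17350,
    "phecode_rash_skin_erupt": 151 / 17350,
    "phecode_symptoms_skin": 0.002,    # chosen
    "consult_allergy": 0.003,          # chosen
    "consult_dermatology": 0.004,      # chosen
    "prior_year_antibiotic_allergy": 203 / 17350,
}


def default_feature_probs(p_allergic: float = 0.006) -> dict:
    """(P(flag|allergic), P(flag|no event)) per detection channel.

    Background rates solve r_cohort = p_allergic*p1 + (1-p_allergic)*p0
    for p0 (floored at 0), so simulated cohort marginals match the
    development cohort's detection-rate column.
    """
    out = {}
    for name, p1 in P_GIVEN_ALLERGIC.items():
        r = COHORT_DETECTION_RATE[name]
        p0 = max(0.0, (r - p_allergic * p1) / (1.0 - p_allergic))
        out[name] = (p1, p0)
    return out


def default_class_mix() -> dict:
    """Antibiotic-class weights from the adjudicated reaction mix."""
    w = SEVERITY_REFERENCE.set_index("antibiotic_class")["reactions"]
    return (w / w.sum()).to_dict()


#: Severity weights from the adjudicated grade totals (43/52/20), normalized.
DEFAULT_SEVERITY_MIX = {"mild": 43 / 115, "moderate": 52 / 115, "severe": 20 / 115}


@dataclasses.dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults encode the study conditions."""

    n_patients: int = 1000
    procedures_per_patient: dict = dataclasses.field(
        default_factory=lambda: {1: 0.95, 2: 0.05}
    )
    p_periprocedural_antibiotic: float = 0.96
    #: postprocedural prophylaxis duration: round(lognormal) clipped to
    #: [1, 45]; ln-scale median 4 d / sigma 0.83 gives median 4, IQR 2-7.
    duration_median_days: float = 4.0
    duration_log_sigma: float = 0.83
    duration_max_days: int = 45
    p_allergic_event: float = 0.006
    p_adverse_event: float = 0.01
    p_other_event: float = 0.002
    conditional_feature_probs: dict = dataclasses.field(default_factory=dict)
    antibiotic_class_mix: dict = dataclasses.field(default_factory=default_class_mix)
    severity_mix: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_MIX)
    )
    #: rate of keyword-bearing but non-qualifying notes (negated or
    #: symptom-only mentions) in event-free cases.
    noise_note_rate: float = 0.05
    p_prior_allergy_history: float = 0.012   # prior-year allergy-module entry
    p_prior_allergy_code: float = 0.01       # prior-year Z88* code (suppressor)
    p_late_exposure_if_unexposed: float = 0.3
    start_date: str = "2015-10-01"
    study_days: int = 1461
    seed: int = 0

    def __post_init__(self):
        if not self.conditional_feature_probs:
            self.conditional_feature_probs = default_feature_probs(
                self.p_allergic_event
            )

    def validate(self) -> None:
        if int(self.n_patients) < 1:
            raise ConfigurationError("n_patients must be >= 1")
        for field in (
            "p_periprocedural_antibiotic", "p_allergic_event",
            "p_adverse_event", "p_other_event", "noise_note_rate",
            "p_prior_allergy_history", "p_prior_allergy_code",
            "p_late_exposure_if_unexposed",
        ):
            v = getattr(self, field)
            if not 0.0 <= float(v) <= 1.0:
                raise ConfigurationError(f"{field} must be in [0, 1], got {v}")
        if self.p_allergic_event + self.p_adverse_event + self.p_other_event > 1:
            raise ConfigurationError("event probabilities sum above 1")
        if not 1 <= int(self.duration_max_days) <= 45:
            raise ConfigurationError("duration_max_days must be in [1, 45]")
        for name, mix in (
            ("procedures_per_patient", self.procedures_per_patient),
            ("antibiotic_class_mix", self.antibiotic_class_mix),
            ("severity_mix", self.severity_mix),
        ):
            if not mix or any(w < 0 for w in mix.values()) or sum(mix.values()) <= 0:
                raise ConfigurationError(f"{name} must have nonnegative weights summing > 0")
        for chan, (p1, p0) in self.conditional_feature_probs.items():
            if not (0 <= p1 <= 1 and 0 <= p0 <= 1):
                raise ConfigurationError(
                    f"conditional_feature_probs[{chan}] outside [0, 1]"
                )

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


TABLE_COLUMNS = {
    "procedures": ["patient_id", "procedure_id", "procedure_date", "procedure_type"],
    "exposures": ["patient_id", "procedure_id", "drug_name", "drug_class",
                  "setting", "date", "days_supply"],
    "diagnoses": ["patient_id", "date", "icd10_code"],
    "art": ["patient_id", "entry_date", "drug_name", "entry_kind", "reaction_text"],
    "med_admins": ["patient_id", "date", "med_class", "route"],
    "notes": ["patient_id", "date", "note_id", "text"],
    "consults": ["patient_id", "date", "specialty"],
    "truth": ["procedure_id", "event_type", "event_day_offset", "culprit_class",
              "severity", "exposure_gt_24h"],
}


@dataclasses.dataclass
class EHRBundle:
    """The set of linked raw event tables plus generator ground truth."""

    procedures: pd.DataFrame
    exposures: pd.DataFrame
    diagnoses: pd.DataFrame
    art: pd.DataFrame
    med_admins: pd.DataFrame
    notes: pd.DataFrame
    consults: pd.DataFrame
    truth: pd.DataFrame
    meta: dict = dataclasses.field(default_factory=dict)

    def tables(self) -> dict:
        return {name: getattr(self, name) for name in TABLE_COLUMNS}

    @classmethod
    def empty(cls) -> "EHRBundle":
        return cls(**{
            name: pd.DataFrame(columns=cols) for name, cols in TABLE_COLUMNS.items()
        })

    def equals(self, other: "EHRBundle") -> bool:
        def canon(df: pd.DataFrame) -> pd.DataFrame:
            df = df.reset_index(drop=True)
            return df.astype(object).mask(df.isna(), "").astype(str)

        return all(
            canon(self.tables()[n]).equals(canon(other.tables()[n]))
            for n in TABLE_COLUMNS
        )


def _weighted_choice(rng, mix: dict):
    keys = list(mix)
    w = np.asarray([mix[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def _positive_note(rng, drug: str) -> str:
    s = SYMPTOM_WORDS[rng.integers(len(SYMPTOM_WORDS))]
    forms = [
        f"patient developed {s} after {drug} dose. incision site otherwise clean.",
        f"new {s} noted following {drug}. will monitor closely.",
        f"presents with {s} attributed to {drug}. plan to hold further doses.",
    ]
    return forms[rng.integers(len(forms))]


def _noise_note(rng, drug: str) -> str:
    s = SYMPTOM_WORDS[rng.integers(len(SYMPTOM_WORDS))]
    forms = [
        f"denies {s} or fevers. tolerated {drug} well.",
        f"no {s} with {drug}. wound healing appropriately.",
        f"mild {s} noted at dressing edge, resolved. no new medications.",
    ]
    return forms[rng.integers(len(forms))]


DISTRACTOR_NOTES = [
    "routine device interrogation. leads functioning within normal limits.",
    "follow up in clinic. incision clean dry and intact.",
    "telephone encounter. patient doing well. no complaints.",
]


def simulate_cohort(config: GeneratorConfig) -> EHRBundle:
    """Generate a linked synthetic EHR bundle.

    Deterministic for a fixed config (single seeded RNG, fixed iteration
    order): identical configs produce byte-identical bundles.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.start_date)

    probs = config.conditional_feature_probs
    proc_rows, exp_rows, dx_rows, art_rows = [], [], [], []
    med_rows, note_rows, consult_rows, truth_rows = [], [], [], []
    note_seq = 0

    def day(anchor: pd.Timestamp, offset: int) -> pd.Timestamp:
        return anchor + pd.Timedelta(days=int(offset))

    for p in range(int(config.n_patients)):
        pid = f"P{p:06d}"
        n_proc = int(_weighted_choice(rng, config.procedures_per_patient))
        anchor0 = day(start, rng.integers(0, config.study_days))
        for k in range(n_proc):
            proc_id = f"{pid}-{k}"
            # space repeat procedures far apart so 45-day windows never overlap
            anchor = anchor0 if k == 0 else day(anchor0, 120 * k + rng.integers(0, 600))
            proc_rows.append(
                {
                    "patient_id": pid,
                    "procedure_id": proc_id,
                    "procedure_date": anchor,
                    "procedure_type": PROCEDURE_TYPES[rng.integers(len(PROCEDURE_TYPES))],
                }
            )

            # ---- antibiotic exposure -------------------------------------
            exposed = rng.random() < config.p_periprocedural_antibiotic
            drug_class = _weighted_choice(rng, config.antibiotic_class_mix)
            drugs = CLASS_DRUGS.get(drug_class, [drug_class])
            drug = drugs[rng.integers(len(drugs))]
            last_exposure_day = None
            duration = 0
            if exposed:
                first_day = int(rng.choice([-1, 0, 1], p=[0.15, 0.70, 0.15]))
                duration = int(
                    np.clip(
                        np.rint(rng.lognormal(np.log(config.duration_median_days),
                                              config.duration_log_sigma)),
                        1, config.duration_max_days,
                    )
                )
                inpatient_days = int(min(duration, 1 + rng.integers(0, 3)))
                for d in range(inpatient_days):
                    exp_rows.append(
                        {
                            "patient_id": pid, "procedure_id": proc_id,
                            "drug_name": drug, "drug_class": drug_class,
                            "setting": "inpatient_admin",
                            "date": day(anchor, first_day + d), "days_supply": 0,
                        }
                    )
                if duration > inpatient_days:
                    exp_rows.append(
                        {
                            "patient_id": pid, "procedure_id": proc_id,
                            "drug_name": drug, "drug_class": drug_class,
                            "setting": "outpatient_fill",
                            "date": day(anchor, first_day + inpatient_days),
                            "days_supply": duration - inpatient_days,
                        }
                    )
                last_exposure_day = first_day + duration - 1
            elif rng.random() < config.p_late_exposure_if_unexposed:
                # late, non-qualifying exposure (outside the +/-1 day rule)
                exp_rows.append(
                    {
                        "patient_id": pid, "procedure_id": proc_id,
                        "drug_name": drug, "drug_class": drug_class,
                        "setting": "outpatient_fill",
                        "date": day(anchor, 3 + rng.integers(0, 8)),
                        "days_supply": int(1 + rng.integers(0, 7)),
                    }
                )

            # ---- latent event --------------------------------------------
            event_type = "none"
            if exposed:
                u = rng.random()
                if u < config.p_allergic_event:
                    event_type = "allergic"
                elif u < config.p_allergic_event + config.p_adverse_event:
                    event_type = "adverse"
                elif u < (config.p_allergic_event + config.p_adverse_event
                          + config.p_other_event):
                    event_type = "other"
            attribution_end = (
                min(last_exposure_day + 10, 45) if last_exposure_day is not None else 9
            )
            event_day = (
                int(rng.integers(0, attribution_end + 1))
                if event_type != "none" else None
            )
            allergic = event_type == "allergic"
            truth_rows.append(
                {
                    "procedure_id": proc_id,
                    "event_type": event_type,
                    "event_day_offset": event_day,
                    "culprit_class": drug_class if event_type != "none" else None,
                    "severity": _weighted_choice(rng, config.severity_mix)
                    if allergic else None,
                    "exposure_gt_24h": bool(duration > 1) if event_type != "none" else None,
                }
            )

            def signal_day() -> int:
                if allergic and event_day is not None:
                    return int(min(45, event_day + rng.integers(0, 3)))
                return int(rng.integers(0, 46))

            def fires(chan: str) -> bool:
                p1, p0 = probs[chan]
                return rng.random() < (p1 if allergic else p0)

            # ---- detection channels --------------------------------------
            if fires("art_observed"):
                art_rows.append(
                    {
                        "patient_id": pid, "entry_date": day(anchor, signal_day()),
                        "drug_name": drug, "entry_kind": "observed",
                        "reaction_text": REACTION_TEXTS[rng.integers(len(REACTION_TEXTS))],
                    }
                )
            if fires("art_historical"):
                art_rows.append(
                    {
                        "patient_id": pid, "entry_date": day(anchor, signal_day()),
                        "drug_name": drug, "entry_kind": "historical",
                        "reaction_text": REACTION_TEXTS[rng.integers(len(REACTION_TEXTS))],
                    }
                )
            if fires("keyword_note"):
                note_seq += 1
                note_rows.append(
                    {
                        "patient_id": pid, "date": day(anchor, signal_day()),
                        "note_id": f"N{note_seq:07d}",
                        "text": _positive_note(rng, drug),
                    }
                )
            anti = fires("antihistamine")
            steroid = fires("corticosteroid")
            med_day = signal_day()
            if anti:
                med_rows.append(
                    {"patient_id": pid, "date": day(anchor, med_day),
                     "med_class": "antihistamine", "route": "po"}
                )
            if steroid:
                # co-administered on the same day when both fire
                d = med_day if anti else signal_day()
                med_rows.append(
                    {"patient_id": pid, "date": day(anchor, d),
                     "med_class": "corticosteroid",
                     "route": "po" if rng.random() < 0.7 else "iv"}
                )
            if fires("epinephrine_iv"):
                med_rows.append(
                    {"patient_id": pid, "date": day(anchor, signal_day()),
                     "med_class": "epinephrine_iv", "route": "iv"}
                )
            if fires("new_allergy_icd"):
                dx_rows.append(
                    {
                        "patient_id": pid,
                        "date": day(anchor, max(1, signal_day())),
                        "icd10_code": NEW_ALLERGY_CODES[rng.integers(len(NEW_ALLERGY_CODES))],
                    }
                )
            for chan, codes in PHECODE_CHANNEL_CODES.items():
                if fires(chan):
                    dx_rows.append(
                        {
                            "patient_id": pid, "date": day(anchor, signal_day()),
                            "icd10_code": codes[rng.integers(len(codes))],
                        }
                    )
            if fires("consult_allergy"):
                consult_rows.append(
                    {"patient_id": pid, "date": day(anchor, signal_day()),
                     "specialty": "allergy"}
                )
            if fires("consult_dermatology"):
                consult_rows.append(
                    {"patient_id": pid, "date": day(anchor, signal_day()),
                     "specialty": "dermatology"}
                )
            if fires("prior_year_antibiotic_allergy"):
                art_rows.append(
                    {
                        "patient_id": pid,
                        "entry_date": day(anchor, -int(rng.integers(30, 366))),
                        "drug_name": drug, "entry_kind": "historical",
                        "reaction_text": REACTION_TEXTS[rng.integers(len(REACTION_TEXTS))],
                    }
                )

            # ---- background clutter --------------------------------------
            if rng.random() < config.p_prior_allergy_code:
                dx_rows.append(
                    {
                        "patient_id": pid,
                        "date": day(anchor, -int(rng.integers(30, 366))),
                        "icd10_code": NEW_ALLERGY_CODES[rng.integers(len(NEW_ALLERGY_CODES))],
                    }
                )
            if not allergic and rng.random() < config.noise_note_rate:
                note_seq += 1
                note_rows.append(
                    {
                        "patient_id": pid, "date": day(anchor, int(rng.integers(0, 46))),
                        "note_id": f"N{note_seq:07d}",
                        "text": _noise_note(rng, drug),
                    }
                )
            if event_type == "adverse":
                note_seq += 1
                note_rows.append(
                    {
                        "patient_id": pid, "date": day(anchor, signal_day()),
                        "note_id": f"N{note_seq:07d}",
                        "text": f"reports nausea and vomiting after {drug}. "
                                "advised supportive care.",
                    }
                )
            if rng.random() < 0.8:
                note_seq += 1
                note_rows.append(
                    {
                        "patient_id": pid, "date": day(anchor, int(rng.integers(0, 46))),
                        "note_id": f"N{note_seq:07d}",
                        "text": DISTRACTOR_NOTES[rng.integers(len(DISTRACTOR_NOTES))],
                    }
                )
            if rng.random() < 0.5:
                dx_rows.append(
                    {
                        "patient_id": pid, "date": day(anchor, int(rng.integers(0, 46))),
                        "icd10_code": DISTRACTOR_CODES[rng.integers(len(DISTRACTOR_CODES))],
                    }
                )

    def frame(rows, name):
        df = pd.DataFrame(rows, columns=TABLE_COLUMNS[name])
        if name == "truth" and len(df):
            df["event_day_offset"] = df["event_day_offset"].astype("Int64")
        return df

    bundle = EHRBundle(
        procedures=frame(proc_rows, "procedures"),
        exposures=frame(exp_rows, "exposures"),
        diagnoses=frame(dx_rows, "diagnoses"),
        art=frame(art_rows, "art"),
        med_admins=frame(med_rows, "med_admins"),
        notes=frame(note_rows, "notes"),
        consults=frame(consult_rows, "consults"),
        truth=frame(truth_rows, "truth"),
        meta={"config_hash": config.hash(), "seed": config.seed},
    )
    return bundle


def labels_from_truth(truth: pd.DataFrame) -> pd.Series:
    """0/1 adjudicated-allergic labels by procedure_id (simulated review)."""
    return pd.Series(
        (truth["event_type"] == "allergic").astype(int).to_numpy(),
        index=truth["procedure_id"],
        name="adjudicated_label",
    )


def adjudications_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Chart-review-shaped records derived from generator ground truth.

    Interventions and level-of-care changes are back-filled consistently
    with the latent severity grade (mild: untreated; moderate: treated;
    severe: treated with care escalation), mirroring what an adjudicator
    would have abstracted.
    """
    events = truth[truth["event_type"] != "none"].copy()
    rows = []
    for r in events.itertuples():
        sev = r.severity if r.event_type == "allergic" else None
        rows.append(
            {
                "procedure_id": r.procedure_id,
                "event_type": r.event_type,
                "culprit_class": r.culprit_class,
                "severity": sev,
                "interventions": "" if sev in (None, "mild") else "antihistamine",
                "level_of_care_change": sev == "severe",
                "intubation_or_icu": False,
                "exposure_gt_24h": bool(r.exposure_gt_24h),
                "prophylaxis_attributed": True,
                "art_observed_flag": False,
                "art_historical_flag": False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "procedure_id", "event_type", "culprit_class", "severity",
            "interventions", "level_of_care_change", "intubation_or_icu",
            "exposure_gt_24h", "prophylaxis_attributed",
            "art_observed_flag", "art_historical_flag",
        ],
    )


DATE_COLUMNS = {
    "procedures": ["procedure_date"],
    "exposures": ["date"],
    "diagnoses": ["date"],
    "art": ["entry_date"],
    "med_admins": ["date"],
    "notes": ["date"],
    "consults": ["date"],
    "truth": [],
}


def write_bundle(bundle: EHRBundle, directory) -> dict:
    """Write one CSV per table (ISO dates, UTF-8) plus a JSON manifest.

    Returns the manifest: file names, row counts and the config hash.
    """
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"files": {}, "config_hash": bundle.meta.get("config_hash")}
    for name, df in bundle.tables().items():
        out = df.copy()
        for col in DATE_COLUMNS[name]:
            if len(out):
                out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        path = directory / f"{name}.csv"
        out.to_csv(path, index=False)
        manifest["files"][f"{name}.csv"] = int(len(df))
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_bundle(directory) -> EHRBundle:
    """Read a bundle written by :func:`write_bundle`, parsing dates."""
    directory = pathlib.Path(directory)
    tables = {}
    for name, cols in TABLE_COLUMNS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise ValidationError(f"missing table file: {path.name}")
        dtypes = {"icd10_code": str}
        if name == "truth":
            dtypes["event_day_offset"] = "Int64"
        df = pd.read_csv(path, dtype=dtypes)
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValidationError(f"{path.name} missing columns {sorted(missing)}")
        for col in DATE_COLUMNS[name]:
            df[col] = pd.to_datetime(df[col], format="%Y-%m-%d", errors="raise")
        if name == "truth" and len(df):
            df["exposure_gt_24h"] = df["exposure_gt_24h"].map(
                {"True": True, "False": False, True: True, False: False}
            )
        tables[name] = df[cols]
    meta = {}
    mpath = directory / "manifest.json"
    if mpath.exists():
        meta = json.loads(mpath.read_text())
        meta = {"config_hash": meta.get("config_hash")}
    return EHRBundle(meta=meta, **tables)
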