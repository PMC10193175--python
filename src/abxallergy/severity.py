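"""Severity grading and event-type classification of adjudicated reactions.

Severity of an allergic-type reaction follows a three-level clinical scale:

* **mild** — no treatment and no change in level of care;
* **moderate** — treated (antihistamine, corticosteroid or IV epinephrine)
  without a change in level of care;
* **severe** — treated with a change in level of care, or any
  intubation / ICU admission.

Intubation or ICU admission forces the severe grade even when no
premedication was recorded: an intubated patient must not grade mild on a
documentation gap.

Event types distinguish immune-mediated hypersensitivity (rash, hives,
anaphylaxis — "allergic-type") from non-immune adverse drug responses
(nausea, vomiting, diarrhea) and everything else ("other").  The
classifier here is advisory; manual adjudication remains ground truth.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import pandas as pd

from .errors import ContractError
from .reference import ANTIBIOTIC_CLASSES

VALID_INTERVENTIONS = {"antihistamine", "corticosteroid", "epinephrine_iv"}

#: Hypersensitivity terms that mark an event allergic-type.
HYPERSENSITIVITY_TERMS = frozenset(
    {
        "rash", "hives", "urticaria", "itching", "pruritus", "swelling",
        "angioedema", "anaphylaxis", "wheeze", "wheezing",
        "shortness of breath", "flushing",
    }
)

#: Non-immune adverse-response terms (GI-dominant).
NONIMMUNE_TERMS = frozenset(
    {"nausea", "vomiting", "diarrhea", "headache", "dizziness", "fever"}
)


@dataclasses.dataclass
class AdjudicationRecord:
    """One manually adjudicated case.

    ``interventions`` is the set of anti-allergy treatments administered;
    ``exposure_gt_24h`` marks attribution to prophylaxis continued beyond
    24 h after skin closure.
    """

    procedure_id: str
    event_type: str  # allergic | adverse | other | none
    event_date: dt.date | None = None
    culprit_class: str | None = None
    interventions: frozenset = frozenset()
    level_of_care_change: bool = False
    intubation_or_icu: bool = False
    exposure_gt_24h: bool = False
    art_observed_flag: bool = False
    art_historical_flag: bool = False

    def __post_init__(self):
        self.interventions = frozenset(self.interventions)
        bad = self.interventions - VALID_INTERVENTIONS
        if bad:
            raise ContractError(f"unknown interventions: {sorted(bad)}")
        if self.event_type == "none" and (
            self.interventions or self.level_of_care_change
            or self.intubation_or_icu or self.event_date is not None
        ):
            raise ContractError("event_type=none requires empty event fields")


def classify_severity(record: AdjudicationRecord) -> str:
    """Grade an allergic-type reaction as mild / moderate / severe.

    Severe iff (any intervention AND level-of-care change) OR intubation /
    ICU; moderate iff any intervention and not severe; mild otherwise.
    Total over all flag combinations: every record maps to exactly one
    grade.  Calling this on a non-allergic record is a contract error.
    """
    if record.event_type != "allergic":
        raise ContractError(
            f"severity is defined for allergic events, got {record.event_type!r}"
        )
    treated = bool(record.interventions)
    if record.intubation_or_icu or (treated and record.level_of_care_change):
        return "severe"
    if treated:
        return "moderate"
    return "mild"


def classify_event_type(
    symptom_terms,
    hypersensitivity_terms=HYPERSENSITIVITY_TERMS,
    nonimmune_terms=NONIMMUNE_TERMS,
) -> str:
    """Advisory event-type call from abstracted symptom terms.

    Hypersensitivity dominates: any immune-type term makes the event
    allergic even when GI terms co-occur; otherwise any non-immune term
    makes it adverse; anything else is other.
    """
    terms = {str(t).lower().strip() for t in symptom_terms}
    if not terms:
        raise ContractError("symptom set must be nonempty")
    if terms & set(hypersensitivity_terms):
        return "allergic"
    if terms & set(nonimmune_terms):
        return "adverse"
    return "other"


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "interventions" in df.columns:
            df["interventions"] = df["interventions"].apply(
                lambda v: frozenset()
                if v is None or (isinstance(v, float) and pd.isna(v)) or v == ""
                else frozenset(str(v).split(";")) if isinstance(v, str) else frozenset(v)
            )
        return df
    return pd.DataFrame(
        [
            {
                "procedure_id": r.procedure_id,
                "event_type": r.event_type,
                "culprit_class": r.culprit_class,
                "interventions": r.interventions,
                "level_of_care_change": r.level_of_care_change,
                "intubation_or_icu": r.intubation_or_icu,
                "exposure_gt_24h": r.exposure_gt_24h,
                "art_observed_flag": r.art_observed_flag,
                "art_historical_flag": r.art_historical_flag,
            }
            for r in records
        ]
    )


def severity_summary(records) -> pd.DataFrame:
    """Summarize allergic-type reactions by antibiotic class.

    ``records`` is an iterable of :class:`AdjudicationRecord` or an
    equivalent DataFrame (``interventions`` as a ';'-joined string).  If a
    ``severity`` column is absent it is derived with
    :func:`classify_severity`.  Reactions without a culprit class group
    under ``unattributed``.  Returns per-class reaction counts and
    percentages, intervention counts, severity counts, and a totals row.
    """
    df = _records_frame(records)
    cols = [
        "antibiotic_class", "reactions", "pct", "antihistamine",
        "corticosteroid", "epinephrine_iv", "mild", "moderate", "severe",
        "intubation_or_icu",
    ]
    if len(df) == 0:
        total = {c: 0 for c in cols}
        total["antibiotic_class"] = "total"
        total["pct"] = 0.0
        return pd.DataFrame([total], columns=cols)

    df = df[df["event_type"] == "allergic"].copy()
    if "severity" not in df.columns or df["severity"].isna().any():
        df["severity"] = [
            classify_severity(
                AdjudicationRecord(
                    procedure_id=str(r.procedure_id),
                    event_type="allergic",
                    interventions=r.interventions,
                    level_of_care_change=bool(r.level_of_care_change),
                    intubation_or_icu=bool(r.intubation_or_icu),
                )
            )
            for r in df.itertuples()
        ]
    df["culprit_class"] = df["culprit_class"].fillna("unattributed")

    rows = []
    classes = [c for c in ANTIBIOTIC_CLASSES if c in set(df["culprit_class"])]
    classes += sorted(set(df["culprit_class"]) - set(ANTIBIOTIC_CLASSES))
    n_total = len(df)
    for cls in classes:
        sub = df[df["culprit_class"] == cls]
        rows.append(
            {
                "antibiotic_class": cls,
                "reactions": len(sub),
                "pct": 100.0 * len(sub) / n_total,
                "antihistamine": int(sub["interventions"].apply(lambda s: "antihistamine" in s).sum()),
                "corticosteroid": int(sub["interventions"].apply(lambda s: "corticosteroid" in s).sum()),
                "epinephrine_iv": int(sub["interventions"].apply(lambda s: "epinephrine_iv" in s).sum()),
                "mild": int((sub["severity"] == "mild").sum()),
                "moderate": int((sub["severity"] == "moderate").sum()),
                "severe": int((sub["severity"] == "severe").sum()),
                "intubation_or_icu": int(sub["intubation_or_icu"].sum()),
            }
        )
    out = pd.DataFrame(rows, columns=cols)
    total = out.drop(columns=["antibiotic_class", "pct"]).sum()
    total_row = {"antibiotic_class": "total", "pct": 100.0, **total.to_dict()}
    return pd.concat([out, pd.DataFrame([total_row], columns=cols)], ignore_index=True)


def adjudication_summary(records) -> dict:
    """Cohort-level marginals of an adjudicated reaction set.

    Reports, over allergic-type reactions: the total count, the count and
    percent attributed to prophylaxis, and — among prophylaxis-attributed
    reactions — observed / historical allergy-module flag prevalence, the
    share with no allergy-module entry, and the share attributed to >24 h
    of antibiotic exposure.
    """
    df = _records_frame(records)
    df = df[df["event_type"] == "allergic"]
    out = {"n_reactions": int(len(df))}
    if "prophylaxis_attributed" in df.columns:
        sub = df[df["prophylaxis_attributed"].astype(bool)]
    else:
        sub = df
    n = len(sub)
    out["n_prophylaxis_attributed"] = int(n)
    if n:
        obs = int(sub["art_observed_flag"].astype(bool).sum())
        hist = int(sub["art_historical_flag"].astype(bool).sum())
        unlisted = int(
            (~sub["art_observed_flag"].astype(bool)
             & ~sub["art_historical_flag"].astype(bool)).sum()
        )
        out.update(
            art_observed_n=obs,
            art_observed_pct=100.0 * obs / n,
            art_historical_n=hist,
            art_historical_pct=100.0 * hist / n,
            not_in_allergy_module_n=unlisted,
            not_in_allergy_module_pct=100.0 * unlisted / n,
            exposure_gt_24h_n=int(sub["exposure_gt_24h"].astype(bool).sum()),
            exposure_gt_24h_pct=100.0 * sub["exposure_gt_24h"].astype(bool).mean(),
        )
    return out
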