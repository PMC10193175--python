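"""Analytic cohort construction, exposure duration, and case windows.

A procedure enters the cohort when at least one antibiotic exposure falls
within one day of the procedure (day offsets {-1, 0, +1}; all intervals on
the day axis are closed).  Exposure duration is the number of distinct
covered calendar days: an inpatient administration covers its own day, an
outpatient fill covers ``[fill_date, fill_date + days_supply - 1]``, with
overlaps counted once and coverage capped at procedure day +45.

Each included case gets two windows:

* **extraction window** — [procedure, procedure + 45 d], the span from
  which detection variables are drawn;
* **attribution window** — [procedure, min(last exposure + 10 d,
  procedure + 45 d)], the span in which an event is attributable to the
  periprocedural antibiotics.

The train/test split is randomized at the *patient* level (all procedures
of a patient land on one side) so no patient straddles model fitting and
validation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError
from .synthetic_ehr import EHRBundle

logger = logging.getLogger(__name__)

EXTRACTION_DAYS = 45
ATTRIBUTION_LAG_DAYS = 10


def _covered_days(exposures: pd.DataFrame, procedure_date: pd.Timestamp) -> set:
    """Day offsets (from the procedure) covered by a case's exposures."""
    days: set[int] = set()
    for r in exposures.itertuples():
        offset = int((pd.Timestamp(r.date) - procedure_date).days)
        if r.setting == "inpatient_admin":
            span = 1
        elif r.setting == "outpatient_fill":
            supply = int(r.days_supply)
            if supply < 0:
                raise ValidationError(f"negative days_supply ({supply})")
            span = max(supply, 0)
        else:
            raise ValidationError(f"unknown exposure setting {r.setting!r}")
        for d in range(offset, offset + span):
            if -1 <= d <= EXTRACTION_DAYS:
                days.add(d)
    return days


def exposure_duration(exposures: pd.DataFrame, procedure_date) -> int:
    """Distinct covered exposure days for one case (capped at day +45)."""
    return len(_covered_days(exposures, pd.Timestamp(procedure_date)))


def build_cohort(bundle: EHRBundle) -> pd.DataFrame:
    """One row per procedure with inclusion flag and exposure summary.

    Exposure linkage is by ``procedure_id`` restricted to dates within
    [procedure - 1 d, procedure + 45 d]; the inclusion rule is an exposure
    within one day of the procedure.  Procedures with unparseable dates
    are excluded with a logged reason rather than aborting the build.
    """
    procs = bundle.procedures.copy()
    procs["procedure_date"] = pd.to_datetime(procs["procedure_date"], errors="coerce")
    bad = procs["procedure_date"].isna()
    for pid in procs.loc[bad, "procedure_id"]:
        logger.warning("procedure %s excluded: invalid date", pid)

    exp_groups: dict = {}
    if len(bundle.exposures):
        exp = bundle.exposures.merge(
            procs.loc[~bad, ["procedure_id", "procedure_date"]],
            on="procedure_id", how="inner",
        )
        exp["offset"] = (
            pd.to_datetime(exp["date"]) - exp["procedure_date"]
        ).dt.days.astype(int)
        exp = exp[(exp["offset"] >= -1) & (exp["offset"] <= EXTRACTION_DAYS)]
        if (exp["days_supply"].fillna(0) < 0).any():
            raise ValidationError("negative days_supply in exposures")
        exp_groups = {k: g for k, g in exp.groupby("procedure_id", sort=False)}

    rows = []
    for r in procs.itertuples():
        if pd.isna(r.procedure_date):
            rows.append(
                {
                    "procedure_id": r.procedure_id, "patient_id": r.patient_id,
                    "procedure_date": pd.NaT, "included": False,
                    "exposure_days": 0, "last_exposure_day": None,
                    "antibiotic_classes": frozenset(),
                }
            )
            continue
        g = exp_groups.get(r.procedure_id)
        if g is None or len(g) == 0:
            included, days, classes = False, set(), frozenset()
        else:
            days = set()
            for e in zip(g["offset"], g["setting"], g["days_supply"].fillna(0)):
                offset, setting, supply = int(e[0]), e[1], int(e[2])
                if setting == "inpatient_admin":
                    span = 1
                elif setting == "outpatient_fill":
                    span = max(supply, 0)
                else:
                    raise ValidationError(f"unknown exposure setting {setting!r}")
                days.update(
                    d for d in range(offset, offset + span)
                    if -1 <= d <= EXTRACTION_DAYS
                )
            included = bool(g["offset"].isin([-1, 0, 1]).any())
            classes = frozenset(g["drug_class"].unique())
        rows.append(
            {
                "procedure_id": r.procedure_id,
                "patient_id": r.patient_id,
                "procedure_date": r.procedure_date,
                "included": included,
                "exposure_days": len(days),
                "last_exposure_day": max(days) if days else None,
                "antibiotic_classes": classes,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "procedure_id", "patient_id", "procedure_date", "included",
            "exposure_days", "last_exposure_day", "antibiotic_classes",
        ],
    )


def case_windows(cohort: pd.DataFrame) -> pd.DataFrame:
    """Extraction and attribution windows for the included cases.

    All boundaries inclusive.  A preprocedural-only exposure (last
    exposure on day -1) yields an attribution window ending on day +9.
    """
    rows = []
    for r in cohort[cohort["included"]].itertuples():
        last = r.last_exposure_day
        if last is None or pd.isna(last):
            raise ValidationError(
                f"included case {r.procedure_id} has no linked exposure"
            )
        last = int(last)
        if last < -1:
            raise ValidationError(
                f"case {r.procedure_id}: last exposure precedes day -1"
            )
        attr_end = min(last + ATTRIBUTION_LAG_DAYS, EXTRACTION_DAYS)
        rows.append(
            {
                "procedure_id": r.procedure_id,
                "extraction_start": r.procedure_date,
                "extraction_end": r.procedure_date + pd.Timedelta(days=EXTRACTION_DAYS),
                "attribution_end": r.procedure_date + pd.Timedelta(days=attr_end),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["procedure_id", "extraction_start", "extraction_end",
                 "attribution_end"],
    )


def split_train_test(cohort: pd.DataFrame, seed: int = 0):
    """Patient-level randomized split into near-equal procedure halves.

    Patients are shuffled (seeded), ordered by descending procedure count
    within the shuffle, and greedily assigned to the currently smaller
    arm; this keeps the arm sizes within one procedure of each other
    whenever the per-patient counts permit, while never splitting a
    patient across arms.

    Returns ``(train_ids, test_ids)`` lists of procedure ids.
    """
    if len(cohort) == 0:
        raise ValidationError("cannot split an empty cohort")
    rng = np.random.default_rng(seed)
    counts = cohort.groupby("patient_id")["procedure_id"].apply(list)
    patients = sorted(counts.index)
    order = rng.permutation(len(patients))
    shuffled = [patients[i] for i in order]
    shuffled.sort(key=lambda p: -len(counts[p]))  # stable: keeps shuffle order

    train: list = []
    test: list = []
    for p in shuffled:
        target = train if len(train) <= len(test) else test
        target.extend(counts[p])
    return train, test
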