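"""Chart-review sampling: probability strata and review-sample selection.

Two sampling designs feed the manual-adjudication stages:

* **coverage sampling** for the training arm — charts are picked so that
  every candidate detection variable is represented a minimum number of
  times, plus a block of flag-free negatives, so the model sees both
  signal and background;
* **weighted (outcome-enriched) sampling** for the test arm — simple
  random samples within estimated-probability strata, oversampling
  high-probability cases so the positive predictive value can be
  estimated from a feasible number of chart reviews.

A *stratum table* is a DataFrame with columns ``stratum``, ``prob_lo``,
``prob_hi`` (half-open bins (lo, hi]), ``cohort_n``, ``reviewed_n`` and
``allergic_n``; the ten default bins are (0, 0.10], (0.10, 0.20], ...,
(0.90, 1].
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .reference import DEFAULT_TEST_PLAN_COUNTS, STRATUM_EDGES, STRATUM_LABELS

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SamplingPlan:
    """Per-stratum chart-review targets for the weighted test sample.

    ``targets`` maps stratum index (0 = lowest probability bin) to the
    number of charts to draw from that stratum without replacement.
    """

    targets: dict[int, int]
    seed: int = 0

    def validate(self) -> None:
        for k, v in self.targets.items():
            if not (0 <= int(k) < len(STRATUM_LABELS)):
                raise ConfigurationError(f"unknown stratum index {k}")
            if int(v) < 0:
                raise ConfigurationError(f"negative target for stratum {k}")


def default_test_plan(seed: int = 0) -> SamplingPlan:
    """The review allocation realized in the development cohort's test arm.

    The original allocation was described as predetermined but arbitrary;
    this default is a replication convenience, not an optimal design.
    """
    return SamplingPlan(
        targets={i: n for i, n in enumerate(DEFAULT_TEST_PLAN_COUNTS)},
        seed=seed,
    )


def assign_strata(scores: pd.Series) -> pd.Series:
    """Map each estimated probability to its stratum index (0-9).

    Bins are half-open (lo, hi]: a score of exactly 0.10 falls in the
    lowest bin, 0.101 in the second.  Scores must lie in (0, 1).
    """
    p = np.asarray(scores, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValidationError("probabilities must lie strictly inside (0, 1)")
    # right-closed bins: searchsorted on the left edges
    idx = np.searchsorted(STRATUM_EDGES, p, side="left") - 1
    return pd.Series(idx, index=scores.index, name="stratum")


def stratify(scores: pd.Series) -> pd.DataFrame:
    """Build a stratum table with ``cohort_n`` filled from scored cases."""
    idx = assign_strata(scores)
    counts = idx.value_counts().reindex(range(10), fill_value=0)
    table = pd.DataFrame(
        {
            "stratum": STRATUM_LABELS,
            "prob_lo": STRATUM_EDGES[:-1],
            "prob_hi": STRATUM_EDGES[1:],
            "cohort_n": counts.to_numpy(),
            "reviewed_n": 0,
            "allergic_n": 0,
        }
    )
    return table


def validate_stratum_table(table: pd.DataFrame) -> None:
    """Check ordering, disjointness and count monotonicity invariants."""
    required = {"prob_lo", "prob_hi", "reviewed_n", "allergic_n"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"stratum table missing columns: {sorted(missing)}")
    lo = table["prob_lo"].to_numpy(float)
    hi = table["prob_hi"].to_numpy(float)
    if not (np.all(np.diff(lo) > 0) and np.allclose(lo[1:], hi[:-1])):
        raise ValidationError("strata must be ordered, disjoint and contiguous")
    if (table["allergic_n"] > table["reviewed_n"]).any():
        raise ValidationError("allergic_n exceeds reviewed_n in some stratum")
    if "cohort_n" in table.columns:
        cohort = table["cohort_n"]
        bad = cohort.notna() & (table["reviewed_n"] > cohort)
        if bad.any():
            raise ValidationError("reviewed_n exceeds cohort_n in some stratum")


def coverage_sample_training(
    features: pd.DataFrame,
    negatives_target: int = 60,
    per_variable_target: int = 5,
    seed: int = 0,
) -> list:
    """Select training charts so every candidate variable is represented.

    For each binary feature column, tops up the selection with random
    flagged cases until at least ``per_variable_target`` selected cases
    carry that flag (or the flagged pool is exhausted, which is logged as
    uncoverable).  Then adds ``negatives_target`` cases with no flags set.
    Deterministic for a fixed seed and input order-invariant (cases are
    processed in sorted-id order).

    Returns the selected case ids (index values of ``features``).
    """
    rng = np.random.default_rng(seed)
    feats = features.sort_index()
    flag_cols = [c for c in feats.columns if feats[c].dropna().isin([0, 1]).all()]
    selected: list = []
    selected_set: set = set()

    for col in flag_cols:
        flagged = feats.index[feats[col] == 1]
        have = sum(1 for i in selected if feats.at[i, col] == 1)
        need = per_variable_target - have
        if need <= 0:
            continue
        pool = [i for i in flagged if i not in selected_set]
        if len(flagged) == 0:
            logger.warning("variable %s has no flagged cases; uncoverable", col)
            continue
        if len(pool) < need:
            logger.warning(
                "variable %s: only %d additional flagged cases available "
                "(target %d)", col, len(pool), need,
            )
        take = rng.choice(len(pool), size=min(need, len(pool)), replace=False)
        for j in sorted(take):
            selected.append(pool[j])
            selected_set.add(pool[j])

    negatives = feats.index[(feats[flag_cols] == 0).all(axis=1)]
    pool = [i for i in negatives if i not in selected_set]
    if len(pool) < negatives_target:
        logger.warning(
            "only %d flag-free negatives available (target %d)",
            len(pool), negatives_target,
        )
    take = rng.choice(len(pool), size=min(negatives_target, len(pool)), replace=False)
    for j in sorted(take):
        selected.append(pool[j])
        selected_set.add(pool[j])
    return selected


def weighted_sample_test(scores: pd.Series, plan: SamplingPlan) -> list:
    """Draw the stratified test review sample without replacement.

    ``scores`` are estimated probabilities indexed by case id.  Within each
    stratum a simple random sample of the planned size is drawn; if a
    stratum holds fewer cases than planned, the whole stratum is taken and
    a warning is logged.  Bit-reproducible for a fixed plan and seed,
    invariant to the ordering of ``scores``.
    """
    plan.validate()
    strata = assign_strata(scores)
    rng = np.random.default_rng(plan.seed)
    chosen: list = []
    for k in range(10):
        target = int(plan.targets.get(k, 0))
        if target == 0:
            continue
        members = sorted(scores.index[strata == k])
        if len(members) < target:
            logger.warning(
                "stratum %s holds %d cases; plan asked for %d — taking all",
                STRATUM_LABELS[k], len(members), target,
            )
            chosen.extend(members)
            continue
        take = rng.choice(len(members), size=target, replace=False)
        chosen.extend(members[j] for j in sorted(take))
    return chosen


def review_counts(
    sample_ids, scores: pd.Series, adjudicated_allergic: pd.Series
) -> pd.DataFrame:
    """Fill ``reviewed_n`` / ``allergic_n`` of the stratum table for a sample.

    ``adjudicated_allergic`` is a 0/1 series indexed by case id covering at
    least the sampled cases.
    """
    table = stratify(scores)
    strata = assign_strata(scores)
    sample_ids = list(sample_ids)
    reviewed = strata.loc[sample_ids]
    table["reviewed_n"] = (
        reviewed.value_counts().reindex(range(10), fill_value=0).to_numpy()
    )
    allergic = reviewed[adjudicated_allergic.loc[sample_ids].astype(bool).to_numpy()]
    table["allergic_n"] = (
        allergic.value_counts().reindex(range(10), fill_value=0).to_numpy()
    )
    return table
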