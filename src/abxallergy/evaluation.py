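"""Criterion validity of the detection algorithm against chart review.

Performance is computed from a stratum table (probability bin x cohort /
reviewed / adjudicated-allergic counts) at a probability cutoff aligned
with the bin edges:

* PPV   = adjudicated allergic / reviewed, over strata above the cutoff;
* sensitivity = allergic above cutoff / all reviewed allergic;
* specificity = non-allergic below cutoff / all reviewed non-allergic.

Because the review sample is outcome-enriched (high-probability strata
are oversampled), sensitivity and specificity are *sample-conditional*
quantities: they describe the reviewed charts, not the source population.
Confidence intervals are exact Clopper-Pearson binomial intervals.
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IntegrityError, ValidationError
from .sampling import (
    STRATUM_EDGES,
    assign_strata,
    review_counts,
    stratify,
    validate_stratum_table,
)


class Proportion(NamedTuple):
    """A point estimate with its exact 95% CI and underlying counts.

    ``point`` is NaN when the quantity is not estimable (0 denominator);
    a not-estimable proportion is never reported as 0.
    """

    point: float
    low: float
    high: float
    successes: int
    trials: int

    @property
    def estimable(self) -> bool:
        return self.trials > 0


def exact_binomial_ci(successes: int, trials: int, level: float = 0.95):
    """Clopper-Pearson exact binomial confidence interval.

    Uses the beta-quantile form: the lower bound is the ``alpha/2``
    quantile of Beta(k, n-k+1) (0 when k=0) and the upper bound the
    ``1-alpha/2`` quantile of Beta(k+1, n-k) (1 when k=n).
    """
    successes, trials = int(successes), int(trials)
    if trials < 1 or not 0 <= successes <= trials:
        raise ValidationError(f"invalid counts ({successes}, {trials})")
    if not 0.0 < level < 1.0:
        raise ValidationError("confidence level must be in (0, 1)")
    alpha = 1.0 - level
    low = 0.0 if successes == 0 else stats.beta.ppf(alpha / 2, successes, trials - successes + 1)
    high = 1.0 if successes == trials else stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes)
    return float(low), float(high)


def _proportion(successes: int, trials: int) -> Proportion:
    if trials == 0:
        return Proportion(math.nan, math.nan, math.nan, 0, 0)
    low, high = exact_binomial_ci(successes, trials)
    return Proportion(successes / trials, low, high, int(successes), int(trials))


@dataclasses.dataclass
class PerformanceReport:
    """Operating characteristics of the algorithm at one cutoff."""

    cutoff: float
    ppv: Proportion
    sensitivity: Proportion
    specificity: Proportion
    stratum_table: pd.DataFrame
    n_below_cutoff: int
    c_statistic: float = math.nan

    def to_dict(self) -> dict:
        def prop(p: Proportion) -> dict:
            return {
                "point": None if not p.estimable else p.point,
                "ci95": None if not p.estimable else [p.low, p.high],
                "successes": p.successes,
                "trials": p.trials,
            }

        return {
            "cutoff": self.cutoff,
            "ppv": prop(self.ppv),
            "sensitivity": prop(self.sensitivity),
            "specificity": prop(self.specificity),
            "n_below_cutoff": int(self.n_below_cutoff),
            "c_statistic": None if math.isnan(self.c_statistic) else self.c_statistic,
        }


def stratum_performance(strata: pd.DataFrame, cutoff: float) -> PerformanceReport:
    """Compute PPV / sensitivity / specificity from a stratum table.

    ``cutoff`` must coincide with a stratum boundary; "above the cutoff"
    means strata whose lower edge is >= cutoff (so cutoff 0.30 flags the
    (0.30, 0.40] bin upward, matching a ">30%" decision rule).
    """
    validate_stratum_table(strata)
    lo = strata["prob_lo"].to_numpy(float)
    if not np.any(np.isclose(lo, cutoff)):
        raise ValidationError(f"cutoff {cutoff} does not align with stratum edges")
    above = lo >= cutoff - 1e-12

    reviewed = strata["reviewed_n"].to_numpy(int)
    allergic = strata["allergic_n"].to_numpy(int)
    ppv = _proportion(allergic[above].sum(), reviewed[above].sum())
    total_allergic = allergic.sum()
    sens = _proportion(allergic[above].sum(), total_allergic)
    nonallergic = reviewed - allergic
    spec = _proportion(nonallergic[~above].sum(), nonallergic.sum())

    if "cohort_n" in strata.columns and strata["cohort_n"].notna().all():
        n_below = int(strata.loc[~above, "cohort_n"].sum())
    else:
        n_below = int(reviewed[~above].sum())
    return PerformanceReport(
        cutoff=float(cutoff),
        ppv=ppv,
        sensitivity=sens,
        specificity=spec,
        stratum_table=strata.copy(),
        n_below_cutoff=n_below,
    )


def art_only_report(
    art_flags: pd.Series, adjudicated_allergic: pd.Series
) -> PerformanceReport:
    """Operating characteristics of the observed-allergy-flag comparator.

    The simplest deployable rule flags a case when the allergy module
    carries an observed entry; no probability model involved.  Both series
    are 0/1 and must share an index (the reviewed charts).
    """
    if not art_flags.index.equals(adjudicated_allergic.index):
        raise IntegrityError("comparator and adjudications cover different cases")
    flag = art_flags.astype(bool)
    truth = adjudicated_allergic.astype(bool)
    ppv = _proportion((flag & truth).sum(), flag.sum())
    sens = _proportion((flag & truth).sum(), truth.sum())
    spec = _proportion((~flag & ~truth).sum(), (~truth).sum())
    table = pd.DataFrame(
        {
            "stratum": ["flag=0", "flag=1"],
            "prob_lo": [0.0, 0.5],
            "prob_hi": [0.5, 1.0],
            "cohort_n": [int((~flag).sum()), int(flag.sum())],
            "reviewed_n": [int((~flag).sum()), int(flag.sum())],
            "allergic_n": [int((~flag & truth).sum()), int((flag & truth).sum())],
        }
    )
    return PerformanceReport(
        cutoff=0.5, ppv=ppv, sensitivity=sens, specificity=spec,
        stratum_table=table, n_below_cutoff=int((~flag).sum()),
    )


def compare_models(
    report_full: PerformanceReport, report_simple: PerformanceReport
) -> pd.DataFrame:
    """Side-by-side comparison of two performance reports.

    Both reports must describe the same adjudicated sample (same total
    reviewed and allergic counts); differences are full minus simple.
    Non-estimable entries propagate as NaN.
    """
    n_full = report_full.stratum_table["reviewed_n"].sum()
    n_simple = report_simple.stratum_table["reviewed_n"].sum()
    a_full = report_full.stratum_table["allergic_n"].sum()
    a_simple = report_simple.stratum_table["allergic_n"].sum()
    if (n_full, a_full) != (n_simple, a_simple):
        raise IntegrityError(
            "reports describe different samples: "
            f"({n_full} reviewed, {a_full} allergic) vs ({n_simple}, {a_simple})"
        )
    rows = []
    for name in ("ppv", "sensitivity", "specificity"):
        pf: Proportion = getattr(report_full, name)
        ps: Proportion = getattr(report_simple, name)
        rows.append(
            {
                "metric": name,
                "full": pf.point,
                "full_ci_low": pf.low,
                "full_ci_high": pf.high,
                "simple": ps.point,
                "simple_ci_low": ps.low,
                "simple_ci_high": ps.high,
                "difference": pf.point - ps.point,
            }
        )
    return pd.DataFrame(rows)


def stratum_report(
    scores: pd.Series,
    review_ids,
    adjudicated_allergic: pd.Series,
    cutoff: float = 0.30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full stratum report for a scored cohort with a reviewed subsample.

    Returns ``(table, per_side)`` where ``table`` has one row per
    probability stratum (cohort count with percent, reviewed and
    adjudicated-allergic counts, reviewed percent) and ``per_side`` gives
    the pooled PPV below/above the cutoff.  Adjudications for cases
    outside the review sample are ignored with a warning.
    """
    review_ids = list(review_ids)
    known = [i for i in review_ids if i in scores.index]
    extra = set(adjudicated_allergic.index) - set(known)
    if extra:
        import logging

        logging.getLogger(__name__).warning(
            "%d adjudications do not match a sampled case; excluded", len(extra)
        )
    adj = adjudicated_allergic.reindex(known).fillna(0)
    table = review_counts(known, scores, adj)
    total = table["cohort_n"].sum()
    table["cohort_pct"] = 100.0 * table["cohort_n"] / max(total, 1)
    rev_total = table["reviewed_n"].sum()
    table["reviewed_pct"] = 100.0 * table["reviewed_n"] / max(rev_total, 1)

    lo = table["prob_lo"].to_numpy(float)
    above = lo >= cutoff - 1e-12
    sides = []
    for label, mask in (("below", ~above), ("above", above)):
        rev = int(table.loc[mask, "reviewed_n"].sum())
        alg = int(table.loc[mask, "allergic_n"].sum())
        p = _proportion(alg, rev)
        sides.append(
            {
                "side": label,
                "cohort_n": int(table.loc[mask, "cohort_n"].sum()),
                "reviewed_n": rev,
                "allergic_n": alg,
                "ppv": p.point,
                "ppv_ci_low": p.low,
                "ppv_ci_high": p.high,
            }
        )
    return table, pd.DataFrame(sides)


def format_stratum_table(table: pd.DataFrame) -> str:
    """Render a stratum table as aligned plain text (whole-percent display)."""
    out = ["stratum    cohort_n (%)      reviewed  allergic"]
    for _, r in table.iterrows():
        pct = f"({r['cohort_pct']:.1f})" if "cohort_pct" in table.columns else ""
        cohort = "NA" if pd.isna(r.get("cohort_n")) else f"{int(r['cohort_n']):>7d}"
        out.append(
            f"{r['stratum']:<9s} {cohort} {pct:<8s} "
            f"{int(r['reviewed_n']):>8d} {int(r['allergic_n']):>9d}"
        )
    return "\n".join(out)
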