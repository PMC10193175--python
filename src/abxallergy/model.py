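"""Detection model: L1-penalized variable selection and logistic scoring.

The detection score is a plain logistic regression over binary EHR flags,
fit on the adjudicated training review sample.  Variable selection uses
L1-penalized (lasso) logistic regression along a decreasing penalty path
with 10-fold cross-validated deviance and the one-standard-error rule;
the selected variables are then refit unpenalized by maximum likelihood
so coefficients and Wald intervals are unshrunken.

The penalized solver is written here (iteratively reweighted least
squares with cyclic coordinate descent, intercept unpenalized, flags not
standardized — they share a scale already) so that every path point can
be certified against the exact stationarity (KKT) conditions:

* ``|g_j| <= lambda``            for zero coefficients,
* ``g_j + lambda * sign(b_j) = 0`` for active coefficients,

with ``g = (1/n) X'(p - y)`` the exact log-likelihood gradient.

Quasi-separation is expected (the strongest flag carries an odds ratio
near 175 in the development cohort): the refit falls back to Firth's
bias-reduced likelihood when ordinary ML diverges, and the report says
which method produced the estimates.

Probabilities estimated on the outcome-enriched review sample are applied
to the cohort without recalibration, mirroring the original deployment;
an optional intercept shift to a target prevalence is available but off
by default.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy.stats import rankdata

from .errors import ConfigurationError, EstimationError, IntegrityError, ValidationError
from .reference import REFERENCE_ADJUSTED_OR, REFERENCE_CUTOFF, REFERENCE_UNADJUSTED_OR

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# penalized solver


def _sigmoid(eta):
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    intercept: float = 0.0,
    beta: np.ndarray | None = None,
    max_outer: int = 200,
    tol: float = 1e-11,
    kkt_tol: float = 1e-9,
):
    """Solve min (1/n) sum log(1+e^eta) - y.eta + lam*||beta||_1.

    IRLS outer loop with cyclic coordinate descent on the weighted
    quadratic approximation; warm-startable.  Returns (intercept, beta).
    """
    n, p = X.shape
    beta = np.zeros(p) if beta is None else beta.copy()
    # binary flag columns admit index-set coordinate updates (x_ij in {0,1})
    binary = bool(np.all((X == 0.0) | (X == 1.0)))
    nz = [np.flatnonzero(X[:, j]) for j in range(p)] if binary else None
    Xsq = None if binary else X * X
    for _ in range(max_outer):
        eta = intercept + X @ beta
        prob = _sigmoid(eta)
        w = np.clip(prob * (1.0 - prob), 1e-9, None)
        z = eta + (y - prob) / w
        r = z - eta  # working residual
        if binary:
            w_nz = [w[idx] for idx in nz]
            denom = np.array([wj.sum() / n for wj in w_nz])
        else:
            denom = (w[:, None] * Xsq).sum(axis=0) / n
        w_sum = w.sum()
        max_delta = np.inf
        for _ in range(1000):
            max_delta = 0.0
            for j in range(p):
                if denom[j] <= 0:
                    continue
                bj = beta[j]
                if binary:
                    rho = (w_nz[j] * r[nz[j]]).sum() / n + denom[j] * bj
                else:
                    rho = (w * X[:, j] * r).sum() / n + denom[j] * bj
                new = _soft(rho, lam) / denom[j]
                if new != bj:
                    if binary:
                        r[nz[j]] -= new - bj
                    else:
                        r -= X[:, j] * (new - bj)
                    beta[j] = new
                    max_delta = max(max_delta, abs(new - bj))
            b0_new = intercept + (w * r).sum() / w_sum
            r -= b0_new - intercept
            intercept = b0_new
            if max_delta < tol:
                break
        # exact-gradient stationarity on the true (non-approximated) problem
        if kkt_violation(X, y, intercept, beta, lam) < kkt_tol:
            break
    return intercept, beta


def _soft(x: float, lam: float) -> float:
    if x > lam:
        return x - lam
    if x < -lam:
        return x + lam
    return 0.0


def kkt_violation(X, y, intercept, beta, lam) -> float:
    """Largest violation of the exact stationarity conditions."""
    n = len(y)
    prob = _sigmoid(intercept + X @ beta)
    g = X.T @ (prob - y) / n
    active = beta != 0
    v = abs((prob - y).mean())  # intercept condition
    if active.any():
        v = max(v, np.max(np.abs(g[active] + lam * np.sign(beta[active]))))
    if (~active).any():
        v = max(v, float(np.max(np.abs(g[~active])) - lam), 0.0)
    return float(v)


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is zero (closed form)."""
    ybar = y.mean()
    return float(np.max(np.abs(X.T @ (y - ybar))) / len(y))


def lasso_path(X, y, lambdas=None, n_lambdas: int = 40, min_ratio: float = 0.01,
               tol: float = 1e-11, kkt_tol: float = 1e-9):
    """Fit the penalty path (decreasing), warm-starting each point.

    Returns a list of ``(lam, intercept, beta)`` triples.  The default
    tolerances certify each point against the exact KKT conditions well
    inside 1e-6; cross-validation fold fits may loosen them since only
    held-out predictions matter there.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lambdas is None:
        lmax = lambda_max(X, y)
        lambdas = np.geomspace(lmax, lmax * min_ratio, n_lambdas)
    lambdas = np.asarray(sorted(lambdas, reverse=True), dtype=float)
    if len(lambdas) == 0:
        raise ConfigurationError("empty penalty grid")
    intercept = float(np.log(y.mean() / (1 - y.mean())))
    beta = np.zeros(X.shape[1])
    out = []
    for lam in lambdas:
        intercept, beta = lasso_logistic(X, y, lam, intercept, beta,
                                         tol=tol, kkt_tol=kkt_tol)
        out.append((float(lam), intercept, beta.copy()))
    return out


@dataclasses.dataclass
class LassoSelection:
    """Outcome of cross-validated penalized selection."""

    selected: list
    lambda_chosen: float
    lambda_min: float
    cv_table: pd.DataFrame  # lambda, mean deviance, se, n_nonzero
    path: list              # (lam, intercept, beta) on the full sample


def lasso_select(
    sample: pd.DataFrame,
    variables: list | None = None,
    lambda_grid=None,
    folds: int = 10,
    seed: int = 0,
    label_col: str = "adjudicated_label",
) -> LassoSelection:
    """Select variables by 10-fold CV deviance with the one-SE rule.

    ``sample`` holds binary feature columns plus the adjudicated 0/1
    label.  Deterministic under ``seed`` (fold assignment is the only
    randomness).
    """
    variables = list(variables) if variables is not None else [
        c for c in sample.columns if c != label_col
    ]
    y = sample[label_col].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise EstimationError("training labels contain a single class")
    if np.bincount(y.astype(int)).min() < 2:
        raise EstimationError("need at least 2 cases per class")
    X = sample[variables].to_numpy(dtype=float)
    if lambda_grid is not None and len(lambda_grid) == 0:
        raise ConfigurationError("empty penalty grid")

    if lambda_grid is None:
        lmax = lambda_max(X, y)
        lambda_grid = np.geomspace(lmax, lmax * 0.01, 40)
    lambdas = np.asarray(sorted(lambda_grid, reverse=True), dtype=float)

    # stratified folds so each holds both classes
    rng = np.random.default_rng(seed)
    fold_id = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold_id[idx] = np.arange(len(idx)) % folds
    dev = np.zeros((folds, len(lambdas)))
    for k in range(folds):
        tr, te = fold_id != k, fold_id == k
        path = lasso_path(X[tr], y[tr], lambdas=lambdas, tol=1e-8, kkt_tol=1e-6)
        for i, (lam, b0, b) in enumerate(path):
            prob = np.clip(_sigmoid(b0 + X[te] @ b), 1e-12, 1 - 1e-12)
            dev[k, i] = -2.0 * np.mean(
                y[te] * np.log(prob) + (1 - y[te]) * np.log(1 - prob)
            )
    mean = dev.mean(axis=0)
    se = dev.std(axis=0, ddof=1) / math.sqrt(folds)
    i_min = int(np.argmin(mean))
    threshold = mean[i_min] + se[i_min]
    i_1se = int(np.flatnonzero(mean <= threshold)[0])  # largest qualifying lam

    full_path = lasso_path(X, y, lambdas=lambdas)
    _, _, beta = full_path[i_1se]
    selected = [v for v, b in zip(variables, beta) if b != 0.0]
    cv_table = pd.DataFrame(
        {
            "lambda": lambdas,
            "cv_deviance": mean,
            "cv_se": se,
            "n_nonzero": [int(np.count_nonzero(b)) for _, _, b in full_path],
        }
    )
    return LassoSelection(
        selected=selected,
        lambda_chosen=float(lambdas[i_1se]),
        lambda_min=float(lambdas[i_min]),
        cv_table=cv_table,
        path=full_path,
    )


# ---------------------------------------------------------------------------
# unpenalized refit


@dataclasses.dataclass
class DetectionModel:
    """A fitted (or frozen) detection model ready for cohort scoring."""

    selected_variables: list
    intercept: float
    coefficients: dict
    standard_errors: dict
    odds_ratios_ci: dict        # name -> (point, low, high)
    unadjusted_or: dict = dataclasses.field(default_factory=dict)
    cutoff: float | None = None
    c_statistic: float = math.nan
    method: str = "ml"          # ml | firth | frozen
    dropped_variables: list = dataclasses.field(default_factory=list)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["odds_ratios_ci"] = {
            k: [float(x) for x in v] for k, v in self.odds_ratios_ci.items()
        }
        payload["unadjusted_or"] = {
            k: [float(x) for x in v] for k, v in self.unadjusted_or.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DetectionModel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["odds_ratios_ci"] = {
            k: tuple(v) for k, v in payload.get("odds_ratios_ci", {}).items()
        }
        payload["unadjusted_or"] = {
            k: tuple(v) for k, v in payload.get("unadjusted_or", {}).items()
        }
        return cls(**payload)


def firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200,
                   tol: float = 1e-10):
    """Firth's bias-reduced logistic regression (Jeffreys-prior score).

    Returns (beta, se); ``X`` must already include the intercept column.
    Finite estimates exist even under complete separation.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        prob = _sigmoid(eta)
        w = np.clip(prob * (1 - prob), 1e-12, None)
        XW = X * w[:, None]
        info = X.T @ XW / 1.0
        info_inv = np.linalg.pinv(info)
        # leverages of the weighted design
        h = np.einsum("ij,jk,ik->i", X * np.sqrt(w)[:, None], info_inv,
                      X * np.sqrt(w)[:, None])
        score = X.T @ (y - prob + h * (0.5 - prob))
        step = info_inv @ score
        # dampen huge steps for stability
        nrm = np.linalg.norm(step)
        if nrm > 5.0:
            step *= 5.0 / nrm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    prob = _sigmoid(eta)
    w = np.clip(prob * (1 - prob), 1e-12, None)
    info_inv = np.linalg.pinv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(info_inv))
    return beta, se


def fit_logistic(
    sample: pd.DataFrame,
    variables: list,
    label_col: str = "adjudicated_label",
    compute_unadjusted: bool = True,
) -> DetectionModel:
    """Unpenalized ML refit with Wald 95% CIs on the OR scale.

    Constant (all-zero or all-one) columns are inestimable and dropped
    with a warning.  When ML shows separation (a fitted probability
    within 1e-8 of 0/1 together with a diverging coefficient), the fit
    falls back to Firth's penalized likelihood and the result is flagged
    via ``method='firth'``.
    """
    missing = [v for v in variables if v not in sample.columns]
    if missing:
        raise IntegrityError(f"variables absent from sample: {missing}")
    y = sample[label_col].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise EstimationError("labels contain a single class")

    kept, dropped = [], []
    for v in variables:
        if sample[v].nunique() < 2:
            dropped.append(v)
            logger.warning("variable %s is constant; dropped from refit", v)
        else:
            kept.append(v)
    X = sample[kept].to_numpy(dtype=float)
    Xc = np.column_stack([np.ones(len(y)), X])

    method = "ml"
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params, bse = fit.params, fit.bse
        prob = _sigmoid(Xc @ params)
        converged = bool(fit.mle_retvals.get("converged", True))
        separated = (
            (
                ((prob < 1e-8) | (prob > 1 - 1e-8)).any()
                and (np.abs(params[1:]) > 15).any()
            )
            or not np.isfinite(bse).all()
            or (not converged and (np.abs(params) > 15).any())
        )
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        separated = True
    if separated:
        logger.warning("separation detected; falling back to Firth penalized fit")
        params, bse = firth_logistic(Xc, y)
        method = "firth"

    coefficients = dict(zip(kept, params[1:]))
    standard_errors = dict(zip(kept, bse[1:]))
    or_ci = {
        v: (
            float(np.exp(coefficients[v])),
            float(np.exp(coefficients[v] - Z95 * standard_errors[v])),
            float(np.exp(coefficients[v] + Z95 * standard_errors[v])),
        )
        for v in kept
    }

    unadjusted = {}
    if compute_unadjusted:
        for v in kept:
            x1 = np.column_stack([np.ones(len(y)), sample[v].to_numpy(float)])
            try:
                with np.errstate(all="ignore"):
                    f1 = sm.Logit(y, x1).fit(disp=0, maxiter=200)
                b, s = f1.params[1], f1.bse[1]
                if not (np.isfinite(b) and np.isfinite(s)) or abs(b) > 15 or s > 50:
                    raise ValueError("diverged")
            except Exception:
                b, s = firth_logistic(x1, y)
                b, s = b[1], s[1]
            unadjusted[v] = (
                float(np.exp(b)),
                float(np.exp(b - Z95 * s)),
                float(np.exp(b + Z95 * s)),
            )

    return DetectionModel(
        selected_variables=kept,
        intercept=float(params[0]),
        coefficients={k: float(v) for k, v in coefficients.items()},
        standard_errors={k: float(v) for k, v in standard_errors.items()},
        odds_ratios_ci=or_ci,
        unadjusted_or=unadjusted,
        method=method,
        dropped_variables=dropped,
    )


# ---------------------------------------------------------------------------
# scoring, cutoff, discrimination


def predict_probability(model: DetectionModel, features: pd.DataFrame,
                        recalibrate_to: float | None = None) -> pd.Series:
    """Per-case event probability logistic(intercept + sum coef*flag).

    ``recalibrate_to`` shifts the intercept by the log prevalence ratio
    between the target and the model's implied baseline; off by default
    (the development deployment applied review-sample probabilities
    directly).
    """
    missing = [v for v in model.selected_variables if v not in features.columns]
    if missing:
        raise IntegrityError(f"feature matrix missing columns: {missing}")
    intercept = model.intercept
    if recalibrate_to is not None:
        base = _sigmoid(np.array([model.intercept]))[0]
        intercept += math.log(recalibrate_to / (1 - recalibrate_to)) - math.log(
            base / (1 - base)
        )
        logger.info("intercept recalibrated to prevalence %.4f", recalibrate_to)
    eta = intercept + sum(
        model.coefficients[v] * features[v].to_numpy(dtype=float)
        for v in model.selected_variables
    )
    prob = _sigmoid(np.asarray(eta, dtype=float))
    eps = np.finfo(float).tiny
    return pd.Series(np.clip(prob, eps, 1 - eps), index=features.index, name="probability")


@dataclasses.dataclass
class CutoffResult:
    cutoff: float
    table: pd.DataFrame
    stable: bool = True


def choose_cutoff(
    probabilities,
    labels,
    grid=tuple(np.round(np.arange(0.1, 1.0, 0.1), 10)),
    override: float | None = None,
    weights=None,
) -> CutoffResult:
    """Per-cutoff PPV / sensitivity / specificity with a recommendation.

    A case is flagged when its probability exceeds the cutoff.  The
    recommended cutoff maximizes Youden's J (sensitivity + specificity -
    1); PPV is reported alongside.  ``override`` forces a specific value
    (logged), matching the development cohort's choice of 0.30.  When all
    probabilities land in a single grid cell the recommendation is
    flagged unstable.
    """
    p = np.asarray(probabilities, dtype=float)
    ylab = np.asarray(labels, dtype=float)
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    grid = np.asarray(list(grid), dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ConfigurationError("cutoff grid must lie inside (0, 1)")
    if len(np.unique(ylab)) < 2:
        raise EstimationError("both classes required to evaluate cutoffs")

    rows = []
    for c in grid:
        flag = p > c
        tp = w[flag & (ylab == 1)].sum()
        fp = w[flag & (ylab == 0)].sum()
        fn = w[~flag & (ylab == 1)].sum()
        tn = w[~flag & (ylab == 0)].sum()
        ppv = tp / (tp + fp) if tp + fp > 0 else math.nan
        sens = tp / (tp + fn) if tp + fn > 0 else math.nan
        spec = tn / (tn + fp) if tn + fp > 0 else math.nan
        j = (sens if not math.isnan(sens) else 0.0) + (
            spec if not math.isnan(spec) else 0.0
        ) - 1.0
        rows.append(
            {"cutoff": float(c), "ppv": ppv, "sensitivity": sens,
             "specificity": spec, "youden_j": j}
        )
    table = pd.DataFrame(rows)
    stable = len(np.unique(np.searchsorted(grid, p))) > 1
    if override is not None:
        logger.info("cutoff overridden to %.2f", override)
        chosen = float(override)
    else:
        chosen = float(table.loc[table["youden_j"].idxmax(), "cutoff"])
    if not stable:
        logger.warning("all probabilities fall in one grid cell; "
                       "cutoff recommendation is unstable")
    return CutoffResult(cutoff=chosen, table=table, stable=stable)


def c_statistic(probabilities, labels) -> float:
    """Rank-based area under the ROC curve with half-credit for ties.

    Invariant to strictly increasing transforms of the scores.
    """
    p = np.asarray(probabilities, dtype=float)
    ylab = np.asarray(labels)
    pos = ylab == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise EstimationError("both classes required for the C statistic")
    ranks = rankdata(p)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------------------
# frozen development-cohort model


def reference_model(target_prevalence: float = 0.005) -> DetectionModel:
    """The frozen seven-variable model from the development cohort.

    Coefficients are the logs of the published adjusted odds ratios;
    standard errors are recovered from the CI widths; the intercept is
    calibrated so an all-negative case scores ``target_prevalence``
    (default 0.5%, the approximate cohort event rate).  Lets cohorts be
    scored without retraining; flagged via ``method='frozen'``.
    """
    if not 0 < target_prevalence < 1:
        raise ValidationError("target_prevalence must be in (0, 1)")
    coefficients, ses, or_ci = {}, {}, {}
    for name, (point, low, high) in REFERENCE_ADJUSTED_OR.items():
        coefficients[name] = math.log(point)
        ses[name] = (math.log(high) - math.log(low)) / (2 * Z95)
        or_ci[name] = (point, low, high)
    return DetectionModel(
        selected_variables=list(REFERENCE_ADJUSTED_OR),
        intercept=math.log(target_prevalence / (1 - target_prevalence)),
        coefficients=coefficients,
        standard_errors=ses,
        odds_ratios_ci=or_ci,
        unadjusted_or=dict(REFERENCE_UNADJUSTED_OR),
        cutoff=REFERENCE_CUTOFF,
        method="frozen",
    )
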