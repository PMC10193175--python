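import math

import numpy as np
import pandas as pd
import pytest

from abxallergy import c_statistic, choose_cutoff, fit_logistic, lasso_select, predict_probability, reference_model
from abxallergy.errors import ConfigurationError, EstimationError, IntegrityError
from abxallergy.model import (
    kkt_violation,
    lambda_max,
    lasso_logistic,
    lasso_path,
    firth_logistic,
    _sigmoid,
)


def _sample(n=600, seed=0, betas=(2.0, 0.0), prev=(0.3, 0.3), b0=-1.5):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, len(betas))) < np.asarray(prev)).astype(float)
    p = 1 / (1 + np.exp(-(b0 + X @ np.asarray(betas))))
    y = (rng.random(n) < p).astype(float)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(len(betas))])
    df["adjudicated_label"] = y
    return df


def test_null_feature_excluded_at_one_se_penalty():
    sample = _sample(n=2000, seed=1, betas=(2.5, 0.0))
    sel = lasso_select(sample, seed=0)
    assert "x0" in sel.selected
    assert "x1" not in sel.selected


def test_penalty_above_lambda_max_gives_empty_model():
    sample = _sample(n=500, seed=2)
    X = sample[["x0", "x1"]].to_numpy(float)
    y = sample["adjudicated_label"].to_numpy(float)
    lmax = lambda_max(X, y)
    b0, beta = lasso_logistic(X, y, lmax * 1.01)
    assert np.all(beta == 0)
    assert b0 == pytest.approx(math.log(y.mean() / (1 - y.mean())), abs=1e-6)


def test_kkt_certificate_along_path():
    sample = _sample(n=800, seed=3, betas=(2.0, 1.0), prev=(0.2, 0.4))
    X = sample[["x0", "x1"]].to_numpy(float)
    y = sample["adjudicated_label"].to_numpy(float)
    for lam, b0, beta in lasso_path(X, y):
        assert kkt_violation(X, y, b0, beta, lam) < 1e-6


def test_solution_matches_independent_l1_solver():
    """Coordinate-descent solution agrees with liblinear's L1 logistic."""
    sklearn = pytest.importorskip("sklearn.linear_model")
    sample = _sample(n=1000, seed=4, betas=(1.5, 0.8), prev=(0.25, 0.35))
    X = sample[["x0", "x1"]].to_numpy(float)
    y = sample["adjudicated_label"].to_numpy(float)
    lam = 0.3 * lambda_max(X, y)
    b0, beta = lasso_logistic(X, y, lam)
    sk = sklearn.LogisticRegression(
        penalty="l1", C=1.0 / (lam * len(y)), solver="liblinear",
        tol=1e-10, max_iter=5000, intercept_scaling=100.0,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sk.fit(X, y)
    assert beta == pytest.approx(sk.coef_[0], abs=2e-3)
    assert b0 == pytest.approx(float(sk.intercept_[0]), abs=5e-3)


def test_single_class_labels_rejected():
    sample = _sample(n=100, seed=5)
    sample["adjudicated_label"] = 1
    with pytest.raises(EstimationError):
        lasso_select(sample)


def test_empty_penalty_grid_rejected():
    sample = _sample(n=100, seed=5)
    with pytest.raises(ConfigurationError):
        lasso_select(sample, lambda_grid=[])


def test_two_by_two_or_matches_closed_form():
    """8/2 vs 2/8 events give cross-product OR (8*8)/(2*2) = 16."""
    x = [1] * 10 + [0] * 10
    y = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
    sample = pd.DataFrame({"x0": x, "adjudicated_label": y})
    fit = fit_logistic(sample, ["x0"])
    assert fit.odds_ratios_ci["x0"][0] == pytest.approx(16.0, rel=1e-4)
    assert fit.unadjusted_or["x0"][0] == pytest.approx(16.0, rel=1e-4)


def test_constant_column_dropped_with_warning():
    sample = _sample(n=300, seed=6)
    sample["zero"] = 0
    fit = fit_logistic(sample, ["x0", "zero"])
    assert "zero" in fit.dropped_variables
    assert "zero" not in fit.coefficients


def test_intercept_only_fit_on_balanced_sample():
    sample = pd.DataFrame({"adjudicated_label": [0, 1] * 25})
    fit = fit_logistic(sample, [])
    assert fit.intercept == pytest.approx(0.0, abs=1e-6)


def test_separation_falls_back_to_firth():
    """A perfectly separating flag gets finite Firth estimates."""
    sample = pd.DataFrame(
        {"x0": [1] * 20 + [0] * 20, "adjudicated_label": [1] * 20 + [0] * 20}
    )
    fit = fit_logistic(sample, ["x0"], compute_unadjusted=False)
    assert fit.method == "firth"
    assert np.isfinite(fit.coefficients["x0"])
    assert np.isfinite(fit.standard_errors["x0"])


def test_firth_shrinks_toward_finite_estimates():
    X = np.column_stack([np.ones(8), [0, 0, 0, 0, 1, 1, 1, 1]])
    y = np.array([0, 0, 0, 1, 1, 1, 1, 1.0])
    beta, se = firth_logistic(X, y)
    assert np.all(np.isfinite(beta)) and np.all(se > 0)


def test_predicted_probability_closed_form():
    model = reference_model()
    model.intercept = 0.0
    model.coefficients = {v: 0.0 for v in model.selected_variables}
    model.coefficients["art_observed"] = math.log(9)
    feats = pd.DataFrame(
        0, index=["a", "b"], columns=model.selected_variables
    )
    feats.loc["b", "art_observed"] = 1
    p = predict_probability(model, feats)
    assert p["a"] == pytest.approx(0.5)
    assert p["b"] == pytest.approx(0.9)


def test_positive_coefficient_monotonicity():
    model = reference_model()
    base = pd.DataFrame(0, index=["c"], columns=model.selected_variables)
    p0 = predict_probability(model, base)["c"]
    for v in model.selected_variables:
        up = base.copy()
        up.loc["c", v] = 1
        assert predict_probability(model, up)["c"] > p0


def test_missing_feature_column_is_integrity_error():
    model = reference_model()
    feats = pd.DataFrame(0, index=["a"], columns=model.selected_variables[:-1])
    with pytest.raises(IntegrityError):
        predict_probability(model, feats)


def test_cutoff_perfect_separation():
    p = np.array([0.05] * 50 + [0.95] * 50)
    y = np.array([0] * 50 + [1] * 50)
    res = choose_cutoff(p, y)
    row = res.table[res.table["cutoff"] == 0.5].iloc[0]
    assert row["sensitivity"] == 1.0 and row["specificity"] == 1.0
    assert res.cutoff in res.table["cutoff"].values


def test_cutoff_on_stratum_midpoints_reproduces_reference_ppv():
    """Stratum midpoints weighted by the published training review counts
    give 77% PPV above the 0.30 cutoff."""
    from abxallergy.reference import TRAINING_REVIEW_STRATA

    t = TRAINING_REVIEW_STRATA
    mids, labels, weights = [], [], []
    for r in t.itertuples():
        mid = (r.prob_lo + r.prob_hi) / 2
        mids += [mid, mid]
        labels += [1, 0]
        weights += [r.allergic_n, r.reviewed_n - r.allergic_n]
    res = choose_cutoff(np.array(mids), np.array(labels), weights=np.array(weights))
    row = res.table[np.isclose(res.table["cutoff"], 0.3)].iloc[0]
    assert row["ppv"] == pytest.approx(54 / 70)


def test_cutoff_single_cell_flagged_unstable():
    p = np.full(30, 0.15)
    y = np.array([0, 1] * 15)
    res = choose_cutoff(p, y)
    assert not res.stable


def test_c_statistic_perfect_and_tied():
    assert c_statistic([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert c_statistic([0.5] * 10, [0, 1] * 5) == 0.5
    with pytest.raises(EstimationError):
        c_statistic([0.1, 0.2], [1, 1])


def test_c_statistic_equals_brute_force_concordance():
    rng = np.random.default_rng(7)
    for n in (20, 97, 200):
        p = np.round(rng.random(n), 2)  # force ties
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        pos, neg = p[y == 1], p[y == 0]
        brute = np.mean(
            (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        )
        assert c_statistic(p, y) == pytest.approx(brute, abs=1e-12)


def test_c_statistic_null_simulation():
    rng = np.random.default_rng(8)
    p = rng.random(10000)
    y = rng.integers(0, 2, 10000)
    n1, n0 = (y == 1).sum(), (y == 0).sum()
    se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
    assert abs(c_statistic(p, y) - 0.5) < 3 * se


def test_c_statistic_rank_invariance():
    p = np.array([0.01, 0.2, 0.35, 0.6, 0.9])
    y = np.array([0, 1, 0, 1, 1])
    assert c_statistic(p, y) == c_statistic(np.log(p / (1 - p)), y)


def test_refit_deviance_never_exceeds_intercept_only():
    sample = _sample(n=500, seed=9, betas=(1.5, 0.5))
    sel = lasso_select(sample, seed=0)
    variables = sel.selected or ["x0"]
    fit = fit_logistic(sample, variables, compute_unadjusted=False)
    y = sample["adjudicated_label"].to_numpy(float)
    X = sample[fit.selected_variables].to_numpy(float)
    eta = fit.intercept + X @ np.array([fit.coefficients[v] for v in fit.selected_variables])
    p = np.clip(_sigmoid(eta), 1e-12, 1 - 1e-12)
    dev = -2 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
    pbar = y.mean()
    dev0 = -2 * np.sum(y * np.log(pbar) + (1 - y) * np.log(1 - pbar))
    assert dev <= dev0 + 1e-8


def test_reference_model_consistency():
    model = reference_model(target_prevalence=0.005)
    assert model.cutoff == 0.30
    assert model.method == "frozen"
    for v, (point, low, high) in model.odds_ratios_ci.items():
        assert math.exp(model.coefficients[v]) == pytest.approx(point)
        assert low <= point <= high
    feats = pd.DataFrame(0, index=["neg"], columns=model.selected_variables)
    assert predict_probability(model, feats)["neg"] == pytest.approx(0.005)


def test_model_yaml_round_trip(tmp_path):
    model = reference_model()
    model.to_yaml(tmp_path / "m.yaml")
    from abxallergy import DetectionModel

    back = DetectionModel.from_yaml(tmp_path / "m.yaml")
    assert back.selected_variables == model.selected_variables
    assert back.coefficients == pytest.approx(model.coefficients)
    assert back.cutoff == model.cutoff
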