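"""Best-subset logistic panel search: subset enumeration, the IRLS fit,
probability predictions, repeated two-fold CV, and model selection."""

import numpy as np
import pytest

from mirnapanel import (CohortDesign, DataError, Outcome, cv_evaluate,
                        enumerate_subsets, export_equation, fit_logistic,
                        import_equation, predict_prob, search,
                        simulate_expression)
from mirnapanel.experiments import binormal_shift


# ----------------------------------------------------------- enumeration

@pytest.mark.parametrize("n, expected", [(1, 1), (2, 3), (8, 255), (9, 511)])
def test_subset_counts(n, expected):
    ids = [f"p{i}" for i in range(n)]
    assert len(enumerate_subsets(ids)) == expected


@pytest.mark.parametrize("n", range(1, 13))
def test_subset_count_is_two_to_k_minus_one(n):
    subs = enumerate_subsets([f"p{i}" for i in range(n)])
    assert len(subs) == 2 ** n - 1
    assert len(set(subs)) == len(subs)                 # all distinct
    sizes = [len(s) for s in subs]
    assert sizes == sorted(sizes)                      # ordered by size


def test_duplicate_predictors_rejected():
    with pytest.raises(DataError):
        enumerate_subsets(["a", "a"])


# ------------------------------------------------------------ logistic fit

def test_saturated_two_by_two_matches_closed_form():
    """Events 2/10 at x=0 and 8/10 at x=1: the saturated fit reproduces the
    empirical log-odds exactly."""
    x = np.array([0.0] * 10 + [1.0] * 10)
    y = np.array([0] * 8 + [1] * 2 + [0] * 2 + [1] * 8, dtype=float)
    m = fit_logistic(x, y)
    assert m.intercept == pytest.approx(np.log(2 / 8), abs=1e-6)
    assert m.coefficients[0] == pytest.approx(np.log((8 / 2) / (2 / 8)), abs=1e-6)
    assert m.converged and not m.separation
    # predicted probability at x=1 equals the empirical event rate
    assert predict_prob(m, np.array([[1.0]]))[0] == pytest.approx(0.8, abs=1e-6)


def test_symmetric_outcome_gives_zero_coefficients():
    m = fit_logistic(np.array([0.0, 1.0, 0.0, 1.0]), np.array([0, 0, 1, 1.0]))
    assert m.intercept == pytest.approx(0.0, abs=1e-8)
    assert m.coefficients[0] == pytest.approx(0.0, abs=1e-8)


def test_intercept_only_model_matches_prevalence():
    m = fit_logistic(np.empty((8, 0)), np.array([0, 1, 0, 1, 0, 1, 0, 1.0]))
    assert m.intercept == pytest.approx(0.0, abs=1e-10)


def test_fit_matches_statsmodels_oracle():
    import statsmodels.api as sm

    rng = np.random.default_rng(5)
    X = rng.normal(size=(120, 3))
    eta = 0.4 - 0.8 * X[:, 0] + 1.1 * X[:, 2]
    y = (rng.random(120) < 1 / (1 + np.exp(-eta))).astype(float)
    ours = fit_logistic(X, y)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    assert ours.intercept == pytest.approx(ref.params[0], abs=1e-6)
    assert np.allclose(ours.coefficients, ref.params[1:], atol=1e-6)


def test_mean_predicted_probability_equals_prevalence():
    """Score-equation identity of the logistic MLE."""
    rng = np.random.default_rng(9)
    X = rng.normal(size=(80, 2))
    y = (rng.random(80) < 0.35).astype(float)
    m = fit_logistic(X, y)
    assert predict_prob(m, X).mean() == pytest.approx(y.mean(), abs=1e-8)


def test_separation_is_flagged_and_coefficients_stay_finite():
    x = np.array([0.0, 0.1, 0.2, 0.9, 1.0, 1.1])
    y = np.array([0, 0, 0, 1, 1, 1.0])
    m = fit_logistic(x, y)
    assert m.separation
    assert np.isfinite(m.coefficients).all() and np.isfinite(m.intercept)
    eq = export_equation(m)
    assert "WARNING" in eq and "separation" in eq


def test_single_class_outcome_rejected():
    with pytest.raises(DataError):
        fit_logistic(np.zeros((4, 1)), np.ones(4))


def test_missing_predictor_named_in_error(signal_table):
    m = fit_logistic(np.zeros((4, 1)), np.array([0, 1, 0, 1.0]),
                     subset=("miR-042",), transforms=("log2",))
    import pandas as pd
    with pytest.raises(DataError, match="miR-042"):
        predict_prob(m, pd.DataFrame({"miR-001": [1.0]}))


def test_predict_prob_midpoint_and_limits():
    from mirnapanel import FittedPanelModel

    m = FittedPanelModel(subset=("x",), intercept=0.0, coefficients=np.array([1.0]),
                         transforms=("identity",))
    assert predict_prob(m, np.array([[0.0]]))[0] == pytest.approx(0.5)
    probs = predict_prob(m, np.array([[-1e4], [1e4]]))
    assert probs[0] == pytest.approx(0.0, abs=1e-12)
    assert probs[1] == pytest.approx(1.0, abs=1e-12)
    grid = predict_prob(m, np.linspace(-5, 5, 11)[:, None])
    assert (np.diff(grid) > 0).all()                  # monotone in the lp


# -------------------------------------------------------------------- CV

def test_cv_is_deterministic_for_fixed_seed(signal_table):
    out = Outcome.cancer_vs_healthy(signal_table)
    r1 = cv_evaluate(signal_table, ("miR-001",), out, n_reps=1, seed=42)
    r2 = cv_evaluate(signal_table, ("miR-001",), out, n_reps=1, seed=42)
    assert r1 == r2


def test_cv_null_auc_near_half(null_table):
    out = Outcome.cancer_vs_healthy(null_table)
    res = cv_evaluate(null_table, ("miR-001", "miR-002"), out, n_reps=200, seed=0)
    n1, n0 = 15, 15
    se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
    assert abs(res.mean_test_auc - 0.5) < 3 * se


def test_cv_strong_predictor_auc_high():
    delta = binormal_shift(0.995)          # single-marker binormal AUC > 0.99
    design = CohortDesign(
        n_healthy=40, n_benign=0, n_early=20, n_advanced=20, n_mirnas=2,
        informative_effects={"miR-001": {"early": delta, "advanced": delta}},
        seed=6,
    )
    table, _ = simulate_expression(design)
    res = cv_evaluate(table, ("miR-001",), Outcome.cancer_vs_healthy(table),
                      n_reps=100, seed=1)
    assert res.mean_test_auc > 0.95


def test_cv_train_auc_dominates_test_auc_on_null(null_table):
    out = Outcome.cancer_vs_healthy(null_table)
    res = cv_evaluate(null_table, ("miR-001", "miR-002", "miR-003"), out,
                      n_reps=300, seed=3)
    # fitting optimism: train-half AUC exceeds held-out AUC on pure noise
    assert res.mean_train_auc > res.mean_test_auc


def test_cv_class_size_precondition(null_table):
    out = Outcome.cancer_vs_healthy(null_table)
    with pytest.raises(DataError, match="class"):
        cv_evaluate(null_table, tuple(null_table.mirna_ids) * 4, out, n_reps=2, seed=0)


# ---------------------------------------------------------------- search

def test_search_evaluates_every_subset(signal_table):
    out = Outcome.cancer_vs_healthy(signal_table)
    res = search(signal_table, ["miR-001", "miR-002"], out, n_reps=20, seed=0)
    assert len(res.ranking) == 3
    assert res.final_model is not None
    assert "miR-001" in res.final_model.subset


def test_search_results_independent_of_pool_order(signal_table):
    out = Outcome.cancer_vs_healthy(signal_table)
    r1 = search(signal_table, ["miR-001", "miR-002", "miR-003"], out, n_reps=10, seed=7)
    r2 = search(signal_table, ["miR-003", "miR-001", "miR-002"], out, n_reps=10, seed=7)
    m1 = {r.subset: (r.mean_train_auc, r.mean_test_auc) for r in r1.ranking}
    m2 = {r.subset: (r.mean_train_auc, r.mean_test_auc) for r in r2.ranking}
    assert m1 == m2


def test_search_with_unreachable_floor_returns_diagnostics(null_table):
    out = Outcome.cancer_vs_healthy(null_table)
    with pytest.warns(UserWarning, match="floor"):
        res = search(null_table, ["miR-001", "miR-002"], out, n_reps=10,
                     auc_floor=1.01, seed=0)
    assert res.selected == [] and res.final_model is None
    assert len(res.ranking) == 3


def test_noise_predictor_leaves_top_test_auc_stable(signal_table):
    """Adding a pure-noise marker to the pool must not change the winning
    panel's mean test AUC beyond Monte-Carlo error (paired seeds)."""
    out = Outcome.cancer_vs_healthy(signal_table)
    base = search(signal_table, ["miR-001", "miR-002"], out, n_reps=60, seed=2)
    wider = search(signal_table, ["miR-001", "miR-002", "miR-006"], out,
                   n_reps=60, seed=2)
    best_base = base.ranking[0].mean_test_auc
    # the same subset's score is unchanged under the wider pool (same splits)
    same = {r.subset: r.mean_test_auc for r in wider.ranking}[base.ranking[0].subset]
    assert same == pytest.approx(best_base, abs=1e-12)
    assert abs(wider.ranking[0].mean_test_auc - best_base) < 0.05


def test_equation_round_trip(signal_table):
    out = Outcome.cancer_vs_healthy(signal_table)
    res = search(signal_table, ["miR-001", "miR-002"], out, n_reps=20, seed=0)
    model = res.final_model
    back = import_equation(export_equation(model))
    assert back.subset == model.subset
    assert back.intercept == model.intercept
    assert np.array_equal(back.coefficients, model.coefficients)
    rng = np.random.default_rng(0)
    probe = rng.normal(size=(50, len(model.subset)))
    assert np.array_equal(predict_prob(model, probe), predict_prob(back, probe))
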