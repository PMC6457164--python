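"""Empirical weighted ROC, cut-point tables and placement-value ROC regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from screendx import (CohortConfig, EstimationError, compare_roc_groups,
                      config_from_roc_params, cutpoint_table, empirical_roc,
                      empirical_roc_truth, fit_roc_glm, generate_population,
                      placement_values)


def _frame(case_scores, control_scores, case_w=None, control_w=None):
    n1, n0 = len(case_scores), len(control_scores)
    return pd.DataFrame({
        "dx_depression": [1] * n1 + [0] * n0,
        "total_score": list(case_scores) + list(control_scores),
        "design_weight": list(case_w or [1.0] * n1) + list(control_w or [1.0] * n0),
    })


def test_perfect_separation_auc_one():
    curve = empirical_roc(_frame([20, 25, 28], [1, 3, 5]),
                          "total_score", "depression")
    assert curve.auc == pytest.approx(1.0)


def test_identical_distributions_auc_half():
    scores = [3, 7, 7, 12, 20]
    curve = empirical_roc(_frame(scores, scores), "total_score", "depression")
    assert curve.auc == pytest.approx(0.5, abs=1e-12)


def test_roc_endpoints_and_monotonicity():
    rng = np.random.default_rng(0)
    df = _frame(rng.integers(5, 30, 60), rng.integers(0, 25, 90),
                case_w=rng.uniform(1, 5, 60).tolist(),
                control_w=rng.uniform(1, 5, 90).tolist())
    curve = empirical_roc(df, "total_score", "depression")
    assert curve.fpr[0] == curve.tpr[0] == 0.0
    assert curve.fpr[-1] == curve.tpr[-1] == 1.0
    assert (np.diff(curve.fpr) >= -1e-12).all()
    assert (np.diff(curve.tpr) >= -1e-12).all()


def test_weighted_auc_equals_pairwise_concordance():
    """Trapezoid AUC equals exhaustive weighted concordance with tie credit."""
    rng = np.random.default_rng(3)
    n1, n0 = 70, 90
    df = _frame(rng.integers(0, 31, n1), rng.integers(0, 31, n0),
                case_w=rng.uniform(0.5, 8, n1).tolist(),
                control_w=rng.uniform(0.5, 8, n0).tolist())
    curve = empirical_roc(df, "total_score", "depression")
    cases = df[df.dx_depression == 1]
    ctrls = df[df.dx_depression == 0]
    num = sum(
        wi * wj * ((si > sj) + 0.5 * (si == sj))
        for si, wi in zip(cases.total_score, cases.design_weight)
        for sj, wj in zip(ctrls.total_score, ctrls.design_weight))
    brute = num / (cases.design_weight.sum() * ctrls.design_weight.sum())
    assert curve.auc == pytest.approx(brute, abs=1e-12)


def test_unit_weights_match_textbook_roc():
    """With weights 1 the weighted AUC equals the Mann-Whitney U statistic."""
    rng = np.random.default_rng(4)
    case, ctrl = rng.normal(1, 1, 80), rng.normal(0, 1, 120)
    df = _frame(case, ctrl)
    curve = empirical_roc(df, "total_score", "depression")
    u = stats.mannwhitneyu(case, ctrl).statistic
    assert curve.auc == pytest.approx(u / (80 * 120), abs=1e-12)


def test_no_cases_or_controls_error():
    with pytest.raises(EstimationError):
        empirical_roc(_frame([1, 2], []), "total_score", "depression")
    with pytest.raises(EstimationError):
        empirical_roc(_frame([], [1, 2]), "total_score", "depression")


# ---------------------------------------------------------------------------
# cut-point table


def test_cutpoint_table_matches_independent_computation(study_frame):
    rng = np.random.default_rng(6)
    df = _frame(rng.integers(5, 26, 40), rng.integers(2, 22, 50),
                case_w=rng.uniform(1, 4, 40).tolist(),
                control_w=rng.uniform(1, 4, 50).tolist())
    from screendx import TestDefinition, accuracy_from_2x2, weighted_2x2
    cutoffs = [8, 10, 13, 16]
    table = cutpoint_table(df, "total_score", "depression", cutoffs=cutoffs)
    for _, row in table.iterrows():
        test = TestDefinition("t", "score_threshold", int(row["cutoff"]))
        est = accuracy_from_2x2(weighted_2x2(df, test, "depression"))
        assert row["sensitivity"] == pytest.approx(est.sensitivity)
        assert row["specificity"] == pytest.approx(est.specificity)
        assert row["lr_pos"] == pytest.approx(est.lr_pos)
    assert table["optimal"].sum() == 1
    best = table.loc[table["optimal"], "youden"].iloc[0]
    assert best == table["youden"].max()


def test_cutpoint_extremes():
    df = _frame([10, 15, 20], [5, 8, 12])  # scores within [5, 20]
    table = cutpoint_table(df, "total_score", "depression", cutoffs=[2, 25])
    low = table[table.cutoff == 2].iloc[0]
    high = table[table.cutoff == 25].iloc[0]
    assert low["sensitivity"] == 1.0 and low["specificity"] == 0.0
    assert high["sensitivity"] == 0.0 and high["specificity"] == 1.0


def test_cutpoint_empty_list_error():
    with pytest.raises(EstimationError):
        cutpoint_table(_frame([1], [2]), "total_score", "depression", cutoffs=[])


# ---------------------------------------------------------------------------
# placement values and ROC-GLM


def test_placement_values_of_controls_mean_half():
    """Controls placed against their own distribution have mean exactly 0.5."""
    rng = np.random.default_rng(8)
    scores = rng.integers(0, 31, 2000).astype(float)
    pv = placement_values(scores, scores)
    assert pv.mean() == pytest.approx(0.5, abs=1e-12)
    assert (pv >= 0).all() and (pv <= 1).all()


def test_placement_values_decrease_in_case_score():
    ctrl = np.array([1.0, 4.0, 4.0, 9.0, 15.0])
    pv = placement_values(np.array([0.0, 4.0, 10.0, 20.0]), ctrl)
    assert (np.diff(pv) < 0).all()
    # mid-rank: two controls above 4 plus half credit for the two ties -> 3/5
    assert pv[1] == pytest.approx(0.6, abs=1e-12)


def _latent_records(config, seed, n_screen=None):
    pop = generate_population(config, seed)
    pop["design_weight"] = 1.0
    pop["module_observed_depression"] = 1
    pop["age_dec"] = (pop["age"] - 30.0) / 10.0
    return pop


def test_roc_glm_recovers_generating_parameters():
    """Single large fit lands within 3 SEs of (alpha0, alpha1, beta_age)."""
    config = config_from_roc_params(
        1.2, 0.9, age_slope=-0.3, n_screen=12_000, consent_rate=1.0)
    pop = _latent_records(config, seed=21)
    fit = fit_roc_glm(pop, "latent_score", "depression", ["age_dec"],
                      "design_weight", t_grid=np.arange(0.02, 1.0, 0.02))
    for name, truth in [("const", 1.2), ("probit_t", 0.9), ("age_dec", -0.3)]:
        se = np.sqrt(fit.vcov.loc[name, name])
        assert abs(fit.params[name] - truth) < 3 * se
    assert fit.alpha1_positive


def test_roc_glm_auc_formula_identity():
    config = config_from_roc_params(1.0, 1.0, n_screen=3000, consent_rate=1.0)
    pop = _latent_records(config, seed=22)
    fit = fit_roc_glm(pop, "latent_score", "depression", [], "design_weight")
    expected = stats.norm.cdf(fit.alpha0 / np.sqrt(1 + fit.alpha1 ** 2))
    assert fit.auc() == pytest.approx(float(expected), abs=1e-12)


def test_roc_glm_matches_empirical_roc_without_covariates():
    """Fitted ROC within 0.02 of the empirical curve at t = 0.1, 0.25, 0.5."""
    config = config_from_roc_params(1.1, 1.0, n_screen=20_000, consent_rate=1.0)
    pop = _latent_records(config, seed=23)
    fit = fit_roc_glm(pop, "latent_score", "depression", [], "design_weight")
    curve = empirical_roc(pop, "latent_score", "depression", "design_weight")
    for t in (0.1, 0.25, 0.5):
        fitted = fit.roc(np.array([t]))[0]
        empirical = np.interp(t, curve.fpr, curve.tpr)
        assert abs(fitted - empirical) < 0.02


def test_roc_glm_singular_design_error():
    config = config_from_roc_params(1.2, 1.0, n_screen=2000, consent_rate=1.0)
    pop = _latent_records(config, seed=24)
    pop["age_copy"] = pop["age_dec"]
    with pytest.raises(EstimationError, match="singular|collinear"):
        fit_roc_glm(pop, "latent_score", "depression", ["age_dec", "age_copy"],
                    "design_weight")


def test_roc_glm_requires_enough_cases():
    config = config_from_roc_params(
        1.2, 1.0, n_screen=60, consent_rate=1.0,
        prevalence={"depression": 0.1, "anxiety": 0.1, "any_disorder": 0.2})
    pop = _latent_records(config, seed=25)
    with pytest.raises(EstimationError, match="cases"):
        fit_roc_glm(pop, "latent_score", "depression", [], "design_weight")


def test_compare_groups_single_beta_is_z_squared():
    """1-df Wald statistic equals (beta/se)^2 with the chi2(1) p-value."""
    config = config_from_roc_params(1.2, 0.9, age_slope=-0.3,
                                    n_screen=6000, consent_rate=1.0)
    pop = _latent_records(config, seed=26)
    fit = fit_roc_glm(pop, "latent_score", "depression", ["age_dec"],
                      "design_weight", t_grid=np.arange(0.05, 1.0, 0.05))
    chi2, df, p = compare_roc_groups(fit, "age_dec")
    beta = fit.params["age_dec"]
    se = np.sqrt(fit.vcov.loc["age_dec", "age_dec"])
    assert df == 1
    assert chi2 == pytest.approx((beta / se) ** 2, rel=1e-10)
    assert p == pytest.approx(float(stats.chi2.sf(chi2, 1)), rel=1e-10)


def test_compare_groups_categorical_df_and_unknown_group():
    config = config_from_roc_params(1.2, 0.9, n_screen=8000, consent_rate=1.0)
    pop = _latent_records(config, seed=27)
    fit = fit_roc_glm(pop, "latent_score", "depression", ["ethnicity"],
                      "design_weight", t_grid=np.arange(0.05, 1.0, 0.05))
    chi2, df, p = compare_roc_groups(fit, "ethnicity")
    assert df == 4  # five categories, reference-coded
    assert chi2 >= 0 and 0 <= p <= 1
    with pytest.raises(EstimationError, match="unknown"):
        compare_roc_groups(fit, "shoe_size")


def test_detectable_age_effect_rejected_with_power():
    """A real age effect is flagged by the Wald test at a planned n."""
    config = config_from_roc_params(1.2, 0.9, age_slope=-0.4,
                                    n_screen=6000, consent_rate=1.0)
    rejected = 0
    for r in range(10):
        pop = _latent_records(config, seed=300 + r)
        fit = fit_roc_glm(pop, "latent_score", "depression", ["age_dec"],
                          "design_weight", t_grid=np.arange(0.05, 1.0, 0.05))
        _, _, p = compare_roc_groups(fit, "age_dec")
        rejected += p < 0.05
    assert rejected >= 8


def test_bootstrap_vcov_agrees_with_sandwich():
    """Resampling covariance and the clustered sandwich give similar SEs."""
    config = config_from_roc_params(1.2, 1.0, n_screen=2500, consent_rate=1.0)
    pop = _latent_records(config, seed=29)
    grid = np.arange(0.05, 1.0, 0.05)
    sandwich = fit_roc_glm(pop, "latent_score", "depression", [],
                           "design_weight", t_grid=grid)
    boot = fit_roc_glm(pop, "latent_score", "depression", [],
                       "design_weight", t_grid=grid,
                       bootstrap_B=40, bootstrap_seed=1)
    assert boot.params.equals(sandwich.params)  # point estimate unchanged
    for name in ("const", "probit_t"):
        se_s = np.sqrt(sandwich.vcov.loc[name, name])
        se_b = np.sqrt(boot.vcov.loc[name, name])
        assert se_b > 0
        assert 0.4 < se_b / se_s < 2.5


def test_truth_and_fit_agree_on_discretised_scores():
    """AUC from the ROC-GLM on 0-30 scores tracks the generating AUC."""
    config = config_from_roc_params(1.23, 1.0, n_screen=20_000, consent_rate=1.0)
    pop = _latent_records(config, seed=28)
    truth = empirical_roc_truth(config)["auc"]
    curve = empirical_roc(pop, "total_score", "depression", "design_weight")
    assert abs(curve.auc - truth) < 0.02  # ties on the ordinal scale cost a little
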