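"""GLM closed forms, dispersion, information criteria, contrasts."""

import numpy as np
import pandas as pd
import pytest

from parastage import (
    dispersion_estimate,
    filter_superparasitism,
    glm_fit,
    information_criteria,
    parse_formula,
    posthoc_contrasts,
)
from parastage.glm import AliasedTermError, DispersionError, ModelSpec, SmoothTerm


def test_intercept_only_binomial_is_logit_of_proportion():
    data = pd.DataFrame({"y": [1.0] * 7 + [0.0] * 3})
    fit = glm_fit(parse_formula("y ~ 1", "binomial"), data)
    assert fit.params[0] == pytest.approx(np.log(7 / 3), abs=1e-8)


def test_gaussian_identity_is_exact_least_squares():
    data = pd.DataFrame({"y": [1.0, 2.0, 3.0], "x": [0.0, 1.0, 2.0]})
    fit = glm_fit(parse_formula("y ~ x", "gaussian"), data)
    np.testing.assert_allclose(fit.params, [1.0, 1.0], atol=1e-10)


def test_gaussian_matches_normal_equations_on_random_fixtures():
    rng = np.random.default_rng(4)
    for _ in range(5):
        n = 40
        data = pd.DataFrame(
            {"y": rng.normal(size=n), "x1": rng.normal(size=n), "x2": rng.normal(size=n)}
        )
        fit = glm_fit(parse_formula("y ~ x1 + x2", "gaussian"), data)
        X = np.column_stack([np.ones(n), data["x1"], data["x2"]])
        beta = np.linalg.solve(X.T @ X, X.T @ data["y"].to_numpy())
        np.testing.assert_allclose(fit.params, beta, atol=1e-10)


def test_intercept_only_gamma_inverse_is_reciprocal_mean():
    data = pd.DataFrame({"y": [2.0, 4.0, 6.0, 4.0]})
    fit = glm_fit(parse_formula("y ~ 1", "gamma"), data)
    assert fit.params[0] == pytest.approx(1.0 / 4.0, abs=1e-8)


def test_aliased_design_names_the_offending_column():
    data = pd.DataFrame({"y": [0.0, 1.0, 0.0, 1.0], "x": [1.0, 2.0, 3.0, 4.0]})
    data["z"] = 2 * data["x"]
    with pytest.raises(AliasedTermError, match="z"):
        glm_fit(parse_formula("y ~ x + z", "binomial"), data)


def test_dispersion_is_pearson_over_residual_df():
    rng = np.random.default_rng(5)
    data = pd.DataFrame({"y": (rng.random(200) < 0.4).astype(float)})
    fit = glm_fit(parse_formula("y ~ 1", "binomial"), data)
    chi2 = np.sum((data["y"] - fit.fitted) ** 2 / (fit.fitted * (1 - fit.fitted)))
    assert dispersion_estimate(fit) == pytest.approx(chi2 / (200 - 1))


def test_dispersion_requires_residual_df():
    data = pd.DataFrame({"y": [1.0, 3.0], "x": [0.0, 1.0]})
    fit = glm_fit(parse_formula("y ~ x", "gaussian"), data)  # saturated
    with pytest.raises(DispersionError):
        dispersion_estimate(fit)


def test_no_overdispersion_calibration():
    """Binomial data without overdispersion: c-hat near 1 across seeds."""
    chats = []
    for seed in range(50):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=500)
        p = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
        data = pd.DataFrame({"y": (rng.random(500) < p).astype(float), "x": x})
        chats.append(dispersion_estimate(glm_fit(parse_formula("y ~ x", "binomial"), data)))
    assert np.mean(chats) == pytest.approx(1.0, abs=0.2)
    assert np.all(np.abs(np.array(chats) - 1.0) < 0.35)


def test_information_criteria_formulas():
    # use a real fit but override what the formulas consume
    data = pd.DataFrame({"y": [1.0, 2.0, 3.0, 5.0], "x": [0.0, 1.0, 2.0, 4.0]})
    fit = glm_fit(parse_formula("y ~ x", "gaussian"), data)
    fit.llf, fit.edf = -10.0, 2.0
    assert information_criteria(fit)["aic"] == pytest.approx(24.0)
    fit.edf = 2.0
    out = information_criteria(fit, c_hat=2.0)
    assert out["qaic"] == pytest.approx(-2 * (-10.0) / 2.0 + 2 * 3)  # k = 2 + 1 for c-hat
    with pytest.raises(DispersionError):
        information_criteria(fit, c_hat=0.0)


def test_quasibinomial_inflates_covariance_and_has_no_aic():
    rng = np.random.default_rng(6)
    x = rng.normal(size=300)
    p = 1 / (1 + np.exp(-x))
    data = pd.DataFrame({"y": (rng.random(300) < p).astype(float), "x": x})
    qb = glm_fit(parse_formula("y ~ x", "quasibinomial"), data)
    b = glm_fit(parse_formula("y ~ x", "binomial"), data)
    np.testing.assert_allclose(qb.cov, b.cov * qb.dispersion, atol=1e-12)
    assert np.isnan(information_criteria(qb)["aic"])


def test_aic_ranking_shift_invariant_for_gaussian():
    rng = np.random.default_rng(7)
    x = rng.normal(size=120)
    y = 1.0 + 0.5 * x + rng.normal(0, 1, 120)
    d1 = pd.DataFrame({"y": y, "x": x})
    d2 = pd.DataFrame({"y": y + 57.0, "x": x})
    delta1 = (
        glm_fit(parse_formula("y ~ x", "gaussian"), d1).aic
        - glm_fit(parse_formula("y ~ 1", "gaussian"), d1).aic
    )
    delta2 = (
        glm_fit(parse_formula("y ~ x", "gaussian"), d2).aic
        - glm_fit(parse_formula("y ~ 1", "gaussian"), d2).aic
    )
    assert delta1 == pytest.approx(delta2, abs=1e-8)


def _toy_records():
    return pd.DataFrame(
        {
            "host_id": list("abcdef"),
            "parasitized": [True, True, True, True, False, False],
            "n_eggs": [1, 2, 1, 3, None, None],
            "parasitoid_emerged": [True, True, False, True, None, None],
        }
    )


def test_superparasitism_filter_removes_multi_egg_hosts_only():
    records = _toy_records()
    out, n_hosts, n_wasps = filter_superparasitism(records)
    assert n_hosts == 2
    assert n_wasps == 2  # hosts b and d carried emerged parasitoids
    assert set(out["host_id"]) == {"a", "c", "e", "f"}


def test_superparasitism_filter_is_noop_without_multi_eggs():
    records = _toy_records()
    records["n_eggs"] = [1, 1, 1, 1, None, None]
    out, n_hosts, n_wasps = filter_superparasitism(records)
    assert n_hosts == 0 and n_wasps == 0
    pd.testing.assert_frame_equal(out, records)


def test_contrast_of_level_against_itself_is_null():
    data = pd.DataFrame(
        {"y": [1.0, 2.0, 2.5, 3.5, 1.2, 2.2], "g": pd.Categorical(list("ababab"))}
    )
    fit = glm_fit(parse_formula("y ~ g", "gaussian"), data)
    res = posthoc_contrasts(fit, np.array([[0.0, 0.0]]))
    assert res["estimate"][0] == pytest.approx(0.0)
    assert res["p"][0] == pytest.approx(1.0)


def test_group_difference_contrast_equals_group_coefficient():
    data = pd.DataFrame(
        {"y": [1.0, 2.0, 2.5, 3.5, 1.2, 2.2], "g": pd.Categorical(list("ababab"))}
    )
    fit = glm_fit(parse_formula("y ~ g", "gaussian"), data)
    res = posthoc_contrasts(fit, np.array([[0.0, 1.0]]))
    assert res["estimate"][0] == pytest.approx(fit.params[1])


def test_bonferroni_adjustment_of_contrast_pvalues():
    data = pd.DataFrame({"y": np.r_[np.zeros(20), np.ones(20)] + np.linspace(0, 0.1, 40),
                         "g": pd.Categorical(["a"] * 20 + ["b"] * 20)})
    fit = glm_fit(parse_formula("y ~ g", "gaussian"), data)
    C = np.array([[0.0, 1.0], [0.0, -1.0], [0.0, 0.0]])
    res = posthoc_contrasts(fit, C)
    np.testing.assert_allclose(res["p_adj"], np.minimum(res["p"] * 3, 1.0))


def test_contrast_dimension_mismatch_raises():
    data = pd.DataFrame({"y": [1.0, 2.0, 3.0], "x": [0.0, 1.0, 2.0]})
    fit = glm_fit(parse_formula("y ~ x", "gaussian"), data)
    with pytest.raises(ValueError):
        posthoc_contrasts(fit, np.ones((1, 5)))


def test_parse_formula_grammar():
    spec = parse_formula("T ~ Q * S + s(A, by=Q) + s(A, k=12)", "gaussian")
    assert spec.parametric == ("Q * S",)
    assert spec.smooths[0] == SmoothTerm(covariate="A", by="Q")
    assert spec.smooths[1].k == 12 and spec.smooths[1].by is None
    assert parse_formula("y ~ 1", "binomial").parametric == ()
    with pytest.raises(ValueError):
        parse_formula("no tilde", "binomial")
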