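"""Cox partial likelihood and per-stage fitting.

The package computes the tie-corrected partial likelihood from
per-(time, group) count matrices; these tests check it against an
independent per-subject brute-force implementation, a grid-search
maximizer, and lifelines.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parastage import cox_fit, cox_partial_loglik, fit_stage_hazards
from parastage.hazard import (
    DegenerateDesignError,
    SkippedStage,
    UndefinedLikelihoodError,
)
from parastage import (
    DesignConfig,
    generate_exposure_dataset,
    impute_stages,
)
from conftest import make_exposure_frame


# --- independent oracle: per-subject risk-set enumeration ------------------


def brute_loglik(time, event, group, beta_by_level, tie_method="efron"):
    """Textbook per-subject Efron/Breslow partial log-likelihood."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    eta = np.array([beta_by_level[g] for g in group])
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[event]):
        D = np.where(event & (time == t))[0]
        R = np.where(time >= t)[0]
        d = len(D)
        ll += eta[D].sum()
        sum_R = w[R].sum()
        sum_D = w[D].sum()
        for j in range(d):
            frac = j / d if tie_method == "efron" else 0.0
            ll -= np.log(sum_R - frac * sum_D)
    return ll


def grid_search_lambda(time, event, group, reference, tie_method="efron"):
    """1-D grid maximization of the partial likelihood on [-5, 5]."""
    others = sorted({g for g in group if g != reference})
    assert len(others) == 1
    grid = np.arange(-5.0, 5.0 + 1e-12, 1e-4)
    lls = np.array(
        [
            brute_loglik(time, event, group, {reference: 0.0, others[0]: b}, tie_method)
            for b in grid[:: 100]
        ]
    )
    # refine around the coarse optimum
    centre = grid[::100][np.argmax(lls)]
    fine = np.arange(centre - 0.02, centre + 0.02, 1e-4)
    lls_fine = np.array(
        [brute_loglik(time, event, group, {reference: 0.0, others[0]: b}, tie_method) for b in fine]
    )
    return fine[np.argmax(lls_fine)]


SMALL_FIXTURES = [
    # (time, event, group) with <= 8 subjects, ties included; group
    # patterns are interleaved so the likelihood has an interior optimum
    ([1, 2, 3, 4], [1, 1, 1, 1], list("ABAB")),
    ([1, 1, 2, 2], [1, 1, 1, 0], list("ABAB")),
    ([3, 3, 3, 5, 5, 7], [1, 1, 0, 1, 1, 0], list("AABABB")),
    ([2, 2, 2, 2, 4, 4, 6, 6], [1, 0, 1, 1, 0, 1, 1, 0], list("ABABABAB")),
    ([1, 2, 2, 3, 3, 3], [1, 1, 1, 1, 0, 1], list("ABBAAB")),
]


def test_two_subject_loglik_is_minus_log_two():
    ll = cox_partial_loglik([1, 2], [1, 1], ["A", "B"], [0.0], reference="A")
    assert ll == pytest.approx(-np.log(2))


def test_no_events_is_an_error():
    with pytest.raises(UndefinedLikelihoodError):
        cox_partial_loglik([1, 2], [0, 0], ["A", "B"], [0.0], reference="A")


@pytest.mark.parametrize("tie_method", ["efron", "breslow"])
@pytest.mark.parametrize("fixture", SMALL_FIXTURES)
def test_count_based_loglik_matches_per_subject_enumeration(tie_method, fixture):
    time, event, group = fixture
    for beta in (-1.2, 0.0, 0.7):
        ours = cox_partial_loglik(time, event, group, [beta], tie_method, reference="A")
        oracle = brute_loglik(time, event, group, {"A": 0.0, "B": beta}, tie_method)
        assert ours == pytest.approx(oracle, abs=1e-10)


@settings(max_examples=30, deadline=None)
@given(
    data=st.lists(
        st.tuples(st.integers(1, 4), st.booleans(), st.sampled_from("AB")), min_size=2, max_size=10
    ),
    beta=st.floats(-2, 2),
)
def test_loglik_property_matches_oracle_on_random_data(data, beta):
    time = [t for t, _, _ in data]
    event = [e for _, e, _ in data]
    group = [g for _, _, g in data]
    if not any(event) or len(set(group)) < 2:
        return
    for tie in ("efron", "breslow"):
        ours = cox_partial_loglik(time, event, group, [beta], tie, reference="A")
        oracle = brute_loglik(time, event, group, {"A": 0.0, "B": beta}, tie)
        assert ours == pytest.approx(oracle, abs=1e-9)


def test_efron_equals_breslow_without_ties():
    time, event, group = [1, 2, 3, 5, 8], [1, 0, 1, 1, 1], list("ABABA")
    for beta in (-0.5, 0.3):
        assert cox_partial_loglik(time, event, group, [beta], "efron", reference="A") == (
            pytest.approx(cox_partial_loglik(time, event, group, [beta], "breslow", reference="A"))
        )


def test_duplicating_subjects_rescales_breslow_consistently():
    time, event, group = [1, 2, 3, 4], [1, 1, 0, 1], list("ABAB")
    dup = (time * 2, event * 2, group * 2)
    for beta in (-0.8, 0.4):
        ours = cox_partial_loglik(*dup, [beta], "breslow", reference="A")
        oracle = brute_loglik(dup[0], dup[1], dup[2], {"A": 0.0, "B": beta}, "breslow")
        assert ours == pytest.approx(oracle, abs=1e-9)


@pytest.mark.parametrize("fixture", SMALL_FIXTURES)
def test_fit_matches_grid_search_oracle(fixture):
    time, event, group = fixture
    fit = cox_fit(time, event, group, reference="A")
    oracle = grid_search_lambda(time, event, group, reference="A")
    assert fit.lambda_["B"] == pytest.approx(oracle, abs=1e-3)
    # the optimum never sits below the null likelihood
    assert fit.loglik >= cox_partial_loglik(time, event, group, [0.0], reference="A") - 1e-12


def test_mirror_image_groups_give_zero_coefficient():
    time = [1, 2, 3, 1, 2, 3]
    event = [1, 0, 1, 1, 0, 1]
    group = list("AAABBB")
    fit = cox_fit(time, event, group, reference="A")
    assert fit.lambda_["B"] == pytest.approx(0.0, abs=1e-8)


def test_events_in_one_group_only_is_flagged_monotone():
    fit = cox_fit([1, 2, 3, 4], [1, 1, 0, 0], list("AABB"), reference="A")
    assert not fit.converged
    assert fit.monotone


def test_single_group_is_degenerate():
    with pytest.raises(DegenerateDesignError):
        cox_fit([1, 2], [1, 1], ["A", "A"])


def test_scale_invariance_of_event_times():
    time, event, group = [2, 4, 6, 8, 10, 12], [1, 1, 0, 1, 1, 0], list("ABABAB")
    a = cox_fit(time, event, group, reference="A")
    b = cox_fit([t * 7.3 for t in time], event, group, reference="A")
    assert a.lambda_["B"] == pytest.approx(b.lambda_["B"], abs=1e-9)


def test_reference_swap_negates_the_contrast(usable_dataset, exchangeable_table, rng):
    staged = impute_stages(usable_dataset, exchangeable_table, rng, nearest_age_fallback=True)
    two = staged[staged["quality"].isin([90, 100])]
    f1 = fit_stage_hazards(two, reference=100, stages=("L4",))["L4"]
    f2 = fit_stage_hazards(two, reference=90, stages=("L4",))["L4"]
    assert f1.lambda_[90] == pytest.approx(-f2.lambda_[100], abs=1e-6)


def test_all_one_stage_yields_one_fit_and_skip_markers():
    df = make_exposure_frame([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1], [90, 100] * 3, stage="L4")
    fits = fit_stage_hazards(df, reference=100)
    assert not isinstance(fits["L4"], SkippedStage)
    assert sum(isinstance(f, SkippedStage) for f in fits.values()) == 4


def test_matches_lifelines_on_moderate_data(usable_dataset, exchangeable_table, rng):
    """Independent cross-check: lifelines CoxPHFitter, Efron ties."""
    lifelines = pytest.importorskip("lifelines")
    staged = impute_stages(usable_dataset, exchangeable_table, rng, nearest_age_fallback=True)
    sub = staged[staged["stage_at_parasitism"] == "L4"]
    ours = fit_stage_hazards(sub, reference=100)["L4"]
    frame = pd.DataFrame(
        {
            "T": sub["age_at_exposure"].to_numpy(float),
            "E": sub["parasitized"].astype(bool).to_numpy(),
            "q90": (sub["quality"] == 90).astype(float).to_numpy(),
            "q95": (sub["quality"] == 95).astype(float).to_numpy(),
        }
    )
    cph = lifelines.CoxPHFitter()
    cph.fit(frame, duration_col="T", event_col="E")
    assert ours.lambda_[90] == pytest.approx(cph.params_["q90"], abs=1e-4)
    assert ours.lambda_[95] == pytest.approx(cph.params_["q95"], abs=1e-4)
    assert ours.se[90] == pytest.approx(cph.standard_errors_["q90"], abs=1e-4)


def test_null_generator_coefficients_center_on_zero(exchangeable_params, exchangeable_table):
    """Exchangeable treatments: each stage's coefficient lies within
    2 SE of zero in at least 90% of seeded runs."""
    n_runs, hits, total = 50, 0, 0
    for seed in range(n_runs):
        cfg = DesignConfig(n_replicates=18, seed=9_000 + seed)  # 3024 hosts
        df = generate_exposure_dataset(cfg, dev_params=exchangeable_params)
        usable = df[~df["host_died"].astype(bool) & ~df["host_emerged"].astype(bool)]
        staged = impute_stages(
            usable, exchangeable_table, np.random.default_rng(seed), nearest_age_fallback=True
        )
        fits = fit_stage_hazards(staged, reference=100)
        for fit in fits.values():
            if isinstance(fit, SkippedStage) or not fit.converged:
                continue
            for lv in fit.levels:
                total += 1
                hits += abs(fit.lambda_[lv]) <= 2.0 * fit.se[lv]
    assert total > 300
    assert hits / total >= 0.90
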