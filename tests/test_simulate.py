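"""Generator tests: design arithmetic, development model, outcome sampling."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from parastage import (
    DesignConfig,
    HostDevelopmentParams,
    ParasitismParams,
    ParasitoidTraitParams,
    build_design,
    generate_exposure_dataset,
    generate_reference_table,
    simulate_development_trajectory,
    simulate_exposure_outcome,
    simulate_parasitoid_traits,
)
from parastage.params import InvalidDesignError, UnknownTreatmentError


@pytest.mark.parametrize(
    "n_rep, a0, a1, quals, expected",
    [
        (1, 5, 5, (100,), 1),
        (2, 5, 7, (95, 100), 12),
        (54, 5, 60, (90, 95, 100), 9072),
    ],
)
def test_design_enumerates_factorial_product(n_rep, a0, a1, quals, expected):
    cfg = DesignConfig(n_replicates=n_rep, age_start=a0, age_stop=a1, qualities=quals)
    df = build_design(cfg)
    assert len(df) == expected
    assert df["host_id"].is_unique
    assert df["parasitized"].isna().all()


@settings(max_examples=10, deadline=None)
@given(
    n_rep=st.integers(1, 8),
    a0=st.integers(1, 20),
    span=st.integers(0, 15),
    quals=st.sets(st.integers(50, 100), min_size=1, max_size=4),
)
def test_design_cardinality_is_product_of_factor_levels(n_rep, a0, span, quals):
    cfg = DesignConfig(n_replicates=n_rep, age_start=a0, age_stop=a0 + span, qualities=tuple(quals))
    assert len(build_design(cfg)) == n_rep * (span + 1) * len(quals)


def test_invalid_designs_are_rejected():
    with pytest.raises(InvalidDesignError):
        DesignConfig(n_replicates=0)
    with pytest.raises(InvalidDesignError):
        DesignConfig(age_start=10, age_stop=5)
    with pytest.raises(InvalidDesignError):
        DesignConfig(qualities=())
    with pytest.raises(InvalidDesignError):
        DesignConfig(qualities=(90, 90))


def test_trajectory_stage_at_age_zero_is_first_instar(rng):
    traj = simulate_development_trajectory(HostDevelopmentParams(), 100, rng)
    assert traj.stage_at(0.0) == "L1"


def test_delay_factor_scales_boundaries_multiplicatively(rng):
    # a 22% development delay moves a 20 d pupation boundary to 24.4 d
    params = HostDevelopmentParams(
        baseline_transition_ages=(8.0, 12.0, 16.0, 20.0, 28.0),
        delay_factor={100: 1.0, 90: 1.22},
        size_reduction={100: 0.0, 90: 0.5},
        transition_noise_sd=0.0,
    )
    traj = simulate_development_trajectory(params, 90, rng)
    assert traj.boundary_ages[3] == pytest.approx(24.4)


def test_unknown_quality_raises(rng):
    with pytest.raises(UnknownTreatmentError):
        simulate_development_trajectory(HostDevelopmentParams(), 85, rng)


def test_stage_occupancy_matches_lognormal_boundary_model(rng):
    """Monte-Carlo occupancy fractions agree with the closed-form
    lognormal boundary-age distribution."""
    params = HostDevelopmentParams.exchangeable(transition_noise_sd=0.1)
    base = np.asarray(params.baseline_transition_ages)
    ages = np.array([6.0, 10.0, 15.0, 22.0, 30.0])
    n = 10_000
    occ = np.zeros((len(ages), 6))
    for _ in range(n):
        traj = simulate_development_trajectory(params, 100, rng)
        occ[np.arange(len(ages)), traj.stage_index_at(ages)] += 1
    occ /= n
    # P(stage index >= j at age a) = P(boundary_j <= a), boundary lognormal
    for ai, a in enumerate(ages):
        for j in range(1, 6):
            expected = stats.norm.cdf(np.log(a / base[j - 1]) / 0.1)
            observed = occ[ai, j:].sum()
            se = np.sqrt(max(expected * (1 - expected), 1e-6) / n)
            assert observed == pytest.approx(expected, abs=max(5 * se, 5e-3))


def test_biomass_is_nondecreasing_and_saturates(rng):
    params = HostDevelopmentParams()
    traj = simulate_development_trajectory(params, 95, rng)
    ages = np.linspace(0.5, 60, 200)
    biomass = traj.biomass_at(ages)
    assert np.all(np.diff(biomass) >= -1e-12)
    assert biomass[-1] <= params.asymptote(95) + 1e-9


@pytest.mark.parametrize("p, expect_all", [(0.0, False), (1.0, True)])
def test_degenerate_attack_probabilities(rng, p, expect_all):
    params = ParasitismParams(attack_success={s: p for s in "L1 L2 L3 L4 P A".split()})
    rec = {"quality": 100}
    hits = [
        simulate_exposure_outcome(rec, "L4", params, rng)["parasitized"] for _ in range(200)
    ]
    assert all(hits) if expect_all else not any(hits)


def test_attack_fraction_matches_binomial_expectation(rng):
    params = ParasitismParams()
    n = 10_000
    hits = sum(
        simulate_exposure_outcome({"quality": 100}, "L4", params, rng)["parasitized"]
        for _ in range(n)
    )
    p = params.prob("L4", 100)
    se = np.sqrt(p * (1 - p) / n)
    assert hits / n == pytest.approx(p, abs=4 * se)


def test_traits_require_parasitized_record(rng):
    with pytest.raises(ValueError):
        simulate_parasitoid_traits(
            {"parasitized": False, "stage_at_parasitism": "L4", "age_at_exposure": 20},
            ParasitoidTraitParams(),
            rng,
        )


def test_all_female_when_curve_is_one(rng):
    params = ParasitoidTraitParams(
        p_female_curve=lambda a: np.ones_like(np.asarray(a, float)),
        emergence_success={s: 1.0 for s in "L1 L2 L3 L4 P A".split()},
    )
    rec = {"parasitized": True, "stage_at_parasitism": "L4", "age_at_exposure": 20}
    sexes = {simulate_parasitoid_traits(rec, params, rng)["sex"] for _ in range(50)}
    assert sexes == {"female"}


def test_female_development_excess_recovered(rng):
    params = ParasitoidTraitParams(
        emergence_success={s: 1.0 for s in "L1 L2 L3 L4 P A".split()}
    )
    rec = {"parasitized": True, "stage_at_parasitism": "L4", "age_at_exposure": 25}
    draws = [simulate_parasitoid_traits(rec, params, rng) for _ in range(10_000)]
    dev = pd.DataFrame(draws)
    means = dev.groupby("sex")["development_time"].mean()
    excess = means["female"] - means["male"]
    assert excess == pytest.approx(params.devtime_female_excess, abs=0.1)


def test_tibia_plateau_gives_equal_expected_length():
    params = ParasitoidTraitParams()
    t30 = params.tibia_mean(np.array([30.0]), np.array([True]))
    t55 = params.tibia_mean(np.array([55.0]), np.array([True]))
    assert t30[0] == pytest.approx(t55[0])


def test_reference_table_minimal_and_degenerate_cells(rng):
    params = HostDevelopmentParams(transition_noise_sd=0.0, biomass_noise_sd=0.0)
    one = generate_reference_table(params, 1, rng, qualities=(100,), ages=[10])
    assert len(one) == 1
    table = generate_reference_table(params, 25, rng, qualities=(100,), ages=range(5, 26))
    per_cell = table.groupby(["quality", "age"])["stage"].nunique()
    assert (per_cell == 1).all()


def test_reference_stage_frequencies_match_trajectory_probabilities(rng):
    params = HostDevelopmentParams.exchangeable(transition_noise_sd=0.1)
    base = np.asarray(params.baseline_transition_ages)
    table = generate_reference_table(params, 4000, rng, qualities=(100,), ages=[15])
    freq = table["stage"].value_counts(normalize=True)
    # stage occupancy at age 15 from the lognormal boundary model
    upper = stats.norm.cdf(np.log(15.0 / base) / 0.1)
    expected = {"L1": 1 - upper[0], "L2": upper[0] - upper[1], "L3": upper[1] - upper[2],
                "L4": upper[2] - upper[3], "P": upper[3] - upper[4]}
    for stage, p in expected.items():
        if p > 1e-4:
            assert freq.get(stage, 0.0) == pytest.approx(p, abs=0.02)


def test_dataset_stage_missing_iff_unparasitized(small_dataset):
    df = small_dataset
    assert (df["stage_at_parasitism"].notna() == df["parasitized"]).all()
    assert (df.loc[df["parasitized"], "n_eggs"] >= 1).all()
    assert df.loc[~df["parasitized"], "n_eggs"].isna().all()


def test_dataset_seed_reproducibility_is_byte_identical(exchangeable_params):
    cfg = DesignConfig(n_replicates=3, seed=99)
    a = generate_exposure_dataset(cfg, dev_params=exchangeable_params)
    b = generate_exposure_dataset(cfg, dev_params=exchangeable_params)
    buf_a, buf_b = io.StringIO(), io.StringIO()
    a.to_csv(buf_a, index=False, na_rep="NA")
    b.to_csv(buf_b, index=False, na_rep="NA")
    assert buf_a.getvalue() == buf_b.getvalue()


def test_treatments_exchangeable_without_quality_effects(rng):
    """With delay = 1 and no size reduction, a two-sample statistic on
    realized boundary ages is distributed as under label exchange."""
    params = HostDevelopmentParams.exchangeable()
    n = 500
    b90 = np.array(
        [simulate_development_trajectory(params, 90, rng).boundary_ages[3] for _ in range(n)]
    )
    b100 = np.array(
        [simulate_development_trajectory(params, 100, rng).boundary_ages[3] for _ in range(n)]
    )
    observed = b90.mean() - b100.mean()
    pooled = np.concatenate([b90, b100])
    perm_stats = np.empty(500)
    for i in range(500):
        perm = rng.permutation(pooled)
        perm_stats[i] = perm[:n].mean() - perm[n:].mean()
    p = np.mean(np.abs(perm_stats) >= abs(observed))
    assert p > 0.01
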