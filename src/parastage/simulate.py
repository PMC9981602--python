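"""Synthetic exposure-experiment generator.

Emulates the cross-sectional design in which independent hosts aged 5-60 d,
raised on a three-level seed-quality gradient, are each exposed once to a
mated female parasitoid for 24 h.  The generator reproduces the statistical
structure the downstream analysis relies on:

* quality-dependent development delay and growth reduction,
* stage-dependent parasitism success,
* stage observed (via molted head capsules) exactly when parasitized,
* parasitoid life-history outcomes (female-biased sex allocation on
  older hosts, ~1 d female development excess, saturating tibia-age
  relation, per-sex mass-tibia allometry).

All randomness flows through one seeded generator per dataset, with draws
made in a fixed vectorized order over the design grid, so a fixed seed
reproduces the output table byte for byte.  The scalar per-host operations
(:func:`simulate_development_trajectory`, :func:`simulate_exposure_outcome`,
:func:`simulate_parasitoid_traits`) define the sampling model one host at a
time; the dataset builders apply the same model across the whole grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    STAGES,
    DesignConfig,
    HostDevelopmentParams,
    ParasitismParams,
    ParasitoidTraitParams,
)

#: Column order of the exposure table (CSV schema).
EXPOSURE_COLUMNS = [
    "host_id",
    "replicate",
    "quality",
    "age_at_exposure",
    "host_died",
    "host_emerged",
    "parasitized",
    "stage_at_parasitism",
    "n_eggs",
    "sex",
    "parasitoid_emerged",
    "development_time",
    "emergence_mass",
    "hind_tibia_length",
]

REFERENCE_COLUMNS = ["quality", "age", "stage", "dry_biomass"]


def build_design(config: DesignConfig) -> pd.DataFrame:
    """Enumerate the factorial exposure grid as skeleton records.

    Returns one row per (replicate, age, quality) with a unique
    ``host_id`` and all outcome fields unset.
    """
    reps = np.arange(1, config.n_replicates + 1)
    ages = config.ages
    quals = np.asarray(config.qualities)
    rep_g, age_g, qual_g = np.meshgrid(reps, ages, quals, indexing="ij")
    df = pd.DataFrame(
        {
            "replicate": rep_g.ravel(),
            "quality": qual_g.ravel(),
            "age_at_exposure": age_g.ravel(),
        }
    )
    df.insert(
        0,
        "host_id",
        [
            f"r{r:03d}-q{q:03d}-a{a:02d}"
            for r, q, a in zip(df["replicate"], df["quality"], df["age_at_exposure"])
        ],
    )
    for col in EXPOSURE_COLUMNS[4:]:
        df[col] = pd.NA
    assert len(df) == config.n_units
    return df


@dataclass(frozen=True)
class DevelopmentTrajectory:
    """One host's realized stage-boundary ages and growth curve."""

    quality: int
    boundary_ages: np.ndarray  # 5 strictly increasing ages
    asymptote: float
    growth_rate: float
    emergence_age: float  # adult leaves the seed at this age

    def stage_at(self, age: float) -> str:
        return STAGES[int(np.searchsorted(self.boundary_ages, age, side="right"))]

    def stage_index_at(self, age) -> np.ndarray:
        return np.searchsorted(self.boundary_ages, np.asarray(age, float), side="right")

    def biomass_at(self, age) -> np.ndarray:
        """Mean dry biomass (mg): saturating growth toward the
        quality-scaled asymptote, frozen after pupation."""
        age = np.asarray(age, float)
        capped = np.minimum(age, self.boundary_ages[3])  # growth stops at pupation
        return self.asymptote * (1.0 - np.exp(-self.growth_rate * capped))


def simulate_development_trajectory(
    params: HostDevelopmentParams, quality: int, rng: np.random.Generator
) -> DevelopmentTrajectory:
    """Draw one host's development trajectory for a seed quality.

    Boundary ages are the baseline schedule scaled by the quality delay
    factor and one shared lognormal individual factor, so boundaries stay
    strictly ordered within a host.
    """
    delay = params.delay(quality)
    noise = np.exp(rng.normal(0.0, params.transition_noise_sd)) if params.transition_noise_sd > 0 else 1.0
    boundaries = np.asarray(params.baseline_transition_ages, float) * delay * noise
    return DevelopmentTrajectory(
        quality=quality,
        boundary_ages=boundaries,
        asymptote=params.asymptote(quality),
        growth_rate=params.biomass_growth_rate / delay,
        emergence_age=boundaries[-1] + params.adult_emergence_lag,
    )


def simulate_exposure_outcome(
    record: pd.Series | dict,
    stage_at_exposure: str,
    params: ParasitismParams,
    rng: np.random.Generator,
    host_emerged: bool = False,
) -> dict:
    """Complete the parasitism fields of one skeleton record."""
    if stage_at_exposure not in STAGES:
        raise ValueError(f"invalid stage {stage_at_exposure!r}")
    quality = int(record["quality"])
    if host_emerged and params.adult_hosts_attackable_only_pre_emergence:
        p = 0.0
    else:
        p = params.prob(stage_at_exposure, quality)
    parasitized = bool(rng.random() < p)
    out = {
        "parasitized": parasitized,
        "stage_at_parasitism": stage_at_exposure if parasitized else pd.NA,
        "n_eggs": pd.NA,
        "host_emerged": host_emerged,
    }
    if parasitized:
        out["n_eggs"] = 2 if rng.random() < params.superparasitism_rate else 1
    return out


def simulate_parasitoid_traits(
    record: pd.Series | dict,
    params: ParasitoidTraitParams,
    rng: np.random.Generator,
) -> dict:
    """Draw the emerging parasitoid's sex and life-history traits.

    Must only be called on a parasitized record; trait fields other than
    emergence stay missing when the parasitoid fails to reach adulthood.
    """
    if not bool(record["parasitized"]):
        raise ValueError("simulate_parasitoid_traits called on an unparasitized record")
    stage = record["stage_at_parasitism"]
    age = float(record["age_at_exposure"])
    emerged = bool(rng.random() < float(params.emergence_success.get(stage, 0.0)))
    out = {
        "parasitoid_emerged": emerged,
        "sex": pd.NA,
        "development_time": pd.NA,
        "emergence_mass": pd.NA,
        "hind_tibia_length": pd.NA,
    }
    if not emerged:
        return out
    female = bool(rng.random() < float(np.asarray(params.p_female_curve(np.array([age])))[0]))
    sex = "female" if female else "male"
    mean_dev = params.devtime_mean_male + (params.devtime_female_excess if female else 0.0)
    dev = rng.gamma(params.devtime_shape, mean_dev / params.devtime_shape)
    tibia = params.tibia_mean(np.array([age]), np.array([female]))[0] + rng.normal(0.0, params.tibia_noise_sd)
    tibia = max(tibia, 1e-3)
    intercept, slope = params.mass_allometry[sex]
    log_mass = intercept + slope * np.log(tibia) + rng.normal(0.0, params.mass_noise_sd)
    out.update(
        sex=sex,
        development_time=float(dev),
        emergence_mass=float(np.exp(log_mass)),
        hind_tibia_length=float(tibia),
    )
    return out


def _boundary_matrix(
    params: HostDevelopmentParams, qualities: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(n, 5) realized boundary ages for hosts with given quality labels."""
    base = np.asarray(params.baseline_transition_ages, float)
    delays = np.array([params.delay(int(q)) for q in np.unique(qualities)])
    delay_of = dict(zip(np.unique(qualities), delays))
    delay_vec = np.array([delay_of[q] for q in qualities])
    if params.transition_noise_sd > 0:
        noise = np.exp(rng.normal(0.0, params.transition_noise_sd, len(qualities)))
    else:
        noise = np.ones(len(qualities))
    return base[None, :] * (delay_vec * noise)[:, None]


def generate_reference_table(
    params: HostDevelopmentParams,
    n_per_cell: int,
    rng: np.random.Generator,
    qualities=(90, 95, 100),
    ages=None,
) -> pd.DataFrame:
    """Simulate the reference development data set.

    For every (quality, age) cell, simulates ``n_per_cell`` independent
    trajectories and records the stage and dry biomass of each host still
    inside its seed at that age (emerged adults leave no record, so late
    ages on fast schedules can yield thin or empty cells, which downstream
    estimation simply omits).
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    if ages is None:
        ages = np.arange(5, 61)
    ages = np.asarray(ages, int)
    frames = []
    for quality in qualities:
        qvec = np.full(n_per_cell, int(quality))
        bounds = _boundary_matrix(params, qvec, rng)  # (m, 5)
        emergence = bounds[:, -1] + params.adult_emergence_lag
        # stage index of host i at age a: number of boundaries <= a
        stage_idx = (bounds[:, None, :] <= ages[None, :, None]).sum(axis=2)  # (m, n_ages)
        asym = params.asymptote(int(quality))
        rate = params.biomass_growth_rate / params.delay(int(quality))
        capped = np.minimum(ages[None, :], bounds[:, 3][:, None])
        biomass = asym * (1.0 - np.exp(-rate * capped))
        if params.biomass_noise_sd > 0:
            biomass = biomass * np.exp(rng.normal(0.0, params.biomass_noise_sd, biomass.shape))
        present = ages[None, :] < emergence[:, None]
        m_idx, a_idx = np.nonzero(present)
        frames.append(
            pd.DataFrame(
                {
                    "quality": int(quality),
                    "age": ages[a_idx],
                    "stage": np.array(STAGES)[stage_idx[m_idx, a_idx]],
                    "dry_biomass": np.maximum(biomass[m_idx, a_idx], 1e-6),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[REFERENCE_COLUMNS]


def generate_exposure_dataset(
    config: DesignConfig,
    dev_params: HostDevelopmentParams | None = None,
    parasitism_params: ParasitismParams | None = None,
    trait_params: ParasitoidTraitParams | None = None,
) -> pd.DataFrame:
    """Generate a complete exposure table for the factorial design.

    Draws are vectorized over the design grid in a fixed column order, so
    the same config and seed always reproduce the same table.
    """
    dev_params = dev_params or HostDevelopmentParams()
    parasitism_params = parasitism_params or ParasitismParams()
    trait_params = trait_params or ParasitoidTraitParams()

    df = build_design(config)
    n = len(df)
    rng = np.random.default_rng(config.seed)
    quality = df["quality"].to_numpy(int)
    age = df["age_at_exposure"].to_numpy(int)

    bounds = _boundary_matrix(dev_params, quality, rng)
    stage_idx = (bounds <= age[:, None]).sum(axis=1)
    emergence_age = bounds[:, -1] + dev_params.adult_emergence_lag
    host_emerged = age >= emergence_age

    mort = np.array([float(dev_params.mortality_rate.get(int(q), 0.0)) for q in quality])
    died = rng.random(n) < 1.0 - (1.0 - mort) ** age

    prob_mat = parasitism_params.prob_matrix(sorted(set(config.qualities)))
    q_codes = pd.Categorical(quality, categories=sorted(set(config.qualities))).codes
    p_attack = prob_mat[q_codes, stage_idx]
    if parasitism_params.adult_hosts_attackable_only_pre_emergence:
        p_attack = np.where(host_emerged, 0.0, p_attack)
    p_attack = np.where(died, 0.0, p_attack)
    parasitized = rng.random(n) < p_attack
    super_p = rng.random(n) < parasitism_params.superparasitism_rate
    n_eggs = np.where(super_p, 2, 1)

    emer_probs = np.array([float(trait_params.emergence_success.get(s, 0.0)) for s in STAGES])
    wasp_emerged = rng.random(n) < emer_probs[stage_idx]
    female = rng.random(n) < np.asarray(trait_params.p_female_curve(age.astype(float)))
    shape = trait_params.devtime_shape
    mean_dev = trait_params.devtime_mean_male + np.where(female, trait_params.devtime_female_excess, 0.0)
    devtime = rng.gamma(shape, mean_dev / shape)
    tibia = np.maximum(
        trait_params.tibia_mean(age.astype(float), female) + rng.normal(0.0, trait_params.tibia_noise_sd, n),
        1e-3,
    )
    fi, fs = trait_params.mass_allometry["female"]
    mi, ms = trait_params.mass_allometry["male"]
    log_mass = (
        np.where(female, fi, mi)
        + np.where(female, fs, ms) * np.log(tibia)
        + rng.normal(0.0, trait_params.mass_noise_sd, n)
    )

    stage_names = np.array(STAGES)[stage_idx]
    alive = ~died
    traits_on = parasitized & wasp_emerged
    out = df[EXPOSURE_COLUMNS[:4]].copy()
    out["host_died"] = died
    out["host_emerged"] = np.where(alive, host_emerged, False)
    out["parasitized"] = parasitized
    out["stage_at_parasitism"] = pd.array(np.where(parasitized, stage_names, None), dtype="string")
    out["n_eggs"] = pd.array(np.where(parasitized, n_eggs, -1), dtype="Int64")
    out.loc[~parasitized, "n_eggs"] = pd.NA
    out["sex"] = pd.array(np.where(traits_on, np.where(female, "female", "male"), None), dtype="string")
    out["parasitoid_emerged"] = pd.array(np.where(parasitized, wasp_emerged, None), dtype="boolean")
    out["development_time"] = pd.array(np.where(traits_on, devtime, np.nan), dtype="Float64")
    out["emergence_mass"] = pd.array(np.where(traits_on, np.exp(log_mass), np.nan), dtype="Float64")
    out["hind_tibia_length"] = pd.array(np.where(traits_on, tibia, np.nan), dtype="Float64")
    return out[EXPOSURE_COLUMNS]
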