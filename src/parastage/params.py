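"""Parameter types for the synthetic host-parasitoid exposure experiment.

The simulated system is a seed beetle (*Callosobruchus maculatus*) host
developing inside an artificial seed of one of three flour qualities
(90 / 95 / 100 % flour by dry mass), exposed once, at a known age, to a
mated female idiobiont parasitoid (*Anisopteromalus calandrae*) for 24 h.
Each parameter block below controls one layer of that generative story:
host development, the parasitism outcome, and the emerging parasitoid's
life-history traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

#: Ordered host developmental stages: four larval instars, pupa, adult.
STAGES: tuple[str, ...] = ("L1", "L2", "L3", "L4", "P", "A")
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Stage boundaries, in order of crossing.
BOUNDARIES: tuple[str, ...] = ("L1->L2", "L2->L3", "L3->L4", "L4->P", "P->A")


class InvalidDesignError(ValueError):
    """The factorial design is empty or malformed."""


class UnknownTreatmentError(KeyError):
    """A quality level without configured parameters was requested."""


class ConfigError(ValueError):
    """A parameter value violates its documented range."""


@dataclass(frozen=True)
class DesignConfig:
    """Factorial exposure design: replicates x daily ages x seed qualities.

    The reference design is 54 replicates x ages 5..60 d x qualities
    (90, 95, 100), i.e. 9072 exposure units, one host per unit.
    """

    n_replicates: int = 54
    age_start: int = 5
    age_stop: int = 60  # inclusive
    qualities: tuple[int, ...] = (90, 95, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise InvalidDesignError("n_replicates must be >= 1")
        if self.age_stop < self.age_start:
            raise InvalidDesignError("age range is empty")
        if len(self.qualities) == 0:
            raise InvalidDesignError("qualities must be nonempty")
        if len(set(self.qualities)) != len(self.qualities):
            raise InvalidDesignError("qualities must be distinct")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_start, self.age_stop + 1)

    @property
    def n_units(self) -> int:
        return self.n_replicates * len(self.ages) * len(self.qualities)


def _delay_defaults() -> dict[int, float]:
    # 95% seeds: 1.4% slower than 100%; 90% seeds: a further 22% slower.
    return {100: 1.0, 95: 1.014, 90: 1.014 * 1.22}


def _size_reduction_defaults() -> dict[int, float]:
    # 95%: 15% smaller than 100%; 90%: a further 46% smaller (0.85 * 0.54).
    return {100: 0.0, 95: 0.15, 90: 1.0 - 0.85 * 0.54}


@dataclass(frozen=True)
class HostDevelopmentParams:
    """Host stage-boundary schedule and growth, by seed quality.

    ``baseline_transition_ages`` are the ages (days since oviposition, at
    100% quality) at which an average host crosses each stage boundary
    L1->L2, L2->L3, L3->L4, L4->P, P->A.  Egg-to-adult takes ~28 d on
    100% seeds and stretches toward 60 d on poor seeds, which the
    per-quality ``delay_factor`` produces multiplicatively.  Individual
    hosts share one lognormal factor across all their boundaries, so the
    stage ordering is always preserved.
    """

    baseline_transition_ages: tuple[float, ...] = (8.0, 12.0, 16.0, 21.0, 28.0)
    delay_factor: Mapping[int, float] = field(default_factory=_delay_defaults)
    size_reduction: Mapping[int, float] = field(default_factory=_size_reduction_defaults)
    transition_noise_sd: float = 0.08
    mortality_rate: Mapping[int, float] = field(default_factory=dict)
    biomass_asymptote_mg: float = 3.0
    biomass_growth_rate: float = 0.22
    biomass_noise_sd: float = 0.10
    adult_emergence_lag: float = 3.0

    def __post_init__(self) -> None:
        b = np.asarray(self.baseline_transition_ages, float)
        if b.ndim != 1 or len(b) != len(BOUNDARIES) or np.any(np.diff(b) <= 0):
            raise ConfigError("baseline_transition_ages must be 5 strictly increasing ages")
        for q, d in self.delay_factor.items():
            if d < 1.0 - 1e-12:
                raise ConfigError(f"delay_factor[{q}] must be >= 1")
        for q, r in self.size_reduction.items():
            if not (0.0 <= r < 1.0):
                raise ConfigError(f"size_reduction[{q}] must be in [0, 1)")
        for q, m in self.mortality_rate.items():
            if not (0.0 <= m <= 1.0):
                raise ConfigError(f"mortality_rate[{q}] must be a probability")
        if self.transition_noise_sd < 0:
            raise ConfigError("transition_noise_sd must be >= 0")

    @classmethod
    def exchangeable(cls, **overrides) -> "HostDevelopmentParams":
        """Parameters with no seed-quality effect on development or size.

        Used by calibration and parameter-recovery simulations where the
        three treatments must be exchangeable apart from any configured
        attack-probability difference.
        """
        base = dict(
            delay_factor={90: 1.0, 95: 1.0, 100: 1.0},
            size_reduction={90: 0.0, 95: 0.0, 100: 0.0},
        )
        base.update(overrides)
        return cls(**base)

    def delay(self, quality: int) -> float:
        try:
            return float(self.delay_factor[quality])
        except KeyError as exc:
            raise UnknownTreatmentError(f"no delay_factor for quality {quality}") from exc

    def asymptote(self, quality: int) -> float:
        try:
            red = float(self.size_reduction[quality])
        except KeyError as exc:
            raise UnknownTreatmentError(f"no size_reduction for quality {quality}") from exc
        return self.biomass_asymptote_mg * (1.0 - red)


def _attack_defaults() -> dict[str, float]:
    # Efficacy rises through larval development, peaks at L4, and is rare
    # on L1 hosts and on pre-emergence adults.
    return {"L1": 0.001, "L2": 0.05, "L3": 0.35, "L4": 0.55, "P": 0.35, "A": 0.08}


@dataclass(frozen=True)
class ParasitismParams:
    """Per-stage (optionally per-quality) 24-h attack-success probabilities.

    ``attack_success`` maps stage -> probability, or quality -> {stage ->
    probability} when success depends on seed quality.  Adults are
    attackable only while still inside the seed when
    ``adult_hosts_attackable_only_pre_emergence`` is set.
    """

    attack_success: Mapping = field(default_factory=_attack_defaults)
    adult_hosts_attackable_only_pre_emergence: bool = True
    superparasitism_rate: float = 0.01

    def __post_init__(self) -> None:
        for p in self._flat_probs():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"attack probability {p} outside [0, 1]")
        if not (0.0 <= self.superparasitism_rate <= 1.0):
            raise ConfigError("superparasitism_rate must be a probability")

    def _flat_probs(self):
        for key, val in self.attack_success.items():
            if isinstance(val, Mapping):
                yield from val.values()
            else:
                yield val

    def prob(self, stage: str, quality: int) -> float:
        table = self.attack_success
        if quality in table and isinstance(table[quality], Mapping):
            table = table[quality]
        try:
            return float(table[stage])
        except KeyError as exc:
            raise ConfigError(f"no attack_success for stage {stage}") from exc

    def prob_matrix(self, qualities: Sequence[int]) -> np.ndarray:
        """(n_quality, n_stage) probability matrix."""
        return np.array([[self.prob(s, q) for s in STAGES] for q in qualities])

    def with_log_hazard_ratio(
        self, stage: str, quality: int, log_hr: float, reference: int = 100
    ) -> "ParasitismParams":
        """Return params whose daily parasitism risk in ``stage`` for
        ``quality`` sits at ``log_hr`` (log hazard ratio) relative to
        ``reference``.

        Grouped-time proportional hazards: with per-exposure success p,
        the underlying continuous hazard over the 24-h window is
        -log(1 - p), so the target probability is
        1 - (1 - p_ref)^(exp(log_hr)).
        """
        base = {s: self.prob(s, reference) for s in STAGES}
        p_ref = base[stage]
        p_new = 1.0 - (1.0 - p_ref) ** float(np.exp(log_hr))
        per_quality = {q: dict(base) for q in (90, 95, 100)}
        per_quality[quality] = dict(base, **{stage: p_new})
        return ParasitismParams(
            attack_success=per_quality,
            adult_hosts_attackable_only_pre_emergence=self.adult_hosts_attackable_only_pre_emergence,
            superparasitism_rate=self.superparasitism_rate,
        )


def _emergence_defaults() -> dict[str, float]:
    # Parasitized L1 hosts never yield an adult parasitoid.
    return {"L1": 0.0, "L2": 0.75, "L3": 0.85, "L4": 0.9, "P": 0.9, "A": 0.8}


def default_p_female(age: np.ndarray) -> np.ndarray:
    """Probability an emerging parasitoid is female, by host age at attack.

    Mothers allocate daughters to older/larger hosts; the logistic is
    centred near the observed even-sex-ratio window (~22 d).
    """
    age = np.asarray(age, float)
    return 1.0 / (1.0 + np.exp(-(age - 22.0) / 6.0))


@dataclass(frozen=True)
class ParasitoidTraitParams:
    """Life-history outcomes of the wasp emerging from a parasitized host.

    Sex is Bernoulli in ``p_female_curve`` (monotone in host age); female
    development takes ``devtime_female_excess`` days longer than the male
    mean; hind tibia length rises with host age and saturates at
    ``tibia_plateau_age`` (~25 d); emergence mass follows a per-sex
    log-log allometry on tibia length.
    """

    p_female_curve: Callable[[np.ndarray], np.ndarray] = default_p_female
    devtime_mean_male: float = 13.0
    devtime_female_excess: float = 1.0
    devtime_shape: float = 80.0
    tibia_base_mm: float = 0.45
    tibia_gain_mm: float = 0.35
    tibia_plateau_age: float = 25.0
    tibia_sex_offset_mm: float = 0.05  # added for females
    tibia_noise_sd: float = 0.04
    mass_allometry: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"female": (-0.20, 2.9), "male": (-0.35, 2.6)}
    )
    mass_noise_sd: float = 0.10
    emergence_success: Mapping[str, float] = field(default_factory=_emergence_defaults)

    def __post_init__(self) -> None:
        if self.devtime_mean_male <= 0 or self.devtime_mean_male + self.devtime_female_excess <= 0:
            raise ConfigError("development times must be positive")
        if self.devtime_shape <= 0:
            raise ConfigError("devtime_shape must be positive")
        for s, p in self.emergence_success.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"emergence_success[{s}] must be a probability")

    def tibia_mean(self, age: np.ndarray, female: np.ndarray) -> np.ndarray:
        age = np.asarray(age, float)
        ramp = np.minimum(age, self.tibia_plateau_age) / self.tibia_plateau_age
        return self.tibia_base_mm + self.tibia_gain_mm * ramp + self.tibia_sex_offset_mm * np.asarray(female, float)
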