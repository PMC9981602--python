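"""End-to-end analysis pipeline: generate -> impute -> hazards -> models.

A :class:`RunConfig` (usually loaded from a YAML profile) drives one
reproducible run: synthetic exposure and reference tables, stage
distribution estimation, a single-imputation per-stage hazard report,
the imputation-bootstrap / permutation-null inference, and the
regression model-selection suite.  Every output file is plain delimited
text; the manifest records the seed, a config hash, failure counts and
the produced files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .glm import filter_superparasitism
from .hazard import fit_stage_hazards, hazard_report
from .io import validate_exposure_table, write_exposure_csv, write_reference_csv
from .params import (
    DesignConfig,
    HostDevelopmentParams,
    ParasitismParams,
    ParasitoidTraitParams,
)
from .resampling import resampling_report, run_resampling
from .selection import analysis_frame, enumerate_and_select
from .simulate import generate_exposure_dataset, generate_reference_table
from .stages import estimate_stage_distribution, impute_stages


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    B: int = 200
    tie_method: str = "efron"
    reference_quality: int = 100
    nominal_level: float = 0.05
    null_scheme: str = "permutation"
    nearest_age_fallback: bool = True
    n_reference_per_cell: int = 40
    lambda_grid: tuple[float, ...] = tuple(np.logspace(-3.0, 7.0, 7))
    run_model_suite: bool = True


@dataclass
class RunConfig:
    design: DesignConfig = field(default_factory=DesignConfig)
    host_development: HostDevelopmentParams = field(default_factory=HostDevelopmentParams)
    parasitism: ParasitismParams = field(default_factory=ParasitismParams)
    traits: ParasitoidTraitParams = field(default_factory=ParasitoidTraitParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    out_dir: str = "results/run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(klass, section):
            kwargs = dict(raw.get(section) or {})
            if klass is HostDevelopmentParams and kwargs.pop("exchangeable", False):
                return HostDevelopmentParams.exchangeable(**_coerce(klass, kwargs))
            return klass(**_coerce(klass, kwargs))

        def _coerce(klass, kwargs):
            fields = {f.name for f in dataclasses.fields(klass)}
            unknown = set(kwargs) - fields
            if unknown:
                raise ValueError(f"unknown keys for {klass.__name__}: {sorted(unknown)}")
            for key in ("qualities", "lambda_grid"):
                if key in kwargs and isinstance(kwargs[key], list):
                    kwargs[key] = tuple(kwargs[key])
            return kwargs

        seed = int(raw.get("seed", 0))
        design_kwargs = dict(raw.get("design") or {})
        design_kwargs.setdefault("seed", seed)
        if isinstance(design_kwargs.get("qualities"), list):
            design_kwargs["qualities"] = tuple(design_kwargs["qualities"])
        return cls(
            design=DesignConfig(**design_kwargs),
            host_development=build(HostDevelopmentParams, "host_development"),
            parasitism=build(ParasitismParams, "parasitism"),
            traits=build(ParasitoidTraitParams, "traits"),
            analysis=AnalysisConfig(**_coerce(AnalysisConfig, dict(raw.get("analysis") or {}))),
            out_dir=str((raw.get("io") or {}).get("out_dir", "results/run")),
            seed=seed,
        )

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return {f.name: getattr(o, f.name) for f in dataclasses.fields(o)}
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if callable(o):
                return getattr(o, "__name__", repr(o))
            return repr(o)

        blob = json.dumps(self, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


#: Candidate model sets of the standard regression suite, by analysis name:
#: (response description, family, data subset, candidate formulas).
def _suite_definition() -> list[dict]:
    return [
        dict(
            name="efficacy_stage",
            family="quasibinomial",
            subset="exposed",
            candidates=[
                "parasitized ~ 1",
                "parasitized ~ Q",
                "parasitized ~ S",
                "parasitized ~ Q + S",
            ],
        ),
        dict(
            name="adult_production_stage",
            family="binomial",
            subset="parasitized",
            candidates=[
                "parasitoid_emerged ~ 1",
                "parasitoid_emerged ~ Q",
                "parasitoid_emerged ~ S",
                "parasitoid_emerged ~ Q + S",
            ],
        ),
        dict(
            name="efficacy_age",
            family="binomial",
            subset="exposed",
            candidates=[
                "parasitized ~ Q + s(A, by=Q)",
                "parasitized ~ Q + s(A)",
                "parasitized ~ s(A)",
                "parasitized ~ Q",
            ],
        ),
        dict(
            name="emergence_mass_stage",
            family="gaussian",
            subset="life_history",
            candidates=[
                "emergence_mass ~ T + G",
                "emergence_mass ~ T * G",
                "emergence_mass ~ T",
                "emergence_mass ~ G",
            ],
        ),
        dict(
            name="tibia_stage",
            family="gaussian",
            subset="life_history_no_l1",
            candidates=["T ~ G * S", "T ~ G + S", "T ~ Q + G + S", "T ~ G", "T ~ S"],
        ),
        dict(
            name="devtime_stage",
            family="gamma",
            subset="life_history_no_l1",
            candidates=[
                "development_time ~ Q + S + G",
                "development_time ~ G",
                "development_time ~ S + G",
                "development_time ~ Q + G",
            ],
        ),
        dict(
            name="sex_ratio_stage",
            family="binomial",
            subset="life_history_no_l1",
            candidates=["female ~ Q + S", "female ~ S", "female ~ Q", "female ~ 1"],
        ),
        dict(
            name="devtime_age",
            family="gamma",
            subset="life_history",
            candidates=[
                "development_time ~ G + s(A)",
                "development_time ~ Q + G + s(A, by=Q) + s(A, by=G)",
                "development_time ~ G",
            ],
        ),
        dict(
            name="sex_ratio_age",
            family="binomial",
            subset="life_history",
            candidates=["female ~ Q + s(A, by=Q)", "female ~ Q + s(A)", "female ~ s(A)"],
        ),
        dict(
            name="tibia_age",
            family="gaussian",
            subset="life_history",
            candidates=[
                "T ~ Q + G + s(A, by=Q) + s(A, by=G)",
                "T ~ Q + G + s(A)",
                "T ~ G + s(A)",
            ],
        ),
        dict(
            name="host_biomass_age",
            family="gamma",
            subset="reference",
            candidates=[
                "dry_biomass ~ Q + s(A, by=Q)",
                "dry_biomass ~ Q + s(A)",
                "dry_biomass ~ s(A)",
            ],
        ),
    ]


def run_model_suite(
    imputed: pd.DataFrame,
    reference: pd.DataFrame,
    lambda_grid,
    reference_quality: int = 100,
) -> dict:
    """Fit and rank the standard candidate sets; returns name -> SelectionTable."""
    exposed = analysis_frame(imputed, reference_quality=reference_quality)
    par = imputed[imputed["parasitized"].astype(bool)]
    par_frame = analysis_frame(par, reference_quality=reference_quality)
    life_all, _, _ = filter_superparasitism(par)
    life = life_all[life_all["parasitoid_emerged"].astype("boolean").fillna(False).astype(bool)]
    life_frame = analysis_frame(life, reference_quality=reference_quality)
    life_no_l1 = life[life["stage_at_parasitism"] != "L1"]
    life_no_l1_frame = analysis_frame(
        life_no_l1, reference_quality=reference_quality, stage_reference="L2", include_l1=False
    )
    ref_frame = reference.rename(columns={"age": "A"}).copy()
    quals = sorted(ref_frame["quality"].unique())
    ref_frame["Q"] = pd.Categorical(
        ref_frame["quality"],
        categories=[reference_quality] + [q for q in quals if q != reference_quality],
    )
    subsets = {
        "exposed": exposed,
        "parasitized": par_frame,
        "life_history": life_frame,
        "life_history_no_l1": life_no_l1_frame,
        "reference": ref_frame,
    }
    out = {}
    grid = np.asarray(lambda_grid, float)
    for spec in _suite_definition():
        data = subsets[spec["subset"]]
        needed = {f.split("~")[0].strip() for f in spec["candidates"]}
        data = data.dropna(subset=[c for c in needed if c in data.columns])
        try:
            out[spec["name"]] = enumerate_and_select(
                spec["candidates"], data, family=spec["family"], lambda_grid=grid
            )
        except Exception as exc:
            out[spec["name"]] = exc
    return out


def run_full_analysis(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the whole pipeline and write its report bundle.

    Returns a manifest dict (also written as ``manifest.json``) listing
    inputs, outputs, versions and replicate failure counts.  A stage
    failure raises :class:`PipelineError` after writing a partial
    manifest.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "outputs": [],
        "stages_completed": [],
    }

    def fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineError(stage, exc)

    def emit(name: str, df: pd.DataFrame):
        path = out / name
        df.to_csv(path, index=False, na_rep="NA")
        manifest["outputs"].append(name)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))

    try:
        exposures = generate_exposure_dataset(
            config.design, config.host_development, config.parasitism, config.traits
        )
        write_exposure_csv(exposures, out / "exposures.csv")
        manifest["outputs"].append("exposures.csv")
        manifest["n_exposures"] = int(len(exposures))
        reference = generate_reference_table(
            config.host_development,
            config.analysis.n_reference_per_cell,
            rng,
            qualities=config.design.qualities,
            ages=config.design.ages,
        )
        write_reference_csv(reference, out / "reference.csv")
        manifest["outputs"].append("reference.csv")
        manifest["stages_completed"].append("simulate")
    except Exception as exc:
        fail("simulate", exc)

    try:
        check = validate_exposure_table(exposures)
        if not check.ok:
            raise ValueError(f"generated table failed validation: {len(check.diagnostics)} issues")
        manifest["stages_completed"].append("validate")
    except Exception as exc:
        fail("validate", exc)

    try:
        table = estimate_stage_distribution(reference, provenance="reference.csv")
        table.to_csv(out / "stage_distribution.csv")
        manifest["outputs"].append("stage_distribution.csv")
        usable = exposures[
            ~exposures["host_died"].astype(bool) & ~exposures["host_emerged"].astype(bool)
        ].reset_index(drop=True)
        manifest["n_usable"] = int(len(usable))
        imputed = impute_stages(
            usable, table, rng, nearest_age_fallback=config.analysis.nearest_age_fallback
        )
        manifest["stages_completed"].append("impute")
    except Exception as exc:
        fail("impute", exc)

    try:
        fits = fit_stage_hazards(
            imputed,
            reference=config.analysis.reference_quality,
            tie_method=config.analysis.tie_method,
        )
        emit("hazards.csv", hazard_report(fits))
        results = run_resampling(
            usable,
            table,
            config.analysis.B,
            rng,
            reference=config.analysis.reference_quality,
            tie_method=config.analysis.tie_method,
            nearest_age_fallback=config.analysis.nearest_age_fallback,
            null_scheme=config.analysis.null_scheme,
        )
        report = resampling_report(results)
        emit("resampling.csv", report)
        manifest["resampling_failures"] = {
            f"{r.stage}:{r.contrast}": [r.n_boot_failed, r.n_null_failed] for r in results
        }
        manifest["stages_completed"].append("hazard")
    except Exception as exc:
        fail("hazard", exc)

    if config.analysis.run_model_suite:
        try:
            suite = run_model_suite(
                imputed,
                reference,
                config.analysis.lambda_grid,
                reference_quality=config.analysis.reference_quality,
            )
            rows = []
            for name, sel in suite.items():
                if isinstance(sel, Exception):
                    rows.append({"analysis": name, "model": pd.NA, "note": str(sel)})
                    continue
                for _, r in sel.table.iterrows():
                    rows.append(
                        {
                            "analysis": name,
                            "family": sel.family,
                            "model": r["model"],
                            "criterion": sel.criterion,
                            "value": r[sel.criterion],
                            "delta": r["delta"],
                            "edf": r["edf"],
                            "note": r.get("note", ""),
                        }
                    )
            emit("model_selection.csv", pd.DataFrame(rows))
            manifest["stages_completed"].append("select")
        except Exception as exc:
            fail("select", exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    manifest["outputs"].append("manifest.json")
    return manifest
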