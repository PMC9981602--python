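"""Imputation-bootstrap and permutation-null inference for stage hazards.

The stage of an unparasitized host is never observed, so the per-stage
log hazard ratios are re-estimated across many random completions of the
missing stages ("multiple-imputation bootstrap"): replicate ``b`` imputes
every unparasitized host's stage from its (quality, age) probability
cell and refits all stage models.  Observed (head-capsule) stages are
never resampled.

The treatment-agnostic null re-estimates the same coefficients after
(i) permuting seed-quality labels across all individuals (preserving
group sizes) and (ii) assigning *every* individual - parasitized ones
included - a stage drawn from the probability cell of its permuted label
and age.  The probability of the observed mean coefficient is then its
two-sided percentile position within the null distribution (Efron's
percentile method), with a Bonferroni adjustment across the stage x
contrast comparisons.

A pooled with-replacement label-resampling variant of the null is
available behind ``null_scheme="pooled"``; the permutation scheme is the
default reading of "resampling without regard to treatment".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hazard import DEFAULT_HAZARD_STAGES, StageHazardEngine, cox_fit
from .params import STAGES
from .stages import MissingCellError, StageDistributionTable


@dataclass
class ResamplingResult:
    """Bootstrap and null coefficient distributions for one stage x contrast."""

    stage: str
    contrast: str  # e.g. "90_vs_100"
    boot_lambdas: np.ndarray  # successful bootstrap replicates
    null_lambdas: np.ndarray  # successful null replicates
    lambda_obs: float  # mean of boot_lambdas
    p_value: float  # two-sided percentile p
    B: int  # replicates requested
    n_boot_failed: int
    n_null_failed: int
    wald_p: float = np.nan  # analytic cross-check from one imputation pass


def percentile_pvalue(lambda_obs: float, null_lambdas) -> float:
    """Two-sided percentile-method p-value of ``lambda_obs`` in the null.

    With r the (tie-half-counted) fraction of null values below the
    observation, p = max(2 * min(r, 1 - r), 1/B); never zero, at most 1.
    """
    null_lambdas = np.asarray(null_lambdas, float)
    if null_lambdas.size == 0:
        raise ValueError("empty null distribution")
    B = null_lambdas.size
    r = (np.sum(null_lambdas < lambda_obs) + 0.5 * np.sum(null_lambdas == lambda_obs)) / B
    return float(max(2.0 * min(r, 1.0 - r), 1.0 / B))


def bonferroni_adjust(p_values) -> np.ndarray:
    """Bonferroni multiplicity adjustment: p_adj = min(m * p, 1)."""
    p = np.asarray(p_values, float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(len(p) * p, 1.0)


def _null_labels(group_code: np.ndarray, rng: np.random.Generator, scheme: str) -> np.ndarray:
    """Treatment labels for one null replicate.

    ``permutation`` shuffles the observed labels (group sizes exactly
    preserved); ``pooled`` redraws them with replacement from the pooled
    empirical labels.
    """
    n = len(group_code)
    if scheme == "permutation":
        return group_code[rng.permutation(n)]
    return group_code[rng.integers(0, n, n)]


class _Prep:
    """Precomputed arrays shared by all resampling replicates."""

    def __init__(
        self,
        records: pd.DataFrame,
        table: StageDistributionTable,
        reference,
        stages,
        tie_method,
        nearest_age_fallback: bool,
        need_all_cells: bool,
    ):
        usable = records
        for col in ("host_died", "host_emerged"):
            if col in usable.columns:
                usable = usable[~usable[col].astype("boolean").fillna(False).astype(bool)]
        self.records = usable.reset_index(drop=True)
        n = len(self.records)
        self.event = self.records["parasitized"].astype(bool).to_numpy()
        self.age = self.records["age_at_exposure"].to_numpy(int)
        group = self.records["quality"].to_numpy()
        levels = sorted(pd.unique(group).tolist())
        if reference not in levels:
            raise ValueError(f"reference level {reference!r} not in data")
        self.level_order = [reference] + [lv for lv in levels if lv != reference]
        code_of = {lv: i for i, lv in enumerate(self.level_order)}
        self.group_code = np.array([code_of[g] for g in group])
        self.contrasts = [f"{lv}_vs_{reference}" for lv in self.level_order[1:]]

        self.engine = StageHazardEngine(
            self.age, self.event, self.group_code, len(self.level_order), stages, tie_method
        )
        # slot of each stage code (0..5) in the analysed-stage list, -1 if excluded
        self.slot_of_code = np.array(
            [self.engine.slot_of.get(s, -1) for s in STAGES], int
        )
        obs_stage = self.records["stage_at_parasitism"]
        stage_code_obs = np.array(
            [STAGES.index(s) if isinstance(s, str) and s in STAGES else -1 for s in obs_stage]
        )
        self.obs_slot = np.where(
            self.event, np.where(stage_code_obs >= 0, self.slot_of_code[stage_code_obs], -1), -1
        )
        self.unparasitized = ~self.event

        # cumulative stage probabilities per (level, age) grid
        uages = self.engine.unique_ages
        L = len(self.level_order)
        self.cumgrid = np.full((L, len(uages), len(STAGES)), np.nan)
        missing = np.zeros((L, len(uages)), bool)
        for li, lv in enumerate(self.level_order):
            for ai, a in enumerate(uages):
                try:
                    self.cumgrid[li, ai] = np.cumsum(
                        table.lookup(lv, int(a), nearest_age_fallback=nearest_age_fallback)
                    )
                except MissingCellError:
                    missing[li, ai] = True
        needed = np.zeros((L, len(uages)), bool)
        if need_all_cells:
            needed[:, np.unique(self.engine.age_code)] = True
        else:
            needed[self.group_code[self.unparasitized], self.engine.age_code[self.unparasitized]] = True
        bad = missing & needed
        if bad.any():
            li, ai = np.argwhere(bad)[0]
            raise MissingCellError(
                f"no stage distribution for quality={self.level_order[li]}, age={uages[ai]}"
            )

    def sample_stage_slots(self, level_idx: np.ndarray, row_mask: np.ndarray, rng) -> np.ndarray:
        """Draw stage slots for ``row_mask`` rows from their (level, age) cell."""
        cum = self.cumgrid[level_idx[row_mask], self.engine.age_code[row_mask]]
        u = rng.random(row_mask.sum())
        codes = (cum < u[:, None]).sum(axis=1)
        return self.slot_of_code[codes]


def bootstrap_hazard_distribution(
    records: pd.DataFrame,
    table: StageDistributionTable,
    B: int,
    rng: np.random.Generator,
    reference=100,
    stages=DEFAULT_HAZARD_STAGES,
    tie_method: str = "efron",
    nearest_age_fallback: bool = False,
    _prep: "_Prep | None" = None,
):
    """Imputation-bootstrap distributions of the stage hazard coefficients.

    Returns ``(lam, contrasts)`` where ``lam`` has shape
    (B, n_stages, n_contrasts) with NaN for replicates whose fit failed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    prep = _prep or _Prep(
        records, table, reference, stages, tie_method, nearest_age_fallback, need_all_cells=False
    )
    out = np.full((B, len(prep.engine.stages), len(prep.contrasts)), np.nan)
    for b, child in enumerate(rng.spawn(B)):
        slots = prep.obs_slot.copy()
        slots[prep.unparasitized] = prep.sample_stage_slots(
            prep.group_code, prep.unparasitized, child
        )
        lam, ok = prep.engine.fit_all(slots)
        out[b][ok] = lam[ok]
    return out, prep.contrasts


def build_null_distribution(
    records: pd.DataFrame,
    table: StageDistributionTable,
    B: int,
    rng: np.random.Generator,
    reference=100,
    stages=DEFAULT_HAZARD_STAGES,
    tie_method: str = "efron",
    nearest_age_fallback: bool = False,
    null_scheme: str = "permutation",
    _prep: "_Prep | None" = None,
):
    """Treatment-agnostic null distributions of the stage coefficients.

    Each replicate shuffles quality labels across individuals (or, with
    ``null_scheme="pooled"``, redraws them with replacement from the
    pooled labels), assigns every individual a stage from the cell of
    its new label and age, and refits all stage models.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if null_scheme not in ("permutation", "pooled"):
        raise ValueError(f"unknown null scheme {null_scheme!r}")
    prep = _prep or _Prep(
        records, table, reference, stages, tie_method, nearest_age_fallback, need_all_cells=True
    )
    n = len(prep.group_code)
    all_rows = np.ones(n, bool)
    out = np.full((B, len(prep.engine.stages), len(prep.contrasts)), np.nan)
    for b, child in enumerate(rng.spawn(B)):
        g = _null_labels(prep.group_code, child, null_scheme)
        slots = prep.sample_stage_slots(g, all_rows, child)
        lam, ok = prep.engine.fit_all(slots, group_code=g)
        out[b][ok] = lam[ok]
    return out, prep.contrasts


def run_resampling(
    records: pd.DataFrame,
    table: StageDistributionTable,
    B: int,
    rng: np.random.Generator,
    reference=100,
    stages=DEFAULT_HAZARD_STAGES,
    tie_method: str = "efron",
    nearest_age_fallback: bool = False,
    null_scheme: str = "permutation",
) -> list[ResamplingResult]:
    """Full inference pass: bootstrap, null, percentile p per stage x contrast."""
    prep_boot = _Prep(
        records, table, reference, stages, tie_method, nearest_age_fallback, need_all_cells=False
    )
    prep_null = _Prep(
        records, table, reference, stages, tie_method, nearest_age_fallback, need_all_cells=True
    )
    boot, contrasts = bootstrap_hazard_distribution(
        records, table, B, rng, reference, stages, tie_method, nearest_age_fallback, _prep=prep_boot
    )
    null, _ = build_null_distribution(
        records,
        table,
        B,
        rng,
        reference,
        stages,
        tie_method,
        nearest_age_fallback,
        null_scheme,
        _prep=prep_null,
    )
    # analytic cross-check from a single imputation pass
    single = rng.spawn(1)[0]
    slots = prep_boot.obs_slot.copy()
    slots[prep_boot.unparasitized] = prep_boot.sample_stage_slots(
        prep_boot.group_code, prep_boot.unparasitized, single
    )
    results: list[ResamplingResult] = []
    from scipy import stats

    for si, stage in enumerate(prep_boot.engine.stages):
        sub_mask = slots == si
        wald = {}
        if sub_mask.sum() and prep_boot.event[sub_mask].any():
            try:
                fit = cox_fit(
                    prep_boot.age[sub_mask],
                    prep_boot.event[sub_mask],
                    np.array(prep_boot.level_order)[prep_boot.group_code[sub_mask]],
                    tie_method=tie_method,
                    reference=reference,
                    stage=stage,
                )
                for lv in fit.levels:
                    z = fit.lambda_[lv] / fit.se[lv] if fit.se[lv] > 0 else np.nan
                    wald[f"{lv}_vs_{reference}"] = float(2 * stats.norm.sf(abs(z)))
            except Exception:
                pass
        for ci, contrast in enumerate(contrasts):
            bl = boot[:, si, ci]
            nl = null[:, si, ci]
            bl_ok = bl[np.isfinite(bl)]
            nl_ok = nl[np.isfinite(nl)]
            if bl_ok.size == 0 or nl_ok.size == 0:
                results.append(
                    ResamplingResult(
                        stage=stage,
                        contrast=contrast,
                        boot_lambdas=bl_ok,
                        null_lambdas=nl_ok,
                        lambda_obs=np.nan,
                        p_value=np.nan,
                        B=B,
                        n_boot_failed=int(B - bl_ok.size),
                        n_null_failed=int(B - nl_ok.size),
                    )
                )
                continue
            lam_obs = float(bl_ok.mean())
            results.append(
                ResamplingResult(
                    stage=stage,
                    contrast=contrast,
                    boot_lambdas=bl_ok,
                    null_lambdas=nl_ok,
                    lambda_obs=lam_obs,
                    p_value=percentile_pvalue(lam_obs, nl_ok),
                    B=B,
                    n_boot_failed=int(B - bl_ok.size),
                    n_null_failed=int(B - nl_ok.size),
                    wald_p=wald.get(contrast, np.nan),
                )
            )
    return results


def resampling_report(results: list[ResamplingResult]) -> pd.DataFrame:
    """Tabular report with Bonferroni adjustment across all comparisons."""
    rows = []
    estimable = [r for r in results if np.isfinite(r.p_value)]
    p_adj = {}
    if estimable:
        adj = bonferroni_adjust([r.p_value for r in estimable])
        p_adj = {(r.stage, r.contrast): a for r, a in zip(estimable, adj)}
    for r in results:
        rows.append(
            {
                "stage": r.stage,
                "contrast": r.contrast,
                "lambda_obs": r.lambda_obs,
                "p_value": r.p_value,
                "p_adj": p_adj.get((r.stage, r.contrast), np.nan),
                "wald_p": r.wald_p,
                "B": r.B,
                "n_boot_failed": r.n_boot_failed,
                "n_null_failed": r.n_null_failed,
                "note": "" if np.isfinite(r.p_value) else "unestimable",
            }
        )
    return pd.DataFrame(rows)


def dump_distributions(results: list[ResamplingResult], path) -> None:
    """Write the raw bootstrap and null coefficient draws as long-format
    CSV (stage, contrast, which, value) for density plots."""
    frames = []
    for r in results:
        for which, vals in (("bootstrap", r.boot_lambdas), ("null_resample", r.null_lambdas)):
            if len(vals):
                frames.append(
                    pd.DataFrame(
                        {"stage": r.stage, "contrast": r.contrast, "which": which, "value": vals}
                    )
                )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["stage", "contrast", "which", "value"]
    )
    out.to_csv(path, index=False)
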