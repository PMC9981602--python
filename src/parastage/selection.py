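"""AIC/qAIC candidate comparison and the standard analysis suite.

Candidates sharing a response and family class are fitted and ranked by
AIC, or by qAIC for quasi families, in which case every candidate is
scaled by the Pearson dispersion (c-hat) of the most complex candidate.
The top model is reported conservatively: near-ties (< 2 criterion
units) are flagged rather than averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gam import gam_fit
from .glm import ModelFit, ModelSpec, dispersion_estimate, glm_fit, information_criteria, parse_formula


@dataclass
class SelectionTable:
    """Ranked candidate models for one response."""

    response: str
    family: str
    criterion: str  # "aic" or "qaic"
    table: pd.DataFrame  # ranked: label, edf, loglik, dispersion, criterion, delta
    fits: dict  # label -> ModelFit (successful fits only)
    c_hat: float | None = None

    @property
    def top(self) -> ModelFit:
        return self.fits[self.table.iloc[0]["model"]]

    @property
    def near_ties(self) -> list[str]:
        t = self.table
        return list(t.loc[(t["delta"] < 2.0) & (t["delta"] > 0.0), "model"])


def fit_model(spec: ModelSpec, data: pd.DataFrame, **gam_kwargs) -> ModelFit:
    """Dispatch a candidate to the GLM or GAM fitter."""
    if spec.has_smooths:
        return gam_fit(spec, data, **gam_kwargs)
    return glm_fit(spec, data)


def enumerate_and_select(
    specs: list[ModelSpec] | list[str],
    data: pd.DataFrame,
    family: str | None = None,
    **gam_kwargs,
) -> SelectionTable:
    """Fit all candidates and rank them by AIC (qAIC for quasi families).

    String formulas are parsed with the supplied ``family``.  All
    candidates must share one response and one family.  Candidates whose
    fit fails are kept in the table with an explanatory note and no
    criterion value.  Ties keep insertion order (stable sort).
    """
    parsed: list[ModelSpec] = []
    for s in specs:
        parsed.append(parse_formula(s, family) if isinstance(s, str) else s)
    if len(parsed) < 2:
        raise ValueError("need at least two candidate models")
    if len({s.response for s in parsed}) != 1:
        raise ValueError("candidates mix different responses")
    if len({s.family for s in parsed}) != 1:
        raise ValueError("candidates mix different families")
    fam = parsed[0].family
    quasi = fam.startswith("quasi")
    criterion = "qaic" if quasi else "aic"

    fits: dict[str, ModelFit] = {}
    errors: dict[str, str] = {}
    for spec in parsed:
        if spec.label in fits or spec.label in errors:
            continue  # duplicate spec: same fit, insertion order preserved
        try:
            fits[spec.label] = fit_model(spec, data, **gam_kwargs)
        except Exception as exc:  # recorded, not fatal to the set
            errors[spec.label] = f"{type(exc).__name__}: {exc}"

    c_hat = None
    if quasi and fits:
        most_complex = max(fits.values(), key=lambda f: f.edf)
        c_hat = dispersion_estimate(most_complex)

    rows = []
    for spec in parsed:
        label = spec.label
        if label in errors:
            rows.append(
                {
                    "model": label,
                    "edf": np.nan,
                    "loglik": np.nan,
                    "dispersion": np.nan,
                    criterion: np.nan,
                    "note": errors[label],
                }
            )
            continue
        fit = fits[label]
        ic = information_criteria(fit, c_hat=c_hat)
        rows.append(
            {
                "model": label,
                "edf": fit.edf,
                "loglik": fit.llf,
                "dispersion": fit.dispersion,
                criterion: ic[criterion] if quasi else ic["aic"],
                "note": "",
            }
        )
    table = pd.DataFrame(rows).drop_duplicates(subset="model", keep="first")
    table = table.sort_values(criterion, kind="stable", na_position="last").reset_index(drop=True)
    best = table[criterion].iloc[0]
    table["delta"] = table[criterion] - best
    return SelectionTable(
        response=parsed[0].response,
        family=fam,
        criterion=criterion,
        table=table,
        fits=fits,
        c_hat=c_hat,
    )


def additive_expansion(response: str, terms: list[str]) -> list[str]:
    """All additive sub-models of main effects: 2^len(terms) formulas.

    ``additive_expansion("y", ["Q", "S"])`` gives
    ``["y ~ 1", "y ~ Q", "y ~ S", "y ~ Q + S"]``.
    """
    from itertools import combinations

    out = []
    for r in range(len(terms) + 1):
        for combo in combinations(terms, r):
            out.append(f"{response} ~ {' + '.join(combo) if combo else '1'}")
    return out


# ---------------------------------------------------------------------------
# Analysis frame: the field's standard shorthand for the model suite.
# Q = seed quality, S = host stage at attack, A = host age at attack,
# G = parasitoid sex, T = log hind tibia length.


def analysis_frame(
    records: pd.DataFrame,
    reference_quality: int = 100,
    stage_reference: str = "L1",
    include_l1: bool = True,
) -> pd.DataFrame:
    """Recode an exposure table into the notation of the model suite.

    Treatment-coded categoricals put the reference level first: quality
    100%, stage L1 (L2 when L1 is excluded), sex male.
    """
    from .params import STAGES

    df = records.copy()
    quals = sorted(df["quality"].dropna().unique())
    q_order = [reference_quality] + [q for q in quals if q != reference_quality]
    stages = [s for s in STAGES if include_l1 or s != "L1"]
    s_order = [stage_reference] + [s for s in stages if s != stage_reference]
    out = pd.DataFrame(index=df.index)
    out["Q"] = pd.Categorical(df["quality"], categories=q_order)
    out["S"] = pd.Categorical(df["stage_at_parasitism"].astype(object), categories=s_order)
    out["A"] = df["age_at_exposure"].astype(float)
    sex = df["sex"].astype(object) if "sex" in df else pd.Series(pd.NA, index=df.index, dtype=object)
    out["G"] = pd.Categorical(sex, categories=["male", "female"])
    tib = pd.to_numeric(df.get("hind_tibia_length"), errors="coerce")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["T"] = np.log(tib.to_numpy(float))
    out["parasitized"] = df["parasitized"].astype(bool).astype(float)
    emer = df.get("parasitoid_emerged")
    out["parasitoid_emerged"] = pd.to_numeric(emer, errors="coerce").astype(float) if emer is not None else np.nan
    out["female"] = (sex == "female").astype(float)
    out["development_time"] = pd.to_numeric(df.get("development_time"), errors="coerce").to_numpy(float)
    out["emergence_mass"] = pd.to_numeric(df.get("emergence_mass"), errors="coerce").to_numpy(float)
    return out
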