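"""GLM fitting, dispersion and information criteria for the model suite.

The regression suite compares candidate models of parasitoid efficacy and
life history with AIC, or quasi-AIC where a quasi-likelihood family
absorbs overdispersion.  Families used: binomial (logit), quasibinomial
(logit; binomial fit plus a Pearson dispersion), Gaussian (identity) and
Gamma (inverse link).  Fitting is IRLS via statsmodels; this module owns
the family handling, treatment coding, dispersion and AIC/qAIC logic.

Factor coding is treatment coding against fixed reference levels: seed
quality 100%, host stage L1 (L2 where L1 is excluded from an analysis),
parasitoid sex male.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats

FAMILIES = ("binomial", "quasibinomial", "gaussian", "gamma")


class AliasedTermError(ValueError):
    """The design matrix is rank deficient."""


class DispersionError(ValueError):
    """Pearson dispersion is undefined (no residual df) or degenerate."""


@dataclass(frozen=True)
class SmoothTerm:
    """A penalized B-spline smooth s(covariate, by=factor)."""

    covariate: str
    by: str | None = None
    k: int = 10
    penalty_order: int = 2

    def label(self) -> str:
        return f"s({self.covariate}, by={self.by})" if self.by else f"s({self.covariate})"


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response ~ parametric terms + smooth terms."""

    response: str
    parametric: tuple[str, ...]
    smooths: tuple[SmoothTerm, ...]
    family: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")

    @property
    def label(self) -> str:
        rhs = list(self.parametric) + [s.label() for s in self.smooths]
        return f"{self.response} ~ {' + '.join(rhs) if rhs else '1'}"

    @property
    def has_smooths(self) -> bool:
        return len(self.smooths) > 0


def parse_formula(formula: str, family: str) -> ModelSpec:
    """Parse a formula-like string, e.g. ``"parasitized ~ Q + s(A, by=Q)"``.

    Grammar: ``response ~ term + term + ...`` where a term is either a
    parametric expression (``Q``, ``Q:S``, ``Q*S``) or a smooth
    ``s(x)`` / ``s(x, by=F)`` / ``s(x, k=12)``.  ``1`` denotes the
    intercept-only model.
    """
    if "~" not in formula:
        raise ValueError(f"formula {formula!r} has no '~'")
    lhs, rhs = (part.strip() for part in formula.split("~", 1))
    parametric: list[str] = []
    smooths: list[SmoothTerm] = []
    depth = 0
    term = ""
    pieces: list[str] = []
    for ch in rhs + "+":
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "+" and depth == 0:
            pieces.append(term.strip())
            term = ""
        else:
            term += ch
    for piece in pieces:
        if not piece or piece == "1":
            continue
        if piece.startswith("s(") and piece.endswith(")"):
            args = [a.strip() for a in piece[2:-1].split(",")]
            cov = args[0]
            kw = dict(a.split("=", 1) for a in args[1:])
            smooths.append(
                SmoothTerm(
                    covariate=cov,
                    by=kw.get("by", "").strip() or None,
                    k=int(kw.get("k", 10)),
                )
            )
        else:
            parametric.append(piece)
    return ModelSpec(response=lhs, parametric=tuple(parametric), smooths=tuple(smooths), family=family)


@dataclass
class ModelFit:
    """A fitted candidate: coefficients, covariance, likelihood, criteria."""

    spec: ModelSpec
    params: np.ndarray
    cov: np.ndarray
    coef_names: list[str]
    fitted: np.ndarray  # response scale
    linpred: np.ndarray
    llf: float  # binomial/gaussian/gamma log-likelihood (quasi uses the binomial one)
    deviance: float
    dispersion: float  # Pearson chi^2 / residual df
    edf: float  # parametric count + smooth edf
    nobs: int
    converged: bool
    design_info: object = None
    smooth_blocks: list = field(default_factory=list)  # filled by gam_fit
    smoothing_params: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return information_criteria(self)["aic"]


def _family_object(name: str):
    if name in ("binomial", "quasibinomial"):
        return sm.families.Binomial()
    if name == "gaussian":
        return sm.families.Gaussian()
    if name == "gamma":
        return sm.families.Gamma(link=sm.families.links.InversePower())
    raise ValueError(name)


def build_parametric_matrix(terms: Sequence[str], data: pd.DataFrame):
    """Treatment-coded design matrix (with intercept) for parametric terms."""
    rhs = " + ".join(terms) if terms else "1"
    mat = patsy.dmatrix(rhs, data, return_type="dataframe", NA_action="raise")
    X = np.asarray(mat)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns via QR pivoting
        _, R = np.linalg.qr(X)
        bad = [mat.columns[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8]
        raise AliasedTermError(f"aliased design columns: {bad}")
    return X, list(mat.columns), mat.design_info


def glm_fit(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Fit a parametric candidate by IRLS.

    quasibinomial is a binomial fit whose covariance is inflated by the
    Pearson dispersion and whose model comparison goes through qAIC
    rather than a likelihood-based AIC.
    """
    if spec.has_smooths:
        raise ValueError("spec has smooth terms; use gam_fit")
    y = np.asarray(data[spec.response], float)
    X, names, dinfo = build_parametric_matrix(spec.parametric, data)
    fam = _family_object(spec.family)
    with warnings.catch_warnings():
        # the Gamma/inverse pairing is canonical and deliberate
        warnings.simplefilter("ignore", sm.tools.sm_exceptions.DomainWarning)
        res = sm.GLM(y, X, family=fam).fit(maxiter=100, tol=1e-10)
    df_resid = res.df_resid
    dispersion = float(res.pearson_chi2 / df_resid) if df_resid > 0 else np.nan
    cov = np.asarray(res.cov_params())
    if spec.family == "quasibinomial":
        if not np.isfinite(dispersion):
            raise DispersionError("quasibinomial needs residual df for the dispersion")
        cov = cov * dispersion
    return ModelFit(
        spec=spec,
        params=np.asarray(res.params),
        cov=cov,
        coef_names=names,
        fitted=np.asarray(res.fittedvalues),
        linpred=np.asarray(X @ res.params),
        llf=float(res.llf),
        deviance=float(res.deviance),
        dispersion=dispersion,
        edf=float(X.shape[1]),
        nobs=len(y),
        converged=bool(res.converged),
        design_info=dinfo,
    )


def dispersion_estimate(fit: ModelFit) -> float:
    """Pearson overdispersion c-hat = chi^2_Pearson / residual df."""
    df_resid = fit.nobs - fit.edf
    if df_resid <= 0:
        raise DispersionError("no residual degrees of freedom")
    if not np.isfinite(fit.dispersion) or fit.dispersion <= 0:
        raise DispersionError("degenerate (zero) Pearson dispersion")
    return fit.dispersion


def information_criteria(fit: ModelFit, c_hat: float | None = None) -> dict:
    """AIC and, when a dispersion is supplied, qAIC.

    AIC = -2 l + 2 k with k = edf (smooth terms count their effective
    degrees of freedom).  qAIC = -2 l / c-hat + 2 k with one extra
    parameter for c-hat itself.  A quasi family has no likelihood-based
    AIC of its own, so only qAIC is reported for it.
    """
    out: dict = {}
    k = fit.edf
    quasi = fit.spec.family.startswith("quasi")
    out["aic"] = np.nan if quasi else -2.0 * fit.llf + 2.0 * k
    if c_hat is not None:
        if not np.isfinite(c_hat) or c_hat <= 0:
            raise DispersionError("qAIC requires a positive c-hat")
        out["qaic"] = -2.0 * fit.llf / c_hat + 2.0 * (k + 1)
    elif quasi:
        out["qaic"] = None  # caller must supply c-hat
    return out


def filter_superparasitism(records: pd.DataFrame):
    """Drop parasitoid life-history rows from superparasitized hosts.

    Hosts carrying more than one egg stay in the efficacy analyses; only
    their parasitoid trait rows are removed from life-history analyses.
    Returns ``(filtered, n_hosts_flagged, n_parasitoid_rows_removed)``.
    """
    eggs = pd.to_numeric(records.get("n_eggs"), errors="coerce")
    multi = eggs.fillna(0) > 1
    has_wasp = records["parasitized"].astype(bool) & records["parasitoid_emerged"].astype("boolean").fillna(False).astype(bool)
    removed = int((multi & has_wasp).sum())
    return records[~multi].copy(), int(multi.sum()), removed


def posthoc_contrasts(fit: ModelFit, contrast_matrix: np.ndarray, names: list[str] | None = None):
    """Wald z-tests of linear contrasts with Bonferroni adjustment.

    Each row of ``contrast_matrix`` is a linear combination of the model
    coefficients, tested against zero on the linear-predictor scale.
    """
    C = np.atleast_2d(np.asarray(contrast_matrix, float))
    if C.shape[1] != len(fit.params):
        raise ValueError(
            f"contrast matrix has {C.shape[1]} columns; model has {len(fit.params)} coefficients"
        )
    est = C @ fit.params
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", C, fit.cov, C), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(se == 0, 1.0, p)
    p_adj = np.minimum(p * len(est), 1.0)
    return pd.DataFrame(
        {
            "contrast": names if names is not None else [f"c{i}" for i in range(len(est))],
            "estimate": est,
            "se": se,
            "z": z,
            "p": p,
            "p_adj": p_adj,
        }
    )
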