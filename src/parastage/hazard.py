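"""Cox proportional-hazards estimation of daily parasitism risk.

Each host contributes a single row: it was exposed to a parasitoid once,
at a known age, so ``time`` is host age at exposure and ``event`` is
whether it was parasitized; unparasitized hosts are right-censored at
their exposure age.  Within each developmental stage the model is

    hazard(age | Q) = h0(age) * exp(lambda_Q),

with seed-quality treatment Q the sole covariate and the 100% treatment
as reference, so ``lambda`` is the log hazard ratio of daily parasitism
risk relative to hosts on full-quality seeds (lambda > 0: increased
risk).  Event times are integer ages, so ties are pervasive; the partial
likelihood uses the Efron tie correction by default (Breslow optional).

Because the covariate is a small factor and times are a small set of
integer ages, the partial likelihood depends on the data only through
per-(time, group) at-risk and event counts.  All fitting runs on those
counts, which keeps a 100,000-replicate resampling loop tractable and is
exactly equivalent to the per-subject definition (verified in tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Stages analysed by default; L1 is excluded because parasitism there is
#: essentially never successful, leaving no events to model.
DEFAULT_HAZARD_STAGES: tuple[str, ...] = ("L2", "L3", "L4", "P", "A")


class UndefinedLikelihoodError(ValueError):
    """No events: the partial likelihood is identically 1."""


class DegenerateDesignError(ValueError):
    """Fewer than two treatment groups present."""


@dataclass
class HazardFit:
    """Per-stage Cox fit: one log hazard ratio per non-reference level."""

    stage: str
    reference: object
    levels: list  # non-reference levels, in coefficient order
    lambda_: dict  # level -> log hazard ratio vs reference
    se: dict  # level -> standard error
    loglik: float
    tie_method: str
    converged: bool
    monotone: bool
    n: int
    n_events: int

    def coef_array(self) -> np.ndarray:
        return np.array([self.lambda_[lv] for lv in self.levels])


@dataclass
class SkippedStage:
    stage: str
    reason: str


def _tie_layout(d_total: np.ndarray, tie_method: str):
    """Flat (row, fraction, weight) layout of the tie-corrected sum.

    Efron expands each event time t into d_t terms with fractions
    j/d_t, j = 0..d_t-1; Breslow keeps one term per time with weight d_t
    and fraction 0.  The two coincide exactly when no times are tied.
    """
    if tie_method == "efron":
        rows = np.repeat(np.arange(len(d_total)), d_total)
        j = np.concatenate([np.arange(d) for d in d_total]) if len(d_total) else np.array([])
        frac = j / np.repeat(d_total, d_total)
        wt = np.ones(len(rows))
    elif tie_method == "breslow":
        rows = np.arange(len(d_total))
        frac = np.zeros(len(rows))
        wt = d_total.astype(float)
    else:
        raise ValueError(f"unknown tie method {tie_method!r}")
    return rows, frac, wt


def _loglik_counts(beta, n_risk, d, rows, frac, wt):
    """Partial log-likelihood from (time, group) count matrices."""
    w = np.exp(np.concatenate(([0.0], np.atleast_1d(beta))))
    A = n_risk @ w
    B = d @ w
    denom = A[rows] - frac * B[rows]
    return float(np.sum(d[:, 1:].sum(axis=0) * np.atleast_1d(beta)) - np.sum(wt * np.log(denom)))


def _grad_hess_counts(beta, n_risk, d, rows, frac, wt):
    _, grad, H = _ll_grad_hess(np.atleast_1d(beta), n_risk, d, rows, frac, wt, d[:, 1:].sum(axis=0))
    return grad, H


def _ll_grad_hess(beta, n_risk, d, rows, frac, wt, d_plus):
    """One fused pass: partial log-likelihood, gradient and Hessian."""
    w = np.exp(np.concatenate(([0.0], beta)))
    A = n_risk @ w
    B = d @ w
    denom = A[rows] - frac * B[rows]
    ll = float(d_plus @ beta - wt @ np.log(denom))
    nu = (n_risk[rows, 1:] - frac[:, None] * d[rows, 1:]) * w[1:]
    ratio = (wt / denom)[:, None] * nu
    rs = ratio.sum(axis=0)
    grad = d_plus - rs
    H = (ratio / denom[:, None]).T @ nu
    H[np.diag_indices_from(H)] -= rs
    return ll, grad, H


def _solve_small(H, g):
    """Newton step -H^{-1} g ... solved directly for the 1x1/2x2 cases."""
    if H.shape[0] == 1:
        return np.array([g[0] / H[0, 0]])
    if H.shape[0] == 2:
        det = H[0, 0] * H[1, 1] - H[0, 1] * H[1, 0]
        return np.array(
            [
                (H[1, 1] * g[0] - H[0, 1] * g[1]) / det,
                (H[0, 0] * g[1] - H[1, 0] * g[0]) / det,
            ]
        )
    return np.linalg.solve(H, g)


def _counts_from_samples(time, event, group_codes, n_groups):
    """Collapse per-subject rows to per-(event-time, group) counts."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    ut, t_code = np.unique(time, return_inverse=True)
    flat = t_code * n_groups + np.asarray(group_codes)
    tot = np.bincount(flat, minlength=len(ut) * n_groups).reshape(len(ut), n_groups)
    dmat = np.bincount(flat, weights=event.astype(float), minlength=len(ut) * n_groups).reshape(
        len(ut), n_groups
    )
    n_risk = tot[::-1].cumsum(axis=0)[::-1]  # at risk: time >= t
    keep = dmat.sum(axis=1) > 0
    return n_risk[keep], dmat[keep].astype(int)


def _prepare(time, event, group, reference=None):
    group = np.asarray(group)
    levels = sorted(pd.unique(group).tolist())
    if reference is None:
        reference = levels[-1]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not present")
    order = [reference] + [lv for lv in levels if lv != reference]
    code_of = {lv: i for i, lv in enumerate(order)}
    codes = np.array([code_of[g] for g in group])
    return codes, order


def cox_partial_loglik(time, event, group, beta, tie_method="efron", reference=None) -> float:
    """Tie-corrected Cox partial log-likelihood for a factor covariate.

    ``beta`` holds one log hazard ratio per non-reference level, in
    sorted level order.  With no tied event times, Efron and Breslow
    produce identical values.
    """
    event = np.asarray(event, bool)
    if not event.any():
        raise UndefinedLikelihoodError("no events: partial likelihood undefined")
    codes, order = _prepare(time, event, group, reference)
    beta = np.atleast_1d(np.asarray(beta, float))
    if len(beta) != len(order) - 1:
        raise ValueError(f"beta must have length {len(order) - 1}")
    n_risk, d = _counts_from_samples(time, event, codes, len(order))
    rows, frac, wt = _tie_layout(d.sum(axis=1), tie_method)
    return _loglik_counts(beta, n_risk, d, rows, frac, wt)


def _newton_counts(
    n_risk, d, tie_method, max_iter=25, tol=1e-8, monotone_bound=10.0, beta0=None, want_se=True
):
    """Newton-Raphson with step halving on count matrices.

    Returns (beta, se, loglik, converged, monotone).  Groups with all or
    no events yield a monotone likelihood; detected either up front
    (zero-event group) or when a coefficient escapes ``monotone_bound``.
    """
    n_groups = n_risk.shape[1]
    p = n_groups - 1
    rows, frac, wt = _tie_layout(d.sum(axis=1), tie_method)
    d_plus = d[:, 1:].sum(axis=0)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()
    monotone = bool((d.sum(axis=0) == 0).any())
    converged = False
    ll, grad, H = _ll_grad_hess(beta, n_risk, d, rows, frac, wt, d_plus)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        step = _solve_small(H, grad)
        if not np.all(np.isfinite(step)):
            break
        new = beta - step
        new_ll, new_grad, new_H = _ll_grad_hess(new, n_risk, d, rows, frac, wt, d_plus)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings <= 30:
            step = step / 2.0
            new = beta - step
            new_ll, new_grad, new_H = _ll_grad_hess(new, n_risk, d, rows, frac, wt, d_plus)
            halvings += 1
        beta, ll, grad, H = new, new_ll, new_grad, new_H
        if np.max(np.abs(beta)) > monotone_bound:
            monotone = True
            break
    if monotone:
        converged = False
    if want_se:
        try:
            cov = np.linalg.inv(-H)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    else:
        se = np.full(p, np.nan)
    return beta, se, ll, converged, monotone


def cox_fit(
    time,
    event,
    group,
    tie_method: str = "efron",
    max_iter: int = 25,
    tol: float = 1e-8,
    reference=None,
    stage: str = "",
) -> HazardFit:
    """Maximize the tie-corrected partial likelihood for ``Y ~ group``.

    Monotone-likelihood designs (a group with all or no events) are
    flagged non-converged with the runaway coefficient's sign preserved.
    """
    event = np.asarray(event, bool)
    codes, order = _prepare(time, event, group, reference)
    if len(order) < 2:
        raise DegenerateDesignError("need at least two treatment groups")
    if not event.any():
        raise UndefinedLikelihoodError("no events in sample")
    n_risk, d = _counts_from_samples(time, event, codes, len(order))
    beta, se, ll, converged, monotone = _newton_counts(
        n_risk, d, tie_method, max_iter=max_iter, tol=tol
    )
    others = order[1:]
    return HazardFit(
        stage=stage,
        reference=order[0],
        levels=others,
        lambda_=dict(zip(others, beta)),
        se=dict(zip(others, se)),
        loglik=ll,
        tie_method=tie_method,
        converged=converged,
        monotone=monotone,
        n=len(codes),
        n_events=int(event.sum()),
    )


def fit_stage_hazards(
    records: pd.DataFrame,
    reference=100,
    stages=DEFAULT_HAZARD_STAGES,
    tie_method: str = "efron",
    stage_col: str = "stage_at_parasitism",
) -> dict:
    """Fit ``Y ~ Q`` separately within each developmental stage.

    ``records`` must be fully staged (observed or imputed).  Stages whose
    subset cannot support a fit (no rows, no events, or a single
    treatment) are returned as :class:`SkippedStage` markers rather than
    raising.
    """
    out: dict = {}
    for stage in stages:
        sub = records[records[stage_col] == stage]
        if sub.empty:
            out[stage] = SkippedStage(stage, "no records in stage")
            continue
        if sub["quality"].nunique() < 2:
            out[stage] = SkippedStage(stage, "fewer than two treatment groups")
            continue
        if not sub["parasitized"].astype(bool).any():
            out[stage] = SkippedStage(stage, "no parasitism events")
            continue
        out[stage] = cox_fit(
            sub["age_at_exposure"].to_numpy(float),
            sub["parasitized"].astype(bool).to_numpy(),
            sub["quality"].to_numpy(),
            tie_method=tie_method,
            reference=reference,
            stage=stage,
        )
    return out


def hazard_report(fits: dict) -> pd.DataFrame:
    """Flatten per-stage fits into a delimited-text-ready report."""
    rows = []
    for stage, fit in fits.items():
        if isinstance(fit, SkippedStage):
            rows.append(
                {
                    "stage": stage,
                    "contrast": pd.NA,
                    "lambda": pd.NA,
                    "se": pd.NA,
                    "n": pd.NA,
                    "n_events": pd.NA,
                    "converged": pd.NA,
                    "note": fit.reason,
                }
            )
            continue
        for lv in fit.levels:
            rows.append(
                {
                    "stage": stage,
                    "contrast": f"{lv}_vs_{fit.reference}",
                    "lambda": fit.lambda_[lv],
                    "se": fit.se[lv],
                    "n": fit.n,
                    "n_events": fit.n_events,
                    "converged": fit.converged,
                    "note": "monotone" if fit.monotone else "",
                }
            )
    return pd.DataFrame(rows)


class StageHazardEngine:
    """Vectorized repeated stage-wise Cox fitting for resampling loops.

    Holds the fixed parts of an exposure data set (ages, events, group
    codes) and refits all stage models for any stage assignment (and
    optionally permuted group labels) using count matrices only.
    """

    def __init__(
        self,
        age: np.ndarray,
        event: np.ndarray,
        group_code: np.ndarray,
        n_groups: int,
        stages=DEFAULT_HAZARD_STAGES,
        tie_method: str = "efron",
        stage_codes_of=None,
    ):
        self.age = np.asarray(age)
        self.event = np.asarray(event, bool).astype(float)
        self.group_code = np.asarray(group_code)
        self.n_groups = int(n_groups)
        self.stages = tuple(stages)
        self.tie_method = tie_method
        self.unique_ages, self.age_code = np.unique(self.age, return_inverse=True)
        self.n_ages = len(self.unique_ages)
        # stage name -> analysis slot
        self.slot_of = {s: i for i, s in enumerate(self.stages)}
        # warm starts: the likelihood is concave, so the converged optimum
        # does not depend on the start point; reusing the previous
        # replicate's solution just cuts Newton iterations.
        self._warm = np.zeros((len(self.stages), self.n_groups - 1))
        # replicates with bit-identical count matrices (e.g. a degenerate
        # imputation table) must give bit-identical coefficients
        self._cache: dict[int, tuple] = {}

    def fit_all(self, stage_slot: np.ndarray, group_code: np.ndarray | None = None):
        """Fit every stage model for one stage assignment.

        ``stage_slot`` maps each row to an analysis slot (index into
        ``self.stages``) or -1 for rows outside the analysed stages.
        Returns ``(lam, ok)``: an (n_stages, n_groups - 1) coefficient
        matrix (NaN where the fit failed) and a per-stage success flag.
        """
        g = self.group_code if group_code is None else group_code
        S, T, G = len(self.stages), self.n_ages, self.n_groups
        mask = stage_slot >= 0
        flat = (stage_slot[mask] * T + self.age_code[mask]) * G + g[mask]
        tot = np.bincount(flat, minlength=S * T * G).reshape(S, T, G)
        ev = np.bincount(flat, weights=self.event[mask], minlength=S * T * G).reshape(S, T, G)
        lam = np.full((S, G - 1), np.nan)
        ok = np.zeros(S, bool)
        for s in range(S):
            d_all = ev[s]
            if d_all.sum() < 1:
                continue
            per_group_n = tot[s].sum(axis=0)
            per_group_d = d_all.sum(axis=0)
            if (per_group_n == 0).any() or (per_group_d == 0).any():
                continue  # absent group or monotone likelihood
            key = tot[s].tobytes() + d_all.tobytes()
            cached = self._cache.get(s)
            if cached is not None and cached[0] == key:
                lam[s], ok[s] = cached[1], cached[2]
                continue
            n_risk = tot[s][::-1].cumsum(axis=0)[::-1]
            keep = d_all.sum(axis=1) > 0
            beta, _, _, converged, monotone = _newton_counts(
                n_risk[keep],
                d_all[keep].astype(int),
                self.tie_method,
                beta0=self._warm[s],
                want_se=False,
            )
            if converged and not monotone:
                lam[s] = beta
                ok[s] = True
                self._warm[s] = beta
            self._cache[s] = (key, lam[s].copy(), bool(ok[s]))
        return lam, ok
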