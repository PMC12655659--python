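"""Covariate relationships, derived covariates and stepwise covariate
modelling (SCM).

Forward addition keeps the best candidate whose drop in the objective
function exceeds 3.84 (chi-square, 1 df, p < 0.05) and repeats until no
candidate qualifies; backward elimination then removes, one at a time,
any retained covariate whose removal raises the objective by no more
than 6.63 (p < 0.01).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import CovariateSet, EventTable

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateCandidate",
    "ScmStep",
    "ScmTrace",
    "covariate_function",
    "derive_covariates",
    "scm",
    "FORWARD_DOFV",
    "BACKWARD_DOFV",
]

FORWARD_DOFV = 3.84    # chi2(1), alpha = 0.05
BACKWARD_DOFV = 6.63   # chi2(1), alpha = 0.01

CONTINUOUS_FORMS = ("linear", "power", "exponential")
CATEGORICAL_FORMS = ("proportional", "additive")


@dataclass(frozen=True)
class CovariateCandidate:
    """One parameter-covariate relationship to test in SCM."""

    parameter: str          # 'cl', 'vc' or 'vp'
    covariate: str          # covariate name (see derive_covariates)
    form: str               # linear/power/exponential | proportional/additive
    centering: float = 0.0  # reference value (dataset median for continuous)

    def __post_init__(self):
        if self.parameter not in ("cl", "vc", "vp"):
            raise ValueError(f"unsupported parameter {self.parameter!r}")
        if self.form not in CONTINUOUS_FORMS + CATEGORICAL_FORMS:
            raise ValueError(f"unknown form {self.form!r}")

    @property
    def key(self) -> str:
        return f"effect:{self.parameter}:{self.covariate}:{self.form}"


def covariate_function(form: str, theta_cov: float, value: float,
                       centering: float = 0.0) -> float:
    """Evaluate one covariate relationship.

    Multiplier forms: linear ``1 + theta*(x - ref)``, power
    ``(x/ref)**theta``, exponential ``exp(theta*(x - ref))``,
    proportional ``1 + theta*z``.  The additive form returns the addend
    ``theta*z`` (applied after all multipliers).
    """
    x = value
    if form == "linear":
        return 1.0 + theta_cov * (x - centering)
    if form == "power":
        if x <= 0 or centering <= 0:
            raise ValueError("power form requires positive covariate and centering")
        return (x / centering) ** theta_cov
    if form == "exponential":
        return math.exp(theta_cov * (x - centering))
    if form == "proportional":
        return 1.0 + theta_cov * x
    if form == "additive":
        return theta_cov * x
    raise ValueError(f"unknown form {form!r}")


def derive_covariates(cov: CovariateSet) -> Dict[str, float]:
    """Flatten a CovariateSet into named values plus derived quantities.

    Adds Mosteller body-surface area and, when serum creatinine is not
    carried (this dataset reports creatinine clearance directly), passes
    the measured creatinine clearance through as ``clcr``.  Missing
    optional covariates are simply absent from the mapping.
    """
    if cov.weight <= 0 or cov.height <= 0:
        raise ValueError("weight and height must be positive")
    out = {
        "age": float(cov.age),
        "cml": float(cov.cml),
        "hv": float(1 - cov.cml),
        "sex": 1.0 if cov.sex == "male" else 0.0,
        "weight": float(cov.weight),
        "height": float(cov.height),
        "bsa": math.sqrt(cov.height * cov.weight / 3600.0),
    }
    for name, val in (("alt", cov.alt), ("ast", cov.ast),
                      ("clcr", cov.creatinine_clearance)):
        if val is not None:
            out[name] = float(val)
    return out


def cockcroft_gault(age: float, weight: float, serum_creatinine_mg_dl: float,
                    sex: str) -> float:
    """Cockcroft-Gault creatinine clearance, mL/min."""
    if weight <= 0 or serum_creatinine_mg_dl <= 0:
        raise ValueError("weight and serum creatinine must be positive")
    clcr = (140.0 - age) * weight / (72.0 * serum_creatinine_mg_dl)
    return clcr * (0.85 if sex == "female" else 1.0)


@dataclass
class ScmStep:
    phase: str            # 'forward' or 'backward'
    candidate: CovariateCandidate
    ofv_before: float
    ofv_after: float
    decision: str         # 'added', 'not added', 'kept', 'removed', 'skipped'

    @property
    def delta_ofv(self) -> float:
        return self.ofv_after - self.ofv_before


@dataclass
class ScmTrace:
    steps: List[ScmStep] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "phase": s.phase, "parameter": s.candidate.parameter,
            "covariate": s.candidate.covariate, "form": s.candidate.form,
            "ofv_before": s.ofv_before, "ofv_after": s.ofv_after,
            "delta_ofv": s.delta_ofv, "decision": s.decision,
        } for s in self.steps])


def _covariate_matrix(table: EventTable, names: Sequence[str]) -> pd.DataFrame:
    rows = []
    for sid in table.subject_ids:
        vals = derive_covariates(table.covariates(sid))
        rows.append({n: vals.get(n, np.nan) for n in names})
    return pd.DataFrame(rows)


def scm(table: EventTable, base_fit, candidates: Sequence[CovariateCandidate],
        fit_function: Callable, forward_dofv: float = FORWARD_DOFV,
        backward_dofv: float = BACKWARD_DOFV,
        collinearity_r: float = 0.9) -> tuple:
    """Greedy forward-addition / backward-elimination covariate search.

    ``base_fit`` is the FitResult of the covariate-free model.
    ``fit_function(effects)`` must refit the model with the given extra
    candidates (estimating their coefficients) and return a FitResult.
    Candidates whose covariate is strongly collinear (|r| > 0.9) with an
    already-included one are skipped; candidate fit failures are skipped
    with a log entry.  Returns (final_fit, included_candidates, trace).
    """
    trace = ScmTrace()
    included: List[CovariateCandidate] = []
    current_fit = base_fit
    remaining = list(candidates)
    covmat = _covariate_matrix(
        table, sorted({c.covariate for c in candidates}))
    fit_cache: Dict[tuple, object] = {(): base_fit}

    def fit_with(effs: Sequence[CovariateCandidate]):
        key = tuple(sorted(e.key for e in effs))
        if key not in fit_cache:
            fit_cache[key] = fit_function(list(effs))
        return fit_cache[key]

    def collinear(cand: CovariateCandidate) -> bool:
        for inc in included:
            if inc.covariate == cand.covariate:
                continue
            a = covmat[cand.covariate].to_numpy(float)
            b = covmat[inc.covariate].to_numpy(float)
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() > 2 and np.std(a[ok]) > 0 and np.std(b[ok]) > 0:
                r = np.corrcoef(a[ok], b[ok])[0, 1]
                if abs(r) > collinearity_r:
                    return True
        return False

    # ---- forward addition ------------------------------------------
    while remaining:
        results = []
        for cand in list(remaining):
            if any(inc.parameter == cand.parameter and inc.covariate == cand.covariate
                   for inc in included):
                remaining.remove(cand)
                continue
            if collinear(cand):
                logger.info("skipping collinear candidate %s", cand.key)
                trace.steps.append(ScmStep("forward", cand, current_fit.ofv,
                                           current_fit.ofv, "skipped"))
                remaining.remove(cand)
                continue
            try:
                f = fit_with(included + [cand])
            except Exception as exc:  # candidate fit failure: skip, keep going
                logger.warning("candidate %s failed: %s", cand.key, exc)
                trace.steps.append(ScmStep("forward", cand, current_fit.ofv,
                                           current_fit.ofv, "skipped"))
                remaining.remove(cand)
                continue
            trace.steps.append(ScmStep("forward", cand, current_fit.ofv, f.ofv,
                                       "tested"))
            results.append((current_fit.ofv - f.ofv, cand, f))
        if not results:
            break
        results.sort(key=lambda t: -t[0])
        best_drop, best_cand, best_fit = results[0]
        if best_drop > forward_dofv:
            included.append(best_cand)
            current_fit = best_fit
            remaining.remove(best_cand)
            for s in trace.steps:
                if s.candidate is best_cand and s.decision == "tested":
                    s.decision = "added"
        else:
            break

    # ---- backward elimination --------------------------------------
    changed = True
    while changed and included:
        changed = False
        for cand in list(included):
            others = [c for c in included if c is not cand]
            reduced = fit_with(others)
            rise = reduced.ofv - current_fit.ofv
            if rise > backward_dofv:
                trace.steps.append(ScmStep("backward", cand, current_fit.ofv,
                                           reduced.ofv, "kept"))
            else:
                trace.steps.append(ScmStep("backward", cand, current_fit.ofv,
                                           reduced.ofv, "removed"))
                included = others
                current_fit = reduced
                changed = True
                break
    return current_fit, included, trace
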