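"""FOCE-with-interaction estimation, empirical Bayes etas, OFV and CWRES.

The marginal likelihood of each subject's data is approximated by
linearizing the model about the subject's empirical Bayes (MAP) eta mode
with the residual variance evaluated at the individual prediction
(the "interaction"):

    eta_hat_i = argmin  sum_j [ (y_ij - f_ij)^2 / v_ij + ln v_ij ]
                        + eta' Omega^-1 eta,      v_ij = sigma^2 f_ij^2

    V_i  = F_i Omega F_i' + diag(sigma^2 f_i(eta_hat)^2),
    r_i  = y_i - f_i(eta_hat) + F_i eta_hat,
    OFV  = sum_i [ ln det V_i + r_i' V_i^-1 r_i ],

with F_i = df/deta at eta_hat (central differences).  The n*ln(2*pi)
constant is omitted (NONMEM convention).  CWRES are the Cholesky-
whitened residuals L^-1 r (V = L L'), approximately iid standard normal
under a correct model.

The FOCE machinery is generic: it only needs, per subject, the usable
observations and a prediction function f(eta).  The PK binding in
:class:`PkProblem` builds those predictors from an event table, using
direct integration for occasion-1 records and the periodic steady state
of the subject's repeating regimen for occasion-2 (Day 14) records.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from . import _ode
from .covariates import CovariateCandidate, covariate_function, derive_covariates
from .datamodel import EventTable
from .engine import periodic_steady_state_window
from .params import IndividualParams, ThetaSet, VarianceSpec
from .structural import conc_from_central, typical_params

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "PkProblem",
    "foce_subject",
    "foce_objective",
    "fit",
    "cwres",
]

F_FLOOR = 1e-10       # ng/mL floor inside the error variance
ETA_FD_STEP = 1e-3    # central-difference step for F = df/deta
PENALTY_OFV = 1e10

# parameters estimated on the log scale
_LOG_SCALE = {"cl_pop", "vc_pop", "q_pop", "vp_pop", "ka", "mtt", "n_transit",
              "omega_cl", "omega_mtt", "omega_n", "omega_iov", "sigma_prop"}


# ----------------------------------------------------------------------
# Generic FOCE-I core
# ----------------------------------------------------------------------

def _inner_objective(eta: np.ndarray, y: np.ndarray, predict: Callable,
                     om2_inv: np.ndarray, sigma: float) -> float:
    z2 = eta ** 2 * om2_inv
    if z2.size and np.max(z2) > 36.0:
        # soft barrier beyond 6 prior SDs: keeps line searches finite
        return 1e8 * (1.0 + float(np.sum(z2)))
    f = np.maximum(predict(eta), F_FLOOR)
    v = (sigma * f) ** 2
    return float(np.sum((y - f) ** 2 / v + np.log(v)) + np.sum(z2))


@dataclass
class SubjectFoce:
    ofv: float
    eta_hat: np.ndarray
    f_ind: np.ndarray        # individual predictions f(eta_hat)
    f_pop: np.ndarray        # population-corrected predictions f - F eta
    residual: np.ndarray     # y - f_pop
    cwres: np.ndarray
    converged: bool = True


def foce_subject(y: np.ndarray, predict: Callable, omega: np.ndarray,
                 sigma: float, eta0: Optional[np.ndarray] = None,
                 ) -> SubjectFoce:
    """FOCE-I contribution of one subject.

    ``omega`` holds the SDs of the subject's eta components (possibly
    empty).  ``predict(eta)`` returns model concentrations at the
    subject's usable observation times.
    """
    y = np.asarray(y, dtype=float)
    d = len(omega)
    if d == 0:
        f = np.maximum(predict(np.zeros(0)), F_FLOOR)
        v = (sigma * f) ** 2
        r = y - f
        ofv = float(np.sum(r ** 2 / v + np.log(v)))
        return SubjectFoce(ofv, np.zeros(0), f, f, r, r / np.sqrt(v))
    omega = np.asarray(omega, dtype=float)
    om2_inv = 1.0 / omega ** 2
    eta0 = np.zeros(d) if eta0 is None else np.asarray(eta0, dtype=float)
    converged = True
    if d == 1:
        lim = 5.0 * omega[0]
        res = optimize.minimize_scalar(
            lambda e: _inner_objective(np.array([e]), y, predict, om2_inv, sigma),
            bounds=(-lim, lim), method="bounded",
            options={"xatol": 1e-3})
        eta_hat = np.array([res.x])
        converged = bool(res.success)
    else:
        res = optimize.minimize(
            _inner_objective, eta0, args=(y, predict, om2_inv, sigma),
            method="BFGS", options={"gtol": 1e-4, "maxiter": 60})
        eta_hat = res.x
        if not res.success and not np.all(np.isfinite(eta_hat)):
            eta_hat = np.zeros(d)  # fall back to the prior mode
            converged = False
    f_hat = np.maximum(predict(eta_hat), F_FLOOR)
    # model gradient wrt eta (central differences)
    F = np.empty((len(y), d))
    for k in range(d):
        step = ETA_FD_STEP
        ep = eta_hat.copy(); ep[k] += step
        em = eta_hat.copy(); em[k] -= step
        F[:, k] = (predict(ep) - predict(em)) / (2.0 * step)
    v = (sigma * f_hat) ** 2
    V = F @ np.diag(omega ** 2) @ F.T + np.diag(v)
    r = y - f_hat + F @ eta_hat
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        # near-singular covariance: per-subject ridge regularization
        logger.warning("singular FOCE covariance; regularizing")
        V = V + np.eye(len(y)) * (1e-8 * np.trace(V) / len(y) + 1e-12)
        L = np.linalg.cholesky(V)
    w = solve_triangular(L, r, lower=True)
    ofv = float(2.0 * np.sum(np.log(np.diag(L))) + w @ w)
    f_pop = f_hat - F @ eta_hat
    return SubjectFoce(ofv, eta_hat, f_hat, f_pop, r, w, converged)


def foce_objective(subjects: Sequence[Tuple[np.ndarray, Callable, np.ndarray]],
                   sigma: float,
                   eta_cache: Optional[Dict[int, np.ndarray]] = None) -> float:
    """Total FOCE-I objective over (y, predict, omega) subject triples."""
    total = 0.0
    for i, (y, predict, omega) in enumerate(subjects):
        eta0 = None if eta_cache is None else eta_cache.get(i)
        sf = foce_subject(y, predict, omega, sigma, eta0)
        if eta_cache is not None:
            eta_cache[i] = sf.eta_hat
        total += sf.ofv
    return total


# ----------------------------------------------------------------------
# PK model binding
# ----------------------------------------------------------------------

@dataclass
class PkModelSpec:
    """A fittable model: fixed effects + variability + optional extra
    covariate effects (used by stepwise covariate modelling)."""

    theta: ThetaSet
    variance: VarianceSpec
    extra_effects: Tuple = ()          # (CovariateCandidate, coefficient) pairs

    def replace_value(self, name: str, value: float) -> "PkModelSpec":
        if name.startswith("effect:"):
            effs = []
            hit = False
            for cand, coef in self.extra_effects:
                if cand.key == name:
                    effs.append((cand, value)); hit = True
                else:
                    effs.append((cand, coef))
            if not hit:
                raise KeyError(name)
            return dataclasses.replace(self, extra_effects=tuple(effs))
        if hasattr(self.theta, name):
            return dataclasses.replace(self, theta=self.theta.replace(**{name: value}))
        if hasattr(self.variance, name):
            return dataclasses.replace(self, variance=self.variance.replace(**{name: value}))
        raise KeyError(name)

    def get_value(self, name: str) -> float:
        if name.startswith("effect:"):
            for cand, coef in self.extra_effects:
                if cand.key == name:
                    return coef
            raise KeyError(name)
        if hasattr(self.theta, name):
            return getattr(self.theta, name)
        if hasattr(self.variance, name):
            return getattr(self.variance, name)
        raise KeyError(name)

    def individual_typical(self, cov) -> IndividualParams:
        params = typical_params(self.theta, cov)
        if self.extra_effects:
            values = derive_covariates(cov)
            mult = {"cl": 1.0, "vc": 1.0, "vp": 1.0}
            add = {"cl": 0.0, "vc": 0.0, "vp": 0.0}
            for cand, coef in self.extra_effects:
                x = values.get(cand.covariate)
                if x is None:
                    raise ValueError(f"covariate {cand.covariate!r} unavailable")
                term = covariate_function(cand.form, coef, x, cand.centering)
                if cand.form == "additive":
                    add[cand.parameter] += term
                else:
                    mult[cand.parameter] *= term
            params = params.replace(cl=params.cl * mult["cl"] + add["cl"],
                                    vc=params.vc * mult["vc"] + add["vc"],
                                    vp=params.vp * mult["vp"] + add["vp"])
        return params


@dataclass
class _SubjectDesign:
    sid: object
    cov: object
    dose_t: np.ndarray
    dose_a: np.ndarray
    t1: np.ndarray          # occasion-1 observation times
    y1: np.ndarray
    t2_win: np.ndarray      # occasion-2 times mapped into the 24 h window
    y2: np.ndarray
    regimen: Optional[Tuple[float, float]]   # (dose, interval) when periodic
    occasions: Tuple[int, ...] = (1,)


def _detect_regimen(dose_t: np.ndarray, dose_a: np.ndarray):
    if len(dose_t) < 3:
        return None
    iv = np.diff(dose_t)
    if np.allclose(iv, iv[0], rtol=1e-6, atol=1e-6) and \
       np.allclose(dose_a, dose_a[0], rtol=1e-9) and 24.0 % iv[0] < 1e-9:
        return float(dose_a[0]), float(iv[0])
    return None


class PkProblem:
    """Prepared estimation problem: per-subject designs + predictors."""

    def __init__(self, table: EventTable, h: float = 0.1):
        self.h = h
        self.subjects: List[_SubjectDesign] = []
        for sid, sub in table.iter_subjects():
            obs = sub[(sub.EVID == 0) & (sub.MDV == 0)]
            if len(obs) == 0:
                continue
            doses = sub[sub.EVID == 1]
            dose_t = doses.TIME.to_numpy(float)
            dose_a = doses.AMT.to_numpy(float)
            occ1 = obs[obs.OCC != 2]
            occ2 = obs[obs.OCC == 2]
            reg = _detect_regimen(dose_t, dose_a)
            if len(occ2) and reg is None:
                raise ValueError(
                    f"subject {sid}: occasion-2 observations require a "
                    "periodic dosing pattern")
            occasions = tuple(sorted(set(
                int(o) for o in obs.OCC.dropna().unique())) or [1])
            self.subjects.append(_SubjectDesign(
                sid=sid, cov=table.covariates(sid),
                dose_t=dose_t, dose_a=dose_a,
                t1=occ1.TIME.to_numpy(float), y1=occ1.DV.to_numpy(float),
                t2_win=occ2.TIME.to_numpy(float) % 24.0,
                y2=occ2.DV.to_numpy(float),
                regimen=reg, occasions=occasions))

    # -- eta layout ---------------------------------------------------
    def eta_layout(self, variance: VarianceSpec, design: _SubjectDesign):
        """(names, omega SDs) of the subject's eta vector: IIV components
        with non-zero SD followed by one IOV eta per occasion."""
        names = list(variance.iiv_names())
        sds = [variance.omega_for(n) for n in names]
        if variance.omega_iov > 0:
            for occ in design.occasions:
                names.append(f"iov{occ}")
                sds.append(variance.omega_iov)
        return names, np.asarray(sds)

    def _individual(self, spec: PkModelSpec, design: _SubjectDesign,
                    names: Sequence[str], eta: np.ndarray, occasion: int
                    ) -> IndividualParams:
        p = spec.individual_typical(design.cov)
        e = dict(zip(names, eta))
        iov = e.get(f"iov{occasion}", 0.0)
        return p.replace(
            cl=p.cl * math.exp(e.get("cl", 0.0)),
            vc=p.vc * math.exp(e.get("vc", 0.0) + iov),
            q=p.q * math.exp(e.get("q", 0.0)),
            vp=p.vp * math.exp(e.get("vp", 0.0) + iov),
            ka=p.ka * math.exp(e.get("ka", 0.0)),
            mtt=p.mtt * math.exp(e.get("mtt", 0.0)),
            n_transit=p.n_transit * math.exp(e.get("n", 0.0)))

    def predictor(self, spec: PkModelSpec, design: _SubjectDesign,
                  names: Sequence[str]) -> Callable:
        """f(eta) -> concentrations at the subject's usable observations,
        occasion-1 block first, then occasion-2."""
        theta = spec.theta
        h = self.h

        def predict(eta: np.ndarray) -> np.ndarray:
            out = []
            if len(design.t1):
                ind = self._individual(spec, design, names, eta, occasion=1)
                p = _ode.pack_params(ind, theta)
                pos = design.t1 > 0
                conc = np.zeros(len(design.t1))
                if pos.any():
                    t_eval = design.t1[pos]
                    keep = design.dose_t < t_eval[-1]
                    central = _ode.integrate_forced(
                        0.0, t_eval, h, p, design.dose_t[keep], design.dose_a[keep])
                    conc[pos] = conc_from_central(central, ind.vc)
                out.append(np.maximum(conc, 0.0))
            if len(design.t2_win):
                ind = self._individual(spec, design, names, eta, occasion=2)
                order = np.argsort(design.t2_win, kind="stable")
                conc = np.empty(len(design.t2_win))
                conc[order] = periodic_steady_state_window(
                    ind, theta, design.regimen, design.t2_win[order], h=h)
                out.append(conc)
            return np.concatenate(out) if out else np.zeros(0)

        return predict

    def triples(self, spec: PkModelSpec):
        """(y, predict, omega) per subject, for the generic FOCE core."""
        out = []
        for design in self.subjects:
            names, sds = self.eta_layout(spec.variance, design)
            y = np.concatenate([design.y1, design.y2])
            out.append((y, self.predictor(spec, design, names), sds))
        return out

    def objective(self, spec: PkModelSpec,
                  eta_cache: Optional[Dict[int, np.ndarray]] = None) -> float:
        if abs(spec.theta.theta_circadian) >= 1:
            return PENALTY_OFV
        try:
            return foce_objective(self.triples(spec), spec.variance.sigma_prop,
                                  eta_cache)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return PENALTY_OFV

    def subject_fits(self, spec: PkModelSpec) -> List[SubjectFoce]:
        return [foce_subject(y, pred, om, spec.variance.sigma_prop)
                for y, pred, om in self.triples(spec)]


# ----------------------------------------------------------------------
# Fitting
# ----------------------------------------------------------------------

@dataclass
class FitResult:
    spec: PkModelSpec
    ofv: float
    free: Tuple[str, ...]
    rse_percent: Dict[str, float] = field(default_factory=dict)
    eta_hat: Dict[object, np.ndarray] = field(default_factory=dict)
    converged: bool = True
    n_fev: int = 0
    message: str = ""

    @property
    def theta_hat(self) -> ThetaSet:
        return self.spec.theta

    @property
    def variance_hat(self) -> VarianceSpec:
        return self.spec.variance


def _pack(spec: PkModelSpec, free: Sequence[str]) -> np.ndarray:
    x = []
    for name in free:
        v = spec.get_value(name)
        x.append(math.log(v) if name in _LOG_SCALE else v)
    return np.asarray(x)


def _unpack(spec: PkModelSpec, free: Sequence[str], x: np.ndarray) -> PkModelSpec:
    for name, xi in zip(free, x):
        v = math.exp(min(xi, 50.0)) if name in _LOG_SCALE else float(xi)
        spec = spec.replace_value(name, v)
    return spec


def fit(table_or_problem, init: PkModelSpec,
        free: Sequence[str] = ("cl_pop", "omega_cl", "sigma_prop"),
        h: float = 0.1, maxfev: Optional[int] = None, compute_rse: bool = False,
        xatol: float = 1e-3, fatol: float = 0.05) -> FitResult:
    """Estimate the free parameters by minimizing the FOCE-I objective.

    Positive-definite parameters are optimized on the log scale;
    signed covariate coefficients on the natural scale.  With an empty
    ``free`` set the initial model's OFV is evaluated with no optimizer
    steps.  Standard errors (RSE%) come from the finite-difference
    inverse Hessian of the objective (cov = 2 H^-1).
    """
    problem = table_or_problem if isinstance(table_or_problem, PkProblem) \
        else PkProblem(table_or_problem, h=h)
    eta_cache: Dict[int, np.ndarray] = {}

    def objective(x: np.ndarray) -> float:
        try:
            spec = _unpack(init, free, x)
        except (ValueError, OverflowError):
            return PENALTY_OFV
        return problem.objective(spec, eta_cache)

    if len(free) == 0:
        if abs(init.theta.theta_circadian) >= 1:
            raise ValueError("invalid initial model")
        sfs = problem.subject_fits(init)
        result = FitResult(init, float(sum(sf.ofv for sf in sfs)), (),
                           converged=True, n_fev=1,
                           message="all parameters fixed")
        for i, sf in enumerate(sfs):
            result.eta_hat[problem.subjects[i].sid] = sf.eta_hat
        return result
    else:
        x0 = _pack(init, free)
        if maxfev is None:
            maxfev = 200 * len(free)
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxfev": maxfev,
                     "maxiter": maxfev})
        spec_hat = _unpack(init, free, res.x)
        result = FitResult(spec_hat, float(res.fun), tuple(free),
                           converged=bool(res.success), n_fev=int(res.nfev),
                           message=str(res.message))
    for i, sf in enumerate(problem.subject_fits(result.spec)):
        result.eta_hat[problem.subjects[i].sid] = sf.eta_hat
    if compute_rse and len(free):
        result.rse_percent = _rse(problem, result, free)
    return result


def _rse(problem: PkProblem, result: FitResult, free: Sequence[str],
         rel_step: float = 1e-3) -> Dict[str, float]:
    """RSE% from the finite-difference Hessian of the OFV on the natural
    scale of the free parameters (cov = 2 H^-1 since OFV = -2 log L)."""
    names = list(free)
    x0 = np.array([result.spec.get_value(n) for n in names])
    steps = np.maximum(np.abs(x0) * rel_step, 1e-8)

    def f(x):
        spec = result.spec
        for n, v in zip(names, x):
            spec = spec.replace_value(n, float(v))
        return problem.objective(spec)

    k = len(names)
    H = np.empty((k, k))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            xi = x0.copy()
            if i == j:
                xi[i] = x0[i] + steps[i]; fp = f(xi)
                xi[i] = x0[i] - steps[i]; fm = f(xi)
                H[i, i] = (fp - 2 * f0 + fm) / steps[i] ** 2
            else:
                vals = 0.0
                for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                    xi = x0.copy()
                    xi[i] += si * steps[i]; xi[j] += sj * steps[j]
                    vals += si * sj * f(xi)
                H[i, j] = H[j, i] = vals / (4 * steps[i] * steps[j])
    out = {}
    try:
        cov = 2.0 * np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        for n, s, v in zip(names, se, x0):
            out[n] = float(100.0 * s / abs(v)) if v != 0 else math.inf
    except np.linalg.LinAlgError:
        logger.warning("singular Hessian; RSEs unavailable")
    return out


def cwres(table_or_problem, fit_result, h: float = 0.1):
    """Per-observation predictions and conditional weighted residuals.

    Returns a tidy DataFrame with ID, TIME, OCC, DV, PRED (population-
    corrected), IPRED (at eta-hat) and CWRES, in the order (occasion 1
    then occasion 2) the estimation machinery uses.
    """
    import pandas as pd

    problem = table_or_problem if isinstance(table_or_problem, PkProblem) \
        else PkProblem(table_or_problem, h=h)
    spec = fit_result.spec if isinstance(fit_result, FitResult) else fit_result
    rows = []
    for design, sf in zip(problem.subjects, problem.subject_fits(spec)):
        times = np.concatenate([design.t1, design.t2_win + 312.0]) \
            if len(design.t2_win) else design.t1
        occs = [1] * len(design.t1) + [2] * len(design.t2_win)
        y = np.concatenate([design.y1, design.y2])
        for k in range(len(y)):
            rows.append({"ID": design.sid, "TIME": float(times[k]),
                         "OCC": occs[k], "DV": float(y[k]),
                         "PRED": float(sf.f_pop[k]), "IPRED": float(sf.f_ind[k]),
                         "CWRES": float(sf.cwres[k])})
    return pd.DataFrame(rows)
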