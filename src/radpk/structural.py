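"""Deterministic structural model.

Covariate-adjusted typical parameters, the circadian clearance factor,
the analytic transit-chain absorption input, the two-compartment ODE
right-hand side and secondary (derived) parameters.

Model sketch (amounts in mg)::

    depot:      dA_a/dt = sum_doses r_d(t) - ka * A_a
    central:    dA_c/dt = ka * A_a - [CL*g(t)/Vc + Q/Vc] * A_c + (Q/Vp) * A_p
    peripheral: dA_p/dt = (Q/Vc) * A_c - (Q/Vp) * A_p

with circadian factor g(t) = 1 + a * cos(2*pi*(t - t_peak)/24) applied to
elimination only, and the transit-chain input for a dose D given at t_d

    r_d(t) = F * D * ktr * (ktr*(t-t_d))^N * exp(-ktr*(t-t_d)) / Gamma(N+1),
    ktr = (N + 1) / MTT.

Concentration output is A_c / Vc * 1000 (mg/L -> ng/mL); the factor 1000
is applied exactly once, at concentration output.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln

from .params import IndividualParams, SecondaryParams, ThetaSet

__all__ = [
    "typical_params",
    "circadian_factor",
    "transit_ktr",
    "transit_input_rate",
    "ode_rhs",
    "secondary_params",
    "conc_from_central",
]

MG_PER_L_TO_NG_PER_ML = 1000.0


def typical_params(theta: ThetaSet, cov) -> IndividualParams:
    """Typical (eta = 0) individual parameters for given covariates.

    The circadian factor is *not* applied here; ``cl`` is the circadian-
    mean clearance.  Raises ``ValueError`` when the linear age model
    predicts a non-positive central volume (age outside its support).
    """
    cl = theta.cl_pop * (1.0 + theta.theta_disease * (1 - cov.cml))
    vc = theta.vc_pop * (1.0 + theta.theta_age * (cov.age - theta.age_ref))
    if vc <= 0:
        raise ValueError(
            f"age {cov.age} outside the support of the linear Vc-age model "
            f"(predicted Vc {vc:.3g} L <= 0)")
    return IndividualParams(cl=cl, vc=vc, q=theta.q_pop, vp=theta.vp_pop,
                            ka=theta.ka, mtt=theta.mtt, n_transit=theta.n_transit,
                            f=theta.bioavailability_f)


def circadian_factor(theta: ThetaSet, t):
    """Dimensionless multiplier on clearance at time ``t`` (hours since
    the subject's first dose).  Period-mean is exactly 1."""
    t = np.asarray(t, dtype=float)
    out = 1.0 + theta.theta_circadian * np.cos(
        2.0 * np.pi * (t - theta.circadian_acrophase) / theta.circadian_period)
    return out if out.ndim else float(out)


def transit_ktr(params: IndividualParams) -> float:
    """Transit rate constant; the chain counts the step feeding the
    absorption depot, so ktr = (N + 1) / MTT."""
    if params.mtt <= 0:
        raise ValueError("mtt must be positive")
    return (params.n_transit + 1.0) / params.mtt


def transit_input_rate(dose_mg: float, params: IndividualParams, t_since_dose):
    """Drug input rate (mg/h) into the depot, ``t_since_dose`` hours after
    a ``dose_mg`` dose.  Integrates to F*dose over (0, inf)."""
    t = np.asarray(t_since_dose, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_dose must be >= 0")
    ktr = transit_ktr(params)
    n = params.n_transit
    x = ktr * t
    with np.errstate(divide="ignore", invalid="ignore"):
        logx = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), -np.inf)
        logr = math.log(ktr) + n * logx - x - gammaln(n + 1.0)
    rate = params.f * dose_mg * np.exp(logr)
    if n == 0:
        rate = np.where(t >= 0, params.f * dose_mg * ktr * np.exp(-x), 0.0)
    else:
        rate = np.where(x > 0, rate, 0.0)
    return rate if rate.ndim else float(rate)


def ode_rhs(state, t, params: IndividualParams, theta: ThetaSet, dose_history,
            clock_offset: float = 0.0):
    """Right-hand side of the disposition system (reference NumPy path).

    ``state`` is (A_depot, A_central, A_peripheral) in mg; ``dose_history``
    is an iterable of (time, amount) pairs; only doses with time <= t
    contribute.  ``clock_offset`` shifts the circadian clock relative to
    the dosing clock (t=0 at first dose by convention).
    """
    a_a, a_c, a_p = state
    rate = 0.0
    for t_d, amt in dose_history:
        if t > t_d:
            rate += transit_input_rate(amt, params, t - t_d)
    g = 1.0 + theta.theta_circadian * math.cos(
        2.0 * math.pi * (t + clock_offset - theta.circadian_acrophase)
        / theta.circadian_period)
    ke = params.cl * g / params.vc
    k12 = params.q / params.vc
    k21 = params.q / params.vp
    return np.array([
        rate - params.ka * a_a,
        params.ka * a_a - (ke + k12) * a_c + k21 * a_p,
        k12 * a_c - k21 * a_p,
    ])


def conc_from_central(a_central, vc: float):
    """Central amount (mg) -> plasma concentration (ng/mL)."""
    return np.asarray(a_central, dtype=float) / vc * MG_PER_L_TO_NG_PER_ML


def secondary_params(params: IndividualParams) -> SecondaryParams:
    """Micro constants, hybrid rate constants, half-lives and total volume.

    Computed from the circadian-mean clearance, which is what the
    terminal-half-life estimates (28.8 h patients / 18.2 h healthy
    volunteers) refer to.  Handles the one-compartment limit q = 0.
    """
    k10 = params.cl / params.vc
    k12 = params.q / params.vc
    k21 = params.q / params.vp
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    if params.q == 0:
        alpha, beta = k10, k10
    return SecondaryParams(
        k10=k10, k12=k12, k21=k21, alpha=alpha, beta=beta,
        t_half_alpha=math.log(2.0) / alpha,
        t_half_beta=math.log(2.0) / beta,
        v_total=params.vc + params.vp,
    )
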