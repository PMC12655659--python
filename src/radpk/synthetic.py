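"""Synthetic study generation.

Emulates the two-cohort design that produced the modelling dataset:

* 23 healthy volunteers (HV), single oral 400 mg dose, samples pre-dose
  and at 0.5, 1, 2, 3, 4, 5, 6, 8, 10, 12, 18, 24, 32, 48 h;
* 24 CML-CP patients, 300 mg every 12 h, samples pre-dose and 1, 2, 3,
  4, 6, 8, 12 h post-dose on Day 1 (first dose) and Day 14 (steady
  state).

Covariates are drawn to match the published demographics (HVs all male,
ages 20-51; patients 54% male, age median 32, range 21-72).  True
concentrations come from the structural model; Day-14 profiles are
evaluated at the exact periodic steady state of the 12 h regimen (the
transient remaining after 312 h is < 0.1%).  Proportional residual error
and the 5 ng/mL LLOQ flagging are then applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .datamodel import CovariateSet, EventTable, LloqPolicy, _sex_code
from .engine import periodic_steady_state_window, simulate_profile
from .params import ThetaSet, VarianceSpec
from .population import apply_residual_error, draw_etas, realize_individual
from .structural import typical_params

__all__ = [
    "StudyDesign",
    "CovariateSampler",
    "generate_study",
    "virtual_population",
    "dropout_and_missingness",
]

HV_SAMPLING_H = (0.0, 0.5, 1, 2, 3, 4, 5, 6, 8, 10, 12, 18, 24, 32, 48)
PATIENT_SAMPLING_H = (0.0, 1, 2, 3, 4, 6, 8, 12)
PATIENT_DAY14_START_H = 312.0  # 13 full days of q12h dosing


@dataclass(frozen=True)
class StudyDesign:
    """Cohort sizes, dosing and nominal sampling schedules."""

    n_hv: int = 23
    hv_dose_mg: float = 400.0
    hv_sampling: tuple = HV_SAMPLING_H
    n_patients: int = 24
    patient_dose_mg: float = 300.0
    patient_interval_h: float = 12.0
    patient_sampling: tuple = PATIENT_SAMPLING_H
    day14_start_h: float = PATIENT_DAY14_START_H

    def __post_init__(self):
        if self.n_hv < 0 or self.n_patients < 0:
            raise ValueError("cohort sizes must be non-negative")
        if max(self.hv_sampling, default=0) > 48 + 1e-9:
            raise ValueError("HV sampling must lie within the 48 h follow-up")
        if max(self.patient_sampling, default=0) > self.patient_interval_h + 1e-9:
            raise ValueError("patient sampling must lie within one dosing interval")


class CovariateSampler:
    """Draws baseline covariates matching the published Table-1 ranges.

    Patient ages follow a log-normal (median 32, log-SD 0.28) truncated
    to [21, 72]; HV ages are uniform over 20-51.  Weights/heights/labs
    are truncated normals (log-normals for the skewed lab values) within
    the published ranges; they are carried as candidate covariates but
    drive nothing in the final model.
    """

    def _trunc(self, rng, draw, lo, hi):
        for _ in range(1000):
            x = draw(rng)
            if lo <= x <= hi:
                return float(x)
        return float(min(max(x, lo), hi))

    def hv(self, n: int, rng: np.random.Generator) -> List[CovariateSet]:
        out = []
        for _ in range(n):
            out.append(CovariateSet(
                age=float(rng.integers(20, 52)), cml=0, sex="male",
                weight=self._trunc(rng, lambda r: r.normal(71.0, 7.0), 55.1, 85.2),
                height=self._trunc(rng, lambda r: r.normal(173.0, 5.0), 166, 186),
                alt=self._trunc(rng, lambda r: math.exp(r.normal(math.log(16), 0.45)), 7, 80),
                ast=self._trunc(rng, lambda r: math.exp(r.normal(math.log(19), 0.35)), 11, 76),
                creatinine_clearance=self._trunc(rng, lambda r: r.normal(114, 14), 72, 139),
            ))
        return out

    def patient(self, n: int, rng: np.random.Generator) -> List[CovariateSet]:
        out = []
        for _ in range(n):
            out.append(CovariateSet(
                age=self._trunc(rng, lambda r: math.exp(r.normal(math.log(32.0), 0.28)), 21, 72),
                cml=1, sex="male" if rng.random() < 0.54 else "female",
                weight=self._trunc(rng, lambda r: r.normal(66.0, 10.0), 47, 96),
                height=self._trunc(rng, lambda r: r.normal(167.0, 6.0), 155, 178),
                alt=self._trunc(rng, lambda r: math.exp(r.normal(math.log(21), 0.35)), 15, 75),
                ast=self._trunc(rng, lambda r: math.exp(r.normal(math.log(25), 0.25)), 15, 41),
                creatinine_clearance=self._trunc(rng, lambda r: math.exp(r.normal(math.log(109), 0.2)), 74, 200),
            ))
        return out


def _cov_row(cov: CovariateSet) -> dict:
    return {"AGE": cov.age, "CML": cov.cml, "SEX": _sex_code(cov.sex),
            "WT": cov.weight, "HT": cov.height, "ALT": cov.alt, "AST": cov.ast,
            "CLCR": cov.creatinine_clearance}


def generate_study(theta: ThetaSet, variance: VarianceSpec,
                   design: Optional[StudyDesign] = None,
                   seed: Optional[int] = None,
                   lloq_policy: Optional[LloqPolicy] = LloqPolicy(),
                   sampler: Optional[CovariateSampler] = None,
                   h: float = 0.05) -> EventTable:
    """Simulate one complete synthetic study as an event table.

    HVs are a single-occasion cohort (occasion 1); patients contribute
    occasions 1 (Day 1) and 2 (Day 14) with independent IOV draws.
    Pre-dose Day-1 observations are true zeros (flagged BLQ).
    """
    design = design or StudyDesign()
    sampler = sampler or CovariateSampler()
    rng = np.random.default_rng(seed)
    hv_covs = sampler.hv(design.n_hv, rng)
    pat_covs = sampler.patient(design.n_patients, rng)
    etas = draw_etas(variance, design.n_hv + design.n_patients, n_occasions=2,
                     rng=rng)
    rows = []
    sid = 0
    for cov, eta in zip(hv_covs, etas[:design.n_hv]):
        sid += 1
        crow = _cov_row(cov)
        ind = realize_individual(typical_params(theta, cov), eta, occasion=1)
        times = np.asarray(design.hv_sampling, dtype=float)
        pos = times[times > 0]
        prof = simulate_profile(ind, theta, [(0.0, design.hv_dose_mg)], pos, h=h)
        conc = np.concatenate(([0.0], prof.conc)) if times[0] == 0 else prof.conc
        obs, _ = apply_residual_error(conc, variance, rng)
        rows.append({"ID": sid, "TIME": 0.0, "AMT": design.hv_dose_mg, "EVID": 1,
                     "DV": np.nan, "MDV": 1, "OCC": 1, **crow})
        for t, y in zip(times, obs):
            rows.append({"ID": sid, "TIME": float(t), "AMT": 0.0, "EVID": 0,
                         "DV": float(y), "MDV": 0, "OCC": 1, **crow})
    n_day1_doses = int(round(design.day14_start_h / design.patient_interval_h))
    for cov, eta in zip(pat_covs, etas[design.n_hv:]):
        sid += 1
        crow = _cov_row(cov)
        typ = typical_params(theta, cov)
        times = np.asarray(design.patient_sampling, dtype=float)
        # Day 1: first-dose kinetics, occasion-1 parameters
        ind1 = realize_individual(typ, eta, occasion=1)
        pos = times[times > 0]
        doses_d1 = [(k * design.patient_interval_h, design.patient_dose_mg)
                    for k in range(2)]
        prof1 = simulate_profile(ind1, theta, doses_d1, pos, h=h)
        conc1 = np.concatenate(([0.0], prof1.conc)) if times[0] == 0 else prof1.conc
        # Day 14: periodic steady state, occasion-2 parameters
        ind2 = realize_individual(typ, eta, occasion=2)
        wtimes = (design.day14_start_h + times) % 24.0
        order = np.argsort(wtimes, kind="stable")
        conc2 = np.empty_like(wtimes)
        conc2[order] = periodic_steady_state_window(
            ind2, theta, (design.patient_dose_mg, design.patient_interval_h),
            wtimes[order], h=h)
        obs1, _ = apply_residual_error(conc1, variance, rng)
        obs2, _ = apply_residual_error(conc2, variance, rng)
        for k in range(n_day1_doses + 1):
            rows.append({"ID": sid, "TIME": k * design.patient_interval_h,
                         "AMT": design.patient_dose_mg, "EVID": 1, "DV": np.nan,
                         "MDV": 1, "OCC": 1 if k == 0 else 2, **crow})
        for t, y in zip(times, obs1):
            rows.append({"ID": sid, "TIME": float(t), "AMT": 0.0, "EVID": 0,
                         "DV": float(y), "MDV": 0, "OCC": 1, **crow})
        for t, y in zip(times, obs2):
            rows.append({"ID": sid, "TIME": float(design.day14_start_h + t),
                         "AMT": 0.0, "EVID": 0, "DV": float(y), "MDV": 0,
                         "OCC": 2, **crow})
    df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"],
                                        kind="stable").reset_index(drop=True)
    table = EventTable(df)
    if lloq_policy is not None:
        table = table.apply_lloq(lloq_policy)
    return table


def virtual_population(n: int, covariate_sampler: Optional[CovariateSampler] = None,
                       cml_only: bool = True, seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None) -> List[CovariateSet]:
    """Covariate draws for Monte Carlo regimen simulation.

    With ``cml_only`` (the default, matching the published simulations)
    all subjects are CML-CP patients; otherwise the 23:24 cohort mix is
    preserved.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = covariate_sampler or CovariateSampler()
    if rng is None:
        rng = np.random.default_rng(seed)
    if cml_only:
        return sampler.patient(n, rng)
    n_hv = round(n * 23 / 47)
    return sampler.hv(n_hv, rng) + sampler.patient(n - n_hv, rng)


def dropout_and_missingness(table: EventTable, rate: float,
                            seed: Optional[int] = None) -> EventTable:
    """Randomly blank observations (MDV=1) at the given rate.

    Doses are never removed.  Identity at rate 0; reproducible by seed.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    obs = df.EVID == 0
    hit = obs & (rng.random(len(df)) < rate)
    df.loc[hit, "MDV"] = 1
    return EventTable(df, validate=False)
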