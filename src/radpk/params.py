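"""Parameter containers for the radotinib population PK model.

The model is a two-compartment disposition model with transit-compartment
oral absorption, first-order elimination modulated by a 24 h cosine
(circadian) rhythm, a linear disease-status effect on apparent clearance
and a linear age effect on the central volume.  All clearances and volumes
are apparent (bioavailability-confounded, "/F") quantities.

Units: clearances L/h, volumes L, times h, doses mg, concentrations ng/mL.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ThetaSet",
    "VarianceSpec",
    "IndividualParams",
    "SecondaryParams",
    "final_theta",
    "final_variance",
    "load_profile",
    "save_profile",
]


@dataclass
class ThetaSet:
    """Fixed-effect (typical-value) parameters of the final model.

    Defaults are the published population estimates.  ``theta_disease``
    scales clearance up for healthy subjects: CL = cl_pop * (1 +
    theta_disease * (1 - CML)).  ``theta_age`` is the signed linear slope
    of the central volume per year, centred at ``age_ref``.
    """

    cl_pop: float = 23.0            # L/h, typical CML-CP patient (circadian mean)
    theta_disease: float = 0.646    # fractional CL increase for healthy subjects
    theta_circadian: float = 0.683  # cosine amplitude on CL (|.| < 1)
    circadian_acrophase: float = 7.0   # h after first dose at which CL peaks
    circadian_period: float = 24.0     # h
    vc_pop: float = 383.0           # L at the reference age
    theta_age: float = -0.0129      # 1/year slope on Vc
    age_ref: float = 31.0           # years (study median)
    q_pop: float = 132.0            # L/h intercompartmental clearance
    vp_pop: float = 519.0           # L peripheral volume
    ka: float = 1.59                # 1/h depot -> central rate constant
    mtt: float = 1.88               # h mean transit time of the absorption chain
    n_transit: float = 6.58         # number of transit compartments (continuous)
    bioavailability_f: float = 1.0  # fixed; absolute F is not identifiable here

    def __post_init__(self) -> None:
        for name in ("cl_pop", "vc_pop", "q_pop", "vp_pop", "ka", "mtt",
                     "circadian_period", "bioavailability_f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.n_transit < 0:
            raise ValueError("n_transit must be >= 0")
        if abs(self.theta_circadian) >= 1:
            raise ValueError("|theta_circadian| must be < 1 so clearance stays positive")

    def replace(self, **kw) -> "ThetaSet":
        return dataclasses.replace(self, **kw)


@dataclass
class VarianceSpec:
    """Random-effect standard deviations and the residual error SD.

    All omegas are SDs of normal etas entering through ``exp(eta)``
    (log-normal parameter variability).  ``omega_iov`` is a per
    subject-per-occasion eta shared by Vc and Vp.  ``sigma_prop`` is the
    proportional residual SD (0.20 = 20% CV).  ``estimated`` names the
    components an estimation run treats as free by default; the remaining
    components were fixed in the final model (omega_mtt^2 ~ 0.1,
    omega_n^2 ~ 0.2).
    """

    omega_cl: float = 0.389
    omega_vc: float = 0.0
    omega_q: float = 0.0
    omega_vp: float = 0.0
    omega_ka: float = 0.0
    omega_mtt: float = 0.316
    omega_n: float = 0.447
    omega_iov: float = 0.698
    sigma_prop: float = 0.20
    estimated: tuple = ("omega_cl", "omega_iov", "sigma_prop")
    iov_shared: bool = True  # one IOV eta shared by vc and vp per occasion

    def __post_init__(self) -> None:
        for name in ("omega_cl", "omega_vc", "omega_q", "omega_vp", "omega_ka",
                     "omega_mtt", "omega_n", "omega_iov", "sigma_prop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kw) -> "VarianceSpec":
        return dataclasses.replace(self, **kw)

    def iiv_names(self) -> list:
        """IIV eta components with non-zero SD, in canonical order."""
        return [n for n, om in (("cl", self.omega_cl), ("vc", self.omega_vc),
                                ("q", self.omega_q), ("vp", self.omega_vp),
                                ("ka", self.omega_ka), ("mtt", self.omega_mtt),
                                ("n", self.omega_n)) if om > 0]

    def omega_for(self, name: str) -> float:
        return getattr(self, f"omega_{name}")


@dataclass
class IndividualParams:
    """Realised per-subject (per-occasion) PK parameters.

    ``cl`` is the pre-circadian clearance; the cosine factor is applied
    inside the ODE right-hand side, not here.
    """

    cl: float
    vc: float
    q: float
    vp: float
    ka: float
    mtt: float
    n_transit: float
    f: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cl", "vc", "vp", "ka", "mtt", "f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        # q = 0 is allowed: the one-compartment reduction used by closed-form checks
        if self.q < 0:
            raise ValueError("q must be >= 0")
        if self.n_transit < 0:
            raise ValueError("n_transit must be >= 0")

    def replace(self, **kw) -> "IndividualParams":
        return dataclasses.replace(self, **kw)


@dataclass
class SecondaryParams:
    """Derived two-compartment quantities (micro constants, hybrid rate
    constants, phase half-lives and total volume)."""

    k10: float
    k12: float
    k21: float
    alpha: float
    beta: float
    t_half_alpha: float
    t_half_beta: float
    v_total: float


def final_theta() -> ThetaSet:
    """The published final-model fixed effects."""
    return ThetaSet()


def final_variance() -> VarianceSpec:
    """The published final-model variability parameters."""
    return VarianceSpec()


_PROFILE_KEYS = ("theta", "variance")


def save_profile(path, theta: ThetaSet, variance: VarianceSpec) -> Path:
    """Serialize a parameter profile to YAML."""
    path = Path(path)
    data = {
        "theta": dataclasses.asdict(theta),
        "variance": {k: v for k, v in dataclasses.asdict(variance).items()},
    }
    data["variance"]["estimated"] = list(variance.estimated)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path


def load_profile(path) -> tuple:
    """Load a (ThetaSet, VarianceSpec) profile from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    for key in _PROFILE_KEYS:
        if key not in data:
            raise ValueError(f"profile {path} missing section {key!r}")
    var = dict(data["variance"])
    var["estimated"] = tuple(var.get("estimated", ()))
    return ThetaSet(**data["theta"]), VarianceSpec(**var)
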