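"""Hierarchical random-effects layer.

Interindividual variability (IIV) enters through log-normal multipliers
``exp(eta)`` on CL, MTT and N (SDs from the final model: 0.389, 0.316,
0.447); interoccasion variability (IOV, SD 0.698) is a single eta per
subject-occasion shared by the central and peripheral volumes.  Residual
variability is proportional: y = c * (1 + eps), eps ~ N(0, sigma^2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .params import IndividualParams, VarianceSpec

__all__ = [
    "EtaVector",
    "draw_etas",
    "realize_individual",
    "apply_residual_error",
    "eta_log_density",
]


@dataclass
class EtaVector:
    """Realised random effects for one subject.

    ``iiv`` maps parameter name ('cl', 'mtt', 'n', ...) to the subject's
    eta; ``iov`` maps occasion id to the occasion's volume eta.
    """

    iiv: Dict[str, float] = field(default_factory=dict)
    iov: Dict[int, float] = field(default_factory=dict)

    def get(self, name: str) -> float:
        return self.iiv.get(name, 0.0)

    def iov_for(self, occasion: int) -> float:
        return self.iov.get(occasion, 0.0)


def draw_etas(spec: VarianceSpec, n_subjects: int, n_occasions: int = 2,
              seed: Optional[int] = None, rng: Optional[np.random.Generator] = None,
              ) -> list:
    """Independent normal eta draws for ``n_subjects`` subjects.

    Occasion etas are independent across occasions within a subject.
    Reproducible given ``seed`` (or an explicit generator).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    names = spec.iiv_names()
    sds = np.array([spec.omega_for(n) for n in names])
    out = []
    for _ in range(n_subjects):
        iiv = {n: float(rng.normal(0.0, sd)) for n, sd in zip(names, sds)}
        iov = {occ: float(rng.normal(0.0, spec.omega_iov)) if spec.omega_iov > 0 else 0.0
               for occ in range(1, n_occasions + 1)}
        out.append(EtaVector(iiv=iiv, iov=iov))
    return out


def realize_individual(typical: IndividualParams, etas: EtaVector,
                       occasion: int = 1) -> IndividualParams:
    """Apply log-normal random effects to the typical parameters.

    CL, MTT and N carry IIV etas; Vc and Vp share the occasion's IOV eta;
    Q and ka have no variability in the final model (their etas default
    to zero but are honoured if present).
    """
    iov = math.exp(etas.iov_for(occasion))
    return typical.replace(
        cl=typical.cl * math.exp(etas.get("cl")),
        vc=typical.vc * math.exp(etas.get("vc")) * iov,
        q=typical.q * math.exp(etas.get("q")),
        vp=typical.vp * math.exp(etas.get("vp")) * iov,
        ka=typical.ka * math.exp(etas.get("ka")),
        mtt=typical.mtt * math.exp(etas.get("mtt")),
        n_transit=typical.n_transit * math.exp(etas.get("n")),
    )


def apply_residual_error(true_conc, spec: VarianceSpec, rng: np.random.Generator):
    """Proportional residual error; negative results truncated at zero.

    Returns (observed, truncated_flags).
    """
    c = np.asarray(true_conc, dtype=float)
    eps = rng.normal(0.0, spec.sigma_prop, size=c.shape)
    y = c * (1.0 + eps)
    truncated = y < 0
    if np.any(truncated):
        warnings.warn(f"{int(truncated.sum())} simulated concentration(s) "
                      "truncated at zero", RuntimeWarning)
        y = np.where(truncated, 0.0, y)
    return y, truncated


def eta_log_density(etas: EtaVector, spec: VarianceSpec) -> float:
    """Sum of normal log-densities of all eta components.

    A zero-SD component contributes 0 if its eta is 0 and -inf otherwise
    (degenerate prior).  This is the prior term of the FOCE inner problem.
    """
    total = 0.0
    comps = [(etas.get(n), spec.omega_for(n)) for n in
             ("cl", "vc", "q", "vp", "ka", "mtt", "n")]
    comps += [(e, spec.omega_iov) for e in etas.iov.values()]
    for e, om in comps:
        if om == 0.0:
            if e != 0.0:
                return -math.inf
            continue
        total += -0.5 * math.log(2.0 * math.pi) - math.log(om) - 0.5 * (e / om) ** 2
    return total
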