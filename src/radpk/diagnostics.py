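"""Model diagnostics: visual predictive checks, nonparametric bootstrap
and goodness-of-fit tabulation.

The VPC simulates the observed design (doses, sampling times and
covariates held fixed; etas, IOV and residual error redrawn) many times,
stratified by occasion, and compares observed percentile bands with the
simulation-based ones.  Bins are the nominal protocol sampling times, so
no binning heuristic is needed.  The bootstrap resamples subjects with
replacement within cohort strata (healthy volunteers / patients),
preserving the original cohort sizes, and refits each replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import EventTable
from .estimation import FitResult, PkModelSpec, PkProblem, cwres as _cwres, fit
from .params import ThetaSet, VarianceSpec
from .population import draw_etas

logger = logging.getLogger(__name__)

__all__ = ["VpcBands", "BootstrapResult", "vpc", "bootstrap", "gof_table"]


@dataclass
class VpcBands:
    """Stratified VPC summary.

    ``bands`` has one row per (occasion, time bin) with observed
    percentiles, the across-simulation median of each simulated
    percentile and its 95% confidence band, and the bin's 90% prediction
    interval.  ``inside_pi_fraction`` is the fraction of all usable
    observations inside their bin's 90% PI.
    """

    bands: pd.DataFrame
    inside_pi_fraction: float
    n_sim: int


def _simulate_replicate(problem: PkProblem, spec: PkModelSpec,
                        rng: np.random.Generator) -> List[np.ndarray]:
    """One simulated dataset at the observed design points."""
    out = []
    for design in problem.subjects:
        names, sds = problem.eta_layout(spec.variance, design)
        eta = rng.normal(0.0, 1.0, size=len(sds)) * sds
        predict = problem.predictor(spec, design, names)
        f = predict(eta)
        eps = rng.normal(0.0, spec.variance.sigma_prop, size=f.shape)
        out.append(np.maximum(f * (1.0 + eps), 0.0))
    return out


def vpc(table: EventTable, theta: ThetaSet, variance: VarianceSpec,
        n_sim: int = 1000, seed: Optional[int] = None,
        percentiles=(5.0, 50.0, 95.0), h: float = 0.1) -> VpcBands:
    """Visual predictive check stratified by occasion."""
    problem = PkProblem(table, h=h)
    spec = PkModelSpec(theta, variance)
    rng = np.random.default_rng(seed)

    # bin key per observation: (occasion, nominal time)
    keys, observed = [], []
    for design in problem.subjects:
        for t, y in zip(design.t1, design.y1):
            keys.append((1, float(t))); observed.append(y)
        for t, y in zip(design.t2_win, design.y2):
            keys.append((2, float(t))); observed.append(y)
    keys = pd.MultiIndex.from_tuples(keys, names=["occasion", "time"])
    obs = pd.Series(observed, index=keys)

    sims = np.empty((n_sim, len(obs)))
    for s in range(n_sim):
        sims[s] = np.concatenate(_simulate_replicate(problem, spec, rng))

    rows = []
    inside = 0
    groups = obs.groupby(level=[0, 1])
    for (occ, t), grp in groups:
        idx = obs.index.get_locs((occ, t))
        sim_block = sims[:, idx]                      # (n_sim, n_obs_in_bin)
        per_rep = np.percentile(sim_block, percentiles, axis=1)  # (3, n_sim)
        pi_lo, pi_hi = np.percentile(sim_block, [5.0, 95.0])
        inside += int(((grp.values >= pi_lo) & (grp.values <= pi_hi)).sum())
        row = {"occasion": occ, "time": t, "n_obs": len(grp),
               "pi90_lo": float(pi_lo), "pi90_hi": float(pi_hi)}
        for p, pr in zip(percentiles, per_rep):
            row[f"obs_p{p:g}"] = float(np.percentile(grp.values, p))
            row[f"sim_p{p:g}_median"] = float(np.median(pr))
            row[f"sim_p{p:g}_lo"] = float(np.percentile(pr, 2.5))
            row[f"sim_p{p:g}_hi"] = float(np.percentile(pr, 97.5))
        rows.append(row)
    bands = pd.DataFrame(rows).sort_values(["occasion", "time"]).reset_index(drop=True)
    return VpcBands(bands, inside / len(obs), n_sim)


@dataclass
class BootstrapResult:
    """Parameter medians and percentile 95% CIs over bootstrap refits."""

    estimates: pd.DataFrame        # one row per successful replicate
    summary: pd.DataFrame          # median, ci_lo, ci_hi per parameter
    n_requested: int
    n_failed: int
    replicate_ids: List[list]      # subject-id multiset per replicate
    warning: Optional[str] = None


def bootstrap(table: EventTable, init: PkModelSpec,
              free: Sequence[str] = (), n_boot: int = 1000,
              seed: Optional[int] = None, stratify: bool = True,
              h: float = 0.1, **fit_kw) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects within cohort strata,
    refit each replicate (warm-started from ``init``) and summarize.

    With ``stratify`` every replicate keeps the original number of
    healthy volunteers and patients.  Failed refits are excluded; more
    than 20% failures downgrades the result with a warning.
    """
    rng = np.random.default_rng(seed)
    df = table.df
    ids = table.subject_ids
    cml_of = {sid: int(df[df.ID == sid].CML.iloc[0]) for sid in ids}
    strata = ([ [s for s in ids if cml_of[s] == 0],
                [s for s in ids if cml_of[s] == 1] ] if stratify else [ids])
    strata = [s for s in strata if s]
    rows, rep_ids = [], []
    n_failed = 0
    for b in range(n_boot):
        chosen = []
        for stratum in strata:
            chosen += list(rng.choice(stratum, size=len(stratum), replace=True))
        rep_ids.append(sorted(chosen))
        parts = []
        for new_id, sid in enumerate(chosen, start=1):
            sub = df[df.ID == sid].copy()
            sub["ID"] = new_id
            parts.append(sub)
        rep_table = EventTable(pd.concat(parts, ignore_index=True), validate=False)
        try:
            res = fit(rep_table, init, free=free, h=h, **fit_kw)
            row = {name: res.spec.get_value(name) for name in free}
            row["ofv"] = res.ofv
            rows.append(row)
        except Exception as exc:
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            n_failed += 1
    estimates = pd.DataFrame(rows)
    summary_rows = {}
    for name in free:
        v = estimates[name].to_numpy(float)
        summary_rows[name] = {"median": float(np.median(v)),
                              "ci_lo": float(np.percentile(v, 2.5)),
                              "ci_hi": float(np.percentile(v, 97.5))}
    warning = None
    if n_boot and n_failed / n_boot > 0.2:
        warning = f"{n_failed}/{n_boot} bootstrap replicates failed"
        logger.warning(warning)
    return BootstrapResult(estimates, pd.DataFrame(summary_rows).T,
                           n_boot, n_failed, rep_ids, warning)


def gof_table(table: EventTable, fit_result, h: float = 0.1) -> pd.DataFrame:
    """Tidy goodness-of-fit table: DV, population and individual
    predictions, residuals and CWRES per usable observation."""
    out = _cwres(table, fit_result, h=h)
    out["RES"] = out.DV - out.PRED
    out["IRES"] = out.DV - out.IPRED
    return out
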