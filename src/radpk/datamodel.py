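"""NONMEM-style event-record data model and CSV I/O.

A dataset is a flat table of per-subject dose and observation records:

======  =====================================================
column  meaning
======  =====================================================
ID      subject identifier
TIME    hours since the subject's first dose
AMT     dose amount in mg (0 for observations)
EVID    1 = dose, 0 = observation
DV      observed concentration in ng/mL ('.' for doses)
MDV     1 = DV missing / not used for fitting
OCC     occasion (1 = Day 1 non-steady state, 2 = Day 14 steady state)
AGE     years
CML     1 = CML-CP patient, 0 = healthy volunteer
SEX     1 = male, 0 = female
WT      body weight, kg
HT      height, cm
ALT     alanine aminotransferase, IU/L
AST     aspartate aminotransferase, IU/L
CLCR    creatinine clearance, mL/min
======  =====================================================

Observations below the assay's lower limit of quantification (5 ng/mL)
are flagged at read time and handled per :class:`LloqPolicy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Optional

import numpy as np
import pandas as pd

__all__ = [
    "EventTableError",
    "LloqPolicy",
    "Regimen",
    "DoseEvent",
    "CovariateSet",
    "EventTable",
    "read_event_table",
    "write_event_table",
    "expand_regimen",
]

LLOQ_DEFAULT = 5.0  # ng/mL

REQUIRED_COLUMNS = ["ID", "TIME", "AMT", "EVID", "DV", "MDV", "OCC"]
COVARIATE_COLUMNS = ["AGE", "CML", "SEX", "WT", "HT", "ALT", "AST", "CLCR"]
ALL_COLUMNS = REQUIRED_COLUMNS + COVARIATE_COLUMNS


class EventTableError(ValueError):
    """Malformed event dataset."""


@dataclass(frozen=True)
class LloqPolicy:
    """How below-LLOQ observations are treated.

    ``discard`` (M1) sets MDV=1 so the record is excluded from fitting;
    ``fix_at_half`` replaces DV with LLOQ/2 and keeps the record.
    """

    lloq: float = LLOQ_DEFAULT
    method: str = "discard"

    def __post_init__(self) -> None:
        if self.lloq <= 0:
            raise ValueError("lloq must be positive")
        if self.method not in ("discard", "fix_at_half"):
            raise ValueError(f"unknown LLOQ method {self.method!r}")


@dataclass(frozen=True)
class Regimen:
    """A repeated-dose schedule: ``n_doses`` doses of ``dose_mg`` every
    ``interval_h`` hours starting at ``first_dose_time``."""

    dose_mg: float
    interval_h: float
    n_doses: int
    first_dose_time: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_mg <= 0:
            raise ValueError("dose_mg must be positive")
        if self.interval_h <= 0:
            raise ValueError("interval_h must be positive")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")

    @property
    def span_h(self) -> float:
        return self.first_dose_time + (self.n_doses - 1) * self.interval_h


class DoseEvent(NamedTuple):
    time: float
    amount: float


@dataclass(frozen=True)
class CovariateSet:
    """Baseline covariates of one subject."""

    age: float
    cml: int
    sex: str = "male"          # {male, female}
    weight: float = 70.0       # kg
    height: float = 170.0      # cm
    alt: Optional[float] = None    # IU/L
    ast: Optional[float] = None    # IU/L
    creatinine_clearance: Optional[float] = None  # mL/min

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.cml not in (0, 1):
            raise ValueError("cml must be 0 or 1")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.weight <= 0 or self.height <= 0:
            raise ValueError("weight and height must be positive")

    @property
    def hv(self) -> int:
        """Healthy-volunteer indicator (1 - cml); the form in which the
        disease effect enters the clearance model."""
        return 1 - self.cml


def expand_regimen(regimen: Regimen) -> list:
    """Expand a regimen into its list of dose events."""
    return [DoseEvent(regimen.first_dose_time + k * regimen.interval_h, regimen.dose_mg)
            for k in range(regimen.n_doses)]


def _sex_code(sex: str) -> int:
    return 1 if sex == "male" else 0


def _sex_name(code) -> str:
    return "male" if int(code) == 1 else "female"


class EventTable:
    """Validated ordered collection of dose/observation records.

    Wraps a :class:`pandas.DataFrame` with the columns documented in the
    module docstring plus an internal boolean ``BLQ`` column.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        for col in ALL_COLUMNS:
            if col not in df.columns:
                raise EventTableError(f"missing column {col!r}")
        if "BLQ" not in df.columns:
            df["BLQ"] = False
        df = df[ALL_COLUMNS + ["BLQ"]]
        self.df = df.reset_index(drop=True)
        if validate:
            self._validate()

    # -- construction -------------------------------------------------
    @classmethod
    def empty(cls) -> "EventTable":
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in ALL_COLUMNS})
        return cls(df)

    @classmethod
    def from_records(cls, records: list) -> "EventTable":
        return cls(pd.DataFrame.from_records(records, columns=ALL_COLUMNS + ["BLQ"]))

    def _validate(self) -> None:
        df = self.df
        if len(df) == 0:
            return
        for i, row in df.iterrows():
            if row.EVID not in (0, 1):
                raise EventTableError(f"row {i}: unknown EVID {row.EVID!r}")
            if row.TIME < 0:
                raise EventTableError(f"row {i}: negative TIME {row.TIME!r}")
            if row.EVID == 1:
                if not row.AMT > 0:
                    raise EventTableError(f"row {i}: dose record with AMT {row.AMT!r}")
                if not (pd.isna(row.DV) or row.DV == 0):
                    raise EventTableError(f"row {i}: dose record carries a DV")
            else:
                if not (pd.isna(row.AMT) or row.AMT == 0):
                    raise EventTableError(f"row {i}: observation with AMT {row.AMT!r}")
            if not pd.isna(row.OCC) and row.OCC not in (1, 2):
                raise EventTableError(f"row {i}: OCC must be 1 or 2, got {row.OCC!r}")
        for sid, sub in df.groupby("ID", sort=False):
            t = sub.TIME.to_numpy(float)
            if np.any(np.diff(t) < 0):
                raise EventTableError(f"subject {sid}: TIME not non-decreasing")

    # -- access -------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.df.ID.nunique()

    @property
    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.df.ID))

    def subject(self, sid) -> pd.DataFrame:
        return self.df[self.df.ID == sid]

    def iter_subjects(self) -> Iterator:
        for sid, sub in self.df.groupby("ID", sort=False):
            yield sid, sub

    def doses(self, sid) -> list:
        sub = self.subject(sid)
        d = sub[sub.EVID == 1]
        return [DoseEvent(float(t), float(a)) for t, a in zip(d.TIME, d.AMT)]

    def observations(self, sid, usable_only: bool = True) -> pd.DataFrame:
        sub = self.subject(sid)
        obs = sub[sub.EVID == 0]
        if usable_only:
            obs = obs[obs.MDV == 0]
        return obs

    def covariates(self, sid) -> CovariateSet:
        row = self.subject(sid).iloc[0]

        def opt(v):
            return None if pd.isna(v) else float(v)

        return CovariateSet(age=float(row.AGE), cml=int(row.CML),
                            sex=_sex_name(row.SEX), weight=float(row.WT),
                            height=float(row.HT), alt=opt(row.ALT), ast=opt(row.AST),
                            creatinine_clearance=opt(row.CLCR))

    def n_usable_observations(self) -> int:
        df = self.df
        return int(((df.EVID == 0) & (df.MDV == 0)).sum())

    def apply_lloq(self, policy: LloqPolicy) -> "EventTable":
        """Return a copy with below-LLOQ observations flagged per policy.

        Dose records are never touched.
        """
        df = self.df.copy()
        obs = (df.EVID == 0) & df.DV.notna()
        blq = obs & (df.DV < policy.lloq)
        df.loc[blq, "BLQ"] = True
        if policy.method == "discard":
            df.loc[blq, "MDV"] = 1
        else:  # fix_at_half
            df.loc[blq, "DV"] = policy.lloq / 2.0
        return EventTable(df, validate=False)


def read_event_table(path, lloq_policy: Optional[LloqPolicy] = None) -> EventTable:
    """Read a NONMEM-style CSV dataset.

    '.' and empty fields are treated as missing.  Raises
    :class:`EventTableError` naming the offending row on malformed input.
    """
    path = Path(path)
    df = pd.read_csv(path, na_values=[".", ""], skipinitialspace=True)
    missing = [c for c in ALL_COLUMNS if c not in df.columns]
    if missing:
        raise EventTableError(f"{path}: missing columns {missing}")
    for col in ("ID",):
        df[col] = df[col].astype(int)
    for col in ("TIME", "AMT", "DV", "OCC", "AGE", "CML", "SEX", "WT", "HT",
                "ALT", "AST", "CLCR"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["AMT"] = df["AMT"].fillna(0.0)
    for col in ("EVID", "MDV"):
        df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0).astype(int)
    try:
        table = EventTable(df)
    except EventTableError as exc:
        raise EventTableError(f"{path}: {exc}") from None
    if lloq_policy is not None:
        table = table.apply_lloq(lloq_policy)
    return table


def write_event_table(table: EventTable, path) -> Path:
    """Write a NONMEM-style CSV (doses EVID=1/MDV=1, DV written as '.')."""
    path = Path(path)
    df = table.df.copy()
    df.loc[df.EVID == 1, "MDV"] = 1
    out = df[ALL_COLUMNS]
    out.to_csv(path, index=False, na_rep=".", float_format="%.10g")
    return path
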