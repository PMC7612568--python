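"""Long-format person-period panels with monotone dropout.

A study enrolls ``n`` patients at baseline (visit 0) who are followed over
visits ``1..T``.  Each patient contributes one row per visit; ``R_ij`` (the
in-study indicator) is 1 while the patient remains under observation and,
once it drops to 0, stays 0 (monotone dropout).  Treatment, time-varying
covariates and the outcome are measured on in-study rows only; baseline
covariates are constant within patient.

:class:`PersonPeriodTable` validates these invariants once at construction
and then serves aligned "wide" arrays of shape ``(n, T+1)`` to the rest of
the package, so that cumulative products/sums over visits are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, PanelValidationError, SchemaError

__all__ = ["PanelSchema", "PersonPeriodTable", "load_panel", "uncensored_index"]

_KINDS = ("binary", "ordinal", "continuous")


@dataclass(frozen=True)
class PanelSchema:
    """Column-role mapping for a long-format person-period file.

    Parameters
    ----------
    id, visit, in_study, outcome
        Column names for the patient identifier, integer visit index,
        in-study indicator ``R_ij`` and longitudinal outcome ``Y_ij``.
    treatment_kind
        One of ``binary``, ``ordinal`` (two nested indicators: any
        treatment / highest level) or ``continuous``.
    treatment
        Treatment column for binary/continuous treatments.
    treatment0, treatment1
        Ordinal indicator columns ("any treatment", "highest level").
    covariates
        Time-varying covariate columns ``X_ij``.
    baseline
        Baseline covariate columns ``V_i`` (constant within patient).
    """

    id: str = "id"
    visit: str = "visit"
    in_study: str = "r"
    outcome: str = "y"
    treatment_kind: str = "binary"
    treatment: str | None = "a"
    treatment0: str | None = None
    treatment1: str | None = None
    covariates: tuple[str, ...] = ()
    baseline: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.treatment_kind not in _KINDS:
            raise SchemaError(f"unknown treatment_kind {self.treatment_kind!r}")
        if self.treatment_kind == "ordinal":
            if not (self.treatment0 and self.treatment1):
                raise SchemaError("ordinal treatment requires treatment0 and treatment1 columns")
        elif not self.treatment:
            raise SchemaError(f"{self.treatment_kind} treatment requires a treatment column")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "baseline", tuple(self.baseline))

    @classmethod
    def from_dict(cls, cfg: dict) -> "PanelSchema":
        cfg = dict(cfg)
        trt = cfg.pop("treatment", None)
        if isinstance(trt, dict):
            cfg["treatment_kind"] = trt.get("kind", "binary")
            if cfg["treatment_kind"] == "ordinal":
                cfg["treatment0"] = trt["a0"]
                cfg["treatment1"] = trt["a1"]
            else:
                cfg["treatment"] = trt["column"]
        elif trt is not None:
            cfg["treatment"] = trt
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(cfg) - known
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        return cls(**cfg)

    @property
    def treatment_columns(self) -> tuple[str, ...]:
        if self.treatment_kind == "ordinal":
            return (self.treatment0, self.treatment1)  # type: ignore[return-value]
        return (self.treatment,)  # type: ignore[return-value]

    @property
    def measured_columns(self) -> tuple[str, ...]:
        """Columns that must be present on in-study rows."""
        return self.treatment_columns + self.covariates + (self.outcome,)


class PersonPeriodTable:
    """A validated long-format longitudinal panel with monotone dropout.

    Rows are sorted by ``(patient, visit)`` and every patient carries
    exactly ``T+1`` rows (visits ``0..T``); post-dropout rows are
    materialized with ``R=0`` and empty measurement fields.
    """

    def __init__(self, df: pd.DataFrame, schema: PanelSchema, T: int | None = None):
        self.schema = schema
        self.df = self._validate(df, T)
        self._wide_cache: dict[str, np.ndarray] = {}

    # -- construction / validation -------------------------------------------------

    def _validate(self, df: pd.DataFrame, T: int | None) -> pd.DataFrame:
        s = self.schema
        required = {s.id, s.visit, s.in_study, s.outcome, *s.treatment_columns,
                    *s.covariates, *s.baseline}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"missing required column(s): {sorted(missing)}")
        df = df.copy()
        df[s.visit] = df[s.visit].astype(int)
        if df.duplicated([s.id, s.visit]).any():
            dup = df.loc[df.duplicated([s.id, s.visit]), s.id].iloc[0]
            raise DataError(f"duplicate (patient, visit) rows, e.g. patient {dup}")
        if (df[s.visit] < 0).any():
            raise DataError("negative visit index")
        T_data = int(df[s.visit].max())
        self.T = int(T) if T is not None else T_data
        if T_data > self.T:
            raise DataError(f"visit index {T_data} exceeds declared T={self.T}")

        df = df.sort_values([s.id, s.visit], kind="mergesort").reset_index(drop=True)
        self.patients = df[s.id].drop_duplicates().to_numpy()
        self.n = len(self.patients)

        # materialize a full (patient x visit) grid; absent rows become R=0
        full = pd.MultiIndex.from_product(
            [self.patients, np.arange(self.T + 1)], names=[s.id, s.visit]
        )
        df = df.set_index([s.id, s.visit]).reindex(full).reset_index()
        df[s.in_study] = df[s.in_study].fillna(0).astype(int)
        if not df[s.in_study].isin((0, 1)).all():
            raise DataError("in-study indicator must be 0/1")

        R = df[s.in_study].to_numpy().reshape(self.n, self.T + 1)
        if (R[:, 0] != 1).any():
            bad = self.patients[np.nonzero(R[:, 0] != 1)[0][0]]
            raise PanelValidationError(f"patient {bad} has no baseline (R=1 at visit 0) row")
        nonmono = (np.diff(R, axis=1) > 0).any(axis=1)
        if nonmono.any():
            bad = self.patients[np.nonzero(nonmono)[0][0]]
            raise PanelValidationError(f"non-monotone in-study sequence for patient {bad}")

        # measured fields: required on in-study rows, blanked on out-of-study rows
        in_study = df[s.in_study].to_numpy().astype(bool)
        baselinerow = df[s.visit].to_numpy() == 0
        for col in s.measured_columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            need = in_study.copy()
            if col in s.treatment_columns:
                # no treatment is administered at baseline: absent values mean 0
                vals = vals.where(~(baselinerow & vals.isna()), 0.0)
            miss = need & vals.isna().to_numpy()
            if miss.any():
                k = np.nonzero(miss)[0][0]
                raise PanelValidationError(
                    f"missing {col!r} on in-study row (patient "
                    f"{df[s.id].iloc[k]}, visit {df[s.visit].iloc[k]})"
                )
            df[col] = vals.where(in_study | baselinerow)
        for col in s.baseline:
            vals = pd.to_numeric(df[col], errors="coerce")
            per = vals.groupby(df[s.id], sort=False)
            if per.transform("nunique").gt(1).any():
                raise PanelValidationError(f"baseline covariate {col!r} varies within a patient")
            df[col] = per.transform("first")
            if df[col].isna().any():
                bad = df.loc[df[col].isna(), s.id].iloc[0]
                raise PanelValidationError(f"missing baseline covariate {col!r} for patient {bad}")

        if s.treatment_kind == "ordinal":
            a0 = df[s.treatment0].to_numpy(dtype=float)
            a1 = df[s.treatment1].to_numpy(dtype=float)
            obs = in_study
            ok = ~obs | np.isin(a0, (0.0, 1.0)) & np.isin(a1, (0.0, 1.0)) & (a1 <= a0)
            if not ok.all():
                k = np.nonzero(~ok)[0][0]
                raise PanelValidationError(
                    f"ordinal indicators violate A1<=A0 in {{0,1}} (patient "
                    f"{df[s.id].iloc[k]}, visit {df[s.visit].iloc[k]})"
                )
        elif s.treatment_kind == "binary":
            a = df[s.treatment].to_numpy(dtype=float)
            if not (~in_study | np.isin(a, (0.0, 1.0))).all():
                raise PanelValidationError("binary treatment must be 0/1 on in-study rows")
        return df

    # -- views ---------------------------------------------------------------------

    def wide(self, col: str) -> np.ndarray:
        """Values of ``col`` as an ``(n, T+1)`` array (NaN where unobserved)."""
        if col not in self._wide_cache:
            if col == "trt":
                self._wide_cache[col] = self._trt_wide()
            else:
                v = self.df[col].to_numpy(dtype=float)
                self._wide_cache[col] = v.reshape(self.n, self.T + 1)
        return self._wide_cache[col]

    def _trt_wide(self) -> np.ndarray:
        s = self.schema
        if s.treatment_kind == "ordinal":
            return self.wide(s.treatment0) + self.wide(s.treatment1)
        return self.wide(s.treatment)

    @property
    def R(self) -> np.ndarray:
        if "R" not in self._wide_cache:
            self._wide_cache["R"] = (
                self.df[self.schema.in_study].to_numpy().reshape(self.n, self.T + 1).astype(int)
            )
        return self._wide_cache["R"]

    def uncensored_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(patient-row, visit) integer indices of uncensored person-periods.

        Ordered by patient then visit; this ordering is the single source
        of truth for aligning weights and restriction rows.
        """
        if "unc" not in self._wide_cache:
            ii, jj = np.nonzero(self.R[:, 1:])
            self._wide_cache["unc"] = (ii, jj + 1)
        return self._wide_cache["unc"]  # type: ignore[return-value]

    @property
    def m(self) -> int:
        """Number of uncensored person-periods (visits 1..T with R=1)."""
        return len(self.uncensored_arrays()[0])

    def gather(self, wide: np.ndarray) -> np.ndarray:
        """Read a wide ``(n, T+1)`` array at the uncensored person-periods."""
        ii, jj = self.uncensored_arrays()
        return wide[ii, jj]

    def cumulate(self, per_row: np.ndarray) -> np.ndarray:
        """Cumulative within-patient sum over visits of row-aligned values.

        ``per_row`` is aligned to the uncensored index; the result at row
        (i, j) is the sum of the input over that patient's visits 1..j.
        """
        ii, jj = self.uncensored_arrays()
        wide = np.zeros((self.n, self.T + 1) + per_row.shape[1:])
        wide[ii, jj] = per_row
        return np.cumsum(wide, axis=1)[ii, jj]

    # -- I/O -----------------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"PersonPeriodTable(n={self.n}, T={self.T}, m={self.m}, "
                f"treatment={self.schema.treatment_kind})")


def load_panel(path, schema: PanelSchema | dict, T: int | None = None) -> PersonPeriodTable:
    """Read and validate a delimited person-period file.

    Parameters
    ----------
    path
        CSV file with a header row; one row per patient-visit.
    schema
        :class:`PanelSchema` or a ``schema:`` config mapping.
    T
        Number of follow-up visits; inferred from the largest visit index
        when omitted.  Patients' post-dropout rows may be absent in the
        file and are re-materialized with ``R=0``.
    """
    if isinstance(schema, dict):
        schema = PanelSchema.from_dict(schema)
    df = pd.read_csv(path)
    return PersonPeriodTable(df, schema, T=T)


def uncensored_index(table: PersonPeriodTable) -> list[tuple]:
    """Ordered ``(patient_id, visit)`` pairs with visit >= 1 and R=1."""
    ii, jj = table.uncensored_arrays()
    pats = table.patients
    return [(pats[i], int(j)) for i, j in zip(ii, jj)]
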