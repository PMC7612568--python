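"""Marginal structural model fitting by weighted estimating equations.

With an identity link, unit working variance and independence working
correlation, the weighted estimating equations

    sum_ij R_ij w_ij D(Abar_ij, gamma) {Y_ij - mu(Abar_ij, gamma)} = 0

reduce to weighted least squares of the outcome on the MSM design over
uncensored person-period rows, solved exactly by linear algebra.  Standard
errors come from a nonparametric bootstrap that resamples *patients* with
replacement and re-runs the entire weight-estimation pipeline.

MSM design terms (evaluated at each uncensored row (i, j)):

=====================  =====================================================
``1``                  intercept
``visit``              visit index j; ``visit==k`` its indicator
``NAME``               baseline covariate
``cur:NAME``           time-varying column at visit j
``lagL:NAME``          time-varying column at visit j-L
``cum:NAME``           sum of the column over visits 1..j
``cum:NAME1-NAME2``    cumulative sum of a difference of columns
=====================  =====================================================

``NAME`` may be the derived numeric treatment level ``trt``.  Treatment
terms built with ``cum``/``cur``/``lag`` vanish on the never-treated
sequence, as the MSM parameterization requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CbmsmError, ConfigError, RankError, SpecTermError
from .panel import PersonPeriodTable

__all__ = ["MSMSpec", "MSMFit", "fit_msm", "bootstrap_se", "msm_design"]


@dataclass(frozen=True)
class MSMSpec:
    """MSM mean design: identity link, named design terms."""

    terms: tuple

    def __init__(self, terms):
        object.__setattr__(self, "terms", tuple(terms))

    @property
    def labels(self) -> list[str]:
        return list(self.terms)


@dataclass
class MSMFit:
    gamma: np.ndarray
    labels: list
    se: np.ndarray | None = None
    vcov: np.ndarray | None = None
    n_boot: int = 0
    n_boot_failed: int = 0
    convergence: bool = True
    working_variance: str = "identity (independence working correlation)"

    def coefficient_table(self) -> pd.DataFrame:
        d = {"term": self.labels, "estimate": self.gamma}
        if self.se is not None:
            d["se"] = self.se
        return pd.DataFrame(d)


def _cum_wide(table: PersonPeriodTable, name: str) -> np.ndarray:
    w = np.nan_to_num(table.wide(name), nan=0.0)
    return np.cumsum(w, axis=1)


def _msm_atom(table: PersonPeriodTable, atom: str) -> np.ndarray:
    """Evaluate one MSM design atom at all uncensored rows."""
    ii, jj = table.uncensored_arrays()
    if atom == "1":
        return np.ones(len(ii))
    if atom == "visit":
        return jj.astype(float)
    if atom.startswith("visit=="):
        return (jj == int(atom.split("==", 1)[1])).astype(float)
    if atom.startswith("cum:"):
        expr = atom[4:]
        if "-" in expr:
            a, b = expr.split("-", 1)
            wide = _cum_wide(table, a.strip()) - _cum_wide(table, b.strip())
        else:
            wide = _cum_wide(table, expr)
        return wide[ii, jj]
    if atom.startswith("cur:"):
        return table.wide(atom[4:])[ii, jj]
    if atom.startswith("lag"):
        head, _, name = atom.partition(":")
        L = int(head[3:])
        t = jj - L
        if (t < 0).any():
            raise SpecTermError(f"MSM term {atom!r} undefined at the earliest visit")
        return table.wide(name)[ii, t]
    if atom in table.schema.baseline:
        return table.wide(atom)[ii, 0]
    raise SpecTermError(f"unknown MSM design atom {atom!r}")


def msm_design(table: PersonPeriodTable, spec: MSMSpec) -> np.ndarray:
    cols = []
    for term in spec.terms:
        v = np.ones(table.m)
        for atom in term.split("*"):
            v = v * _msm_atom(table, atom.strip())
        cols.append(v)
    return np.column_stack(cols)


def fit_msm(table: PersonPeriodTable, weights, spec: MSMSpec) -> MSMFit:
    """Solve the weighted estimating equations exactly (identity link).

    ``weights`` may be a :class:`~cbmsm.process_models.WeightSet`, a
    :class:`~cbmsm.calibrate.CalibrationResult`, or a positive array
    aligned to the uncensored index.  The solution is invariant to
    rescaling all weights by a positive constant.
    """
    w = getattr(weights, "weights_star", None)
    if w is None:
        w = getattr(weights, "w_product", None)
    if w is None:
        w = np.asarray(weights, dtype=float)
    if len(w) != table.m:
        raise ConfigError(f"weights length {len(w)} != number of person-periods {table.m}")
    if np.any(w < 0):
        raise ConfigError("negative weights")
    X = msm_design(table, spec)
    y = table.gather(table.wide(table.schema.outcome))
    sw = np.sqrt(w)
    gamma, _, rank, _ = np.linalg.lstsq(sw[:, None] * X, sw * y, rcond=None)
    if rank < X.shape[1]:
        # identify collinear terms by pivoted elimination on the gram matrix
        G = (sw[:, None] * X).T @ (sw[:, None] * X)
        diag = np.sqrt(np.clip(np.diag(G), 1e-300, None))
        C = G / np.outer(diag, diag)
        bad = [spec.labels[i] for i in range(X.shape[1])
               if np.linalg.matrix_rank(C[: i + 1, : i + 1]) < i + 1]
        raise RankError(f"singular weighted MSM design; collinear terms: {bad or spec.labels}")
    return MSMFit(gamma=gamma, labels=spec.labels)


def bootstrap_se(table: PersonPeriodTable, estimator, B: int, seed: int,
                 labels: list | None = None) -> MSMFit:
    """Nonparametric bootstrap treating patients as resampling units.

    ``estimator`` is a callable mapping a :class:`PersonPeriodTable` to a
    coefficient vector; it should re-run the full weight-estimation
    pipeline.  Replicates where the pipeline raises a package error are
    dropped and counted in ``n_boot_failed``.
    """
    if B < 2:
        raise ConfigError("bootstrap requires B >= 2 replicates")
    gamma0 = np.asarray(estimator(table))
    rng = np.random.default_rng(seed)
    s = table.schema
    block = table.T + 1
    base = np.arange(table.n) * block
    reps, failed = [], 0
    for _ in range(B):
        pick = np.sort(rng.integers(0, table.n, table.n))
        rows = (base[pick][:, None] + np.arange(block)).ravel()
        df = table.df.iloc[rows].copy()
        df[s.id] = np.repeat(np.arange(table.n), block)
        try:
            rep_table = PersonPeriodTable(df, s, T=table.T)
            reps.append(np.asarray(estimator(rep_table)))
        except (CbmsmError, np.linalg.LinAlgError):
            failed += 1
    if not reps:
        raise CbmsmError(f"all {B} bootstrap replicates failed")
    G = np.vstack(reps)
    vcov = np.atleast_2d(np.cov(G, rowvar=False, ddof=1))
    return MSMFit(gamma=gamma0, labels=labels or [f"g{k}" for k in range(len(gamma0))],
                  se=np.sqrt(np.diag(vcov)), vcov=vcov,
                  n_boot=len(reps), n_boot_failed=failed)
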