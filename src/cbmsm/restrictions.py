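"""Calibration restrictions: a linear system K'W* = l in the calibrated weights.

Each restriction block stacks, per uncensored person-period (i, j), a
cumulative weighted-score contribution; requiring the weighted column sums
to hit their targets makes the corresponding covariate-process association
vanish exactly in the weighted sample:

* treatment blocks force the pooled weighted score of the treatment model,
  evaluated at "covariate coefficients = 0" with the numerator-model fit
  plugged in, to be zero — i.e. after weighting, treatment assignment up
  to each visit is unassociated with covariate history given treatment
  history;
* the censoring block forces the weighted uncensored sample at each visit
  to be representative of the full baseline cohort in terms of the chosen
  balance functionals H̃ (with the constant term this pins the weighted
  person-period count at n*T);
* normalization blocks (IPTW-only calibration) pin the mean calibrated
  weight to 1 at every visit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import design_matrix, eval_terms_at_risk, validate_history_terms
from .exceptions import ConfigError, SpecTermError
from .panel import PersonPeriodTable
from .process_models import FittedProcessModel, ProcessModelSpec

__all__ = ["RestrictionBlock", "RestrictionSystem", "build_treatment_restrictions",
           "build_continuous_restrictions", "build_normalization_restrictions",
           "build_censoring_restrictions", "assemble_system"]


@dataclass
class RestrictionBlock:
    kind: str
    labels: list
    columns: np.ndarray  # (m, width), aligned to the uncensored index
    target: np.ndarray   # (width,)

    def __post_init__(self) -> None:
        self.columns = np.atleast_2d(np.asarray(self.columns, dtype=float))
        self.target = np.asarray(self.target, dtype=float)
        if not np.isfinite(self.columns).all() or not np.isfinite(self.target).all():
            raise ConfigError(f"non-finite entries in {self.kind} restriction block")
        if self.columns.shape[1] != len(self.target) or len(self.labels) != len(self.target):
            raise ConfigError(f"inconsistent widths in {self.kind} restriction block")

    @property
    def width(self) -> int:
        return len(self.target)


@dataclass
class RestrictionSystem:
    K: np.ndarray
    l: np.ndarray
    labels: list
    m: int
    r: int
    column_scale: np.ndarray | None = None

    def residual(self, w: np.ndarray) -> np.ndarray:
        """K'w - l for a weight vector aligned to the uncensored index."""
        return self.K.T @ np.asarray(w, dtype=float) - self.l

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.K, columns=self.labels)

    def export(self, path) -> None:
        """Write the labeled system (K plus a target row) for audit."""
        df = self.to_frame()
        df.loc["__target__"] = self.l
        df.to_csv(path, index=True)


def _cumscore(table: PersonPeriodTable, per_row: np.ndarray) -> np.ndarray:
    """Cumulative within-patient sums of per-visit score contributions."""
    return table.cumulate(per_row)


def build_treatment_restrictions(table: PersonPeriodTable,
                                 numer: FittedProcessModel,
                                 spec: ProcessModelSpec | None = None,
                                 e_override: dict | None = None) -> RestrictionBlock:
    """Cumulative-score balance block for a binary or ordinal treatment.

    Row (i, j), column c carries ``sum_{k<=j} (A_ik - e^_ik) X~_{i,k-1,c}``
    where ``e^`` is the predicted treatment probability from the
    treatment-history-only (numerator) fit and X~ are the full
    (denominator) model terms; for the ordinal model there is one column
    set per stage and stage-2 sums run over visits with A0=1.  Targets
    are zero.  ``e_override`` substitutes user-supplied fitted probability
    arrays (e.g. the denominator fit) for diagnostics.
    """
    spec = spec or numer.spec
    s = table.schema
    fitted = dict(numer.fitted)
    if e_override:
        fitted.update(e_override)
    cols, labels = [], []
    if spec.kind == "binary_logistic":
        a = table.gather(table.wide(s.treatment))
        e = table.gather(fitted["e_num"])
        X = design_matrix(table, spec.den())
        cols.append(_cumscore(table, (a - e)[:, None] * X))
        labels += [f"treat:{t}" for t in spec.den()]
    elif spec.kind == "ordinal_two_stage":
        a0 = table.gather(table.wide(s.treatment0))
        a1 = table.gather(table.wide(s.treatment1))
        e0 = table.gather(fitted["e0_num"])
        e1 = table.gather(fitted["e1_num"])
        X0 = design_matrix(table, spec.den("stage0"))
        X1 = design_matrix(table, spec.den("stage1"))
        cols.append(_cumscore(table, (a0 - e0)[:, None] * X0))
        cols.append(_cumscore(table, (a0 * (a1 - e1))[:, None] * X1))
        labels += [f"treat0:{t}" for t in spec.den("stage0")]
        labels += [f"treat1:{t}" for t in spec.den("stage1")]
    else:
        raise ConfigError("use build_continuous_restrictions for continuous treatments")
    K = np.concatenate(cols, axis=1)
    return RestrictionBlock("treatment", labels, K, np.zeros(K.shape[1]))


def build_continuous_restrictions(table: PersonPeriodTable,
                                  numer: FittedProcessModel,
                                  spec: ProcessModelSpec | None = None) -> RestrictionBlock:
    """Standardized-residual balance block for a continuous treatment.

    Mean columns: ``sum_{k<=j} (A-mu^)/s2^ * X~mu``; variance columns:
    ``sum_{k<=j} (-1 + (A-mu^)^2/s2^) * X~sigma``; ``mu^``, ``s2^`` come
    from the treatment-history-only heteroscedastic-normal fit.
    """
    spec = spec or numer.spec
    a = table.gather(table.wide(table.schema.treatment))
    mu = table.gather(numer.fitted["mu_num"])
    s2 = table.gather(numer.fitted["s2_num"])
    if np.any(s2 < 1e-12):
        raise ConfigError("fitted treatment variance below tolerance")
    Xm = design_matrix(table, spec.den("mean"))
    Xs = design_matrix(table, spec.den("var"))
    r = a - mu
    Km = _cumscore(table, (r / s2)[:, None] * Xm)
    Ks = _cumscore(table, (-1.0 + r * r / s2)[:, None] * Xs)
    labels = [f"cont_mu:{t}" for t in spec.den("mean")] + \
             [f"cont_sigma:{t}" for t in spec.den("var")]
    K = np.concatenate([Km, Ks], axis=1)
    return RestrictionBlock("treatment_continuous", labels, K, np.zeros(K.shape[1]))


def build_normalization_restrictions(table: PersonPeriodTable) -> RestrictionBlock:
    """Per-visit mean-weight-one block (IPTW-only Type 1 calibration).

    Column j indicates visit j; its target is the uncensored count at
    visit j, so any satisfying weight vector has per-visit mean weight 1.
    """
    _, jj = table.uncensored_arrays()
    T = table.T
    K = np.column_stack([(jj == j).astype(float) for j in range(1, T + 1)])
    target = K.sum(axis=0)
    labels = [f"norm:visit{j}" for j in range(1, T + 1)]
    return RestrictionBlock("normalization", labels, K, target)


def build_censoring_restrictions(table: PersonPeriodTable,
                                 h_terms: list[str]) -> RestrictionBlock:
    """Telescoped censoring-balance block.

    Row (i, j), column c carries ``(T-j+1) H̃_{i,j-1,c} - (T-j) H̃_{ij,c}``
    and the target is ``T * sum_i H̃_{i0,c}`` (using R_i0 = 1, W_i0 = 1).
    Satisfying weights make the weighted uncensored observations at every
    visit representative of the baseline cohort in terms of H̃.
    """
    validate_history_terms(table, h_terms)
    _, jj = table.uncensored_arrays()
    T = table.T
    H_prev = design_matrix(table, h_terms, shift=0)   # H~_{i,j-1}
    H_next = design_matrix(table, h_terms, shift=1)   # H~_{ij}; 0 where j = T
    wj_prev = (T - jj + 1).astype(float)[:, None]
    wj_next = (T - jj).astype(float)[:, None]
    K = wj_prev * H_prev - wj_next * H_next
    H0 = eval_terms_at_risk(table, h_terms, 1, np.arange(table.n))  # H~_{i0}
    target = T * H0.sum(axis=0)
    labels = [f"cens:{t}" for t in h_terms]
    return RestrictionBlock("censoring", labels, K, target)


def assemble_system(blocks: list[RestrictionBlock],
                    standardize: bool = False) -> RestrictionSystem:
    """Concatenate restriction blocks into the full (K, l) system.

    Censoring and normalization blocks must not coexist (the per-visit
    normalization is implied by the censoring restrictions).  Warns on
    rank deficiency and on treatment-only systems, where the Type 1
    objective admits the trivial all-zero weight solution.
    ``standardize`` rescales each column (and its target) to unit root
    mean square for solver conditioning; the solution in W* is invariant.
    """
    if not blocks:
        raise ConfigError("at least one restriction block is required")
    kinds = [b.kind for b in blocks]
    if "censoring" in kinds and "normalization" in kinds:
        raise ConfigError("normalization restrictions are redundant given censoring "
                          "restrictions; include only one of the two blocks")
    m = blocks[0].columns.shape[0]
    if any(b.columns.shape[0] != m for b in blocks):
        raise ConfigError("restriction blocks are not row-aligned")
    labels = [lab for b in blocks for lab in b.labels]
    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise ConfigError(f"duplicated restriction labels: {dup}")
    K = np.concatenate([b.columns for b in blocks], axis=1)
    l = np.concatenate([b.target for b in blocks])

    if not any(k in ("censoring", "normalization") for k in kinds):
        warnings.warn("treatment-only restriction system: the all-zero weight vector "
                      "satisfies it; add normalization or censoring restrictions for "
                      "Type 1 calibration", stacklevel=2)
    scale = None
    if standardize:
        scale = np.sqrt(np.mean(K * K, axis=0))
        scale[scale < 1e-12] = 1.0
        K = K / scale
        l = l / scale
    r = K.shape[1]
    rank = np.linalg.matrix_rank(K) if m and r else 0
    if r and rank < min(m, r):
        sv = np.linalg.svd(K, compute_uv=False)
        weak = [labels[i] for i in range(r) if i >= rank]
        warnings.warn(f"restriction matrix is rank deficient (rank {rank} < {r}); "
                      f"check columns such as {weak[:5]}", stacklevel=2)
    return RestrictionSystem(K, l, labels, m=m, r=r, column_scale=scale)
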