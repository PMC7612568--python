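"""Parametric treatment-assignment and censoring models, and initial weights.

All process models are fitted by unweighted maximum likelihood, pooled over
visits (visit indicators may be included as terms).  Each treatment fit
produces two sets of coefficients:

* the *denominator* model — treatment given the full observed history
  ``pr(A_ij | Xbar_{i,j-1}; beta)``;
* the *numerator* model — treatment given treatment history only
  ``pr(A_ij | Abar_{i,j-1}; alpha)``, used to stabilize the weights.

The stabilized inverse-probability-of-treatment weight telescopes over
visits, ``SW^A_ij = prod_{k<=j} pr(A_ik|Abar;alpha) / pr(A_ik|Xbar;beta)``,
and the (unstabilized) censoring weight is ``W^C_ij = prod_{k<=j} 1/pi_ik``
with ``pi_ik = pr(R_ik=1 | history, R_{i,k-1}=1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.stats import norm

from .design import (design_matrix, eval_terms_at_risk, validate_history_terms,
                     validate_treatment_only_terms)
from .exceptions import (ConfigError, DegenerateDataError, FittingError,
                         PositivityError, RankError)
from .panel import PersonPeriodTable, uncensored_index

__all__ = [
    "ProcessModelSpec", "FittedProcessModel", "WeightSet",
    "fit_binary_treatment_model", "fit_ordinal_treatment_model",
    "fit_continuous_treatment_model", "fit_censoring_model",
    "compute_initial_weights",
]

PROB_FLOOR = 1e-8  # numerical positivity guard on fitted probabilities


@dataclass(frozen=True)
class ProcessModelSpec:
    """Term lists for one process model.

    ``kind`` is one of ``binary_logistic``, ``ordinal_two_stage``,
    ``continuous_heteroscedastic``, ``censoring_logistic``.  For the
    two-stage ordinal model, term lists are mappings with keys ``stage0``
    and ``stage1``; for the heteroscedastic-normal model, keys ``mean``
    and ``var``.  ``numerator_terms`` may reference treatment history only
    and is absent for the censoring model.
    """

    kind: str
    denominator_terms: object = None
    numerator_terms: object = None

    _PARTS = {
        "binary_logistic": (None,),
        "ordinal_two_stage": ("stage0", "stage1"),
        "continuous_heteroscedastic": ("mean", "var"),
        "censoring_logistic": (None,),
    }

    def __post_init__(self) -> None:
        if self.kind not in self._PARTS:
            raise ConfigError(f"unknown process model kind {self.kind!r}")

    def parts(self) -> tuple:
        return self._PARTS[self.kind]

    def den(self, part=None) -> list[str]:
        t = self.denominator_terms
        return list(t[part]) if part else list(t)

    def num(self, part=None) -> list[str]:
        t = self.numerator_terms
        return list(t[part]) if part else list(t)

    def validate(self, table: PersonPeriodTable) -> None:
        for part in self.parts():
            validate_history_terms(table, self.den(part))
            if self.numerator_terms is not None:
                validate_history_terms(table, self.num(part))
                validate_treatment_only_terms(table, self.num(part))


@dataclass
class FittedProcessModel:
    """A fitted process model with per-person-period fitted values.

    ``coefficients`` maps named coefficient vectors (e.g. ``beta0``,
    ``alpha0``); ``fitted`` maps named wide ``(n, T+1)`` arrays of
    predicted probabilities / moments; ``designs`` keeps the denominator
    design matrices aligned to the uncensored index (reused by the
    restriction builders and the Type 2 solver).
    """

    spec: ProcessModelSpec
    coefficients: dict = field(default_factory=dict)
    log_likelihood: float = np.nan
    fitted: dict = field(default_factory=dict)
    designs: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------- logistic core

def _fit_logit(y: np.ndarray, X: np.ndarray, what: str) -> tuple[np.ndarray, float]:
    y = np.asarray(y, dtype=float)
    if len(y) < X.shape[1]:
        raise RankError(f"{what}: fewer rows ({len(y)}) than parameters ({X.shape[1]})")
    if y.min() == y.max():
        raise DegenerateDataError(f"{what}: response is constant ({y[0]:g})")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=200)
    except Exception as e:  # statsmodels PerfectSeparationError or LinAlgError
        raise FittingError(f"{what}: logistic fit failed ({e})") from e
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 1e3:
        raise FittingError(f"{what}: logistic MLE did not converge (possible separation)")
    return np.asarray(res.params), float(res.llf)


def _scatter(table: PersonPeriodTable, rows_vals: np.ndarray,
             ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    wide = np.full((table.n, table.T + 1), np.nan)
    wide[ii, jj] = rows_vals
    return wide


def _expit(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


# ------------------------------------------------------------- treatment models

def fit_binary_treatment_model(table: PersonPeriodTable,
                               spec: ProcessModelSpec) -> FittedProcessModel:
    """Pooled logistic MLE for a binary treatment (denominator + numerator)."""
    if spec.kind != "binary_logistic":
        raise ConfigError("spec.kind must be 'binary_logistic'")
    spec.validate(table)
    ii, jj = table.uncensored_arrays()
    a = table.gather(table.wide(table.schema.treatment))
    Xd = design_matrix(table, spec.den())
    Xn = design_matrix(table, spec.num())
    beta, llf = _fit_logit(a, Xd, "treatment denominator")
    alpha, _ = _fit_logit(a, Xn, "treatment numerator")
    fit = FittedProcessModel(spec, {"beta": beta, "alpha": alpha}, llf)
    fit.fitted["e_den"] = _scatter(table, _expit(Xd @ beta), ii, jj)
    fit.fitted["e_num"] = _scatter(table, _expit(Xn @ alpha), ii, jj)
    fit.designs["den"] = Xd
    fit.designs["num"] = Xn
    return fit


def fit_ordinal_treatment_model(table: PersonPeriodTable,
                                spec: ProcessModelSpec) -> FittedProcessModel:
    """Continuation-ratio two-stage logistic MLE for an ordinal treatment.

    Stage 1 models the "any treatment" indicator A0 on all uncensored
    person-periods; stage 2 models the "highest level" indicator A1 on the
    subset with A0 = 1.  Implied category probabilities are
    ``pr(none) = 1-e0``, ``pr(low) = e0(1-e1)``, ``pr(high) = e0*e1``.
    """
    if spec.kind != "ordinal_two_stage":
        raise ConfigError("spec.kind must be 'ordinal_two_stage'")
    spec.validate(table)
    ii, jj = table.uncensored_arrays()
    s = table.schema
    a0 = table.gather(table.wide(s.treatment0))
    a1 = table.gather(table.wide(s.treatment1))
    sub = a0 == 1
    if not sub.any():
        raise DegenerateDataError("ordinal stage 2: no person-periods with A0 = 1")

    fit = FittedProcessModel(spec)
    llf = 0.0
    for stage, resp, rows_mask in (("stage0", a0, None), ("stage1", a1, sub)):
        k = stage[-1]
        Xd = design_matrix(table, spec.den(stage))
        Xn = design_matrix(table, spec.num(stage))
        yd = resp if rows_mask is None else resp[rows_mask]
        Xd_fit = Xd if rows_mask is None else Xd[rows_mask]
        Xn_fit = Xn if rows_mask is None else Xn[rows_mask]
        beta, l_ = _fit_logit(yd, Xd_fit, f"ordinal {stage} denominator")
        alpha, _ = _fit_logit(yd, Xn_fit, f"ordinal {stage} numerator")
        llf += l_
        fit.coefficients[f"beta{k}"] = beta
        fit.coefficients[f"alpha{k}"] = alpha
        # predictions on ALL uncensored rows; stage-2 values are only ever
        # used where A0 = 1 (the continuation-ratio factor)
        fit.fitted[f"e{k}_den"] = _scatter(table, _expit(Xd @ beta), ii, jj)
        fit.fitted[f"e{k}_num"] = _scatter(table, _expit(Xn @ alpha), ii, jj)
        fit.designs[f"den_{stage}"] = Xd
        fit.designs[f"num_{stage}"] = Xn
    fit.log_likelihood = llf
    fit.designs["stage1_mask"] = sub
    return fit


def _hetnorm_nll_grad(params, a, Xm, Xs):
    pm = Xm.shape[1]
    mu = Xm @ params[:pm]
    sl = np.clip(Xs @ params[pm:], -40, 40)
    r = a - mu
    w = np.exp(-sl)
    nll = 0.5 * np.sum(sl + r * r * w) + 0.5 * len(a) * np.log(2 * np.pi)
    gm = -Xm.T @ (r * w)
    gs = 0.5 * Xs.T @ (1.0 - r * r * w)
    return nll, np.concatenate([gm, gs])


def fit_continuous_treatment_model(table: PersonPeriodTable,
                                   spec: ProcessModelSpec) -> FittedProcessModel:
    """Joint MLE of a heteroscedastic normal treatment model.

    ``A_ij ~ N(X~mu' beta_mu, exp(X~sigma' beta_sigma))``; the numerator
    model has the same form with treatment-history-only terms.
    """
    if spec.kind != "continuous_heteroscedastic":
        raise ConfigError("spec.kind must be 'continuous_heteroscedastic'")
    spec.validate(table)
    ii, jj = table.uncensored_arrays()
    a = table.gather(table.wide(table.schema.treatment))
    if np.var(a) < 1e-12:
        raise DegenerateDataError("continuous treatment is constant; variance model degenerate")

    fit = FittedProcessModel(spec)
    for role, get in (("den", spec.den), ("num", spec.num)):
        Xm, Xs = design_matrix(table, get("mean")), design_matrix(table, get("var"))
        p = Xm.shape[1] + Xs.shape[1]
        if len(a) < p:
            raise RankError(f"continuous model ({role}): fewer rows than parameters")
        # warm start: OLS mean, intercept-only log-variance
        bm0, *_ = np.linalg.lstsq(Xm, a, rcond=None)
        resid = a - Xm @ bm0
        bs0 = np.zeros(Xs.shape[1])
        bs0[get("var").index("1")] = np.log(max(np.mean(resid ** 2), 1e-10))
        res = minimize(_hetnorm_nll_grad, np.concatenate([bm0, bs0]),
                       args=(a, Xm, Xs), jac=True, method="BFGS",
                       options={"maxiter": 500, "gtol": 1e-8})
        if not res.success and np.linalg.norm(res.jac, np.inf) > 1e-4:
            raise FittingError(f"continuous treatment model ({role}) did not converge: "
                               f"{res.message}")
        pm = Xm.shape[1]
        mu = Xm @ res.x[:pm]
        s2 = np.exp(np.clip(Xs @ res.x[pm:], -40, 40))
        key = "beta" if role == "den" else "alpha"
        fit.coefficients[f"{key}_mu"] = res.x[:pm]
        fit.coefficients[f"{key}_sigma"] = res.x[pm:]
        fit.fitted[f"mu_{role}"] = _scatter(table, mu, ii, jj)
        fit.fitted[f"s2_{role}"] = _scatter(table, s2, ii, jj)
        fit.designs[f"{role}_mean"], fit.designs[f"{role}_var"] = Xm, Xs
        if role == "den":
            fit.log_likelihood = -res.fun
    return fit


# -------------------------------------------------------------- censoring model

def fit_censoring_model(table: PersonPeriodTable,
                        spec: ProcessModelSpec) -> FittedProcessModel:
    """Pooled logistic model for remaining in study at each visit.

    The response ``R_ij`` is regressed on H̃_{i,j-1} over at-risk rows
    (``R_{i,j-1}=1``, ``j=1..T``).  With no censoring events the model is
    degenerate: fitted retention probability 1 (weights 1) is returned
    with a warning flag instead of an error.
    """
    if spec.kind != "censoring_logistic":
        raise ConfigError("spec.kind must be 'censoring_logistic'")
    validate_history_terms(table, spec.den())
    R = table.R
    ai, aj = np.nonzero(R[:, : table.T])  # at-risk: R_{j-1}=1
    aj = aj + 1
    y = R[ai, aj].astype(float)

    fit = FittedProcessModel(spec)
    terms = spec.den()
    if y.min() == y.max():
        # no dropout: retention probability 1 at every visit
        fit.coefficients["theta"] = None
        fit.fitted["pi"] = _scatter(table, np.ones(len(ai)), ai, aj)
        fit.flags.append("no-censoring-events")
        fit.designs["unc"] = design_matrix(table, terms)
        return fit

    X = np.zeros((len(ai), len(terms)))
    for j in range(1, table.T + 1):
        mask = aj == j
        if mask.any():
            X[mask] = eval_terms_at_risk(table, terms, j, ai[mask])
    theta, llf = _fit_logit(y, X, "censoring")
    fit.coefficients["theta"] = theta
    fit.log_likelihood = llf
    fit.fitted["pi"] = _scatter(table, _expit(X @ theta), ai, aj)
    fit.designs["unc"] = design_matrix(table, terms)  # at uncensored rows, for Type 2
    return fit


# ------------------------------------------------------------------ weight sets

@dataclass
class WeightSet:
    """Initial stabilized treatment and censoring weights.

    All arrays are aligned to the uncensored person-period index; weights
    telescope over visits within patient and are strictly positive.
    """

    index: list
    sw_treat: np.ndarray
    w_cens: np.ndarray
    scaling: dict = field(default_factory=dict)
    n_clipped: int = 0

    @property
    def w_product(self) -> np.ndarray:
        f = self.scaling.get("product_factor", 1.0)
        return self.sw_treat * self.w_cens * f


def _category_prob(table: PersonPeriodTable, model: FittedProcessModel,
                   which: str) -> np.ndarray:
    """Per-visit likelihood factor of the *observed* treatment, row-aligned."""
    kind = model.spec.kind
    s = table.schema
    if kind == "binary_logistic":
        a = table.gather(table.wide(s.treatment))
        e = table.gather(model.fitted[f"e_{which}"])
        return np.where(a == 1, e, 1.0 - e)
    if kind == "ordinal_two_stage":
        a0 = table.gather(table.wide(s.treatment0))
        a1 = table.gather(table.wide(s.treatment1))
        e0 = table.gather(model.fitted[f"e0_{which}"])
        e1 = table.gather(model.fitted[f"e1_{which}"])
        p = np.where(a0 == 0, 1.0 - e0, np.where(a1 == 0, e0 * (1.0 - e1), e0 * e1))
        return p
    if kind == "continuous_heteroscedastic":
        a = table.gather(table.wide(s.treatment))
        mu = table.gather(model.fitted[f"mu_{which}"])
        s2 = table.gather(model.fitted[f"s2_{which}"])
        if np.any(s2 <= 0):
            raise PositivityError("non-positive fitted treatment variance")
        return norm.pdf(a, loc=mu, scale=np.sqrt(s2))
    raise ConfigError(f"not a treatment model: {kind}")


def compute_initial_weights(table: PersonPeriodTable,
                            treatment: FittedProcessModel,
                            censoring: FittedProcessModel | None = None,
                            rescale: str | None = None) -> WeightSet:
    """Stabilized IPT weights, censoring weights, and their product.

    ``rescale='iptw'`` scales the treatment weights to sum to the number
    of uncensored observations; ``rescale='iptcw'`` scales the product
    weights to sum to ``T x n`` (the observation count of the target
    population without censoring).  Fitted probabilities are clipped to
    ``[1e-8, 1-1e-8]`` before use; clip events are counted.
    """
    if rescale not in (None, "iptw", "iptcw"):
        raise ConfigError(f"unknown rescale option {rescale!r}")
    idx = uncensored_index(table)
    m = table.m
    n_clip = 0

    def _clip(p):
        nonlocal n_clip
        if np.any(~np.isfinite(p)) or np.any(p <= 0):
            bad = int(np.nonzero(~np.isfinite(p) | (p <= 0))[0][0])
            raise PositivityError(f"non-positive fitted probability at person-period {idx[bad]}")
        c = np.clip(p, PROB_FLOOR, None)
        if treatment.spec.kind != "continuous_heteroscedastic":
            c = np.clip(c, None, 1.0 - PROB_FLOOR)
        n_clip += int(np.sum(c != p))
        return c

    p_num = _clip(_category_prob(table, treatment, "num"))
    p_den = _clip(_category_prob(table, treatment, "den"))
    sw = np.exp(table.cumulate(np.log(p_num) - np.log(p_den)))

    if censoring is None:
        wc = np.ones(m)
    else:
        pi = _clip(np.clip(table.gather(censoring.fitted["pi"]), None, 1.0))
        wc = np.exp(table.cumulate(-np.log(pi)))

    ws = WeightSet(idx, sw, wc, n_clipped=n_clip)
    if rescale == "iptw":
        f = m / sw.sum()
        ws.sw_treat = sw * f
        ws.scaling = {"mode": "iptw", "treat_factor": f}
    elif rescale == "iptcw":
        target = table.T * table.n
        f = target / (sw * wc).sum()
        ws.scaling = {"mode": "iptcw", "product_factor": f}
    return ws
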