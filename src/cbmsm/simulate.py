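"""Synthetic longitudinal panels with time-varying confounding and dropout.

The generator emulates an observational cohort: a baseline covariate V and
a time-varying covariate X drive both treatment assignment and monotone
dropout, X responds to treatment (so it is a confounder *affected by*
treatment history), and the outcome follows a linear marginal structural
mean in cumulative and current treatment.

Temporal ordering within visit j >= 1 is A_j -> X_j -> Y_j, with the
retention decision R_j taken first from the visit-(j-1) state:

* ``A_j``  ~ logistic / two nested logistics / heteroscedastic normal in
  (A_{j-1}, X_{j-1}, V),
* ``X_j``  = rho X_{j-1} + kappa A_j + noise,
* ``Y_j``  = theta0 + theta_a * sum_{l<=j} A_l + theta_x X_j + noise,
* ``R_j | R_{j-1}=1`` ~ logistic(psi0 + psi1 X_{j-1} + psi2 A_{j-1}).

With rho = 0 the implied MSM is exactly linear in (cumulative, current)
treatment with coefficients (theta_a, theta_x * kappa).  Setting
``misspecification="transform"`` exports exp(X/2) in place of X (the DGP
itself is unchanged), inducing functional-form misspecification in any
analysis model that is linear in the exported covariate.

Randomness is drawn from two prefix-stable streams (one for normals, one
for uniforms) in patient-major blocks, so growing ``n`` appends patients
without reshuffling earlier ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .calibrate import solve_type1, solve_type2
from .exceptions import CalibrationError, CbmsmError, ConfigError
from .msm import MSMSpec, fit_msm
from .panel import PanelSchema, PersonPeriodTable
from .process_models import (ProcessModelSpec, compute_initial_weights,
                             fit_binary_treatment_model, fit_censoring_model,
                             fit_continuous_treatment_model,
                             fit_ordinal_treatment_model)
from .restrictions import (assemble_system, build_censoring_restrictions,
                           build_continuous_restrictions,
                           build_normalization_restrictions,
                           build_treatment_restrictions)

__all__ = ["SimulationConfig", "TruthRecord", "generate_scenario",
           "true_msm_parameters", "potential_outcome_means",
           "run_replication_study", "ESTIMATORS", "default_treatment_spec",
           "DEFAULT_H_TERMS", "DEFAULT_MSM", "schema_for"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated scenario.

    Defaults give moderate confounding and dropout: treatment logit slopes
    0.5 (confounder), 0.4 (baseline), 0.6 (previous treatment level);
    confounder response kappa = 0.8 with no autoregression (rho = 0);
    outcome effects theta_a = 1 (direct cumulative), theta_x = 0.5;
    censoring logits psi = (2, -0.4, 0.3).
    """

    n: int = 500
    T: int = 3
    treatment_kind: str = "ordinal"
    # treatment assignment
    a_intercepts: tuple = (0.0, -0.5)   # stage 0 / stage 1 (binary & continuous use [0])
    a_prev: float = 0.6
    a_x: float = 0.5
    a_v: float = 0.4
    s_intercept: float = 0.0            # continuous: log-variance intercept
    s_x: float = 0.2                    # continuous: log-variance slope on X_{j-1}
    # confounder law
    rho: float = 0.0
    kappa: float = 0.8
    sd_x: float = 1.0
    # outcome law
    theta0: float = 0.0
    theta_a: float = 1.0
    theta_x: float = 0.5
    sd_y: float = 1.0
    # censoring model (None disables dropout)
    psi: tuple | None = (2.0, -0.4, 0.3)
    misspecification: str = "none"      # none | transform
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.T < 1:
            raise ConfigError("n >= 1 and T >= 1 required")
        if not (0.0 <= self.rho < 1.0):
            raise ConfigError("rho must lie in [0, 1)")
        if self.sd_x <= 0 or self.sd_y <= 0:
            raise ConfigError("noise standard deviations must be positive")
        if self.treatment_kind not in ("binary", "ordinal", "continuous"):
            raise ConfigError(f"unknown treatment_kind {self.treatment_kind!r}")
        if self.misspecification not in ("none", "transform"):
            raise ConfigError(f"unknown misspecification {self.misspecification!r}")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class TruthRecord:
    """Ground truth attached to a simulated scenario."""

    true_gamma: dict
    seed: int
    config_hash: str
    p_obs: np.ndarray | None = None   # true prob of the observed treatment (wide)
    pi: np.ndarray | None = None      # true retention probability (wide)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def schema_for(kind: str) -> PanelSchema:
    common = dict(id="id", visit="visit", in_study="r", outcome="y",
                  covariates=("x",), baseline=("v",))
    if kind == "ordinal":
        return PanelSchema(treatment_kind="ordinal", treatment=None,
                           treatment0="a0", treatment1="a1", **common)
    return PanelSchema(treatment_kind=kind, treatment="a", **common)


def generate_scenario(config: SimulationConfig) -> tuple[PersonPeriodTable, TruthRecord]:
    """Simulate one cohort; returns the panel and its ground-truth record."""
    c = config
    n, T = c.n, c.T
    ss = np.random.SeedSequence(c.seed)
    sn, su = ss.spawn(2)
    normals = np.random.default_rng(sn).standard_normal((n, 3 + 3 * T))
    unifs = np.random.default_rng(su).random((n, 3 * T))

    V = normals[:, 0]
    X = np.zeros((n, T + 1))
    Y = np.zeros((n, T + 1))
    lvl = np.zeros((n, T + 1))          # numeric treatment level / dose
    A0 = np.zeros((n, T + 1))
    A1 = np.zeros((n, T + 1))
    A = np.zeros((n, T + 1))
    R = np.ones((n, T + 1), dtype=int)
    p_obs = np.full((n, T + 1), np.nan)
    pi_true = np.full((n, T + 1), np.nan)

    X[:, 0] = normals[:, 1]
    Y[:, 0] = c.theta0 + c.theta_x * X[:, 0] + c.sd_y * normals[:, 2]

    for j in range(1, T + 1):
        zx, zy, za = (normals[:, 3 * j + k] for k in (0, 1, 2))
        u0, u1, ur = (unifs[:, 3 * (j - 1) + k] for k in (0, 1, 2))
        # retention decided from the visit-(j-1) state
        if c.psi is not None:
            pi = _expit(c.psi[0] + c.psi[1] * X[:, j - 1] + c.psi[2] * lvl[:, j - 1])
            R[:, j] = R[:, j - 1] * (ur < pi)
            pi_true[:, j] = pi
        else:
            R[:, j] = R[:, j - 1]
            pi_true[:, j] = 1.0
        eta = c.a_prev * lvl[:, j - 1] + c.a_x * X[:, j - 1] + c.a_v * V
        if c.treatment_kind == "binary":
            e = _expit(c.a_intercepts[0] + eta)
            A[:, j] = (u0 < e).astype(float)
            lvl[:, j] = A[:, j]
            p_obs[:, j] = np.where(A[:, j] == 1, e, 1 - e)
        elif c.treatment_kind == "ordinal":
            e0 = _expit(c.a_intercepts[0] + eta)
            e1 = _expit(c.a_intercepts[1] + eta)
            A0[:, j] = (u0 < e0).astype(float)
            A1[:, j] = A0[:, j] * (u1 < e1)
            lvl[:, j] = A0[:, j] + A1[:, j]
            p_obs[:, j] = np.where(A0[:, j] == 0, 1 - e0,
                                   np.where(A1[:, j] == 0, e0 * (1 - e1), e0 * e1))
        else:  # continuous
            mu = c.a_intercepts[0] + eta
            s2 = np.exp(c.s_intercept + c.s_x * X[:, j - 1])
            A[:, j] = mu + np.sqrt(s2) * za
            lvl[:, j] = A[:, j]
            p_obs[:, j] = np.exp(-0.5 * (A[:, j] - mu) ** 2 / s2) / np.sqrt(2 * np.pi * s2)
        X[:, j] = c.rho * X[:, j - 1] + c.kappa * lvl[:, j] + c.sd_x * zx
        Y[:, j] = (c.theta0 + c.theta_a * lvl[:, 1:j + 1].sum(axis=1)
                   + c.theta_x * X[:, j] + c.sd_y * zy)

    X_out = np.exp(X / 2.0) if c.misspecification == "transform" else X

    schema = schema_for(c.treatment_kind)
    obs = R.astype(bool)
    rows = {
        "id": np.repeat(np.arange(n), T + 1),
        "visit": np.tile(np.arange(T + 1), n),
        "r": R.ravel(),
        "x": np.where(obs, X_out, np.nan).ravel(),
        "v": np.repeat(V, T + 1),
        "y": np.where(obs, Y, np.nan).ravel(),
    }
    if c.treatment_kind == "ordinal":
        rows["a0"] = np.where(obs, A0, np.nan).ravel()
        rows["a1"] = np.where(obs, A1, np.nan).ravel()
    else:
        rows["a"] = np.where(obs, A, np.nan).ravel()
    table = PersonPeriodTable(pd.DataFrame(rows), schema, T=T)

    gamma = {}
    if c.rho == 0.0:
        gamma = {"1": c.theta0, "cum:trt": c.theta_a, "cur:trt": c.theta_x * c.kappa}
    truth = TruthRecord(gamma, c.seed, c.hash(), p_obs=p_obs, pi=pi_true)
    return table, truth


def potential_outcome_means(config: SimulationConfig, sequence) -> np.ndarray:
    """Exact E(Y_j^abar) for a fixed treatment-level sequence (a_1..a_T).

    Under the linear-Gaussian confounder and outcome laws,
    ``E(X_j^abar) = kappa * sum_{l<=j} rho^(j-l) a_l`` and therefore
    ``E(Y_j^abar) = theta0 + theta_a * sum_{l<=j} a_l + theta_x E(X_j^abar)``.
    """
    a = np.asarray(sequence, dtype=float)
    if len(a) != config.T:
        raise ConfigError("sequence length must equal T")
    out = np.empty(config.T)
    for j in range(1, config.T + 1):
        ex = config.kappa * sum(config.rho ** (j - l) * a[l - 1] for l in range(1, j + 1))
        out[j - 1] = config.theta0 + config.theta_a * a[:j].sum() + config.theta_x * ex
    return out


def true_msm_parameters(config: SimulationConfig, design: MSMSpec) -> TruthRecord:
    """Closed-form true gamma for the {cumulative, current} design (rho = 0)."""
    if config.rho != 0.0:
        raise ConfigError("the {cumulative, current} MSM is only exact at rho = 0; "
                          "use potential_outcome_means for rho > 0")
    known = {"1": config.theta0, "cum:trt": config.theta_a,
             "cur:trt": config.theta_x * config.kappa}
    missing = [t for t in design.terms if t not in known]
    if missing:
        raise ConfigError(f"no closed-form truth for design terms {missing}")
    return TruthRecord({t: known[t] for t in design.terms}, config.seed, config.hash())


# ------------------------------------------------------------ analysis helpers

def default_treatment_spec(kind: str) -> ProcessModelSpec:
    """Correctly specified (up to covariate transforms) analysis models."""
    den = ["1", "lag1:trt", "lag1:x", "v"]
    num = ["1", "lag1:trt"]
    if kind == "ordinal":
        return ProcessModelSpec("ordinal_two_stage",
                                {"stage0": den, "stage1": list(den)},
                                {"stage0": num, "stage1": list(num)})
    if kind == "binary":
        return ProcessModelSpec("binary_logistic", den, num)
    return ProcessModelSpec(
        "continuous_heteroscedastic",
        {"mean": den, "var": ["1", "lag1:x"]},
        {"mean": num, "var": ["1"]},
    )


DEFAULT_H_TERMS = ["1", "lag1:x", "lag1:trt"]
DEFAULT_MSM = MSMSpec(["1", "cum:trt", "cur:trt"])


def _fit_treatment(table, spec):
    return {"binary_logistic": fit_binary_treatment_model,
            "ordinal_two_stage": fit_ordinal_treatment_model,
            "continuous_heteroscedastic": fit_continuous_treatment_model}[spec.kind](table, spec)


def _treat_block(table, model):
    if model.spec.kind == "continuous_heteroscedastic":
        return build_continuous_restrictions(table, model)
    return build_treatment_restrictions(table, model)


def _gamma(table, weights, msm_spec):
    return fit_msm(table, weights, msm_spec).gamma


def _est_unweighted(table, truth, msm_spec):
    return _gamma(table, np.ones(table.m), msm_spec)


def _est_true_weights(table, truth, msm_spec):
    p = table.gather(np.asarray(truth.p_obs))
    pi = table.gather(np.asarray(truth.pi))
    w = np.exp(table.cumulate(-np.log(p) - np.log(pi)))
    return _gamma(table, w, msm_spec)


def _make_mle(censor: bool):
    def est(table, truth, msm_spec):
        treat = _fit_treatment(table, default_treatment_spec(table.schema.treatment_kind))
        cens = (fit_censoring_model(table, ProcessModelSpec("censoring_logistic", DEFAULT_H_TERMS))
                if censor else None)
        return _gamma(table, compute_initial_weights(table, treat, cens), msm_spec)
    return est


def _make_cal1(censor: bool):
    def est(table, truth, msm_spec):
        treat = _fit_treatment(table, default_treatment_spec(table.schema.treatment_kind))
        blocks = [_treat_block(table, treat)]
        if censor:
            cens = fit_censoring_model(table, ProcessModelSpec("censoring_logistic", DEFAULT_H_TERMS))
            blocks.append(build_censoring_restrictions(table, DEFAULT_H_TERMS))
        else:
            cens = None
            blocks.append(build_normalization_restrictions(table))
        w0 = compute_initial_weights(table, treat, cens)
        res = solve_type1(w0, assemble_system(blocks))
        return _gamma(table, res, msm_spec)
    return est


def _est_cal2_iptw(table, truth, msm_spec):
    treat = _fit_treatment(table, default_treatment_spec(table.schema.treatment_kind))
    system = assemble_system([_treat_block(table, treat)])
    res = solve_type2(table, treat, system)
    if not res.converged:
        raise CalibrationError("Type 2 did not converge")
    return _gamma(table, res, msm_spec)


ESTIMATORS = {
    "unweighted": _est_unweighted,
    "mle_iptw": _make_mle(censor=False),
    "mle_iptcw": _make_mle(censor=True),
    "cal1_iptw": _make_cal1(censor=False),
    "cal1_iptcw": _make_cal1(censor=True),
    "cal2_iptw": _est_cal2_iptw,
    "true_weights": _est_true_weights,
}


def run_replication_study(config: SimulationConfig, reps: int,
                          estimators: list[str] | None = None,
                          seed: int = 0,
                          msm_spec: MSMSpec = DEFAULT_MSM,
                          return_draws: bool = False):
    """Monte-Carlo comparison of IPW estimators on repeated scenarios.

    For each replicate a fresh cohort is drawn and every requested
    estimator is applied; the summary reports per-coefficient bias,
    standard deviation, MSE, median absolute error and the count of
    convergence failures.  Estimator failures (e.g. Type 2 with
    censoring) are recorded, not raised.
    """
    estimators = estimators or ["unweighted", "mle_iptcw", "cal1_iptcw", "true_weights"]
    unknown = set(estimators) - set(ESTIMATORS)
    if unknown:
        raise ConfigError(f"unknown estimators: {sorted(unknown)}")
    truth_rec = true_msm_parameters(config, msm_spec)
    truth = np.array([truth_rec.true_gamma[t] for t in msm_spec.terms])

    import warnings as _w
    rep_seeds = np.random.SeedSequence(seed).generate_state(reps) % (2 ** 31)
    draws = {e: np.full((reps, len(msm_spec.terms)), np.nan) for e in estimators}
    fails = {e: 0 for e in estimators}
    for r in range(reps):
        table, tr = generate_scenario(replace(config, seed=int(rep_seeds[r])))
        for e in estimators:
            try:
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    draws[e][r] = ESTIMATORS[e](table, tr, msm_spec)
            except (CbmsmError, np.linalg.LinAlgError):
                fails[e] += 1

    rows = []
    for e in estimators:
        G = draws[e]
        ok = ~np.isnan(G[:, 0])
        for k, term in enumerate(msm_spec.terms):
            g = G[ok, k]
            err = g - truth[k]
            bias = float(err.mean()) if len(g) else np.nan
            var = float(err.var(ddof=0)) if len(g) else np.nan
            rows.append({
                "estimator": e, "term": term, "truth": truth[k],
                "bias": bias,
                "sd": float(g.std(ddof=1)) if len(g) > 1 else np.nan,
                "mse": bias ** 2 + var if len(g) else np.nan,
                "mae": float(np.median(np.abs(err))) if len(g) else np.nan,
                "n_fail": fails[e], "reps_used": int(ok.sum()),
            })
    summary = pd.DataFrame(rows)
    return (summary, draws) if return_draws else summary
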