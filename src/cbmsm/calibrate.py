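"""Solving the calibration restriction system for balanced weights.

Two routes are implemented:

* **Type 1** (exponential tilting): calibrated weights take the form
  ``W*(lam) = W o exp(K lam)`` where W are initial (e.g. MLE) weights.
  Solving ``K'W*(lam) = l`` is equivalent to minimizing the strictly
  convex function ``1'{W o exp(K lam)} - l'lam``, so the solution is
  unique and found by a damped Newton method.

* **Type 2** (estimating equations): calibrated weights keep the standard
  inverse-probability form ``W(alpha^, beta, theta)`` but the model
  parameters (beta, theta) themselves are chosen to satisfy the moment
  conditions, by generic root finding.  This route may legitimately fail
  to converge or admit multiple solutions; both outcomes are reported via
  flags rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import root

from .exceptions import CalibrationError, ConfigError
from .panel import PersonPeriodTable
from .process_models import FittedProcessModel, WeightSet
from .restrictions import RestrictionSystem

__all__ = ["CalibrationResult", "CalibrationDiagnostics",
           "solve_type1", "solve_type2", "diagnose"]


@dataclass
class CalibrationResult:
    method: str
    lam: np.ndarray
    weights_star: np.ndarray
    residuals: np.ndarray
    converged: bool
    iterations: int
    objective_value: float = np.nan
    multiple_solution_flag: bool = False
    n_solutions: int = 1
    tilt: np.ndarray | None = None  # Type 1 multiplicative factor exp(k_i' lam)

    def weights_frame(self, index) -> pd.DataFrame:
        ids, visits = zip(*index) if len(index) else ((), ())
        return pd.DataFrame({"id": ids, "visit": visits, "weight": self.weights_star})


@dataclass
class CalibrationDiagnostics:
    residual_norm: float
    calibration_factor_variance: float
    max_weight: float
    ess_by_visit: dict
    balance_table: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "residual_norm": self.residual_norm,
            "calibration_factor_variance": self.calibration_factor_variance,
            "max_weight": self.max_weight,
            "ess_by_visit": self.ess_by_visit,
            "balance": self.balance_table.to_dict(orient="list"),
        }


# ------------------------------------------------------------------ Type 1

def _objective(w, K, l, lam):
    u = np.clip(K @ lam, -700.0, 40.0)  # clipped inside line search only
    return float(np.sum(w * np.exp(u)) - l @ lam)


def solve_type1(initial: WeightSet | np.ndarray, system: RestrictionSystem,
                gtol: float = 1e-8, maxiter: int = 200,
                start: np.ndarray | None = None) -> CalibrationResult:
    """Minimize the convex tilting objective by damped Newton.

    Gradient ``K'(W o exp(K lam)) - l`` and Hessian
    ``K' diag(W o exp(K lam)) K``; Armijo backtracking line search;
    convergence when the gradient max-norm falls below ``gtol``.
    Raises :class:`CalibrationError` with a direction certificate when the
    targets are infeasible for positive weights (objective unbounded
    below).
    """
    w = initial.w_product if isinstance(initial, WeightSet) else np.asarray(initial, float)
    if np.any(w <= 0) or not np.isfinite(w).all():
        raise CalibrationError("initial weights must be strictly positive and finite")
    K, l = system.K, system.l
    m, r = K.shape
    if len(w) != m:
        raise CalibrationError(f"weight vector length {len(w)} != system rows {m}")
    lam = np.zeros(r) if start is None else np.asarray(start, float).copy()

    f = _objective(w, K, l, lam)
    it = 0
    for it in range(1, maxiter + 1):
        u = K @ lam
        if np.max(np.abs(u)) > 200.0:
            raise CalibrationError(
                "calibration targets appear infeasible for positive weights "
                "(objective unbounded below); descent direction: "
                f"{np.round(lam / max(np.linalg.norm(lam), 1e-300), 3)}")
        wstar = w * np.exp(u)
        g = K.T @ wstar - l
        if np.max(np.abs(g)) <= gtol:
            break
        H = K.T @ (wstar[:, None] * K)
        try:
            step = np.linalg.solve(H + 1e-12 * np.trace(H) / r * np.eye(r), -g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, -g, rcond=None)[0]
        if not np.isfinite(step).all() or g @ step >= 0:
            step = -g / max(np.linalg.norm(g), 1.0)  # quasi-Newton fallback
        # Armijo backtracking
        t, slope = 1.0, g @ step
        while t > 1e-13:
            f_new = _objective(w, K, l, lam + t * step)
            if f_new <= f + 1e-4 * t * slope:
                break
            t *= 0.5
        else:
            break  # stalled: no further progress possible
        lam = lam + t * step
        f = f_new
    u = K @ lam
    wstar = w * np.exp(u)
    g = K.T @ wstar - l
    converged = bool(np.max(np.abs(g)) <= gtol)
    if not converged:
        if np.max(np.abs(g)) <= 1e-6 * max(1.0, np.max(np.abs(l))):
            converged = True  # progress limited by floating point, residual tiny
        else:
            raise CalibrationError(
                f"Type 1 solver did not converge in {it} iterations "
                f"(gradient max-norm {np.max(np.abs(g)):.3e})")
    lam_out, resid = lam, g
    if system.column_scale is not None:  # report in original column units
        lam_out = lam / system.column_scale
        resid = g * system.column_scale
    return CalibrationResult("type1", lam_out, wstar, resid, converged, it,
                             objective_value=f, tilt=np.exp(u))


# ------------------------------------------------------------------ Type 2

def _log_den_factor(table: PersonPeriodTable, model: FittedProcessModel,
                    params: dict) -> np.ndarray:
    """Row-aligned log denominator likelihood factor at given parameters."""
    s, kind = table.schema, model.spec.kind

    def logistic_ll(y, eta):
        # y*log(p) + (1-y)*log(1-p), numerically stable
        return y * eta - np.logaddexp(0.0, eta)

    if kind == "binary_logistic":
        a = table.gather(table.wide(s.treatment))
        return logistic_ll(a, model.designs["den"] @ params["beta"])
    if kind == "ordinal_two_stage":
        a0 = table.gather(table.wide(s.treatment0))
        a1 = table.gather(table.wide(s.treatment1))
        ll = logistic_ll(a0, model.designs["den_stage0"] @ params["beta0"])
        eta1 = model.designs["den_stage1"] @ params["beta1"]
        return ll + a0 * logistic_ll(a1, eta1)
    if kind == "continuous_heteroscedastic":
        a = table.gather(table.wide(s.treatment))
        mu = model.designs["den_mean"] @ params["beta_mu"]
        sl = np.clip(model.designs["den_var"] @ params["beta_sigma"], -40, 40)
        return -0.5 * (np.log(2 * np.pi) + sl + (a - mu) ** 2 * np.exp(-sl))
    raise ConfigError(f"unsupported treatment kind for Type 2: {kind}")


def _param_layout(treat: FittedProcessModel, cens: FittedProcessModel | None):
    names = {"binary_logistic": ["beta"], "ordinal_two_stage": ["beta0", "beta1"],
             "continuous_heteroscedastic": ["beta_mu", "beta_sigma"]}[treat.spec.kind]
    layout = [(k, len(treat.coefficients[k])) for k in names]
    if cens is not None:
        if cens.coefficients.get("theta") is None:
            raise ConfigError("Type 2 with censoring requires a fitted censoring model "
                              "with at least one censoring event")
        layout.append(("theta", len(cens.coefficients["theta"])))
    return layout


def solve_type2(table: PersonPeriodTable, treat: FittedProcessModel,
                system: RestrictionSystem, cens: FittedProcessModel | None = None,
                tol: float = 1e-8, n_starts: int = 3, seed: int = 0,
                perturb_scale: float = 0.25) -> CalibrationResult:
    """Re-estimate the weight-model parameters to satisfy the moment conditions.

    The numerator fit (alpha^) stays fixed at its MLE; the free parameters
    are the denominator treatment coefficients (and censoring coefficients
    when a censoring model is supplied), whose count must equal the number
    of restrictions.  Root finding starts at the MLE and at random
    perturbations of it; solutions differing beyond proportionality set
    ``multiple_solution_flag``.  Non-convergence is reported via the
    ``converged`` flag — an expected outcome for hard IPTCW systems.
    """
    layout = _param_layout(treat, cens)
    npar = sum(p for _, p in layout)
    if npar != system.r:
        raise ConfigError(f"Type 2 requires #parameters ({npar}) == #restrictions "
                          f"({system.r}); drop normalization rows for IPTW-only use")
    if system.column_scale is not None:
        raise ConfigError("Type 2 expects an unstandardized restriction system")

    from .process_models import _category_prob  # numerator factors are fixed
    log_num = np.log(np.clip(_category_prob(table, treat, "num"), 1e-300, None))
    cens_X = cens.designs["unc"] if cens is not None else None

    def unpack(x):
        out, k = {}, 0
        for name, p in layout:
            out[name] = x[k:k + p]
            k += p
        return out

    def weights_of(x):
        p = unpack(x)
        logf = log_num - _log_den_factor(table, treat, p)
        if cens is not None:
            logf = logf + np.logaddexp(0.0, -(cens_X @ p["theta"]))  # -log pi
        return np.exp(np.clip(table.cumulate(logf), -500, 500))

    def resid(x):
        return system.K.T @ weights_of(x) - system.l

    x_mle = np.concatenate([treat.coefficients[n] if n != "theta"
                            else cens.coefficients["theta"] for n, _ in layout])
    rng = np.random.default_rng(seed)
    starts = [x_mle] + [x_mle + perturb_scale * (1 + np.abs(x_mle)) *
                        rng.standard_normal(npar) for _ in range(n_starts - 1)]

    sols, nfev = [], 0
    for x0 in starts:
        r = root(resid, x0, method="hybr")
        nfev += r.nfev
        if np.max(np.abs(r.fun)) <= max(tol, 1e-8 * max(1.0, np.max(np.abs(system.l)))):
            sols.append((np.max(np.abs(r.fun)), r.x))

    if not sols:
        w = weights_of(x_mle)
        return CalibrationResult("type2", x_mle, w, system.K.T @ w - system.l,
                                 converged=False, iterations=nfev)
    sols.sort(key=lambda t: t[0])
    best = sols[0][1]
    w_best = weights_of(best)
    multiple = False
    ref = w_best / w_best.sum()
    for _, x in sols[1:]:
        wx = weights_of(x)
        if np.max(np.abs(wx / wx.sum() - ref)) > 1e-6:
            multiple = True
    return CalibrationResult("type2", best, w_best, system.K.T @ w_best - system.l,
                             converged=True, iterations=nfev,
                             multiple_solution_flag=multiple, n_solutions=len(sols))


# --------------------------------------------------------------- diagnostics

def diagnose(result: CalibrationResult, system: RestrictionSystem,
             initial: WeightSet) -> CalibrationDiagnostics:
    """Model-checking summaries after calibration.

    The variance of the multiplicative calibration factor ``exp(k_i'lam)``
    across person-periods is the headline check: it should be close to
    zero when the initial weights come from correctly specified models.
    """
    w0 = initial.w_product
    ws = result.weights_star
    tilt = result.tilt if result.tilt is not None else ws / w0
    visits = np.array([v for _, v in initial.index])
    ess = {}
    for j in np.unique(visits):
        wj = ws[visits == j]
        ess[int(j)] = float(wj.sum() ** 2 / np.sum(wj ** 2))
    m = max(system.m, 1)
    bal = pd.DataFrame({
        "label": system.labels,
        "target": system.l * (system.column_scale if system.column_scale is not None else 1.0),
        "pre": system.K.T @ w0, "post": system.K.T @ ws,
    })
    if system.column_scale is not None:
        bal["pre"] *= system.column_scale
        bal["post"] *= system.column_scale
    bal["pre_per_obs"] = (bal["pre"] - bal["target"]) / m
    bal["post_per_obs"] = (bal["post"] - bal["target"]) / m
    return CalibrationDiagnostics(
        residual_norm=float(np.max(np.abs(result.residuals))) if system.r else 0.0,
        calibration_factor_variance=float(np.var(tilt)),
        max_weight=float(ws.max()),
        ess_by_visit=ess,
        balance_table=bal,
    )
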