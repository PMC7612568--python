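"""Config-driven pipeline: load -> fit models -> weights -> calibrate -> MSM.

The run configuration is a plain mapping (usually parsed from YAML) with
blocks ``schema``, ``treatment_model``, ``censoring_model`` (optional),
``calibration`` and ``msm``; see the CLI reference in the README for the
full field list.  The same pipeline object serves the command-line entry
points, the bootstrap, and the replication runner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import __version__
from .calibrate import (CalibrationDiagnostics, CalibrationResult, diagnose,
                        solve_type1, solve_type2)
from .exceptions import ConfigError
from .msm import MSMFit, MSMSpec, bootstrap_se, fit_msm
from .panel import PanelSchema, PersonPeriodTable, load_panel, uncensored_index
from .process_models import (FittedProcessModel, ProcessModelSpec, WeightSet,
                             compute_initial_weights, fit_binary_treatment_model,
                             fit_censoring_model, fit_continuous_treatment_model,
                             fit_ordinal_treatment_model)
from .restrictions import (RestrictionSystem, assemble_system,
                           build_censoring_restrictions,
                           build_continuous_restrictions,
                           build_normalization_restrictions,
                           build_treatment_restrictions)

__all__ = ["PipelineResult", "validate_config", "run_pipeline", "make_estimator"]

_TREAT_FITTERS = {
    "binary_logistic": fit_binary_treatment_model,
    "ordinal_two_stage": fit_ordinal_treatment_model,
    "continuous_heteroscedastic": fit_continuous_treatment_model,
}


@dataclass
class PipelineResult:
    table: PersonPeriodTable
    treatment_fit: FittedProcessModel
    censoring_fit: FittedProcessModel | None
    initial_weights: WeightSet
    system: RestrictionSystem | None
    calibration: CalibrationResult | None
    diagnostics: CalibrationDiagnostics | None
    msm_fit: MSMFit
    run_log: dict

    def final_weights(self) -> np.ndarray:
        if self.calibration is not None:
            return self.calibration.weights_star
        return self.initial_weights.w_product

    def write_artifacts(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        idx = uncensored_index(self.table)
        if self.calibration is not None:
            self.calibration.weights_frame(idx).to_csv(out / "weights.csv", index=False)
        else:
            import pandas as pd
            ids, visits = zip(*idx)
            pd.DataFrame({"id": ids, "visit": visits,
                          "weight": self.final_weights()}).to_csv(
                out / "weights.csv", index=False)
        self.msm_fit.coefficient_table().to_csv(out / "coefficients.csv", index=False)
        if self.diagnostics is not None:
            self.diagnostics.balance_table.to_csv(out / "balance.csv", index=False)
        with open(out / "run_log.json", "w") as fh:
            json.dump(self.run_log, fh, indent=2, default=str)


def validate_config(config: dict) -> dict:
    """Check internal consistency before any computation."""
    for key in ("schema", "treatment_model", "msm"):
        if key not in config:
            raise ConfigError(f"config is missing the {key!r} block")
    cal = config.get("calibration", {}) or {}
    method = cal.get("method", "type1")
    if method not in ("none", "type1", "type2"):
        raise ConfigError(f"unknown calibration method {method!r}")
    blocks = list(cal.get("blocks", ["treatment"]))
    if "censoring" in blocks and "normalization" in blocks:
        raise ConfigError("calibration blocks 'censoring' and 'normalization' are "
                          "mutually exclusive (normalization is redundant)")
    if "censoring" in blocks and "censoring_model" not in config:
        raise ConfigError("a censoring block requires a censoring_model config block")
    if method == "type2" and "normalization" in blocks:
        raise ConfigError("Type 2 uses no normalization rows (parameter count must "
                          "equal the number of moment conditions)")
    unknown = set(blocks) - {"treatment", "censoring", "normalization"}
    if unknown:
        raise ConfigError(f"unknown restriction blocks: {sorted(unknown)}")
    return {"method": method, "blocks": blocks, "cal": cal}


def _treatment_spec(cfg: dict) -> ProcessModelSpec:
    kind = cfg.get("kind")
    if kind not in _TREAT_FITTERS:
        raise ConfigError(f"unknown treatment model kind {kind!r}")
    return ProcessModelSpec(kind, cfg.get("denominator"), cfg.get("numerator"))


def run_pipeline(config: dict, table: PersonPeriodTable | None = None) -> PipelineResult:
    """Execute the full estimation pipeline for one panel.

    ``table`` may be passed directly (bootstrap, simulations); otherwise
    ``config['input']`` is loaded through the declared schema.
    """
    v = validate_config(config)
    method, blocks = v["method"], v["blocks"]
    cal_cfg = v["cal"]

    if table is None:
        if "input" not in config:
            raise ConfigError("config has no 'input' path and no table was supplied")
        table = load_panel(config["input"], PanelSchema.from_dict(config["schema"]),
                           T=config.get("T"))

    t_spec = _treatment_spec(config["treatment_model"])
    treat = _TREAT_FITTERS[t_spec.kind](table, t_spec)
    cens = None
    if "censoring_model" in config:
        c_spec = ProcessModelSpec("censoring_logistic",
                                  config["censoring_model"]["terms"])
        cens = fit_censoring_model(table, c_spec)
    w0 = compute_initial_weights(table, treat,
                                 cens if "censoring" in blocks else None,
                                 rescale=cal_cfg.get("rescale"))

    system = calres = diags = None
    if method != "none":
        built = []
        for b in blocks:
            if b == "treatment":
                if t_spec.kind == "continuous_heteroscedastic":
                    built.append(build_continuous_restrictions(table, treat))
                else:
                    built.append(build_treatment_restrictions(table, treat))
            elif b == "censoring":
                built.append(build_censoring_restrictions(
                    table, config["censoring_model"]["terms"]))
            else:
                built.append(build_normalization_restrictions(table))
        system = assemble_system(built, standardize=bool(cal_cfg.get("standardize", False)))
        if method == "type1":
            calres = solve_type1(w0, system, gtol=float(cal_cfg.get("gtol", 1e-8)),
                                 maxiter=int(cal_cfg.get("maxiter", 200)))
        else:
            calres = solve_type2(table, treat, system,
                                 cens=cens if "censoring" in blocks else None,
                                 seed=int(cal_cfg.get("seed", 0)),
                                 n_starts=int(cal_cfg.get("n_starts", 3)))
        diags = diagnose(calres, system, w0)

    msm_cfg = config["msm"]
    spec = MSMSpec(msm_cfg["terms"])
    fit = fit_msm(table, calres if calres is not None else w0, spec)
    B = int(msm_cfg.get("bootstrap", 0))
    if B:
        est = make_estimator(config)
        bs = bootstrap_se(table, est, B, seed=int(msm_cfg.get("seed", 0)),
                          labels=spec.labels)
        fit.se, fit.vcov = bs.se, bs.vcov
        fit.n_boot, fit.n_boot_failed = bs.n_boot, bs.n_boot_failed

    log = {
        "package_version": __version__,
        "seed": msm_cfg.get("seed", 0),
        "n": table.n, "T": table.T, "m": table.m,
        "calibration_method": method,
        "restriction_blocks": blocks,
        "r": None if system is None else system.r,
        "converged": None if calres is None else bool(calres.converged),
        "multiple_solutions": None if calres is None else bool(calres.multiple_solution_flag),
        "residual_norm": None if diags is None else diags.residual_norm,
        "calibration_factor_variance":
            None if diags is None else diags.calibration_factor_variance,
        "weight_clip_events": w0.n_clipped,
        "config_echo": {k: vv for k, vv in config.items() if k != "input"},
    }
    return PipelineResult(table, treat, cens, w0, system, calres, diags, fit, log)


def make_estimator(config: dict):
    """Callable table -> gamma re-running the whole pipeline (for bootstrap)."""
    cfg = {k: v for k, v in config.items() if k != "input"}
    cfg = json.loads(json.dumps(cfg))  # deep copy
    cfg.setdefault("msm", {})
    cfg["msm"] = dict(cfg["msm"], bootstrap=0)

    def est(table: PersonPeriodTable) -> np.ndarray:
        return run_pipeline(cfg, table=table).msm_fit.gamma

    return est
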