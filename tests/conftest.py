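import numpy as np
import pandas as pd
import pytest

from cbmsm.panel import PanelSchema, PersonPeriodTable
from cbmsm.process_models import (ProcessModelSpec, compute_initial_weights,
                                  fit_censoring_model, fit_ordinal_treatment_model)
from cbmsm.restrictions import (assemble_system, build_censoring_restrictions,
                                build_treatment_restrictions)
from cbmsm.simulate import (DEFAULT_H_TERMS, SimulationConfig,
                            default_treatment_spec, generate_scenario)


def long_panel(records, schema):
    """Build a PersonPeriodTable from a list of row dicts."""
    return PersonPeriodTable(pd.DataFrame(records), schema)


@pytest.fixture(scope="session")
def binary_schema():
    return PanelSchema(treatment_kind="binary", treatment="a",
                       covariates=("x",), baseline=("v",), outcome="y")


@pytest.fixture(scope="session")
def toy_binary_table(binary_schema):
    """4 patients, T=1, A=(1,1,0,0), baseline-visit x=(1,-1,1,-1)."""
    rows = []
    for i, (a, x) in enumerate(zip((1, 1, 0, 0), (1.0, -1.0, 1.0, -1.0))):
        rows.append(dict(id=i, visit=0, r=1, a=0, x=x, v=0.0, y=0.0))
        rows.append(dict(id=i, visit=1, r=1, a=a, x=x, v=0.0, y=float(a)))
    return long_panel(rows, binary_schema)


@pytest.fixture(scope="session")
def sim_ordinal():
    """Moderate-size ordinal + censoring scenario (the default study design)."""
    return generate_scenario(SimulationConfig(n=500, T=3, seed=11))


@pytest.fixture(scope="session")
def sim_ordinal_fits(sim_ordinal):
    """Fitted models, initial weights and restriction system for sim_ordinal."""
    table, truth = sim_ordinal
    treat = fit_ordinal_treatment_model(table, default_treatment_spec("ordinal"))
    cens = fit_censoring_model(
        table, ProcessModelSpec("censoring_logistic", list(DEFAULT_H_TERMS)))
    w0 = compute_initial_weights(table, treat, cens)
    system = assemble_system([
        build_treatment_restrictions(table, treat),
        build_censoring_restrictions(table, list(DEFAULT_H_TERMS)),
    ])
    return {"table": table, "truth": truth, "treat": treat, "cens": cens,
            "w0": w0, "system": system}
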