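"""Term lists and design matrices over observed histories.

Process models (treatment assignment, censoring) regress an event at a
"risk visit" ``j`` on functionals of the history observed strictly before
``j``.  Terms are plain strings; products are formed with ``*``:

========================  ====================================================
atom                      value for the row at risk visit ``j``
========================  ====================================================
``1``                     constant
``visit``                 the risk visit index ``j`` (numeric)
``visit==k``              indicator that ``j == k``
``lagL:NAME``             column ``NAME`` at visit ``j-L`` (L >= 1)
``NAME``                  baseline covariate ``NAME`` (constant in time)
========================  ====================================================

``NAME`` may be any time-varying covariate, treatment column, the outcome
column, or the derived numeric treatment level ``trt`` (binary value,
ordinal level 0/1/2, or the continuous dose; 0 at baseline).  Lags must
stay inside the panel: ``lag1`` at risk visit 1 reads the baseline value.

The same vocabulary, with lags taken relative to the risk visit, describes
the censoring balance functionals H̃: evaluated "at history time j-1" for
risk visit ``j``, so visit indicators refer to the visit whose retention is
being modelled.
"""

from __future__ import annotations

import numpy as np

from .exceptions import SpecTermError
from .panel import PersonPeriodTable

__all__ = ["design_matrix", "eval_terms_at_risk", "validate_history_terms",
           "validate_treatment_only_terms"]


def _split_product(term: str) -> list[str]:
    return [a.strip() for a in term.split("*")]


def _eval_atom(table: PersonPeriodTable, atom: str, risk: int, rows: np.ndarray) -> np.ndarray:
    """Evaluate one atom at risk visit ``risk`` for the patient rows ``rows``."""
    n = len(rows)
    if atom == "1":
        return np.ones(n)
    if atom == "visit":
        return np.full(n, float(risk))
    if atom.startswith("visit=="):
        k = int(atom.split("==", 1)[1])
        return np.full(n, 1.0 if risk == k else 0.0)
    if atom.startswith("lag"):
        head, _, name = atom.partition(":")
        if not name:
            raise SpecTermError(f"malformed lag atom {atom!r}")
        try:
            L = int(head[3:])
        except ValueError as e:
            raise SpecTermError(f"malformed lag atom {atom!r}") from e
        t = risk - L
        if t < 0:
            raise SpecTermError(
                f"term {atom!r} is undefined at risk visit {risk} (needs visit {t})"
            )
        return _column_wide(table, name)[rows, t]
    if atom in table.schema.baseline:
        return _column_wide(table, atom)[rows, 0]
    raise SpecTermError(
        f"unknown term atom {atom!r}; time-varying columns must be lagged (lag1:{atom})"
    )


def _column_wide(table: PersonPeriodTable, name: str) -> np.ndarray:
    s = table.schema
    valid = set(s.covariates) | set(s.baseline) | set(s.treatment_columns) | {s.outcome, "trt"}
    if name not in valid:
        raise SpecTermError(f"unknown column {name!r} in term")
    return table.wide(name)


def eval_terms_at_risk(table: PersonPeriodTable, terms: list[str], risk: int,
                       rows: np.ndarray) -> np.ndarray:
    """Design block (len(rows), p) for the given risk visit."""
    cols = []
    for term in terms:
        v = np.ones(len(rows))
        for atom in _split_product(term):
            v = v * _eval_atom(table, atom, risk, rows)
        cols.append(v)
    return np.column_stack(cols) if cols else np.empty((len(rows), 0))


def design_matrix(table: PersonPeriodTable, terms: list[str],
                  shift: int = 0) -> np.ndarray:
    """Design matrix aligned to the uncensored person-period index.

    Row (i, j) is evaluated at risk visit ``j + shift``; ``shift=1`` gives
    the "next visit" evaluation H̃_ij used by the telescoped censoring
    restrictions (rows where ``j + shift > T`` are set to 0 — they always
    carry a zero coefficient there).
    """
    ii, jj = table.uncensored_arrays()
    out = np.zeros((len(ii), len(terms)))
    for j in range(1, table.T + 1):
        mask = jj == j
        if not mask.any():
            continue
        risk = j + shift
        if risk > table.T:
            continue  # multiplied by (T - j) = 0 downstream
        out[mask] = eval_terms_at_risk(table, terms, risk, ii[mask])
    return out


def validate_history_terms(table: PersonPeriodTable, terms: list[str]) -> None:
    """Check a term list is well formed and includes the constant."""
    if "1" not in terms:
        raise SpecTermError("every term list must include the constant term '1'")
    if len(set(terms)) != len(terms):
        raise SpecTermError("duplicate terms in term list")
    ii, jj = table.uncensored_arrays()
    if len(ii):
        j0 = int(jj.min())
        eval_terms_at_risk(table, terms, j0, ii[jj == j0][:1])  # raises on bad atoms


def validate_treatment_only_terms(table: PersonPeriodTable, terms: list[str]) -> None:
    """Numerator (stabilization) terms may involve treatment history only."""
    allowed = set(table.schema.treatment_columns) | {"trt"}
    for term in terms:
        for atom in _split_product(term):
            if atom == "1" or atom == "visit" or atom.startswith("visit=="):
                continue
            if atom.startswith("lag"):
                name = atom.partition(":")[2]
                if name in allowed:
                    continue
            raise SpecTermError(
                f"numerator term {term!r} depends on more than treatment history"
            )
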