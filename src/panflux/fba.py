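"""Flux balance analysis.

Maximizes the objective reaction flux subject to steady state (S v = 0)
and the flux bounds, as a linear program solved with HiGHS.  Only the
optimum value is contractually meaningful; the returned flux vector is
one optimal solution among possibly many.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

from .model import Model

#: objective flux below this is considered zero growth
GROWTH_TOL = 1e-6


@dataclass
class FbaResult:
    status: str  # optimal | infeasible
    objective_value: float
    fluxes: dict[str, float]

    def grows(self, threshold: float = GROWTH_TOL) -> bool:
        return self.status == "optimal" and self.objective_value >= threshold


def run_fba(model: Model, objective: str | None = None) -> FbaResult:
    """Maximize ``objective`` (default: the model's objective reaction).

    A model whose objective cannot carry flux is reported optimal with
    value 0, not infeasible; "infeasible" is reserved for genuinely
    contradictory constraints.
    """
    objective = objective or model.objective
    if objective is None or objective not in model.reactions:
        raise ValueError(f"objective reaction {objective!r} not in model")
    rids = sorted(model.reactions)
    mids = sorted(model.metabolites)
    ridx = {r: i for i, r in enumerate(rids)}
    midx = {m: i for i, m in enumerate(mids)}
    n, m = len(rids), len(mids)
    S = lil_matrix((m, n))
    for rid, rxn in model.reactions.items():
        j = ridx[rid]
        for mid, coef in rxn.stoichiometry.items():
            S[midx[mid], j] = coef
    c = np.zeros(n)
    c[ridx[objective]] = -1.0  # linprog minimizes
    bounds = [(model.reactions[r].lower_bound, model.reactions[r].upper_bound)
              for r in rids]
    res = linprog(c, A_eq=S.tocsr(), b_eq=np.zeros(m), bounds=bounds,
                  method="highs")
    if res.status == 2:
        return FbaResult("infeasible", 0.0, {})
    if not res.success:
        raise RuntimeError(f"LP solver failure: {res.message}")
    fluxes = {r: float(res.x[ridx[r]]) for r in rids}
    return FbaResult("optimal", float(-res.fun), fluxes)


def maximize_demand(model: Model, metabolite_id: str) -> FbaResult:
    """Maximize the production capability of a metabolite.

    Adds a temporary demand reaction consuming the metabolite and
    maximizes its flux; the model is not mutated.
    """
    if metabolite_id not in model.metabolites:
        raise KeyError(metabolite_id)
    probe = model.copy()
    did = f"DM_{metabolite_id}__probe"
    from .model import Reaction  # local import to avoid cycle at module load
    probe.add_reaction(Reaction(did, name=f"probe demand {metabolite_id}",
                                stoichiometry={metabolite_id: -1.0},
                                lower_bound=0.0))
    return run_fba(probe, objective=did)
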