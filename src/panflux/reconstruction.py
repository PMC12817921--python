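"""Reference-free carving of a draft pan-model and penalty gap-filling.

A *universe* is a repository model whose GPR leaves are universal gene
ids with known protein sequences.  Cluster representatives are aligned
one-way against those sequences; a universe reaction is carried into
the draft pan-model only when its GPR, rewritten in cluster space, is
satisfiable — for an enzyme complex (AND) every subunit must have a
supporting cluster; isoforms (OR) are kept whenever any branch
survives.  This is deliberately conservative: a reaction is never
included on partial complex evidence.

Gap-filling adds a minimum-total-penalty set of repository reactions so
the model reaches a required objective flux on a medium; penalties
derive from the alignment support of each reaction (well-supported
reactions are cheap to add), and the search is solved exactly as a
mixed-integer linear program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import lil_matrix

from . import gpr as gpr_mod
from .align import screened_align
from .fba import run_fba
from .model import BIG_BOUND, MediumRecipe, Model, Reaction, apply_medium
from .pangenome import Cluster


@dataclass
class Universe:
    """Repository model plus per-universal-gene protein sequences."""
    model: Model
    gene_sequences: dict[str, str]

    def __post_init__(self) -> None:
        for rxn in self.model.reactions.values():
            for g in rxn.gpr.genes():
                if g not in self.gene_sequences and not rxn.spontaneous:
                    raise ValueError(f"universal gene {g} has no sequence")


@dataclass(frozen=True)
class SupportHit:
    identity: float
    coverage: float  # of the universal gene

    @property
    def score(self) -> float:
        return self.identity * self.coverage


@dataclass
class GeneSupportMap:
    """universal gene id -> {cluster id -> SupportHit}"""
    hits: dict[str, dict[str, SupportHit]] = field(default_factory=dict)

    def clusters_for(self, gene: str) -> set[str]:
        return set(self.hits.get(gene, {}))

    def best_score(self, gene: str) -> float:
        h = self.hits.get(gene)
        return max((x.score for x in h.values()), default=0.0) if h else 0.0


@dataclass
class HomologyParams:
    id_min: float = 0.40
    cov_min: float = 0.70  # coverage of the universal gene


def map_clusters_to_universe(clusters: list[Cluster], universe: Universe,
                             params: HomologyParams = HomologyParams()
                             ) -> GeneSupportMap:
    """One-way alignment of each cluster representative against every
    universal gene; a pair supports when identity >= id_min and the
    universal gene is covered >= cov_min."""
    support = GeneSupportMap()
    for gene in sorted(universe.gene_sequences):
        useq = universe.gene_sequences[gene]
        for cl in clusters:
            stats = screened_align(useq, cl.rep_seq, params.id_min)
            if stats is None:
                continue
            if stats.identity >= params.id_min and stats.coverage_a >= params.cov_min:
                support.hits.setdefault(gene, {})[cl.id] = SupportHit(
                    stats.identity, stats.coverage_a)
    return support


def carve_draft_pan(universe: Universe, support: GeneSupportMap,
                    model_id: str = "draft_pan") -> Model:
    """Carve the draft pan-model: rewrite each universe GPR into cluster
    space and keep the reaction iff the rewritten rule is satisfiable or
    the reaction is spontaneous; add exchanges for every retained
    extracellular metabolite; objective = universe biomass."""
    um = universe.model
    if um.objective is None:
        raise ValueError("universe has no biomass/objective reaction")
    draft = Model(model_id, um.prefixes)
    kept: list[Reaction] = []
    for rid in sorted(um.reactions):
        rxn = um.reactions[rid]
        if um.is_boundary(rxn):
            continue  # boundary reactions re-added for surviving metabolites
        mapping = {g: sorted(support.clusters_for(g)) for g in rxn.gpr.genes()}
        new_gpr = gpr_mod.substitute(rxn.gpr, mapping)
        if new_gpr.is_unsatisfiable and not rxn.spontaneous:
            continue
        new = rxn.copy()
        new.gpr = gpr_mod.EMPTY if rxn.spontaneous else new_gpr
        kept.append(new)
    used: set[str] = set()
    for rxn in kept:
        used |= set(rxn.stoichiometry)
    for mid in sorted(used):
        draft.add_metabolite(um.metabolites[mid].copy())
    for rxn in kept:
        draft.add_reaction(rxn)
    # exchanges for retained extracellular metabolites, closed uptake
    for rid in sorted(um.reactions):
        rxn = um.reactions[rid]
        if um.boundary_kind(rxn) != "exchange":
            continue
        (mid,) = rxn.stoichiometry
        if mid in used:
            ex = rxn.copy()
            ex.lower_bound, ex.upper_bound = 0.0, BIG_BOUND
            draft.add_reaction(ex)
    if um.objective not in draft.reactions:
        raise ValueError("universe biomass was not retained in the carve")
    draft.objective = um.objective
    return draft


# ---------------------------------------------------------------------------
# penalties
# ---------------------------------------------------------------------------

P_MIN, P_MAX = 0.1, 10.0


def _fractional_support(g: gpr_mod.Gpr, score_of) -> float:
    if g.op == "empty":
        return 1.0
    if g.op == "false":
        return 0.0
    if g.op == "leaf":
        return score_of(g.gene)
    parts = [_fractional_support(c, score_of) for c in g.children]
    return min(parts) if g.op == "and" else max(parts)


def compute_penalties(universe: Universe, support: GeneSupportMap,
                      p_min: float = P_MIN, p_max: float = P_MAX
                      ) -> dict[str, float]:
    """Penalty per universe reaction: 1 - fractional GPR support, scaled
    to [p_min, p_max].  Fractional support takes the best branch of an
    OR and the weakest member of an AND (a complex is only as supported
    as its least-supported subunit).  Spontaneous and boundary reactions
    get p_min."""
    um = universe.model
    penalties: dict[str, float] = {}
    for rid, rxn in um.reactions.items():
        if rxn.spontaneous or um.is_boundary(rxn):
            penalties[rid] = p_min
            continue
        frac = _fractional_support(rxn.gpr, support.best_score)
        frac = min(max(frac, 0.0), 1.0)
        penalties[rid] = p_min + (1.0 - frac) * (p_max - p_min)
    return penalties


# ---------------------------------------------------------------------------
# gap-filling
# ---------------------------------------------------------------------------

@dataclass
class GapfillResult:
    status: str  # success | infeasible
    added: list[str]
    total_penalty: float
    achieved_flux: float
    medium: str


def _build_milp(model: Model, candidates: list[str], combined: Model,
                min_flux: float, penalties: dict[str, float]):
    rids = sorted(combined.reactions)
    mids = sorted(combined.metabolites)
    ridx = {r: i for i, r in enumerate(rids)}
    n, m, k = len(rids), len(mids), len(candidates)
    S = lil_matrix((m, n + k))
    midx = {mm: i for i, mm in enumerate(mids)}
    for rid, rxn in combined.reactions.items():
        for mid, coef in rxn.stoichiometry.items():
            S[midx[mid], ridx[rid]] = coef
    rows = [LinearConstraint(S.tocsr(), np.zeros(m), np.zeros(m))]
    # indicator coupling: lb_j*y_j <= v_j <= ub_j*y_j
    cidx = {c: n + i for i, c in enumerate(candidates)}
    A = lil_matrix((2 * k, n + k))
    lo = np.empty(2 * k)
    hi = np.empty(2 * k)
    for i, c in enumerate(candidates):
        rxn = combined.reactions[c]
        A[2 * i, ridx[c]] = 1.0
        A[2 * i, cidx[c]] = -rxn.upper_bound
        lo[2 * i], hi[2 * i] = -np.inf, 0.0
        A[2 * i + 1, ridx[c]] = 1.0
        A[2 * i + 1, cidx[c]] = -rxn.lower_bound
        lo[2 * i + 1], hi[2 * i + 1] = 0.0, np.inf
    if k:
        rows.append(LinearConstraint(A.tocsr(), lo, hi))
    lb = np.empty(n + k)
    ub = np.empty(n + k)
    for r in rids:
        lb[ridx[r]] = combined.reactions[r].lower_bound
        ub[ridx[r]] = combined.reactions[r].upper_bound
    assert combined.objective is not None
    lb[ridx[combined.objective]] = max(lb[ridx[combined.objective]], min_flux)
    lb[n:], ub[n:] = 0.0, 1.0
    integrality = np.zeros(n + k)
    integrality[n:] = 1
    c_vec = np.zeros(n + k)
    for cand in candidates:
        c_vec[cidx[cand]] = penalties.get(cand, 1.0)
    return rows, Bounds(lb, ub), integrality, c_vec, cidx


def gapfill_min_penalty(model: Model, repository: Model,
                        medium: MediumRecipe, min_flux: float,
                        penalties: dict[str, float] | None = None
                        ) -> tuple[GapfillResult, Model]:
    """Add a minimum-total-penalty set of repository reactions so the
    model reaches objective >= min_flux on the medium.

    Exact (MILP, HiGHS).  Among equal-penalty optima the result is made
    deterministic by iteratively forcing out candidates in descending id
    order, which keeps lexicographically small reaction ids.  Returns
    the result and the augmented model; on infeasibility the input model
    is returned unchanged.
    """
    if min_flux <= 0:
        raise ValueError("min_flux must be > 0")
    if penalties is None:
        penalties = {}
    candidates = sorted(r for r in repository.reactions if r not in model.reactions)
    # fast path: the model already grows
    grown = run_fba(apply_medium(model, medium, on_missing="warn"))
    if grown.status == "optimal" and grown.objective_value >= min_flux - 1e-9:
        return (GapfillResult("success", [], 0.0, grown.objective_value,
                              medium.name), model.copy())

    combined = model.copy()
    for mid in sorted(repository.metabolites):
        if mid not in combined.metabolites:
            combined.add_metabolite(repository.metabolites[mid].copy())
    for rid in candidates:
        combined.add_reaction(repository.reactions[rid].copy())
    combined = apply_medium(combined, medium, on_missing="warn")
    if combined.objective is None:
        combined.objective = model.objective
    rows, bounds, integrality, c_vec, cidx = _build_milp(
        model, candidates, combined, min_flux, penalties)

    def solve(extra_zero: set[str]):
        b = Bounds(bounds.lb.copy(), bounds.ub.copy())
        for cand in extra_zero:
            b.ub[cidx[cand]] = 0.0
        return milp(c_vec, constraints=rows, bounds=b,
                    integrality=integrality)

    res = solve(set())
    if res.status != 0:
        return (GapfillResult("infeasible", [], float("nan"), 0.0,
                              medium.name), model)
    best = float(res.fun)
    tol = 1e-6 + 1e-6 * abs(best)
    fixed_out: set[str] = set()
    chosen = {c for c in candidates if res.x[cidx[c]] > 0.5}
    for cand in sorted(candidates, reverse=True):
        if cand not in chosen:
            fixed_out.add(cand)
            continue
        trial = solve(fixed_out | {cand})
        if trial.status == 0 and float(trial.fun) <= best + tol:
            fixed_out.add(cand)
            chosen = {c for c in candidates if trial.x[cidx[c]] > 0.5}
    added = sorted(chosen)
    augmented = model.copy()
    for rid in added:
        rxn = repository.reactions[rid]
        for mid in rxn.stoichiometry:
            if mid not in augmented.metabolites:
                augmented.add_metabolite(repository.metabolites[mid].copy())
        augmented.add_reaction(rxn.copy())
    verify = run_fba(apply_medium(augmented, medium, on_missing="warn"))
    total = sum(penalties.get(r, 1.0) for r in added)
    return (GapfillResult("success", added, total,
                          verify.objective_value, medium.name), augmented)
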