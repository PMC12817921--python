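"""Constraint-based model data structures.

A :class:`Model` is a stoichiometric network: metabolites with optional
formula/charge, reactions with flux bounds and GPR rules, and a biomass
objective.  Ids follow the BiGG convention (compartment suffix on
metabolites, e.g. ``glc__D_e``; boundary reactions prefixed ``EX_``,
``SK_``/``sink_``, ``DM_``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .gpr import EMPTY, Gpr

#: default flux bound magnitude, mmol gDW^-1 h^-1
BIG_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style chemical formula ('C6H12O6') into element counts."""
    out: dict[str, int] = {}
    if not text:
        return out
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"bad formula {text!r}")
        out[m.group(1)] = out.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"bad formula {text!r}")
    return out


def format_formula(counts: Mapping[str, int]) -> str:
    """Render element counts as a Hill-ordered formula string."""
    elems = sorted(counts)
    if "C" in counts:
        elems = ["C"] + (["H"] if "H" in counts else []) + [
            e for e in elems if e not in ("C", "H")
        ]
    return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in elems)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: dict[str, int] = field(default_factory=dict)
    charge: int | None = None
    compartment: str = ""

    def copy(self) -> "Metabolite":
        return Metabolite(self.id, self.name, dict(self.formula), self.charge,
                          self.compartment)


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -BIG_BOUND
    upper_bound: float = BIG_BOUND
    gpr: Gpr = EMPTY
    spontaneous: bool = False
    annotations: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(f"{self.id}: lower bound exceeds upper bound")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return Reaction(self.id, self.name, dict(self.stoichiometry),
                        self.lower_bound, self.upper_bound, self.gpr,
                        self.spontaneous,
                        {k: list(v) for k, v in self.annotations.items()})


@dataclass
class BoundaryPrefixes:
    """Configurable id-prefix dialect for boundary reactions."""
    exchange: tuple[str, ...] = ("EX_",)
    sink: tuple[str, ...] = ("SK_", "sink_")
    demand: tuple[str, ...] = ("DM_",)


DEFAULT_PREFIXES = BoundaryPrefixes()


@dataclass
class MediumRecipe:
    """Named medium: exchanged metabolite (or exchange reaction) id ->
    maximum uptake rate (positive, mmol gDW^-1 h^-1)."""
    name: str
    uptakes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.uptakes.items():
            if v <= 0:
                raise ValueError(f"medium {self.name}: rate for {k} must be > 0")


@dataclass
class BalanceReport:
    element_imbalance: dict[str, float]
    charge_imbalance: float | None
    verdict: str  # balanced | unbalanced | undetermined

    @property
    def balanced(self) -> bool:
        return self.verdict == "balanced"


class Model:
    """A genome-scale metabolic model."""

    def __init__(self, id: str = "model",
                 prefixes: BoundaryPrefixes = DEFAULT_PREFIXES) -> None:
        self.id = id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective: str | None = None
        self.prefixes = prefixes

    # -- construction ------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id}")
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ValueError(f"{rxn.id}: unknown metabolites {missing}")
        self.reactions[rxn.id] = rxn
        return rxn

    def remove_reactions(self, ids: Iterable[str], prune_metabolites: bool = False) -> None:
        for rid in ids:
            self.reactions.pop(rid, None)
        if prune_metabolites:
            self.prune_unused_metabolites()

    def prune_unused_metabolites(self) -> list[str]:
        used: set[str] = set()
        for rxn in self.reactions.values():
            used |= set(rxn.stoichiometry)
        unused = [m for m in self.metabolites if m not in used]
        for m in unused:
            del self.metabolites[m]
        return unused

    def copy(self) -> "Model":
        out = Model(self.id, self.prefixes)
        out.metabolites = {k: v.copy() for k, v in self.metabolites.items()}
        out.reactions = {k: v.copy() for k, v in self.reactions.items()}
        out.objective = self.objective
        return out

    @property
    def compartments(self) -> set[str]:
        return {m.compartment for m in self.metabolites.values() if m.compartment}

    # -- boundary classification -------------------------------------
    def is_boundary(self, rxn: Reaction) -> bool:
        """Exchange/sink/demand: exactly one participating metabolite."""
        return len(rxn.stoichiometry) == 1

    def boundary_kind(self, rxn: Reaction) -> str | None:
        if not self.is_boundary(rxn):
            return None
        for kind in ("exchange", "sink", "demand"):
            if rxn.id.startswith(getattr(self.prefixes, kind)):
                return kind
        return "exchange"  # single-metabolite reactions default to exchange

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values()
                if self.boundary_kind(r) == "exchange"]

    def exchange_for(self, entry: str) -> Reaction | None:
        """Resolve a medium entry (exchange reaction id or exchanged
        metabolite id) to an exchange reaction of this model."""
        if entry in self.reactions and self.is_boundary(self.reactions[entry]):
            return self.reactions[entry]
        for rxn in self.exchanges():
            if entry in rxn.stoichiometry:
                return rxn
        return None


# ---------------------------------------------------------------------------
# balance checking
# ---------------------------------------------------------------------------

def check_balance(rxn: Reaction, metabolites: Mapping[str, Metabolite],
                  prefixes: BoundaryPrefixes = DEFAULT_PREFIXES) -> BalanceReport:
    """Mass/charge balance of a reaction under the given metabolite
    definitions.

    Boundary reactions (single participant) are "undetermined" by
    convention, as is any reaction with a participant lacking a formula
    or charge.  "balanced" requires every element and the charge to net
    exactly zero.
    """
    if len(rxn.stoichiometry) == 1:
        return BalanceReport({}, None, "undetermined")
    elements: dict[str, float] = {}
    charge = 0.0
    unknown = False
    for mid, coef in rxn.stoichiometry.items():
        met = metabolites[mid]
        if not met.formula or met.charge is None:
            unknown = True
            continue
        for el, cnt in met.formula.items():
            elements[el] = elements.get(el, 0.0) + coef * cnt
        charge += coef * met.charge
    elements = {el: v for el, v in elements.items() if abs(v) > 1e-9}
    if unknown:
        return BalanceReport(elements, None, "undetermined")
    if elements or abs(charge) > 1e-9:
        return BalanceReport(elements, charge, "unbalanced")
    return BalanceReport({}, 0.0, "balanced")


# ---------------------------------------------------------------------------
# orphan accounting
# ---------------------------------------------------------------------------

def count_orphans(model: Model) -> tuple[int, set[str], float]:
    """Count orphan reactions: no GPR, not spontaneous, not boundary,
    and whose name does not contain "diffusion" (case-insensitive).

    Returns (count, orphan ids, fraction over counted-eligible
    reactions).  Eligible means internal (non-boundary) and name without
    "diffusion"; the fraction is orphans / eligible.
    """
    orphans: set[str] = set()
    eligible = 0
    for rxn in model.reactions.values():
        if model.is_boundary(rxn):
            continue
        if "diffusion" in rxn.name.lower():
            continue
        eligible += 1
        if rxn.gpr.is_empty and not rxn.spontaneous:
            orphans.add(rxn.id)
    frac = len(orphans) / eligible if eligible else 0.0
    return len(orphans), orphans, frac


# ---------------------------------------------------------------------------
# medium application
# ---------------------------------------------------------------------------

def apply_medium(model: Model, recipe: MediumRecipe,
                 on_missing: str = "error") -> Model:
    """Return a copy of ``model`` constrained to ``recipe``.

    All exchange lower bounds are closed to 0, then each recipe entry's
    exchange lower bound is opened to -rate.  Non-exchange reactions are
    untouched.  Unresolvable entries raise (``on_missing="error"``) or
    warn and skip (``"warn"``).
    """
    if on_missing not in ("error", "warn"):
        raise ValueError("on_missing must be 'error' or 'warn'")
    out = model.copy()
    for rxn in out.exchanges():
        rxn.lower_bound = 0.0
    missing: list[str] = []
    for entry, rate in recipe.uptakes.items():
        rxn = out.exchange_for(entry)
        if rxn is None:
            missing.append(entry)
            continue
        rxn.lower_bound = -rate
    if missing:
        if on_missing == "error":
            raise KeyError(f"medium {recipe.name}: unresolvable entries {missing}")
        warnings.warn(f"medium {recipe.name}: skipped entries {missing}")
    return out


# ---------------------------------------------------------------------------
# species consensus models
# ---------------------------------------------------------------------------

def consensus_models(models: Mapping[str, Model],
                     species_of: Mapping[str, str],
                     pan_gprs: Mapping[str, Gpr] | None = None) -> dict[str, Model]:
    """One consensus model per species: the reactions always present in
    every strain model of that species.

    GPRs are taken from ``pan_gprs`` (cluster-space rules of the pan
    model) when given, else left empty.  Metabolites are restricted to
    those used.  An empty intersection yields a valid empty model plus a
    warning.
    """
    by_species: dict[str, list[str]] = {}
    for strain in models:
        by_species.setdefault(species_of[strain], []).append(strain)
    out: dict[str, Model] = {}
    for species, strains in sorted(by_species.items()):
        common: set[str] | None = None
        for s in strains:
            rids = set(models[s].reactions)
            common = rids if common is None else common & rids
        assert common is not None
        if not common:
            warnings.warn(f"species {species}: empty reaction intersection")
        template = models[strains[0]]
        cons = Model(f"consensus_{species}", template.prefixes)
        needed: set[str] = set()
        for rid in sorted(common):
            needed |= set(template.reactions[rid].stoichiometry)
        for mid in sorted(needed):
            cons.add_metabolite(template.metabolites[mid].copy())
        for rid in sorted(common):
            rxn = template.reactions[rid].copy()
            rxn.gpr = pan_gprs.get(rid, EMPTY) if pan_gprs else EMPTY
            cons.add_reaction(rxn)
        if template.objective in common:
            cons.objective = template.objective
        out[species] = cons
    return out


def models_equal(a: Model, b: Model) -> bool:
    """Structural equality on the documented field set (used by tests
    and round-trip checks)."""
    if set(a.metabolites) != set(b.metabolites):
        return False
    if set(a.reactions) != set(b.reactions):
        return False
    if a.objective != b.objective:
        return False
    for mid, ma in a.metabolites.items():
        mb = b.metabolites[mid]
        if (ma.formula, ma.charge, ma.compartment) != (mb.formula, mb.charge,
                                                       mb.compartment):
            return False
    for rid, ra in a.reactions.items():
        rb = b.reactions[rid]
        if ra.stoichiometry != rb.stoichiometry:
            return False
        if (ra.lower_bound, ra.upper_bound, ra.spontaneous) != (
                rb.lower_bound, rb.upper_bound, rb.spontaneous):
            return False
        if ra.gpr != rb.gpr:
            return False
    return True
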