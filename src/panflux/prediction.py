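"""FBA-based strain phenotype prediction and binary feature tables.

Three phenotype classes are predicted per strain model:

* substrate utilization — swap the medium's default C/N/P/S source for a
  candidate and ask whether growth persists;
* auxotrophy — biosynthetic incapacity: maximize a demand for the
  cytosolic compound on the unsupplemented minimal medium; a strain
  that cannot produce it is auxotrophic;
* biosynthetic potential — maximize a demand for a target metabolite on
  a given medium.

Outcomes are assembled into binary feature tables (BFTs): features in
rows (namespaced, e.g. ``C_source:xyl__D``), strains in columns, 0/1
cells.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import pandas as pd

from .derivation import DEFAULT_SOURCES
from .fba import maximize_demand, run_fba
from .model import MediumRecipe, Model, apply_medium

GROWTH_THRESHOLD = 1e-4


class BFT:
    """Binary feature table: rows = feature ids, columns = strains."""

    def __init__(self, frame: pd.DataFrame) -> None:
        if frame.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if frame.columns.has_duplicates:
            raise ValueError("duplicate strain ids")
        values = frame.to_numpy()
        if not ((values == 0) | (values == 1)).all():
            raise ValueError("BFT cells must be 0/1")
        self.frame = frame.astype(int)

    @property
    def features(self) -> list[str]:
        return list(self.frame.index)

    @property
    def strains(self) -> list[str]:
        return list(self.frame.columns)

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def read_tsv(cls, path) -> "BFT":
        return cls(pd.read_csv(path, sep="\t", index_col="feature"))


def _exchange_entry(model: Model, metabolite_id: str) -> str | None:
    return metabolite_id if model.exchange_for(metabolite_id) else None


def phenotype_substrates(model: Model, base_medium: MediumRecipe,
                         element: str, candidates: list[str],
                         sources: Mapping[str, str] = DEFAULT_SOURCES,
                         threshold: float = GROWTH_THRESHOLD
                         ) -> dict[str, int]:
    """Growth on alternative sources of one element (C, N, P or S).

    For each candidate extracellular metabolite: the element's default
    source uptake is closed, the candidate's exchange opened at the
    default source's rate, and growth re-evaluated.  Candidates without
    an exchange in the model score 0.  The candidate equal to the
    default source reproduces the base-medium growth status.
    """
    if element not in sources:
        raise KeyError(f"no designated default source for element {element}")
    source = sources[element]
    if source not in base_medium.uptakes:
        raise ValueError(f"base medium lacks the default {element} source "
                         f"{source}")
    rate = base_medium.uptakes[source]
    out: dict[str, int] = {}
    for cand in candidates:
        uptakes = {k: v for k, v in base_medium.uptakes.items() if k != source}
        uptakes[cand] = rate
        if model.exchange_for(cand) is None:
            out[cand] = 0
            continue
        recipe = MediumRecipe(f"{base_medium.name}__{element}_{cand}", uptakes)
        res = run_fba(apply_medium(model, recipe, on_missing="warn"))
        out[cand] = int(res.grows(threshold))
    return out


def phenotype_auxotrophies(model: Model, minimal_medium: MediumRecipe,
                           compounds: list[str],
                           threshold: float = GROWTH_THRESHOLD
                           ) -> dict[str, int]:
    """Auxotrophy calls: 1 when the strain cannot synthesize the
    cytosolic compound on the unsupplemented minimal medium.

    The compound's own uptake (if in the recipe) is closed before the
    demand test, so supplying it in the medium cannot mask the call.
    Compounds absent from the model score 1 with a warning (a network
    that does not represent a required compound cannot make it).
    """
    out: dict[str, int] = {}
    for compound in compounds:
        if compound not in model.metabolites:
            warnings.warn(f"{model.id}: {compound} not in model; "
                          f"scored auxotrophic")
            out[compound] = 1
            continue
        exch = compound[:-2] + "_e" if compound.endswith("_c") else compound
        uptakes = {k: v for k, v in minimal_medium.uptakes.items()
                   if k != exch}
        recipe = MediumRecipe(minimal_medium.name + "__noX", uptakes or
                              dict(minimal_medium.uptakes))
        constrained = apply_medium(model, recipe, on_missing="warn")
        res = maximize_demand(constrained, compound)
        out[compound] = int(not res.grows(threshold))
    return out


def phenotype_biosynthesis(model: Model, medium: MediumRecipe,
                           targets: list[str],
                           threshold: float = GROWTH_THRESHOLD
                           ) -> dict[str, int]:
    """Potential biosynthesis: 1 when a temporary demand for the target
    can carry >= threshold flux on the medium; absent targets score 0
    with a warning."""
    out: dict[str, int] = {}
    constrained = None
    for target in targets:
        if target not in model.metabolites:
            warnings.warn(f"{model.id}: {target} not in model; scored 0")
            out[target] = 0
            continue
        if constrained is None:
            constrained = apply_medium(model, medium, on_missing="warn")
        res = maximize_demand(constrained, target)
        out[target] = int(res.grows(threshold))
    return out


def build_bft(outcomes: Mapping[str, Mapping[str, int]],
              strains: list[str] | None = None) -> BFT:
    """Assemble per-strain feature outcomes into a BFT.

    ``outcomes``: feature id -> {strain -> 0/1}.  Missing strain
    outcomes become 0 with a warning; duplicate feature ids raise.
    """
    if strains is None:
        seen: set[str] = set()
        for vals in outcomes.values():
            seen |= set(vals)
        strains = sorted(seen)
    rows = {}
    for feature, vals in outcomes.items():
        missing = [s for s in strains if s not in vals]
        if missing:
            warnings.warn(f"feature {feature}: no outcome for {missing}; "
                          f"scored 0")
        rows[feature] = [int(vals.get(s, 0)) for s in strains]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=strains)
    return BFT(frame)


def reaction_presence_bft(models: Mapping[str, Model],
                          namespace: str = "reaction:") -> BFT:
    """Reaction-presence BFT over a deck of strain models: cell = 1 iff
    the reaction id is in the strain's model."""
    all_rxns: set[str] = set()
    for m in models.values():
        all_rxns |= set(m.reactions)
    strains = sorted(models)
    data = {namespace + rid: [int(rid in models[s].reactions) for s in strains]
            for rid in sorted(all_rxns)}
    return BFT(pd.DataFrame.from_dict(data, orient="index", columns=strains))
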