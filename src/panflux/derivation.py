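"""Strain-specific model derivation and gap-filling.

A strain model is carved out of the pan-model through the PAM: a gene
cluster counts present for a strain only if the strain holds at least
one member gene without a premature stop; cluster ids in GPRs are
replaced by the strain's intact genes, reactions whose rule becomes
unsatisfiable are removed (with now-unused metabolites and their
boundary reactions), and orphan/spontaneous reactions ride along.  The
result can then be gap-filled against the pan-model on one or more
media, each round seeing the previous round's additions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import gpr as gpr_mod
from .expansion import REF_ONLY_PREFIX
from .model import MediumRecipe, Model
from .pangenome import PAM
from .reconstruction import gapfill_min_penalty

DEFAULT_MIN_FLUX = 0.001

#: element -> default sole-source extracellular metabolite
DEFAULT_SOURCES = {"C": "glc__D_e", "N": "nh4_e", "P": "pi_e", "S": "so4_e"}

#: aerobic/housekeeping uptakes opened alongside the four sources
HOUSEKEEPING = ("o2_e", "h2o_e", "h_e")

#: trace ions opened when their exchanges exist
TRACE_IONS = ("fe2_e", "fe3_e", "k_e", "mg2_e", "mn2_e", "zn2_e", "ca2_e",
              "cl_e", "cobalt2_e", "cu2_e", "mobd_e")


@dataclass
class StrainModel:
    model: Model
    strain: str
    gapfilled: dict[str, list[str]] = field(default_factory=dict)
    failed_media: list[str] = field(default_factory=list)


def derive_strain(pan: Model, pam: PAM, strain: str) -> StrainModel:
    """Derive one strain's model from the pan-model (pre gap-fill)."""
    if strain not in pam.strain_ids:
        raise KeyError(f"strain {strain} not a PAM column")
    known = set(pam.cluster_ids)
    mapping: dict[str, list[str]] = {}
    for rxn in pan.reactions.values():
        for leaf in rxn.gpr.genes():
            if leaf in mapping:
                continue
            if leaf.startswith(REF_ONLY_PREFIX):
                mapping[leaf] = []  # reference-only placeholder: absent
            elif leaf in known:
                mapping[leaf] = sorted(
                    pam.genes_of_strain(leaf, strain, intact_only=True))
            else:
                raise KeyError(
                    f"GPR leaf {leaf!r} is neither a PAM cluster nor a "
                    f"reference-only placeholder")
    out = pan.copy()
    out.id = f"{pan.id}__{strain}"
    removed = []
    for rid, rxn in out.reactions.items():
        if rxn.gpr.is_empty:
            continue  # orphan or spontaneous: retained
        new_gpr = gpr_mod.substitute(rxn.gpr, mapping)
        if new_gpr.is_unsatisfiable:
            removed.append(rid)
        else:
            rxn.gpr = new_gpr
    out.remove_reactions(removed)
    _prune_disconnected_boundary(out)
    out.prune_unused_metabolites()
    return StrainModel(out, strain)


def _prune_disconnected_boundary(model: Model) -> None:
    """Drop boundary reactions whose metabolite no internal reaction
    uses any more."""
    used_internal: set[str] = set()
    for rxn in model.reactions.values():
        if not model.is_boundary(rxn):
            used_internal |= set(rxn.stoichiometry)
    drop = [rid for rid, rxn in model.reactions.items()
            if model.is_boundary(rxn)
            and next(iter(rxn.stoichiometry)) not in used_internal]
    model.remove_reactions(drop)


def gapfill_strain(sm: StrainModel, pan: Model, media: list[MediumRecipe],
                   min_flux: float = DEFAULT_MIN_FLUX, skip: bool = False,
                   penalties: dict[str, float] | None = None) -> StrainModel:
    """Gap-fill a strain model against the pan-model on each medium in
    order; later rounds see earlier additions.  ``skip=True`` returns
    the model unchanged (useful for auxotrophy studies on minimal
    media).  Penalties default to uniform 1."""
    if skip:
        return sm
    for medium in media:
        result, augmented = gapfill_min_penalty(sm.model, pan, medium,
                                                min_flux, penalties)
        if result.status == "success":
            sm.model = augmented
            sm.gapfilled[medium.name] = result.added
        else:
            sm.failed_media.append(medium.name)
    return sm


def default_minimal_medium(model: Model, rate: float = 10.0,
                           trace_ions: tuple[str, ...] = TRACE_IONS
                           ) -> MediumRecipe:
    """Generic minimal aerobic medium: glucose, ammonia, phosphate and
    sulfate as sole C, N, P and S sources, plus o2/h2o/h and any trace
    ions whose exchange the model carries.  Entries without a matching
    exchange are silently absent."""
    wanted = list(DEFAULT_SOURCES.values()) + list(HOUSEKEEPING) + list(trace_ions)
    uptakes = {mid: rate for mid in wanted
               if model.exchange_for(mid) is not None}
    return MediumRecipe("minimal_aerobic", uptakes)
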