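"""Model and table I/O.

Two on-disk model formats are supported:

* a JSON dialect (documented below) that round-trips every field the
  package uses, including cluster-space GPRs and the spontaneous flag;
* SBML Level 3 + FBC, read and written through COBRApy/libSBML.  The
  spontaneous flag travels in the reaction notes (key ``spontaneous``);
  alternatively, reactions whose whole GPR is a configurable sentinel
  gene id (default ``"spontaneous"``) are converted to flag + empty GPR
  on load, as some universe distributions encode spontaneity that way.

JSON dialect::

    {"id": str, "objective": str|null,
     "metabolites": [{"id","name","formula","charge","compartment"}],
     "reactions": [{"id","name","stoichiometry":{met: coef},
                    "lower_bound","upper_bound","gpr": str,
                    "spontaneous": bool, "annotations": {key:[values]}}]}

``formula`` is a Hill string ('' = unknown); ``charge`` null = unknown;
``gpr`` uses the conventional "and"/"or" string ('' = no rule).

Media recipes are TSV with columns ``medium_name``, ``metabolite_id``,
``max_uptake`` (one row per uptake; several media may share a file).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import gpr as gpr_mod
from .model import (MediumRecipe, Metabolite, Model, Reaction, format_formula,
                    parse_formula)

SPONTANEOUS_SENTINEL = "spontaneous"


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: Model) -> dict:
    return {
        "id": model.id,
        "objective": model.objective,
        "metabolites": [
            {"id": m.id, "name": m.name,
             "formula": format_formula(m.formula) if m.formula else "",
             "charge": m.charge, "compartment": m.compartment}
            for m in (model.metabolites[k] for k in sorted(model.metabolites))
        ],
        "reactions": [
            {"id": r.id, "name": r.name,
             "stoichiometry": {k: r.stoichiometry[k]
                               for k in sorted(r.stoichiometry)},
             "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
             "gpr": gpr_mod.serialize(r.gpr), "spontaneous": r.spontaneous,
             "annotations": r.annotations}
            for r in (model.reactions[k] for k in sorted(model.reactions))
        ],
    }


def model_from_dict(data: dict) -> Model:
    model = Model(data.get("id", "model"))
    for m in data["metabolites"]:
        model.add_metabolite(Metabolite(
            m["id"], m.get("name", ""), parse_formula(m.get("formula", "")),
            m.get("charge"), m.get("compartment", "")))
    for r in data["reactions"]:
        model.add_reaction(Reaction(
            r["id"], r.get("name", ""), dict(r["stoichiometry"]),
            float(r["lower_bound"]), float(r["upper_bound"]),
            gpr_mod.parse(r.get("gpr", "")), bool(r.get("spontaneous", False)),
            {k: list(v) for k, v in r.get("annotations", {}).items()}))
    model.objective = data.get("objective")
    if model.objective is not None and model.objective not in model.reactions:
        raise ValueError(f"objective {model.objective!r} not among reactions")
    return model


def write_json(model: Model, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def read_json(path: str | Path) -> Model:
    return model_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# SBML L3 + FBC via COBRApy
# ---------------------------------------------------------------------------

def to_cobra(model: Model):
    """Convert to a cobra.Model (GPRs become rule strings)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = []
    for mid in sorted(model.metabolites):
        m = model.metabolites[mid]
        met = cobra.Metabolite(
            m.id, name=m.name or m.id,
            formula=format_formula(m.formula) if m.formula else None,
            charge=m.charge, compartment=m.compartment or "c")
        if m.charge is None:
            # SBML/FBC has no "unknown charge"; mark it in the notes
            met.notes["charge_unknown"] = "true"
        mets.append(met)
    cm.add_metabolites(mets)
    rxns = []
    for rid in sorted(model.reactions):
        r = model.reactions[rid]
        rxn = cobra.Reaction(r.id, name=r.name or r.id,
                             lower_bound=r.lower_bound,
                             upper_bound=r.upper_bound)
        rxns.append(rxn)
    cm.add_reactions(rxns)
    for rid in sorted(model.reactions):
        r = model.reactions[rid]
        rxn = cm.reactions.get_by_id(rid)
        rxn.add_metabolites({cm.metabolites.get_by_id(k): v
                             for k, v in r.stoichiometry.items()})
        rule = gpr_mod.serialize(r.gpr)
        if rule:
            rxn.gene_reaction_rule = rule
        if r.spontaneous:
            rxn.notes["spontaneous"] = "true"
        for key, values in r.annotations.items():
            rxn.annotation[key] = values if len(values) > 1 else values[0]
    if model.objective:
        cm.objective = model.objective
    return cm


def from_cobra(cm, sentinel: str | None = SPONTANEOUS_SENTINEL) -> Model:
    """Convert a cobra.Model into the package's Model."""
    model = Model(cm.id or "model")
    for met in cm.metabolites:
        charge = met.charge
        if str(met.notes.get("charge_unknown", "")).lower() == "true":
            charge = None
        model.add_metabolite(Metabolite(
            met.id, met.name or "",
            parse_formula(met.formula) if met.formula else {},
            charge, met.compartment or ""))
    objective_ids = {r.id for r in cm.reactions
                     if r.objective_coefficient}
    for rxn in cm.reactions:
        rule = rxn.gene_reaction_rule or ""
        g = gpr_mod.parse(rule)
        spontaneous = str(rxn.notes.get("spontaneous", "")).lower() == "true"
        if sentinel and g.op == "leaf" and g.gene == sentinel:
            g = gpr_mod.EMPTY
            spontaneous = True
        annotations = {}
        for key, val in rxn.annotation.items():
            annotations[key] = list(val) if isinstance(val, list) else [str(val)]
        model.add_reaction(Reaction(
            rxn.id, rxn.name or "", dict(
                {m.id: c for m, c in rxn.metabolites.items()}),
            rxn.lower_bound, rxn.upper_bound, g, spontaneous, annotations))
    if objective_ids:
        model.objective = sorted(objective_ids)[0]
    return model


def write_sbml(model: Model, path: str | Path) -> None:
    from cobra.io import write_sbml_model
    write_sbml_model(to_cobra(model), str(path))


def read_sbml(path: str | Path,
              sentinel: str | None = SPONTANEOUS_SENTINEL) -> Model:
    from cobra.io import read_sbml_model
    return from_cobra(read_sbml_model(str(path)), sentinel=sentinel)


def read_model(path: str | Path) -> Model:
    """Dispatch on extension: .json -> JSON dialect, .xml/.sbml -> SBML."""
    p = Path(path)
    if p.suffix == ".json":
        return read_json(p)
    if p.suffix in (".xml", ".sbml"):
        return read_sbml(p)
    raise ValueError(f"unrecognized model format: {p.name}")


def write_model(model: Model, path: str | Path) -> None:
    p = Path(path)
    if p.suffix == ".json":
        write_json(model, p)
    elif p.suffix in (".xml", ".sbml"):
        write_sbml(model, p)
    else:
        raise ValueError(f"unrecognized model format: {p.name}")


# ---------------------------------------------------------------------------
# media TSV
# ---------------------------------------------------------------------------

def read_media_tsv(path: str | Path) -> dict[str, MediumRecipe]:
    df = pd.read_csv(path, sep="\t", dtype={"medium_name": str,
                                            "metabolite_id": str})
    required = {"medium_name", "metabolite_id", "max_uptake"}
    if not required.issubset(df.columns):
        raise ValueError(f"media TSV needs columns {sorted(required)}")
    media: dict[str, MediumRecipe] = {}
    for name, grp in df.groupby("medium_name", sort=True):
        uptakes = {row.metabolite_id: float(row.max_uptake)
                   for row in grp.itertuples()}
        media[str(name)] = MediumRecipe(str(name), uptakes)
    return media


def write_media_tsv(media: dict[str, MediumRecipe], path: str | Path) -> None:
    rows = [{"medium_name": m.name, "metabolite_id": k, "max_uptake": v}
            for m in media.values() for k, v in sorted(m.uptakes.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
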