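"""Reference-model translation and expansion.

A curated reference model speaks in its own gene ids.  Orthologs between
each strain proteome and the reference proteome are determined by
bidirectional best hits (BRH); the reference GPRs are then rewritten in
cluster space so the reference becomes comparable with the PAM and the
reference-free draft.  The draft then serves as a repository of new
content: reactions and metabolites absent from the reference are added,
respecting the reference's curated formulas and charges (a candidate
that is element- or charge-unbalanced under reference-priority
definitions is skipped), while the reference biomass equation and
non-growth associated maintenance (NGAM) reaction are inherited
untouched.  Finally, reference orphan reactions get their GPRs
supplemented from the independent reference-free reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from . import gpr as gpr_mod
from .align import screened_align
from .model import Metabolite, Model, check_balance
from .pangenome import PAM, ProteinRecord

logger = logging.getLogger(__name__)

#: prefix of placeholder GPR leaves for reference genes with no ortholog;
#: these evaluate absent for every input strain during derivation.
REF_ONLY_PREFIX = "refonly__"


@dataclass
class BrhParams:
    id_min: float = 0.40
    cov_min: float = 0.70  # both coverages


@dataclass
class OrthologMap:
    #: strain -> list of (strain gene, reference gene, score) mutual best hits
    pairs: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)
    #: consolidated reference gene -> cluster id
    gene_to_cluster: dict[str, str] = field(default_factory=dict)
    unmapped: set[str] = field(default_factory=set)


def brh_map(strain_proteomes: Mapping[str, Iterable[ProteinRecord]],
            reference_proteome: Mapping[str, str],
            params: BrhParams = BrhParams()) -> OrthologMap:
    """Bidirectional best hits between each strain and the reference.

    Scores are identity x min coverage with thresholds identity >=
    id_min and both coverages >= cov_min; a pair is kept only when each
    member is the other's best hit (ties broken by gene id).
    """
    out = OrthologMap()
    ref_items = sorted(reference_proteome.items())
    for strain in sorted(strain_proteomes):
        records = sorted(strain_proteomes[strain], key=lambda r: r.gene)
        # score all admissible pairs
        scores: dict[tuple[str, str], float] = {}
        for rec in records:
            for rgene, rseq in ref_items:
                st = screened_align(rec.sequence, rseq, params.id_min)
                if st is None:
                    continue
                if (st.identity >= params.id_min
                        and st.coverage_a >= params.cov_min
                        and st.coverage_b >= params.cov_min):
                    scores[(rec.gene, rgene)] = st.score
        best_of_strain: dict[str, str] = {}
        for rec in records:
            hits = [(rg, s) for (g, rg), s in scores.items() if g == rec.gene]
            if hits:
                hits.sort(key=lambda t: (-t[1], t[0]))
                best_of_strain[rec.gene] = hits[0][0]
        best_of_ref: dict[str, str] = {}
        for rgene, _ in ref_items:
            hits = [(g, s) for (g, rg), s in scores.items() if rg == rgene]
            if hits:
                hits.sort(key=lambda t: (-t[1], t[0]))
                best_of_ref[rgene] = hits[0][0]
        pairs = [(g, rg, scores[(g, rg)])
                 for g, rg in best_of_strain.items()
                 if best_of_ref.get(rg) == g]
        out.pairs[strain] = sorted(pairs)
    return out


def translate_reference_gprs(reference: Model, orthologs: OrthologMap,
                             pam: PAM) -> tuple[Model, OrthologMap]:
    """Rewrite reference GPR leaves as cluster ids.

    Each reference gene is assigned to the cluster holding the majority
    of its BRH partners across strains (ties to the smallest cluster
    id); genes with no partner become reference-only placeholder leaves
    that evaluate absent for every strain.  Reactions, bounds, biomass
    and metabolites are copied verbatim.
    """
    votes: dict[str, dict[str, int]] = {}
    for strain, pairs in orthologs.pairs.items():
        for strain_gene, ref_gene, _score in pairs:
            cluster = pam.cluster_of(strain_gene)
            if cluster is None:
                continue
            votes.setdefault(ref_gene, {}).setdefault(cluster, 0)
            votes[ref_gene][cluster] += 1
    ref_genes: set[str] = set()
    for rxn in reference.reactions.values():
        ref_genes |= rxn.gpr.genes()
    mapping: dict[str, list[str]] = {}
    for gene in sorted(ref_genes):
        v = votes.get(gene)
        if not v:
            orthologs.unmapped.add(gene)
            mapping[gene] = [REF_ONLY_PREFIX + gene]
            continue
        ranked = sorted(v.items(), key=lambda t: (-t[1], t[0]))
        if len(ranked) > 1:
            logger.info("reference gene %s: partners span clusters %s; "
                        "majority -> %s", gene, sorted(v), ranked[0][0])
        orthologs.gene_to_cluster[gene] = ranked[0][0]
        mapping[gene] = [ranked[0][0]]
    translated = reference.copy()
    translated.id = reference.id + "_clusterspace"
    for rxn in translated.reactions.values():
        rxn.gpr = gpr_mod.substitute(rxn.gpr, mapping)
    return translated, orthologs


@dataclass
class ExpansionOverrides:
    """User-forced metabolite definitions and reaction whitelist."""
    metabolite_defs: dict[str, tuple[dict[str, int], int | None]] = field(
        default_factory=dict)
    allow_reactions: set[str] = field(default_factory=set)


@dataclass
class ExpansionReport:
    added_reactions: list[str] = field(default_factory=list)
    added_metabolites: list[str] = field(default_factory=list)
    added_cluster_leaves: set[str] = field(default_factory=set)
    skipped_unbalanced: list[str] = field(default_factory=list)
    skipped_collisions: list[str] = field(default_factory=list)
    supplemented_orphans: list[str] = field(default_factory=list)
    biomass_id: str | None = None
    ngam_id: str | None = None
    ngam_bounds: tuple[float, float] | None = None


def expand_with_draft(translated_ref: Model, draft: Model,
                      ngam_id: str = "ATPM",
                      overrides: ExpansionOverrides | None = None,
                      block_undetermined: bool = False
                      ) -> tuple[Model, ExpansionReport]:
    """Expand the translated reference with new content from the draft.

    Draft reactions absent by id are added after a balance re-check in
    which the reference's metabolite formulas/charges take priority
    ("unbalanced" blocks; "undetermined" passes unless
    ``block_undetermined``).  The reference biomass objective and NGAM
    bounds are inherited bit-exactly.
    """
    overrides = overrides or ExpansionOverrides()
    expanded = translated_ref.copy()
    expanded.id = translated_ref.id.replace("_clusterspace", "") + "_expanded"
    report = ExpansionReport(biomass_id=expanded.objective, ngam_id=(
        ngam_id if ngam_id in expanded.reactions else None))
    if report.ngam_id:
        ngam = expanded.reactions[ngam_id]
        report.ngam_bounds = (ngam.lower_bound, ngam.upper_bound)

    def resolved_met(mid: str) -> Metabolite:
        if mid in overrides.metabolite_defs:
            formula, charge = overrides.metabolite_defs[mid]
            base = (expanded.metabolites.get(mid) or draft.metabolites[mid]).copy()
            base.formula, base.charge = dict(formula), charge
            return base
        if mid in expanded.metabolites:  # reference priority
            return expanded.metabolites[mid]
        return draft.metabolites[mid]

    for rid in sorted(draft.reactions):
        rxn = draft.reactions[rid]
        if rid in expanded.reactions:
            if expanded.reactions[rid].stoichiometry != rxn.stoichiometry:
                report.skipped_collisions.append(rid)
            continue
        defs = {mid: resolved_met(mid) for mid in rxn.stoichiometry}
        verdict = check_balance(rxn, defs).verdict
        allowed = (rid in overrides.allow_reactions
                   or verdict == "balanced"
                   or (verdict == "undetermined" and not block_undetermined))
        if not allowed:
            report.skipped_unbalanced.append(rid)
            continue
        for mid, met in sorted(defs.items()):
            if mid not in expanded.metabolites:
                expanded.add_metabolite(met.copy())
                report.added_metabolites.append(mid)
        expanded.add_reaction(rxn.copy())
        report.added_reactions.append(rid)
        report.added_cluster_leaves |= rxn.gpr.genes()
    return expanded, report


def supplement_orphan_gprs(expanded: Model, draft: Model,
                           report: ExpansionReport | None = None) -> Model:
    """Copy the draft's cluster-space GPR onto every expanded orphan
    (empty GPR, not spontaneous) whose id the draft also models with a
    non-empty GPR.  Non-empty GPRs are never overwritten."""
    out = expanded.copy()
    for rid, rxn in out.reactions.items():
        if not rxn.gpr.is_empty or rxn.spontaneous:
            continue
        other = draft.reactions.get(rid)
        if other is not None and not other.gpr.is_empty \
                and not other.gpr.is_unsatisfiable:
            rxn.gpr = other.gpr
            if report is not None:
                report.supplemented_orphans.append(rid)
    return out
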