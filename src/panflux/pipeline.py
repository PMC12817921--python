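"""End-to-end pipeline composition.

``recon`` builds the pan-model and PAM from strain inputs (QC ->
clustering -> gene recovery -> reference-free carving -> optional
reference translation/expansion/orphan supplementation); ``derive_all``
turns pan + PAM into a deck of gap-filled strain models; ``autopilot``
chains recon, an automated penalty-weighted gap-fill of the draft pan,
and derivation — the no-manual-curation path.  ``analyze_deck``
computes phenotype and reaction BFTs and the phylometabolic tree for a
deck.

Every run can write a manifest (inputs, parameters, seed, version)
sufficient to reproduce outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .analysis import (Dendrogram, extract_clusters, jaccard_distance_matrix,
                       merge_bfts, ward_dendrogram)
from .derivation import (DEFAULT_MIN_FLUX, StrainModel, default_minimal_medium,
                         derive_strain, gapfill_strain)
from .expansion import (BrhParams, ExpansionOverrides, ExpansionReport,
                        OrthologMap, brh_map, expand_with_draft,
                        supplement_orphan_gprs, translate_reference_gprs)
from .model import MediumRecipe, Model
from .pangenome import (PAM, Cluster, ClusteringParams, GeneCoord,
                        ProteinRecord, RecoveryParams, build_pam,
                        cluster_proteins, recover_genes)
from .prediction import (BFT, build_bft, phenotype_auxotrophies,
                         phenotype_biosynthesis, phenotype_substrates,
                         reaction_presence_bft)
from .qc import (AssemblyStats, CompletenessRecord, QCReport, QCThresholds,
                 assembly_stats, qc_filter)
from .reconstruction import (GapfillResult, GeneSupportMap, HomologyParams,
                             Universe, carve_draft_pan, compute_penalties,
                             gapfill_min_penalty, map_clusters_to_universe)


@dataclass
class ReconResult:
    pan: Model
    draft: Model
    pam: PAM
    clusters: list[Cluster]
    records: dict[str, list[ProteinRecord]]
    support: GeneSupportMap
    qc_report: QCReport | None = None
    orthologs: OrthologMap | None = None
    expansion_report: ExpansionReport | None = None
    recovered: dict[str, list[ProteinRecord]] = field(default_factory=dict)


def recon(proteomes: Mapping[str, Sequence[ProteinRecord]],
          universe: Universe,
          genomes: Mapping[str, Mapping[str, str]] | None = None,
          gffs: Mapping[str, Sequence[GeneCoord]] | None = None,
          completeness: Sequence[CompletenessRecord] | None = None,
          genome_paths: Mapping[str, str] | None = None,
          reference: Model | None = None,
          reference_proteome: Mapping[str, str] | None = None,
          clustering: ClusteringParams = ClusteringParams(),
          homology: HomologyParams = HomologyParams(),
          brh: BrhParams = BrhParams(),
          recovery: RecoveryParams = RecoveryParams(),
          qc_thresholds: QCThresholds = QCThresholds(),
          overrides: ExpansionOverrides | None = None,
          ngam_id: str = "ATPM") -> ReconResult:
    """Build the pan-model and PAM.

    QC runs when genome paths (or in-memory genomes) plus a completeness
    table are given; gene recovery runs when genomes and GFFs are given.
    With a reference model + proteome the hybrid (expanded
    reference-based) pan is produced, otherwise the reference-free
    draft is the pan.
    """
    qc_report = None
    kept = sorted(proteomes)
    if completeness is not None and (genomes is not None
                                     or genome_paths is not None):
        stats = []
        for s in kept:
            if genome_paths is not None:
                stats.append(assembly_stats(genome_paths[s], strain=s))
            else:
                lengths = {f">{c}": seq for c, seq in genomes[s].items()}
                from .qc import compute_n50
                ls = [len(v) for v in lengths.values()]
                stats.append(AssemblyStats(s, len(ls), compute_n50(ls),
                                           sum(ls)))
        qc_report = qc_filter(stats, list(completeness), qc_thresholds)
        kept = sorted(qc_report.kept)

    records = {s: list(proteomes[s]) for s in kept}
    flat = [r for s in kept for r in records[s]]
    clusters = cluster_proteins(flat, clustering)
    pam = build_pam(clusters, kept, flat)

    recovered: dict[str, list[ProteinRecord]] = {}
    if genomes is not None and gffs is not None:
        for s in kept:
            recs = recover_genes(dict(genomes[s]), list(gffs[s]), clusters,
                                 pam, s, clustering, recovery)
            if recs:
                recovered[s] = recs
                records[s] = records[s] + recs

    support = map_clusters_to_universe(clusters, universe, homology)
    draft = carve_draft_pan(universe, support)

    orthologs = None
    expansion_report = None
    if reference is not None:
        if reference_proteome is None:
            raise ValueError("reference model given without its proteome")
        orthologs = brh_map(records, reference_proteome, brh)
        translated, orthologs = translate_reference_gprs(reference,
                                                         orthologs, pam)
        expanded, expansion_report = expand_with_draft(
            translated, draft, ngam_id=ngam_id, overrides=overrides)
        pan = supplement_orphan_gprs(expanded, draft, expansion_report)
    else:
        pan = draft
    return ReconResult(pan, draft, pam, clusters, records, support,
                       qc_report, orthologs, expansion_report, recovered)


def derive_all(pan: Model, pam: PAM, media: Sequence[MediumRecipe] = (),
               min_flux: float = DEFAULT_MIN_FLUX, skip_gapfill: bool = False,
               penalties: dict[str, float] | None = None
               ) -> dict[str, StrainModel]:
    """Derive one strain model per PAM column and gap-fill it on each
    medium in order (uniform penalties unless a table is given)."""
    media = list(media) or [default_minimal_medium(pan)]
    deck: dict[str, StrainModel] = {}
    for strain in pam.strain_ids:
        sm = derive_strain(pan, pam, strain)
        sm = gapfill_strain(sm, pan, media, min_flux, skip_gapfill, penalties)
        deck[strain] = sm
    return deck


@dataclass
class AutopilotResult:
    recon: ReconResult
    pan_gapfill: GapfillResult
    deck: dict[str, StrainModel]


def autopilot(proteomes: Mapping[str, Sequence[ProteinRecord]],
              universe: Universe,
              media: Sequence[MediumRecipe] = (),
              min_flux: float = DEFAULT_MIN_FLUX,
              **recon_kwargs) -> AutopilotResult:
    """recon, then automated penalty-weighted gap-fill of the pan from
    the universe, then derivation — no manual curation."""
    rr = recon(proteomes, universe, **recon_kwargs)
    media = list(media) or [default_minimal_medium(rr.pan)]
    penalties = compute_penalties(universe, rr.support)
    result, pan = gapfill_min_penalty(rr.pan, universe.model, media[0],
                                      min_flux, penalties)
    if result.status == "success":
        rr.pan = pan
    deck = derive_all(rr.pan, rr.pam, media, min_flux)
    return AutopilotResult(rr, result, deck)


@dataclass
class AnalysisResult:
    bfts: dict[str, BFT]
    merged: BFT
    dendrogram: Dendrogram
    assignment: dict[str, str]


def analyze_deck(deck: Mapping[str, StrainModel],
                 base_medium: MediumRecipe,
                 substrate_candidates: Mapping[str, list[str]] | None = None,
                 auxotrophy_compounds: list[str] | None = None,
                 biosynthesis_targets: list[str] | None = None,
                 n_clusters: int = 3,
                 exclude_features: list[str] | None = None) -> AnalysisResult:
    """Phenotype BFTs + reaction BFT + phylometabolic tree for a deck."""
    strains = sorted(deck)
    bfts: dict[str, BFT] = {}
    outcomes: dict[str, dict[str, int]] = {}
    for element, cands in sorted((substrate_candidates or {}).items()):
        for s in strains:
            calls = phenotype_substrates(deck[s].model, base_medium, element,
                                         cands)
            for cand, val in calls.items():
                outcomes.setdefault(f"{element}_source:{cand}", {})[s] = val
    if outcomes:
        bfts["substrates"] = build_bft(outcomes, strains)
    if auxotrophy_compounds:
        aux: dict[str, dict[str, int]] = {}
        for s in strains:
            calls = phenotype_auxotrophies(deck[s].model, base_medium,
                                           auxotrophy_compounds)
            for comp, val in calls.items():
                aux.setdefault(f"aux:{comp}", {})[s] = val
        bfts["auxotrophies"] = build_bft(aux, strains)
    if biosynthesis_targets:
        bio: dict[str, dict[str, int]] = {}
        for s in strains:
            calls = phenotype_biosynthesis(deck[s].model, base_medium,
                                           biosynthesis_targets)
            for t, val in calls.items():
                bio.setdefault(f"biosynth:{t}", {})[s] = val
        bfts["biosynthesis"] = build_bft(bio, strains)
    bfts["reactions"] = reaction_presence_bft(
        {s: sm.model for s, sm in deck.items()})
    merged = merge_bfts(list(bfts.values()), exclude_features=exclude_features)
    dm = jaccard_distance_matrix(merged)
    dendro = ward_dendrogram(dm)
    assignment = extract_clusters(dendro, n_clusters)
    return AnalysisResult(bfts, merged, dendro, assignment)


def write_manifest(path: str | Path, config: dict) -> None:
    """Machine-readable run manifest: config + hash + package version."""
    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {"version": __version__,
                "config": json.loads(payload),
                "config_sha256": hashlib.sha256(payload.encode()).hexdigest()}
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
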