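"""Seeded synthetic world: a miniature bacterial pan-metabolism with
known ground truth for every pipeline stage.

The world consists of a reaction universe (transport, lumped catabolism,
a two-subunit respiratory complex, an isoform pair, spontaneous
diffusion reactions, biomass), a set of gene families with random
protein sequences, and a strain roster partitioned into metabolic
groups that differ by pathway modules:

* group G1 carries a xylose catabolism module (transporter, isomerase,
  lumped kinase/catabolism) — mirrors a strain-variable alternative
  carbon source;
* group G2 carries a histidine decarboxylase (histamine biosynthesis)
  and lacks tryptophan synthase — a planted amino-acid auxotrophy;
* group G3 carries urease plus a urea transporter — urea as an
  alternative nitrogen source.

Within a family, strain variants differ by point substitutions
(identity >= 0.95, far above the 0.90 clustering threshold); between
families sequences are random (identity well below every threshold), so
clustering, universe mapping and ortholog assignment are unambiguous by
construction.  Designated strains carry planted annotation defects
exercising the three gene-recovery scenarios, and one strain carries a
planted single-gene deletion that creates an exactly-one-reaction gap.

A curated reference model (covering the core plus tryptophan synthase,
with one curated orphan reaction and an NGAM reaction) and its proteome
allow the hybrid, reference-expanded reconstruction path to be tested
against planted truth as well.

Generation is a pure function of the parameters and seed.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .gpr import parse
from .model import MediumRecipe, Metabolite, Model, Reaction, parse_formula
from .pangenome import GeneCoord, ProteinRecord, write_gff3
from .qc import CompletenessRecord
from .reconstruction import Universe

AA20 = "ACDEFGHIKLMNPQRSTVWY"
CODON = {"A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
         "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
         "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
         "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT"}
STOP = "TAA"

#: family name -> carried by (core | G1 | G2-only skip | G3)
CORE_FAMILIES = ["glcT1", "glcT2", "glyc", "resA", "resB", "nh4T", "piT",
                 "so4T", "trpT", "aas", "cysS", "hisS"]
G1_FAMILIES = ["xylT", "xylA", "xylB"]
G2_FAMILIES = ["hdc"]
G3_FAMILIES = ["ure", "ureT"]
TRPS_FAMILY = "trpS"  # in G1 and G3; its absence makes G2 a trp auxotroph

_FORMULAS: dict[str, tuple[str, int | None]] = {
    "glc__D": ("C6H12O6", 0), "xyl__D": ("C5H10O5", 0),
    "xlu__D": ("C5H10O5", 0), "o2": ("O2", 0), "co2": ("CO2", 0),
    "h2o": ("H2O", 0), "h": ("H", 1), "nh4": ("H4N", 1),
    "pi": ("HO4P", -2), "so4": ("O4S", -2), "urea": ("CH4N2O", 0),
    "atp": ("C10H12N5O13P3", -4), "adp": ("C10H12N5O10P2", -3),
    "pyr": ("", None), "ala__L": ("", None), "trp__L": ("", None),
    "cys__L": ("", None), "his__L": ("", None), "hista": ("", None),
}

_EXCHANGED = ["glc__D", "xyl__D", "nh4", "pi", "so4", "o2", "co2", "h2o",
              "h", "trp__L", "urea", "ala__L"]

#: internal universe reactions: id -> (name, stoichiometry, (lb, ub),
#: gpr string in universal-gene space, spontaneous)
_UNIVERSE_RXNS: dict[str, tuple[str, dict[str, float], tuple[float, float],
                                str, bool]] = {
    "GLCt": ("glucose transport", {"glc__D_e": -1, "glc__D_c": 1},
             (0, 1000), "u_glcT1 or u_glcT2", False),
    "GLCCAT": ("glucose catabolism (lumped)",
               {"glc__D_c": -1, "adp_c": -2, "pi_c": -2,
                "pyr_c": 2, "atp_c": 2, "h2o_c": 2},
               (0, 1000), "u_glyc", False),
    "PYRRESP": ("pyruvate respiration (lumped)",
                {"pyr_c": -1, "o2_c": -3, "adp_c": -5, "pi_c": -5,
                 "co2_c": 3, "atp_c": 5, "h2o_c": 5},
                (0, 1000), "u_resA and u_resB", False),
    "NH4t": ("ammonium transport", {"nh4_e": -1, "nh4_c": 1},
             (0, 1000), "u_nh4T", False),
    "PIt": ("phosphate transport", {"pi_e": -1, "pi_c": 1},
            (0, 1000), "u_piT", False),
    "SO4t": ("sulfate transport", {"so4_e": -1, "so4_c": 1},
             (0, 1000), "u_so4T", False),
    "TRPt": ("L-tryptophan transport", {"trp__L_e": -1, "trp__L_c": 1},
             (0, 1000), "u_trpT", False),
    "ALAS": ("L-alanine synthesis (lumped)",
             {"pyr_c": -1, "nh4_c": -1, "atp_c": -1, "h2o_c": -1,
              "ala__L_c": 1, "adp_c": 1, "pi_c": 1},
             (0, 1000), "u_aas", False),
    "CYSS": ("L-cysteine synthesis (lumped)",
             {"pyr_c": -1, "so4_c": -1, "atp_c": -4, "h2o_c": -4,
              "cys__L_c": 1, "adp_c": 4, "pi_c": 4},
             (0, 1000), "u_cysS", False),
    "TRPS": ("L-tryptophan synthesis (lumped)",
             {"pyr_c": -2, "nh4_c": -1, "atp_c": -4, "h2o_c": -4,
              "trp__L_c": 1, "adp_c": 4, "pi_c": 4},
             (0, 1000), "u_trpS", False),
    "HISS": ("L-histidine synthesis (lumped)",
             {"pyr_c": -1, "nh4_c": -1, "atp_c": -3, "h2o_c": -3,
              "his__L_c": 1, "adp_c": 3, "pi_c": 3},
             (0, 1000), "u_hisS", False),
    "HISDC": ("histidine decarboxylase",
              {"his__L_c": -1, "hista_c": 1, "co2_c": 1},
              (0, 1000), "u_hdc", False),
    "XYLt": ("D-xylose transport", {"xyl__D_e": -1, "xyl__D_c": 1},
             (0, 1000), "u_xylT", False),
    "XYLI": ("xylose isomerase", {"xyl__D_c": -1, "xlu__D_c": 1},
             (0, 1000), "u_xylA", False),
    "XYLCAT": ("xylulose catabolism (lumped)",
               {"xlu__D_c": -1, "adp_c": -2, "pi_c": -2,
                "pyr_c": 2, "atp_c": 2, "h2o_c": 2},
               (0, 1000), "u_xylB", False),
    "UREAt": ("urea transport", {"urea_e": -1, "urea_c": 1},
              (0, 1000), "u_ureT", False),
    "UREA": ("urease", {"urea_c": -1, "h2o_c": -1, "h_c": -2,
                        "co2_c": 1, "nh4_c": 2},
             (0, 1000), "u_ure", False),
    "UNUSED1": ("L-alanine export", {"ala__L_c": -1, "ala__L_e": 1},
                (0, 1000), "u_unused", False),
    "O2t": ("o2 diffusion", {"o2_e": -1, "o2_c": 1}, (-1000, 1000), "", True),
    "CO2t": ("co2 diffusion", {"co2_c": -1, "co2_e": 1}, (-1000, 1000),
             "", True),
    "H2Ot": ("h2o diffusion", {"h2o_e": -1, "h2o_c": 1}, (-1000, 1000),
             "", True),
    "Ht": ("h diffusion", {"h_e": -1, "h_c": 1}, (-1000, 1000), "", True),
    "BIOMASS": ("biomass", {"ala__L_c": -2, "trp__L_c": -0.5,
                            "cys__L_c": -0.5, "his__L_c": -0.5,
                            "atp_c": -20, "h2o_c": -20,
                            "adp_c": 20, "pi_c": 20, "h_c": 20},
                (0, 1000), "", False),
}

#: family -> universe reactions its loss removes (for truth building)
_FAMILY_RXNS = {
    "glyc": ["GLCCAT"], "nh4T": ["NH4t"], "piT": ["PIt"], "so4T": ["SO4t"],
    "trpT": ["TRPt"], "aas": ["ALAS"], "cysS": ["CYSS"], "hisS": ["HISS"],
    "trpS": ["TRPS"], "hdc": ["HISDC"], "xylT": ["XYLt"], "xylA": ["XYLI"],
    "xylB": ["XYLCAT"], "ure": ["UREA"], "ureT": ["UREAt"],
}

_CORE_RXNS = ["GLCt", "GLCCAT", "PYRRESP", "NH4t", "PIt", "SO4t", "TRPt",
              "ALAS", "CYSS", "HISS", "O2t", "CO2t", "H2Ot", "Ht", "BIOMASS"]
_CORE_EXCH = ["EX_glc__D_e", "EX_nh4_e", "EX_pi_e", "EX_so4_e", "EX_o2_e",
              "EX_co2_e", "EX_h2o_e", "EX_h_e", "EX_trp__L_e"]

#: reference model content: core + TRPS + NGAM, one curated orphan (GLCt)
_REFERENCE_RXNS = _CORE_RXNS + ["TRPS", "ATPM"]
NGAM_BOUNDS = (0.5, 1000.0)


@dataclass
class WorldParams:
    seed: int = 42
    n_strains: int = 20
    n_groups: int = 3
    mutation_rate: float = 0.02
    generalist: bool = False  # first strain carries every optional module
    min_genome_length: int = 52_000


@dataclass
class SyntheticWorld:
    params: WorldParams
    families: dict[str, str]                      # family -> base sequence
    strains: list[str]
    group_of: dict[str, str]                      # strain -> G1/G2/G3
    strain_families: dict[str, list[str]]         # families truly carried
    records: dict[str, list[ProteinRecord]]       # annotated proteomes
    genomes: dict[str, dict[str, str]]            # strain -> contig -> seq
    gffs: dict[str, list[GeneCoord]]
    universe: Universe
    reference: Model
    reference_proteome: dict[str, str]
    completeness: list[CompletenessRecord]
    media: dict[str, MediumRecipe]
    planted: dict[str, str] = field(default_factory=dict)  # strain -> plant

    # ------------------------------------------------------------------
    def gene_id(self, strain: str, family: str) -> str:
        return f"{strain}_{family}"

    def family_of_gene(self, gene: str) -> str | None:
        base = gene.split("_", 1)[1] if "_" in gene else gene
        for suffix in ("", "a", "b", "part"):
            cand = base[:-1] if suffix and base.endswith(suffix) else base
            if cand in self.families:
                return cand
        return None


def _random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA20) for _ in range(length))


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    max_muts = int(len(seq) * 0.025)
    n_muts = min(max_muts, sum(1 for _ in seq if rng.random() < rate))
    positions = rng.sample(range(len(seq)), n_muts)
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([a for a in AA20 if a != out[p]])
    return "".join(out)


def _dna(protein: str) -> str:
    return "".join(CODON[a] for a in protein)


def _random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def build_universe() -> Universe:
    """The reaction universe; GPR leaves are universal gene ids whose
    sequences are supplied separately (here: the family base
    sequences)."""
    m = Model("toy_universe")
    for met, (formula, charge) in _FORMULAS.items():
        for comp in ("c", "e"):
            if comp == "e" and met not in _EXCHANGED:
                continue
            m.add_metabolite(Metabolite(f"{met}_{comp}", name=met,
                                        formula=parse_formula(formula),
                                        charge=charge, compartment=comp))
    for rid, (name, stoich, (lb, ub), rule, spont) in _UNIVERSE_RXNS.items():
        m.add_reaction(Reaction(rid, name=name, stoichiometry=dict(stoich),
                                lower_bound=lb, upper_bound=ub,
                                gpr=parse(rule), spontaneous=spont))
    for met in _EXCHANGED:
        m.add_reaction(Reaction(f"EX_{met}_e", name=f"{met} exchange",
                                stoichiometry={f"{met}_e": -1.0},
                                lower_bound=-1000.0, upper_bound=1000.0))
    m.objective = "BIOMASS"
    return m  # sequences attached by generate_world


def _group_modules(group: str) -> list[str]:
    if group == "G1":
        return G1_FAMILIES + [TRPS_FAMILY]
    if group == "G2":
        return G2_FAMILIES
    return G3_FAMILIES + [TRPS_FAMILY]


def generate_world(seed: int = 42, n_strains: int = 20, n_groups: int = 3,
                   mutation_rate: float = 0.02, generalist: bool = False,
                   outdir: str | Path | None = None) -> SyntheticWorld:
    """Generate the synthetic world; optionally write it to ``outdir``.

    Deterministic: the same parameters and seed give byte-identical
    outputs.
    """
    if not 1 <= n_groups <= 3 or n_groups > n_strains:
        raise ValueError("need 1 <= n_groups <= min(3, n_strains)")
    params = WorldParams(seed, n_strains, n_groups, mutation_rate, generalist)
    rng = random.Random(seed)

    all_family_names = (CORE_FAMILIES + [TRPS_FAMILY] + G1_FAMILIES
                        + G2_FAMILIES + G3_FAMILIES + ["unused"])
    families = {name: _random_protein(rng, rng.randint(120, 300))
                for name in all_family_names}

    strains = [f"S{i:02d}" for i in range(1, n_strains + 1)]
    group_names = [f"G{i + 1}" for i in range(n_groups)]
    group_of: dict[str, str] = {}
    base = n_strains // n_groups
    extra = n_strains % n_groups
    idx = 0
    for gi, g in enumerate(group_names):
        count = base + (1 if gi < extra else 0)
        for _ in range(count):
            group_of[strains[idx]] = g
            idx += 1

    strain_families: dict[str, list[str]] = {}
    for s in strains:
        fams = list(CORE_FAMILIES) + _group_modules(group_of[s])
        if generalist and s == strains[0]:
            fams = list(CORE_FAMILIES) + sorted(
                set(G1_FAMILIES + G2_FAMILIES + G3_FAMILIES + [TRPS_FAMILY]))
        strain_families[s] = fams

    # planted defects live in the first group, sparing its first strain
    g1_strains = [s for s in strains if group_of[s] == "G1"]
    planted: dict[str, str] = {}
    for plant, pos in (("scenario_i", 1), ("scenario_ii", 2),
                       ("scenario_iii", 3), ("deletion", 4)):
        if len(g1_strains) > pos:
            planted[g1_strains[pos]] = plant

    records: dict[str, list[ProteinRecord]] = {}
    genomes: dict[str, dict[str, str]] = {}
    gffs: dict[str, list[GeneCoord]] = {}
    variants: dict[tuple[str, str], str] = {}
    for s in strains:
        fams = list(strain_families[s])
        plant = planted.get(s)
        if plant == "deletion":
            fams = [f for f in fams if f != "glyc"]
        for f in fams:
            variants[(s, f)] = _mutate(rng, families[f], mutation_rate)
        recs: list[ProteinRecord] = []
        contig: list[str] = []
        coords: list[GeneCoord] = []
        pos = 0

        def spacer(length: int | None = None) -> None:
            nonlocal pos
            length = length if length is not None else rng.randint(500, 2500)
            contig.append(_random_dna(rng, length))
            pos += length

        order = sorted(fams)
        rng.shuffle(order)
        spacer()
        for f in order:
            prot = variants[(s, f)]
            gid = f"{s}_{f}"
            if plant == "scenario_i" and f == "glcT1":
                # premature stop splits the CDS into two annotated genes
                k = len(prot) // 2
                part1, part2 = prot[:k], prot[k + 1:]
                d1 = _dna(part1) + STOP
                contig.append(d1)
                coords.append(GeneCoord(gid + "a", "contig1", pos,
                                        pos + len(d1), "+"))
                recs.append(ProteinRecord(gid + "a", s, part1))
                pos += len(d1)
                d2 = _dna(part2) + STOP
                contig.append(d2)
                coords.append(GeneCoord(gid + "b", "contig1", pos,
                                        pos + len(d2), "+"))
                recs.append(ProteinRecord(gid + "b", s, part2))
                pos += len(d2)
            elif plant == "scenario_ii" and f == "so4T":
                # intact CDS in a region the gene caller missed: no GFF
                # entry, no proteome record; stop guards keep the ORF tidy
                d = STOP + _dna(prot) + STOP
                contig.append(d)
                pos += len(d)
            elif plant == "scenario_iii" and f == "glcT2":
                # annotation stops short of the true ORF
                k = int(len(prot) * 0.55)
                d = _dna(prot) + STOP
                contig.append(d)
                coords.append(GeneCoord(gid, "contig1", pos, pos + 3 * k,
                                        "+"))
                recs.append(ProteinRecord(gid, s, prot[:k]))
                pos += len(d)
            else:
                d = _dna(prot) + STOP
                contig.append(d)
                coords.append(GeneCoord(gid, "contig1", pos, pos + len(d),
                                        "+"))
                recs.append(ProteinRecord(gid, s, prot))
                pos += len(d)
            spacer()
        if pos < params.min_genome_length:
            spacer(params.min_genome_length - pos)
        genomes[s] = {"contig1": "".join(contig)}
        gffs[s] = coords
        records[s] = recs

    universe_model = build_universe()
    universe = Universe(universe_model,
                        {f"u_{name}": seq for name, seq in families.items()})

    reference = Model("toy_reference")
    um = universe_model
    ref_used: set[str] = set()
    for rid in _REFERENCE_RXNS:
        if rid == "ATPM":
            continue
        ref_used |= set(um.reactions[rid].stoichiometry)
    ref_used |= {"atp_c", "h2o_c", "adp_c", "pi_c", "h_c"}
    for mid in sorted(ref_used):
        reference.add_metabolite(um.metabolites[mid].copy())
    ref_gpr = {"GLCCAT": "ref_glyc", "PYRRESP": "ref_resA and ref_resB",
               "NH4t": "ref_nh4T", "PIt": "ref_piT", "SO4t": "ref_so4T",
               "TRPt": "ref_trpT", "ALAS": "ref_aas", "CYSS": "ref_cysS",
               "TRPS": "ref_trpS", "HISS": "ref_hisS",
               "GLCt": ""}  # curated orphan: genes never associated
    for rid in _REFERENCE_RXNS:
        if rid == "ATPM":
            reference.add_reaction(Reaction(
                "ATPM", name="ATP maintenance requirement",
                stoichiometry={"atp_c": -1, "h2o_c": -1, "adp_c": 1,
                               "pi_c": 1, "h_c": 1},
                lower_bound=NGAM_BOUNDS[0], upper_bound=NGAM_BOUNDS[1]))
            continue
        rxn = um.reactions[rid].copy()
        rxn.gpr = parse(ref_gpr.get(rid, ""))
        reference.add_reaction(rxn)
    for met in sorted({m[:-2] for m in ref_used if m.endswith("_e")}):
        reference.add_reaction(um.reactions[f"EX_{met}_e"].copy())
    reference.objective = "BIOMASS"

    ref_fams = ["glcT1", "glcT2", "glyc", "resA", "resB", "nh4T", "piT",
                "so4T", "trpT", "aas", "cysS", "trpS", "hisS"]
    reference_proteome = {f"ref_{f}": _mutate(rng, families[f], 0.01)
                          for f in ref_fams}

    completeness = [CompletenessRecord(s, 0.5, 1.0) for s in strains]
    m1 = MediumRecipe("M1", {"glc__D_e": 10.0, "nh4_e": 10.0, "pi_e": 10.0,
                             "so4_e": 10.0, "o2_e": 20.0, "h2o_e": 100.0,
                             "h_e": 100.0, "trp__L_e": 10.0})
    world = SyntheticWorld(params, families, strains, group_of,
                           strain_families, records, genomes, gffs,
                           universe, reference, reference_proteome,
                           completeness, {"M1": m1}, planted)
    if outdir is not None:
        write_world(world, outdir)
    return world


# ---------------------------------------------------------------------------
# planted truths
# ---------------------------------------------------------------------------

def _truth_reactions(world: SyntheticWorld, strain: str,
                     with_reference: bool = True) -> set[str]:
    rxns = set(_CORE_RXNS) | set(_CORE_EXCH)
    fams = set(world.strain_families[strain])
    if world.planted.get(strain) == "deletion":
        fams.discard("glyc")
    for f in sorted(fams):
        for rid in _FAMILY_RXNS.get(f, []):
            rxns.add(rid)
    if "glyc" not in fams:
        rxns.discard("GLCCAT")
    if "xylT" in fams:
        rxns.add("EX_xyl__D_e")
    if "ureT" in fams:
        rxns.add("EX_urea_e")
    if with_reference:
        rxns.add("ATPM")
    return rxns


def expected_truth(world: SyntheticWorld, query: str):
    """Planted ground truth, in the shapes the pipeline emits.

    queries: ``reactions`` (strain -> reaction id set, hybrid pan),
    ``reactions_rf`` (same, reference-free pan), ``substrates``
    (feature -> strain -> 0/1 for C and N candidates), ``auxotrophies``,
    ``biosynthesis``, ``groups`` (strain -> planted group),
    ``recoveries`` (strain -> scenario tag).
    """
    strains = world.strains
    has = lambda s, f: f in world.strain_families[s]  # noqa: E731
    if query == "reactions":
        return {s: _truth_reactions(world, s, True) for s in strains}
    if query == "reactions_rf":
        return {s: _truth_reactions(world, s, False) for s in strains}
    if query == "substrates":
        return {
            "C_source:glc__D_e": {s: 1 for s in strains},
            "C_source:xyl__D_e": {s: int(has(s, "xylT")) for s in strains},
            "N_source:nh4_e": {s: 1 for s in strains},
            "N_source:urea_e": {s: int(has(s, "ure")) for s in strains},
        }
    if query == "auxotrophies":
        return {"aux:trp__L_c": {s: int(not has(s, "trpS")) for s in strains}}
    if query == "biosynthesis":
        return {"biosynth:hista_c": {s: int(has(s, "hdc")) for s in strains}}
    if query == "groups":
        return dict(world.group_of)
    if query == "recoveries":
        return {s: tag.replace("scenario_", "")
                for s, tag in world.planted.items()
                if tag.startswith("scenario")}
    raise KeyError(f"unknown truth query {query!r}")


# ---------------------------------------------------------------------------
# writing the world to disk
# ---------------------------------------------------------------------------

def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    from . import io as pio

    out = Path(outdir)
    for sub in ("proteomes", "genomes", "gff", "models"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for s in world.strains:
        with open(out / "proteomes" / f"{s}.faa", "w") as fh:
            for rec in world.records[s]:
                fh.write(f">{rec.gene}\n{rec.sequence}\n")
        with open(out / "genomes" / f"{s}.fna", "w") as fh:
            for contig, seq in world.genomes[s].items():
                fh.write(f">{contig}\n{seq}\n")
        write_gff3(world.gffs[s], out / "gff" / f"{s}.gff")
    pio.write_json(world.universe.model, out / "models" / "universe.json")
    with open(out / "models" / "universe_genes.faa", "w") as fh:
        for gene, seq in sorted(world.universe.gene_sequences.items()):
            fh.write(f">{gene}\n{seq}\n")
    pio.write_json(world.reference, out / "models" / "reference.json")
    with open(out / "models" / "reference.faa", "w") as fh:
        for gene, seq in sorted(world.reference_proteome.items()):
            fh.write(f">{gene}\n{seq}\n")
    with open(out / "completeness.tsv", "w") as fh:
        fh.write("strain\tpct_missing\tpct_fragmented\n")
        for c in world.completeness:
            fh.write(f"{c.strain}\t{c.pct_missing}\t{c.pct_fragmented}\n")
    pio.write_media_tsv(world.media, out / "media.tsv")
    p = world.params
    manifest = {"seed": p.seed, "n_strains": p.n_strains,
                "n_groups": p.n_groups, "mutation_rate": p.mutation_rate,
                "generalist": p.generalist,
                "groups": world.group_of, "planted": world.planted}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
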