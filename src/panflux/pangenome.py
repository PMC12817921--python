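"""Protein clustering, presence/absence matrix, and gene recovery.

Strain proteomes are grouped into clusters of near-identical proteins by
greedy incremental clustering (CD-HIT-like: sequences sorted by length,
each joins the best-scoring cluster whose representative it matches at
>= 90% global identity with >= 70% coverage of both sequences, otherwise
founds a new cluster).  Cluster membership across strains is tabulated
as the presence/absence matrix (PAM): clusters in rows, strains in
columns, member gene ids in cells.

Gene recovery then patches three classes of annotation/assembly error
against the genome sequence:

(i)   a premature stop codon split one protein into two adjacent gene
      calls — the concatenated translation is matched back to a cluster
      and recorded as a single pseudogene (``premature_stop=True``);
(ii)  an intact gene sits in a region the gene caller overlooked — its
      ORF is found by six-frame translation of unannotated regions and
      assigned to a cluster the strain was missing;
(iii) a gene call stops short of the true ORF — extending the annotated
      gene in frame into adjacent unannotated sequence recovers the
      full-length product, recorded as a pseudogene and replacing the
      partial call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.Seq import Seq

from .align import AlignmentStats, screened_align

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class ProteinRecord:
    gene: str
    strain: str
    sequence: str
    premature_stop: bool = False
    recovered_scenario: str | None = None  # None | "i" | "ii" | "iii"

    def __post_init__(self) -> None:
        if not self.sequence or not set(self.sequence) <= AA_ALPHABET:
            raise ValueError(f"{self.gene}: invalid amino-acid sequence")


@dataclass
class Cluster:
    id: str
    representative: str
    rep_seq: str
    members: dict[str, set[str]] = field(default_factory=dict)

    def add(self, record: ProteinRecord) -> None:
        self.members.setdefault(record.strain, set()).add(record.gene)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.members.values():
            out |= genes
        return out


@dataclass
class ClusteringParams:
    identity: float = 0.90
    cov_long: float = 0.70
    cov_short: float = 0.70


def _matches(stats: AlignmentStats, params: ClusteringParams) -> bool:
    return (stats.identity >= params.identity
            and stats.coverage_a >= params.cov_long
            and stats.coverage_b >= params.cov_short)


def cluster_proteins(records: Iterable[ProteinRecord],
                     params: ClusteringParams = ClusteringParams()
                     ) -> list[Cluster]:
    """Greedy incremental clustering.

    Sequences are processed longest first (ties by gene id); each joins
    the best-scoring existing cluster (identity x min coverage) whose
    representative satisfies the thresholds, else founds a new cluster
    and becomes its representative.  Deterministic.
    """
    recs = sorted(records, key=lambda r: (-len(r.sequence), r.gene))
    if not recs:
        raise ValueError("no protein records")
    clusters: list[Cluster] = []
    for rec in recs:
        best: tuple[float, int] | None = None  # (-score, index) for min()
        for i, cl in enumerate(clusters):
            stats = screened_align(cl.rep_seq, rec.sequence, params.identity)
            if stats is not None and _matches(stats, params):
                key = (-stats.score, i)
                if best is None or key < best:
                    best = key
        if best is None:
            cl = Cluster(f"C{len(clusters) + 1:04d}", rec.gene, rec.sequence)
            clusters.append(cl)
            cl.add(rec)
        else:
            clusters[best[1]].add(rec)
    return clusters


# ---------------------------------------------------------------------------
# presence/absence matrix
# ---------------------------------------------------------------------------

class PAM:
    """Gene presence/absence matrix: cluster ids x strain ids, cells are
    sets of member gene ids.  Every gene id appears in exactly one cell.
    Premature-stop genes are tracked so derivation can discount them; in
    the TSV serialization they carry a trailing ``!``.
    """

    def __init__(self, cluster_ids: list[str], strain_ids: list[str]) -> None:
        if len(set(cluster_ids)) != len(cluster_ids):
            raise ValueError("duplicate cluster ids")
        if len(set(strain_ids)) != len(strain_ids):
            raise ValueError("duplicate strain ids")
        self.cluster_ids = list(cluster_ids)
        self.strain_ids = list(strain_ids)
        self._cells: dict[str, dict[str, set[str]]] = {
            c: {s: set() for s in strain_ids} for c in cluster_ids}
        self._gene_cluster: dict[str, str] = {}
        self.premature: set[str] = set()

    # -- mutation ------------------------------------------------------
    def add_gene(self, cluster: str, strain: str, gene: str,
                 premature: bool = False) -> None:
        if gene in self._gene_cluster:
            raise ValueError(f"gene {gene} already placed")
        if strain not in self._cells[cluster]:
            raise KeyError(f"unknown strain {strain}")
        self._cells[cluster][strain].add(gene)
        self._gene_cluster[gene] = cluster
        if premature:
            self.premature.add(gene)

    def remove_gene(self, gene: str, drop_empty_cluster: bool = True) -> None:
        cluster = self._gene_cluster.pop(gene)
        for genes in self._cells[cluster].values():
            genes.discard(gene)
        self.premature.discard(gene)
        if drop_empty_cluster and not any(self._cells[cluster].values()):
            del self._cells[cluster]
            self.cluster_ids.remove(cluster)

    # -- queries -------------------------------------------------------
    def cell(self, cluster: str, strain: str) -> set[str]:
        return set(self._cells[cluster][strain])

    def cluster_of(self, gene: str) -> str | None:
        return self._gene_cluster.get(gene)

    def genes_of_strain(self, cluster: str, strain: str,
                        intact_only: bool = False) -> set[str]:
        genes = self._cells[cluster][strain]
        if intact_only:
            return {g for g in genes if g not in self.premature}
        return set(genes)

    def present(self, cluster: str, strain: str) -> bool:
        """A cluster counts present iff the strain holds at least one
        gene without a premature stop."""
        return bool(self.genes_of_strain(cluster, strain, intact_only=True))

    def all_genes(self) -> set[str]:
        return set(self._gene_cluster)

    # -- serialization ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        data = {}
        for s in self.strain_ids:
            col = []
            for c in self.cluster_ids:
                genes = sorted(self._cells[c][s])
                col.append(",".join(g + ("!" if g in self.premature else "")
                                    for g in genes))
            data[s] = col
        return pd.DataFrame(data, index=pd.Index(self.cluster_ids,
                                                 name="cluster"))

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PAM":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         keep_default_na=False)
        pam = cls([str(c) for c in df.index], [str(s) for s in df.columns])
        for c in df.index:
            for s in df.columns:
                cell = df.loc[c, s]
                if not cell:
                    continue
                for token in str(cell).split(","):
                    premature = token.endswith("!")
                    pam.add_gene(str(c), str(s), token.rstrip("!"),
                                 premature=premature)
        return pam


def build_pam(clusters: list[Cluster], strain_ids: list[str],
              records: Iterable[ProteinRecord] | None = None) -> PAM:
    """Tabulate clusters into a PAM over the given strain columns.

    ``records`` supplies premature-stop flags; genes from strains not in
    ``strain_ids`` raise.
    """
    flags = {r.gene: r.premature_stop for r in records} if records else {}
    pam = PAM([c.id for c in clusters], list(strain_ids))
    for cl in clusters:
        for strain, genes in sorted(cl.members.items()):
            if strain not in pam._cells[cl.id]:
                raise KeyError(f"cluster {cl.id}: unknown strain {strain}")
            for g in sorted(genes):
                pam.add_gene(cl.id, strain, g, premature=flags.get(g, False))
    return pam


# ---------------------------------------------------------------------------
# gene recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneCoord:
    """0-based half-open CDS coordinates on a contig."""
    gene: str
    contig: str
    start: int
    end: int
    strand: str  # '+' | '-'


@dataclass
class RecoveryParams:
    min_region: int = 60          # bp, scenario (ii) minimum region
    min_orf_aa: int = 20          # minimum ORF length searched
    max_split_gap: int = 400      # bp between the two parts, scenario (i)
    min_extension_aa: int = 10    # scenario (iii) minimum extension


def read_gff3(path: str | Path) -> list[GeneCoord]:
    """Read CDS coordinates from GFF3 (1-based inclusive on disk,
    converted to 0-based half-open)."""
    coords: list[GeneCoord] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9 or parts[2] not in ("CDS", "gene"):
            continue
        attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
        gene = attrs.get("ID") or attrs.get("locus_tag")
        if gene is None:
            raise ValueError(f"GFF feature without ID: {line}")
        coords.append(GeneCoord(gene, parts[0], int(parts[3]) - 1,
                                int(parts[4]), parts[6]))
    return coords


def write_gff3(coords: list[GeneCoord], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for c in coords:
        lines.append("\t".join([c.contig, "panflux", "CDS", str(c.start + 1),
                                str(c.end), ".", c.strand, "0",
                                f"ID={c.gene}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def _translate(dna: str) -> str:
    trimmed = dna[:len(dna) - len(dna) % 3]
    return str(Seq(trimmed).translate())


def _cds_protein(genome: dict[str, str], c: GeneCoord) -> str:
    dna = genome[c.contig][c.start:c.end]
    if c.strand == "-":
        dna = str(Seq(dna).reverse_complement())
    return _translate(dna).rstrip("*")


@dataclass
class _Candidate:
    scenario: str
    contig: str
    span: tuple[int, int]
    sequence: str
    cluster: str
    identity: float
    premature: bool
    replaces: tuple[str, ...] = ()


def _best_cluster_hit(seq: str, clusters: list[Cluster],
                      params: ClusteringParams,
                      restrict: set[str] | None = None
                      ) -> tuple[Cluster, AlignmentStats] | None:
    best = None
    for cl in clusters:
        if restrict is not None and cl.id not in restrict:
            continue
        stats = screened_align(cl.rep_seq, seq, params.identity)
        if stats is not None and _matches(stats, params):
            key = (-stats.score, cl.id)
            if best is None or key < best[0]:
                best = (key, cl, stats)
    if best is None:
        return None
    return best[1], best[2]


def _unannotated_regions(contig_len: int, coords: list[GeneCoord]
                         ) -> list[tuple[int, int]]:
    regions = []
    pos = 0
    for c in sorted(coords, key=lambda c: c.start):
        if c.start > pos:
            regions.append((pos, c.start))
        pos = max(pos, c.end)
    if pos < contig_len:
        regions.append((pos, contig_len))
    return regions


def _orfs_six_frames(dna: str, min_aa: int) -> list[tuple[str, int, int]]:
    """(peptide, start, end) genomic spans of stop-free stretches in all
    six reading frames."""
    out = []
    rc = str(Seq(dna).reverse_complement())
    for strand, seq in (("+", dna), ("-", rc)):
        for frame in range(3):
            prot = _translate(seq[frame:])
            start_aa = 0
            for chunk in prot.split("*"):
                if len(chunk) >= min_aa:
                    s = frame + start_aa * 3
                    e = s + len(chunk) * 3
                    if strand == "-":
                        s, e = len(dna) - e, len(dna) - s
                    out.append((chunk, s, e))
                start_aa += len(chunk) + 1
    return out


def recover_genes(genome: dict[str, str], coords: list[GeneCoord],
                  clusters: list[Cluster], pam: PAM, strain: str,
                  clustering: ClusteringParams = ClusteringParams(),
                  params: RecoveryParams = RecoveryParams()
                  ) -> list[ProteinRecord]:
    """Run the three recovery scenarios for one strain, updating ``pam``
    and ``clusters`` in place.  Returns the recovered records.

    Overlapping candidate calls at the same locus are resolved keeping
    the highest identity, then the longest, then the lexicographically
    smallest sequence.
    """
    for c in coords:
        if c.contig not in genome:
            raise KeyError(f"GFF contig {c.contig} absent from genome")
    by_contig: dict[str, list[GeneCoord]] = {}
    for c in coords:
        by_contig.setdefault(c.contig, []).append(c)
    for lst in by_contig.values():
        lst.sort(key=lambda c: c.start)

    candidates: list[_Candidate] = []

    # -- scenario (i): adjacent same-strand calls from one broken ORF --
    for contig, genes in by_contig.items():
        for a, b in zip(genes, genes[1:]):
            if a.strand != b.strand or b.start - a.end > params.max_split_gap:
                continue
            first, second = (a, b) if a.strand == "+" else (b, a)
            concat = _cds_protein(genome, first) + _cds_protein(genome, second)
            hit = _best_cluster_hit(concat, clusters, clustering)
            if hit is None:
                continue
            cl, stats = hit
            candidates.append(_Candidate("i", contig, (a.start, b.end),
                                         concat, cl.id, stats.identity,
                                         premature=True,
                                         replaces=(a.gene, b.gene)))

    # -- scenario (iii): annotated call extendable into unannotated DNA --
    for contig, genes in by_contig.items():
        contig_seq = genome[contig]
        for i, g in enumerate(genes):
            nxt = genes[i + 1].start if i + 1 < len(genes) else len(contig_seq)
            prv = genes[i - 1].end if i > 0 else 0
            annotated = _cds_protein(genome, g)
            if g.strand == "+":
                window = contig_seq[g.start:nxt]
            else:
                window = str(Seq(contig_seq[prv:g.end]).reverse_complement())
            prot = _translate(window)
            extended = prot.split("*")[0]
            if len(extended) < len(annotated) + params.min_extension_aa:
                continue
            hit = _best_cluster_hit(extended, clusters, clustering)
            if hit is None:
                continue
            cl, stats = hit
            if g.gene in cl.all_genes():
                continue  # already assigned there; nothing to recover
            span = ((g.start, g.start + 3 * len(extended) + 3)
                    if g.strand == "+"
                    else (g.end - 3 * len(extended) - 3, g.end))
            candidates.append(_Candidate("iii", contig, span, extended,
                                         cl.id, stats.identity,
                                         premature=True, replaces=(g.gene,)))

    # -- scenario (ii): ORFs in unannotated regions ---------------------
    empty_clusters = {cl.id for cl in clusters
                      if not pam.genes_of_strain(cl.id, strain)}
    for contig, contig_seq in genome.items():
        regions = _unannotated_regions(len(contig_seq),
                                       by_contig.get(contig, []))
        for rs, re_ in regions:
            if re_ - rs < params.min_region:
                continue
            region = contig_seq[rs:re_]
            for pep, s, e in _orfs_six_frames(region, params.min_orf_aa):
                hit = _best_cluster_hit(pep, clusters, clustering,
                                        restrict=empty_clusters)
                if hit is None:
                    continue
                cl, stats = hit
                premature = "*" in pep
                candidates.append(_Candidate("ii", contig, (rs + s, rs + e),
                                             pep, cl.id, stats.identity,
                                             premature=premature))

    # -- resolve overlapping candidates ---------------------------------
    candidates.sort(key=lambda c: (-c.identity, -len(c.sequence), c.sequence))
    chosen: list[_Candidate] = []
    for cand in candidates:
        clash = any(c.contig == cand.contig
                    and c.span[0] < cand.span[1] and cand.span[0] < c.span[1]
                    for c in chosen)
        if not clash:
            chosen.append(cand)
    chosen.sort(key=lambda c: (c.contig, c.span))

    # -- apply ------------------------------------------------------------
    by_id = {cl.id: cl for cl in clusters}
    recovered: list[ProteinRecord] = []
    counter = 1
    for cand in chosen:
        gene_id = f"{strain}_rec{counter}"
        counter += 1
        rec = ProteinRecord(gene_id, strain, cand.sequence.replace("*", "X"),
                            premature_stop=cand.premature,
                            recovered_scenario=cand.scenario)
        for old in cand.replaces:
            old_cluster = pam.cluster_of(old)
            if old_cluster is not None:
                pam.remove_gene(old)
                oc = by_id.get(old_cluster)
                if oc is not None:
                    for genes in oc.members.values():
                        genes.discard(old)
                    if not oc.all_genes():
                        clusters.remove(oc)
                        del by_id[old_cluster]
        pam.add_gene(cand.cluster, strain, gene_id, premature=cand.premature)
        by_id[cand.cluster].add(rec)
        recovered.append(rec)
    return recovered
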