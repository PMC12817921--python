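"""Assembly statistics and strain quality filtering.

Strains are kept only if they satisfy all four thresholds: percent
missing and percent fragmented single-copy orthologs (from a completeness
table, e.g. a BUSCO summary), minimum N50 and maximum contig count.
Comparisons are inclusive: a strain exactly at a threshold is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO


@dataclass(frozen=True)
class AssemblyStats:
    strain: str
    n_contigs: int
    n50: int
    total_length: int


@dataclass(frozen=True)
class CompletenessRecord:
    strain: str
    pct_missing: float
    pct_fragmented: float

    def __post_init__(self) -> None:
        for v in (self.pct_missing, self.pct_fragmented):
            if not 0 <= v <= 100:
                raise ValueError(f"{self.strain}: percentages must be in [0,100]")


@dataclass(frozen=True)
class QCThresholds:
    """Defaults: <=2% missing, <=100% fragmented, N50 >= 50,000,
    <= 200 contigs."""
    max_missing_pct: float = 2.0
    max_fragmented_pct: float = 100.0
    min_n50: int = 50_000
    max_contigs: int = 200


def compute_n50(lengths: list[int]) -> int:
    """Length of the contig at which the descending cumulative length
    first reaches half the total."""
    if not lengths:
        raise ValueError("no contigs")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def assembly_stats(fasta_path: str | Path, strain: str | None = None) -> AssemblyStats:
    lengths = [len(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
               if len(rec.seq) > 0]
    if not lengths:
        raise ValueError(f"{fasta_path}: no non-empty sequences")
    return AssemblyStats(strain or Path(fasta_path).stem, len(lengths),
                         compute_n50(lengths), sum(lengths))


@dataclass
class QCReport:
    kept: set[str]
    discarded: set[str]
    reasons: dict[str, list[str]]  # failing criteria per discarded strain

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in sorted(self.kept | self.discarded):
            rows.append({"strain": s,
                         "kept": s in self.kept,
                         "reasons": ";".join(self.reasons.get(s, []))})
        return pd.DataFrame(rows)


def qc_filter(stats: list[AssemblyStats],
              completeness: list[CompletenessRecord],
              thresholds: QCThresholds = QCThresholds(),
              lenient: bool = False) -> QCReport:
    """Keep strains satisfying all thresholds; report every failing
    criterion for discarded strains.

    A strain with no completeness record raises, or is auto-discarded
    with reason ``no_completeness_record`` when ``lenient`` is set.
    """
    comp = {c.strain: c for c in completeness}
    kept: set[str] = set()
    discarded: set[str] = set()
    reasons: dict[str, list[str]] = {}
    for st in stats:
        fails: list[str] = []
        c = comp.get(st.strain)
        if c is None:
            if not lenient:
                raise KeyError(f"no completeness record for strain {st.strain}")
            fails.append("no_completeness_record")
        else:
            if c.pct_missing > thresholds.max_missing_pct:
                fails.append("max_missing_pct")
            if c.pct_fragmented > thresholds.max_fragmented_pct:
                fails.append("max_fragmented_pct")
        if st.n50 < thresholds.min_n50:
            fails.append("min_n50")
        if st.n_contigs > thresholds.max_contigs:
            fails.append("max_contigs")
        if fails:
            discarded.add(st.strain)
            reasons[st.strain] = fails
        else:
            kept.add(st.strain)
    return QCReport(kept, discarded, reasons)


def read_completeness_tsv(path: str | Path) -> list[CompletenessRecord]:
    df = pd.read_csv(path, sep="\t")
    return [CompletenessRecord(str(r.strain), float(r.pct_missing),
                               float(r.pct_fragmented))
            for r in df.itertuples()]
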