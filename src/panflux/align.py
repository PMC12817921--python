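"""Global pairwise sequence identity and coverage.

Identity follows the CD-HIT convention for global clustering: identical
aligned residues divided by the length of the shorter sequence.
Coverage of a sequence is the fraction of it inside the aligned core,
excluding terminal overhangs — the quantities CD-HIT constrains with
``-aL``/``-aS``.

Alignments are semi-global (global with free end gaps), so a fragment
aligns cleanly inside a full-length partner and its overhang shows up
as reduced coverage rather than as scattered gaps.  With the wide
identity margins this package's thresholds assume, the exact scoring
scheme does not move calls across thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import edlib
from Bio import Align


@dataclass(frozen=True)
class AlignmentStats:
    identity: float  # identical residues / len(shorter)
    coverage_a: float
    coverage_b: float

    @property
    def score(self) -> float:
        """identity x min coverage — the ranking score used for cluster
        assignment and ortholog mapping."""
        return self.identity * min(self.coverage_a, self.coverage_b)


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    # free end gaps: overhangs cost nothing and stay terminal
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def align_identity(seq_a: str, seq_b: str) -> AlignmentStats:
    """Align two sequences; return identity and both coverages."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    alignment = _aligner().align(seq_a, seq_b)[0]
    blocks_a, blocks_b = alignment.aligned
    if len(blocks_a) == 0:
        return AlignmentStats(0.0, 0.0, 0.0)
    matches = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        matches += sum(ca == cb
                       for ca, cb in zip(seq_a[as_:ae], seq_b[bs:be]))
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    identity = matches / min(len(seq_a), len(seq_b))
    return AlignmentStats(identity, span_a / len(seq_a),
                          span_b / len(seq_b))


def screened_align(seq_a: str, seq_b: str,
                   min_identity: float) -> AlignmentStats | None:
    """align_identity with a fast banded pre-screen.

    A pair that can possibly reach ``min_identity`` has a bounded edit
    distance for the shorter sequence placed freely inside the longer
    one; pairs beyond that band (with a 0.25 safety slack) are rejected
    without the exact alignment.  Returns None on rejection.
    """
    short, long_ = ((seq_a, seq_b) if len(seq_a) <= len(seq_b)
                    else (seq_b, seq_a))
    k = int(len(short) * (1.0 - min_identity + 0.25)) + 1
    if edlib.align(short, long_, mode="HW", k=k)["editDistance"] == -1:
        return None
    return align_identity(seq_a, seq_b)
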