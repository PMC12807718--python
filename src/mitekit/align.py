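"""Local protein alignment shared by sequence search and the SSN builder.

Smith–Waterman with BLOSUM62 and BLASTp-like affine gaps (open 11, extend 1),
so identity thresholds phrased as fractions (e.g. the common 0.7 convention)
are comparable to BLASTp practice. Identity is computed over the columns of
the best local alignment, counting gap columns in the denominator:

    identity = matches / (matches + mismatches + gaps)
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def local_identity(query: str, subject: str) -> tuple[float, float]:
    """Best local alignment of *query* vs *subject*.

    Returns ``(identity, score)``; identity is 0.0 when no positive-scoring
    local alignment exists. Ties between co-optimal alignments are resolved by
    taking the first alignment in the aligner's deterministic enumeration.
    """
    query = query.strip().upper()
    subject = subject.strip().upper()
    if not query or not subject:
        return 0.0, 0.0
    aligner = _aligner()
    score = aligner.score(query, subject)
    if score <= 0:
        return 0.0, float(score)
    alignment = next(iter(aligner.align(query, subject)))
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return 0.0, float(score)
    return counts.identities / columns, float(score)
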