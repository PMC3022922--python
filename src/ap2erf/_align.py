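"""Shared pairwise global alignment helpers (Needleman-Wunsch, affine gaps)."""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@lru_cache(maxsize=None)
def make_aligner(matrix: str = "BLOSUM62",
                 open_gap: float = -10.0,
                 extend_gap: float = -0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def align_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Fraction of identical residues over aligned columns, excluding any
    column where either sequence carries a gap ("pairwise deletion")."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    retained = counts.identities + counts.mismatches
    if retained == 0:
        return 0.0
    return counts.identities / retained


def align_p_distance(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Pairwise-deletion p-distance: mismatches / gap-free aligned columns."""
    return 1.0 - align_identity(a, b, aligner)
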