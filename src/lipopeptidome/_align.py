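"""Low-level pairwise sequence helpers shared across modules.

Identity here is Levenshtein-based: ``1 - edit_distance / max(len)``.  This
definition is unique (no dependence on which co-optimal alignment a DP
traceback happens to return), symmetric, and 1.0 exactly for identical
sequences, which makes nearest-reference classification order-free and
reproducible.  Blosum62-scored global alignment (used for the windowed
identity profiles) is delegated to Biopython.
"""

from __future__ import annotations

from functools import lru_cache

import edlib

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA20_SET = frozenset(AA20)


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit costs), computed with edlib."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def sequence_identity(a: str, b: str) -> float:
    """Fractional identity ``1 - d/max(|a|,|b|)`` in [0, 1]."""
    if not a and not b:
        raise ValueError("identity of two empty sequences is undefined")
    return 1.0 - edit_distance(a, b) / max(len(a), len(b))


def validate_protein(seq: str, *, name: str = "sequence") -> str:
    """Reject empty input or characters outside the 20 standard amino acids."""
    if not seq:
        raise ValueError(f"{name} is empty")
    bad = set(seq) - _AA20_SET
    if bad:
        raise ValueError(
            f"{name} contains non-amino-acid characters: {sorted(bad)}"
        )
    return seq


@lru_cache(maxsize=1)
def _blosum62_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def blosum62_global(a: str, b: str) -> tuple[str, str]:
    """Blosum62-scored global alignment; returns the two gapped strings."""
    validate_protein(a, name="first sequence")
    validate_protein(b, name="second sequence")
    alignment = _blosum62_aligner().align(a, b)[0]
    return str(alignment[0]), str(alignment[1])
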