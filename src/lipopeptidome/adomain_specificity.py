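"""Substrate-specificity calls for adenylation domains.

Specificity is assigned by nearest reference over pairwise sequence
identity — operationally the same reading as placing a query inside a
specificity clade of an A-domain tree, but deterministic and
order-free.  The classifier reproduces the clade behaviour seen across
Pseudomonas LP synthetases: homogeneous Leu/Val/Ser clades classify
cleanly; the promiscuous Ile clade can also recruit Val or Leu, so
moderate-confidence Ile calls carry a {Val, Leu} promiscuity note; and
Glu/Gln/Asp domains intermix, so low-confidence acidic calls inflate each
other's ambiguity set (this is what hampers Gln2-vs-Glu2 distinctions
among Viscosin-family peptides).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from ._align import sequence_identity, validate_protein
from .knowledge_base import ReferenceADomain

#: expand the ambiguity set to all specificities within this identity of the best
DEFAULT_AMBIGUITY_DELTA = 0.05
#: below this confidence, Glu/Gln/Asp calls mutually inflate ambiguity
ACIDIC_CLADE_THRESHOLD = 0.75
ACIDIC_CLADE = frozenset({"Glu", "Gln", "Asp"})
#: below this confidence, Ile calls are flagged promiscuous for {Val, Leu}
ILE_PROMISCUITY_THRESHOLD = 0.9
#: below this identity floor a call is reported as unknown
UNKNOWN_FLOOR = 0.4


class ClassifierConfigError(ValueError):
    """Empty or unusable reference set."""


@dataclass
class SpecificityCall:
    """Predicted substrate of one A domain."""

    primary: str
    confidence: float
    ambiguity_set: frozenset[str]
    promiscuity: frozenset[str] = frozenset()
    neighbor_id: str = ""

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")
        if self.primary not in self.ambiguity_set:
            raise ValueError("primary must be a member of the ambiguity set")

    @property
    def is_ambiguous(self) -> bool:
        return self.primary == "unknown" or len(self.ambiguity_set) > 1


def adomain_identity(a: str, b: str) -> float:
    """Fractional identity between two A-domain sequences (symmetric)."""
    validate_protein(a, name="first A domain")
    validate_protein(b, name="second A domain")
    return sequence_identity(a, b)


def classify(
    a_sequence: str,
    refs: Sequence[ReferenceADomain],
    *,
    delta: float = DEFAULT_AMBIGUITY_DELTA,
    acidic_threshold: float = ACIDIC_CLADE_THRESHOLD,
    ile_threshold: float = ILE_PROMISCUITY_THRESHOLD,
    floor: float = UNKNOWN_FLOOR,
) -> SpecificityCall:
    """Nearest-reference specificity call with ambiguity handling.

    Ties at exactly equal identity are broken by lexicographically
    smallest reference id (so permuting the reference list never changes
    the call) and inflate the ambiguity set with every tied specificity.
    """
    if not refs:
        raise ClassifierConfigError("empty reference set")
    validate_protein(a_sequence, name="query A domain")

    scored = sorted(
        ((sequence_identity(a_sequence, r.sequence), r) for r in refs),
        key=lambda t: (-t[0], t[1].id),
    )
    best_score, best_ref = scored[0]

    if best_score < floor:
        return SpecificityCall(
            primary="unknown",
            confidence=best_score,
            ambiguity_set=frozenset({"unknown"}),
            neighbor_id=best_ref.id,
        )

    ambiguity = {
        ref.specificity for score, ref in scored if score >= best_score - delta
    }
    primary = best_ref.specificity
    if primary in ACIDIC_CLADE and best_score < acidic_threshold:
        ambiguity |= ACIDIC_CLADE
    promiscuity: frozenset[str] = frozenset()
    if primary == "Ile" and best_score < ile_threshold:
        promiscuity = frozenset({"Val", "Leu"})
    return SpecificityCall(
        primary=primary,
        confidence=best_score,
        ambiguity_set=frozenset(ambiguity),
        promiscuity=promiscuity,
        neighbor_id=best_ref.id,
    )


def clade_tree(
    sequences: dict[str, str],
    labels: dict[str, str],
):
    """NJ tree over identity distances plus a per-specificity monophyly report.

    ``sequences`` maps leaf id -> A-domain sequence and ``labels`` maps
    leaf id -> specificity.  A specificity is monophyletic when some
    bipartition of the tree separates exactly its leaves (trivially true
    for a single specificity).
    """
    from . import phylogenetics

    if len(sequences) < 4:
        raise ValueError("need at least 4 sequences for a clade tree")
    dm = phylogenetics.distance_matrix(sequences, identity_fn=adomain_identity)
    tree = phylogenetics.nj_tree(dm)
    splits = phylogenetics.tree_splits(tree)
    all_leaves = frozenset(sequences)
    monophyly: dict[str, bool] = {}
    for spec in sorted(set(labels.values())):
        group = frozenset(k for k, v in labels.items() if v == spec)
        if len(group) in (1, len(all_leaves)):
            monophyly[spec] = True
            continue
        monophyly[spec] = any(
            group in split for split in splits
        )
    return tree, monophyly


def export_calls_tsv(calls: dict[str, SpecificityCall], path) -> None:
    """Write calls as TSV: id, primary, confidence, ambiguity, promiscuity."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["query_id", "primary", "confidence", "ambiguity_set",
             "promiscuity", "neighbor_id"]
        )
        for qid in sorted(calls):
            call = calls[qid]
            writer.writerow(
                [
                    qid,
                    call.primary,
                    f"{call.confidence:.4f}",
                    ";".join(sorted(call.ambiguity_set)),
                    ";".join(sorted(call.promiscuity)),
                    call.neighbor_id,
                ]
            )


def read_reference_fasta(path) -> list[ReferenceADomain]:
    """Load a labelled reference FASTA (header: ``id|specificity|system|position``)."""
    refs: list[ReferenceADomain] = []
    header: Optional[str] = None
    chunks: list[str] = []

    def _emit():
        if header is None:
            return
        parts = header.split("|")
        refs.append(
            ReferenceADomain(
                id=parts[0],
                sequence="".join(chunks),
                specificity=parts[1] if len(parts) > 1 else "",
                system=parts[2] if len(parts) > 2 else "",
                position=int(parts[3]) if len(parts) > 3 else 0,
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                _emit()
                header = line[1:]
                chunks = []
            elif line:
                chunks.append(line)
    _emit()
    return refs
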