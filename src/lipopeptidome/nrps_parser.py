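"""Domain calling, module segmentation and multi-gene NRPS assembly.

Pseudomonas lipopeptide synthetases are chains of C-A-T modules: a starter
condensation domain (Cs) acylates the first residue with the fatty acid,
every further module condenses (``LCL`` or dual-function ``CE``), selects
(A) and tethers (T) one residue, and the terminal enzyme releases the
product through a tandem of two thioesterase (TE) domains.  Standalone
epimerization (E) domains never occur in these systems — they are called
here only so the miner can exclude siderophore-type synthetases.

The domain caller is a windowed nearest-reference scan: every reference
exemplar is slid along the protein (coarse stride, then local refinement)
and scored by Levenshtein identity; hits are selected greedily best-first
with overlap suppression.  An adapter reads externally produced domain
tables in the same TSV dialect for real-genome use.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from ._align import sequence_identity, validate_protein

C_KINDS = ("Cs", "LCL", "CE")
DOMAIN_KINDS = ("Cs", "LCL", "CE", "A", "T", "TE", "E")

#: Minimum identity to the best reference for a hit to be reported.
DEFAULT_SCORE_THRESHOLD = 0.5
#: Coarse-scan stride in residues; candidate windows are refined locally.
DEFAULT_STRIDE = 10


class DomainCallError(ValueError):
    """Invalid input to the domain caller."""


class ModuleParseError(ValueError):
    """Domain string cannot be segmented into modules."""


class AssemblyError(ValueError):
    """Gene set cannot be assembled into a single NRPS system."""


@dataclass(frozen=True)
class DomainRef:
    """A reference exemplar for one domain kind.

    A-domain references additionally carry the substrate ``specificity``
    label used downstream by the classifier.
    """

    id: str
    kind: str
    sequence: str
    specificity: Optional[str] = None

    def __post_init__(self):
        if self.kind not in DOMAIN_KINDS:
            raise ValueError(f"unknown domain kind {self.kind!r}")
        validate_protein(self.sequence, name=f"reference {self.id!r}")


@dataclass(frozen=True)
class DomainAnnotation:
    """One called domain; coordinates are 0-based half-open on the protein."""

    kind: str
    start: int
    end: int
    score: float
    reference_id: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("domain annotation requires start < end")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("domain score must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Module:
    """One C-A-T elongation unit; ``index`` is 1-based along the peptide."""

    index: int
    c_kind: str  # Cs | LCL | CE | none
    a_sequence: Optional[str]
    has_T: bool
    a_span: Optional[tuple[int, int]] = None


@dataclass
class ParsedGene:
    """A protein with called domains, segmented modules and warnings."""

    gene_id: str
    protein: str
    domains: list[DomainAnnotation]
    modules: list[Module]
    warnings: list[str] = field(default_factory=list)
    genomic_order: Optional[int] = None

    @property
    def domain_string(self) -> tuple[str, ...]:
        return tuple(d.kind for d in self.domains)

    @property
    def starts_with_cs(self) -> bool:
        return bool(self.domains) and self.domains[0].kind == "Cs"

    @property
    def terminal_te_count(self) -> int:
        n = 0
        for d in reversed(self.domains):
            if d.kind == "TE":
                n += 1
            else:
                break
        return n

    @property
    def te_count(self) -> int:
        return sum(1 for d in self.domains if d.kind == "TE")

    @property
    def has_standalone_e(self) -> bool:
        return any(d.kind == "E" for d in self.domains)


@dataclass
class NrpsSystem:
    """Modules of a complete LP synthetase in biosynthetic order."""

    id: str
    genes: list[str]
    modules: list[Module]
    te_tandem: bool
    concatenate: str
    module_config: tuple[int, ...] = ()

    @property
    def a_sequences(self) -> list[str]:
        return [m.a_sequence or "" for m in self.modules]


# ---------------------------------------------------------------------------
# domain calling


def _refine(protein: str, ref: DomainRef, coarse_start: int, stride: int):
    """Best (score, start) in the +-stride neighbourhood of a coarse hit."""
    n, length = len(protein), len(ref.sequence)
    best = (-1.0, coarse_start)
    lo = max(0, coarse_start - stride + 1)
    hi = min(max(n - length, 0), coarse_start + stride - 1)
    for p in range(lo, hi + 1):
        window = protein[p : p + length]
        score = sequence_identity(window, ref.sequence)
        if score > best[0]:
            best = (score, p)
    return best


def call_domains(
    protein: str,
    refs: Sequence[DomainRef],
    *,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    per_kind_thresholds: Optional[dict[str, float]] = None,
    stride: int = DEFAULT_STRIDE,
    max_overlap_frac: float = 0.1,
) -> list[DomainAnnotation]:
    """Call non-overlapping domains on ``protein`` against ``refs``.

    Greedy best-score-first selection; ties broken by higher score, then
    longer hit, then smaller start, then reference id (deterministic and
    permutation-stable).  Hits below the per-kind threshold (default
    ``score_threshold`` for every kind) are dropped.
    """
    validate_protein(protein, name="protein")
    if not refs:
        raise DomainCallError("empty domain reference library")
    thresholds = {k: score_threshold for k in DOMAIN_KINDS}
    if per_kind_thresholds:
        thresholds.update(per_kind_thresholds)
    coarse_floor = min(thresholds.values()) - 0.1

    candidates: list[DomainAnnotation] = []
    n = len(protein)
    for ref in refs:
        length = len(ref.sequence)
        if n < length // 2:
            continue
        starts = list(range(0, max(n - length, 0) + 1, stride))
        last = max(n - length, 0)
        if starts[-1] != last:
            starts.append(last)
        seen: set[int] = set()
        for p in starts:
            window = protein[p : p + length]
            if sequence_identity(window, ref.sequence) < coarse_floor:
                continue
            score, start = _refine(protein, ref, p, stride)
            end = min(start + length, n)
            if score >= thresholds[ref.kind] and start not in seen:
                seen.add(start)
                candidates.append(
                    DomainAnnotation(ref.kind, start, end, score, ref.id)
                )

    # greedy overlap suppression
    candidates.sort(key=lambda d: (-d.score, -d.length, d.start, d.reference_id))
    accepted: list[DomainAnnotation] = []
    for cand in candidates:
        ok = True
        for acc in accepted:
            overlap = min(cand.end, acc.end) - max(cand.start, acc.start)
            if overlap > max_overlap_frac * min(cand.length, acc.length):
                ok = False
                break
        if ok:
            accepted.append(cand)
    accepted.sort(key=lambda d: d.start)
    return accepted


# ---------------------------------------------------------------------------
# module segmentation


def segment_modules(
    domains: Sequence[DomainAnnotation],
    protein: Optional[str] = None,
) -> tuple[list[Module], list[str]]:
    """Split an ordered domain string into C-A-T modules.

    Modules are delimited at every C-type domain; trailing TE domains
    belong to the final module's gene.  Returns ``(modules, warnings)``;
    warnings flag modules without a C domain, A domains without T, and
    C domains without a following A (the latter are dropped).
    """
    if not any(d.kind == "A" for d in domains):
        raise ModuleParseError("no A domains: cannot segment into modules")
    modules: list[Module] = []
    warnings: list[str] = []
    current: Optional[Module] = None

    def _push():
        nonlocal current
        if current is None:
            return
        if current.a_sequence is None and current.a_span is None:
            warnings.append(
                f"module {current.index}: C domain without following A (dropped)"
            )
        else:
            if not current.has_T:
                warnings.append(f"module {current.index}: A domain without T")
            modules.append(current)
        current = None

    next_index = 1
    for dom in domains:
        if dom.kind in C_KINDS:
            _push()
            current = Module(next_index, dom.kind, None, False)
            next_index += 1
        elif dom.kind == "A":
            if current is None or current.a_span is not None:
                if current is not None:
                    _push()
                warnings.append(f"module {next_index}: module without C domain")
                current = Module(next_index, "none", None, False)
                next_index += 1
            current.a_span = (dom.start, dom.end)
            if protein is not None:
                current.a_sequence = protein[dom.start : dom.end]
        elif dom.kind == "T":
            if current is not None:
                current.has_T = True
        # TE and E domains are gene-level features, not module members
    _push()
    for i, mod in enumerate(modules, start=1):
        mod.index = i
    return modules, warnings


def parse_gene(
    gene_id: str,
    protein: str,
    refs: Sequence[DomainRef],
    *,
    genomic_order: Optional[int] = None,
    **call_kwargs,
) -> ParsedGene:
    """Call domains on one protein and segment them into modules."""
    domains = call_domains(protein, refs, **call_kwargs)
    if any(d.kind == "A" for d in domains):
        modules, warnings = segment_modules(domains, protein)
    else:
        modules, warnings = [], []
    return ParsedGene(gene_id, protein, domains, modules, warnings, genomic_order)


# ---------------------------------------------------------------------------
# system assembly


def assemble_system(
    genes: Sequence[ParsedGene],
    order_hint: str = "operon_order",
    *,
    system_id: Optional[str] = None,
) -> NrpsSystem:
    """Concatenate parsed genes into one system in biosynthetic order.

    The Cs-initiated gene goes first and the tandem-TE gene last; middle
    genes keep genomic order (``genomic_order`` attribute when present,
    otherwise input order).  ``order_hint`` is accepted for API symmetry;
    both modes resolve identically because ordering is marker-driven.
    """
    if order_hint not in ("operon_order", "initiator_first"):
        raise ValueError(f"unknown order hint {order_hint!r}")
    genes = list(genes)
    if not genes:
        raise AssemblyError("no genes to assemble")
    cs_genes = [g for g in genes if g.starts_with_cs]
    if len(cs_genes) != 1:
        raise AssemblyError(
            "expected exactly one Cs-initiated gene, found "
            f"{len(cs_genes)}: {[g.gene_id for g in cs_genes]}"
        )
    initiator = cs_genes[0]
    te_genes = [g for g in genes if g.terminal_te_count >= 2]
    if len(te_genes) > 1:
        raise AssemblyError(
            f"multiple tandem-TE genes: {[g.gene_id for g in te_genes]}"
        )
    te_tandem = bool(te_genes)
    if te_genes:
        terminator = te_genes[0]
    else:
        # no valid LP terminator; keep a deterministic order anyway
        tail = [g for g in genes if g is not initiator]
        terminator = tail[-1] if tail else initiator

    middle = [g for g in genes if g is not initiator and g is not terminator]
    if all(g.genomic_order is not None for g in middle):
        middle.sort(key=lambda g: g.genomic_order)
    ordered = [initiator] + middle + ([terminator] if terminator is not initiator else [])

    modules: list[Module] = []
    config: list[int] = []
    for gene in ordered:
        config.append(len(gene.modules))
        modules.extend(gene.modules)
    for i, mod in enumerate(modules, start=1):
        mod.index = i
    return NrpsSystem(
        id=system_id or "+".join(g.gene_id for g in ordered),
        genes=[g.gene_id for g in ordered],
        modules=modules,
        te_tandem=te_tandem,
        concatenate="".join(g.protein for g in ordered),
        module_config=tuple(config),
    )


# ---------------------------------------------------------------------------
# domain-table TSV adapter (0-based half-open coordinates)

_TSV_FIELDS = ["protein_id", "kind", "start", "end", "score", "reference_id"]


def write_domain_table(
    table: dict[str, Sequence[DomainAnnotation]], path: str | Path
) -> None:
    """Write per-protein domain annotations as TSV (0-based half-open)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_FIELDS)
        for protein_id in sorted(table):
            for d in table[protein_id]:
                writer.writerow(
                    [protein_id, d.kind, d.start, d.end, f"{d.score:.4f}", d.reference_id]
                )


def read_domain_table(path: str | Path) -> dict[str, list[DomainAnnotation]]:
    """Read third-party domain annotations in the same TSV dialect."""
    out: dict[str, list[DomainAnnotation]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.setdefault(row["protein_id"], []).append(
                DomainAnnotation(
                    kind=row["kind"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    score=float(row["score"]),
                    reference_id=row["reference_id"],
                )
            )
    for annotations in out.values():
        annotations.sort(key=lambda d: d.start)
    return out
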