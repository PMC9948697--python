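"""Mining annotated genomes for lipopeptide BGCs.

The diagnostic rules: candidate genes carry at least one adenylation and
one condensation-type domain; valid LP systems terminate in a tandem of
two thioesterase domains and contain no standalone epimerization domain
(single-TE or E-carrying systems are siderophore/Mycin-type and are
excluded, as are fragmented genes); flanking synteny (antisense LuxR
regulator upstream, PleC, PleA/PleB downstream, SyrD/Dab or MFS accessory
genes) is scored as supporting evidence; and split ("bifurcate") clusters
are resolved by pairing an orphan Cs-initiated gene with the operon whose
module count completes a known family total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from ._align import sequence_identity
from .knowledge_base import KnowledgeBase, default_knowledge_base
from .nrps_parser import (
    AssemblyError,
    DomainRef,
    NrpsSystem,
    ParsedGene,
    assemble_system,
    parse_gene,
)

#: neighbour scan window for flanking-gene roles: 5 genes / 10 kbp each side
SYNTENY_WINDOW_GENES = 5
SYNTENY_WINDOW_BP = 10_000
#: maximal intergenic gap (bp) between NRPS genes of one cluster; real
#: intra-operon spacers are 150-300 bp, so this is generous
CLUSTER_MAX_GAP = 5_000


class GenomeReadError(IOError):
    """Record could not be parsed."""


class AmbiguousPairingError(ValueError):
    """Multiple equally good initiator/operon pairings."""

    def __init__(self, pairings):
        self.pairings = pairings
        super().__init__(
            "ambiguous initiator/operon pairing; candidates (initiator, "
            f"operon, score): {pairings}"
        )


@dataclass(frozen=True)
class GenomeGene:
    """One annotated CDS; coordinates 0-based half-open on its record."""

    gene_id: str
    record_id: str
    start: int
    end: int
    strand: int
    product: str
    translation: str


@dataclass
class CandidateGene:
    gene: GenomeGene
    parsed: ParsedGene
    internal_stop: bool = False


@dataclass
class Cluster:
    """A run of neighbouring candidate NRPS genes on one record."""

    record_id: str
    candidates: list[CandidateGene]

    @property
    def start(self) -> int:
        return min(c.gene.start for c in self.candidates)

    @property
    def end(self) -> int:
        return max(c.gene.end for c in self.candidates)

    @property
    def n_modules(self) -> int:
        return sum(len(c.parsed.modules) for c in self.candidates)

    @property
    def has_initiator(self) -> bool:
        return any(c.parsed.starts_with_cs for c in self.candidates)

    @property
    def has_te_tandem(self) -> bool:
        return any(c.parsed.terminal_te_count >= 2 for c in self.candidates)

    @property
    def total_te(self) -> int:
        return sum(c.parsed.te_count for c in self.candidates)


@dataclass
class SyntenyReport:
    """Role-labelled flanking-gene evidence around a cluster."""

    upstream_regulator: str = "absent"  # present_antisense | present_sense | absent
    pleC: bool = False
    pleAB: bool = False
    second_regulator: bool = False
    accessory: str = "none"  # none | syrD_dab | mfs


@dataclass
class BgcRecord:
    """One mined LP BGC (or an incomplete partial system)."""

    genome_id: str
    system: Optional[NrpsSystem]
    organization: str  # contiguous | bifurcate
    inter_cluster_distance: Optional[int]
    synteny: SyntenyReport
    exclusion_flags: list[str] = field(default_factory=list)
    spacers: list[int] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)


@dataclass
class MiningResult:
    genome_id: str
    bgcs: list[BgcRecord]
    excluded: list[tuple[Cluster, list[str]]]


# ---------------------------------------------------------------------------
# genome reading


def read_genome(source) -> list[GenomeGene]:
    """Extract CDS genes (with protein translations) from annotated records.

    ``source`` may be a GenBank file path or an iterable of Biopython
    ``SeqRecord`` objects.  Output is sorted by (record id, start) so the
    miner is invariant under record-order permutation.
    """
    from Bio import SeqIO

    if isinstance(source, (str, Path)):
        try:
            records = list(SeqIO.parse(str(source), "genbank"))
        except Exception as exc:  # pragma: no cover - biopython error text varies
            raise GenomeReadError(f"cannot parse {source}: {exc}") from exc
    else:
        records = list(source)
    genes: list[GenomeGene] = []
    for rec in records:
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            if "translation" not in quals:
                continue
            locus = quals.get("locus_tag", quals.get("gene", ["?"]))[0]
            genes.append(
                GenomeGene(
                    gene_id=locus,
                    record_id=rec.id,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand=int(feat.location.strand or 1),
                    product=quals.get("product", [""])[0],
                    translation=quals["translation"][0],
                )
            )
    genes.sort(key=lambda g: (g.record_id, g.start))
    return genes


# ---------------------------------------------------------------------------
# candidate detection and exclusion rules


def find_candidates(
    genes: Sequence[GenomeGene],
    refs: Sequence[DomainRef],
    **call_kwargs,
) -> list[CandidateGene]:
    """Genes with >= 1 called A domain and >= 1 C-type domain."""
    out: list[CandidateGene] = []
    for gene in genes:
        translation = gene.translation.rstrip("*")
        internal_stop = "*" in translation
        cleaned = translation.replace("*", "G")
        if not cleaned:
            continue
        parsed = parse_gene(gene.gene_id, cleaned, refs, **call_kwargs)
        kinds = set(parsed.domain_string)
        if "A" in kinds and kinds & {"Cs", "LCL", "CE"}:
            out.append(CandidateGene(gene, parsed, internal_stop))
    return out


def cluster_candidates(
    candidates: Sequence[CandidateGene], max_gap: int = CLUSTER_MAX_GAP
) -> list[Cluster]:
    """Group candidates into proximity runs per record."""
    clusters: list[Cluster] = []
    by_record: dict[str, list[CandidateGene]] = {}
    for cand in candidates:
        by_record.setdefault(cand.gene.record_id, []).append(cand)
    for record_id in sorted(by_record):
        run: list[CandidateGene] = []
        for cand in sorted(by_record[record_id], key=lambda c: c.gene.start):
            if run and cand.gene.start - run[-1].gene.end > max_gap:
                clusters.append(Cluster(record_id, run))
                run = []
            run.append(cand)
        if run:
            clusters.append(Cluster(record_id, run))
    return clusters


def apply_exclusions(
    clusters: Sequence[Cluster],
) -> tuple[list[Cluster], list[tuple[Cluster, list[str]]]]:
    """Drop siderophore-type (single TE), standalone-E and fragmented clusters."""
    kept: list[Cluster] = []
    excluded: list[tuple[Cluster, list[str]]] = []
    for cluster in clusters:
        flags: list[str] = []
        if any(c.parsed.has_standalone_e for c in cluster.candidates):
            flags.append("standalone_E")
        if cluster.total_te == 1:
            flags.append("single_TE")
        if any(c.internal_stop for c in cluster.candidates):
            flags.append("fragment")
        if flags:
            excluded.append((cluster, flags))
        else:
            kept.append(cluster)
    return kept, excluded


# ---------------------------------------------------------------------------
# flanking synteny

_ROLE_KEYWORDS = (
    ("luxr", "regulator"),
    ("plec", "pleC"),
    ("plea", "pleA"),
    ("pleb", "pleB"),
    ("syrd", "syrD"),
    ("aminotransferase", "dab"),
    ("major facilitator", "mfs"),
)


def _gene_role(product: str) -> Optional[str]:
    text = product.lower()
    for key, role in _ROLE_KEYWORDS:
        if key in text:
            return role
    return None


def check_synteny(
    cluster: Cluster,
    genes: Sequence[GenomeGene],
    *,
    window_genes: int = SYNTENY_WINDOW_GENES,
    window_bp: int = SYNTENY_WINDOW_BP,
    report: Optional[SyntenyReport] = None,
) -> SyntenyReport:
    """Role-labelled neighbour scan around one cluster.

    Passing an existing ``report`` merges evidence across the parts of a
    bifurcate system.
    """
    rep = report or SyntenyReport()
    cluster_ids = {c.gene.gene_id for c in cluster.candidates}
    cluster_strand = cluster.candidates[0].gene.strand
    same_record = [
        g for g in genes if g.record_id == cluster.record_id and g.gene_id not in cluster_ids
    ]
    before = [g for g in same_record if g.end <= cluster.start]
    after = [g for g in same_record if g.start >= cluster.end]
    before = [
        g
        for g in sorted(before, key=lambda g: -g.end)[:window_genes]
        if cluster.start - g.end <= window_bp
    ]
    after = [
        g
        for g in sorted(after, key=lambda g: g.start)[:window_genes]
        if g.start - cluster.end <= window_bp
    ]

    found_dab = rep.accessory == "syrD_dab"
    found_syrd = rep.accessory == "syrD_dab"
    found_mfs = rep.accessory == "mfs"
    found_pleA = found_pleB = False
    for side, neighbours in (("up", before), ("down", after)):
        for g in neighbours:
            role = _gene_role(g.product)
            if role is None:
                continue
            if role == "regulator":
                if side == "up" and rep.upstream_regulator == "absent":
                    rep.upstream_regulator = (
                        "present_antisense"
                        if g.strand != cluster_strand
                        else "present_sense"
                    )
                elif side == "down":
                    rep.second_regulator = True
            elif role == "pleC":
                rep.pleC = True
            elif role == "pleA":
                found_pleA = True
            elif role == "pleB":
                found_pleB = True
            elif role == "syrD":
                found_syrd = True
            elif role == "dab":
                found_dab = True
            elif role == "mfs":
                found_mfs = True
    if found_pleA and found_pleB:
        rep.pleAB = True
    if found_syrd and found_dab:
        rep.accessory = "syrD_dab"
    elif found_mfs and rep.accessory == "none":
        rep.accessory = "mfs"
    return rep


# ---------------------------------------------------------------------------
# organization resolution


def _assemble_cluster(cluster: Cluster, system_id: str) -> NrpsSystem:
    parsed = []
    for order, cand in enumerate(
        sorted(cluster.candidates, key=lambda c: c.gene.start)
    ):
        cand.parsed.genomic_order = order
        parsed.append(cand.parsed)
    return assemble_system(parsed, system_id=system_id)


def _cluster_spacers(cluster: Cluster) -> list[int]:
    ordered = sorted(cluster.candidates, key=lambda c: c.gene.start)
    return [
        nxt.gene.start - prev.gene.end for prev, nxt in zip(ordered, ordered[1:])
    ]


def _mean_cross_identity(init: Cluster, operon: Cluster) -> float:
    init_a = [
        m.a_sequence
        for c in init.candidates
        for m in c.parsed.modules
        if m.a_sequence
    ]
    op_a = [
        m.a_sequence
        for c in operon.candidates
        for m in c.parsed.modules
        if m.a_sequence
    ]
    if not init_a or not op_a:
        return 0.0
    scores = [max(sequence_identity(a, b) for b in op_a) for a in init_a]
    return float(sum(scores) / len(scores))


def resolve_organization(
    clusters: Sequence[Cluster],
    genes: Sequence[GenomeGene],
    *,
    kb: Optional[KnowledgeBase] = None,
    genome_id: str = "genome",
) -> list[BgcRecord]:
    """Build BgcRecords: contiguous clusters directly, split ones by pairing.

    An orphan Cs-initiated cluster is paired with the operon whose module
    count best completes a knowledge-base family total (ties broken by
    A-domain homology between the parts, then by coordinates).  Unpaired
    partial systems are flagged ``incomplete``.
    """
    kb = kb or default_knowledge_base()
    family_totals = sorted({f.peptide_length for f in kb.list_families()})

    complete: list[Cluster] = []
    initiators: list[Cluster] = []
    operons: list[Cluster] = []
    partials: list[Cluster] = []
    for cluster in clusters:
        if cluster.has_initiator and cluster.has_te_tandem:
            complete.append(cluster)
        elif cluster.has_initiator:
            initiators.append(cluster)
        elif cluster.has_te_tandem:
            operons.append(cluster)
        else:
            partials.append(cluster)

    records: list[BgcRecord] = []
    n = 0

    def _synteny_for(*parts: Cluster) -> SyntenyReport:
        rep: Optional[SyntenyReport] = None
        for part in parts:
            rep = check_synteny(part, genes, report=rep)
        return rep or SyntenyReport()

    for cluster in complete:
        n += 1
        system = _assemble_cluster(cluster, f"{genome_id}_sys{n}")
        records.append(
            BgcRecord(
                genome_id=genome_id,
                system=system,
                organization="contiguous",
                inter_cluster_distance=None,
                synteny=_synteny_for(cluster),
                spacers=_cluster_spacers(cluster),
                gene_ids=[c.gene.gene_id for c in cluster.candidates],
            )
        )

    # pair orphan initiators with operons
    used_operons: set[int] = set()
    for init in initiators:
        scored = []
        for j, operon in enumerate(operons):
            if j in used_operons:
                continue
            total = init.n_modules + operon.n_modules
            arch_score = min(abs(total - t) for t in family_totals)
            scored.append((arch_score, -_mean_cross_identity(init, operon), j))
        if scored:
            scored.sort()
            if len(scored) > 1 and scored[0][:2] == scored[1][:2]:
                raise AmbiguousPairingError(
                    [(init.record_id, operons[s[2]].record_id, s[0]) for s in scored]
                )
            best = scored[0]
            operon = operons[best[2]]
            used_operons.add(best[2])
            n += 1
            merged = Cluster(
                record_id=operon.record_id,
                candidates=list(init.candidates) + list(operon.candidates),
            )
            parsed = []
            for order, cand in enumerate(
                sorted(init.candidates, key=lambda c: c.gene.start)
                + sorted(operon.candidates, key=lambda c: c.gene.start)
            ):
                cand.parsed.genomic_order = order
                parsed.append(cand.parsed)
            system = assemble_system(parsed, system_id=f"{genome_id}_sys{n}")
            distance = (
                operon.start - init.end
                if operon.record_id == init.record_id
                else None
            )
            records.append(
                BgcRecord(
                    genome_id=genome_id,
                    system=system,
                    organization="bifurcate",
                    inter_cluster_distance=distance,
                    synteny=_synteny_for(init, operon),
                    spacers=_cluster_spacers(operon),
                    gene_ids=[c.gene.gene_id for c in merged.candidates],
                )
            )
        else:
            records.append(
                BgcRecord(
                    genome_id=genome_id,
                    system=None,
                    organization="bifurcate",
                    inter_cluster_distance=None,
                    synteny=_synteny_for(init),
                    exclusion_flags=["incomplete"],
                    gene_ids=[c.gene.gene_id for c in init.candidates],
                )
            )
    leftovers = [op for j, op in enumerate(operons) if j not in used_operons]
    for cluster in leftovers + partials:
        records.append(
            BgcRecord(
                genome_id=genome_id,
                system=None,
                organization="bifurcate",
                inter_cluster_distance=None,
                synteny=_synteny_for(cluster),
                exclusion_flags=["incomplete"],
                gene_ids=[c.gene.gene_id for c in cluster.candidates],
            )
        )
    records.sort(key=lambda r: tuple(r.gene_ids))
    return records


# ---------------------------------------------------------------------------
# end-to-end convenience


def mine_genome(
    source,
    refs: Sequence[DomainRef],
    *,
    kb: Optional[KnowledgeBase] = None,
    genome_id: Optional[str] = None,
    **call_kwargs,
) -> MiningResult:
    """Read, screen, filter and resolve a genome into BgcRecords."""
    genes = read_genome(source) if not _is_gene_list(source) else list(source)
    gid = genome_id or (genes[0].record_id if genes else "genome")
    candidates = find_candidates(genes, refs, **call_kwargs)
    clusters = cluster_candidates(candidates)
    kept, excluded = apply_exclusions(clusters)
    bgcs = resolve_organization(kept, genes, kb=kb, genome_id=gid)
    return MiningResult(genome_id=gid, bgcs=bgcs, excluded=excluded)


def _is_gene_list(source) -> bool:
    return (
        isinstance(source, (list, tuple))
        and bool(source)
        and isinstance(source[0], GenomeGene)
    )


def write_bgc_table(results: Iterable[MiningResult], path: str | Path) -> None:
    """Export one row per BgcRecord as TSV (documented columns)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "genome_id", "system_id", "organization", "n_modules",
                "module_config", "te_tandem", "inter_cluster_distance",
                "spacers", "upstream_regulator", "pleC", "pleAB",
                "second_regulator", "accessory", "exclusion_flags", "genes",
            ]
        )
        for result in results:
            for bgc in result.bgcs:
                sys_ = bgc.system
                writer.writerow(
                    [
                        bgc.genome_id,
                        sys_.id if sys_ else "",
                        bgc.organization,
                        len(sys_.modules) if sys_ else 0,
                        "-".join(map(str, sys_.module_config)) if sys_ else "",
                        sys_.te_tandem if sys_ else False,
                        bgc.inter_cluster_distance
                        if bgc.inter_cluster_distance is not None
                        else "n/a",
                        ";".join(map(str, bgc.spacers)),
                        bgc.synteny.upstream_regulator,
                        bgc.synteny.pleC,
                        bgc.synteny.pleAB,
                        bgc.synteny.second_regulator,
                        bgc.synteny.accessory,
                        ";".join(bgc.exclusion_flags),
                        ";".join(bgc.gene_ids),
                    ]
                )
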