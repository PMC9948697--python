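"""Seeded generators for reference A domains, BGCs, genomes, markers, HSQC.

Everything the pipeline consumes can be generated here deterministically,
so every stage is testable without downloads.  Synthetic domains are random
amino-acid sequences anchored per domain kind and per substrate
specificity: the classifier contract is nearest-reference, which is
representation-agnostic, so no Pfam-style profiles are needed.  Anchors for
different A-domain specificities are kept mutually below 40% identity by
rejection sampling; diverged copies are produced by per-site substitution
at a configurable rate.

Generated BGCs follow the family templates of the knowledge base: module
configurations per gene, a Cs-A-T initiator module, CE-A-T elongation
modules, a terminal tandem TE, LuxR/PleABC flanking synteny (SyrD/Dab for
the Tolaasin family, a lone MFS transporter for thanafactin), intergenic
spacers of 150-300 bp, and contiguous or bifurcate placement.  Genomes are
emitted as GenBank + GFF3 + protein FASTA with a machine-readable truth
sidecar.  Every generator derives a single RNG stream from
``(seed, call tag)`` so adding generators never shifts existing outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from ._align import AA20, sequence_identity
from .knowledge_base import (
    LP_ALPHABET,
    FamilySpec,
    KnowledgeBase,
    PeptideVariant,
    ReferenceADomain,
    default_knowledge_base,
)
from .nrps_parser import DomainRef

_NT = "ACGT"

#: identity ceiling between specificity anchors (rejection sampling)
ANCHOR_MAX_IDENTITY = 0.40
_MAX_ANCHOR_TRIES = 60


class GenerationError(RuntimeError):
    """Generator could not satisfy its constraints."""


class ConfigError(ValueError):
    """Invalid simulation configuration or generator request."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; same config => byte-identical outputs.

    Domain lengths approximate real NRPS domain sizes (residues).  The
    spacer range reproduces the 150-300 bp intergenic untranslated region
    maintained between the initiator and middle NRPS genes of trigenic
    clusters.  ``mutation_rate`` is the per-site substitution probability
    applied to every domain instance relative to its anchor.
    """

    seed: int = 0
    n_refs_per_specificity: int = 3
    a_domain_length: int = 450
    c_domain_length: int = 440
    t_domain_length: int = 80
    te_domain_length: int = 230
    e_domain_length: int = 300
    mutation_rate: float = 0.05
    module_divergence: float = 0.10
    spacer_range: tuple[int, int] = (150, 300)
    decoy_gene_count: int = 5
    n_siderophore_decoys: int = 0
    n_edomain_decoys: int = 0
    n_fragment_decoys: int = 0
    decoy_length: int = 300
    peak_jitter: tuple[float, float] = (0.01, 0.1)

    def __post_init__(self):
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigError("mutation_rate must lie in [0, 1]")
        lo, hi = self.spacer_range
        if not (1 <= lo <= hi <= 10**5):
            raise ConfigError("spacer_range must lie inside [1, 1e5]")
        if self.n_refs_per_specificity < 1:
            raise ConfigError("n_refs_per_specificity must be >= 1")


def _tag_entropy(tag: str) -> int:
    digest = hashlib.sha256(tag.encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


def _rng(seed: int, tag: str) -> np.random.Generator:
    """One RNG stream per (seed, call tag)."""
    return np.random.default_rng(np.random.SeedSequence([seed, _tag_entropy(tag)]))


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = AA20) -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), length)])


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution at probability ``rate`` (never to the same residue)."""
    if rate <= 0.0:
        return seq
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    for i in np.nonzero(hit)[0]:
        choices = AA20.replace(chars[i], "")
        chars[i] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# anchors

_anchor_cache: dict[tuple[int, int], dict[str, str]] = {}


def specificity_anchors(config: SimConfig) -> dict[str, str]:
    """One anchor A-domain sequence per LP residue, mutually <40% identical.

    Anchors are built in alphabet order with rejection sampling, so the
    anchor of a given specificity depends only on (seed, length).
    """
    key = (config.seed, config.a_domain_length)
    if key in _anchor_cache:
        return _anchor_cache[key]
    anchors: dict[str, str] = {}
    for spec in LP_ALPHABET:
        for attempt in range(_MAX_ANCHOR_TRIES):
            rng = _rng(config.seed, f"anchor:A:{spec}:{attempt}")
            cand = _random_seq(rng, config.a_domain_length)
            if all(
                sequence_identity(cand, other) < ANCHOR_MAX_IDENTITY
                for other in anchors.values()
            ):
                anchors[spec] = cand
                break
        else:
            raise GenerationError(
                f"could not build a {spec} anchor below "
                f"{ANCHOR_MAX_IDENTITY:.0%} identity after {_MAX_ANCHOR_TRIES} tries"
            )
    _anchor_cache[key] = anchors
    return anchors


def _kind_anchor(config: SimConfig, kind: str) -> str:
    lengths = {
        "Cs": config.c_domain_length,
        "LCL": config.c_domain_length,
        "CE": config.c_domain_length,
        "T": config.t_domain_length,
        "TE": config.te_domain_length,
        "E": config.e_domain_length,
    }
    return _random_seq(_rng(config.seed, f"anchor:{kind}"), lengths[kind])


def module_anchor(
    config: SimConfig, variant_name: str, position: int, residue: str
) -> str:
    """Per-(variant, module position) ancestor A-domain sequence.

    Modules activating the same residue within or across systems are
    homologous but diverged, not identical copies; each module position
    therefore gets its own stable ancestor, derived from the specificity
    anchor at ``module_divergence``.  BGC instances then diverge from this
    ancestor at ``mutation_rate``.
    """
    anchor = specificity_anchors(config)[residue]
    rng = _rng(config.seed, f"module-anchor:{variant_name}:{position}:{residue}")
    return mutate_sequence(anchor, config.module_divergence, rng)


def module_anchor_set(
    config: SimConfig, variant: PeptideVariant
) -> list[str]:
    """Ancestor A-domain sequence per module position of a peptide variant."""
    return [
        module_anchor(config, variant.name, i + 1, residue)
        for i, residue in enumerate(variant.sequence)
    ]


def reference_systems(
    config: SimConfig,
    *,
    kb: Optional[KnowledgeBase] = None,
    families: Optional[Iterable[str]] = None,
) -> dict[str, list[list[str]]]:
    """Per-family reference systems (per-module A-domain ancestor lists).

    Characterized variants only; predicted LPs are excluded from
    classification references by design.
    """
    kb = kb or default_knowledge_base()
    fams = (
        [kb.get_family(f) for f in families]
        if families is not None
        else kb.list_families()
    )
    return {
        fam.name: [
            module_anchor_set(config, v)
            for v in fam.variants
            if v.source == "characterized"
        ]
        for fam in fams
    }


def make_reference_set(config: SimConfig) -> list[ReferenceADomain]:
    """n diverged copies of each specificity anchor, as labelled references."""
    refs: list[ReferenceADomain] = []
    anchors = specificity_anchors(config)
    for spec in LP_ALPHABET:
        rng = _rng(config.seed, f"refset:{spec}")
        for i in range(config.n_refs_per_specificity):
            refs.append(
                ReferenceADomain(
                    id=f"{spec}_r{i:02d}",
                    sequence=mutate_sequence(anchors[spec], config.mutation_rate, rng),
                    specificity=spec,
                    system="synthetic",
                    position=0,
                )
            )
    return refs


def make_domain_library(config: SimConfig) -> list[DomainRef]:
    """Reference library for the domain caller: kind anchors + A anchors."""
    refs = [
        DomainRef(id=f"{kind}_anchor", kind=kind, sequence=_kind_anchor(config, kind))
        for kind in ("Cs", "LCL", "CE", "T", "TE", "E")
    ]
    anchors = specificity_anchors(config)
    refs.extend(
        DomainRef(id=f"A_{spec}", kind="A", sequence=anchors[spec], specificity=spec)
        for spec in LP_ALPHABET
    )
    return refs


# ---------------------------------------------------------------------------
# BGCs

ROLE_PRODUCTS = {
    "luxr1": "LuxR-family transcriptional regulator",
    "luxr2": "LuxR-family transcriptional regulator",
    "pleA": "LP export periplasmic adaptor protein PleA",
    "pleB": "LP export ATP-dependent transporter PleB",
    "pleC": "LP export outer membrane protein PleC",
    "syrD": "SyrD-family ATP-dependent transporter",
    "dab": "2,4-diaminobutyrate aminotransferase Dab",
    "mfs": "major facilitator superfamily transporter",
    "decoy": "hypothetical protein",
}


@dataclass
class SynGene:
    """One planted gene: id, role, protein, strand (+1/-1)."""

    gene_id: str
    role: str
    product: str
    protein: str
    strand: int = 1
    modules: list[dict] = field(default_factory=list)


@dataclass
class SyntheticBgc:
    """A family-templated BGC with its planted ground truth."""

    family: str
    organization: str
    variant_name: str
    genes: list[SynGene]  # NRPS genes in biosynthetic order
    flank_upstream: list[SynGene]
    flank_downstream: list[SynGene]
    spacers: list[int]  # intergenic bp between consecutive NRPS genes
    module_config: tuple[int, ...]
    specificities: tuple[str, ...]
    truth: dict


def _resolve_variant(
    family: FamilySpec, variant: Union[None, str, PeptideVariant]
) -> PeptideVariant:
    if isinstance(variant, PeptideVariant):
        return variant
    if variant is None:
        for v in family.variants:
            if v.source == "characterized":
                return v
        raise ConfigError(f"family {family.name} has no characterized variant")
    for v in family.variants:
        if v.name.lower() == variant.lower():
            return v
    raise ConfigError(f"unknown variant {variant!r} for family {family.name}")


def make_bgc(
    family: str,
    organization: str,
    config: SimConfig,
    *,
    variant: Union[None, str, PeptideVariant] = None,
    module_config: Optional[Sequence[int]] = None,
    bgc_id: str = "bgc1",
    kb: Optional[KnowledgeBase] = None,
) -> SyntheticBgc:
    """Generate one family-templated BGC with planted truth.

    Genes carry concatenated synthetic domains ``Cs-A-T | (CE-A-T)* | ..
    -TE-TE`` per the family module configuration; per-module A-domain
    specificities follow the chosen packaged peptide variant.
    """
    kb = kb or default_knowledge_base()
    fam = kb.get_family(family)
    if organization not in fam.organizations:
        raise ConfigError(
            f"organization {organization!r} not observed for family "
            f"{fam.name} (allowed: {fam.organizations})"
        )
    var = _resolve_variant(fam, variant)
    cfg = tuple(module_config) if module_config is not None else fam.module_configs[0]
    if sum(cfg) != fam.peptide_length:
        raise ConfigError(
            f"module config {cfg} does not sum to peptide length {fam.peptide_length}"
        )

    rng = _rng(config.seed, f"bgc:{bgc_id}:{fam.name}:{organization}:{var.name}")
    rate = config.mutation_rate

    genes: list[SynGene] = []
    module_index = 0
    n_genes = len(cfg)
    for gi, n_modules in enumerate(cfg):
        parts: list[str] = []
        modules: list[dict] = []
        offset = 0
        for _ in range(n_modules):
            module_index += 1
            c_kind = "Cs" if module_index == 1 else "CE"
            c_seq = mutate_sequence(_kind_anchor(config, c_kind), rate, rng)
            spec = var.sequence[module_index - 1]
            ancestor = module_anchor(config, var.name, module_index, spec)
            a_seq = mutate_sequence(ancestor, rate, rng)
            t_seq = mutate_sequence(_kind_anchor(config, "T"), rate, rng)
            a_start = offset + len(c_seq)
            modules.append(
                {
                    "module_index": module_index,
                    "c_kind": c_kind,
                    "specificity": spec,
                    "a_start": a_start,
                    "a_end": a_start + len(a_seq),
                }
            )
            parts.extend((c_seq, a_seq, t_seq))
            offset += len(c_seq) + len(a_seq) + len(t_seq)
        if gi == n_genes - 1:
            parts.append(mutate_sequence(_kind_anchor(config, "TE"), rate, rng))
            parts.append(mutate_sequence(_kind_anchor(config, "TE"), rate, rng))
        role = (
            "nrps_initiator"
            if gi == 0
            else ("nrps_terminator" if gi == n_genes - 1 else "nrps_middle")
        )
        genes.append(
            SynGene(
                gene_id=f"{bgc_id}_nrps{gi + 1}",
                role=role,
                product=f"{fam.name} lipopeptide synthetase subunit {gi + 1}",
                protein="".join(parts),
                modules=modules,
            )
        )

    lo, hi = config.spacer_range
    spacers = [int(rng.integers(lo, hi + 1)) for _ in range(n_genes - 1)]

    def _flank(role_key: str, suffix: str, strand: int = 1) -> SynGene:
        return SynGene(
            gene_id=f"{bgc_id}_{suffix}",
            role=role_key,
            product=ROLE_PRODUCTS[role_key],
            protein=_random_seq(rng, config.decoy_length),
            strand=strand,
        )

    if fam.accessory_genes == "mfs":
        upstream: list[SynGene] = []
        downstream = [_flank("mfs", "mfs")]
    else:
        upstream = [_flank("luxr1", "luxr1", strand=-1), _flank("pleC", "pleC")]
        downstream = [
            _flank("pleA", "pleA"),
            _flank("pleB", "pleB"),
            _flank("luxr2", "luxr2"),
        ]
        if fam.accessory_genes == "syrD_dab":
            upstream.append(_flank("syrD", "syrD"))
            downstream.insert(0, _flank("dab", "dab"))

    truth = {
        "bgc_id": bgc_id,
        "family": fam.name,
        "organization": organization,
        "variant": var.name,
        "module_config": list(cfg),
        "specificities": list(var.sequence),
        "spacers": spacers,
        "genes": [
            {
                "gene_id": g.gene_id,
                "role": g.role,
                "domain_string": _truth_domain_string(g, cfg),
                "modules": g.modules,
            }
            for g in genes
        ],
        "flanking_roles": [g.role for g in upstream + downstream],
    }
    return SyntheticBgc(
        family=fam.name,
        organization=organization,
        variant_name=var.name,
        genes=genes,
        flank_upstream=upstream,
        flank_downstream=downstream,
        spacers=spacers,
        module_config=cfg,
        specificities=tuple(var.sequence),
        truth=truth,
    )


def _truth_domain_string(gene: SynGene, cfg: tuple[int, ...]) -> list[str]:
    out: list[str] = []
    for mod in gene.modules:
        out.extend((mod["c_kind"], "A", "T"))
    if gene.role == "nrps_terminator" or len(cfg) == 1:
        out.extend(("TE", "TE"))
    return out


# ---------------------------------------------------------------------------
# genomes


@dataclass
class SyntheticGenome:
    """GenBank-ready records plus the machine-readable truth sidecar."""

    records: list  # Bio.SeqRecord.SeqRecord
    truth: dict

    def write_genbank(self, path: str | Path) -> None:
        from Bio import SeqIO

        with open(path, "w") as fh:
            SeqIO.write(self.records, fh, "genbank")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for rec in self.records:
                fh.write(f"##sequence-region {rec.id} 1 {len(rec.seq)}\n")
            for rec in self.records:
                for feat in rec.features:
                    if feat.type != "CDS":
                        continue
                    start = int(feat.location.start) + 1  # GFF3 is 1-based
                    end = int(feat.location.end)
                    strand = "+" if feat.location.strand >= 0 else "-"
                    locus = feat.qualifiers["locus_tag"][0]
                    product = feat.qualifiers["product"][0]
                    fh.write(
                        f"{rec.id}\tlipopeptidome\tCDS\t{start}\t{end}\t.\t"
                        f"{strand}\t0\tID={locus};product={product}\n"
                    )

    def write_proteins_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                for feat in rec.features:
                    if feat.type != "CDS":
                        continue
                    locus = feat.qualifiers["locus_tag"][0]
                    fh.write(f">{locus} {feat.qualifiers['product'][0]}\n")
                    fh.write(feat.qualifiers["translation"][0] + "\n")

    def write_truth(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


BgcRequest = Union[SyntheticBgc, tuple]


def make_genome(
    bgc_specs: Sequence[BgcRequest],
    config: SimConfig,
    *,
    genome_id: str = "synthetic_genome",
    kb: Optional[KnowledgeBase] = None,
) -> SyntheticGenome:
    """Assemble BGCs, flanking synteny and decoys into annotated records.

    ``bgc_specs`` items are either :class:`SyntheticBgc` objects or
    ``(family, organization)`` / ``(family, organization, variant)``
    tuples.  Bifurcate BGCs place the initiator gene (with its upstream
    flank) on a separate record.  Decoy genes are random proteins; the
    config can additionally request non-LP NRPS mimics (single-TE
    siderophore-like genes, standalone-E genes, fragmented genes) that
    exercise the miner's exclusion rules.
    """
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    kb = kb or default_knowledge_base()
    bgcs: list[SyntheticBgc] = []
    for i, spec in enumerate(bgc_specs):
        if isinstance(spec, SyntheticBgc):
            bgcs.append(spec)
        else:
            family, organization, *rest = spec
            bgcs.append(
                make_bgc(
                    family,
                    organization,
                    config,
                    variant=rest[0] if rest else None,
                    bgc_id=f"{genome_id}_bgc{i + 1}",
                    kb=kb,
                )
            )

    rng = _rng(config.seed, f"genome:{genome_id}")

    # decoy genes
    decoys: list[SynGene] = []
    for i in range(config.decoy_gene_count):
        decoys.append(
            SynGene(
                gene_id=f"{genome_id}_decoy{i + 1}",
                role="decoy",
                product=ROLE_PRODUCTS["decoy"],
                protein=_random_seq(rng, config.decoy_length),
            )
        )
    anchors = specificity_anchors(config)
    specs = list(LP_ALPHABET)
    for i in range(config.n_siderophore_decoys):
        spec = specs[int(rng.integers(0, len(specs)))]
        protein = (
            mutate_sequence(_kind_anchor(config, "Cs"), config.mutation_rate, rng)
            + mutate_sequence(anchors[spec], config.mutation_rate, rng)
            + mutate_sequence(_kind_anchor(config, "T"), config.mutation_rate, rng)
            + mutate_sequence(_kind_anchor(config, "TE"), config.mutation_rate, rng)
        )
        decoys.append(
            SynGene(
                gene_id=f"{genome_id}_sid{i + 1}",
                role="decoy_siderophore",
                product="siderophore-like NRPS (single TE)",
                protein=protein,
            )
        )
    for i in range(config.n_edomain_decoys):
        spec = specs[int(rng.integers(0, len(specs)))]
        protein = (
            mutate_sequence(_kind_anchor(config, "Cs"), config.mutation_rate, rng)
            + mutate_sequence(anchors[spec], config.mutation_rate, rng)
            + mutate_sequence(_kind_anchor(config, "T"), config.mutation_rate, rng)
            + mutate_sequence(_kind_anchor(config, "E"), config.mutation_rate, rng)
        )
        decoys.append(
            SynGene(
                gene_id=f"{genome_id}_edec{i + 1}",
                role="decoy_standalone_e",
                product="pyoverdine-like NRPS with standalone E domain",
                protein=protein,
            )
        )
    for i in range(config.n_fragment_decoys):
        spec = specs[int(rng.integers(0, len(specs)))]
        protein = (
            mutate_sequence(_kind_anchor(config, "Cs"), config.mutation_rate, rng)
            + mutate_sequence(anchors[spec], config.mutation_rate, rng)
        )
        mid = len(protein) // 2
        protein = protein[:mid] + "*" + protein[mid + 1 :]
        decoys.append(
            SynGene(
                gene_id=f"{genome_id}_frag{i + 1}",
                role="decoy_fragment",
                product="fragmented NRPS (internal stop)",
                protein=protein,
            )
        )

    # layout
    class _RecordBuilder:
        def __init__(self, rec_id: str):
            self.rec_id = rec_id
            self.cursor = int(rng.integers(500, 1500))
            self.genes: list[dict] = []

        def place(self, gene: SynGene, gap_before: Optional[int] = None) -> dict:
            if gap_before is None:
                gap_before = int(rng.integers(300, 900))
            start = self.cursor + gap_before
            end = start + 3 * len(gene.protein) + 3  # CDS incl. stop codon
            placed = {
                "gene": gene,
                "record_id": self.rec_id,
                "start": start,  # 0-based half-open internally
                "end": end,
            }
            self.genes.append(placed)
            self.cursor = end
            return placed

    main = _RecordBuilder(f"{genome_id}_ctg1")
    builders = [main]
    truth_clusters = []
    decoy_iter = iter(decoys)

    def _place_some_decoys(builder, k):
        # keep decoys well outside the miner's cluster gap so NRPS-mimic
        # decoys form their own clusters
        for _ in range(k):
            gene = next(decoy_iter, None)
            if gene is None:
                return
            builder.place(gene, gap_before=int(rng.integers(6000, 12000)))

    n_blocks = len(bgcs) + 1
    per_block = (len(decoys) + n_blocks - 1) // n_blocks if decoys else 0
    _place_some_decoys(main, per_block)

    for bgc in bgcs:
        placed_genes: dict[str, dict] = {}
        if bgc.organization == "bifurcate":
            sub = _RecordBuilder(f"{genome_id}_ctg{len(builders) + 1}")
            builders.append(sub)
            for g in bgc.flank_upstream:
                placed_genes[g.gene_id] = sub.place(g)
            placed_genes[bgc.genes[0].gene_id] = sub.place(bgc.genes[0])
            operon_genes = bgc.genes[1:]
            main_gap = int(rng.integers(6000, 12000))
            for j, g in enumerate(operon_genes):
                gap = main_gap if j == 0 else bgc.spacers[j]  # spacers[0] is
                # the initiator-middle spacer, unused when split
                placed_genes[g.gene_id] = main.place(g, gap_before=gap)
            for g in bgc.flank_downstream:
                placed_genes[g.gene_id] = main.place(g)
        else:
            # the block's first gene starts well clear of any upstream decoy
            block_gap: Optional[int] = int(rng.integers(6000, 12000))
            for g in bgc.flank_upstream:
                placed_genes[g.gene_id] = main.place(g, gap_before=block_gap)
                block_gap = None
            for j, g in enumerate(bgc.genes):
                gap = block_gap if j == 0 else bgc.spacers[j - 1]
                placed_genes[g.gene_id] = main.place(g, gap_before=gap)
                block_gap = None
            for g in bgc.flank_downstream:
                placed_genes[g.gene_id] = main.place(g)
        cluster_truth = dict(bgc.truth)
        cluster_truth["gene_locations"] = {
            gid: {
                "record_id": p["record_id"],
                "start": p["start"],
                "end": p["end"],
            }
            for gid, p in placed_genes.items()
        }
        truth_clusters.append(cluster_truth)
        _place_some_decoys(main, per_block)
    _place_some_decoys(main, len(decoys))  # any remainder

    records = []
    truth_genes: dict[str, dict] = {}
    for builder in builders:
        total = builder.cursor + int(rng.integers(500, 1500))
        seq = _random_seq(rng, total, _NT)
        features = []
        for placed in builder.genes:
            gene: SynGene = placed["gene"]
            loc = FeatureLocation(placed["start"], placed["end"], strand=gene.strand)
            features.append(SeqFeature(loc, type="gene", qualifiers={
                "locus_tag": [gene.gene_id],
            }))
            features.append(
                SeqFeature(
                    loc,
                    type="CDS",
                    qualifiers={
                        "locus_tag": [gene.gene_id],
                        "product": [gene.product],
                        "translation": [gene.protein],
                        "transl_table": ["11"],
                        "codon_start": ["1"],
                    },
                )
            )
            truth_genes[gene.gene_id] = {
                "record_id": builder.rec_id,
                "start": placed["start"],
                "end": placed["end"],
                "strand": gene.strand,
                "role": gene.role,
            }
        rec = SeqRecord(
            Seq(seq),
            id=builder.rec_id,
            name=builder.rec_id[-16:],
            description=f"synthetic Pseudomonas contig ({genome_id})",
            features=features,
        )
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "linear"
        rec.annotations["data_file_division"] = "BCT"
        rec.annotations["date"] = "01-JAN-1980"  # fixed for determinism
        records.append(rec)

    truth = {
        "genome_id": genome_id,
        "seed": config.seed,
        "mutation_rate": config.mutation_rate,
        "clusters": truth_clusters,
        "genes": truth_genes,
        "coordinate_system": "0-based half-open",
    }
    return SyntheticGenome(records=records, truth=truth)


# ---------------------------------------------------------------------------
# rpoD-like marker sequences (for taxonomy-tree tests)


def make_random_tree(labels: Sequence[str], config: SimConfig, *, tag: str = "tree"):
    """Random binary tree over ``labels`` with U(0.02, 0.2) branch lengths."""
    from skbio.tree import TreeNode

    if len(labels) < 3:
        raise ConfigError("need at least 3 taxa")
    rng = _rng(config.seed, f"{tag}:{','.join(labels)}")
    nodes = [TreeNode(name=str(lab)) for lab in labels]
    for node in nodes:
        node.length = float(rng.uniform(0.02, 0.2))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        parent.length = float(rng.uniform(0.02, 0.2))
        rest = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes = rest + [parent]
    root = TreeNode(children=nodes)
    return root


def evolve_sequences(
    tree,
    config: SimConfig,
    *,
    length: int = 600,
    alphabet: str = _NT,
    rate_scale: float = 1.0,
    tag: str = "markers",
) -> dict[str, str]:
    """Evolve sequences down ``tree`` by per-site substitution.

    The substitution probability on a branch is ``min(0.75, rate_scale *
    branch_length)``; this emulates a single-copy marker gene (rpoD-like)
    whose distances reflect the generating topology.
    """
    rng = _rng(config.seed, f"{tag}:{length}")
    root_seq = _random_seq(rng, length, alphabet)
    out: dict[str, str] = {}

    def _mutate(seq: str, p: float) -> str:
        chars = np.array(list(seq))
        hit = rng.random(len(chars)) < p
        for i in np.nonzero(hit)[0]:
            choices = alphabet.replace(chars[i], "")
            chars[i] = choices[rng.integers(0, len(choices))]
        return "".join(chars)

    def _walk(node, seq):
        for child in node.children:
            p = min(0.75, rate_scale * (child.length or 0.0))
            child_seq = _mutate(seq, p)
            if child.is_tip():
                out[child.name] = child_seq
            else:
                _walk(child, child_seq)

    _walk(tree, root_seq)
    return out


def make_marker_set(
    n_taxa: int, config: SimConfig, *, length: int = 600, tag: str = "rpoD"
):
    """(generating tree, rpoD-like sequences) for ``n_taxa`` labelled taxa."""
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    tree = make_random_tree(labels, config, tag=f"{tag}-tree")
    seqs = evolve_sequences(tree, config, length=length, tag=f"{tag}-seqs")
    return tree, seqs


# ---------------------------------------------------------------------------
# HSQC peak lists

#: CHalpha fingerprint window (ppm): 1H 3.5-5.5, 13C 48-65
_H_RANGE = (3.5, 5.5)
_C_RANGE = (48.0, 65.0)


def _lookup_variant(
    variant: Union[str, PeptideVariant], kb: Optional[KnowledgeBase]
) -> PeptideVariant:
    if isinstance(variant, PeptideVariant):
        return variant
    kb = kb or default_knowledge_base()
    for fam in kb.list_families():
        for v in fam.variants:
            if v.name.lower() == variant.lower():
                return v
    raise KeyError(f"unknown peptide variant {variant!r}")


def hsqc_reference(
    variant: Union[str, PeptideVariant],
    config: SimConfig,
    *,
    kb: Optional[KnowledgeBase] = None,
) -> list:
    """Reference CHalpha fingerprint: one seeded peak per residue."""
    from .nmr_fingerprint import Peak

    var = _lookup_variant(variant, kb)
    rng = _rng(config.seed, f"hsqc:{var.name}")
    peaks = []
    for i in range(len(var.sequence)):
        peaks.append(
            Peak(
                id=f"{var.name}_a{i + 1}",
                h_ppm=float(rng.uniform(*_H_RANGE)),
                c_ppm=float(rng.uniform(*_C_RANGE)),
            )
        )
    return peaks


def make_hsqc(
    variant: Union[str, PeptideVariant],
    config: SimConfig,
    *,
    replicate: int = 0,
    kb: Optional[KnowledgeBase] = None,
) -> list:
    """Reference fingerprint perturbed by Gaussian jitter of the config SD."""
    from .nmr_fingerprint import Peak

    var = _lookup_variant(variant, kb)
    ref = hsqc_reference(var, config, kb=kb)
    sd_h, sd_c = config.peak_jitter
    if sd_h == 0 and sd_c == 0:
        return ref
    rng = _rng(config.seed, f"hsqc-query:{var.name}:{replicate}")
    return [
        Peak(
            id=p.id,
            h_ppm=p.h_ppm + float(rng.normal(0.0, sd_h)) if sd_h else p.h_ppm,
            c_ppm=p.c_ppm + float(rng.normal(0.0, sd_c)) if sd_c else p.c_ppm,
        )
        for p in ref
    ]


def make_hsqc_library(
    variants: Iterable[Union[str, PeptideVariant]],
    config: SimConfig,
    *,
    kb: Optional[KnowledgeBase] = None,
) -> dict[str, list]:
    """Named reference fingerprints for dereplication."""
    out = {}
    for v in variants:
        var = _lookup_variant(v, kb)
        out[var.name] = hsqc_reference(var, config, kb=kb)
    return out
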