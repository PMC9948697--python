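"""Collinear peptide prediction, family assignment and superfamily grouping.

Type I Pseudomonas LP synthetases obey the collinearity rule: the peptide
sequence follows the module order across the consecutively acting
enzymes, so one specificity call per module (initiator first) yields the
predicted peptide.  Family membership is inferred the way practitioners
read it: candidate families share the peptide length; module distribution
across genes, genomic organization and mean A-domain identity to family
reference systems disambiguate (this is what separates Orfamide from
Poaeamide, both 10:8); and an ambiguity-aware sequence comparison against
the packaged variants decides between known member, new variant and
candidate new family.  The macrocycle size is always copied from the
family table, never derived from the sequence — thioesterase phylogeny
has poor discriminatory value for the cyclization pattern, so a novel
family's macrocycle is simply unknown.

Superfamilies group systems whose A-domain homology profiles largely
overlap: all A domains are clustered by average linkage at an identity
cutoff, each system becomes the string of cluster ids along its modules,
and systems with sufficient profile overlap are joined transitively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._align import sequence_identity
from .adomain_specificity import SpecificityCall, classify
from .knowledge_base import (
    FamilySpec,
    KnowledgeBase,
    PeptideVariant,
    ReferenceADomain,
    default_knowledge_base,
)
from .nrps_parser import NrpsSystem

#: minimum mean A-domain identity to a family's references for new_variant
FAMILY_HOMOLOGY_THRESHOLD = 0.7
#: A-domain clustering identity cutoff for homology profiles
PROFILE_IDENTITY_CUTOFF = 0.6
#: minimum profile overlap for two systems to share a superfamily
SUPERFAMILY_OVERLAP_THRESHOLD = 0.5


class PredictionError(ValueError):
    """System cannot be predicted (missing A domains or invalid system)."""


@dataclass
class PeptidePrediction:
    """Per-module specificity calls in biosynthetic order."""

    system_id: str
    calls: list[SpecificityCall]
    sequence_primary: tuple[str, ...]
    n_ambiguous: int

    def __post_init__(self):
        if tuple(c.primary for c in self.calls) != tuple(self.sequence_primary):
            raise ValueError("sequence_primary must mirror the primary calls")

    def __len__(self) -> int:
        return len(self.calls)


@dataclass
class FamilyAssignment:
    """Family/variant status of a predicted peptide."""

    family: Optional[str]
    status: str  # known_member | new_variant | candidate_new_family | unassigned
    matched_variant: Optional[str] = None
    implied_macrocycle: Optional[int] = None
    organization_match: Optional[bool] = None
    homology_score: Optional[float] = None

    def __post_init__(self):
        if self.status == "known_member" and self.matched_variant is None:
            raise ValueError("known_member requires a matched variant")


@dataclass
class HomologyProfile:
    """Ordered A-domain cluster labels, one per module."""

    system_id: str
    cluster_ids: tuple[int, ...]
    residues: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.cluster_ids)


@dataclass
class VariantComparison:
    """Variable positions (1-based) across equal-length peptide sequences."""

    variable_positions: frozenset[int]
    pairwise_differences: dict[tuple[int, int], int]
    qs_switch_positions: frozenset[int]


# ---------------------------------------------------------------------------
# peptide prediction


def predict_peptide(
    system: NrpsSystem,
    refs: Sequence[ReferenceADomain],
    **classify_kwargs,
) -> PeptidePrediction:
    """One specificity call per module, in module (biosynthetic) order."""
    if not system.modules:
        raise PredictionError(f"system {system.id}: no modules")
    calls: list[SpecificityCall] = []
    for module in system.modules:
        if not module.a_sequence:
            raise PredictionError(
                f"system {system.id}: module {module.index} has no A domain"
            )
        calls.append(classify(module.a_sequence, refs, **classify_kwargs))
    return PeptidePrediction(
        system_id=system.id,
        calls=calls,
        sequence_primary=tuple(c.primary for c in calls),
        n_ambiguous=sum(1 for c in calls if c.is_ambiguous),
    )


# ---------------------------------------------------------------------------
# family assignment


def _variant_matches(
    prediction: PeptidePrediction, variant: PeptideVariant
) -> bool:
    """Ambiguity-aware sequence equality against a packaged variant.

    A position matches when the primary call equals the variant residue or
    the variant residue lies in the call's ambiguity set — this prevents
    Glu/Gln uncertainty from producing spurious new-variant calls.
    """
    if len(variant.sequence) != len(prediction):
        return False
    for call, residue in zip(prediction.calls, variant.sequence):
        if call.primary != residue and residue not in call.ambiguity_set:
            return False
    return True


def _mean_system_identity(
    query_a_sequences: Sequence[str],
    reference_systems: Sequence[Sequence[str]],
) -> float:
    """Mean per-module identity to the best-matching reference system."""
    best = 0.0
    for ref in reference_systems:
        n = min(len(ref), len(query_a_sequences))
        if n == 0:
            continue
        score = float(
            np.mean(
                [sequence_identity(query_a_sequences[i], ref[i]) for i in range(n)]
            )
        )
        best = max(best, score)
    return best


def assign_family(
    prediction: PeptidePrediction,
    *,
    organization: Optional[str] = None,
    module_config: Optional[Sequence[int]] = None,
    a_sequences: Optional[Sequence[str]] = None,
    reference_systems: Optional[dict[str, Sequence[Sequence[str]]]] = None,
    kb: Optional[KnowledgeBase] = None,
    homology_threshold: float = FAMILY_HOMOLOGY_THRESHOLD,
) -> FamilyAssignment:
    """Assign a predicted peptide to an LP family.

    Candidates share the peptide length; they are ranked by (i) module
    distribution against the family's architecture templates, (ii)
    genomic organization, (iii) mean A-domain identity to the family's
    reference systems (``reference_systems`` maps family name -> list of
    per-module A-domain sequence lists).  Status is ``known_member`` iff
    the sequence matches a packaged characterized variant
    (ambiguity-aware), else ``new_variant`` if family homology clears the
    threshold (or, without references, if architecture and organization
    agree), else ``candidate_new_family``.  ``unassigned`` is reserved
    for empty predictions.
    """
    kb = kb or default_knowledge_base()
    if len(prediction) == 0:
        return FamilyAssignment(family=None, status="unassigned")
    candidates = kb.candidates_by_length(len(prediction))
    if not candidates:
        return FamilyAssignment(family=None, status="candidate_new_family")

    scored: list[tuple[tuple, FamilySpec, Optional[float], bool]] = []
    for fam in candidates:
        config_match = (
            module_config is not None
            and tuple(module_config) in fam.module_configs
        )
        org_match = organization is not None and organization in fam.organizations
        homology: Optional[float] = None
        if reference_systems and a_sequences and fam.name in reference_systems:
            homology = _mean_system_identity(
                a_sequences, reference_systems[fam.name]
            )
        rank = (
            not config_match,
            not org_match,
            -(homology if homology is not None else 0.0),
            fam.name,
        )
        scored.append((rank, fam, homology, org_match))
    scored.sort(key=lambda t: t[0])
    _, family, homology, org_match = scored[0]

    # the predicted peptide itself is the strongest discriminator: scan
    # candidates in rank order for a characterized-variant match (this is
    # what separates e.g. xantholysin from entolysin, same length/config)
    for _, fam, fam_homology, fam_org_match in scored:
        matched = next(
            (
                v
                for v in fam.variants
                if v.source == "characterized" and _variant_matches(prediction, v)
            ),
            None,
        )
        if matched is not None:
            return FamilyAssignment(
                family=fam.name,
                status="known_member",
                matched_variant=matched.name,
                implied_macrocycle=fam.macrocycle_size,
                organization_match=fam_org_match if organization is not None else None,
                homology_score=fam_homology,
            )
    if homology is not None:
        is_family = homology >= homology_threshold
    else:
        is_family = bool(
            module_config is not None
            and tuple(module_config) in family.module_configs
        )
    if is_family:
        return FamilyAssignment(
            family=family.name,
            status="new_variant",
            implied_macrocycle=family.macrocycle_size,
            organization_match=org_match if organization is not None else None,
            homology_score=homology,
        )
    return FamilyAssignment(
        family=None,
        status="candidate_new_family",
        organization_match=org_match if organization is not None else None,
        homology_score=homology,
    )


# ---------------------------------------------------------------------------
# variant comparison


def compare_variants(
    sequences: Sequence[Sequence[str]],
) -> VariantComparison:
    """Positions (1-based) at which >= 2 residues occur across sequences.

    Also reports pairwise difference counts and the positions whose
    residue set includes both Gln and Ser (the recurrent "Q-S switch"
    differentiating related LP variants).
    """
    seqs = [tuple(s) for s in sequences]
    if not seqs:
        return VariantComparison(frozenset(), {}, frozenset())
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must have equal length")
    variable: set[int] = set()
    qs: set[int] = set()
    for pos in range(length):
        residues = {s[pos] for s in seqs}
        if len(residues) >= 2:
            variable.add(pos + 1)
            if {"Gln", "Ser"} <= residues:
                qs.add(pos + 1)
    pairwise = {
        (i, j): sum(1 for a, b in zip(seqs[i], seqs[j]) if a != b)
        for i in range(len(seqs))
        for j in range(i + 1, len(seqs))
    }
    return VariantComparison(
        variable_positions=frozenset(variable),
        pairwise_differences=pairwise,
        qs_switch_positions=frozenset(qs),
    )


# ---------------------------------------------------------------------------
# superfamily grouping


def cluster_a_domains(
    systems: dict[str, Sequence[str]],
    identity_cutoff: float = PROFILE_IDENTITY_CUTOFF,
    residues: Optional[dict[str, Sequence[str]]] = None,
) -> list[HomologyProfile]:
    """Average-linkage clustering of all A domains into homology profiles.

    Domains joined at distance <= 1 - identity_cutoff share a cluster id;
    ids are renumbered deterministically by first occurrence along the
    sorted system order.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    order = sorted(systems)
    pool: list[tuple[str, int, str]] = []  # (system, module idx, sequence)
    for sys_id in order:
        for i, seq in enumerate(systems[sys_id]):
            pool.append((sys_id, i, seq))
    if not pool:
        return []
    n = len(pool)
    if n == 1:
        raw = np.array([1])
    else:
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = 1.0 - sequence_identity(pool[i][2], pool[j][2])
                dist[i, j] = dist[j, i] = d
        link = linkage(squareform(dist, checks=False), method="average")
        raw = fcluster(link, t=1.0 - identity_cutoff, criterion="distance")
    relabel: dict[int, int] = {}
    for cl in raw:
        if cl not in relabel:
            relabel[cl] = len(relabel) + 1
    profiles: dict[str, list[int]] = {sys_id: [] for sys_id in order}
    for (sys_id, _, _), cl in zip(pool, raw):
        profiles[sys_id].append(relabel[cl])
    return [
        HomologyProfile(
            system_id=sys_id,
            cluster_ids=tuple(profiles[sys_id]),
            residues=tuple(residues[sys_id]) if residues else (),
        )
        for sys_id in order
    ]


def profile_overlap(a: HomologyProfile, b: HomologyProfile) -> float:
    """Multiset overlap of cluster ids / min profile length."""
    from collections import Counter

    ca, cb = Counter(a.cluster_ids), Counter(b.cluster_ids)
    shared = sum((ca & cb).values())
    return shared / min(len(a), len(b))


def superfamily_group(
    profiles: Sequence[HomologyProfile],
    overlap_threshold: float = SUPERFAMILY_OVERLAP_THRESHOLD,
) -> list[list[str]]:
    """Partition systems into superfamilies by transitive profile overlap.

    Two systems join when their profile overlap reaches the threshold;
    groups are connected components, output deterministically sorted.
    """
    import networkx as nx

    if not profiles:
        return []
    graph = nx.Graph()
    graph.add_nodes_from(p.system_id for p in profiles)
    for i, a in enumerate(profiles):
        for b in profiles[i + 1 :]:
            if profile_overlap(a, b) >= overlap_threshold:
                graph.add_edge(a.system_id, b.system_id)
    return sorted(sorted(comp) for comp in nx.connected_components(graph))


def export_profile_matrix(profiles: Sequence[HomologyProfile], path) -> None:
    """TSV matrix: rows = systems, cols = module positions, values = cluster id + residue."""
    with open(path, "w") as fh:
        width = max((len(p) for p in profiles), default=0)
        fh.write("system\t" + "\t".join(f"m{i + 1}" for i in range(width)) + "\n")
        for p in profiles:
            cells = [
                f"{cid}:{p.residues[i]}" if p.residues else str(cid)
                for i, cid in enumerate(p.cluster_ids)
            ]
            cells += [""] * (width - len(cells))
            fh.write(p.system_id + "\t" + "\t".join(cells) + "\n")
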