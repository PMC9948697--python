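"""Packaged knowledge base of Pseudomonas lipopeptide families.

Pseudomonas lipopeptides (LPs) fall into chemical families defined by the
``[l:m]`` signature — peptide length *l* and macrocycle size *m* (0 for the
linear Factin and Thanafactin families) — together with the modular
architecture of the nonribosomal peptide synthetase (NRPS) genes that encode
them and the peptide sequence variants observed in producers.  The tables
shipped under :mod:`lipopeptidome.data` encode the 13 families of
nonpathogenic pseudomonads, their characterized peptide variants, and a
separate list of BGC-predicted peptides that await chemical validation.

Every downstream stage (synthetic generator, miner, family assignment)
queries this module.  Tables are versioned TSV files; a user-supplied
directory with the same schema can be loaded instead of the packaged one.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

#: Residue alphabet of nonpathogenic Pseudomonas lipopeptides.  Hse =
#: homoserine, Dab = 2,4-diaminobutyric acid, Dhb = 2,3-dehydroaminobutyric
#: acid (the latter three occur in the Tolaasin family only).
LP_ALPHABET: tuple[str, ...] = (
    "Leu", "Ile", "Val", "Ser", "Thr", "Glu", "Gln",
    "Asp", "Gly", "Pro", "Lys", "Hse", "Dab", "Dhb",
)

ORGANIZATIONS = ("contiguous", "bifurcate")


class KnowledgeBaseError(ValueError):
    """Corrupt or inconsistent knowledge-base table."""


class UnknownFamilyError(KeyError):
    """Family name not present in the knowledge base."""

    def __init__(self, name: str, valid: Iterable[str]):
        self.name = name
        self.valid = sorted(valid)
        super().__init__(
            f"unknown family {name!r}; valid names: {', '.join(self.valid)}"
        )


@dataclass(frozen=True)
class PeptideVariant:
    """One peptide sequence variant of a family.

    ``leu5_stereo`` carries the L/D configuration of the position-5 leucine
    that differentiates e.g. viscosin from WLIP; stereochemistry is stored
    as an annotation only and never predicted.
    """

    name: str
    family: str
    sequence: tuple[str, ...]
    leu5_stereo: Optional[str] = None
    source: str = "characterized"
    provenance: str = ""


@dataclass(frozen=True)
class PredictedLp:
    """BGC-inferred peptide without chemical validation (kept off-reference)."""

    name: str
    sequence: tuple[str, ...]
    related_family: str
    module_config: tuple[int, ...]
    provenance: str = ""


@dataclass(frozen=True)
class FamilySpec:
    """One LP family: ``[l:m]`` signature, NRPS architecture and variants."""

    name: str
    peptide_length: int
    macrocycle_size: int
    module_configs: tuple[tuple[int, ...], ...]
    organizations: tuple[str, ...]
    variants: tuple[PeptideVariant, ...] = ()
    taxon_groups: tuple[str, ...] = ()
    accessory_genes: str = "none"
    superfamily: int = 0
    aliases: tuple[str, ...] = ()
    provenance: str = ""

    @property
    def signature(self) -> tuple[int, int]:
        """The ``(l, m)`` pair."""
        return (self.peptide_length, self.macrocycle_size)

    @property
    def is_linear(self) -> bool:
        return self.macrocycle_size == 0


@dataclass(frozen=True)
class ReferenceADomain:
    """An adenylation-domain sequence with experimentally known specificity."""

    id: str
    sequence: str
    specificity: str
    system: str = ""
    position: int = 0

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"reference A domain {self.id!r}: empty sequence")
        if self.specificity not in LP_ALPHABET:
            raise ValueError(
                f"reference A domain {self.id!r}: specificity "
                f"{self.specificity!r} not in the LP alphabet"
            )


def _read_tsv(path: Path) -> list[dict]:
    with open(path, newline="") as fh:
        rows = [r for r in fh if not r.startswith("#")]
    return list(csv.DictReader(rows, delimiter="\t"))


def _parse_sequence(text: str, *, where: str) -> tuple[str, ...]:
    residues = tuple(text.split("-"))
    for r in residues:
        if r not in LP_ALPHABET:
            raise KnowledgeBaseError(f"{where}: residue {r!r} not in LP alphabet")
    return residues


class KnowledgeBase:
    """Loaded, validated family/variant tables with lookup operations."""

    def __init__(self, families: list[FamilySpec], predicted: list[PredictedLp]):
        self._families = tuple(families)
        self._predicted = tuple(predicted)
        self._by_name: dict[str, FamilySpec] = {}
        for fam in families:
            for key in (fam.name, *fam.aliases):
                self._by_name[key.lower()] = fam

    # -- loading -----------------------------------------------------------

    @classmethod
    def load(cls, path: Optional[str | Path] = None) -> "KnowledgeBase":
        """Load from ``path`` (directory with the v1 schema) or package data."""
        if path is None:
            data_dir = Path(str(resources.files("lipopeptidome").joinpath("data")))
        else:
            data_dir = Path(path)
        fam_rows = _read_tsv(data_dir / "families.tsv")
        var_rows = _read_tsv(data_dir / "variants.tsv")
        pred_path = data_dir / "predicted_lps.tsv"
        pred_rows = _read_tsv(pred_path) if pred_path.exists() else []

        variants_by_family: dict[str, list[PeptideVariant]] = {}
        seen_variants: set[str] = set()
        for row in var_rows:
            name = row["name"]
            if name in seen_variants:
                raise KnowledgeBaseError(f"variants.tsv: duplicated variant {name!r}")
            seen_variants.add(name)
            stereo = row["leu5_stereo"]
            variants_by_family.setdefault(row["family"], []).append(
                PeptideVariant(
                    name=name,
                    family=row["family"],
                    sequence=_parse_sequence(
                        row["sequence"], where=f"variants.tsv:{name}"
                    ),
                    leu5_stereo=None if stereo == "." else stereo,
                    source=row["source"],
                    provenance=row["provenance"],
                )
            )

        families: list[FamilySpec] = []
        seen: set[str] = set()
        for row in fam_rows:
            name = row["name"]
            if name.lower() in seen:
                raise KnowledgeBaseError(f"families.tsv: duplicated family {name!r}")
            seen.add(name.lower())
            length = int(row["peptide_length"])
            macro = int(row["macrocycle_size"])
            configs = tuple(
                tuple(int(x) for x in cfg.split("-"))
                for cfg in row["module_configs"].split(";")
            )
            for cfg in configs:
                if sum(cfg) != length:
                    raise KnowledgeBaseError(
                        f"families.tsv:{name}: module config {cfg} sums to "
                        f"{sum(cfg)}, expected peptide length {length}"
                    )
            if not 0 <= macro <= length:
                raise KnowledgeBaseError(
                    f"families.tsv:{name}: macrocycle size {macro} outside [0, {length}]"
                )
            orgs = tuple(row["organizations"].split(";"))
            for org in orgs:
                if org not in ORGANIZATIONS:
                    raise KnowledgeBaseError(
                        f"families.tsv:{name}: unknown organization {org!r}"
                    )
            fam_variants = tuple(variants_by_family.pop(name, ()))
            for var in fam_variants:
                if len(var.sequence) != length:
                    raise KnowledgeBaseError(
                        f"variants.tsv:{var.name}: sequence length "
                        f"{len(var.sequence)} != family peptide length {length}"
                    )
            families.append(
                FamilySpec(
                    name=name,
                    peptide_length=length,
                    macrocycle_size=macro,
                    module_configs=configs,
                    organizations=orgs,
                    variants=fam_variants,
                    taxon_groups=tuple(
                        t for t in row["taxon_groups"].split(";") if t
                    ),
                    accessory_genes=row["accessory_genes"],
                    superfamily=int(row["superfamily"]),
                    aliases=tuple(a for a in row["aliases"].split(";") if a),
                    provenance=row["provenance"],
                )
            )
        if variants_by_family:
            orphan = next(iter(variants_by_family))
            raise KnowledgeBaseError(
                f"variants.tsv: variants for unknown family {orphan!r}"
            )

        predicted = [
            PredictedLp(
                name=row["name"],
                sequence=_parse_sequence(
                    row["sequence"], where=f"predicted_lps.tsv:{row['name']}"
                ),
                related_family=row["related_family"],
                module_config=tuple(int(x) for x in row["module_config"].split("-")),
                provenance=row["provenance"],
            )
            for row in pred_rows
        ]
        return cls(families, predicted)

    # -- queries -----------------------------------------------------------

    def list_families(self) -> list[FamilySpec]:
        """All families, exactly once each, in stable (table) order."""
        return list(self._families)

    def get_family(self, name: str) -> FamilySpec:
        """Case-insensitive lookup of a family by name or alias."""
        try:
            return self._by_name[name.lower()]
        except KeyError:
            raise UnknownFamilyError(
                name, (f.name for f in self._families)
            ) from None

    def candidates_by_length(self, peptide_length: int) -> list[FamilySpec]:
        """Families whose peptide length matches (may be empty or >1)."""
        if peptide_length < 1:
            raise ValueError("peptide_length must be >= 1")
        return [f for f in self._families if f.peptide_length == peptide_length]

    def variants_of(self, name: str) -> list[PeptideVariant]:
        """Ordered packaged variants of a family (characterized compounds)."""
        return list(self.get_family(name).variants)

    def predicted_lps(self) -> list[PredictedLp]:
        """BGC-predicted peptides; never used as classification references."""
        return list(self._predicted)


_DEFAULT: Optional[KnowledgeBase] = None


def default_knowledge_base() -> KnowledgeBase:
    """The packaged knowledge base (lazily loaded, shared instance)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = KnowledgeBase.load()
    return _DEFAULT


def list_families() -> list[FamilySpec]:
    return default_knowledge_base().list_families()


def get_family(name: str) -> FamilySpec:
    return default_knowledge_base().get_family(name)


def candidates_by_length(peptide_length: int) -> list[FamilySpec]:
    return default_knowledge_base().candidates_by_length(peptide_length)


def variants_of(name: str) -> list[PeptideVariant]:
    return default_knowledge_base().variants_of(name)
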