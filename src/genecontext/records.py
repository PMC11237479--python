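"""Core record types shared across the pipeline.

Coordinates are stored 0-based half-open internally; every external file
dialect (GFF3, domain-hit TSV) is 1-based inclusive and converted on
read/write. Gene order along a replicon is defined by ascending start
coordinate, never by file order.
"""
from __future__ import annotations

from dataclasses import dataclass, field

#: Reserved label for proteins with no domain or feature annotation.
UNANNOTATED = "UNANNOTATED"

#: Labels treated as sequence features rather than domains. Features are
#: interleaved into architectures at their positions but never count toward
#: fusion status and are never the sole basis of a repeat collapse.
FEATURE_LABELS = frozenset({"TM", "SIG"})


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """One gene on one replicon.

    ``gene_ordinal`` is the 0-based position in the gene order along the
    replicon (ascending start coordinate). ``strand`` is +1 or -1.
    """

    genome_id: str
    replicon_id: str
    gene_ordinal: int
    start: int
    end: int
    strand: int
    protein_accession: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.protein_accession}: start {self.start} >= end {self.end}"
            )
        if self.strand not in (1, -1):
            raise ValueError(f"gene {self.protein_accession}: strand must be +1/-1")


@dataclass(frozen=True, slots=True)
class DomainHit:
    """A domain or feature hit on a protein, in amino-acid coordinates."""

    protein_accession: str
    label: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"hit {self.label}@{self.protein_accession}: start >= end"
            )
        if not self.label:
            raise ValueError("empty domain label")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_feature(self) -> bool:
        return self.label in FEATURE_LABELS


@dataclass(frozen=True, slots=True)
class TaxonRecord:
    """Genome -> (species, phylum, superkingdom) assignment."""

    genome_id: str
    species: str
    phylum: str
    superkingdom: str


@dataclass(frozen=True, slots=True)
class FamilyMembership:
    """Membership of a protein in a query family (homolog-search rollup)."""

    protein_accession: str
    query_family: str


@dataclass(slots=True)
class Taxonomy:
    """Indexed view over a set of :class:`TaxonRecord` rows."""

    records: list[TaxonRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_genome = {}
        for rec in self.records:
            if rec.genome_id in self._by_genome:
                raise ValueError(f"duplicate taxonomy row for genome {rec.genome_id}")
            self._by_genome[rec.genome_id] = rec

    _by_genome: dict = field(init=False, repr=False)

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._by_genome

    def __len__(self) -> int:
        return len(self.records)

    def species(self, genome_id: str) -> str:
        rec = self._by_genome.get(genome_id)
        return rec.species if rec else "unknown"

    def phylum(self, genome_id: str) -> str:
        rec = self._by_genome.get(genome_id)
        return rec.phylum if rec else "unknown"

    def superkingdom(self, genome_id: str) -> str:
        rec = self._by_genome.get(genome_id)
        return rec.superkingdom if rec else "unknown"
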