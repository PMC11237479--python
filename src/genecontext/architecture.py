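"""Ordered N→C domain architectures.

A protein's architecture is the ordered list of its domain and feature
labels along the sequence, after resolving competing overlapping domain
hits. Tandem repeats of a label collapse to ``label×k`` in the signature;
a protein carrying two or more distinct domain labels is a fusion. Features
(transmembrane segments ``TM``, signal peptides ``SIG``) are interleaved at
their positions but never make a protein a fusion and can be excluded from
signatures.
"""
from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .records import FEATURE_LABELS, UNANNOTATED, DomainHit, Taxonomy

#: Joiner between (collapsed) labels inside a single protein's signature.
SIGNATURE_JOIN = "+"
REPEAT_MARK = "×"

OVERLAP_POLICIES = ("score_then_length", "keep_all")


@dataclass(frozen=True, slots=True)
class DomainArchitecture:
    """Resolved architecture of one protein."""

    protein_accession: str
    ordered_labels: tuple[str, ...]
    collapsed_signature: str
    is_fusion: bool
    #: total hit multiplicity per label (repeats count), for node weighting
    label_occurrences: tuple[tuple[str, int], ...] = field(default=())

    @property
    def domain_labels(self) -> tuple[str, ...]:
        """Ordered labels with features removed."""
        return tuple(l for l in self.ordered_labels if l not in FEATURE_LABELS)

    def signature(self, include_features: bool = True) -> str:
        if include_features:
            return self.collapsed_signature
        return collapse_repeats(self.domain_labels) or UNANNOTATED


def collapse_repeats(ordered_labels) -> str:
    """Collapse maximal runs of an identical label to ``label×k`` (k ≥ 2).

    The result joins collapsed tokens with ``+``. Idempotent: collapsing a
    sequence of already-collapsed tokens changes nothing, because a
    collapsed token never equals its bare label.
    """
    return SIGNATURE_JOIN.join(collapse_repeat_tokens(ordered_labels))


def collapse_repeat_tokens(ordered_labels) -> list[str]:
    tokens: list[str] = []
    run_label: str | None = None
    run_len = 0
    for label in list(ordered_labels) + [None]:
        if label == run_label:
            run_len += 1
            continue
        if run_label is not None:
            tokens.append(run_label if run_len == 1 else f"{run_label}{REPEAT_MARK}{run_len}")
        run_label, run_len = label, 1
    return tokens


def _resolve_overlaps(domain_hits: list[DomainHit]) -> list[DomainHit]:
    """Greedy overlap resolution: score desc, then length desc, then start asc.

    Two hits conflict when their overlap exceeds 50% of the shorter hit.
    """
    def precedence(h: DomainHit):
        score = h.score if h.score is not None else -math.inf
        return (-score, -h.length, h.start, h.label)

    kept: list[DomainHit] = []
    for hit in sorted(domain_hits, key=precedence):
        if all(not _conflicts(hit, other) for other in kept):
            kept.append(hit)
    return kept


def _conflicts(a: DomainHit, b: DomainHit) -> bool:
    overlap = min(a.end, b.end) - max(a.start, b.start)
    if overlap <= 0:
        return False
    return overlap > 0.5 * min(a.length, b.length)


def build_architecture(protein_accession: str, hits: list[DomainHit],
                       overlap_policy: str = "score_then_length") -> DomainArchitecture:
    """Build the architecture of one protein from its domain/feature hits.

    Non-feature hits overlapping by more than half the shorter hit are
    resolved under ``score_then_length`` (higher score wins; ties go to the
    longer hit, then the smaller start). Features are kept as-is and
    interleaved at their positions. A protein with zero hits gets the
    reserved ``UNANNOTATED`` label.
    """
    if overlap_policy not in OVERLAP_POLICIES:
        raise ValueError(f"unknown overlap_policy {overlap_policy!r}")
    hits = [h for h in hits if h.protein_accession == protein_accession]
    if not hits:
        return DomainArchitecture(protein_accession, (UNANNOTATED,), UNANNOTATED, False)

    features = [h for h in hits if h.is_feature]
    domains = [h for h in hits if not h.is_feature]
    if overlap_policy == "score_then_length":
        domains = _resolve_overlaps(domains)
    survivors = sorted(domains + features, key=lambda h: (h.start, h.end, h.label))
    ordered = tuple(h.label for h in survivors)
    occurrences: dict[str, int] = defaultdict(int)
    for h in survivors:
        occurrences[h.label] += 1
    distinct_domains = {h.label for h in survivors if not h.is_feature}
    return DomainArchitecture(
        protein_accession,
        ordered,
        collapse_repeats(ordered),
        len(distinct_domains) >= 2,
        tuple(sorted(occurrences.items())),
    )


def build_architectures(hits: list[DomainHit], proteins: list[str] | None = None,
                        overlap_policy: str = "score_then_length",
                        ) -> dict[str, DomainArchitecture]:
    """Architectures for every protein with hits, plus any extra accessions.

    ``proteins`` lists accessions that must appear even with zero hits
    (they become UNANNOTATED) — typically every gene product in the input
    genomes.
    """
    by_protein: dict[str, list[DomainHit]] = defaultdict(list)
    for h in hits:
        by_protein[h.protein_accession].append(h)
    accessions = set(by_protein)
    if proteins is not None:
        accessions.update(proteins)
    return {acc: build_architecture(acc, by_protein.get(acc, []), overlap_policy)
            for acc in sorted(accessions)}


def architecture_census(architectures: dict[str, DomainArchitecture],
                        genome_of: dict[str, str], taxonomy: Taxonomy,
                        min_species: int = 2) -> pd.DataFrame:
    """Count proteins and species per architecture signature.

    ``conserved_flag`` marks signatures seen in at least ``min_species``
    species (default 2, the conventional bar for calling an architecture
    conserved rather than a one-off). Sorted by ``n_proteins`` descending,
    signature ascending on ties.
    """
    proteins: dict[str, int] = defaultdict(int)
    species: dict[str, set[str]] = defaultdict(set)
    for acc, arch in architectures.items():
        sig = arch.collapsed_signature
        proteins[sig] += 1
        genome = genome_of.get(acc)
        if genome is not None:
            species[sig].add(taxonomy.species(genome))
    rows = [{"signature": sig, "n_proteins": proteins[sig],
             "n_species": len(species[sig]),
             "conserved_flag": len(species[sig]) >= min_species}
            for sig in proteins]
    df = pd.DataFrame(rows, columns=["signature", "n_proteins", "n_species", "conserved_flag"])
    return df.sort_values(["n_proteins", "signature"], ascending=[False, True],
                          ignore_index=True)


def architectures_table(architectures: dict[str, DomainArchitecture],
                        genome_of: dict[str, str]) -> pd.DataFrame:
    rows = [{"protein": acc, "genome": genome_of.get(acc, ""),
             "ordered_labels": ",".join(a.ordered_labels),
             "collapsed_signature": a.collapsed_signature,
             "is_fusion": a.is_fusion}
            for acc, a in sorted(architectures.items())]
    return pd.DataFrame(rows, columns=["protein", "genome", "ordered_labels",
                                       "collapsed_signature", "is_fusion"])
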