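"""Gene-neighborhood contexts around query-family homologs.

Each homolog (anchor) gets a ±N gene window along its replicon (default
N = 7). The window is canonically oriented 5′→3′ along the anchor's coding
strand, so the signature is independent of which DNA strand the anchor
happens to sit on and of the direction the replicon was numbered in. A
``||`` token marks every change of transcription direction between adjacent
members, and the anchor is bracketed.

Contexts are grouped into conserved neighborhoods by signature, in two
modes: ``exact`` keeps internal unannotated members (so an inserted
uncharacterized gene breaks identity) while ``gapped`` deletes them first.
In both modes, flanking runs of uninformative members — unannotated genes
or genes whose label is essentially private to one genome — are trimmed
before grouping, since they carry no conservation signal and would make
every window signature unique.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .architecture import DomainArchitecture
from .records import UNANNOTATED, GeneRecord, Taxonomy

STRAND_CHANGE = "||"
CLUSTER_MODES = ("exact", "gapped")


@dataclass(frozen=True, slots=True)
class ContextMember:
    """One gene inside a context window, in canonical orientation."""

    label: str
    relative_strand: int  # +1 = same strand as anchor, -1 = opposite
    is_anchor: bool
    protein_accession: str
    gene_ordinal: int


@dataclass(frozen=True, slots=True)
class NeighborhoodContext:
    """Canonically oriented ±N window around one anchor."""

    anchor_accession: str
    genome_id: str
    replicon_id: str
    window: int
    members: tuple[ContextMember, ...]
    truncated_left: bool
    truncated_right: bool

    @property
    def signature(self) -> str:
        return render_signature(self.members)


def render_signature(members) -> str:
    """Serialize members into the canonical context signature string."""
    parts: list[str] = []
    prev = None
    for m in members:
        if prev is not None and m.relative_strand != prev.relative_strand:
            parts.append(STRAND_CHANGE)
        parts.append(f"[{m.label}]" if m.is_anchor else m.label)
        prev = m
    return " ".join(parts)


def extract_context(anchor: GeneRecord, replicon_genes: list[GeneRecord],
                    signatures: dict[str, str], window: int = 7) -> NeighborhoodContext:
    """Extract the ±``window`` gene context around ``anchor``.

    ``replicon_genes`` must be the genes of the anchor's replicon;
    ``signatures`` maps protein accession to its architecture signature
    (missing proteins are treated as UNANNOTATED). Windows never cross
    replicon ends; truncation is flagged. The member list is stored in
    canonical orientation: when the anchor is on the − strand, the window
    is read in reverse so that members run 5′→3′ along the anchor's coding
    strand, and the truncation flags follow.
    """
    ordered = sorted(replicon_genes, key=lambda g: g.gene_ordinal)
    idx = next((i for i, g in enumerate(ordered)
                if g.protein_accession == anchor.protein_accession
                and g.gene_ordinal == anchor.gene_ordinal), None)
    if idx is None:
        raise ValueError(
            f"anchor {anchor.protein_accession} not found on replicon {anchor.replicon_id}")
    lo = max(0, idx - window)
    hi = min(len(ordered), idx + window + 1)
    members = tuple(
        ContextMember(
            label=signatures.get(g.protein_accession, UNANNOTATED),
            relative_strand=g.strand * anchor.strand,
            is_anchor=(i == idx),
            protein_accession=g.protein_accession,
            gene_ordinal=g.gene_ordinal,
        )
        for i, g in enumerate(ordered[lo:hi], start=lo)
    )
    truncated_left = (idx - window) < 0
    truncated_right = (idx + window + 1) > len(ordered)
    if anchor.strand == -1:
        members = tuple(reversed(members))
        truncated_left, truncated_right = truncated_right, truncated_left
    return NeighborhoodContext(
        anchor_accession=anchor.protein_accession,
        genome_id=anchor.genome_id,
        replicon_id=anchor.replicon_id,
        window=window,
        members=members,
        truncated_left=truncated_left,
        truncated_right=truncated_right,
    )


def canonicalize(context: NeighborhoodContext) -> str:
    """Canonical signature of a context (see :func:`render_signature`)."""
    return render_signature(context.members)


def extract_all_contexts(genes: list[GeneRecord], anchors: list[GeneRecord],
                         architectures: dict[str, DomainArchitecture],
                         window: int = 7,
                         include_features: bool = True) -> list[NeighborhoodContext]:
    """Contexts for every anchor gene, in deterministic order."""
    by_replicon: dict[tuple[str, str], list[GeneRecord]] = defaultdict(list)
    for g in genes:
        by_replicon[(g.genome_id, g.replicon_id)].append(g)
    signatures = {acc: arch.signature(include_features=include_features)
                  for acc, arch in architectures.items()}
    contexts = []
    for anchor in sorted(anchors, key=lambda g: (g.genome_id, g.replicon_id, g.gene_ordinal)):
        replicon = by_replicon[(anchor.genome_id, anchor.replicon_id)]
        contexts.append(extract_context(anchor, replicon, signatures, window))
    return contexts


# ---------------------------------------------------------------------------
# Clustering into conserved neighborhoods
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class ContextCluster:
    """Contexts sharing one signature under one comparison mode."""

    signature: str
    mode: str
    member_anchors: tuple[str, ...]
    n_species: int
    phylum_counts: tuple[tuple[str, int], ...]
    conserved_flag: bool


def _label_genome_counts(contexts) -> dict[str, int]:
    genomes: dict[str, set[str]] = defaultdict(set)
    for ctx in contexts:
        for m in ctx.members:
            if m.label != UNANNOTATED:
                genomes[m.label].add(ctx.genome_id)
    return {label: len(gs) for label, gs in genomes.items()}


def _informative(member: ContextMember, genome_counts: dict[str, int],
                 rare_genome_threshold: int) -> bool:
    if member.is_anchor:
        return True
    if member.label == UNANNOTATED:
        return False
    return genome_counts.get(member.label, 0) >= rare_genome_threshold


def trim_flanks(members, genome_counts: dict[str, int],
                rare_genome_threshold: int = 2):
    """Drop uninformative members from both ends of a context.

    A member is uninformative when it is unannotated or its label occurs in
    fewer than ``rare_genome_threshold`` genomes corpus-wide. The anchor is
    never trimmed; internal members are never touched.
    """
    members = list(members)
    lo, hi = 0, len(members)
    while lo < hi and not _informative(members[lo], genome_counts, rare_genome_threshold):
        lo += 1
    while hi > lo and not _informative(members[hi - 1], genome_counts, rare_genome_threshold):
        hi -= 1
    return tuple(members[lo:hi])


def comparison_signature(context: NeighborhoodContext, mode: str,
                         genome_counts: dict[str, int],
                         rare_genome_threshold: int = 2) -> str:
    """Signature used for clustering a context under the given mode."""
    members = trim_flanks(context.members, genome_counts, rare_genome_threshold)
    if mode == "gapped":
        members = tuple(m for m in members if m.is_anchor or m.label != UNANNOTATED)
    return render_signature(members)


def cluster_contexts(contexts: list[NeighborhoodContext], mode: str = "exact",
                     min_species: int = 5, taxonomy: Taxonomy | None = None,
                     rare_genome_threshold: int = 2) -> list[ContextCluster]:
    """Group contexts into clusters by comparison signature.

    ``conserved_flag`` marks clusters spanning at least ``min_species``
    species (default 5). Clusters partition the input contexts: every
    context lands in exactly one cluster. Exact-mode clusters always refine
    gapped-mode clusters, since deleting unannotated members is a function
    of the exact comparison signature.
    """
    if mode not in CLUSTER_MODES:
        raise ValueError(f"unknown cluster mode {mode!r}")
    genome_counts = _label_genome_counts(contexts)
    groups: dict[str, list[NeighborhoodContext]] = defaultdict(list)
    for ctx in contexts:
        groups[comparison_signature(ctx, mode, genome_counts, rare_genome_threshold)].append(ctx)
    clusters = []
    for sig in sorted(groups):
        members = groups[sig]
        species = {taxonomy.species(c.genome_id) if taxonomy else c.genome_id
                   for c in members}
        phyla: dict[str, int] = defaultdict(int)
        for c in members:
            phyla[taxonomy.phylum(c.genome_id) if taxonomy else "unknown"] += 1
        clusters.append(ContextCluster(
            signature=sig,
            mode=mode,
            member_anchors=tuple(sorted(c.anchor_accession for c in members)),
            n_species=len(species),
            phylum_counts=tuple(sorted(phyla.items())),
            conserved_flag=len(species) >= min_species,
        ))
    clusters.sort(key=lambda c: (-len(c.member_anchors), c.signature))
    return clusters


def contexts_table(contexts: list[NeighborhoodContext]) -> pd.DataFrame:
    rows = [{"anchor": c.anchor_accession, "genome": c.genome_id,
             "replicon": c.replicon_id, "signature": c.signature,
             "truncated_left": c.truncated_left, "truncated_right": c.truncated_right}
            for c in contexts]
    return pd.DataFrame(rows, columns=["anchor", "genome", "replicon", "signature",
                                       "truncated_left", "truncated_right"])


def clusters_table(clusters: list[ContextCluster]) -> pd.DataFrame:
    rows = [{"mode": c.mode, "signature": c.signature,
             "n_members": len(c.member_anchors), "n_species": c.n_species,
             "phylum_counts": ";".join(f"{p}:{n}" for p, n in c.phylum_counts),
             "conserved_flag": c.conserved_flag,
             "member_anchors": ",".join(c.member_anchors)}
            for c in clusters]
    return pd.DataFrame(rows, columns=["mode", "signature", "n_members", "n_species",
                                       "phylum_counts", "conserved_flag", "member_anchors"])


# ---------------------------------------------------------------------------
# Adjacent paralogs (dyads/triads)
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class ParalogCluster:
    """A maximal run of same-family genes on one replicon."""

    query_family: str
    genome_id: str
    replicon_id: str
    accessions: tuple[str, ...]
    ordinals: tuple[int, ...]
    strands: tuple[int, ...]
    any_fusion: bool

    @property
    def size(self) -> int:
        return len(self.accessions)


def detect_adjacent_paralogs(genes: list[GeneRecord],
                             family_of: dict[str, set[str]],
                             architectures: dict[str, DomainArchitecture] | None = None,
                             max_gap_genes: int = 1) -> list[ParalogCluster]:
    """Find dyads/triads/… of adjacent same-family paralogs.

    ``family_of`` maps protein accession to its query families. Two
    consecutive family members belong to the same run when at most
    ``max_gap_genes`` unrelated genes sit between them (default 1, so a
    single interleaved gene does not break a tandem pair). Runs of size ≥ 2
    are reported with strands and whether any member is a fusion protein.
    """
    by_key: dict[tuple[str, str, str], list[GeneRecord]] = defaultdict(list)
    for g in genes:
        for fam in family_of.get(g.protein_accession, ()):
            by_key[(fam, g.genome_id, g.replicon_id)].append(g)
    clusters = []
    for (fam, genome, replicon) in sorted(by_key):
        run: list[GeneRecord] = []
        members = sorted(by_key[(fam, genome, replicon)], key=lambda g: g.gene_ordinal)
        for g in members + [None]:
            if g is not None and (not run or g.gene_ordinal - run[-1].gene_ordinal - 1 <= max_gap_genes):
                run.append(g)
                continue
            if len(run) >= 2:
                clusters.append(ParalogCluster(
                    query_family=fam, genome_id=genome, replicon_id=replicon,
                    accessions=tuple(r.protein_accession for r in run),
                    ordinals=tuple(r.gene_ordinal for r in run),
                    strands=tuple(r.strand for r in run),
                    any_fusion=any(
                        architectures[r.protein_accession].is_fusion
                        for r in run
                        if architectures and r.protein_accession in architectures),
                ))
            run = [g] if g is not None else []
    return clusters


def paralogs_table(clusters: list[ParalogCluster]) -> pd.DataFrame:
    rows = [{"family": c.query_family, "genome": c.genome_id, "replicon": c.replicon_id,
             "size": c.size, "accessions": ",".join(c.accessions),
             "ordinals": ",".join(map(str, c.ordinals)),
             "strands": ",".join("+" if s == 1 else "-" for s in c.strands),
             "any_fusion": c.any_fusion}
            for c in clusters]
    return pd.DataFrame(rows, columns=["family", "genome", "replicon", "size",
                                       "accessions", "ordinals", "strands", "any_fusion"])
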