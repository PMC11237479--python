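"""Phyletic spreads and context-combination (upSet) summaries.

Homolog distributions are rolled up over a two-level taxonomy
(superkingdom → phylum): per-level counts, proportions of the family total,
and a long-format table ready for heatmap plotting. Homologs are counted
per protein by default, so paralogs count individually; a per-genome
presence/absence mode supports heatmaps of lineage coverage.

The upSet summary uses exact-combination (disjoint) semantics: each anchor
contributes its full set of distinct neighbor signatures, and counts are
tallied per exact combination, so combination counts partition the anchors.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .neighborhood import NeighborhoodContext
from .records import UNANNOTATED, Taxonomy

COMBO_JOIN = " & "


@dataclass(slots=True)
class PhyleticProfile:
    """Homolog counts and proportions of one family across lineages."""

    family: str
    total: int
    superkingdom_counts: dict[str, int]
    phylum_counts: dict[str, int]
    #: phylum -> superkingdom containment used for nesting checks
    phylum_parent: dict[str, str]
    superkingdom_proportions: dict[str, float] = field(default_factory=dict)
    phylum_proportions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total > 0:
            self.superkingdom_proportions = {
                k: v / self.total for k, v in self.superkingdom_counts.items()}
            self.phylum_proportions = {
                k: v / self.total for k, v in self.phylum_counts.items()}


def phyletic_spread(family: str, homolog_accessions: list[str],
                    genome_of: dict[str, str], taxonomy: Taxonomy,
                    per_genome: bool = False) -> PhyleticProfile:
    """Distribution of a family's homologs across superkingdoms and phyla.

    Homologs whose genome is missing from the taxonomy are counted under
    the "unknown" lineage. With ``per_genome=True`` each genome counts at
    most once (presence/absence), the mode used for lineage-coverage
    heatmaps.
    """
    units: list[str]
    if per_genome:
        units = sorted({genome_of.get(acc, "unknown") for acc in homolog_accessions})
    else:
        units = [genome_of.get(acc, "unknown") for acc in homolog_accessions]
    sk_counts: Counter = Counter()
    ph_counts: Counter = Counter()
    parent: dict[str, str] = {}
    for genome in units:
        sk = taxonomy.superkingdom(genome)
        ph = taxonomy.phylum(genome)
        sk_counts[sk] += 1
        ph_counts[ph] += 1
        parent[ph] = sk
    return PhyleticProfile(
        family=family, total=len(units),
        superkingdom_counts=dict(sk_counts), phylum_counts=dict(ph_counts),
        phylum_parent=parent,
    )


def phyletics_long_table(profiles: list[PhyleticProfile]) -> pd.DataFrame:
    """Long-format (family × level × lineage) table with counts and proportions."""
    rows = []
    for p in profiles:
        for lineage in sorted(p.superkingdom_counts):
            rows.append({"family": p.family, "level": "superkingdom", "lineage": lineage,
                         "count": p.superkingdom_counts[lineage],
                         "proportion": p.superkingdom_proportions.get(lineage, 0.0)})
        for lineage in sorted(p.phylum_counts):
            rows.append({"family": p.family, "level": "phylum", "lineage": lineage,
                         "count": p.phylum_counts[lineage],
                         "proportion": p.phylum_proportions.get(lineage, 0.0)})
    return pd.DataFrame(rows, columns=["family", "level", "lineage", "count", "proportion"])


def heatmap_table(profiles: list[PhyleticProfile]) -> pd.DataFrame:
    """Family × phylum count matrix (wide), raw counts; zero where absent."""
    data = {p.family: p.phylum_counts for p in profiles}
    df = pd.DataFrame(data).T.fillna(0).astype(int)
    df.index.name = "family"
    return df.sort_index().reindex(sorted(df.columns), axis=1).reset_index()


# ---------------------------------------------------------------------------
# upSet summary
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class UpSetSummary:
    """Exact-combination tally of neighbor signatures across anchors."""

    min_count: int
    #: frozenset of neighbor signatures -> number of anchors with exactly that set
    combination_counts: dict[frozenset, int]
    total_anchors: int

    def shown(self) -> dict[frozenset, int]:
        """Combinations surviving the display threshold."""
        return {c: n for c, n in self.combination_counts.items() if n >= self.min_count}

    def table(self, shown_only: bool = False) -> pd.DataFrame:
        rows = [{"combination": COMBO_JOIN.join(sorted(combo)), "size": len(combo),
                 "count": count, "shown": count >= self.min_count}
                for combo, count in self.combination_counts.items()]
        rows.sort(key=lambda r: (-r["count"], r["combination"]))
        df = pd.DataFrame(rows, columns=["combination", "size", "count", "shown"])
        return df[df["shown"]].reset_index(drop=True) if shown_only else df


def neighbor_signature_set(context: NeighborhoodContext) -> frozenset:
    """Distinct annotated neighbor signatures in one anchor's window."""
    return frozenset(m.label for m in context.members
                     if not m.is_anchor and m.label != UNANNOTATED)


def upset_summary(contexts: list[NeighborhoodContext], min_count: int = 100) -> UpSetSummary:
    """Tally exact combinations of neighbor signatures over anchors.

    Each anchor contributes the set of distinct annotated architecture
    signatures among its window members (anchor excluded). Counts are per
    exact combination, hence disjoint: they partition the anchor set.
    Combinations under ``min_count`` are suppressed from the shown view but
    kept in the full table.
    """
    counts: dict[frozenset, int] = defaultdict(int)
    for ctx in contexts:
        counts[neighbor_signature_set(ctx)] += 1
    return UpSetSummary(min_count=min_count,
                        combination_counts=dict(counts),
                        total_anchors=len(contexts))
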