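"""Domain proximity network.

Nodes are domain/feature labels; an edge records co-occurrence of two
distinct labels either within one protein or across two member genes of one
neighborhood context. Before building the network, homologs are filtered to
the top fraction (default 97%) of each family after sorting architecture
signatures by decreasing frequency, so that rare one-off architectures do
not contribute nodes or edges. Pair counting is presence-based: a label
pair counts once per protein (or per context) regardless of repeat
multiplicity, and repeats never create self-loops — they only raise the
label's occurrence count.
"""
from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .architecture import DomainArchitecture
from .neighborhood import NeighborhoodContext
from .records import FEATURE_LABELS, UNANNOTATED

PROVENANCES = ("within_protein", "within_neighborhood")


def retain_top_fraction(architectures: dict[str, DomainArchitecture],
                        fraction: float = 0.97) -> set[str]:
    """Keep the most frequent architecture classes covering ``fraction`` of proteins.

    Signature classes are sorted by decreasing protein count (signature
    ascending on ties, for determinism) and kept greedily until the
    cumulative count reaches ``fraction`` of the total; the class that
    crosses the boundary is kept whole — a class is retained or dropped
    atomically.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not architectures:
        return set()
    by_signature: dict[str, list[str]] = defaultdict(list)
    for acc, arch in architectures.items():
        by_signature[arch.collapsed_signature].append(acc)
    total = len(architectures)
    retained: set[str] = set()
    cumulative = 0
    for sig in sorted(by_signature, key=lambda s: (-len(by_signature[s]), s)):
        if cumulative >= fraction * total:
            break
        retained.update(by_signature[sig])
        cumulative += len(by_signature[sig])
    return retained


def retain_per_family(architectures: dict[str, DomainArchitecture],
                      family_of: dict[str, set[str]],
                      fraction: float = 0.97) -> set[str]:
    """Apply :func:`retain_top_fraction` within each query family, then union.

    Proteins outside every family are ignored. A protein in two families is
    retained if it survives the cut in either.
    """
    by_family: dict[str, dict[str, DomainArchitecture]] = defaultdict(dict)
    for acc, arch in architectures.items():
        for fam in family_of.get(acc, ()):
            by_family[fam][acc] = arch
    retained: set[str] = set()
    for fam in sorted(by_family):
        retained |= retain_top_fraction(by_family[fam], fraction)
    return retained


@dataclass(slots=True)
class ProximityNetwork:
    """Per-provenance undirected simple graphs over domain labels."""

    graphs: dict[str, nx.Graph] = field(default_factory=dict)
    retention: float = 0.97
    #: label -> total hit multiplicity (repeats counted), per provenance
    occurrence_counts: dict[str, Counter] = field(default_factory=dict)

    def graph(self, provenance: str) -> nx.Graph:
        return self.graphs[provenance]

    def merged(self) -> nx.Graph:
        """Union of all provenances; edge weights summed, provenance annotated."""
        merged = nx.Graph()
        for provenance, g in sorted(self.graphs.items()):
            for node, data in g.nodes(data=True):
                if merged.has_node(node):
                    merged.nodes[node]["weight"] += data["weight"]
                else:
                    merged.add_node(node, weight=data["weight"])
            for u, v, data in g.edges(data=True):
                if merged.has_edge(u, v):
                    merged[u][v]["weight"] += data["weight"]
                    merged[u][v]["provenance"] += "," + provenance
                else:
                    merged.add_edge(u, v, weight=data["weight"], provenance=provenance)
        return merged


def build_network(retained: set[str] | None,
                  architectures: dict[str, DomainArchitecture],
                  contexts: list[NeighborhoodContext] | None = None,
                  provenance_mix: tuple[str, ...] = ("within_protein",),
                  retention: float = 0.97) -> ProximityNetwork:
    """Build the domain proximity network from retained homologs.

    ``retained`` restricts which proteins (and which context anchors)
    contribute; ``None`` means no restriction. ``within_protein`` edges
    join distinct labels of one protein; ``within_neighborhood`` edges join
    labels carried by two *different* member genes of one context (each
    unordered pair counted once per context). UNANNOTATED never enters the
    graph.
    """
    unknown = set(provenance_mix) - set(PROVENANCES)
    if unknown:
        raise ValueError(f"unknown provenance(s): {sorted(unknown)}")
    net = ProximityNetwork(retention=retention)

    if "within_protein" in provenance_mix:
        g = nx.Graph()
        occurrences: Counter = Counter()
        for acc in sorted(architectures):
            if retained is not None and acc not in retained:
                continue
            arch = architectures[acc]
            labels = [l for l in arch.ordered_labels if l != UNANNOTATED]
            for label, count in arch.label_occurrences:
                if label != UNANNOTATED:
                    occurrences[label] += count
            for label in set(labels):
                if g.has_node(label):
                    g.nodes[label]["weight"] += 1
                else:
                    g.add_node(label, weight=1)
            for a, b in itertools.combinations(sorted(set(labels)), 2):
                if g.has_edge(a, b):
                    g[a][b]["weight"] += 1
                else:
                    g.add_edge(a, b, weight=1, provenance="within_protein")
        net.graphs["within_protein"] = g
        net.occurrence_counts["within_protein"] = occurrences

    if "within_neighborhood" in provenance_mix:
        if contexts is None:
            raise ValueError("within_neighborhood provenance requires contexts")
        g = nx.Graph()
        occurrences = Counter()
        for ctx in contexts:
            if retained is not None and ctx.anchor_accession not in retained:
                continue
            member_labels: list[set[str]] = []
            for m in ctx.members:
                arch = architectures.get(m.protein_accession)
                labels = set(arch.ordered_labels) - {UNANNOTATED} if arch else set()
                member_labels.append(labels)
                for label in labels:
                    occurrences[label] += 1
                    if g.has_node(label):
                        g.nodes[label]["weight"] += 1
                    else:
                        g.add_node(label, weight=1)
            pairs: set[tuple[str, str]] = set()
            for la_set, lb_set in itertools.combinations(member_labels, 2):
                for a in la_set:
                    for b in lb_set:
                        if a != b:
                            pairs.add((min(a, b), max(a, b)))
            for a, b in pairs:
                if g.has_edge(a, b):
                    g[a][b]["weight"] += 1
                else:
                    g.add_edge(a, b, weight=1, provenance="within_neighborhood")
        net.graphs["within_neighborhood"] = g
        net.occurrence_counts["within_neighborhood"] = occurrences

    return net


def node_table(network: ProximityNetwork) -> pd.DataFrame:
    rows = []
    for provenance in sorted(network.graphs):
        g = network.graphs[provenance]
        occ = network.occurrence_counts.get(provenance, Counter())
        for node in sorted(g.nodes):
            rows.append({"provenance": provenance, "label": node,
                         "weight": g.nodes[node]["weight"],
                         "occurrences": occ.get(node, 0),
                         "is_feature": node in FEATURE_LABELS})
    return pd.DataFrame(rows, columns=["provenance", "label", "weight",
                                       "occurrences", "is_feature"])
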