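"""Frequency-based retention and proximity-network construction."""
import itertools
from collections import Counter

import pytest

from genecontext import (DomainHit, build_architecture, build_network,
                         retain_top_fraction)
from genecontext.neighborhood import ContextMember, NeighborhoodContext


def arch_of(acc, labels):
    hits = [DomainHit(acc, lab, 120 * i, 120 * i + 100) for i, lab in enumerate(labels)]
    return build_architecture(acc, hits)


def archs_from(spec):
    """spec: {accession: [labels]}"""
    return {acc: arch_of(acc, labels) for acc, labels in spec.items()}


def test_fraction_one_retains_everything():
    archs = archs_from({"a": ["PspA"], "b": ["Snf7"], "c": ["PspA", "NlpC"]})
    assert retain_top_fraction(archs, 1.0) == set(archs)
    assert retain_top_fraction({}, 0.97) == set()


def test_ninety_seven_three_split_drops_the_rare_class():
    archs = archs_from({f"a{i}": ["PspA"] for i in range(97)} |
                       {f"b{i}": ["PspAA"] for i in range(3)})
    retained = retain_top_fraction(archs, 0.97)
    assert retained == {f"a{i}" for i in range(97)}


def test_boundary_crossing_class_is_kept_whole():
    archs = archs_from({f"a{i}": ["PspA"] for i in range(6)} |
                       {f"b{i}": ["Snf7"] for i in range(4)})
    # 0.7 * 10 = 7: class A (6) doesn't reach it, so class B crosses and is kept whole
    assert retain_top_fraction(archs, 0.7) == set(archs)


def test_rare_partner_edge_absent_after_thresholding():
    # a rare PspA-PspAA pairing below the retention bar contributes no edge
    archs = archs_from({f"a{i}": ["PspA"] for i in range(97)} |
                       {f"b{i}": ["PspA", "PspAA"] for i in range(3)})
    retained = retain_top_fraction(archs, 0.97)
    net = build_network(retained, archs)
    g = net.graph("within_protein")
    assert not g.has_edge("PspA", "PspAA")
    full = build_network(None, archs).graph("within_protein")
    assert full.has_edge("PspA", "PspAA")


def test_single_fusion_protein_gives_one_edge():
    archs = archs_from({"p": ["PspA", "NlpC-P60"]})
    g = build_network(None, archs).graph("within_protein")
    assert g.nodes["PspA"]["weight"] == 1
    assert g.nodes["NlpC-P60"]["weight"] == 1
    assert g["PspA"]["NlpC-P60"]["weight"] == 1


def test_tandem_repeat_makes_no_self_loop_but_counts_occurrences():
    archs = archs_from({"p": ["PspA", "PspA"]})
    net = build_network(None, archs)
    g = net.graph("within_protein")
    assert g.nodes["PspA"]["weight"] == 1
    assert g.number_of_edges() == 0
    assert net.occurrence_counts["within_protein"]["PspA"] == 2


@pytest.mark.parametrize("seed", range(5))
def test_edge_weights_match_brute_force_pair_enumeration(seed):
    import random
    rng = random.Random(seed)
    pool = ["PspA", "PspC", "Snf7", "Toastrack", "TM"]
    spec = {f"p{i}": [rng.choice(pool) for _ in range(rng.randrange(1, 5))]
            for i in range(20)}
    archs = archs_from(spec)
    g = build_network(None, archs).graph("within_protein")
    # oracle: count unordered distinct-label pairs per protein
    expected_edges = Counter()
    expected_nodes = Counter()
    for acc, arch in archs.items():
        labels = sorted(set(arch.ordered_labels))
        expected_nodes.update(labels)
        expected_edges.update(itertools.combinations(labels, 2))
    assert {n: d["weight"] for n, d in g.nodes(data=True)} == dict(expected_nodes)
    assert {tuple(sorted(e)): d["weight"] for *e, d in g.edges(data=True)} == \
        dict(expected_edges)


def test_neighborhood_edges_span_genes_not_within_them():
    archs = archs_from({"x": ["PspA"], "y": ["PspC", "TM"], "z": []})
    members = tuple(ContextMember("sig", 1, i == 0, acc, i)
                    for i, acc in enumerate(["x", "y", "z"]))
    ctx = NeighborhoodContext("x", "G1", "chr", 7, members, False, False)
    net = build_network(None, archs, [ctx], provenance_mix=("within_neighborhood",))
    g = net.graph("within_neighborhood")
    # z is unannotated: contributes nothing; PspC-TM are same-gene labels
    assert set(map(frozenset, g.edges)) == {frozenset({"PspA", "PspC"}),
                                            frozenset({"PspA", "TM"})}


def test_retention_monotonicity_and_weight_bound(small_results):
    archs = small_results.architectures
    family_archs = {a: archs[a] for c in small_results.contexts
                    for a in [c.anchor_accession]}
    nested = [build_network(retain_top_fraction(family_archs, f), archs,
                            small_results.contexts,
                            provenance_mix=("within_protein", "within_neighborhood"))
              for f in (1.0, 0.97, 0.5)]
    for bigger, smaller in zip(nested, nested[1:]):
        for prov in ("within_protein", "within_neighborhood"):
            gb, gs = bigger.graph(prov), smaller.graph(prov)
            assert set(gs.nodes) <= set(gb.nodes)
            assert set(map(frozenset, gs.edges)) <= set(map(frozenset, gb.edges))
    for prov, g in nested[0].graphs.items():
        for u, v, d in g.edges(data=True):
            assert d["weight"] <= min(g.nodes[u]["weight"], g.nodes[v]["weight"])
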