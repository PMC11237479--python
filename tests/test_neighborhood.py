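"""Context extraction, canonical orientation, clustering and paralog runs."""
import itertools
from collections import defaultdict

import pytest

from genecontext import (GeneRecord, TaxonRecord, Taxonomy, UNANNOTATED,
                         canonicalize, cluster_contexts,
                         detect_adjacent_paralogs, extract_context)
from genecontext.neighborhood import (ContextMember, NeighborhoodContext,
                                      comparison_signature,
                                      _label_genome_counts, render_signature)
from conftest import make_gene, make_replicon


def ctx_for(genes, anchor_idx, signatures, window=7):
    return extract_context(genes[anchor_idx], genes, signatures, window)


def test_same_strand_operon_has_no_strand_change_markers():
    genes = make_replicon([1, 1, 1, 1])
    sigs = {"p0": "ClgR", "p1": "PspA", "p2": "PspM", "p3": "PspN_N+DUF3046"}
    ctx = ctx_for(genes, 1, sigs)
    assert canonicalize(ctx) == "ClgR [PspA] PspM PspN_N+DUF3046"


def test_divergent_regulator_gets_strand_change_marker():
    genes = make_replicon([-1, 1, 1, 1])
    sigs = {"p0": "PspF", "p1": "PspA", "p2": "PspB", "p3": "PspC"}
    ctx = ctx_for(genes, 1, sigs)
    assert canonicalize(ctx) == "PspF || [PspA] PspB PspC"


def test_lone_gene_context_is_anchor_only_and_truncated():
    genes = make_replicon([1])
    ctx = ctx_for(genes, 0, {"p0": "PspA"})
    assert canonicalize(ctx) == "[PspA]"
    assert ctx.truncated_left and ctx.truncated_right


def test_window_seven_mid_replicon_yields_fifteen_members():
    genes = make_replicon([1] * 30)
    ctx = ctx_for(genes, 15, {}, window=7)
    assert len(ctx.members) == 15
    assert not ctx.truncated_left and not ctx.truncated_right


def test_minus_strand_anchor_reads_window_in_coding_direction():
    # pspF || pspABC planted on the opposite strand: same canonical signature
    genes = make_replicon([1, -1, -1, -1])[::-1]
    genes = [GeneRecord(g.genome_id, g.replicon_id, i, i * 1000, i * 1000 + 900,
                        g.strand, g.protein_accession)
             for i, g in enumerate(genes)]
    sigs = {"p0": "PspF", "p1": "PspA", "p2": "PspB", "p3": "PspC"}
    anchor = next(g for g in genes if g.protein_accession == "p1")
    ctx = extract_context(anchor, genes, sigs)
    assert canonicalize(ctx) == "PspF || [PspA] PspB PspC"


def _reverse_replicon(genes):
    """Reverse gene order, flip every strand, mirror coordinates."""
    span = max(g.end for g in genes) + 50
    flipped = [GeneRecord(g.genome_id, g.replicon_id, 0, span - g.end,
                          span - g.start, -g.strand, g.protein_accession)
               for g in genes]
    flipped.sort(key=lambda g: g.start)
    return [GeneRecord(g.genome_id, g.replicon_id, i, g.start, g.end, g.strand,
                       g.protein_accession) for i, g in enumerate(flipped)]


@pytest.mark.parametrize("seed", range(10))
def test_signature_invariant_under_replicon_reversal(seed):
    import random
    rng = random.Random(seed)
    n = rng.randrange(3, 25)
    genes = make_replicon([rng.choice([1, -1]) for _ in range(n)])
    sigs = {f"p{i}": rng.choice(["PspA", "PspC", "Snf7", UNANNOTATED, f"X{i}"])
            for i in range(n)}
    reversed_genes = _reverse_replicon(genes)
    rev_by_acc = {g.protein_accession: g for g in reversed_genes}
    for anchor in genes:
        fwd = canonicalize(extract_context(anchor, genes, sigs))
        rev = canonicalize(extract_context(
            rev_by_acc[anchor.protein_accession], reversed_genes, sigs))
        assert fwd == rev


def _context(genome, anchor, tokens, anchor_pos, strands=None):
    strands = strands or [1] * len(tokens)
    members = tuple(
        ContextMember(tok, strands[i], i == anchor_pos, f"{genome}_{anchor}_{i}", i)
        for i, tok in enumerate(tokens))
    return NeighborhoodContext(anchor, genome, "chr", 7, members, False, False)


def test_cluster_conservation_thresholds():
    taxonomy = Taxonomy([TaxonRecord(f"G{i}", f"sp{i}", "ph", "Bacteria")
                         for i in range(8)])
    contexts = [_context(f"G{i}", f"a{i}", ["ClgR", "PspA", "PspM"], 1)
                for i in range(5)]
    contexts += [_context(f"G{i}", f"s{i}", ["PspA", "Toastrack"], 0)
                 for i in (6, 7)]
    clusters = cluster_contexts(contexts, "exact", min_species=5, taxonomy=taxonomy)
    by_sig = {c.signature: c for c in clusters}
    assert by_sig["ClgR [PspA] PspM"].conserved_flag        # exactly 5 species
    assert not by_sig["[PspA] Toastrack"].conserved_flag    # 2 species < 5
    four = cluster_contexts(contexts[:4], "exact", min_species=5, taxonomy=taxonomy)
    assert not four[0].conserved_flag                        # 4 species: below bar


def test_gapped_mode_absorbs_unannotated_insertions():
    # planted operon with one uncharacterized insertion in 2 of 6 species
    taxonomy = Taxonomy([TaxonRecord(f"G{i}", f"sp{i}", "ph", "Bacteria")
                         for i in range(6)])
    clean = [_context(f"G{i}", f"a{i}", ["ClgR", "PspA", "PspM"], 1)
             for i in range(4)]
    noisy = [_context(f"G{i}", f"a{i}", ["ClgR", UNANNOTATED, "PspA", "PspM"], 2)
             for i in range(4, 6)]
    contexts = clean + noisy
    gapped = cluster_contexts(contexts, "gapped", min_species=5, taxonomy=taxonomy)
    assert len(gapped) == 1 and len(gapped[0].member_anchors) == 6
    assert gapped[0].conserved_flag
    exact = cluster_contexts(contexts, "exact", min_species=5, taxonomy=taxonomy)
    assert sorted(len(c.member_anchors) for c in exact) == [2, 4]


def test_flanking_rare_labels_are_trimmed_but_internal_kept():
    contexts = [_context(f"G{i}", f"a{i}", [f"BG{i}A", "ClgR", "PspA", f"BG{i}B"], 2)
                for i in range(5)]
    clusters = cluster_contexts(contexts, "exact", min_species=5)
    assert len(clusters) == 1
    assert clusters[0].signature == "ClgR [PspA]"


def test_clusters_partition_contexts_and_exact_refines_gapped(small_results):
    contexts = small_results.contexts
    for mode, clusters in small_results.clusters.items():
        assert sum(len(c.member_anchors) for c in clusters) == len(contexts)
    anchor_to_gapped = {}
    for c in small_results.clusters["gapped"]:
        for a in c.member_anchors:
            anchor_to_gapped.setdefault(a, set()).add(c.signature)
    for c in small_results.clusters["exact"]:
        gapped_homes = set()
        for a in c.member_anchors:
            gapped_homes |= anchor_to_gapped[a]
        assert len(gapped_homes) == 1, "an exact cluster straddles gapped clusters"


def test_cluster_grouping_matches_brute_force_signature_group_by(small_results):
    contexts = small_results.contexts
    counts = _label_genome_counts(contexts)
    for mode, clusters in small_results.clusters.items():
        oracle = defaultdict(list)
        for ctx in contexts:
            oracle[comparison_signature(ctx, mode, counts)].append(ctx.anchor_accession)
        assert {c.signature: sorted(c.member_anchors) for c in clusters} == \
               {sig: sorted(accs) for sig, accs in oracle.items()}


# ---------------------------------------------------------------------------
# adjacent paralogs
# ---------------------------------------------------------------------------

def test_two_adjacent_family_genes_form_a_dyad():
    genes = make_replicon([1] * 20)
    fams = {"p12": {"PspA"}, "p13": {"PspA"}}
    (dyad,) = detect_adjacent_paralogs(genes, fams)
    assert dyad.size == 2 and dyad.ordinals == (12, 13)


def test_single_copy_family_yields_no_clusters():
    genes = make_replicon([1] * 10)
    assert detect_adjacent_paralogs(genes, {"p4": {"PspA"}}) == []


def _brute_force_paralog_runs(ordinals, max_gap):
    """All maximal runs over sorted ordinals with gaps <= max_gap."""
    runs, run = [], []
    for o in sorted(ordinals):
        if run and o - run[-1] - 1 > max_gap:
            runs.append(run)
            run = []
        run.append(o)
    if run:
        runs.append(run)
    return [tuple(r) for r in runs if len(r) >= 2]


@pytest.mark.parametrize("seed,max_gap", [(s, g) for s in range(6) for g in (0, 1, 2)])
def test_paralog_runs_match_brute_force_scan(seed, max_gap):
    import random
    rng = random.Random(seed)
    genes = make_replicon([1] * 40)
    member_ordinals = sorted(rng.sample(range(40), rng.randrange(2, 12)))
    fams = {f"p{o}": {"PspA"} for o in member_ordinals}
    found = detect_adjacent_paralogs(genes, fams, max_gap_genes=max_gap)
    assert sorted(c.ordinals for c in found) == \
        _brute_force_paralog_runs(member_ordinals, max_gap)
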