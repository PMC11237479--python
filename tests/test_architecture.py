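"""Domain architecture construction, repeat collapsing and the census."""
import itertools

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from genecontext import (DomainHit, TaxonRecord, Taxonomy, UNANNOTATED,
                         architecture_census, build_architecture,
                         collapse_repeats)
from genecontext.architecture import _conflicts, collapse_repeat_tokens

labels_st = st.lists(st.sampled_from(["PspA", "PspC", "Snf7", "TM"]), max_size=8)


def hit(acc, label, start, end, score=None):
    return DomainHit(acc, label, start, end, score)


def test_single_domain_protein_is_not_a_fusion():
    arch = build_architecture("LiaH", [hit("LiaH", "PspA", 0, 210)])
    assert arch.ordered_labels == ("PspA",)
    assert arch.collapsed_signature == "PspA"
    assert not arch.is_fusion


def test_two_distinct_domains_make_a_fusion():
    arch = build_architecture("PspN", [hit("PspN", "PspN_N", 0, 50),
                                       hit("PspN", "DUF3046", 59, 120)])
    assert arch.ordered_labels == ("PspN_N", "DUF3046")
    assert arch.is_fusion


def test_zero_hits_yield_reserved_unannotated_label():
    arch = build_architecture("orphan", [])
    assert arch.ordered_labels == (UNANNOTATED,)
    assert not arch.is_fusion


def test_features_interleave_but_never_count_toward_fusion():
    arch = build_architecture("PspC1", [hit("PspC1", "TM", 0, 20),
                                        hit("PspC1", "PspC", 30, 120)])
    assert arch.ordered_labels == ("TM", "PspC")
    assert not arch.is_fusion
    assert arch.signature(include_features=False) == "PspC"


def _brute_force_selection(hits):
    """Unique conflict-free subset maximal under score>length>start precedence.

    Independent oracle: enumerate all subsets; the resolved architecture is
    the unique conflict-free subset where every excluded hit conflicts with
    a retained hit of higher precedence.
    """
    def prec(h):
        score = h.score if h.score is not None else float("-inf")
        return (-score, -h.length, h.start, h.label)

    candidates = []
    for r in range(len(hits) + 1):
        for subset in itertools.combinations(hits, r):
            if any(_conflicts(a, b) for a, b in itertools.combinations(subset, 2)):
                continue
            excluded = [h for h in hits if h not in subset]
            if all(any(_conflicts(h, k) and prec(k) < prec(h) for k in subset)
                   for h in excluded):
                candidates.append(subset)
    assert len(candidates) == 1
    return sorted(candidates[0], key=lambda h: (h.start, h.end, h.label))


@pytest.mark.parametrize("seed", range(5))
def test_overlap_resolution_matches_exhaustive_oracle(seed):
    import random
    rng = random.Random(seed)
    hits = []
    for i in range(8):
        start = rng.randrange(0, 200)
        hits.append(hit("P", f"D{i % 4}", start, start + rng.randrange(20, 120),
                        score=rng.choice([None, 10.0, 50.0, 90.0])))
    arch = build_architecture("P", hits)
    expected = _brute_force_selection(hits)
    assert arch.ordered_labels == tuple(h.label for h in expected)


@given(labels_st)
@settings(max_examples=100, derandomize=True)
def test_collapse_is_idempotent(labels):
    tokens = collapse_repeat_tokens(labels)
    assert collapse_repeat_tokens(tokens) == tokens


def test_tandem_repeat_collapses_with_count():
    assert collapse_repeats(["PspA", "PspA"]) == "PspA×2"
    assert collapse_repeats(["PspA"]) == "PspA"
    assert collapse_repeats(["PspA", "PspA", "NlpC", "PspA"]) == "PspA×2+NlpC+PspA"


@given(st.lists(st.tuples(st.sampled_from("ABCD"), st.integers(0, 30)), min_size=1, max_size=6))
@settings(max_examples=100, derandomize=True)
def test_architecture_invariant_to_hit_order(spec):
    hits = [hit("P", lab, 300 * i + off, 300 * i + off + 100)
            for i, (lab, off) in enumerate(spec)]
    reference = build_architecture("P", hits)
    assert build_architecture("P", list(reversed(hits))) == reference


def test_keep_all_on_nonoverlapping_hits_equals_sorted_collapse():
    hits = [hit("P", "A", 0, 50), hit("P", "A", 60, 110), hit("P", "B", 120, 170)]
    arch = build_architecture("P", hits, overlap_policy="keep_all")
    assert arch.collapsed_signature == collapse_repeats(["A", "A", "B"])


def _census_fixture():
    taxonomy = Taxonomy([
        TaxonRecord("G1", "sp1", "ph1", "Bacteria"),
        TaxonRecord("G2", "sp2", "ph1", "Bacteria"),
        TaxonRecord("G3", "sp3", "ph2", "Bacteria"),
    ])
    archs = {
        "a1": build_architecture("a1", [hit("a1", "PspA", 0, 100)]),
        "a2": build_architecture("a2", [hit("a2", "PspA", 0, 100)]),
        "b1": build_architecture("b1", [hit("b1", "Snf7", 0, 100)]),
    }
    genome_of = {"a1": "G1", "a2": "G2", "b1": "G3"}
    return archs, genome_of, taxonomy


def test_census_threshold_semantics_at_two_species():
    archs, genome_of, taxonomy = _census_fixture()
    census = architecture_census(archs, genome_of, taxonomy, min_species=2)
    rows = census.set_index("signature")
    assert bool(rows.loc["PspA", "conserved_flag"])       # exactly 2 species
    assert not bool(rows.loc["Snf7", "conserved_flag"])   # 1 species


def test_census_counts_match_group_by_oracle(small_results):
    census = small_results.census
    table = small_results.tables["architectures"]
    # oracle: plain pandas group-by over the architectures table
    expected = table.groupby("collapsed_signature").agg(
        n_proteins=("protein", "size")).reset_index()
    merged = census.merge(expected, left_on="signature",
                          right_on="collapsed_signature", how="outer")
    assert (merged["n_proteins_x"] == merged["n_proteins_y"]).all()
    assert census["n_proteins"].sum() == len(table)
    assert (census["n_proteins"].values == sorted(census["n_proteins"], reverse=True)).all()
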