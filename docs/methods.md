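# Methods

## Data model and coordinate conventions

Internally every interval is 0-based half-open; the external dialects
(GFF3 for genes, TSV for domain hits) are 1-based inclusive and converted at
the boundary, so interval arithmetic inside the package never needs ±1
corrections. Gene order along a replicon is defined by ascending start
coordinate, never by file order: neighborhoods depend on physical order, and
unsorted input is sorted rather than rejected. Two labels, `TM`
(transmembrane segment) and `SIG` (signal peptide), are treated as sequence
features: they interleave into architecture strings at their positions but
never make a protein a fusion and can be excluded from signatures. The label
`UNANNOTATED` is reserved for proteins with no hits; input data must not use
it as a domain name.

## Domain architectures

Competing domain hits on one protein are resolved greedily: hits conflict
when they overlap by more than 50% of the shorter hit, and precedence is
higher score, then greater length, then smaller start (a deterministic
version of common domain-annotation practice; the choice matters only for
genuinely ambiguous annotations, and a `keep_all` policy is available).
Tandem runs of one label collapse to `label×k` in the signature; collapsing
is idempotent because a collapsed token never equals its bare label. A
protein is a fusion when it carries ≥2 distinct non-feature domains. The
census counts proteins and species per signature; the conservation bar
defaults to 2 species — one species can be an annotation artifact, two
independent genomes are the minimal evidence of evolutionary retention. Both
the literal ordered labels and the repeat-collapsed signature are emitted,
since counting "architectures" on either form is defensible.

## Neighborhood contexts and canonical orientation

Each query-family homolog anchors a window of up to 7 genes on each side of
it (15 genes total), never crossing a replicon end (truncation is flagged,
and truncated contexts still cluster by their shorter signatures). Windows
are gene-count based only; no intergenic-distance operon model is applied,
because curated operon calls would import assumptions the downstream
statistics do not need.

The canonical signature lists members 5′→3′ along the anchor's own coding
strand: when the anchor lies on the − strand the window is read in reverse.
Member strands are recorded relative to the anchor, a `||` token is inserted
between adjacent members transcribed in opposite directions, and the anchor
is bracketed. This makes the signature invariant under full replicon
reversal (reverse gene order, flip strands, mirror coordinates) — a property
the test suite checks for 100% of anchors on randomized replicons — and
matches the convention of drawing the query left-to-right. Anchor-strand
orientation was chosen over the lexicographic minimum of the two readings
because it keeps upstream/downstream semantics interpretable.

Multi-domain members render as their architecture signature joined with `+`
(e.g. `PspN_N+DUF3046`), so a context signature is a space-separated list of
per-gene tokens.

## Clustering contexts into conserved neighborhoods

Contexts are grouped by a comparison signature under two modes:

* **exact** — the trimmed member list as-is; an internal unannotated
  insertion breaks identity.
* **gapped** — unannotated members are deleted before rendering, so
  contexts differing only by uncharacterized insertions merge. Gapped mode
  never deletes annotated members: losses of annotated genes are reported by
  comparing clusters, not absorbed automatically.

Both modes first **trim the window flanks**: members are dropped from the
two ends of the window while they are unannotated or carry a label observed
in fewer than 2 genomes corpus-wide (the anchor is never trimmed, and
internal members are never touched). The rationale: a ±7 window almost
always extends past the conserved unit into genes private to one genome;
such flanking genes carry no conservation signal, and keeping them would
make every window signature unique, so no neighborhood could ever recur
across species. Trimming by corpus rarity rather than by a fixed gene count
keeps genuinely shared partners (which, by definition of the conservation
question, recur in ≥2 genomes) while removing genome-private flanks. The
rarity threshold is exposed (`rare_genome_threshold`, default 2 genomes).
Because gapped deletion is a function of the trimmed member list, every
exact-mode cluster is contained in exactly one gapped-mode cluster, and both
clusterings partition the context set.

A cluster is conserved at ≥5 species (default): recurrence of a multi-gene
arrangement in five species is unlikely to be drift of a single ancestral
arrangement sampled five times at typical taxon spacing. Contexts of
distinct anchors inside the same operon are deliberately distinct contexts
(no cross-anchor deduplication): each family member's view of the
neighborhood is its own observation.

Adjacent paralog detection reports maximal runs of same-family genes on one
replicon where consecutive members are separated by at most `max_gap_genes`
unrelated genes (default 1, so a single interleaved gene does not break a
tandem pair), with strand layout and whether any member is a fusion.

## Domain proximity network

Before building the network, each query family's homologs are filtered to
the top 97% by architecture-signature frequency: signature classes are
sorted by descending count and kept greedily until the cumulative count
reaches the bound, the boundary-crossing class kept whole, so retention is
atomic per class and monotone in the fraction. Retention is applied per
family and unioned (a global mode exists behind a flag), since a rare
architecture of one family may be common in another.

Edges are presence-based: an unordered pair of distinct labels counts once
per protein (within-protein provenance) or once per context when carried by
two different member genes (within-neighborhood provenance), regardless of
repeat multiplicity. Repeats therefore never create self-loops; they only
raise a label's occurrence count, which is reported separately from its node
weight. The two provenances are kept as separate graphs and merged only on
request, because mixing them changes edge semantics. Edge weight can never
exceed either endpoint's node weight, and lowering the retention fraction
can only remove nodes and edges.

## Phyletic spreads and upSet summaries

Taxonomy is two-level (superkingdom → phylum), matching the rings of a
sunburst view; deeper ranks are out of scope. Homologs are counted per
protein by default, so paralogs count individually; a per-genome
presence/absence mode serves lineage-coverage heatmaps. Proportions are of
the family total and sum to 1 per level; each superkingdom count equals the
sum of its phyla. Genomes missing from the taxonomy are counted under
`unknown` and warned about, not dropped.

The upSet summary uses exact-combination (disjoint) semantics: each anchor
contributes the set of distinct annotated neighbor signatures in its window,
and counts are tallied per exact set, so the counts partition the anchor
set — superset-containment semantics would double-count anchors.
Combinations under the display threshold (default 100 occurrences) are
suppressed from the shown view but retained in the full table; raw counts
are emitted and any per-row normalization is left to plotting.

## Synthetic corpus: what it emulates and what it does not

The generator's defaults define the reference conditions used throughout
the tests and the acceptance script: 200 species in a balanced taxonomy
(2 superkingdoms × 8 phyla), one 500-gene single-replicon genome per
species, and ten planted operon templates modeled on well-studied
membrane-stress layouts — a divergent regulator‖operon, a four-gene
same-strand operon restricted to one phylum, a six-gene two-component
operon, dyad/triad layouts and an operon with an optional trailing gene —
each planted in 7–30 species. Per-species rates add standalone paralog
dyads/triads (0.10), fusion proteins (0.05), tandem-repeat proteins (0.05)
and phylum-restricted singleton families; insertion and loss noise default
to 0 and are switched on explicitly where a test needs them. Background
genes draw labels from a globally unique pool, so no background arrangement
can recur across genomes and any spurious conserved cluster would indicate
a pipeline defect, not sampling luck.

Planted blocks are placed with at least one window width of background
between blocks and replicon ends, so each anchor's window contains exactly
its own block plus trimmable background; the manifest can therefore state
the exact comparison signature every planted anchor must produce. Each
block is planted on a random replicon orientation as a true reversal (order
and strands flipped), exercising canonicalization on every run. Protein
lengths, hit coordinates and scores are synthesized arbitrarily but
consistently (non-overlapping ordered domains, scores uniform on 20–100
bits).

Deliberately not modeled: real intergenic distances and operon-length
distributions, unequal genome sizes, multiple replicons, annotation error,
homology-detection noise, and any evolutionary process (no birth–death, no
substitution model, no phylogenetic correlation between related species).
Passing recovery tests therefore demonstrates the correctness of the
bookkeeping — extraction, canonicalization, clustering, counting — under
known ground truth, not the sensitivity of the method to the noise sources
of real annotation pipelines.

## Numerical and degenerate-input choices

Ties everywhere resolve deterministically (signature class sorting by count
then name; hit precedence by score, length, start, label), so identical
inputs and seed reproduce byte-identical outputs — verified end to end. An
anchor that is the only gene on its replicon yields the context `[token]`,
truncated on both sides. Empty inputs produce empty tables and header-only
edge lists rather than errors. Proportion sums are asserted to 1e−9;
all counting is integer-exact.

## Problem sizes

The default test suite runs on 24-genome (120 genes each) corpora with
template targets capped at 6 species, which preserves every planted element
class; the acceptance script runs the full 200 × 500 conditions for recovery
and a 60 × 200 corpus for the double-run determinism check. These sizes keep
a complete run in the tens of seconds on one CPU while leaving every
threshold (≥5 species conservation, ≥2 species architectures, 97%
retention, 100-count upSet display) at its operational default.

## Known limitations

Flank trimming makes cluster signatures corpus-dependent: adding genomes
can promote a previously rare flanking label above the rarity threshold and
lengthen signatures. Gapped mode only absorbs unannotated insertions; it
does not align contexts or tolerate substitutions of annotated members —
reported relationships between clusters that differ by an annotated member
are left to the user. The ±N window is symmetric and gene-count based, so
very long operons (> N genes from the anchor) are truncated by
construction. The upSet summary ignores member order and strand, by design.
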