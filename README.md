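# genecontext

Comparative-genomics analysis of **conserved gene neighborhoods and protein
domain architectures** across many annotated genomes, of the kind used to map
membrane-stress response systems (phage-shock-protein-like components such as
PspA/Snf7, PspB/PspC, Toastrack, two-component regulators) across the tree of
life. It is aimed at molecular evolution researchers who have per-genome gene
orders, per-protein domain annotations and a taxonomy, and want to know which
domain combinations and operon-like gene arrangements are evolutionarily
conserved, and where.

## What it computes

Given gene tables (GFF3), domain/feature hit tables (TSV), a taxonomy and a
query-family membership table, the pipeline produces:

* **Domain architectures** — the ordered N→C list of domain and feature labels
  per protein, after resolving overlapping hits (score, then length, then
  position), with tandem repeats collapsed to `label×k` and fusions flagged
  (≥2 distinct domains). A census counts proteins and species per signature;
  a signature in ≥2 species is called conserved.
* **Gene-neighborhood contexts** — the ±7 genes around each query-family
  homolog, read 5′→3′ along the anchor's coding strand so the signature is
  independent of replicon orientation. `||` marks each change of transcription
  direction, and the anchor is bracketed, e.g. a divergently transcribed
  regulator upstream of a three-gene operon renders as
  `PspF || [PspA] PspB PspC`.
* **Conserved context clusters** — contexts grouped by signature, in `exact`
  mode and in `gapped` mode (unannotated members deleted first, so an inserted
  uncharacterized gene does not break identity). Flanking genes that carry no
  conservation signal (unannotated, or labels private to a single genome) are
  trimmed before grouping. Clusters spanning ≥5 species are called conserved.
* **Adjacent paralog clusters** — dyads/triads of same-family genes in tandem
  on one replicon, with strand layout and fusion status.
* **Domain proximity network** — nodes are domain/feature labels, edges count
  co-occurrence within a protein or across genes of one neighborhood, built
  from the top 97% of each family's homologs after sorting architecture
  signatures by decreasing frequency.
* **Phyletic spreads and upSet summaries** — homolog counts and proportions
  per superkingdom and phylum, plus exact-combination counts of neighbor
  architectures across anchors (combinations under 100 occurrences are
  suppressed from the shown view).

A **synthetic-genome generator** plants conserved operons, paralog dyads,
fusions, repeats and lineage-restricted families into background genomes with
globally unique background labels, writes a ground-truth manifest, and a
verifier scores the pipeline's recall and spurious-cluster count against it.

## Worked example

Generate a small 24-genome synthetic corpus, run the full pipeline, and score
recovery of the planted neighborhoods:

```bash
genecontext synth --outdir corpus --seed 7 --n-species 24 --n-phyla 4 \
    --cap-template-species 6
# generated 10 planted templates -> corpus

genecontext all --indir corpus --outdir out
# {"architectures": 12000, "contexts": 115,
#  "conserved_clusters": {"exact": 17, "gapped": 17},
#  "window": 7, "min_species_context": 5}

genecontext verify --indir corpus --outdir verify
# {"recall": {"exact": 1.0, "gapped": 1.0},
#  "spurious_conserved": {"exact": 0, "gapped": 0}}
```

The 24 genomes (12,000 genes) yield 115 family-anchored contexts; 17 context
signatures are conserved in ≥5 species, every planted template is recovered
(`recall 1.0`), and no unplanted signature reaches the conservation bar
(`spurious_conserved 0`). The conserved clusters in `out/clusters.tsv` are the
planted layouts, seen once per anchored family member:

```
                                         signature  n_members  n_species
                ClgR PspA [PspM+TM] PspN_N+DUF3046          6          6
                ClgR [PspA] PspM+TM PspN_N+DUF3046          6          6
                           ClgR [PspA] Thioredoxin          6          6
                          Flotillin NfeD || [PspA]          6          6
LiaI+TM PspA [Toastrack] LiaF+TM HisKinase RespReg          6          6
```

Here `PspM+TM` is a protein whose architecture is a PspM domain followed by a
transmembrane segment; `Flotillin NfeD || [PspA]` is a context whose two
upstream genes run opposite to the anchor's strand. The same stages are
available as a library (`genecontext.run_all`, `generate`, `verify_recovery`)
and as per-stage subcommands (`architect`, `contexts`, `cluster`, `network`,
`phyletics`, `upset`).

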