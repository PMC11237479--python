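"""Synthetic genomes with planted ground truth.

The generator emulates the statistical structure of a prokaryote-style
comparative-genomics corpus: a balanced two-level taxonomy, one genome per
species, and a configurable set of planted elements —

* conserved operons from templates (including divergent regulator‖operon
  layouts), each planted in a target number of species, optionally with
  per-slot gene loss and unannotated-gene insertion noise;
* tandem paralog dyads/triads of the main query family;
* fusion proteins and tandem-repeat proteins;
* lineage-restricted singleton families (narrow phyletic spreads);
* background genes whose domain labels come from a globally unique pool,
  so that no two background genes ever share a label and spurious
  conserved neighborhoods are impossible by construction.

Planted blocks are separated from each other and from replicon ends by at
least one window width of background genes, so every anchor's window
contains exactly its own block plus background. Each block is planted on a
random replicon orientation (a true reversal: gene order flipped and all
strands inverted), exercising the canonical orientation of the
neighborhood stage. A ground-truth manifest records every planted element
and the exact/gapped context signatures it should produce, enabling exact
recovery scoring.

The same seed regenerates byte-identical files.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .architecture import collapse_repeats
from .io import write_domain_hits, write_family, write_gff, write_taxonomy
from .neighborhood import ContextMember, render_signature
from .records import (DomainHit, FamilyMembership, GeneRecord, TaxonRecord,
                      Taxonomy, UNANNOTATED)

SUPERKINGDOM_NAMES = ("Bacteria", "Archaea", "Eukaryota")

GENE_SPAN = 1200     # nt allotted per gene slot
GENE_LEN = 999      # nt coding length
DOMAIN_AA = 100     # aa per synthesized domain hit
DOMAIN_STEP = 110


@dataclass(frozen=True, slots=True)
class OperonTemplate:
    """Layout of one conserved neighborhood to plant.

    ``genes`` lists, per gene, the ordered domain/feature labels of its
    product (two distinct domain labels = fusion; a repeated label = tandem
    repeat). ``strands`` gives the layout strand of each gene; a leading
    −1 against +1 neighbors models a divergently transcribed regulator.
    ``optional_slots`` are genes that can be lost under ``loss_rate``;
    ``allowed_phyla`` (phylum indices) restricts which lineages can carry
    the template.
    """

    template_id: str
    genes: tuple[tuple[str, ...], ...]
    strands: tuple[int, ...]
    target_species: int
    optional_slots: tuple[int, ...] = ()
    allowed_phyla: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.strands):
            raise ValueError(f"{self.template_id}: genes/strands length mismatch")
        if self.target_species < 1:
            raise ValueError(f"{self.template_id}: target_species must be >= 1")


def default_templates() -> tuple[OperonTemplate, ...]:
    """Ten operon layouts modeled on well-studied membrane-stress systems.

    They include a divergent regulator‖operon layout (pspF‖pspABC-like),
    a four-gene same-strand operon (clgR-pspA-pspM-pspN-like), a six-gene
    two-component operon (liaIHGFSR-like), dyad/triad layouts, and an
    operon with an optional trailing gene.
    """
    return (
        OperonTemplate("pspF_pspABC", (("PspF",), ("PspA",), ("PspB", "TM"), ("PspC", "TM")),
                       (-1, 1, 1, 1), target_species=30),
        OperonTemplate("clgR_pspAMN", (("ClgR",), ("PspA",), ("PspM", "TM"), ("PspN_N", "DUF3046")),
                       (1, 1, 1, 1), target_species=12, allowed_phyla=(0,)),
        OperonTemplate("lia_operon",
                       (("LiaI", "TM"), ("PspA",), ("Toastrack",), ("LiaF", "TM"),
                        ("HisKinase",), ("RespReg",)),
                       (1, 1, 1, 1, 1, 1), target_species=20),
        OperonTemplate("pspA_pspAA_2CS", (("PspA",), ("PspAA",), ("HisKinase",), ("RespReg",)),
                       (1, 1, 1, 1), target_species=10),
        OperonTemplate("pspAB_system",
                       (("M23-peptidase", "TM"), ("PspAB",), ("PspAA",), ("SHOCT-like",)),
                       (1, 1, 1, 1), target_species=8, optional_slots=(3,)),
        OperonTemplate("clgR_thioredoxin", (("ClgR",), ("PspA",), ("Thioredoxin",)),
                       (1, 1, 1), target_species=8, allowed_phyla=(0, 1)),
        OperonTemplate("toastrack_HAAS", (("Toastrack",), ("HAAS",), ("PspC", "TM")),
                       (1, 1, 1), target_species=15),
        OperonTemplate("snf7_dyad_vps4", (("Snf7",), ("Snf7",), ("Vps4-ATPase",)),
                       (1, 1, 1), target_species=9),
        OperonTemplate("flotillin_nfed", (("Flotillin",), ("NfeD",), ("PspA",)),
                       (-1, -1, 1), target_species=11),
        OperonTemplate("cyano_pspA_dyad", (("PspA",), ("PspA",), ("ThylakoidTM", "TM")),
                       (1, 1, 1), target_species=7),
    )


def scaled_templates(max_target: int,
                     templates: tuple[OperonTemplate, ...] | None = None,
                     ) -> tuple[OperonTemplate, ...]:
    """Default templates with ``target_species`` capped, for small corpora."""
    from dataclasses import replace
    return tuple(replace(t, target_species=min(t.target_species, max_target))
                 for t in (templates or default_templates()))


@dataclass(slots=True)
class SynthConfig:
    """Full parameterization of one synthetic corpus. Seed determines everything."""

    seed: int = 0
    n_superkingdoms: int = 2
    n_phyla: int = 8
    n_species: int = 200
    genes_per_genome: int = 500
    window: int = 7
    operon_templates: tuple[OperonTemplate, ...] = field(default_factory=default_templates)
    query_families: tuple[str, ...] = ("PspA", "PspC", "Snf7", "Toastrack", "PspAA", "PspM")
    #: family label -> {phylum index: presence probability} for singleton plants
    family_presence: dict = field(
        default_factory=lambda: {"PspM": {0: 0.8}})
    paralog_dyad_rate: float = 0.10
    fusion_rate: float = 0.05
    repeat_rate: float = 0.05
    insertion_rate: float = 0.0
    loss_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("paralog_dyad_rate", "fusion_rate", "repeat_rate",
                     "insertion_rate", "loss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for t in self.operon_templates:
            if t.target_species > self.n_species:
                raise ValueError(
                    f"template {t.template_id}: target_species {t.target_species} "
                    f"> n_species {self.n_species}")
        if self.n_phyla < self.n_superkingdoms:
            raise ValueError("need at least one phylum per superkingdom")


# ---------------------------------------------------------------------------
# Internal planting plan
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class _PlannedGene:
    labels: tuple[str, ...]   # empty => unannotated
    strand: int               # layout strand

    @property
    def token(self) -> str:
        return collapse_repeats(self.labels) if self.labels else UNANNOTATED


@dataclass(slots=True)
class _Block:
    kind: str                 # template | dyad | fusion | repeat | singleton
    block_id: str
    genes: list[_PlannedGene]
    template_id: str | None = None
    #: accession per layout slot, filled at emission (orientation-corrected)
    accessions: list[str | None] = field(default_factory=list)


def _anchor_indices(block: _Block, query_families: tuple[str, ...]) -> list[int]:
    fams = set(query_families)
    return [i for i, g in enumerate(block.genes) if fams & set(g.labels)]


def _expected_signatures(block: _Block, anchor_idx: int) -> tuple[str, str]:
    """(exact, gapped) context signature this anchor should produce.

    Computed from the block layout alone: flanking background is trimmed by
    the clustering stage, so the comparison signature is exactly the block.
    """
    def members(gene_filter) -> list[ContextMember]:
        out = []
        anchor_strand = block.genes[anchor_idx].strand
        for i, g in enumerate(block.genes):
            if i != anchor_idx and not gene_filter(g):
                continue
            out.append(ContextMember(
                label=g.token, relative_strand=g.strand * anchor_strand,
                is_anchor=(i == anchor_idx), protein_accession="", gene_ordinal=i))
        if anchor_strand == -1:
            out = list(reversed(out))
        return out

    exact = render_signature(members(lambda g: True))
    gapped = render_signature(members(lambda g: bool(g.labels)))
    return exact, gapped


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _build_taxonomy(config: SynthConfig) -> Taxonomy:
    records = []
    for i in range(config.n_species):
        phylum = i % config.n_phyla
        sk = phylum % config.n_superkingdoms
        sk_name = (SUPERKINGDOM_NAMES[sk] if sk < len(SUPERKINGDOM_NAMES)
                   else f"Superkingdom{sk:02d}")
        records.append(TaxonRecord(
            genome_id=f"G{i:04d}", species=f"Species{i:04d}",
            phylum=f"Phylum{phylum:02d}", superkingdom=sk_name))
    return Taxonomy(records)


def _phylum_index(taxon: TaxonRecord) -> int:
    return int(taxon.phylum.replace("Phylum", ""))


def generate(config: SynthConfig, outdir: str | Path) -> dict:
    """Generate the corpus into ``outdir`` and return the ground-truth manifest.

    Emits one GFF3 per genome under ``genomes/``, plus ``hits.tsv``,
    ``taxonomy.tsv``, ``families.tsv`` and ``ground_truth.json``.
    """
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    taxonomy = _build_taxonomy(config)
    genomes = sorted(t.genome_id for t in taxonomy.records)
    by_genome = {t.genome_id: t for t in taxonomy.records}

    blocks_per_genome: dict[str, list[_Block]] = {g: [] for g in genomes}
    template_species: dict[str, list[str]] = {}

    # -- assign templates to species -------------------------------------
    for tmpl in config.operon_templates:
        if tmpl.allowed_phyla is not None:
            pool = [g for g in genomes if _phylum_index(by_genome[g]) in tmpl.allowed_phyla]
        else:
            pool = list(genomes)
        if tmpl.target_species > len(pool):
            raise ValueError(
                f"template {tmpl.template_id}: target_species {tmpl.target_species} "
                f"exceeds eligible genomes ({len(pool)})")
        chosen = sorted(rng.choice(pool, size=tmpl.target_species, replace=False))
        template_species[tmpl.template_id] = chosen
        for genome in chosen:
            genes = [_PlannedGene(tuple(labels), strand)
                     for labels, strand in zip(tmpl.genes, tmpl.strands)]
            # gene loss on optional slots
            keep = [i for i in range(len(genes))
                    if i not in tmpl.optional_slots or rng.random() >= config.loss_rate]
            genes = [genes[i] for i in keep]
            # unannotated-gene insertion at internal boundaries
            if config.insertion_rate > 0:
                noisy: list[_PlannedGene] = []
                for i, g in enumerate(genes):
                    noisy.append(g)
                    if i < len(genes) - 1 and rng.random() < config.insertion_rate:
                        noisy.append(_PlannedGene((), int(rng.choice([1, -1]))))
                genes = noisy
            blocks_per_genome[genome].append(
                _Block("template", f"{tmpl.template_id}@{genome}", genes, tmpl.template_id))

    # -- dyads/triads, fusions, repeats, restricted singletons -----------
    main_family = config.query_families[0] if config.query_families else "PspA"
    for genome in genomes:
        if rng.random() < config.paralog_dyad_rate:
            size = 2 if rng.random() < 0.7 else 3
            strand = int(rng.choice([1, -1]))
            genes = [_PlannedGene((main_family,), strand) for _ in range(size)]
            blocks_per_genome[genome].append(_Block("dyad", f"dyad@{genome}", genes))
        if rng.random() < config.fusion_rate:
            blocks_per_genome[genome].append(_Block(
                "fusion", f"fusion@{genome}",
                [_PlannedGene((main_family, "NlpC-P60"), 1)]))
        if rng.random() < config.repeat_rate:
            blocks_per_genome[genome].append(_Block(
                "repeat", f"repeat@{genome}",
                [_PlannedGene((main_family, main_family), 1)]))
    for family in sorted(config.family_presence):
        presence = config.family_presence[family]
        for genome in genomes:
            prob = presence.get(_phylum_index(by_genome[genome]), 0.0)
            if prob > 0 and rng.random() < prob:
                labels = (family, "TM") if family in ("PspM", "PspC") else (family,)
                blocks_per_genome[genome].append(_Block(
                    "singleton", f"{family}@{genome}", [_PlannedGene(labels, 1)]))

    # -- emit genomes -----------------------------------------------------
    all_hits: list[DomainHit] = []
    family_rows: list[FamilyMembership] = []
    bg_counter = 0
    window = config.window
    for genome in genomes:
        blocks = blocks_per_genome[genome]
        order = rng.permutation(len(blocks))
        blocks = [blocks[i] for i in order]
        n_plant_genes = sum(len(b.genes) for b in blocks)
        min_bg = (2 * window + (len(blocks) - 1) * window) if blocks else 0
        n_background = config.genes_per_genome - n_plant_genes
        if n_background < min_bg:
            raise ValueError(
                f"{genome}: {config.genes_per_genome} gene slots cannot hold "
                f"{n_plant_genes} planted genes with window-{window} spacing")
        # distribute surplus background among the len(blocks)+1 gaps
        gaps = [window] * (len(blocks) + 1) if blocks else [n_background]
        if blocks:
            surplus = n_background - min_bg
            extra = rng.multinomial(surplus, np.full(len(gaps), 1.0 / len(gaps)))
            gaps = [g + int(e) for g, e in zip(gaps, extra)]

        plan: list[tuple[_Block | None, _PlannedGene | None, int]] = []
        for i, block in enumerate(blocks):
            plan.extend((None, None, -1) for _ in range(gaps[i]))
            block.accessions = [None] * len(block.genes)
            orientation = int(rng.choice([1, -1]))
            slots = (list(enumerate(block.genes)) if orientation == 1
                     else list(reversed(list(enumerate(block.genes)))))
            for slot, g in slots:
                plan.append((block, _PlannedGene(g.labels, g.strand * orientation), slot))
        plan.extend((None, None, -1) for _ in range(gaps[-1]))

        genes_out: list[GeneRecord] = []
        for ordinal, (block, planned, slot) in enumerate(plan):
            acc = f"{genome}_{ordinal:05d}"
            start = ordinal * GENE_SPAN
            if planned is None:
                strand = int(rng.choice([1, -1]))
                label = f"BG{bg_counter:07d}"
                bg_counter += 1
                all_hits.append(DomainHit(acc, label, 0, DOMAIN_AA,
                                          round(float(rng.uniform(20, 100)), 1)))
            else:
                strand = planned.strand
                block.accessions[slot] = acc
                for j, label in enumerate(planned.labels):
                    all_hits.append(DomainHit(
                        acc, label, j * DOMAIN_STEP, j * DOMAIN_STEP + DOMAIN_AA,
                        round(float(rng.uniform(20, 100)), 1)))
                for fam in sorted(set(config.query_families) & set(planned.labels)):
                    family_rows.append(FamilyMembership(acc, fam))
            genes_out.append(GeneRecord(genome, "chr", ordinal, start,
                                        start + GENE_LEN, strand, acc))
        write_gff(genes_out, outdir / "genomes" / f"{genome}.gff3")

    write_domain_hits(all_hits, outdir / "hits.tsv")
    write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
    write_family(family_rows, outdir / "families.tsv")

    manifest = _build_manifest(config, taxonomy, blocks_per_genome, template_species)
    with (outdir / "ground_truth.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _build_manifest(config: SynthConfig, taxonomy: Taxonomy,
                    blocks_per_genome: dict[str, list[_Block]],
                    template_species: dict[str, list[str]]) -> dict:
    by_genome = {t.genome_id: t for t in taxonomy.records}
    templates: dict[str, dict] = {
        tid: {"species": [by_genome[g].species for g in sp], "genomes": sp,
              "n_slots": 0, "anchors": []}
        for tid, sp in template_species.items()}
    paralogs, fusions, repeats, singletons = [], [], [], []
    expected: dict[str, set] = {"exact": set(), "gapped": set()}
    family_counts: dict[str, dict[str, dict[str, int]]] = {}

    for genome in sorted(blocks_per_genome):
        taxon = by_genome[genome]
        for block in blocks_per_genome[genome]:
            anchor_idx = _anchor_indices(block, config.query_families)
            for k, idx in enumerate(anchor_idx):
                exact, gapped = _expected_signatures(block, idx)
                expected["exact"].add(exact)
                expected["gapped"].add(gapped)
                if block.kind == "template":
                    entry = templates[block.template_id]
                    entry["n_slots"] = max(entry["n_slots"], len(anchor_idx))
                    entry["anchors"].append({
                        "genome": genome, "accession": block.accessions[idx],
                        "slot": k, "expected_exact": exact, "expected_gapped": gapped})
            for idx, gene in enumerate(block.genes):
                for fam in set(config.query_families) & set(gene.labels):
                    counts = family_counts.setdefault(
                        fam, {"superkingdom": {}, "phylum": {}})
                    counts["superkingdom"][taxon.superkingdom] = \
                        counts["superkingdom"].get(taxon.superkingdom, 0) + 1
                    counts["phylum"][taxon.phylum] = counts["phylum"].get(taxon.phylum, 0) + 1
            if block.kind == "dyad":
                paralogs.append({"family": config.query_families[0], "genome": genome,
                                 "accessions": block.accessions,
                                 "size": len(block.accessions)})
            elif block.kind == "fusion":
                fusions.append({"genome": genome, "accession": block.accessions[0],
                                "signature": block.genes[0].token})
            elif block.kind == "repeat":
                repeats.append({"genome": genome, "accession": block.accessions[0],
                                "signature": block.genes[0].token})
            elif block.kind == "singleton":
                singletons.append({"genome": genome, "accession": block.accessions[0],
                                   "family": block.block_id.split("@")[0]})
            # same-family runs inside a template are planted paralog clusters
            # (gap rule mirrors detect_adjacent_paralogs' default max_gap_genes=1)
            if block.kind == "template":
                for fam in sorted(set(config.query_families)):
                    idxs = [i for i, g in enumerate(block.genes) if fam in g.labels]
                    run = []
                    for i in idxs + [None]:
                        if i is not None and (not run or i - run[-1] - 1 <= 1):
                            run.append(i)
                            continue
                        if len(run) >= 2:
                            paralogs.append({
                                "family": fam, "genome": genome,
                                "accessions": [block.accessions[i2] for i2 in run],
                                "size": len(run)})
                        run = [i] if i is not None else []

    return {
        "seed": config.seed,
        "config": {
            "n_superkingdoms": config.n_superkingdoms, "n_phyla": config.n_phyla,
            "n_species": config.n_species, "genes_per_genome": config.genes_per_genome,
            "window": config.window, "insertion_rate": config.insertion_rate,
            "loss_rate": config.loss_rate,
            "templates": [t.template_id for t in config.operon_templates]},
        "templates": templates,
        "paralog_clusters": paralogs,
        "fusions": fusions,
        "repeats": repeats,
        "singletons": singletons,
        "family_counts": family_counts,
        "expected_context_signatures": {k: sorted(v) for k, v in expected.items()},
    }


# ---------------------------------------------------------------------------
# Recovery verification
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class RecoveryReport:
    """Comparison of pipeline output against the ground-truth manifest."""

    recall: dict[str, float]                 # mode -> recovered / planted
    spurious_conserved: dict[str, int]       # mode -> conserved clusters not planted
    per_template: dict[str, dict[str, bool]]  # template -> mode -> recovered
    n_planted: int

    def as_dict(self) -> dict:
        return asdict(self)


def verify_recovery(manifest: dict, clusters_by_mode: dict) -> RecoveryReport:
    """Score recovered planted neighborhoods against the manifest.

    ``clusters_by_mode`` maps mode ('exact'/'gapped') to the cluster list
    from :func:`genecontext.neighborhood.cluster_contexts`. A planted
    template counts as recovered under a mode when some *conserved* cluster
    carries one of the signatures its planted anchors were given. Spurious
    clusters are conserved clusters whose signature matches no planted
    element.
    """
    recall: dict[str, float] = {}
    spurious: dict[str, int] = {}
    per_template: dict[str, dict[str, bool]] = {
        tid: {} for tid in manifest["templates"]}
    for mode, clusters in clusters_by_mode.items():
        conserved_sigs = {c.signature for c in clusters if c.conserved_flag}
        key = "expected_exact" if mode == "exact" else "expected_gapped"
        recovered = 0
        for tid, entry in manifest["templates"].items():
            expected_sigs = {a[key] for a in entry["anchors"]}
            ok = bool(expected_sigs & conserved_sigs)
            per_template[tid][mode] = ok
            recovered += ok
        n_templates = len(manifest["templates"])
        recall[mode] = recovered / n_templates if n_templates else 1.0
        planted_all = set(manifest["expected_context_signatures"][mode])
        spurious[mode] = sum(1 for s in conserved_sigs if s not in planted_all)
    return RecoveryReport(recall=recall, spurious_conserved=spurious,
                          per_template=per_template,
                          n_planted=len(manifest["templates"]))
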