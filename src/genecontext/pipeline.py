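"""End-to-end orchestration of the analysis stages.

Reads a corpus (per-genome GFF3 + hits/taxonomy/family TSVs), builds
architectures, neighborhood contexts, conserved clusters, the domain
proximity network, phyletic spreads and the upSet summary, and writes all
result tables, graphs and a JSON manifest. Every stage is a pure function
of (inputs, config), so identical inputs and config reproduce identical
outputs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import architecture as arch_mod
from . import io as io_mod
from . import neighborhood as nbh_mod
from . import network as net_mod
from . import phyletics as phy_mod
from .records import FamilyMembership, GeneRecord, Taxonomy

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass(slots=True)
class PipelineConfig:
    """Tunable thresholds of the full analysis.

    Defaults follow the field's working conventions for this kind of
    survey: ±7-gene windows, architectures conserved at ≥2 species,
    contexts conserved at ≥5 species, the top 97% of homologs per family
    retained for the network, and upSet combinations shown at ≥100
    occurrences.
    """

    window: int = 7
    min_species_context: int = 5
    min_species_arch: int = 2
    retention_fraction: float = 0.97
    upset_min_count: int = 100
    cluster_mode: str = "both"       # exact | gapped | both
    global_retention: bool = False   # retention across all families at once
    rare_genome_threshold: int = 2
    max_gap_genes: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ConfigError("window must be >= 0")
        if self.min_species_context < 1 or self.min_species_arch < 1:
            raise ConfigError("species thresholds must be >= 1")
        if not 0 < self.retention_fraction <= 1:
            raise ConfigError("retention_fraction must be in (0, 1]")
        if self.upset_min_count < 0:
            raise ConfigError("upset_min_count must be >= 0")
        if self.cluster_mode not in ("exact", "gapped", "both"):
            raise ConfigError(f"unknown cluster_mode {self.cluster_mode!r}")

    @property
    def cluster_modes(self) -> tuple[str, ...]:
        return ("exact", "gapped") if self.cluster_mode == "both" else (self.cluster_mode,)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a key/value mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(slots=True)
class CorpusInputs:
    genes: list[GeneRecord]
    hits: list
    taxonomy: Taxonomy
    families: list[FamilyMembership]


def load_corpus(indir: str | Path) -> CorpusInputs:
    """Load a corpus directory: ``genomes/*.gff3`` + the three TSVs."""
    indir = Path(indir)
    genome_dir = indir / "genomes"
    for required in (genome_dir, indir / "hits.tsv", indir / "taxonomy.tsv",
                     indir / "families.tsv"):
        if not required.exists():
            raise FileNotFoundError(f"missing input: {required}")
    genes: list[GeneRecord] = []
    for gff in sorted(genome_dir.glob("*.gff3")):
        genes.extend(io_mod.read_gff(gff))
    return CorpusInputs(
        genes=genes,
        hits=io_mod.read_domain_hits(indir / "hits.tsv"),
        taxonomy=io_mod.read_taxonomy(indir / "taxonomy.tsv"),
        families=io_mod.read_family(indir / "families.tsv"),
    )


@dataclass(slots=True)
class PipelineResults:
    """In-memory results of one full run."""

    config: PipelineConfig
    architectures: dict
    census: pd.DataFrame
    contexts: list
    clusters: dict                  # mode -> list[ContextCluster]
    paralogs: list
    network: net_mod.ProximityNetwork
    profiles: list
    upset: phy_mod.UpSetSummary
    tables: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def run_all(indir: str | Path, outdir: str | Path | None = None,
            config: PipelineConfig | None = None) -> PipelineResults:
    """Run every stage on a corpus; optionally write results to ``outdir``."""
    config = config or PipelineConfig()
    inputs = load_corpus(indir)
    log.info("loaded %d genes, %d hits, %d taxa, %d family rows",
             len(inputs.genes), len(inputs.hits), len(inputs.taxonomy),
             len(inputs.families))

    genome_of = {g.protein_accession: g.genome_id for g in inputs.genes}
    architectures = arch_mod.build_architectures(
        inputs.hits, proteins=[g.protein_accession for g in inputs.genes])
    census = arch_mod.architecture_census(
        architectures, genome_of, inputs.taxonomy, min_species=config.min_species_arch)

    family_of: dict[str, set[str]] = {}
    for fam in inputs.families:
        family_of.setdefault(fam.protein_accession, set()).add(fam.query_family)
    anchors = [g for g in inputs.genes if g.protein_accession in family_of]
    contexts = nbh_mod.extract_all_contexts(
        inputs.genes, anchors, architectures, window=config.window)
    log.info("built %d architectures, %d contexts", len(architectures), len(contexts))

    clusters = {mode: nbh_mod.cluster_contexts(
                    contexts, mode=mode, min_species=config.min_species_context,
                    taxonomy=inputs.taxonomy,
                    rare_genome_threshold=config.rare_genome_threshold)
                for mode in config.cluster_modes}
    for mode, cls in clusters.items():
        log.info("%s mode: %d clusters, %d conserved", mode, len(cls),
                 sum(c.conserved_flag for c in cls))

    paralogs = nbh_mod.detect_adjacent_paralogs(
        inputs.genes, family_of, architectures, max_gap_genes=config.max_gap_genes)

    family_archs = {acc: architectures[acc] for acc in family_of if acc in architectures}
    if config.global_retention:
        retained = net_mod.retain_top_fraction(family_archs, config.retention_fraction)
    else:
        retained = net_mod.retain_per_family(
            family_archs, family_of, config.retention_fraction)
    network = net_mod.build_network(
        retained, architectures, contexts,
        provenance_mix=("within_protein", "within_neighborhood"),
        retention=config.retention_fraction)

    members_by_family: dict[str, list[str]] = {}
    for fam in inputs.families:
        members_by_family.setdefault(fam.query_family, []).append(fam.protein_accession)
    profiles = [phy_mod.phyletic_spread(family, sorted(accs), genome_of, inputs.taxonomy)
                for family, accs in sorted(members_by_family.items())]
    upset = phy_mod.upset_summary(contexts, min_count=config.upset_min_count)

    tables = {
        "architectures": arch_mod.architectures_table(architectures, genome_of),
        "architecture_census": census,
        "contexts": nbh_mod.contexts_table(contexts),
        "clusters": pd.concat(
            [nbh_mod.clusters_table(cls) for cls in clusters.values()],
            ignore_index=True) if clusters else pd.DataFrame(),
        "paralogs": nbh_mod.paralogs_table(paralogs),
        "phyletics": phy_mod.phyletics_long_table(profiles),
        "heatmap": phy_mod.heatmap_table(profiles) if profiles else pd.DataFrame(),
        "upset": upset.table(),
        "network_nodes": net_mod.node_table(network),
    }
    results = PipelineResults(
        config=config, architectures=architectures, census=census,
        contexts=contexts, clusters=clusters, paralogs=paralogs,
        network=network, profiles=profiles, upset=upset, tables=tables)

    if outdir is not None:
        graphs = {f"network_{prov}": g for prov, g in network.graphs.items()}
        results.manifest = io_mod.write_results(
            tables, graphs, outdir, parameters=asdict(config), seed=config.seed)
    return results


def run_verify(indir: str | Path, results: PipelineResults) -> dict:
    """Score planted-structure recovery for a synthetic corpus directory."""
    from .synth import verify_recovery
    path = Path(indir) / "ground_truth.json"
    if not path.exists():
        raise FileNotFoundError(f"missing ground-truth manifest: {path}")
    with path.open() as fh:
        manifest = json.load(fh)
    return verify_recovery(manifest, results.clusters).as_dict()
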