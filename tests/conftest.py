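import pathlib

import pytest

from genecontext import GeneRecord, run_all
from genecontext.pipeline import PipelineConfig
from genecontext.synth import SynthConfig, generate, scaled_templates


def make_gene(acc, ordinal, strand=1, genome="G0001", replicon="chr"):
    start = ordinal * 1000
    return GeneRecord(genome, replicon, ordinal, start, start + 900, strand, acc)


def make_replicon(strands, genome="G0001", replicon="chr", prefix="p"):
    return [make_gene(f"{prefix}{i}", i, strand, genome, replicon)
            for i, strand in enumerate(strands)]


def small_config(seed=11, **overrides):
    """A small corpus preserving all planted element kinds."""
    kwargs = dict(seed=seed, n_species=24, n_phyla=4, genes_per_genome=120,
                  operon_templates=scaled_templates(6))
    kwargs.update(overrides)
    return SynthConfig(**kwargs)


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("corpus")
    manifest = generate(small_config(), outdir)
    return pathlib.Path(outdir), manifest


@pytest.fixture(scope="session")
def small_results(small_corpus):
    indir, _ = small_corpus
    return run_all(indir, config=PipelineConfig(seed=11))
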