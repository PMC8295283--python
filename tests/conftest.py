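import numpy as np
import pytest

from cardioscreen import design as dz
from cardioscreen import models, screenstats as ss
from cardioscreen import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    return sim.SimConfig(seed=11, n_genes=10, n_hit_genes=2, genome_length=80_000)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return sim.gen_genome(small_config)


@pytest.fixture(scope="session")
def small_library(small_genome):
    genome, genes = small_genome
    return dz.design_library(genes, genome, seed=11)


@pytest.fixture(scope="session")
def default_screen():
    """The default simulated screen: 500 genes, 50 hits at log2FC 3."""
    cfg = sim.SimConfig(seed=101)
    lib = sim.synthetic_library(cfg)
    truth = sim.screen_truth(lib, cfg)
    table = sim.sim_screen_counts(lib, truth, cfg, n_input=14, n_sorted=11)
    stats = ss.guide_test(table.counts, table.roles)
    return cfg, lib, truth, table, stats


@pytest.fixture(scope="session")
def default_gene_scores(default_screen):
    _, lib, _, _, stats = default_screen
    return ss.score_genes(stats, lib.gene_map(), n_perm=10_000, seed=7)


@pytest.fixture(scope="session")
def coupled_multiomics():
    """5000-gene multi-omics simulation at the default coupling of 0.4."""
    cfg = sim.SimConfig(seed=202, n_genes=5000)
    return cfg, sim.sim_multiomics(None, cfg)
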