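import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from histonet import synth

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scenario():
    """Default feature scenario: 10 marks + gene + exon expression, m=2000."""
    return synth.scenario("small", seed=1)


@pytest.fixture(scope="session")
def ggm_scenario():
    """Pure 10-node Gaussian graphical model (ring, true pcor 0.3), m=2000."""
    return synth.scenario("ggm10", seed=1)


@pytest.fixture(scope="session")
def readlevel_dataset(tmp_path_factory):
    """A quantified toy read-level dataset shared across quantify tests."""
    from scipy import stats as _  # noqa: F401  (keep import local to fixtures)
    from histonet import quantify
    from histonet.intervals import read_alt_events, read_bed6_reads, read_gene_models

    genome = synth.GenomeSpec(n_genes=20, exons_per_gene=5, exon_len=400)
    data, truth = synth.scenario("small", m=genome.n_exons, seed=5)
    feats = truth.feature_names[:4]
    signals = synth.scale_to_density(data[feats])
    expr = synth.scale_to_density(data["exon_expr"])
    out = tmp_path_factory.mktemp("readlevel")
    sim = synth.make_read_level(signals, expr, out, genome=genome, seed=5)
    genes = read_gene_models(sim.annotation, "refFlat")
    exons = quantify.classify_exons(genes, read_alt_events(sim.alt_table))
    chip = {f: read_bed6_reads(p) for f, p in sim.chip_reads.items()}
    result = quantify.quantify_dataset(genes, exons, chip, read_bed6_reads(sim.rna_reads))
    return {
        "sim": sim,
        "genes": genes,
        "exons": exons,
        "result": result,
        "signals": signals,
        "expr": expr,
        "features": feats,
    }
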