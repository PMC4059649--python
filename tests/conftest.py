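import pytest

from lincscout.io_formats import STAGES
from lincscout.synthetic_data import (
    DECOY_KINDS,
    GenomeConfig,
    generate_bundle,
)
from lincscout.tu_discovery import run_cascade


@pytest.fixture(scope="session")
def bundle():
    """Default-sized synthetic bundle (2 contigs, 10 genes, 6 lincRNAs)."""
    return generate_bundle(seed=7)


@pytest.fixture(scope="session")
def bundle_features(bundle):
    return bundle.genes + [
        f for stage in STAGES for f in bundle.transcripts[stage]
    ]


@pytest.fixture(scope="session")
def cascade_result(bundle, bundle_features):
    return run_cascade(
        bundle_features, bundle.genome, bundle.hits, bundle.scores,
        bundle.mirna_hits,
    )


@pytest.fixture(scope="session")
def large_bundle():
    """Ten planted lincRNAs and three decoys of every kind."""
    cfg = GenomeConfig(
        n_contigs=2, contig_length=80_000, n_genes=14, n_lincrnas=10,
        decoy_counts={k: 3 for k in DECOY_KINDS},
    )
    return generate_bundle(cfg, seed=11)
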