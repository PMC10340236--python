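import numpy as np
import pytest

from gastromut import (
    FeatureConfig,
    SimulationConfig,
    extract_table,
    simulate_corpus,
)

# Motif long and composition-biased enough to shift the global descriptors:
# the feature stack summarises composition and positional mass, so a short
# composition-neutral insert carries no signal at this scale.
SEPARABILITY_MOTIF = (
    "TTGATTTGCTTTGTTTAGTTTTGTTGTTTCTTGTTTTGATTTGTTTGTTTTGGTTTTGTTTGT"
    "TGTTTGTTTGTTTTGTTTTGTTTGTTTGTTTT"
)


@pytest.fixture(scope="session")
def motif_corpus():
    cfg = SimulationConfig(
        n_genes=110,
        length_range=(300, 512),
        mutation_count_range=(1, 3),
        separability_motif=SEPARABILITY_MOTIF,
        seed=11,
    )
    return simulate_corpus(cfg)


@pytest.fixture(scope="session")
def motif_features(motif_corpus):
    corpus, _ = motif_corpus
    table = extract_table(corpus, FeatureConfig())
    X = table.drop(columns="label").to_numpy(float)
    y = table["label"].to_numpy(int)
    return X, y


@pytest.fixture(scope="session")
def tiny_refs():
    from gastromut import ReferenceGene

    return [
        ReferenceGene("g1", "G1", "ACGTACGTAA"),
        ReferenceGene("g2", "G2", "TTTTCCCCGG"),
    ]
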