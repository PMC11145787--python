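"""Shared fixtures: one synthetic study per session, reused across tests.

The expensive artefacts (trained networks, balanced contact maps) are
session-scoped so the suite trains each model once.
"""

from __future__ import annotations

import numpy as np
import pytest

from hmcnet import (
    FcdnnClassifier,
    FcdnnConfig,
    GhmcnClassifier,
    GhmcnConfig,
    SynthConfig,
    distance_normalize,
    featurize_sample,
    ice_normalize,
    label_genes,
    synth_genome,
    synth_hic,
    synth_loop_label_graph,
    synth_loop_tracks,
    synth_tracks,
)

# number of minibatch updates comparable to the full-data optimisation
# regime; at ~200 training genes and batch 128 this is epochs ~= updates/2
FCDNN_SYNTH_EPOCHS = 3000


@pytest.fixture(scope="session")
def genome():
    return synth_genome(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def tracks(genome):
    return synth_tracks(genome)


@pytest.fixture(scope="session")
def feature_matrix(genome, tracks):
    fm = featurize_sample(genome.genes, tracks.ip, tracks.input)
    labels = label_genes(genome.expression, "synth")
    return fm.with_labels(labels, genome.expression.tpm("synth"))


@pytest.fixture(scope="session")
def fcdnn_results(feature_matrix):
    model = FcdnnClassifier(feature_matrix, FcdnnConfig(seed=7))
    return model.fit(test_chrom="chr1", val_chrom="chr2", epochs=FCDNN_SYNTH_EPOCHS)


@pytest.fixture(scope="session")
def loop_study():
    """Genome with loops for both classes, normalised maps, loop-label graph."""
    g = synth_genome(SynthConfig(seed=7, enhancers_for_all=True))
    maps, pairs = synth_hic(g)
    normed = {c: distance_normalize(ice_normalize(m)[0]) for c, m in maps.items()}
    ip, inp = synth_loop_tracks(g)
    graph, enh_nodes = synth_loop_label_graph(g, ip, inp, normed, k=10, seed=7)
    return {
        "genome": g,
        "maps": maps,
        "pairs": pairs,
        "normed": normed,
        "graph": graph,
        "enhancer_nodes": enh_nodes,
    }


# full-batch epochs for the loop-study fit: the explainer needs a model
# whose predictions are right for the right reason, and the 2-feature
# graph task converges slowly under Adam at lr 1e-3
GHMCN_LOOP_EPOCHS = 1200


@pytest.fixture(scope="session")
def ghmcn_results(loop_study):
    return GhmcnClassifier(
        loop_study["graph"], GhmcnConfig(seed=7, epochs=GHMCN_LOOP_EPOCHS)
    ).fit()
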