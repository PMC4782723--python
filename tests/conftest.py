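from __future__ import annotations

import numpy as np
import pytest

from otunet.amplicon_io import dereplicate
from otunet.alignment import build_similarity_graph
from otunet.clustering import (
    filter_small_otus,
    greedy_centroid_cluster,
    network_components,
    swarm_cluster,
)
from otunet.synthetic_data import generate_community, generate_references


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_community():
    """A small synthetic community (4 refs x 150 bp) with all three clusterings."""
    refs = generate_references(n_ref=4, length=150, min_divergence=0.10, seed=3)
    env, truths = generate_community(
        refs, cloud_size=8, novel_lineages=1, threshold=0.97, seed=4
    )
    env = dereplicate(env)
    combined = sorted(env + refs, key=lambda a: (-a.abundance, a.id))
    graph = build_similarity_graph(combined, 0.97)
    results = {
        "greedy": filter_small_otus(greedy_centroid_cluster(combined, 0.97)),
        "network": filter_small_otus(network_components(graph)),
        "swarm": filter_small_otus(swarm_cluster(combined)),
    }
    truth = {t.amplicon_id: t for t in truths}
    return {
        "refs": refs,
        "env": env,
        "combined": combined,
        "graph": graph,
        "results": results,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_community():
    """The default-scale community: 20 refs x 380 bp, 1% clouds, 5 novel lineages."""
    refs = generate_references(seed=11)
    env, truths = generate_community(refs, seed=12)
    env = dereplicate(env)
    combined = sorted(env + refs, key=lambda a: (-a.abundance, a.id))
    return {
        "refs": refs,
        "env": env,
        "combined": combined,
        "truth": {t.amplicon_id: t for t in truths},
    }
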