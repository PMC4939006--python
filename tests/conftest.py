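"""Shared fixtures: tiny hand-built networks and generated datasets."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from chasnet import ContactNetwork, GenomicFragment
from chasnet.network import OTHER_END, PROMOTER
from chasnet.synthetic import FeatureSpec, GeneratorConfig, generate


def make_net(edges, promoters=(), nodes=(), chrom="chr1", frag_len=1000):
    """Build a ContactNetwork from an abstract edge list.

    Node names are arbitrary strings/ints; fragments get synthetic
    non-overlapping coordinates on one chromosome in sorted-name order.
    ``edges`` items are (u, v) or (u, v, score).
    """
    names = sorted(
        {str(n) for e in edges for n in e[:2]} | {str(n) for n in nodes}
    )
    net = ContactNetwork(provenance="test fixture")
    for i, name in enumerate(names):
        start = i * 2 * frag_len
        cls = PROMOTER if name in {str(p) for p in promoters} else OTHER_END
        net.add_fragment(GenomicFragment(chrom, start, start + frag_len, name, cls))
    for e in edges:
        u, v = str(e[0]), str(e[1])
        score = float(e[2]) if len(e) > 2 else float("nan")
        net.add_edge(u, v, score)
    return net


def clique_edges(nodes):
    return list(itertools.combinations(nodes, 2))


@pytest.fixture(scope="session")
def planted_dataset(tmp_path_factory):
    """Capture-shaped fixture with features spanning the planted-rho range."""
    cfg = GeneratorConfig(
        seed=11,
        features=tuple(
            FeatureSpec(f"rho_{str(r).replace('-', 'm')}", r, 0.3)
            for r in (-0.5, 0.0, 0.3, 0.6, 0.9)
        ),
    )
    return generate(cfg, tmp_path_factory.mktemp("planted"))


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Small default-panel fixture for cheap end-to-end tests."""
    cfg = GeneratorConfig(seed=2, n_fragments=600, n_chromosomes=2)
    return generate(cfg, tmp_path_factory.mktemp("small"))
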