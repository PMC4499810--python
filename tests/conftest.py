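"""Shared fixtures: small random bipartite networks and scored instances."""

from __future__ import annotations

import numpy as np
import pytest

from iinalign import IIN, Interface, Kind
from iinalign.features import BaseScores, PairScores


def make_random_iin(
    rng: np.random.Generator,
    n_dom: int,
    n_lig: int,
    edge_prob: float = 0.3,
    prefix: str = "P",
) -> IIN:
    """Random bipartite IIN with canonical interface ids."""
    doms = [Interface(f"{prefix}D{i}", 1, 30, Kind.DOMAIN) for i in range(n_dom)]
    ligs = [Interface(f"{prefix}L{j}", 1, 15, Kind.LIGAND) for j in range(n_lig)]
    edges = [
        (d.id, l.id)
        for d in doms
        for l in ligs
        if rng.uniform() < edge_prob
    ]
    return IIN(doms + ligs, edges)


def make_random_instance(
    rng: np.random.Generator,
    n_dom: int = 3,
    n_lig: int = 6,
    edge_prob: float = 0.3,
) -> tuple[IIN, IIN, BaseScores]:
    """Two random networks of the same shape plus random base scores."""
    net1 = make_random_iin(rng, n_dom, n_lig, edge_prob, prefix="A")
    net2 = make_random_iin(rng, n_dom, n_lig, edge_prob, prefix="B")
    base = BaseScores(
        domain=PairScores(
            net1.domain_ids, net2.domain_ids, rng.uniform(size=(n_dom, n_dom))
        ),
        ligand=PairScores(
            net1.ligand_ids, net2.ligand_ids, rng.uniform(size=(n_lig, n_lig))
        ),
    )
    return net1, net2, base


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
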