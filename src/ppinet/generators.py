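"""Programmatic graph generators with known statistical structure.

Everything downstream (degree statistics, null models, distances,
clustering, sub-sampling) is exercised on graphs built here, so no
downloaded interactome is ever needed: Erdős–Rényi graphs, uniform
configuration-model samples for a given (graphical) degree sequence,
graphs with a planted assortative or disassortative degree-degree
correlation, and exact deterministic toys (star, cycle, path, perfect
matching, regular).

The planted families start from an Erdős–Rényi realisation and apply
degree-preserving swaps that steer ``S = sum_edges k_i k_j`` — an affine
proxy of the assortativity, since all degrees are conserved — towards the
target, leaving the degree sequence untouched while bending ``W(k, k')``
away from 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from . import _kernels
from .degree_stats import degree_distribution, assortativity
from .network import InteractionNetwork
from .nullmodel import RandomisationConfig, randomise

__all__ = [
    "GeneratorSpec",
    "erdos_renyi",
    "star",
    "cycle",
    "path",
    "perfect_matching",
    "regular",
    "configuration_model",
    "planted_correlation",
    "generate",
]

logger = logging.getLogger(__name__)


def _names(n: int) -> list[str]:
    return [f"n{i}" for i in range(n)]


def erdos_renyi(n: int, mean_degree: float, seed: int) -> InteractionNetwork:
    """G(N, p) with independent edges at p = <k>/(N-1)."""
    if not 0 <= mean_degree <= n - 1:
        raise ValueError("mean degree must lie in [0, N-1]")
    g = nx.fast_gnp_random_graph(n, mean_degree / (n - 1), seed=seed)
    g = nx.relabel_nodes(g, dict(enumerate(_names(n))))
    return InteractionNetwork.from_networkx(g)


def star(leaves: int) -> InteractionNetwork:
    """K_{1,leaves}: one hub connected to each leaf."""
    nodes = tuple(["hub"] + [f"leaf{i}" for i in range(leaves)])
    return InteractionNetwork(nodes, frozenset((0, i) for i in range(1, leaves + 1)))


def cycle(n: int) -> InteractionNetwork:
    if n < 3:
        raise ValueError("a cycle needs at least 3 nodes")
    nodes = tuple(_names(n))
    edges = {(i, i + 1) for i in range(n - 1)} | {(0, n - 1)}
    return InteractionNetwork(nodes, frozenset(edges))


def path(n: int) -> InteractionNetwork:
    nodes = tuple(_names(n))
    return InteractionNetwork(nodes, frozenset((i, i + 1) for i in range(n - 1)))


def perfect_matching(pairs: int) -> InteractionNetwork:
    """2*pairs nodes, all of degree 1."""
    nodes = tuple(_names(2 * pairs))
    return InteractionNetwork(nodes, frozenset((2 * i, 2 * i + 1) for i in range(pairs)))


def regular(n: int, degree: int, seed: int) -> InteractionNetwork:
    g = nx.random_regular_graph(degree, n, seed=seed)
    g = nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes()})
    return InteractionNetwork.from_networkx(g)


def configuration_model(
    degree_sequence: Sequence[int],
    seed: int,
    accepted_per_link: float = 100.0,
) -> InteractionNetwork:
    """Uniform simple graph with the given degree sequence.

    The sequence is checked with the Erdős–Gallai condition, realised
    deterministically (Havel–Hakimi) and then randomised by the unbiased
    edge-swap sampler, so that across seeds the draw is uniform over all
    simple graphs with these degrees.
    """
    degs = [int(d) for d in degree_sequence]
    if not nx.is_graphical(degs):
        raise ValueError("degree sequence fails the Erdős–Gallai condition")
    g = nx.havel_hakimi_graph(degs)
    g = nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes()})
    net = InteractionNetwork.from_networkx(g)
    if net.E < 2:
        return net
    result = randomise(net, RandomisationConfig(seed=seed, target_accepted_per_link=accepted_per_link))
    return result.graph


def planted_correlation(
    n: int,
    mean_degree: float,
    target_assortativity: float,
    seed: int,
    tol: float = 0.02,
    max_proposals_factor: int = 20_000,
) -> InteractionNetwork:
    """Graph with a planted assortativity (and hence a non-trivial W).

    Starts from an Erdős–Rényi graph and greedily applies degree-preserving
    swaps that pull the assortativity towards ``target_assortativity``.
    If the target is unreachable the achieved value is logged and the best
    graph found is returned.
    """
    net = erdos_renyi(n, mean_degree, seed)
    deg = net.degree_sequence().astype(np.float64)
    edges = net.edge_array()
    e = net.E
    if e < 2:
        raise ValueError("planted construction needs at least 2 edges")
    # Edge-end moments are swap invariants: r is affine in S = sum k_i k_j.
    m1 = float(np.sum(deg**2)) / (2 * e)
    m2 = float(np.sum(deg**3)) / (2 * e)
    var = m2 - m1 * m1
    if var <= 0:
        raise ValueError("degenerate degree sequence: assortativity undefined")
    s_target = e * (target_assortativity * var + m1 * m1)
    s_tol = tol * var * e

    adj = np.zeros((n, n), dtype=np.bool_)
    adj[edges[:, 0], edges[:, 1]] = True
    adj[edges[:, 1], edges[:, 0]] = True
    seed32 = int(np.random.SeedSequence(seed).generate_state(1, dtype=np.uint32)[0] >> 1)
    s_final, proposed = _kernels.anneal_degree_product(
        adj, edges, deg, s_target, s_tol, max_proposals_factor * e, seed32
    )
    out = net.with_edges(map(tuple, edges))
    achieved = assortativity(degree_distribution(out))
    if abs(s_final - s_target) > s_tol:
        logger.warning(
            "planted correlation target %.3f unreachable; achieved %.3f",
            target_assortativity, achieved,
        )
    return out


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one synthetic network."""

    family: str
    N: int = 0
    mean_degree: float = 0.0
    degree_sequence: tuple[int, ...] | None = None
    correlation_strength: float = 0.0
    seed: int = 0
    toy: str = ""          # star | cycle | path | matching | regular
    toy_param: int = 0     # leaves / pairs / regular degree

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorSpec":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown generator spec fields: {sorted(extra)}")
        if "degree_sequence" in data and data["degree_sequence"] is not None:
            data = {**data, "degree_sequence": tuple(data["degree_sequence"])}
        return cls(**data)


def generate(spec: GeneratorSpec) -> InteractionNetwork:
    """Build the network a :class:`GeneratorSpec` describes."""
    fam = spec.family
    if fam == "er":
        return erdos_renyi(spec.N, spec.mean_degree, spec.seed)
    if fam == "configuration":
        if spec.degree_sequence is None:
            raise ValueError("configuration family needs degree_sequence")
        return configuration_model(spec.degree_sequence, spec.seed)
    if fam == "planted_assortative":
        return planted_correlation(spec.N, spec.mean_degree, abs(spec.correlation_strength), spec.seed)
    if fam == "planted_disassortative":
        return planted_correlation(spec.N, spec.mean_degree, -abs(spec.correlation_strength), spec.seed)
    if fam == "toy":
        if spec.toy == "star":
            return star(spec.toy_param)
        if spec.toy == "cycle":
            return cycle(spec.toy_param)
        if spec.toy == "path":
            return path(spec.toy_param)
        if spec.toy == "matching":
            return perfect_matching(spec.toy_param)
        if spec.toy == "regular":
            return regular(spec.N, spec.toy_param, spec.seed)
        raise ValueError(f"unknown toy family {spec.toy!r}")
    raise ValueError(f"unknown generator family {fam!r}")
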