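"""Unbiased degree-preserving null models and the normalised Hamming distance.

A null model of an observed network is a graph drawn uniformly at random
from the set of *all* simple graphs with the same degree sequence.  Naive
edge-swapping with retry-until-valid does not sample that set uniformly;
the chains here do, by one of two acceptance rules:

``hold_counting`` (default, JIT-compiled)
    Candidate swaps are drawn uniformly from a state-independent set
    (ordered pairs of distinct edges plus a rewiring orientation) and
    candidates that would create a self-loop or duplicate edge are counted
    as executed "stay" moves.  The proposal kernel is symmetric, so the
    stationary distribution is uniform.

``mobility_ratio`` (pure Python, for small graphs)
    Only executable swaps are proposed (uniformly among the ``n(c)`` valid
    moves of the current state ``c``) and a move to ``c'`` is accepted with
    the Metropolis–Hastings probability ``min(1, n(c)/n(c'))``, which again
    yields the uniform distribution.

Equilibration follows the standard criterion of at least 100 accepted
edge-changing moves per link, with an observable trace (normalised Hamming
distance to the original, assortativity, exact wiring complexity) logged at
a configurable interval so equilibration can be assessed and runs extended.

The normalised Hamming distance between two graphs on the same node set is
the number of adjacency disagreements scaled by the total link count,

    Delta(A, B) = |E_A symdiff E_B| / (|E_A| + |E_B|),

which is 0 exactly when the two networks are identical and has expectation
approaching 1 when they are statistically independent apart from their
(preserved) degrees.  At finite N that expectation sits slightly below 1,
by the expected edge overlap of independent degree-matched graphs; see
:func:`expected_independent_hamming`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .degree_stats import characterize, degree_distribution, assortativity
from .infotheory import complexity, ComplexityReport
from .network import InteractionNetwork

__all__ = [
    "RandomisationConfig",
    "RandomisationResult",
    "NullModelReport",
    "randomise",
    "hamming_distance",
    "expected_independent_hamming",
    "sample_states",
    "null_model_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RandomisationConfig:
    """Settings for one randomisation run.

    ``target_accepted_per_link`` is the equilibration criterion: the chain
    runs until the number of accepted (edge-changing) moves reaches this
    multiple of the link count.  ``monitor_interval`` is the trace
    resolution, in accepted moves per link between logged observable rows
    (0 disables the trace).
    """

    seed: int
    target_accepted_per_link: float = 100.0
    acceptance_mode: str = "hold_counting"
    monitor_interval: float = 0.0
    max_proposals_factor: int = 1000

    def __post_init__(self) -> None:
        if self.target_accepted_per_link <= 0:
            raise ValueError("target_accepted_per_link must be positive")
        if self.acceptance_mode not in ("hold_counting", "mobility_ratio"):
            raise ValueError("acceptance_mode must be 'hold_counting' or 'mobility_ratio'")


@dataclass
class RandomisationResult:
    graph: InteractionNetwork
    accepted_moves: int
    proposed_moves: int
    hamming_to_original: float
    trace: list[dict] = field(default_factory=list)


def hamming_distance(net_a: InteractionNetwork, net_b: InteractionNetwork) -> float:
    """Normalised Hamming distance between two graphs on the same node set."""
    if not net_a.same_node_set(net_b):
        raise ValueError("Hamming distance requires identical node sets")
    ea = net_a.edge_name_set()
    eb = net_b.edge_name_set()
    total = len(ea) + len(eb)
    if total == 0:
        return 0.0
    return len(ea.symmetric_difference(eb)) / total


def expected_independent_hamming(net: InteractionNetwork) -> float:
    """Expected Delta(original, null) for a *statistically independent* null.

    For an independent degree-matched graph the chance that edge (i, j) is
    re-created is approximately k_i k_j / 2E, so the expected normalised
    Hamming distance is 1 - sum_edges k_i k_j / (2E)^2 / ... , i.e.
    1 - E[overlap]/E.  This is the finite-size ceiling an equilibrated
    randomisation should reach.
    """
    deg = net.degree_sequence().astype(float)
    e = net.E
    if e == 0:
        return 0.0
    edges = net.edge_array()
    overlap = float(np.sum(deg[edges[:, 0]] * deg[edges[:, 1]])) / (2.0 * e)
    return 1.0 - overlap / e


def _observables(net: InteractionNetwork, original: InteractionNetwork) -> dict:
    stats = degree_distribution(net)
    try:
        wiring = complexity(characterize(net, sigma=0.0)).wiring_complexity_per_node
    except ValueError:
        wiring = float("nan")
    return {
        "hamming_to_original": hamming_distance(original, net),
        "assortativity": assortativity(stats),
        "wiring_complexity_per_node": wiring,
    }


def _run_hold_counting(
    net: InteractionNetwork, cfg: RandomisationConfig, original: InteractionNetwork
) -> RandomisationResult:
    n, e = net.N, net.E
    adj = np.zeros((n, n), dtype=np.bool_)
    edges = net.edge_array()
    adj[edges[:, 0], edges[:, 1]] = True
    adj[edges[:, 1], edges[:, 0]] = True

    target_total = int(np.ceil(cfg.target_accepted_per_link * e))
    chunk = target_total
    if cfg.monitor_interval > 0:
        chunk = max(1, int(np.ceil(cfg.monitor_interval * e)))
    seeds = np.random.SeedSequence(cfg.seed).generate_state(
        int(np.ceil(target_total / chunk)) + 1, dtype=np.uint32
    ) >> np.uint32(1)  # keep seeds below 2^31

    accepted = 0
    proposed = 0
    trace: list[dict] = []
    budget = cfg.max_proposals_factor * target_total + 10_000
    i = 0
    while accepted < target_total and proposed < budget:
        want = min(chunk, target_total - accepted)
        acc, prop = _kernels.edge_swap_chain(
            adj, edges, want, budget - proposed, int(seeds[i])
        )
        i += 1
        accepted += int(acc)
        proposed += int(prop)
        if cfg.monitor_interval > 0:
            current = net.with_edges(map(tuple, edges))
            row = {"accepted_moves": accepted, "proposed_moves": proposed}
            row.update(_observables(current, original))
            trace.append(row)
    if accepted < target_total:
        warnings.warn(
            "edge-swap chain exhausted its proposal budget before reaching the "
            "equilibration target; the degree sequence may admit (almost) a "
            "unique graph",
            stacklevel=3,
        )
    result_net = net.with_edges(map(tuple, edges))
    return RandomisationResult(
        graph=result_net,
        accepted_moves=accepted,
        proposed_moves=proposed,
        hamming_to_original=hamming_distance(original, result_net),
        trace=trace,
    )


def _valid_moves(edge_set: frozenset, adj: set) -> list[tuple]:
    """All executable swaps from a state: ((old1, old2), (new1, new2))."""
    edges = sorted(edge_set)
    moves = []
    for idx1 in range(len(edges)):
        a, b = edges[idx1]
        for idx2 in range(idx1 + 1, len(edges)):
            c, d = edges[idx2]
            for (x1, y1, x2, y2) in ((a, c, b, d), (a, d, c, b)):
                if x1 == y1 or x2 == y2:
                    continue
                n1 = (min(x1, y1), max(x1, y1))
                n2 = (min(x2, y2), max(x2, y2))
                if n1 in adj or n2 in adj or n1 == n2:
                    continue
                moves.append((((a, b), (c, d)), (n1, n2)))
    return moves


def _run_mobility_ratio(
    net: InteractionNetwork, cfg: RandomisationConfig, original: InteractionNetwork
) -> RandomisationResult:
    rng = np.random.default_rng(cfg.seed)
    e = net.E
    target_total = int(np.ceil(cfg.target_accepted_per_link * e))
    edge_set = set(net.edges)
    accepted = 0
    proposed = 0
    trace: list[dict] = []
    monitor_every = int(np.ceil(cfg.monitor_interval * e)) if cfg.monitor_interval > 0 else 0
    next_log = monitor_every
    budget = cfg.max_proposals_factor * target_total + 10_000
    moves = _valid_moves(frozenset(edge_set), edge_set)
    while accepted < target_total and proposed < budget:
        n_here = len(moves)
        if n_here == 0:
            warnings.warn("no executable edge swap exists; graph returned unchanged", stacklevel=3)
            break
        proposed += 1
        (old1, old2), (new1, new2) = moves[rng.integers(n_here)]
        edge_set.discard(old1)
        edge_set.discard(old2)
        edge_set.add(new1)
        edge_set.add(new2)
        moves_after = _valid_moves(frozenset(edge_set), edge_set)
        if rng.random() < min(1.0, n_here / len(moves_after)):
            accepted += 1
            moves = moves_after
        else:
            edge_set.discard(new1)
            edge_set.discard(new2)
            edge_set.add(old1)
            edge_set.add(old2)
        if monitor_every and accepted >= next_log:
            current = net.with_edges(edge_set)
            row = {"accepted_moves": accepted, "proposed_moves": proposed}
            row.update(_observables(current, original))
            trace.append(row)
            next_log += monitor_every
    result_net = net.with_edges(edge_set)
    return RandomisationResult(
        graph=result_net,
        accepted_moves=accepted,
        proposed_moves=proposed,
        hamming_to_original=hamming_distance(original, result_net),
        trace=trace,
    )


def randomise(net: InteractionNetwork, cfg: RandomisationConfig) -> RandomisationResult:
    """Draw an (approximately) uniform degree-preserving randomisation.

    The chain preserves every node degree exactly, never creates self-loops
    or duplicate edges, and runs until the accepted edge-changing moves
    reach ``target_accepted_per_link`` times the link count.
    """
    if net.E < 2:
        raise ValueError("randomisation needs at least 2 edges")
    if cfg.acceptance_mode == "mobility_ratio":
        return _run_mobility_ratio(net, cfg, net)
    return _run_hold_counting(net, cfg, net)


def sample_states(
    net: InteractionNetwork,
    seed: int,
    n_samples: int,
    proposals_per_sample: int,
    mode: str = "hold_counting",
    burn_in: int = 0,
) -> list[frozenset]:
    """Record the chain's state at fixed proposal intervals.

    Returns ``n_samples`` canonical edge sets (frozensets of index pairs),
    one every ``proposals_per_sample`` proposals after ``burn_in``
    proposals.  Sampling on the proposal clock (holds included) makes the
    visit frequencies estimate the chain's stationary distribution, which
    for a correct sampler is uniform over all simple graphs with the
    original degree sequence — the basis of the enumeration uniformity
    checks.
    """
    if net.E < 2:
        raise ValueError("sampling needs at least 2 edges")
    states: list[frozenset] = []
    if mode == "hold_counting":
        n = net.N
        adj = np.zeros((n, n), dtype=np.bool_)
        edges = net.edge_array()
        adj[edges[:, 0], edges[:, 1]] = True
        adj[edges[:, 1], edges[:, 0]] = True
        total_calls = n_samples + (1 if burn_in else 0)
        seeds = np.random.SeedSequence(seed).generate_state(
            total_calls, dtype=np.uint32
        ) >> np.uint32(1)
        i = 0
        if burn_in:
            _kernels.edge_swap_chain(adj, edges, 2**62, burn_in, int(seeds[i]))
            i += 1
        for _ in range(n_samples):
            _kernels.edge_swap_chain(adj, edges, 2**62, proposals_per_sample, int(seeds[i]))
            i += 1
            states.append(frozenset(map(tuple, edges)))
        return states
    if mode != "mobility_ratio":
        raise ValueError("mode must be 'hold_counting' or 'mobility_ratio'")
    rng = np.random.default_rng(seed)
    edge_set = set(net.edges)
    moves = _valid_moves(frozenset(edge_set), edge_set)
    done = 0
    target = burn_in + n_samples * proposals_per_sample
    while done < target:
        if not moves:
            raise ValueError("chain cannot move from the initial state")
        (old1, old2), (new1, new2) = moves[rng.integers(len(moves))]
        n_here = len(moves)
        edge_set.discard(old1)
        edge_set.discard(old2)
        edge_set.add(new1)
        edge_set.add(new2)
        moves_after = _valid_moves(frozenset(edge_set), edge_set)
        if rng.random() < min(1.0, n_here / len(moves_after)):
            moves = moves_after
        else:
            edge_set.discard(new1)
            edge_set.discard(new2)
            edge_set.add(old1)
            edge_set.add(old2)
        done += 1
        if done > burn_in and (done - burn_in) % proposals_per_sample == 0:
            states.append(frozenset(edge_set))
    return states


@dataclass(frozen=True)
class NullModelReport:
    """Original-vs-null comparison bundle."""

    result: RandomisationResult
    original_assortativity: float | None
    null_assortativity: float | None
    original_complexity: ComplexityReport
    null_complexity: ComplexityReport


def null_model_report(net: InteractionNetwork, cfg: RandomisationConfig) -> NullModelReport:
    """Randomise and report assortativity + complexity for original and null."""
    result = randomise(net, cfg)
    return NullModelReport(
        result=result,
        original_assortativity=assortativity(degree_distribution(net)),
        null_assortativity=assortativity(degree_distribution(result.graph)),
        original_complexity=complexity(characterize(net, sigma=0.0)),
        null_complexity=complexity(characterize(result.graph, sigma=0.0)),
    )
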