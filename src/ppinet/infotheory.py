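"""Network complexity and the information-theoretic network distance.

Both quantities come from viewing a network as a sample of a maximum-entropy
random-graph ensemble tailored to its degree distribution ``p(k)`` and
normalised degree-degree correlation kernel ``W(k, k')``.

**Complexity** (per node, in nats) is the KL divergence of that tailored
ensemble from the Erdős–Rényi ensemble with the same mean degree.  It
splits into two non-negative parts:

* degree complexity ``Sum_k p(k) ln[p(k)/pi(k)]`` — the information in the
  degree statistics relative to the Poissonian reference ``pi`` with the
  same mean degree;
* wiring complexity ``(<k>/2) Sum_kk' Pi(k,k') ln W(k,k')`` — the
  information in the degree correlations beyond the degrees; identically
  zero for degree-matched uncorrelated graphs (``W == 1``).

Dividing by ``<k>/2`` (links per node) converts either term to a per-link
complexity, which is independent of the average degree.

**Distance** between two networks A and B is the symmetrised KL divergence,
per node, of their tailored max-entropy graph distributions, evaluated in
the sparse regime:

    d(A,B) = 1/2 Sum_k [p_A ln(p_A/p_B) + p_B ln(p_B/p_A)]
             - 1/4 (kbar_A - kbar_B) ln(kbar_A / kbar_B)
             + kbar_A/4 Sum_kk' Pi_A ln(W_A/W_B)
             + kbar_B/4 Sum_kk' Pi_B ln(W_B/W_A)

with ``kbar_X = Sum_k k p_X(k)``.  The last two lines carry all the
DDC information; dropping them leaves the simplified degree-only distance.
For two Erdős–Rényi ensembles the expression collapses to the exactly
computable ``(kbar_A - kbar_B) ln(kbar_A/kbar_B) / 4``, and for equal degree
statistics it is ``kbar/4`` times the symmetrised KL divergence between the
two edge-end joint laws.  Distances require smoothed profiles
(``sigma > 0``): smoothening keeps every probability strictly positive,
without which the KL terms are ill-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .degree_stats import NetworkProfile, characterize
from .network import InteractionNetwork

__all__ = [
    "ComplexityReport",
    "DistanceResult",
    "DistanceMatrix",
    "poisson_reference",
    "poisson_kmax",
    "complexity",
    "network_distance",
    "profile_distance",
    "characterize_collection",
    "distance_matrix",
]


def poisson_kmax(mean_degree: float, tail_mass: float = 1e-9) -> int:
    """Smallest grid cap whose Poisson tail mass is below ``tail_mass``."""
    if mean_degree <= 0:
        raise ValueError("mean degree must be positive")
    return int(sps.poisson.isf(tail_mass, mean_degree)) + 1


def poisson_reference(mean_degree: float, kmax: int) -> tuple[np.ndarray, float]:
    """Poisson probabilities for k = 0..kmax and the mass beyond kmax.

    The tail mass bounds the truncation error of any KL computed against
    this reference on the grid.
    """
    if mean_degree <= 0:
        raise ValueError("mean degree must be positive")
    if kmax < 1:
        raise ValueError("kmax must be a positive integer")
    pmf = sps.poisson.pmf(np.arange(kmax + 1), mean_degree)
    tail = float(sps.poisson.sf(kmax, mean_degree))
    return pmf, tail


@dataclass(frozen=True)
class ComplexityReport:
    """Degree and wiring complexity of one network, per node and per link."""

    degree_complexity_per_node: float
    wiring_complexity_per_node: float
    degree_complexity_per_link: float
    wiring_complexity_per_link: float
    mean_degree: float
    sigma: float
    poisson_tail_mass: float

    @property
    def total_per_node(self) -> float:
        return self.degree_complexity_per_node + self.wiring_complexity_per_node


def _xlogyx(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """x * ln(x / y) with the 0 ln 0 = 0 convention."""
    out = np.zeros_like(x, dtype=float)
    mask = x > 0
    out[mask] = x[mask] * (np.log(x[mask]) - np.log(y[mask]))
    return out


def complexity(profile: NetworkProfile) -> ComplexityReport:
    """Degree and wiring complexity (nats) from a network profile.

    Works on exact profiles (``sigma == 0``, with the 0 ln 0 convention)
    and on smoothed ones alike.  Both terms are KL divergences and hence
    non-negative.
    """
    if profile.E == 0:
        raise ValueError("complexity is undefined for an edgeless network")
    kbar = profile.mean_degree
    pi, tail = poisson_reference(kbar, profile.kmax)
    degree_term = float(_xlogyx(profile.p, pi).sum())

    u = profile.edge_end_marginal()
    ref = np.outer(u, u)
    wiring_term = 0.5 * kbar * float(_xlogyx(profile.joint, ref).sum())

    links_per_node = kbar / 2.0
    return ComplexityReport(
        degree_complexity_per_node=degree_term,
        wiring_complexity_per_node=wiring_term,
        degree_complexity_per_link=degree_term / links_per_node,
        wiring_complexity_per_link=wiring_term / links_per_node,
        mean_degree=kbar,
        sigma=profile.sigma,
        poisson_tail_mass=tail,
    )


@dataclass(frozen=True)
class DistanceResult:
    """Full and degree-only information-theoretic distance (nats)."""

    full_distance: float
    degree_only_distance: float
    ddc_contribution: float
    sigma: float


def profile_distance(a: NetworkProfile, b: NetworkProfile) -> DistanceResult:
    """Distance between two characterised networks.

    Both profiles must be smoothed with the same ``sigma > 0`` on the same
    degree grid (use :func:`characterize_collection`, which guarantees a
    shared grid covering the union of the degree supports).
    """
    if a.sigma <= 0 or b.sigma <= 0 or a.sigma != b.sigma:
        raise ValueError("distances need both profiles smoothed with one common sigma > 0")
    if a.kmax != b.kmax:
        raise ValueError("profiles live on different degree grids")
    if np.any(a.p <= 0) or np.any(b.p <= 0) or np.any(a.joint <= 0) or np.any(b.joint <= 0):
        raise ValueError("smoothening contract violated: zero probability on the grid")

    dp = a.p - b.p
    dlp = np.log(a.p) - np.log(b.p)
    degree_term = 0.5 * float(dp @ dlp)

    ka, kb = a.mean_degree, b.mean_degree
    mean_term = -0.25 * (ka - kb) * float(np.log(ka / kb))

    dlW = np.log(a.W) - np.log(b.W)
    ddc_term = 0.25 * ka * float((a.joint * dlW).sum()) \
        - 0.25 * kb * float((b.joint * dlW).sum())

    degree_only = degree_term + mean_term
    return DistanceResult(
        full_distance=degree_only + ddc_term,
        degree_only_distance=degree_only,
        ddc_contribution=ddc_term,
        sigma=a.sigma,
    )


def network_distance(
    net_a: InteractionNetwork,
    net_b: InteractionNetwork,
    sigma: float = 1.0,
    kmax: int | None = None,
) -> DistanceResult:
    """Characterise two networks on a shared grid and return their distance."""
    if sigma <= 0:
        raise ValueError("distances require sigma > 0")
    if kmax is None:
        kmax = max(
            int(max(net_a.degree_sequence().max(), 1)),
            int(max(net_b.degree_sequence().max(), 1)),
        )
    return profile_distance(
        characterize(net_a, sigma=sigma, kmax=kmax),
        characterize(net_b, sigma=sigma, kmax=kmax),
    )


def characterize_collection(
    networks: dict[str, InteractionNetwork],
    sigma: float = 1.0,
    kmax: int | None = None,
) -> dict[str, NetworkProfile]:
    """Profiles of several networks on one shared degree grid."""
    if kmax is None:
        kmax = 1
        for net in networks.values():
            deg = net.degree_sequence()
            if deg.size:
                kmax = max(kmax, int(deg.max()))
    return {name: characterize(net, sigma=sigma, kmax=kmax) for name, net in networks.items()}


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix over labelled networks."""

    labels: tuple[str, ...]
    values: np.ndarray
    mode: str      # "full" | "degree_only"
    sigma: float

    def to_tsv(self, path) -> None:
        """Labelled lower-triangular TSV (the supplementary-table shape)."""
        with open(path, "wt", encoding="utf-8") as handle:
            handle.write("network\t" + "\t".join(self.labels) + "\n")
            for i, name in enumerate(self.labels):
                row = "\t".join(f"{self.values[i, j]:.6g}" for j in range(i + 1))
                handle.write(f"{name}\t{row}\n")


def distance_matrix(
    networks: dict[str, InteractionNetwork],
    mode: str = "full",
    sigma: float = 1.0,
    kmax: int | None = None,
) -> DistanceMatrix:
    """Pairwise full or degree-only distances between >= 2 networks."""
    if mode not in ("full", "degree_only"):
        raise ValueError("mode must be 'full' or 'degree_only'")
    if len(networks) < 2:
        raise ValueError("need at least two networks")
    profiles = characterize_collection(networks, sigma=sigma, kmax=kmax)
    labels = tuple(networks)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = profile_distance(profiles[labels[i]], profiles[labels[j]])
            d = res.full_distance if mode == "full" else res.degree_only_distance
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values, mode=mode, sigma=sigma)
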