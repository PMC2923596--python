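"""Macroscopic characterisation of a network.

The observables here are the ones the information-theoretic machinery is
built on:

* the degree distribution ``p(k)``, the fraction of nodes with ``k``
  interaction partners, and the mean degree ``<k> = 2E/N``;
* the edge-end joint law ``Pi(k, k')``, the probability that a uniformly
  drawn interaction (both orientations counted) joins nodes of degrees
  ``k`` and ``k'``;
* the normalised degree-degree correlation kernel ``W(k, k')``: the
  likelihood that nodes of degrees ``k`` and ``k'`` are connected,
  relative to a large random graph with the same degree distribution but
  uncorrelated degrees,

      W(k, k') = Pi(k, k') <k>^2 / (k p(k) k' p(k')),

  so that ``W == 1`` everywhere signals no correlation beyond the degrees;
* the assortativity, the Pearson correlation of the degree pair under
  ``Pi``, computable either directly from ``Pi`` or from ``(p, W)``;
* a weak Gaussian smoothening of ``p`` and of the joint law, which keeps
  every probability strictly positive on a truncated degree range (a
  prerequisite of the Kullback-Leibler distance downstream).

Degree-zero nodes contribute to ``p`` and ``<k>`` but never to ``Pi`` or
``W``; ``W`` is defined only for ``k, k' >= 1``.  Degree pairs outside the
support of ``p`` carry no data and are stored as NaN ("undefined"); pairs
inside the support with no observed edge are true zeros (suppression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import InteractionNetwork

__all__ = [
    "DegreeStatistics",
    "NormalizedDDC",
    "NetworkProfile",
    "degree_distribution",
    "normalized_ddc",
    "assortativity",
    "assortativity_from_ddc",
    "gaussian_kernel",
    "smooth_distribution",
    "characterize",
]

_VAR_TOL = 1e-12


@dataclass(frozen=True)
class DegreeStatistics:
    """Exact (counted) degree statistics of one network."""

    p: dict[int, float]           # degree -> probability
    mean_degree: float            # <k> = 2E/N
    joint: dict[tuple[int, int], float]  # (k, k') -> Pi(k, k'), symmetric
    N: int
    E: int

    def max_degree(self) -> int:
        return max(self.p) if self.p else 0


@dataclass(frozen=True)
class NormalizedDDC:
    """The kernel W(k, k') on the support of p; NaN entries mean "no data"."""

    W: dict[tuple[int, int], float]
    sigma: float
    support_max: int

    def value(self, k: int, kp: int) -> float:
        return self.W.get((k, kp), math.nan)


def degree_distribution(net: InteractionNetwork) -> DegreeStatistics:
    """Exact p(k), <k> and Pi(k, k') by direct counting."""
    deg = net.degree_sequence()
    n = net.N
    counts: dict[int, int] = {}
    for k in deg:
        counts[int(k)] = counts.get(int(k), 0) + 1
    p = {k: c / n for k, c in counts.items()}
    joint: dict[tuple[int, int], float] = {}
    e = net.E
    if e > 0:
        jcounts: dict[tuple[int, int], int] = {}
        for i, j in net.edges:
            ki, kj = int(deg[i]), int(deg[j])
            jcounts[(ki, kj)] = jcounts.get((ki, kj), 0) + 1
            jcounts[(kj, ki)] = jcounts.get((kj, ki), 0) + 1
        joint = {key: c / (2.0 * e) for key, c in jcounts.items()}
    return DegreeStatistics(p=p, mean_degree=2.0 * e / n, joint=joint, N=n, E=e)


def normalized_ddc(stats: DegreeStatistics) -> NormalizedDDC:
    """W(k, k') = Pi(k, k') <k>^2 / (k p(k) k' p(k')) on the support of p.

    Raises if the network has no edges (the reference probability is then
    identically zero and W is undefined everywhere).
    """
    if stats.E == 0:
        raise ValueError("W is undefined for an edgeless network")
    kbar = stats.mean_degree
    W: dict[tuple[int, int], float] = {}
    support = [k for k in stats.p if k >= 1]
    for k in support:
        for kp in support:
            ref = k * stats.p[k] * kp * stats.p[kp] / (kbar * kbar)
            W[(k, kp)] = stats.joint.get((k, kp), 0.0) / ref
    return NormalizedDDC(W=W, sigma=0.0, support_max=max(support))


def _edge_end_moments(stats: DegreeStatistics) -> tuple[float, float, float]:
    """(<k>_e, <k^2>_e, <k k'>_e) under the edge-end measure Pi."""
    m1 = m2 = cross = 0.0
    for (k, kp), pi in stats.joint.items():
        m1 += k * pi
        m2 += k * k * pi
        cross += k * kp * pi
    return m1, m2, cross


def assortativity(stats: DegreeStatistics) -> float | None:
    """Pearson correlation of the degree pair at the two ends of an edge.

    Returns ``None`` for the degenerate regular-graph case (zero variance
    of the edge-end degree marginal), where the correlation is undefined —
    deliberately not reported as 0.
    """
    if stats.E == 0:
        raise ValueError("assortativity requires at least one edge")
    m1, m2, cross = _edge_end_moments(stats)
    var = m2 - m1 * m1
    if var <= _VAR_TOL * max(1.0, m2):
        return None
    return (cross - m1 * m1) / var


def assortativity_from_ddc(stats: DegreeStatistics, ddc: NormalizedDDC) -> float | None:
    """Assortativity recomputed from (p, W) instead of from Pi.

    Uses Pi(k, k') = [k p(k)/<k>][k' p(k')/<k>] W(k, k'); must agree with
    :func:`assortativity` to numerical precision on exact statistics.
    """
    kbar = stats.mean_degree
    m1 = m2 = cross = 0.0
    for (k, kp), w in ddc.W.items():
        pi = (k * stats.p[k] / kbar) * (kp * stats.p[kp] / kbar) * w
        cross += k * kp * pi
    for k, pk in stats.p.items():
        if k >= 1:
            u = k * pk / kbar
            m1 += k * u
            m2 += k * k * u
    var = m2 - m1 * m1
    if var <= _VAR_TOL * max(1.0, m2):
        return None
    return (cross - m1 * m1) / var


# ---------------------------------------------------------------------------
# Gaussian smoothening
# ---------------------------------------------------------------------------

def gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    """Column-stochastic discrete Gaussian kernel on ``size`` bins.

    ``K[i, j] ∝ exp(-(i-j)^2 / 2 sigma^2)`` with each column renormalised,
    so clipping at the range boundaries loses no probability mass.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    idx = np.arange(size, dtype=float)
    K = np.exp(-((idx[:, None] - idx[None, :]) ** 2) / (2.0 * sigma * sigma))
    return K / K.sum(axis=0, keepdims=True)


def smooth_distribution(values: np.ndarray, sigma: float) -> np.ndarray:
    """Smooth a 1-d probability vector; output is positive and sums to 1."""
    values = np.asarray(values, dtype=float)
    out = gaussian_kernel(values.size, sigma) @ values
    return out / out.sum()


@dataclass(frozen=True)
class NetworkProfile:
    """(p, Pi, W, <k>) on a fixed degree grid, optionally smoothed.

    ``p`` covers degrees ``0..kmax``; ``joint`` and ``W`` cover
    ``1..kmax`` on both axes (index ``k-1``).  With ``sigma > 0`` every
    entry of ``p``, ``joint`` and ``W`` is strictly positive, which is what
    the KL-based distance requires.  With ``sigma == 0`` the arrays are the
    exact counts and ``W`` is NaN off the support of ``p``.
    """

    kmax: int
    sigma: float
    p: np.ndarray          # shape (kmax+1,)
    mean_degree: float     # Sum k p(k) on the grid
    joint: np.ndarray      # shape (kmax, kmax)
    W: np.ndarray          # shape (kmax, kmax)
    N: int
    E: int

    def edge_end_marginal(self) -> np.ndarray:
        """u(k) = k p(k)/<k> for k = 1..kmax."""
        k = np.arange(1, self.kmax + 1, dtype=float)
        return k * self.p[1:] / self.mean_degree


def _stats_to_arrays(stats: DegreeStatistics, kmax: int) -> tuple[np.ndarray, np.ndarray]:
    p = np.zeros(kmax + 1)
    for k, v in stats.p.items():
        if k <= kmax:
            p[k] = v
    joint = np.zeros((kmax, kmax))
    for (k, kp), v in stats.joint.items():
        if 1 <= k <= kmax and 1 <= kp <= kmax:
            joint[k - 1, kp - 1] = v
    return p, joint


def characterize(
    net: InteractionNetwork,
    sigma: float = 1.0,
    kmax: int | None = None,
) -> NetworkProfile:
    """Measure (p, Pi, W, <k>) on the grid 0..kmax, smoothed with ``sigma``.

    ``kmax`` defaults to the largest observed degree.  Truncating below it
    discards the (renormalised) high-degree tail, mirroring the practice of
    capping the degree axes where counts are too thin to act as clean
    probability estimators.  Smoothening is applied on the truncated range.
    """
    stats = degree_distribution(net)
    if kmax is None:
        kmax = max(1, stats.max_degree())
    p, joint = _stats_to_arrays(stats, kmax)
    psum, jsum = p.sum(), joint.sum()
    if psum <= 0:
        raise ValueError("degree distribution has no mass on the grid")
    p = p / psum
    if jsum > 0:
        joint = joint / jsum

    if sigma > 0:
        p = smooth_distribution(p, sigma)
        if stats.E == 0:
            raise ValueError("smoothed profile of an edgeless network is undefined")
        K = gaussian_kernel(kmax, sigma)
        joint = K @ joint @ K.T
        joint = joint / joint.sum()
        kbar = float(np.arange(kmax + 1) @ p)
        u = np.arange(1, kmax + 1) * p[1:] / kbar
        W = joint / np.outer(u, u)
    else:
        kbar = float(np.arange(kmax + 1) @ p)
        u = np.arange(1, kmax + 1) * p[1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            W = joint * kbar * kbar / np.outer(u, u)
        W[np.outer(p[1:] == 0, p[1:] == 0)] = np.nan
        W[p[1:] == 0, :] = np.nan
        W[:, p[1:] == 0] = np.nan

    return NetworkProfile(
        kmax=kmax, sigma=sigma, p=p, mean_degree=kbar,
        joint=joint, W=W, N=stats.N, E=stats.E,
    )
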