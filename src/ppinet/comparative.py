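"""Distance-based comparison of network collections.

Two tools: average-linkage hierarchical clustering of a pairwise network
distance matrix (dendrogram + Newick export), and the sub-sampling
robustness experiment — randomly removing a growing fraction of nodes and
tracking the information-theoretic distance between the sub-sampled and the
original network.  Networks whose topology carries more information
(higher complexity) drift away faster under sub-sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .degree_stats import characterize
from .infotheory import DistanceMatrix, profile_distance
from .network import InteractionNetwork

__all__ = ["Dendrogram", "SubsampleCurve", "cluster", "subsample_curve"]

DEFAULT_FRACTIONS = tuple(round(0.1 * i, 1) for i in range(1, 10))


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge tree over network labels.

    ``linkage`` is a scipy linkage matrix whose rows merge the clusters of
    the (label-sorted) leaves; merge heights are non-decreasing along any
    root path because average linkage is ultrametric on a proper distance
    matrix.
    """

    labels: tuple[str, ...]
    linkage: np.ndarray
    method: str = "average"

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths.

        A cluster merged at height h sits at depth h/2 from its leaves, so
        the branch from a child at height hc to its parent at height h has
        length (h - hc)/2 and leaf-to-root depth equals h_root/2.
        """
        n = len(self.labels)
        heights = np.concatenate([np.zeros(n), self.linkage[:, 2]])

        def render(idx: int, parent_height: float) -> str:
            length = (parent_height - heights[idx]) / 2.0
            if idx < n:
                return f"{_escape(self.labels[idx])}:{length:.10g}"
            left, right = int(self.linkage[idx - n, 0]), int(self.linkage[idx - n, 1])
            inner = ",".join(render(c, heights[idx]) for c in (left, right))
            return f"({inner}):{length:.10g}"

        root = n + self.linkage.shape[0] - 1
        left, right = int(self.linkage[-1, 0]), int(self.linkage[-1, 1])
        inner = ",".join(render(c, heights[root]) for c in (left, right))
        return f"({inner});"

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster membership for a given number of clusters."""
        flat = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return {label: int(c) for label, c in zip(self.labels, flat)}

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()


def _escape(label: str) -> str:
    if any(ch in label for ch in "(),:; \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def cluster(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage clustering of a symmetric, zero-diagonal matrix.

    Leaves are processed in sorted label order, which fixes agglomeration
    tie-breaks deterministically and makes the result invariant under
    permutations of the input collection.
    """
    values = np.asarray(dm.values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 networks to cluster")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(values) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(values < 0):
        raise ValueError("distance matrix must be non-negative")
    order = np.argsort(np.asarray(dm.labels))
    labels = tuple(dm.labels[i] for i in order)
    reordered = values[np.ix_(order, order)]
    linkage = hierarchy.linkage(squareform(reordered, checks=False), method="average")
    return Dendrogram(labels=labels, linkage=linkage)


@dataclass(frozen=True)
class SubsampleCurve:
    """Distance-to-original versus node-removal fraction."""

    fractions: tuple[float, ...]
    mean: np.ndarray
    sd: np.ndarray
    n_effective: np.ndarray   # repeats that yielded an edge-bearing subsample
    repeats: int
    seed: int
    sigma: float
    mode: str = "full"
    per_repeat: np.ndarray = field(default=None, repr=False)

    def to_tsv(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as handle:
            handle.write("fraction\tmean_distance\tsd\tn_effective\n")
            for f, m, s, n in zip(self.fractions, self.mean, self.sd, self.n_effective):
                handle.write(f"{f:g}\t{m:.6g}\t{s:.6g}\t{int(n)}\n")


def subsample_curve(
    net: InteractionNetwork,
    repeats: int = 10,
    seed: int = 0,
    sigma: float = 1.0,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    mode: str = "full",
) -> SubsampleCurve:
    """Random node-removal robustness curve.

    For each removal fraction f, ``floor(f N)`` uniformly chosen nodes are
    deleted; the induced subgraph (isolated survivors retained) is
    characterised on the original's degree grid and its full (or
    degree-only) distance to the original is recorded.  Repeats with an
    edgeless subsample are skipped with a warning and reported in
    ``n_effective``.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if list(fractions) != sorted(set(fractions)) or not all(0 < f < 1 for f in fractions):
        raise ValueError("fractions must be strictly increasing values in (0, 1)")
    if mode not in ("full", "degree_only"):
        raise ValueError("mode must be 'full' or 'degree_only'")
    rng = np.random.default_rng(seed)
    deg = net.degree_sequence()
    kmax = max(1, int(deg.max()))
    original = characterize(net, sigma=sigma, kmax=kmax)

    values = np.full((len(fractions), repeats), np.nan)
    for rep in range(repeats):
        for fi, f in enumerate(fractions):
            remove = int(np.floor(f * net.N))
            keep = rng.permutation(net.N)[remove:]
            sub = net.induced_subgraph(np.sort(keep))
            if sub.E == 0:
                warnings.warn(
                    f"subsample at fraction {f} (repeat {rep}) has no edges; skipped",
                    stacklevel=2,
                )
                continue
            profile = characterize(sub, sigma=sigma, kmax=kmax)
            res = profile_distance(original, profile)
            values[fi, rep] = (
                res.full_distance if mode == "full" else res.degree_only_distance
            )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(values, axis=1)
        sd = np.nanstd(values, axis=1, ddof=1)
    n_eff = np.sum(~np.isnan(values), axis=1)
    return SubsampleCurve(
        fractions=tuple(fractions), mean=mean, sd=sd, n_effective=n_eff,
        repeats=repeats, seed=seed, sigma=sigma, mode=mode, per_repeat=values,
    )
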