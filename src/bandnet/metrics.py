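"""Complex-network analysis of band networks.

Small-worldness is diagnosed the classical way: the average clustering
coefficient C and the characteristic path length L of the network of
interest are compared with the same quantities in random reference
networks with the identical degree sequence (degree-preserving double
edge swaps).  gamma = C / C_R, lambda = L / L_R, and the scalar summary
sigma = gamma / lambda is > 1 for small-world organisation.

The degree distribution is fitted with a discrete power law by maximum
likelihood (Hurwitz-zeta normalisation), with the lower cutoff x_min
chosen by minimal Kolmogorov–Smirnov distance.  Hub vertices are the
top-degree vertices; their spatial spread is scored against a region
atlas (match within a radius delta, each region counted once, coverage
A = M / R).  Differences between two networks on the same vertex set
are assessed with permutation tests on named statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import cdist
from scipy.special import zeta

from .network import VoxelGraph

__all__ = [
    "GraphMetrics",
    "DegreeDistribution",
    "PowerLawFit",
    "RegionAtlas",
    "AtlasCoverage",
    "RegionConnectivityMatrix",
    "PathLengthResult",
    "PermutationTestResult",
    "average_clustering",
    "characteristic_path_length",
    "degree_preserving_rewire",
    "small_world_indices",
    "degree_distribution",
    "fit_power_law",
    "hub_vertices",
    "atlas_coverage",
    "region_connectivity_matrix",
    "network_difference_test",
    "default_delta",
]

logger = logging.getLogger(__name__)


# --- small-world ------------------------------------------------------------


class PathLengthResult(NamedTuple):
    length: float
    connected_pair_fraction: float


@dataclass
class GraphMetrics:
    """C, L and their degree-matched random references, with the ratios
    gamma = C/C_R, lambda = L/L_R and sigma = gamma/lambda."""

    clustering_C: float
    path_length_L: float
    C_random: float
    L_random: float
    gamma: float
    lambda_ratio: float
    sigma: float
    connected_pair_fraction: float
    C_random_refs: list[float]
    L_random_refs: list[float]


def average_clustering(g: VoxelGraph) -> float:
    """Mean over vertices of closed triplets / (k(k-1)/2); k < 2 counts 0."""
    if g.n_vertices < 3:
        raise ValueError("need at least 3 vertices")
    return float(nx.average_clustering(g.to_networkx(), count_zeros=True))


def _pairwise_hops(g: VoxelGraph) -> np.ndarray:
    n = g.n_vertices
    if g.n_edges == 0:
        raise ValueError("empty graph: characteristic path length undefined")
    rows, cols = [], []
    for i, j in g.edges:
        rows += [i, j]
        cols += [j, i]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return shortest_path(adj, method="D", unweighted=True, directed=False)


def characteristic_path_length(g: VoxelGraph) -> PathLengthResult:
    """Mean shortest-path length over connected vertex pairs.

    Disconnected pairs are excluded from the mean; the fraction of
    connected pairs is reported alongside so the exclusion is visible.
    """
    if g.n_vertices < 2:
        raise ValueError("need at least 2 vertices")
    hops = _pairwise_hops(g)
    iu = np.triu_indices(g.n_vertices, k=1)
    d = hops[iu]
    finite = np.isfinite(d)
    if not finite.any():
        raise ValueError("empty graph: no connected pairs")
    return PathLengthResult(
        length=float(d[finite].mean()),
        connected_pair_fraction=float(finite.mean()),
    )


def degree_preserving_rewire(
    g: VoxelGraph, n_swaps: int | None = None, seed: int | None = None
) -> VoxelGraph:
    """Randomise a graph while preserving its degree sequence exactly.

    Runs a double-edge-swap Markov chain for ``n_swaps`` accepted swaps
    (default 10x the edge count); self-loops and multi-edges are never
    introduced.  If no legal swap can be found the input is returned
    unchanged with a warning.
    """
    if g.n_edges < 2:
        warnings.warn("graph has < 2 edges; no swap possible, returning input")
        return g
    if n_swaps is None:
        n_swaps = 10 * g.n_edges
    gx = g.to_networkx()
    try:
        nx.double_edge_swap(gx, nswap=n_swaps, max_tries=100 * n_swaps, seed=seed)
    except nx.NetworkXException as exc:
        warnings.warn(f"degree-preserving rewire gave up early: {exc}")
    return VoxelGraph.from_networkx(gx, g.vertex_coords, band_label=g.band_label)


def small_world_indices(
    g: VoxelGraph,
    n_random: int = 20,
    seed: int | None = None,
    n_swaps: int | None = None,
) -> GraphMetrics:
    """Small-world indices of a graph against rewired references.

    C_random and L_random are means over ``n_random`` degree-preserving
    rewirings of ``g``; per-reference values are kept for dispersion.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    C = average_clustering(g)
    L, frac = characteristic_path_length(g)
    if frac < 0.5:
        warnings.warn(
            f"only {frac:.1%} of vertex pairs are connected; "
            "path-length ratio may be unreliable"
        )
    rng = np.random.default_rng(seed)
    c_refs: list[float] = []
    l_refs: list[float] = []
    for _ in range(n_random):
        ref = degree_preserving_rewire(
            g, n_swaps=n_swaps, seed=int(rng.integers(2**31))
        )
        c_refs.append(average_clustering(ref))
        l_refs.append(characteristic_path_length(ref).length)
    C_R = float(np.mean(c_refs))
    L_R = float(np.mean(l_refs))
    gamma = C / C_R
    lam = L / L_R
    return GraphMetrics(
        clustering_C=C,
        path_length_L=L,
        C_random=C_R,
        L_random=L_R,
        gamma=gamma,
        lambda_ratio=lam,
        sigma=gamma / lam,
        connected_pair_fraction=frac,
        C_random_refs=c_refs,
        L_random_refs=l_refs,
    )


# --- scale-free -------------------------------------------------------------


@dataclass
class DegreeDistribution:
    degrees: np.ndarray
    histogram: dict[int, int]

    @property
    def n_distinct(self) -> int:
        return len(self.histogram)


def degree_distribution(g: VoxelGraph) -> DegreeDistribution:
    deg = g.degrees()
    vals, counts = np.unique(deg, return_counts=True)
    return DegreeDistribution(
        degrees=deg, histogram={int(v): int(c) for v, c in zip(vals, counts)}
    )


@dataclass
class PowerLawFit:
    exponent: float | None
    xmin: int | None
    ks_distance: float | None
    reason: str | None = None

    @property
    def fitted(self) -> bool:
        return self.exponent is not None


def _plaw_nll(alpha: float, x: np.ndarray, xmin: int) -> float:
    return len(x) * np.log(zeta(alpha, xmin)) + alpha * np.sum(np.log(x))


def _plaw_ks(alpha: float, x: np.ndarray, xmin: int) -> float:
    # discrete KS: sup over support points of |ECDF - CDF|, both right-continuous
    xs = np.sort(x)
    support = np.unique(xs)
    z = zeta(alpha, xmin)
    cdf_theo = 1.0 - zeta(alpha, support + 1) / z
    ecdf = np.searchsorted(xs, support, side="right") / len(xs)
    return float(np.max(np.abs(ecdf - cdf_theo)))


def fit_power_law(
    dd: DegreeDistribution | np.ndarray,
    max_xmin_candidates: int = 25,
    min_tail: int = 50,
) -> PowerLawFit:
    """Discrete maximum-likelihood power-law fit P(k) ~ k^-alpha, k >= x_min.

    The exponent maximises the zeta-normalised likelihood on the tail
    k >= x_min; x_min is chosen among the smallest distinct degrees to
    minimise the Kolmogorov–Smirnov distance between the fitted and
    empirical tail distributions.  Refuses degenerate inputs (< 10
    distinct positive degrees).
    """
    degrees = dd.degrees if isinstance(dd, DegreeDistribution) else np.asarray(dd)
    x_all = degrees[degrees >= 1].astype(float)
    distinct = np.unique(x_all)
    if len(distinct) < 10:
        return PowerLawFit(
            None, None, None, reason=f"only {len(distinct)} distinct degrees (< 10)"
        )
    best: tuple[float, float, int] | None = None  # (ks, alpha, xmin)
    for xm in distinct[:max_xmin_candidates]:
        xm = int(xm)
        tail = x_all[x_all >= xm]
        if len(tail) < min_tail:
            break
        res = minimize_scalar(
            _plaw_nll, bounds=(1.01, 8.0), args=(tail, xm), method="bounded"
        )
        alpha = float(res.x)
        ks = _plaw_ks(alpha, tail, xm)
        if best is None or ks < best[0]:
            best = (ks, alpha, xm)
    if best is None:
        return PowerLawFit(None, None, None, reason="tail too short for any x_min")
    ks, alpha, xm = best
    return PowerLawFit(exponent=alpha, xmin=xm, ks_distance=ks)


# --- hubs and atlas ---------------------------------------------------------


def hub_vertices(g: VoxelGraph, k: int | None = None) -> list[int]:
    """Top-k vertices by degree centrality, ties broken by ascending index.

    Default k is the top 1% of vertices (at least 1).
    """
    if k is None:
        k = max(1, round(0.01 * g.n_vertices))
    if not (1 <= k <= g.n_vertices):
        raise ValueError(f"k must be in [1, {g.n_vertices}]")
    deg = g.degrees()
    order = np.lexsort((np.arange(g.n_vertices), -deg))
    return [int(v) for v in order[:k]]


@dataclass
class RegionAtlas:
    """Region centers of an anatomical parcellation (ids 1..R)."""

    centers: np.ndarray  # (R, 3)
    names: list[str]

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[1] != 3:
            raise ValueError("centers must be (R, 3)")
        if self.centers.shape[0] < 1:
            raise ValueError("atlas must have at least one region")
        if len(self.names) != self.centers.shape[0]:
            raise ValueError("one name per region required")

    @property
    def n_regions(self) -> int:
        return self.centers.shape[0]

    @property
    def region_ids(self) -> np.ndarray:
        return np.arange(1, self.n_regions + 1)


def default_delta(atlas: RegionAtlas) -> float:
    """Half the mean nearest-neighbour distance between region centers."""
    if atlas.n_regions < 2:
        return 1.0
    d = cdist(atlas.centers, atlas.centers)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean() / 2.0)


@dataclass
class AtlasCoverage:
    matched_regions_M: int
    accuracy_A: float
    delta: float


def atlas_coverage(
    hub_coords: np.ndarray, atlas: RegionAtlas, delta: float | None = None
) -> AtlasCoverage:
    """Fraction of atlas regions hit by at least one hub vertex.

    A hub at coordinate c matches region k iff ||c - center_k|| < delta;
    a region matched by several hubs is counted once.  A = M / R.
    """
    hub_coords = np.atleast_2d(np.asarray(hub_coords, dtype=float))
    if hub_coords.shape[1] != 3:
        raise ValueError("hub coordinates must be 3-dimensional")
    if delta is None:
        delta = default_delta(atlas)
    if delta <= 0:
        raise ValueError("delta must be positive")
    d = cdist(hub_coords, atlas.centers)
    matched = np.flatnonzero((d < delta).any(axis=0))
    M = int(len(matched))
    return AtlasCoverage(
        matched_regions_M=M, accuracy_A=M / atlas.n_regions, delta=float(delta)
    )


@dataclass
class RegionConnectivityMatrix:
    counts: np.ndarray  # (R, R) symmetric, int
    region_ids: np.ndarray

    @property
    def total_edges(self) -> int:
        return int(np.triu(self.counts).sum())


def _assign_regions(
    coords: np.ndarray, atlas: RegionAtlas, delta: float | None
) -> np.ndarray:
    d = cdist(coords, atlas.centers)
    nearest = d.argmin(axis=1)
    if delta is not None:
        far = d[np.arange(len(coords)), nearest] >= delta
        if far.any():
            logger.warning(
                "%d vertices farther than delta=%.3g from every region center; "
                "assigned to nearest center",
                int(far.sum()),
                delta,
            )
    return nearest


def region_connectivity_matrix(
    g: VoxelGraph, atlas: RegionAtlas, delta: float | None = None
) -> RegionConnectivityMatrix:
    """Count multigraph edges between (and within) atlas regions.

    Every vertex is assigned to its nearest region center (a warning is
    logged for vertices farther than delta); counts[i][j] is the number
    of edges with one endpoint in region i and the other in region j.
    The matrix is symmetric and its upper triangle (diagonal included)
    sums to |E(g)|.
    """
    if atlas.n_regions < 1:
        raise ValueError("empty atlas")
    if delta is None:
        delta = default_delta(atlas)
    assign = _assign_regions(g.vertex_coords, atlas, delta)
    R = atlas.n_regions
    counts = np.zeros((R, R), dtype=int)
    for i, j in g.edges:
        a, b = assign[i], assign[j]
        if a == b:
            counts[a, a] += 1
        else:
            counts[a, b] += 1
            counts[b, a] += 1
    return RegionConnectivityMatrix(counts=counts, region_ids=atlas.region_ids)


# --- network difference test ------------------------------------------------


@dataclass
class PermutationTestResult:
    p_value: float
    observed: float
    statistic: str
    n_perm: int


def _jaccard_distance(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    if union == 0:
        return 0.0
    return 1.0 - len(a & b) / union


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    allv = np.concatenate([x, y])
    grid = np.unique(allv)
    cx = np.searchsorted(np.sort(x), grid, side="right") / len(x)
    cy = np.searchsorted(np.sort(y), grid, side="right") / len(y)
    return float(np.max(np.abs(cx - cy)))


def network_difference_test(
    gA: VoxelGraph,
    gB: VoxelGraph,
    statistic: str = "degree_ks",
    n_perm: int = 999,
    seed: int | None = None,
    atlas: RegionAtlas | None = None,
    delta: float | None = None,
) -> PermutationTestResult:
    """Permutation test for a difference between two networks on the
    same vertex set.

    Statistics (all are distances, 0 when the graphs are identical):

    - ``"jaccard"``: Jaccard distance between the edge sets; the null is
      generated by random vertex relabellings of the second graph.
    - ``"degree_ks"``: Kolmogorov–Smirnov distance between the two degree
      distributions; the null pools the degrees and re-splits at random.
    - ``"region_frobenius"``: Frobenius norm of the difference of the two
      region connectivity matrices (requires an atlas); vertex-relabel null.

    p = (1 + #replicates >= observed) / (1 + n_perm), so p >= 1/(1+n_perm)
    and identical graphs give p = 1 under every statistic.
    """
    if gA.n_vertices != gB.n_vertices:
        raise ValueError("graphs must share the vertex set")
    if n_perm < 99:
        warnings.warn("n_perm < 99: p-value resolution is very coarse")
    rng = np.random.default_rng(seed)
    n = gA.n_vertices

    if statistic == "degree_ks":
        dA, dB = gA.degrees(), gB.degrees()
        obs = _ks_statistic(dA, dB)
        pooled = np.concatenate([dA, dB])
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(pooled))
            rep = _ks_statistic(pooled[perm[:n]], pooled[perm[n:]])
            if rep >= obs - 1e-15:
                count += 1
    elif statistic in ("jaccard", "region_frobenius"):
        if statistic == "region_frobenius":
            if atlas is None:
                raise ValueError("region_frobenius requires an atlas")
            mA = region_connectivity_matrix(gA, atlas, delta).counts

            def stat(g: VoxelGraph) -> float:
                mB = region_connectivity_matrix(g, atlas, delta).counts
                return float(np.linalg.norm(mA - mB))

        else:

            def stat(g: VoxelGraph) -> float:
                return _jaccard_distance(gA.edges, g.edges)

        obs = stat(gB)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            relabelled = VoxelGraph(
                n_vertices=n,
                vertex_coords=gB.vertex_coords,
                edges=frozenset(
                    (int(perm[i]), int(perm[j])) for i, j in gB.edges
                ),
                band_label=gB.band_label,
            )
            if stat(relabelled) >= obs - 1e-15:
                count += 1
    else:
        raise ValueError(
            f"unknown statistic {statistic!r}; "
            "choose jaccard | degree_ks | region_frobenius"
        )
    return PermutationTestResult(
        p_value=(1 + count) / (1 + n_perm),
        observed=float(obs),
        statistic=statistic,
        n_perm=n_perm,
    )
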