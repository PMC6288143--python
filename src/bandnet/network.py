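"""Thresholded voxelwise networks and the multi-graph band model.

Two voxels are functionally connected in a band when the Euclidean
distance between their band signals falls strictly below a threshold
lambda.  One graph is built per band over the shared voxel vertex set;
the collection is a multi-graph: up to one parallel edge per band
between any vertex pair.  Pattern graphs (collaboration = bands agree,
interleaved = any band connects) and Boolean edge-set algebra operate on
the per-band edge sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist, pdist

from .decomposition import (
    DEFAULT_BANDS,
    FULL_BAND_HZ,
    BandSignals,
    BoldMatrix,
    FrequencyBand,
    bandpass_full,
    decompose,
)

__all__ = [
    "VoxelGraph",
    "MultiGraph",
    "EdgeThreshold",
    "euclidean_distance",
    "zscore_rows",
    "build_band_network",
    "threshold_for_density",
    "build_multigraph",
    "cohort_thresholds",
    "build_cohort_multigraphs",
    "pattern_graph",
    "edge_algebra_count",
    "edge_algebra_set",
]

logger = logging.getLogger(__name__)

Edge = tuple[int, int]


@dataclass(frozen=True)
class EdgeThreshold:
    """The distance threshold lambda: edge present iff d(x, y) < value."""

    value: float

    def __post_init__(self) -> None:
        if not (self.value > 0):
            raise ValueError("edge threshold must be positive")


@dataclass
class VoxelGraph:
    """An undirected simple graph over voxels (no self-loops, 0-based)."""

    n_vertices: int
    vertex_coords: np.ndarray
    edges: frozenset[Edge]
    band_label: str = ""

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float)
        canon = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop at vertex {i}")
            if not (0 <= i < self.n_vertices and 0 <= j < self.n_vertices):
                raise ValueError(f"edge ({i},{j}) outside vertex range")
            canon.add((min(i, j), max(i, j)))
        self.edges = frozenset(canon)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(
        cls, g: nx.Graph, vertex_coords: np.ndarray | None = None, band_label: str = ""
    ) -> "VoxelGraph":
        n = g.number_of_nodes()
        if vertex_coords is None:
            # default grid coordinates (x-fastest scan order)
            vertex_coords = scan_order_coords(n)
        return cls(
            n_vertices=n,
            vertex_coords=vertex_coords,
            edges=frozenset((min(u, v), max(u, v)) for u, v in g.edges()),
            band_label=band_label,
        )


def scan_order_coords(n: int, side: int | None = None) -> np.ndarray:
    """Place n vertices on an integer grid in scan order (x varies fastest)."""
    if side is None:
        side = int(np.ceil(n ** (1.0 / 3.0)))
    idx = np.arange(n)
    x = idx % side
    y = (idx // side) % side
    z = idx // (side * side)
    return np.column_stack([x, y, z]).astype(float)


@dataclass
class MultiGraph:
    """Shared voxel vertex set with one edge set per frequency band.

    ``edge_sets`` maps band name -> frozenset of undirected edges; an
    optional ``"full"`` entry holds the full-band network H_Full.  The
    union of the per-band sets is the multi-graph's total edge set.
    """

    n_vertices: int
    vertex_coords: np.ndarray
    edge_sets: dict[str, frozenset[Edge]] = field(default_factory=dict)

    def band_graph(self, band: str) -> VoxelGraph:
        if band not in self.edge_sets:
            raise KeyError(f"unknown band {band!r}; have {sorted(self.edge_sets)}")
        return VoxelGraph(
            n_vertices=self.n_vertices,
            vertex_coords=self.vertex_coords,
            edges=self.edge_sets[band],
            band_label=band,
        )

    @property
    def band_names(self) -> list[str]:
        return [b for b in self.edge_sets if b != "full"]

    def union_edges(self) -> frozenset[Edge]:
        out: set[Edge] = set()
        for name in self.band_names:
            out |= self.edge_sets[name]
        return frozenset(out)


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance d(x, y) = sqrt(sum_n (x_n - y_n)^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    # same C kernel as the blockwise construction, so thresholding near a
    # tie is bit-identical between single-pair and matrix paths
    return float(cdist(x.reshape(1, -1), y.reshape(1, -1))[0, 0])


def zscore_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each row (mean 0, unit variance).

    Returns ``(zscored, flat_mask)`` where ``flat_mask`` flags
    zero-variance rows, which are left as all-zero.
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    flat = (sd[:, 0] == 0.0) | ~np.isfinite(sd[:, 0])
    sd_safe = np.where(sd == 0.0, 1.0, sd)
    out = (values - mean) / sd_safe
    out[flat] = 0.0
    return out, flat


def _signal_values(signals) -> np.ndarray:
    if isinstance(signals, (BandSignals, BoldMatrix)):
        return signals.values
    return np.asarray(signals, dtype=float)


def _coords_of(signals, n: int) -> np.ndarray:
    coords = getattr(signals, "voxel_coords", None)
    if coords is None:
        coords = scan_order_coords(n)
    return np.asarray(coords, dtype=float)


def build_band_network(
    signals,
    thr: EdgeThreshold,
    normalize: bool = True,
    block_size: int = 512,
) -> VoxelGraph:
    """Build a thresholded distance network from band signals.

    An edge joins voxels i and j iff the Euclidean distance between
    their series is strictly below ``thr.value``.  With ``normalize``
    each voxel series is z-scored first, so one lambda is meaningful
    across bands of very different raw amplitude.  Zero-variance voxels
    under normalization are flagged, logged, and left edgeless.
    Distances are computed in row blocks, O(block_size * n) memory.
    """
    values = _signal_values(signals)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 vertices")
    flat = np.zeros(n, dtype=bool)
    if normalize:
        values, flat = zscore_rows(values)
        if flat.any():
            logger.warning(
                "%d zero-variance voxel(s) flagged, left without edges: %s",
                int(flat.sum()),
                np.flatnonzero(flat)[:20].tolist(),
            )
    edges: set[Edge] = set()
    lam = thr.value
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        d = cdist(values[start:stop], values)
        for bi in range(stop - start):
            i = start + bi
            if flat[i]:
                continue
            js = np.flatnonzero(d[bi, i + 1 :] < lam) + i + 1
            for j in js:
                if not flat[j]:
                    edges.add((i, int(j)))
    label = getattr(getattr(signals, "band", None), "name", "") or ""
    return VoxelGraph(
        n_vertices=n,
        vertex_coords=_coords_of(signals, n),
        edges=frozenset(edges),
        band_label=label,
    )


def threshold_for_density(
    signals, density: float, normalize: bool = True
) -> EdgeThreshold:
    """Choose lambda so the resulting network has (about) the requested
    edge density: the density-quantile of the pairwise distances, nudged
    up by a hair so strict inequality keeps distances at the quantile."""
    if not (0.0 < density < 1.0):
        raise ValueError("density must be in (0, 1)")
    values = _signal_values(signals)
    if normalize:
        values, _ = zscore_rows(values)
    d = pdist(values)
    lam = float(np.quantile(d, density))
    return EdgeThreshold(lam * (1.0 + 1e-12) + 1e-300)


def build_multigraph(
    bold: BoldMatrix,
    bands: Sequence[FrequencyBand] = DEFAULT_BANDS,
    thr: EdgeThreshold | None = None,
    density: float | None = None,
    include_full: bool = True,
    normalize: bool = True,
) -> MultiGraph:
    """Decompose a BOLD matrix and build one band network per band.

    Either a single absolute threshold ``thr`` is applied to every band
    ("the same threshold lambda"), or ``density`` selects a per-band
    lambda hitting the requested edge density in each band.  With
    ``include_full`` the full-band network H_Full (band-pass over the
    union interval) is built as well, under the same rule.
    """
    if (thr is None) == (density is None):
        raise ValueError("give exactly one of thr or density")
    band_signals = decompose(bold, bands)
    mg = MultiGraph(
        n_vertices=bold.n_voxels,
        vertex_coords=np.asarray(bold.voxel_coords, dtype=float),
    )
    for sig in band_signals:
        t = thr if thr is not None else threshold_for_density(sig, density, normalize)
        g = build_band_network(sig, t, normalize=normalize)
        mg.edge_sets[sig.band.name] = g.edges
    if include_full:
        lo = min(b.f_low_hz for b in bands)
        hi = max(b.f_high_hz for b in bands)
        full = bandpass_full(bold, lo, hi)
        t = thr if thr is not None else threshold_for_density(full, density, normalize)
        g = build_band_network(full, t, normalize=normalize)
        mg.edge_sets["full"] = g.edges
    return mg


def cohort_thresholds(
    bolds: Sequence[BoldMatrix],
    bands: Sequence[FrequencyBand] = DEFAULT_BANDS,
    density: float = 0.15,
    include_full: bool = True,
    normalize: bool = True,
) -> dict[str, EdgeThreshold]:
    """One shared lambda per band for a whole cohort.

    The paper-style construction applies the *same* threshold to every
    subject's band network, so between-subject differences in overall
    connectivity stay visible.  The shared lambda is the density-quantile
    of the pooled pairwise distances across subjects (an unsupervised
    calibration; labels are never consulted).
    """
    pooled: dict[str, list[np.ndarray]] = {}
    for bold in bolds:
        for sig in decompose(bold, bands):
            v = sig.values
            if normalize:
                v, _ = zscore_rows(v)
            pooled.setdefault(sig.band.name, []).append(pdist(v))
        if include_full:
            lo = min(b.f_low_hz for b in bands)
            hi = max(b.f_high_hz for b in bands)
            v = bandpass_full(bold, lo, hi).values
            if normalize:
                v, _ = zscore_rows(v)
            pooled.setdefault("full", []).append(pdist(v))
    return {
        name: EdgeThreshold(float(np.quantile(np.concatenate(ds), density)))
        for name, ds in pooled.items()
    }


def build_cohort_multigraphs(
    bolds: Sequence[BoldMatrix],
    bands: Sequence[FrequencyBand] = DEFAULT_BANDS,
    density: float = 0.15,
    include_full: bool = True,
    normalize: bool = True,
) -> list[MultiGraph]:
    """Build every subject's multigraph under shared per-band thresholds."""
    thrs = cohort_thresholds(bolds, bands, density, include_full, normalize)
    out = []
    for bold in bolds:
        mg = MultiGraph(
            n_vertices=bold.n_voxels,
            vertex_coords=np.asarray(bold.voxel_coords, dtype=float),
        )
        for sig in decompose(bold, bands):
            g = build_band_network(sig, thrs[sig.band.name], normalize=normalize)
            mg.edge_sets[sig.band.name] = g.edges
        if include_full:
            lo = min(b.f_low_hz for b in bands)
            hi = max(b.f_high_hz for b in bands)
            g = build_band_network(
                bandpass_full(bold, lo, hi), thrs["full"], normalize=normalize
            )
            mg.edge_sets["full"] = g.edges
        out.append(mg)
    return out


def pattern_graph(
    mg: MultiGraph, bands_required: Iterable[str], mode: str = "collaboration"
) -> VoxelGraph:
    """Connection-pattern graphs over a subset of bands.

    ``collaboration``: an edge is present iff it is present in *every*
    band of ``bands_required`` (set intersection; at least two bands).
    ``interleaved``: an edge is present iff present in *any* of them
    (set union).
    """
    names = list(bands_required)
    for b in names:
        if b not in mg.edge_sets:
            raise KeyError(f"unknown band {b!r}; have {sorted(mg.edge_sets)}")
    if mode == "collaboration":
        if len(names) < 2:
            raise ValueError("collaboration pattern requires at least two bands")
        acc = set(mg.edge_sets[names[0]])
        for b in names[1:]:
            acc &= mg.edge_sets[b]
    elif mode == "interleaved":
        acc = set()
        for b in names:
            acc |= mg.edge_sets[b]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return VoxelGraph(
        n_vertices=mg.n_vertices,
        vertex_coords=mg.vertex_coords,
        edges=frozenset(acc),
        band_label="+".join(names) + f":{mode}",
    )


# --- edge-set algebra -------------------------------------------------------

_ALIASES = {
    "l": "low",
    "h_l": "low",
    "hl": "low",
    "low": "low",
    "i": "intermediate",
    "h_i": "intermediate",
    "hi": "intermediate",
    "intermediate": "intermediate",
    "h": "high",
    "h_h": "high",
    "hh": "high",
    "high": "high",
    "full": "full",
    "h_full": "full",
    "hfull": "full",
}

_INTERSECT = {"∩", "&", "^"}
_UNION = {"∪", "+", "u", "U"}


def _tokenize(expr: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(expr)
    while i < n:
        c = expr[i]
        if c.isspace() or c == "|":
            i += 1
            continue
        if c in "()":
            tokens.append(("paren", c, i))
            i += 1
            continue
        if c in _INTERSECT:
            tokens.append(("op", "intersect", i))
            i += 1
            continue
        if c in _UNION and not (c in "uU" and i + 1 < n and expr[i + 1].isalnum()):
            tokens.append(("op", "union", i))
            i += 1
            continue
        if c.isalpha() or c == "_":
            j = i
            while j < n and (expr[j].isalnum() or expr[j] == "_"):
                j += 1
            word = expr[i:j]
            if word == "E" and j < n and expr[j] == "(":
                i = j  # E(...) wrapper: the '(' token follows
                continue
            tokens.append(("name", word, i))
            i = j
            continue
        raise ValueError(f"edge-algebra parse error at position {i}: {c!r}")
    return tokens


class _Parser:
    """Left-to-right evaluation, equal precedence, parentheses explicit."""

    def __init__(self, tokens, sets: Mapping[str, frozenset[Edge]]):
        self.tokens = tokens
        self.pos = 0
        self.sets = sets

    def _atom(self) -> frozenset[Edge]:
        if self.pos >= len(self.tokens):
            raise ValueError("edge-algebra parse error: unexpected end of expression")
        kind, val, at = self.tokens[self.pos]
        if kind == "paren" and val == "(":
            self.pos += 1
            inner = self._expr()
            if self.pos >= len(self.tokens) or self.tokens[self.pos][1] != ")":
                raise ValueError(f"edge-algebra parse error: unclosed '(' at {at}")
            self.pos += 1
            return inner
        if kind == "name":
            self.pos += 1
            key = _ALIASES.get(val.lower(), val)
            if key not in self.sets:
                key2 = _ALIASES.get(val.lower().removeprefix("h_"), None)
                if key2 in self.sets:
                    return self.sets[key2]
                raise ValueError(
                    f"edge-algebra parse error at {at}: unknown set {val!r} "
                    f"(available: {sorted(self.sets)})"
                )
            return self.sets[key]
        raise ValueError(f"edge-algebra parse error at {at}: unexpected {val!r}")

    def _expr(self) -> frozenset[Edge]:
        acc = self._atom()
        while self.pos < len(self.tokens):
            kind, val, at = self.tokens[self.pos]
            if kind == "paren" and val == ")":
                break
            if kind != "op":
                raise ValueError(
                    f"edge-algebra parse error at {at}: expected operator, got {val!r}"
                )
            self.pos += 1
            rhs = self._atom()
            acc = acc & rhs if val == "intersect" else acc | rhs
        return acc

    def parse(self) -> frozenset[Edge]:
        out = self._expr()
        if self.pos != len(self.tokens):
            _, val, at = self.tokens[self.pos]
            raise ValueError(f"edge-algebra parse error at {at}: trailing {val!r}")
        return out


def edge_algebra_set(mg: MultiGraph, expression: str) -> frozenset[Edge]:
    """Evaluate a set expression over named edge sets.

    Accepts names like ``H_L``, ``L``, ``low``, ``H_Full``; operators
    ``∩``/``&``/``^`` (intersection) and ``∪``/``+``/``u`` (union);
    the decorative ``|E( ... )|`` wrapper is ignored.  Operators have
    equal precedence and evaluate left-to-right; use parentheses to
    group explicitly.
    """
    return _Parser(_tokenize(expression), mg.edge_sets).parse()


def edge_algebra_count(mg: MultiGraph, expression: str) -> int:
    """``|E(expression)|``: the size of the evaluated edge set."""
    return len(edge_algebra_set(mg, expression))
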