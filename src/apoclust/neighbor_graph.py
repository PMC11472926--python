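"""Per-frame pruned Delaunay adjacency graphs over nucleus centroids.

Neighborhood in the monolayer is approximated by the Delaunay triangulation
of the nucleus centroids, pruned at a maximum edge length to remove false
adjacencies (e.g. long hull edges bridging separate body segments).  The
pruning threshold defaults to twice the median Delaunay edge length of the
initial frame — a scale-free choice robust to magnification — and may be
overridden with an absolute value in micrometres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from . import track_io

logger = logging.getLogger(__name__)

Edge = tuple[Hashable, Hashable]

DEFAULT_MAX_DIST_FACTOR = 2.0


def _canon(a: Hashable, b: Hashable) -> Edge:
    return (a, b) if str(a) <= str(b) else (b, a)


def delaunay_edges(positions: Mapping[Hashable, tuple[float, float]]) -> set[Edge]:
    """Edge set of the Delaunay triangulation of 2-D points.

    Degenerate cases: fewer than 2 points yields an empty set with a
    warning; exactly 2 points yields the single edge; collinear point sets
    yield the path of consecutive points along the line.  Duplicate points
    raise ``ValueError`` naming the offending ids.  For cocircular
    configurations either valid triangulation may be returned (backend
    choice).
    """
    ids = list(positions.keys())
    pts = np.asarray([positions[i] for i in ids], dtype=float)
    if len(ids) < 2:
        logger.warning("delaunay_edges: fewer than 2 points, no edges")
        return set()
    if not np.isfinite(pts).all():
        raise ValueError("non-finite coordinates")
    # Duplicate detection (exact or near-exact coincidence).
    order = np.lexsort(pts.T)
    close = np.flatnonzero(np.linalg.norm(np.diff(pts[order], axis=0), axis=1) < 1e-9)
    if close.size:
        pairs = [(ids[order[i]], ids[order[i + 1]]) for i in close]
        raise ValueError(f"duplicate points for ids {pairs}")
    if len(ids) == 2:
        return {_canon(ids[0], ids[1])}

    if _is_collinear(pts):
        return _collinear_path(ids, pts)
    try:
        tri = Delaunay(pts)
    except QhullError:  # numerically flat input
        return _collinear_path(ids, pts)
    edges: set[Edge] = set()
    for simplex in tri.simplices:
        for k in range(3):
            a, b = simplex[k], simplex[(k + 1) % 3]
            edges.add(_canon(ids[a], ids[b]))
    return edges


def _is_collinear(pts: np.ndarray, tol: float = 1e-12) -> bool:
    c = pts - pts.mean(axis=0)
    sv = np.linalg.svd(c, compute_uv=False)
    scale = sv[0] if sv[0] > 0 else 1.0
    return sv[-1] / scale < tol


def _collinear_path(ids, pts: np.ndarray) -> set[Edge]:
    c = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(c)
    proj = c @ vt[0]
    order = np.argsort(proj)
    return {_canon(ids[order[k]], ids[order[k + 1]]) for k in range(len(ids) - 1)}


def edge_lengths(
    edges: Iterable[Edge], positions: Mapping[Hashable, tuple[float, float]]
) -> dict[Edge, float]:
    out = {}
    for a, b in edges:
        pa, pb = np.asarray(positions[a], float), np.asarray(positions[b], float)
        out[(a, b)] = float(np.hypot(*(pa - pb)))
    return out


def prune_edges(
    edges: Iterable[Edge],
    positions: Mapping[Hashable, tuple[float, float]],
    max_dist_um: float,
    segment_labels: Mapping[Hashable, str] | None = None,
) -> set[Edge]:
    """Drop edges longer than ``max_dist_um`` and, if segment labels are
    given, edges joining different segments (false connections across the
    segmental boundary)."""
    if max_dist_um <= 0:
        raise ValueError("max_dist_um must be positive")
    lengths = edge_lengths(edges, positions)
    kept = {e for e, ln in lengths.items() if ln <= max_dist_um}
    if segment_labels is not None:
        kept = {
            (a, b) for (a, b) in kept if segment_labels.get(a) == segment_labels.get(b)
        }
    return kept


def median_delaunay_edge_um(positions: Mapping[Hashable, tuple[float, float]]) -> float:
    edges = delaunay_edges(positions)
    if not edges:
        raise ValueError("cannot measure edge lengths of an edgeless graph")
    return float(np.median(list(edge_lengths(edges, positions).values())))


def resolve_max_dist(
    positions: Mapping[Hashable, tuple[float, float]],
    max_dist_um: float | None = None,
    max_dist_factor: float = DEFAULT_MAX_DIST_FACTOR,
) -> float:
    """Absolute pruning threshold: explicit value, or factor x median
    Delaunay edge length of ``positions``."""
    if max_dist_um is not None:
        return float(max_dist_um)
    return max_dist_factor * median_delaunay_edge_um(positions)


@dataclass(frozen=True)
class NeighborGraph:
    """Pruned Delaunay adjacency over the cells alive at one frame."""

    frame: int
    nodes: frozenset
    edges: frozenset  # of canonical (a, b) tuples
    positions: dict = field(repr=False)
    max_dist_um: float = float("inf")

    def has_edge(self, a: Hashable, b: Hashable) -> bool:
        return _canon(a, b) in self.edges

    def neighbors(self, a: Hashable) -> set:
        out = set()
        for u, v in self.edges:
            if u == a:
                out.add(v)
            elif v == a:
                out.add(u)
        return out

    def edge_length_um(self, a: Hashable, b: Hashable) -> float:
        pa = np.asarray(self.positions[a], float)
        pb = np.asarray(self.positions[b], float)
        return float(np.hypot(*(pa - pb)))

    def to_edge_table(self) -> pd.DataFrame:
        rows = [
            dict(frame=self.frame, cell_id_a=a, cell_id_b=b,
                 length_um=self.edge_length_um(a, b))
            for a, b in sorted(self.edges, key=lambda e: (str(e[0]), str(e[1])))
        ]
        return pd.DataFrame(rows, columns=["frame", "cell_id_a", "cell_id_b", "length_um"])


def build_frame_graph(
    tracks: pd.DataFrame | None,
    fates: pd.DataFrame,
    frame: int,
    max_dist_um: float | None = None,
    max_dist_factor: float = DEFAULT_MAX_DIST_FACTOR,
    position_mode: str = "at_frame",
    use_segments: bool = False,
) -> NeighborGraph:
    """Neighbor graph over the cells alive at ``frame``.

    ``position_mode="at_frame"`` uses each cell's tracked position at the
    frame (requires ``tracks``); ``"initial"`` uses first-frame positions
    from ``fates`` (the convention of the randomized-removal null, which
    ignores migration).  When ``max_dist_um`` is None the threshold is
    ``max_dist_factor`` x the median Delaunay edge length over first-frame
    positions, so that one consistent threshold serves the whole movie.
    """
    alive = track_io.alive_at(fates, frame)
    if position_mode == "initial":
        positions = {
            cid: (fates.at[cid, "x0_um"], fates.at[cid, "y0_um"]) for cid in alive
        }
    elif position_mode == "at_frame":
        if tracks is None:
            raise ValueError("position_mode='at_frame' requires the track table")
        sub = tracks[(tracks["frame"] == frame) & tracks["cell_id"].isin(alive)]
        positions = {
            r.cell_id: (r.x_um, r.y_um) for r in sub.itertuples(index=False)
        }
    else:
        raise ValueError(f"unknown position_mode {position_mode!r}")

    segment_labels = None
    if use_segments and tracks is not None and "segment_label" in tracks.columns:
        first = tracks.loc[tracks.groupby("cell_id")["frame"].idxmin()]
        segment_labels = dict(zip(first["cell_id"], first["segment_label"]))

    if len(positions) < 2:
        logger.warning("frame %d has fewer than 2 alive cells; empty graph", frame)
        return NeighborGraph(
            frame=frame,
            nodes=frozenset(positions),
            edges=frozenset(),
            positions=dict(positions),
            max_dist_um=max_dist_um or float("inf"),
        )

    initial_positions = {
        cid: (fates.at[cid, "x0_um"], fates.at[cid, "y0_um"]) for cid in fates.index
    }
    cutoff = resolve_max_dist(initial_positions, max_dist_um, max_dist_factor)
    edges = prune_edges(delaunay_edges(positions), positions, cutoff, segment_labels)
    return NeighborGraph(
        frame=frame,
        nodes=frozenset(positions),
        edges=frozenset(edges),
        positions=dict(positions),
        max_dist_um=cutoff,
    )


class FrameGraphProvider:
    """Caching ``frame -> NeighborGraph`` factory with one resolved cutoff."""

    def __init__(
        self,
        tracks: pd.DataFrame | None,
        fates: pd.DataFrame,
        max_dist_um: float | None = None,
        max_dist_factor: float = DEFAULT_MAX_DIST_FACTOR,
        position_mode: str = "at_frame",
        use_segments: bool = False,
    ):
        self.tracks = tracks
        self.fates = fates
        self.position_mode = position_mode
        self.use_segments = use_segments
        initial = {
            cid: (fates.at[cid, "x0_um"], fates.at[cid, "y0_um"]) for cid in fates.index
        }
        self.max_dist_um = (
            resolve_max_dist(initial, max_dist_um, max_dist_factor)
            if len(initial) >= 3
            else (max_dist_um or float("inf"))
        )
        self._cache: dict[int, NeighborGraph] = {}

    def __call__(self, frame: int) -> NeighborGraph:
        if frame not in self._cache:
            self._cache[frame] = build_frame_graph(
                self.tracks,
                self.fates,
                frame,
                max_dist_um=self.max_dist_um,
                position_mode=self.position_mode,
                use_segments=self.use_segments,
            )
        return self._cache[frame]


def static_initial_graph(
    fates: pd.DataFrame,
    max_dist_um: float | None = None,
    max_dist_factor: float = DEFAULT_MAX_DIST_FACTOR,
) -> NeighborGraph:
    """Single triangulation over *all* cells at their first-frame positions.

    This is the graph of the randomized-removal null: positions are frozen
    at the first frame and the adjacency is computed once, over every cell.
    """
    positions = {
        cid: (fates.at[cid, "x0_um"], fates.at[cid, "y0_um"]) for cid in fates.index
    }
    if len(positions) < 2:
        return NeighborGraph(0, frozenset(positions), frozenset(), dict(positions))
    cutoff = resolve_max_dist(positions, max_dist_um, max_dist_factor)
    edges = prune_edges(delaunay_edges(positions), positions, cutoff)
    return NeighborGraph(
        frame=0,
        nodes=frozenset(positions),
        edges=frozenset(edges),
        positions=dict(positions),
        max_dist_um=cutoff,
    )


def edge_index_arrays(
    graph: NeighborGraph, id_order: Iterable[Hashable]
) -> tuple[np.ndarray, np.ndarray]:
    """Graph edges as parallel integer-index arrays over ``id_order``
    (the fast-path representation used by the null simulation)."""
    idx = {cid: k for k, cid in enumerate(id_order)}
    if not graph.edges:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ia, ib = zip(*[(idx[a], idx[b]) for a, b in graph.edges])
    return np.asarray(ia, dtype=np.int64), np.asarray(ib, dtype=np.int64)
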