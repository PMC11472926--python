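"""Concurrent-death pairs, cluster merging, and elimination dynamics.

Two adjacent cells whose tracks end at the same frame or one frame apart
(the 10-min frame interval serving as the margin for nuclear breakdown)
form a *concurrent-death pair*.  Pairs sharing a cell are interconnected;
the connected components of the pair graph are death clusters, and
components of three or more cells are counted as *clustered* apoptosis.
Isolated concurrent pairs (size 2) are reported but not counted as
clustered by default.  Candidate clusters may be accepted or rejected by a
curation file, mirroring visual inspection of the raw movies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Hashable, Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import track_io
from .neighbor_graph import NeighborGraph

logger = logging.getLogger(__name__)

DEFAULT_MARGIN_FRAMES = 1
DEFAULT_MIN_CLUSTER_SIZE = 3


class DeathPair(NamedTuple):
    cell_a: Hashable
    cell_b: Hashable
    frame_a: int
    frame_b: int
    edge_length_um: float


@dataclass(frozen=True)
class DeathCluster:
    """Connected component of the concurrent-death pair graph."""

    cluster_id: int
    members: frozenset
    death_frames: Mapping[Hashable, int]
    onset_frame: int
    clustered: bool  # size >= min_cluster_size
    accepted: bool = True

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PhaseWindows:
    """Early/late elimination phases in hours APF, half-open [start, end)."""

    early: tuple[float, float] = (20.0, 25.0)
    late: tuple[float, float] = (25.0, 40.0)

    def __post_init__(self):
        if not (self.early[0] < self.early[1] <= self.late[0] < self.late[1]):
            raise ValueError("phase windows must be ordered and disjoint")

    def items(self):
        return (("early", self.early), ("late", self.late))


GraphSource = NeighborGraph | Mapping[int, NeighborGraph] | Callable[[int], NeighborGraph]


def _graph_at(graphs: GraphSource, frame: int) -> NeighborGraph:
    if isinstance(graphs, NeighborGraph):
        return graphs
    if callable(graphs):
        return graphs(frame)
    return graphs[frame]


def find_death_pairs(
    fates: pd.DataFrame,
    graphs: GraphSource,
    margin_frames: int = DEFAULT_MARGIN_FRAMES,
) -> list[DeathPair]:
    """All unordered pairs of dead cells that die within ``margin_frames``
    of each other and are graph-adjacent at the last frame both are alive
    (the earlier of the two death frames).  Censored cells never pair.

    ``graphs`` may be a single static graph, a frame-indexed mapping, or a
    callable ``frame -> NeighborGraph``.
    """
    dead = fates[~fates["censored"]]
    order = dead["last_frame"].sort_values(kind="stable")
    ids = list(order.index)
    frames = order.to_numpy(int)
    pairs: list[DeathPair] = []
    for i in range(len(ids)):
        j = i + 1
        while j < len(ids) and frames[j] - frames[i] <= margin_frames:
            g = _graph_at(graphs, int(frames[i]))
            if g.has_edge(ids[i], ids[j]):
                a, b = ids[i], ids[j]
                pairs.append(
                    DeathPair(a, b, int(frames[i]), int(frames[j]), g.edge_length_um(a, b))
                )
            j += 1
    return pairs


def merge_pairs(
    pairs: Iterable[DeathPair],
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> list[DeathCluster]:
    """Connected components of the pair graph ('if one cell ID of a pair is
    found in another pair, the pairs are interconnected').  Components with
    ``size >= min_cluster_size`` are flagged ``clustered``; smaller ones
    (isolated concurrent pairs) are retained with ``clustered=False``."""
    g = nx.Graph()
    death_frame: dict[Hashable, int] = {}
    for p in pairs:
        g.add_edge(p.cell_a, p.cell_b)
        death_frame[p.cell_a] = p.frame_a
        death_frame[p.cell_b] = p.frame_b
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (min(death_frame[m] for m in c), sorted(map(str, c))))
    clusters = []
    for k, members in enumerate(comps):
        frames = {m: death_frame[m] for m in members}
        clusters.append(
            DeathCluster(
                cluster_id=k,
                members=members,
                death_frames=frames,
                onset_frame=min(frames.values()),
                clustered=len(members) >= min_cluster_size,
            )
        )
    return clusters


def apply_curation(
    clusters: Sequence[DeathCluster],
    curation: Mapping[int, bool] | str | None = None,
) -> list[DeathCluster]:
    """Set the ``accepted`` flag from a curation table (cluster_id ->
    accept).  ``curation`` may be a mapping or a path to a two-column
    delimited file (``cluster_id``, ``accept|reject``); with no curation
    every cluster is accepted.  Unknown ids trigger a warning."""
    if curation is None:
        return [replace(c, accepted=True) for c in clusters]
    if not isinstance(curation, Mapping):
        tbl = pd.read_csv(curation, sep=None, engine="python")
        tbl.columns = [c.strip().lower() for c in tbl.columns]
        decisions = {
            int(r["cluster_id"]): str(r.iloc[1]).strip().lower() in ("accept", "true", "1")
            for _, r in tbl.iterrows()
        }
    else:
        decisions = {int(k): bool(v) for k, v in curation.items()}
    known = {c.cluster_id for c in clusters}
    for cid in decisions:
        if cid not in known:
            logger.warning("curation refers to unknown cluster id %d", cid)
    return [replace(c, accepted=decisions.get(c.cluster_id, True)) for c in clusters]


def clustered_cells(clusters: Iterable[DeathCluster]) -> int:
    """Total number of cells dying in accepted clustered components."""
    return sum(c.size for c in clusters if c.clustered and c.accepted)


def _frame_to_hAPF(frame, frame_interval_min: float, start_hAPF: float):
    return start_hAPF + np.asarray(frame, float) * frame_interval_min / 60.0


def cluster_timecourse(
    clusters: Sequence[DeathCluster],
    frame_interval_min: float = 10.0,
    start_hAPF: float = 20.0,
    bin_h: float = 1.0,
    end_hAPF: float | None = None,
) -> pd.Series:
    """Cells dying in accepted clustered components per time bin, binned by
    cluster onset (hAPF); the per-hour counting of the cluster timecourse
    figures."""
    onsets, sizes = [], []
    for c in clusters:
        if c.clustered and c.accepted:
            onsets.append(_frame_to_hAPF(c.onset_frame, frame_interval_min, start_hAPF))
            sizes.append(c.size)
    if end_hAPF is None:
        end_hAPF = max(onsets) + bin_h if onsets else start_hAPF + bin_h
    edges = np.arange(start_hAPF, end_hAPF + bin_h, bin_h)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for t, s in zip(onsets, sizes):
        k = int(np.clip(np.floor((t - start_hAPF) / bin_h), 0, len(counts) - 1))
        counts[k] += s
    return pd.Series(counts, index=pd.Index(edges[:-1], name="bin_start_hAPF"),
                     name="clustered_cells")


def clustered_proportion(
    clusters: Sequence[DeathCluster],
    fates: pd.DataFrame,
    phases: PhaseWindows = PhaseWindows(),
    frame_interval_min: float = 10.0,
    start_hAPF: float = 20.0,
) -> dict[str, float]:
    """Per phase: cells dying as members of accepted clustered components
    (cluster onset in the phase) / all deaths in the phase.  A phase with
    zero deaths yields NaN (missing), not 0."""
    dead_t = _frame_to_hAPF(
        fates.loc[~fates["censored"], "last_frame"], frame_interval_min, start_hAPF
    )
    out: dict[str, float] = {}
    for name, (t0, t1) in phases.items():
        n_deaths = int(((dead_t >= t0) & (dead_t < t1)).sum())
        if n_deaths == 0:
            logger.warning("phase %r has zero deaths; proportion undefined", name)
            out[name] = float("nan")
            continue
        n_clustered = sum(
            c.size
            for c in clusters
            if c.clustered
            and c.accepted
            and t0 <= _frame_to_hAPF(c.onset_frame, frame_interval_min, start_hAPF) < t1
        )
        out[name] = n_clustered / n_deaths
    return out


def elimination_curve(
    fates: pd.DataFrame,
    frame_interval_min: float = 10.0,
    start_hAPF: float = 20.0,
    reference_time_hAPF: float = 20.0,
) -> pd.DataFrame:
    """Percent of cells remaining over time, normalized to the count at the
    reference time (100% there by construction; non-increasing afterwards
    when every track starts at the first frame)."""
    end_frame = int(fates.attrs.get("movie_end_frame", fates["last_frame"].max()))
    frames = np.arange(end_frame + 1)
    first = fates["first_frame"].to_numpy(int)
    last = fates["last_frame"].to_numpy(int)
    alive = ((first[None, :] <= frames[:, None]) & (frames[:, None] <= last[None, :])).sum(axis=1)
    ref_frame = int(round((reference_time_hAPF - start_hAPF) * 60.0 / frame_interval_min))
    if not (0 <= ref_frame <= end_frame):
        raise ValueError("reference time outside the movie")
    n0 = alive[ref_frame]
    if n0 == 0:
        raise ValueError("zero cells at the reference time")
    return pd.DataFrame(
        {
            "frame": frames,
            "t_hAPF": _frame_to_hAPF(frames, frame_interval_min, start_hAPF),
            "n_cells": alive,
            "percent_remaining": 100.0 * alive / n0,
        }
    )


def clusters_to_table(clusters: Sequence[DeathCluster],
                      frame_interval_min: float = 10.0,
                      start_hAPF: float = 20.0) -> pd.DataFrame:
    """Cluster report: one row per component."""
    rows = [
        dict(
            cluster_id=c.cluster_id,
            size=c.size,
            onset_frame=c.onset_frame,
            onset_hAPF=float(_frame_to_hAPF(c.onset_frame, frame_interval_min, start_hAPF)),
            clustered=c.clustered,
            accepted=c.accepted,
            members=";".join(sorted(map(str, c.members))),
        )
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "size", "onset_frame", "onset_hAPF",
                 "clustered", "accepted", "members"],
    )


# ---------------------------------------------------------------------------
# Fast numeric path (used heavily by the randomized-removal null)

def concurrent_components_fast(
    death_frames: np.ndarray,
    edges_a: np.ndarray,
    edges_b: np.ndarray,
    margin_frames: int = DEFAULT_MARGIN_FRAMES,
) -> tuple[np.ndarray, np.ndarray]:
    """Sizes and onset frames of concurrent-death components on a static
    graph, vectorized.

    ``death_frames`` holds one death frame per cell (NaN = censored);
    ``edges_a``/``edges_b`` are integer endpoint arrays of the static
    adjacency.  Returns ``(sizes, onsets)`` for every component with at
    least one concurrent pair (size >= 2); equivalent to
    ``merge_pairs(find_death_pairs(...))`` on a static graph.
    """
    df = np.asarray(death_frames, float)
    n = df.size
    both_dead = np.isfinite(df[edges_a]) & np.isfinite(df[edges_b])
    concurrent = both_dead & (np.abs(df[edges_a] - df[edges_b]) <= margin_frames)
    ea, eb = edges_a[concurrent], edges_b[concurrent]
    if ea.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    adj = coo_matrix((np.ones(ea.size), (ea, eb)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    paired = np.zeros(n, dtype=bool)
    paired[ea] = True
    paired[eb] = True
    sizes = np.bincount(labels[paired], minlength=n_comp)
    comp_ids = np.flatnonzero(sizes >= 2)
    onsets = np.full(n_comp, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(onsets, labels[paired], df[paired].astype(np.int64))
    return sizes[comp_ids].astype(np.int64), onsets[comp_ids]


def clustered_cell_count_fast(
    death_frames: np.ndarray,
    edges_a: np.ndarray,
    edges_b: np.ndarray,
    margin_frames: int = DEFAULT_MARGIN_FRAMES,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> int:
    """Total cells in clustered components (size >= min_cluster_size)."""
    sizes, _ = concurrent_components_fast(death_frames, edges_a, edges_b, margin_frames)
    return int(sizes[sizes >= min_cluster_size].sum())


def static_death_frames(fates: pd.DataFrame) -> np.ndarray:
    """Death-frame vector aligned with ``fates.index`` (NaN = censored)."""
    return track_io.death_frames(fates).to_numpy(float)
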