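"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths (scipy.spatial,
networkx, scipy.stats): Delaunay membership by empty-circumcircle
enumeration over all triples, concurrent-death pairs by an all-pairs scan,
components by hand-rolled union-find, and the KS/Mann-Whitney statistics by
direct definition.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# Delaunay by empty circumcircle

def circumcircle(p1, p2, p3):
    """Centre and radius of the circle through three points, or None if
    (near-)collinear."""
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    scale = max(abs(ax), abs(ay), abs(bx), abs(by), abs(cx), abs(cy), 1.0)
    if abs(d) < 1e-12 * scale * scale:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    r = float(np.hypot(ax - ux, ay - uy))
    return (ux, uy), r


def delaunay_edges_bruteforce(positions, cocircular_tol=1e-9):
    """Union of edges of all triangles whose circumcircle contains no other
    point.  Returns None when the configuration is degenerate at the given
    tolerance (a point within ``cocircular_tol`` of some circumcircle, or
    all points collinear), so callers can resample.
    """
    ids = list(positions.keys())
    n = len(ids)
    if n < 3:
        return {tuple(sorted(ids, key=str))} if n == 2 else set()
    edges = set()
    any_triangle = False
    for a, b, c in combinations(ids, 3):
        cc = circumcircle(positions[a], positions[b], positions[c])
        if cc is None:
            continue
        (ux, uy), r = cc
        empty = True
        for other in ids:
            if other in (a, b, c):
                continue
            dist = float(np.hypot(positions[other][0] - ux, positions[other][1] - uy))
            if abs(dist - r) < cocircular_tol * max(r, 1.0):
                return None  # cocircular within tolerance: degenerate
            if dist < r:
                empty = False
                break
        if empty:
            any_triangle = True
            for u, v in ((a, b), (b, c), (a, c)):
                edges.add(tuple(sorted((u, v), key=str)))
    if not any_triangle:
        return None  # fully collinear; path semantics tested separately
    return edges


# ---------------------------------------------------------------------------
# Concurrent-death pairs / components

def death_pairs_bruteforce(fates, graph_at, margin_frames=1):
    """All-pairs scan: dead cells, time margin, adjacency at the earlier
    death frame.  ``graph_at`` maps frame -> object with ``has_edge``."""
    dead = {cid: int(fates.at[cid, "last_frame"])
            for cid in fates.index if not fates.at[cid, "censored"]}
    pairs = set()
    for a, b in combinations(dead, 2):
        if abs(dead[a] - dead[b]) <= margin_frames:
            g = graph_at(min(dead[a], dead[b]))
            if g.has_edge(a, b):
                pairs.add(tuple(sorted((a, b), key=str)))
    return pairs


def components_bruteforce(pairs):
    """Connected components of a pair set via union-find."""
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for x in parent:
        comps.setdefault(find(x), set()).add(x)
    return {frozenset(c) for c in comps.values()}


# ---------------------------------------------------------------------------
# Statistics by definition

def ks_statistic_bruteforce(a, b):
    """max_x |ECDF_a(x) - ECDF_b(x)| over all sample points."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    xs = np.concatenate([a, b])
    d = 0.0
    for x in xs:
        d = max(d, abs(np.mean(a <= x) - np.mean(b <= x)))
    return float(d)


def mw_u_bruteforce(a, b):
    """U of the first sample: #(a_i > b_j) + 0.5 #(a_i == b_j)."""
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u
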