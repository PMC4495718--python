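"""Independent brute-force oracles used to check the implementation.

These deliberately use naive algorithms (exhaustive enumeration, O(n^3)
geometry, grid search) and share no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_hull_area(points: np.ndarray) -> float:
    """O(n^3) convex hull: an edge (i, j) is on the hull iff all other
    points lie on one side; area by the shoelace formula on the ordered
    hull vertices."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    hull_vertices = set()
    for i, j in itertools.permutations(range(n), 2):
        a, b = pts[i], pts[j]
        d = b - a
        cross = d[0] * (pts[:, 1] - a[1]) - d[1] * (pts[:, 0] - a[0])
        others = np.delete(cross, [i, j])
        if np.all(others >= -1e-9) or np.all(others <= 1e-9):
            hull_vertices.add(i)
            hull_vertices.add(j)
    if len(hull_vertices) < 3:
        return 0.0
    verts = pts[sorted(hull_vertices)]
    centroid = verts.mean(axis=0)
    order = np.argsort(np.arctan2(verts[:, 1] - centroid[1], verts[:, 0] - centroid[0]))
    v = verts[order]
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def brute_force_neighbor_counts(points: np.ndarray, radius: float) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    counts = np.zeros(len(pts), dtype=int)
    for i in range(len(pts)):
        for j in range(len(pts)):
            if i != j and math.dist(pts[i], pts[j]) <= radius:
                counts[i] += 1
    return counts


def union_find_partition(nodes, hyperedges):
    """Chain partition via union-find, independent of networkx."""
    parent = {n: n for n in nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for members in hyperedges:
        members = sorted(members, key=str)
        for m in members[1:]:
            ra, rb = find(members[0]), find(m)
            if ra != rb:
                parent[rb] = ra
    groups: dict = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return sorted((frozenset(g) for g in groups.values()),
                  key=lambda g: str(min(g, key=str)))


def brute_force_minimax_center(points: np.ndarray) -> np.ndarray:
    """Exact minimax (1-center) by exhaustive candidate enumeration.

    The smallest enclosing circle is determined by two points (diameter)
    or three points (circumcircle); enumerate every candidate and keep the
    enclosing one with the smallest maximum distance."""
    pts = np.asarray(points, dtype=float)
    if len(pts) == 1:
        return pts[0].copy()

    def maxdist(c):
        return float(np.max(np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])))

    best = None
    for i, j in itertools.combinations(range(len(pts)), 2):
        c = (pts[i] + pts[j]) / 2
        m = maxdist(c)
        if m <= np.linalg.norm(pts[i] - pts[j]) / 2 + 1e-9:
            if best is None or m < best[0]:
                best = (m, c)
    for i, j, k in itertools.combinations(range(len(pts)), 3):
        ax, ay = pts[i]
        bx, by = pts[j]
        cx, cy = pts[k]
        d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            continue
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
              + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
              + (cx**2 + cy**2) * (bx - ax)) / d
        c = np.array([ux, uy])
        r = np.linalg.norm(pts[i] - c)
        m = maxdist(c)
        if m <= r + 1e-9 and (best is None or m < best[0]):
            best = (m, c)
    return best[1]


def exact_rank_sum_p(x, y) -> float:
    """Two-sided exact permutation p-value of the Mann-Whitney U."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    nx = len(x)

    def u_of(sample_x, sample_y):
        u = 0.0
        for a in sample_x:
            for b in sample_y:
                u += (a > b) + 0.5 * (a == b)
        return u

    mu = nx * len(y) / 2.0
    dev = abs(u_of(x, y) - mu)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), nx):
        comb = set(comb)
        gx = [pooled[i] for i in comb]
        gy = [pooled[i] for i in range(len(pooled)) if i not in comb]
        total += 1
        if abs(u_of(gx, gy) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total
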