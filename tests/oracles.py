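"""Independent brute-force oracles for the geometric descriptors.

Everything here is written as plain O(n²) Python loops, deliberately
avoiding the vectorized/indexed code paths of the package, so tests can
compare the two routes. The hull oracle recomputes volume and area from the
hull's facet simplices by explicit triangle/tetrahedron sums rather than
trusting the library's volume/area attributes.
"""

from __future__ import annotations

import math

import numpy as np


def dist(a, b) -> float:
    return math.sqrt(sum((float(x) - float(y)) ** 2 for x, y in zip(a, b)))


def brute_loop_anchor_mean(loop_ca, anchor_ca) -> float:
    c = [(anchor_ca[0][i] + anchor_ca[1][i]) / 2.0 for i in range(3)]
    return sum(dist(p, c) for p in loop_ca) / len(loop_ca)


def brute_loop_ref_min(loop_ca, reference_centroid) -> float:
    return min(dist(p, reference_centroid) for p in loop_ca)


def brute_ach_ach_dist(anchor_ca) -> float:
    return dist(anchor_ca[0], anchor_ca[1])


def brute_loop_max_distance(loop_ca) -> float:
    best = 0.0
    for i in range(len(loop_ca)):
        for j in range(i + 1, len(loop_ca)):
            best = max(best, dist(loop_ca[i], loop_ca[j]))
    return best


def brute_every_k_mean(loop_ca, k: int) -> float:
    ds = [dist(loop_ca[i], loop_ca[i + k]) for i in range(len(loop_ca) - k)]
    return sum(ds) / len(ds)


def brute_max_cons_bb(backbone) -> float:
    """Max consecutive bonded backbone distance: N–Cα, Cα–C, C–N(next)."""
    lengths = []
    have_nc = any(n is not None or c is not None for n, _, c in backbone)
    if not have_nc:
        for i in range(len(backbone) - 1):
            lengths.append(dist(backbone[i][1], backbone[i + 1][1]))
        return max(lengths)
    for i, (n, ca, c) in enumerate(backbone):
        if n is not None:
            lengths.append(dist(n, ca))
        if c is not None:
            lengths.append(dist(ca, c))
            if i + 1 < len(backbone) and backbone[i + 1][0] is not None:
                lengths.append(dist(c, backbone[i + 1][0]))
    return max(lengths)


def brute_min_interset(a, b) -> float:
    best = float("inf")
    for p in a:
        for q in b:
            best = min(best, dist(p, q))
    return best


def brute_hull_v2a(points) -> float:
    """Hull volume/area recomputed facet-by-facet from the hull simplices."""
    from scipy.spatial import ConvexHull

    points = np.asarray(points, dtype=float)
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 3:
        return 0.0
    hull = ConvexHull(points)
    interior = points[hull.vertices].mean(axis=0)
    area = 0.0
    volume = 0.0
    for simplex in hull.simplices:
        a, b, c = points[simplex]
        cross = np.cross(b - a, c - a)
        tri_area = 0.5 * float(np.linalg.norm(cross))
        area += tri_area
        # facet tetrahedra around an interior point tile a convex hull, so
        # each one's unsigned volume contributes directly
        volume += abs(float(np.dot(np.cross(b - interior, c - interior), a - interior))) / 6.0
    return volume / area


def brute_descriptors(sel) -> dict:
    """All nine descriptors of a LoopSelection via the brute-force routes."""
    out = {
        "loop_anchor_mean": brute_loop_anchor_mean(sel.loop_ca, sel.anchor_ca),
        "loop_ref_min": brute_loop_ref_min(sel.loop_ca, sel.reference_centroid),
        "ach_ach_dist": brute_ach_ach_dist(sel.anchor_ca),
        "loop_max_distance": brute_loop_max_distance(sel.loop_ca),
        "every_two_mean": brute_every_k_mean(sel.loop_ca, 2),
        "every_three_mean": brute_every_k_mean(sel.loop_ca, 3)
        if len(sel.loop_ca) >= 4
        else float("nan"),
        "loop_max_cons_distance_bb": brute_max_cons_bb(sel.loop_backbone),
        "loop_prot_sh": brute_min_interset(sel.loop_heavy, sel.protein_heavy)
        if len(sel.protein_heavy)
        else float("nan"),
        "loop_prot_v2a": brute_hull_v2a(sel.loop_heavy)
        if len(sel.loop_heavy) >= 4
        else float("nan"),
    }
    return out
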