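"""Nine geometry-based loop shape descriptors.

Given a resolved loop selection (Cα trace, backbone, heavy atoms, anchors
and a reference centroid), this module computes a fixed set of nine
descriptors of the loop's shape, all in Å:

==========================  ==================================================
loop_anchor_mean            mean distance from loop Cα atoms to the centroid
                            (midpoint) of the two anchor Cα atoms
loop_ref_min                minimum distance from loop Cα atoms to the
                            reference-residue Cα centroid (e.g. an
                            active-site Trp)
ach_ach_dist                distance between the two anchor Cα atoms
loop_max_distance           maximum pairwise distance between loop Cα atoms
every_two_mean              mean Cα(i)–Cα(i+2) distance along the loop
every_three_mean            mean Cα(i)–Cα(i+3) distance along the loop
loop_max_cons_distance_bb   maximum distance between consecutive bonded
                            backbone atoms (N–Cα, Cα–C, C–N of next residue)
loop_prot_sh                minimum distance between loop heavy atoms and
                            non-loop protein heavy atoms
loop_prot_v2a               convex-hull volume / surface-area ratio of the
                            loop heavy atoms (a sphericity proxy)
==========================  ==================================================

The first four ("arch-shape" parameters) describe the loop's overall arc and
drive the flexibility classifier and state analysis; the remainder capture
local chain geometry and the loop's packing against the rest of the protein.
Descriptors that are undefined for a given selection (no protein context, or
a loop too short for the i..i+3 ladder) are reported as NaN, never silently
zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import pdist

from .errors import InputError
from .structure_io import ConformerEnsemble, LoopSelection, LoopSpec, ScoreRecord, resolve_loop

#: Canonical descriptor column order, used everywhere downstream.
DESCRIPTOR_NAMES = (
    "loop_anchor_mean",
    "loop_ref_min",
    "ach_ach_dist",
    "loop_max_distance",
    "every_two_mean",
    "every_three_mean",
    "loop_max_cons_distance_bb",
    "loop_prot_sh",
    "loop_prot_v2a",
)

#: The four arch-shape parameters used for flexibility and state analysis.
ARCH_PARAMETERS = (
    "loop_anchor_mean",
    "loop_ref_min",
    "ach_ach_dist",
    "loop_max_distance",
)

SCORE_NAMES = ("dope", "soap")


@dataclass
class DescriptorVector:
    """The nine shape descriptors of one conformer (Å; NaN = undefined)."""

    loop_anchor_mean: float
    loop_ref_min: float
    ach_ach_dist: float
    loop_max_distance: float
    every_two_mean: float
    every_three_mean: float
    loop_max_cons_distance_bb: float
    loop_prot_sh: float
    loop_prot_v2a: float
    model_id: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in DESCRIPTOR_NAMES], dtype=float)

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "model_id":
                continue
            v = getattr(self, f.name)
            if np.isfinite(v) and v < -1e-12:
                raise InputError(f"descriptor {f.name} is negative ({v})")


def convex_hull_v2a(points: np.ndarray) -> float:
    """Convex-hull volume-to-surface-area ratio of a 3-D point set, in Å.

    Degenerate sets (all points coplanar or collinear, hull rank < 3) return
    0.0 with a warning. Fewer than 4 points is an error.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if points.shape[0] < 4:
        raise InputError(f"convex hull needs at least 4 points, got {points.shape[0]}")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 3:
        warnings.warn("degenerate (rank < 3) point set; volume/area ratio set to 0", stacklevel=2)
        return 0.0
    try:
        hull = ConvexHull(points)
    except QhullError:
        warnings.warn("degenerate convex hull; volume/area ratio set to 0", stacklevel=2)
        return 0.0
    return float(hull.volume / hull.area)


def min_interset_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum Euclidean distance between two point sets (KD-tree backed)."""
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if a.size == 0 or b.size == 0:
        raise InputError("both point sets must be non-empty")
    tree = cKDTree(b)
    dists, _ = tree.query(a, k=1)
    return float(np.min(dists))


def _backbone_bond_lengths(
    backbone: Sequence[tuple[Optional[np.ndarray], np.ndarray, Optional[np.ndarray]]],
) -> list[float]:
    """Consecutive bonded distances along the loop backbone.

    Uses N(i)–Cα(i), Cα(i)–C(i) and C(i)–N(i+1) where those atoms exist; a
    pure Cα trace falls back to consecutive Cα–Cα distances.
    """
    have_nc = any(n is not None or c is not None for n, _, c in backbone)
    lengths: list[float] = []
    if not have_nc:
        cas = np.array([ca for _, ca, _ in backbone])
        return list(np.linalg.norm(np.diff(cas, axis=0), axis=1))
    for i, (n, ca, c) in enumerate(backbone):
        if n is not None:
            lengths.append(float(np.linalg.norm(ca - n)))
        if c is not None:
            lengths.append(float(np.linalg.norm(c - ca)))
            nxt = backbone[i + 1][0] if i + 1 < len(backbone) else None
            if nxt is not None:
                lengths.append(float(np.linalg.norm(nxt - c)))
    return lengths


def compute_descriptors(
    sel: LoopSelection,
    model_id: str = "",
    allow_short: bool = False,
    ca_only: bool = False,
    arch_only: bool = False,
) -> DescriptorVector:
    """Compute the nine shape descriptors for one resolved loop selection.

    ``ca_only`` restricts the heavy-atom descriptors (loop_prot_sh,
    loop_prot_v2a) to Cα atoms — intended for Cα-trace fixtures. Loops
    shorter than 4 residues have no i..i+3 ladder; that raises unless
    ``allow_short`` is set (then every_three_mean is NaN). ``arch_only``
    computes just the four arch-shape parameters (the rest NaN) — the fast
    path for long trajectory series.
    """
    ca = sel.loop_ca
    n = ca.shape[0]
    if n < 4 and not allow_short:
        raise InputError(
            f"loop of {n} residues has no i..i+3 distances; pass allow_short to get NaN"
        )

    anchor_centroid = sel.anchor_ca.mean(axis=0)
    loop_anchor_mean = float(np.mean(np.linalg.norm(ca - anchor_centroid, axis=1)))
    loop_ref_min = float(np.min(np.linalg.norm(ca - sel.reference_centroid, axis=1)))
    ach_ach_dist = float(np.linalg.norm(sel.anchor_ca[0] - sel.anchor_ca[1]))
    loop_max_distance = float(np.max(pdist(ca))) if n >= 2 else 0.0
    if arch_only:
        nan = float("nan")
        return DescriptorVector(
            loop_anchor_mean=loop_anchor_mean,
            loop_ref_min=loop_ref_min,
            ach_ach_dist=ach_ach_dist,
            loop_max_distance=loop_max_distance,
            every_two_mean=nan,
            every_three_mean=nan,
            loop_max_cons_distance_bb=nan,
            loop_prot_sh=nan,
            loop_prot_v2a=nan,
            model_id=model_id,
        )
    every_two_mean = float(np.mean(np.linalg.norm(ca[2:] - ca[:-2], axis=1)))
    every_three_mean = (
        float(np.mean(np.linalg.norm(ca[3:] - ca[:-3], axis=1))) if n >= 4 else float("nan")
    )

    bond_lengths = _backbone_bond_lengths(sel.loop_backbone)
    loop_max_cons_distance_bb = float(np.max(bond_lengths)) if bond_lengths else float("nan")

    loop_pts = ca if ca_only else sel.loop_heavy
    prot_pts = sel.protein_heavy
    if prot_pts.shape[0] == 0:
        loop_prot_sh = float("nan")
    else:
        loop_prot_sh = min_interset_distance(loop_pts, prot_pts)

    if loop_pts.shape[0] >= 4:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loop_prot_v2a = convex_hull_v2a(loop_pts)
    else:
        loop_prot_v2a = float("nan")

    return DescriptorVector(
        loop_anchor_mean=loop_anchor_mean,
        loop_ref_min=loop_ref_min,
        ach_ach_dist=ach_ach_dist,
        loop_max_distance=loop_max_distance,
        every_two_mean=every_two_mean,
        every_three_mean=every_three_mean,
        loop_max_cons_distance_bb=loop_max_cons_distance_bb,
        loop_prot_sh=loop_prot_sh,
        loop_prot_v2a=loop_prot_v2a,
        model_id=model_id,
    )


def descriptor_matrix(
    ensemble: ConformerEnsemble,
    spec: LoopSpec,
    scores: Optional[Sequence[ScoreRecord]] = None,
    allow_short: bool = False,
    ca_only: bool = False,
) -> pd.DataFrame:
    """Descriptor matrix over an ensemble: one row per model, in order.

    Columns are the nine descriptors in canonical order, plus ``dope`` and
    ``soap`` when score records are supplied. The index holds model ids.
    Every model must resolve under ``spec``; when scores are given, every
    model id must have a record.
    """
    rows, ids = [], []
    for model in ensemble.models:
        sel = resolve_loop(spec, model)
        vec = compute_descriptors(
            sel, model_id=str(model.model_id), allow_short=allow_short, ca_only=ca_only
        )
        rows.append(vec.as_array())
        ids.append(str(model.model_id))
    matrix = pd.DataFrame(rows, index=pd.Index(ids, name="model_id"), columns=DESCRIPTOR_NAMES)

    if scores is not None:
        by_id = {str(r.model_id): r for r in scores}
        missing = [mid for mid in ids if mid not in by_id]
        if missing:
            raise InputError(f"no score record for model id(s) {missing}")
        matrix["dope"] = [by_id[mid].dope for mid in ids]
        matrix["soap"] = [by_id[mid].soap for mid in ids]
    return matrix
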