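"""Synthetic loop-conformer ensembles and state-switching frame series.

The generator emulates, at Cα-trace + pseudo-backbone resolution, the two
situations the descriptor pipeline is built to distinguish:

* a *static* loop, whose overall arch is held in place by its surroundings
  and whose models vary mainly near the attachment points (anchor-proximal
  positional jitter, ``sigma_anchor``);
* a *flexible* loop, free to swing its arch plane about the anchor–anchor
  axis (``sigma_arch``, radians) and to widen/tighten its arc
  (``sigma_radial``).

Each model's loop Cα atoms lie on a circular arc: the two anchors sit at
(0, 0, 0) and (anchor_separation, 0, 0), and the arc through them is solved
so consecutive Cα–Cα chords equal ``ca_spacing`` exactly. Radial jitter
re-solves the arc at the scaled radius (chord lengths stay exact), so the
loop endpoints drift off the fixed anchors the way a hinging loop would.
Pseudo N and C backbone atoms are emitted at ±1.2 Å along the local chain
tangent from each Cα, a reference residue sits 8 Å off the arc plane on the
"closed" side (negative z), and an optional hemispherical shell of
pseudo-protein atoms provides non-loop context for the loop–protein
descriptors.

Pseudo DOPE/SOAP scores are an explicit toy: mean loop-Cα distance to the
protein-context centroid plus small Gaussian noise, so "lowest DOPE"
prefers compact conformers. They exist only to exercise score columns.

All output is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InputError
from .states import STATE_PARAMETERS, FrameSeries
from .structure_io import Atom, ConformerEnsemble, LoopSpec, ScoreRecord, Structure

CHAIN = "A"
REFERENCE_RES_ID = 50
ANCHOR_START = 100
REF_OFFPLANE_Å = 8.0
BACKBONE_OFFSET_Å = 1.2
BACKBONE_PUCKER_Å = 0.25
SHELL_ATOMS = 60
SHELL_CLEARANCE_Å = 6.0


@dataclass
class EnsembleSpec:
    """Conditions for one synthetic loop-model ensemble."""

    n_models: int
    loop_length: int = 7
    anchor_separation: float = 10.0
    ca_spacing: float = 3.8
    sigma_anchor: float = 0.0  # Å, jitter on anchors and anchor-adjacent residues
    sigma_arch: float = 0.0  # rad, sd of arc-plane rotation about the anchor axis
    sigma_radial: float = 0.0  # fractional sd of the arc radius
    context: str = "none"  # "none" | "shell"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise InputError("n_models must be >= 2")
        if self.loop_length < 4:
            raise InputError("loop_length must be >= 4")
        if min(self.sigma_anchor, self.sigma_arch, self.sigma_radial) < 0:
            raise InputError("sigma values must be >= 0")
        if self.context not in ("none", "shell"):
            raise InputError(f"unknown context {self.context!r}")


def static_regime(n_models: int = 200, seed: int = 0, **overrides) -> EnsembleSpec:
    """A static loop: fixed arch, jitter concentrated at the anchors."""
    params = dict(sigma_arch=0.02, sigma_anchor=0.6, sigma_radial=0.0)
    params.update(overrides)
    return EnsembleSpec(n_models=n_models, seed=seed, **params)


def flexible_regime(n_models: int = 200, seed: int = 0, **overrides) -> EnsembleSpec:
    """A flexible loop: the arch swings and breathes, anchors stay put."""
    params = dict(sigma_arch=0.6, sigma_radial=0.15, sigma_anchor=0.0)
    params.update(overrides)
    return EnsembleSpec(n_models=n_models, seed=seed, **params)


@dataclass
class StateSeriesSpec:
    """Conditions for a synthetic state-switching trajectory."""

    n_frames: int
    state_fractions: Sequence[float]
    mean_dwell: float = 20.0  # frames
    arc_orientations: Optional[Sequence[float]] = None  # rad, one angle per state
    radial_scales: Optional[Sequence[float]] = None  # arc-radius factor per state
    noise: float = 0.15  # Å, per-axis coordinate jitter on loop atoms
    seed: int = 0
    loop_length: int = 7
    anchor_separation: float = 10.0
    ca_spacing: float = 3.8

    def __post_init__(self) -> None:
        self.state_fractions = [float(f) for f in self.state_fractions]
        if abs(sum(self.state_fractions) - 1.0) > 1e-9:
            raise InputError("state_fractions must sum to 1")
        if any(f < 0 for f in self.state_fractions):
            raise InputError("state_fractions must be non-negative")
        if self.mean_dwell < 1:
            raise InputError("mean_dwell must be >= 1 frame")
        k = len(self.state_fractions)
        if self.arc_orientations is None:
            # evenly spaced tilts from "closed" (towards the reference, -z)
            # to "open" (in-plane); for k=3: -1.2, -0.6, 0.0 rad
            self.arc_orientations = [-1.2 + 1.2 * i / max(k - 1, 1) for i in range(k)]
        self.arc_orientations = [float(a) for a in self.arc_orientations]
        if len(self.arc_orientations) != k:
            raise InputError("need one arc orientation per state")
        if self.radial_scales is None:
            # closed conformations are more compact, open more extended,
            # so the states also separate in loop_anchor_mean and
            # loop_max_distance (as trajectory data shows for real loops)
            self.radial_scales = [1.0 + 0.08 * (i - (k - 1) / 2.0) for i in range(k)]
        self.radial_scales = [float(r) for r in self.radial_scales]
        if len(self.radial_scales) != k:
            raise InputError("need one radial scale per state")
        if any(r <= 0 for r in self.radial_scales):
            raise InputError("radial scales must be positive")


@dataclass
class SyntheticEnsemble:
    """A generated ensemble plus the spec resolving it and pseudo scores."""

    ensemble: ConformerEnsemble
    loop_spec: LoopSpec
    scores: list[ScoreRecord]
    spec: EnsembleSpec


@dataclass
class SyntheticStateSeries:
    """A generated trajectory with its hidden ground-truth state labels."""

    ensemble: ConformerEnsemble
    loop_spec: LoopSpec
    series: FrameSeries
    true_labels: np.ndarray
    spec: StateSeriesSpec


# ---------------------------------------------------------------------------
# Arc geometry
# ---------------------------------------------------------------------------


def _solve_arc_angle(n_points: int, spacing: float, separation: float) -> float:
    """Per-chord subtended angle θ for an equal-chord arc.

    ``n_points`` points (endpoints included) with chord ``spacing`` between
    neighbours must span endpoint distance ``separation``. Infeasible
    geometries raise with the feasible range.
    """
    n_seg = n_points - 1
    if separation >= n_seg * spacing:
        raise InputError(
            f"anchor separation {separation} Å unreachable: {n_seg} chords of "
            f"{spacing} Å span at most {n_seg * spacing} Å; reduce separation "
            f"or increase loop_length/ca_spacing"
        )

    def endpoint_gap(theta: float) -> float:
        return spacing * math.sin(n_seg * theta / 2.0) / math.sin(theta / 2.0) - separation

    return float(brentq(endpoint_gap, 1e-9, 2.0 * math.pi / n_seg - 1e-9, xtol=1e-13))


def _arc_points(
    n_points: int, spacing: float, separation: float, radius: Optional[float] = None
) -> np.ndarray:
    """Equal-chord arc in the z = 0 plane, symmetric about x = separation/2.

    With ``radius`` None the arc passes exactly through (0,0,0) and
    (separation,0,0); with an explicit radius the chord lengths stay exact
    and the endpoints land symmetrically near those anchors. The arc always
    bulges towards +y.
    """
    n_seg = n_points - 1
    if radius is None:
        theta = _solve_arc_angle(n_points, spacing, separation)
        radius = spacing / (2.0 * math.sin(theta / 2.0))
    else:
        ratio = spacing / (2.0 * radius)
        if ratio >= 1.0:
            raise InputError(f"radius {radius} Å too small for chord {spacing} Å")
        theta = 2.0 * math.asin(ratio)
        if n_seg * theta >= 2.0 * math.pi:
            raise InputError(f"radius {radius} Å makes the arc self-overlap")
    span = n_seg * theta
    half_chord = separation / 2.0
    h = math.sqrt(max(radius * radius - half_chord * half_chord, 0.0))
    center_y = h if span > math.pi else -h
    angles = math.pi / 2.0 + span / 2.0 - theta * np.arange(n_points)
    points = np.zeros((n_points, 3))
    points[:, 0] = half_chord + radius * np.cos(angles)
    points[:, 1] = center_y + radius * np.sin(angles)
    return points


def _min_radius(n_points: int, spacing: float) -> float:
    """Smallest radius at which the equal-chord arc stays below one full turn."""
    n_seg = n_points - 1
    return 1.02 * spacing / (2.0 * math.sin(math.pi / n_seg))


def _rotate_about_x(points: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    out = points.copy()
    out[:, 1] = points[:, 1] * c - points[:, 2] * s
    out[:, 2] = points[:, 1] * s + points[:, 2] * c
    return out


def _chain_tangents(ca: np.ndarray) -> np.ndarray:
    """Unit tangents along a Cα chain (central differences, one-sided ends)."""
    t = np.empty_like(ca)
    t[1:-1] = ca[2:] - ca[:-2]
    t[0] = ca[1] - ca[0]
    t[-1] = ca[-1] - ca[-2]
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def _shell_points(arc: np.ndarray, separation: float) -> np.ndarray:
    """Fixed pseudo-protein shell: points on the z ≤ 0 hemisphere clear of the arc."""
    center = np.array([separation / 2.0, 0.0, 0.0])
    r_shell = float(np.max(np.linalg.norm(arc - center, axis=1))) + SHELL_CLEARANCE_Å
    golden = math.pi * (3.0 - math.sqrt(5.0))
    pts = []
    i = 0
    while len(pts) < SHELL_ATOMS:
        n_total = 2 * SHELL_ATOMS + 8
        z = 1.0 - 2.0 * (i + 0.5) / n_total
        if z <= 0.0:
            rad = math.sqrt(max(1.0 - z * z, 0.0))
            phi = golden * i
            pts.append(center + r_shell * np.array([rad * math.cos(phi), rad * math.sin(phi), z]))
        i += 1
        if i > 10 * n_total:  # pragma: no cover - geometry always terminates
            break
    return np.asarray(pts)


# ---------------------------------------------------------------------------
# Structure assembly
# ---------------------------------------------------------------------------


def _loop_structure(
    loop_ca: np.ndarray,
    anchors: np.ndarray,
    reference: np.ndarray,
    shell: Optional[np.ndarray],
    loop_length: int,
    model_id: str,
) -> Structure:
    anchor_end = ANCHOR_START + loop_length + 1
    atoms: list[Atom] = []
    serial = 1

    def add(name: str, res_name: str, res_id: int, xyz: np.ndarray) -> None:
        nonlocal serial
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                res_name=res_name,
                res_id=res_id,
                chain=CHAIN,
                element="C" if name != "N" else "N",
                xyz=xyz,
            )
        )
        serial += 1

    add("CA", "TRP", REFERENCE_RES_ID, reference)
    add("CA", "GLY", ANCHOR_START, anchors[0])
    tangents = _chain_tangents(loop_ca)
    # pseudo N/C sit 1.2 Å along the chain tangent with a small fixed
    # out-of-plane pucker, so the loop's heavy atoms are never coplanar
    # (a rank-2 point set would make the hull descriptor degenerate)
    centered = loop_ca - loop_ca.mean(axis=0)
    normal = np.linalg.svd(centered, full_matrices=False)[2][-1]
    pucker = BACKBONE_PUCKER_Å * normal
    for i in range(loop_length):
        res_id = ANCHOR_START + 1 + i
        add("N", "GLY", res_id, loop_ca[i] - BACKBONE_OFFSET_Å * tangents[i] + pucker)
        add("CA", "GLY", res_id, loop_ca[i])
        add("C", "GLY", res_id, loop_ca[i] + BACKBONE_OFFSET_Å * tangents[i] - pucker)
    add("CA", "GLY", anchor_end, anchors[1])
    if shell is not None:
        for j, xyz in enumerate(shell):
            add("CA", "SHL", 1000 + j, xyz)
    return Structure(atoms=atoms, model_id=model_id)


def _loop_spec(loop_length: int) -> LoopSpec:
    return LoopSpec(
        chain=CHAIN,
        anchor_start=ANCHOR_START,
        anchor_end=ANCHOR_START + loop_length + 1,
        reference_res_ids=[REFERENCE_RES_ID],
    )


def generate_loop_ensemble(spec: EnsembleSpec) -> SyntheticEnsemble:
    """Generate an ensemble of loop conformers under ``spec``.

    Returns the ensemble, the :class:`LoopSpec` that resolves it, and pseudo
    DOPE/SOAP score records (one per model).
    """
    rng = np.random.default_rng(spec.seed)
    L, d, s = spec.loop_length, spec.anchor_separation, spec.ca_spacing
    n_points = L + 2
    base_theta = _solve_arc_angle(n_points, s, d)
    base_radius = s / (2.0 * math.sin(base_theta / 2.0))
    r_min = _min_radius(n_points, s)

    anchors0 = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
    reference = np.array([d / 2.0, 0.0, -REF_OFFPLANE_Å])
    base_arc = _arc_points(n_points, s, d)
    shell = _shell_points(base_arc, d) if spec.context == "shell" else None
    context_centroid = (
        shell.mean(axis=0) if shell is not None else reference
    )

    models, scores = [], []
    for m in range(spec.n_models):
        radius = base_radius
        if spec.sigma_radial > 0:
            radius = max(base_radius * (1.0 + rng.normal(0.0, spec.sigma_radial)), r_min)
        arc = _arc_points(n_points, s, d, radius=None if radius == base_radius else radius)
        if spec.sigma_arch > 0:
            arc = _rotate_about_x(arc, rng.normal(0.0, spec.sigma_arch))
        loop_ca = arc[1:-1].copy()
        anchors = anchors0.copy()
        if spec.sigma_anchor > 0:
            anchors += rng.normal(0.0, spec.sigma_anchor, size=(2, 3))
            loop_ca[0] += rng.normal(0.0, spec.sigma_anchor, size=3)
            loop_ca[-1] += rng.normal(0.0, spec.sigma_anchor, size=3)
        model_id = f"{m + 1}"
        models.append(_loop_structure(loop_ca, anchors, reference, shell, L, model_id))
        spread = float(np.mean(np.linalg.norm(loop_ca - context_centroid, axis=1)))
        scores.append(
            ScoreRecord(
                model_id=model_id,
                dope=spread + rng.normal(0.0, 0.1),
                soap=0.9 * spread + rng.normal(0.0, 0.1),
            )
        )
    ensemble = ConformerEnsemble(models=models, source="synthetic")
    return SyntheticEnsemble(
        ensemble=ensemble, loop_spec=_loop_spec(L), scores=scores, spec=spec
    )


def three_regime_ensemble(
    n_models: int = 1000, seed: int = 0
) -> tuple[SyntheticEnsemble, np.ndarray]:
    """An ensemble drawn from three well-separated geometric regimes.

    Equal thirds of models at three distinct arc orientations (with small
    within-regime jitter), as ground truth for selection-pipeline tests.
    Returns the synthetic ensemble and the per-model regime labels.
    """
    rng = np.random.default_rng(seed)
    orientations = [-1.2, -0.6, 0.0]
    radial_scales = [0.92, 1.0, 1.08]
    spec = EnsembleSpec(n_models=n_models, seed=seed)
    L, d, s = spec.loop_length, spec.anchor_separation, spec.ca_spacing
    base_theta = _solve_arc_angle(L + 2, s, d)
    base_radius = s / (2.0 * math.sin(base_theta / 2.0))
    regime_arcs = [
        _arc_points(L + 2, s, d, radius=None if scale == 1.0 else base_radius * scale)
        for scale in radial_scales
    ]
    anchors = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
    reference = np.array([d / 2.0, 0.0, -REF_OFFPLANE_Å])

    labels = np.arange(n_models) % 3
    models, scores = [], []
    for m in range(n_models):
        regime = int(labels[m])
        angle = orientations[regime] + rng.normal(0.0, 0.03)
        arc = _rotate_about_x(regime_arcs[regime], angle)
        loop_ca = arc[1:-1] + rng.normal(0.0, 0.05, size=(L, 3))
        model_id = f"{m + 1}"
        models.append(_loop_structure(loop_ca, anchors, reference, None, L, model_id))
        spread = float(np.mean(np.linalg.norm(loop_ca - reference, axis=1)))
        scores.append(
            ScoreRecord(
                model_id=model_id,
                dope=spread + rng.normal(0.0, 0.1),
                soap=0.9 * spread + rng.normal(0.0, 0.1),
            )
        )
    synth = SyntheticEnsemble(
        ensemble=ConformerEnsemble(models=models, source="synthetic"),
        loop_spec=_loop_spec(L),
        scores=scores,
        spec=spec,
    )
    return synth, labels


# ---------------------------------------------------------------------------
# State-switching series
# ---------------------------------------------------------------------------


def _dwell_labels(spec: StateSeriesSpec, rng: np.random.Generator) -> np.ndarray:
    """Label sequence with geometric dwell segments hitting the target mix.

    Per-state frame budgets are fixed by largest-remainder rounding of the
    target fractions, then spent in geometrically distributed dwell segments
    (mean ``mean_dwell``) drawn against the remaining budgets, so empirical
    occupancies match the targets to rounding accuracy while dwell structure
    is preserved.
    """
    n, k = spec.n_frames, len(spec.state_fractions)
    raw = np.array(spec.state_fractions) * n
    budget = np.floor(raw).astype(int)
    remainder = raw - budget
    for idx in np.argsort(-remainder)[: n - budget.sum()]:
        budget[idx] += 1

    labels = np.empty(n, dtype=int)
    pos = 0
    previous = -1
    p_leave = min(1.0 / spec.mean_dwell, 1.0)
    while pos < n:
        open_states = np.flatnonzero(budget > 0)
        weights = budget[open_states].astype(float)
        if len(open_states) > 1 and previous in open_states:
            # discourage (not forbid) immediately re-entering the same state
            weights = weights * np.where(open_states != previous, 1.0, 0.25)
        state = int(rng.choice(open_states, p=weights / weights.sum()))
        dwell = int(min(rng.geometric(p_leave), budget[state]))
        labels[pos : pos + dwell] = state
        budget[state] -= dwell
        pos += dwell
        previous = state
    return labels


def generate_state_series(spec: StateSeriesSpec, run_id: str = "run1") -> SyntheticStateSeries:
    """Generate a state-switching trajectory with known ground truth.

    Each frame's loop is the base arc rotated to its state's orientation
    angle about the anchor–anchor axis, plus per-atom Gaussian coordinate
    noise; the four arch-shape parameters are computed per frame into a
    :class:`FrameSeries` alongside the hidden true labels.
    """
    from .descriptors import compute_descriptors
    from .structure_io import resolve_loop

    rng = np.random.default_rng(spec.seed)
    labels = _dwell_labels(spec, rng)
    L, d, s = spec.loop_length, spec.anchor_separation, spec.ca_spacing
    base_theta = _solve_arc_angle(L + 2, s, d)
    base_radius = s / (2.0 * math.sin(base_theta / 2.0))
    r_min = _min_radius(L + 2, s)
    state_arcs = [
        _rotate_about_x(
            _arc_points(
                L + 2, s, d,
                radius=None if scale == 1.0 else max(base_radius * scale, r_min),
            ),
            angle,
        )
        for angle, scale in zip(spec.arc_orientations, spec.radial_scales)
    ]
    anchors = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
    reference = np.array([d / 2.0, 0.0, -REF_OFFPLANE_Å])
    loop_spec = _loop_spec(L)

    models = []
    rows = np.empty((spec.n_frames, len(STATE_PARAMETERS)))
    for t, state in enumerate(labels):
        arc = state_arcs[int(state)]
        loop_ca = arc[1:-1] + rng.normal(0.0, spec.noise, size=(L, 3))
        model = _loop_structure(loop_ca, anchors, reference, None, L, f"{t + 1}")
        models.append(model)
        vec = compute_descriptors(resolve_loop(loop_spec, model), arch_only=True)
        rows[t] = [getattr(vec, p) for p in STATE_PARAMETERS]

    series = FrameSeries(
        run_id=run_id, frames=pd.DataFrame(rows, columns=list(STATE_PARAMETERS))
    )
    return SyntheticStateSeries(
        ensemble=ConformerEnsemble(models=models, source="synthetic"),
        loop_spec=loop_spec,
        series=series,
        true_labels=labels,
        spec=spec,
    )
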