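"""Loop conformational states from descriptor time series.

Trajectory frames (e.g. saved MD snapshots exported as multi-model PDB, or
precomputed descriptor tables) are described by the four arch-shape
parameters — loop_anchor_mean, loop_ref_min, ach_ach_dist and
loop_max_distance — pooled across runs, standardized, and partitioned with
K-means into loop conformational states. For k = 3 the states are named by
the mean distance of their members to the reference (active-site) centroid:
the smallest mean loop_ref_min is the "closed" state (loop wrapped towards
the active site), the largest is "open" (solvent-exposed), the middle one
"semi-open". Per-run occupancies (fraction of frames per state) and raw
transition-count matrices between consecutive frames are reported.

Also here: coordinate averaging over an ensemble and Kabsch-superposed RMSD,
the utilities used to compare averaged loop structures between runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .descriptors import ARCH_PARAMETERS
from .errors import InputError
from .structure_io import Atom, ConformerEnsemble, Structure

STATE_PARAMETERS = ARCH_PARAMETERS  # the four arch-shape parameters


@dataclass
class FrameSeries:
    """Ordered per-frame arch-parameter values for one trajectory run."""

    run_id: str
    frames: pd.DataFrame  # columns = STATE_PARAMETERS, one row per frame
    frame_spacing: Optional[float] = None

    def __post_init__(self) -> None:
        missing = [p for p in STATE_PARAMETERS if p not in self.frames.columns]
        if missing:
            raise InputError(f"run {self.run_id!r}: missing parameter column(s) {missing}")
        self.frames = self.frames[list(STATE_PARAMETERS)].astype(float)
        if len(self.frames) < 2:
            raise InputError(f"run {self.run_id!r}: need at least 2 frames")
        if self.frames.isna().any().any():
            raise InputError(f"run {self.run_id!r}: missing values in state parameters")


@dataclass
class StateModel:
    """K-means state decomposition of pooled trajectory frames."""

    k: int
    centroids: np.ndarray  # k x 4, original parameter units (Å)
    labels: dict[str, np.ndarray]  # run_id -> per-frame state indices
    state_names: dict[int, str]
    occupancy_by_run: dict[str, dict[int, float]]
    transitions_by_run: dict[str, np.ndarray]
    parameter_names: tuple[str, ...] = STATE_PARAMETERS

    def occupancy(self, run_id: str) -> dict[int, float]:
        if run_id not in self.occupancy_by_run:
            raise InputError(f"unknown run {run_id!r}")
        return self.occupancy_by_run[run_id]

    def named_occupancy(self, run_id: str) -> dict[str, float]:
        return {self.state_names[s]: f for s, f in self.occupancy(run_id).items()}

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "parameter_names": list(self.parameter_names),
            "centroids": self.centroids.tolist(),
            "state_names": {int(i): n for i, n in self.state_names.items()},
            "occupancy": {
                run: {self.state_names[s]: float(f) for s, f in occ.items()}
                for run, occ in self.occupancy_by_run.items()
            },
            "transitions": {run: t.tolist() for run, t in self.transitions_by_run.items()},
        }


def transitions(labels: Sequence[int], k: Optional[int] = None) -> np.ndarray:
    """k×k counts of consecutive label pairs (s_t, s_{t+1}), diagonal included.

    The number of state changes is the off-diagonal sum.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size < 2:
        raise InputError("need at least 2 labels to count transitions")
    if k is None:
        k = int(labels.max()) + 1
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (labels[:-1], labels[1:]), 1)
    return counts


def occupancy(labels: Sequence[int], k: int) -> dict[int, float]:
    """Fraction of frames in each state; sums to 1."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise InputError("empty label sequence")
    return {s: float(np.mean(labels == s)) for s in range(k)}


def _name_states(centroids: np.ndarray, k: int) -> dict[int, str]:
    """Name states by ascending centroid loop_ref_min (column 1).

    k = 3 gives closed / semi-open / open; other k give ordinal names in the
    same ascending-ref-min order.
    """
    ref_min_col = STATE_PARAMETERS.index("loop_ref_min")
    order = np.argsort(centroids[:, ref_min_col], kind="stable")
    if k == 3:
        ordered_names = ["closed", "semi-open", "open"]
    else:
        ordered_names = [f"state-{i + 1}" for i in range(k)]
    return {int(state): ordered_names[rank] for rank, state in enumerate(order)}


def cluster_states(
    series: Sequence[FrameSeries], k: int = 3, seed: int = 0, n_init: int = 10
) -> StateModel:
    """Pool frames from all runs, standardize, K-means into k states.

    Standardization uses the pooled mean and sample sd of each of the four
    parameters so that runs are clustered in one shared space; centroids are
    reported back in original Å units. Per-run labels, occupancies and
    transition counts are attached to the returned :class:`StateModel`.
    """
    from .selection import kmeans_cluster

    if not series:
        raise InputError("no frame series given")
    run_ids = [s.run_id for s in series]
    if len(set(run_ids)) != len(run_ids):
        raise InputError("run ids must be unique")
    pooled = np.vstack([s.frames.to_numpy() for s in series])
    if pooled.shape[0] < k:
        raise InputError(f"k={k} exceeds pooled frame count {pooled.shape[0]}")

    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1)
    sd_safe = np.where(sd == 0.0, 1.0, sd)
    standardized = (pooled - mean) / sd_safe

    flat_labels, std_centroids = kmeans_cluster(standardized, k, seed=seed, n_init=n_init)
    centroids = std_centroids * sd_safe + mean

    state_names = _name_states(centroids, k)
    labels_by_run: dict[str, np.ndarray] = {}
    occupancy_by_run: dict[str, dict[int, float]] = {}
    transitions_by_run: dict[str, np.ndarray] = {}
    offset = 0
    for s in series:
        n = len(s.frames)
        run_labels = flat_labels[offset : offset + n]
        offset += n
        labels_by_run[s.run_id] = run_labels
        occupancy_by_run[s.run_id] = occupancy(run_labels, k)
        transitions_by_run[s.run_id] = transitions(run_labels, k)

    return StateModel(
        k=k,
        centroids=centroids,
        labels=labels_by_run,
        state_names=state_names,
        occupancy_by_run=occupancy_by_run,
        transitions_by_run=transitions_by_run,
    )


# ---------------------------------------------------------------------------
# Ensemble averaging and RMSD
# ---------------------------------------------------------------------------


def kabsch_rmsd(a: np.ndarray, b: np.ndarray, fit: bool = True) -> float:
    """RMSD between two corresponding coordinate sets, in Å.

    With ``fit`` (default) the sets are first optimally superposed by the
    least-squares proper rotation (reflections excluded) after centroid
    removal; otherwise the raw positional RMSD is returned.
    """
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise InputError(f"coordinate sets differ in size: {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise InputError("need at least 3 atoms for RMSD")
    if not fit:
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a_c, b_c)
    return float(rssd / np.sqrt(a.shape[0]))


def average_structure(ensemble: ConformerEnsemble, fit_to_first: bool = False) -> Structure:
    """Per-atom arithmetic mean of coordinates across all models.

    With ``fit_to_first`` each model is first Kabsch-superposed onto the
    first model (useful when models are not already in a common frame).
    """
    coords = np.stack([m.coords() for m in ensemble.models])
    if fit_to_first and len(ensemble.models) > 1:
        ref = coords[0] - coords[0].mean(axis=0)
        fitted = [ref]
        for c in coords[1:]:
            c_c = c - c.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref, c_c)
            fitted.append(rot.apply(c_c))
        coords = np.stack(fitted)
    mean_coords = coords.mean(axis=0)
    template = ensemble.models[0]
    atoms = [
        Atom(
            serial=a.serial,
            name=a.name,
            res_name=a.res_name,
            res_id=a.res_id,
            chain=a.chain,
            element=a.element,
            xyz=mean_coords[i],
            ins_code=a.ins_code,
        )
        for i, a in enumerate(template.atoms)
    ]
    return Structure(atoms=atoms, model_id="average")
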