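"""Multi-model PDB ensembles, score tables and loop selections.

This module owns the plumbing between files on disk and the in-memory types
the rest of the package computes on:

* :class:`ConformerEnsemble` — an ordered set of conformers (homology models
  or trajectory frames) sharing one atom topology, read from / written to
  multi-model PDB (``MODEL``/``ENDMDL`` records) via biotite;
* :class:`ScoreRecord` — externally produced per-model quality scores
  (DOPE/SOAP pseudo-energies, lower is better) read from TSV;
* :class:`LoopSpec` / :class:`LoopSelection` — the declarative description
  of a loop (chain, anchor residues, reference residues) and its concrete
  resolution into coordinate sets on one conformer.

Conventions: author residue numbering is kept as-is; hydrogens, HETATM
records and waters are dropped on read by default; for alternate locations
the highest-occupancy conformation is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    InputError,
    ResolutionError,
    SchemaError,
    TopologyError,
)

_WATER_RES = {"HOH", "WAT", "DOD", "TIP", "TIP3", "SOL"}
_HYDROGEN = {"H", "D"}


@dataclass
class Atom:
    """One atom: identity plus Cartesian coordinates in Å."""

    serial: int
    name: str
    res_name: str
    res_id: int
    chain: str
    element: str
    xyz: np.ndarray
    ins_code: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise InputError(f"atom {self.serial} {self.name}: coordinates must be a finite 3-vector")
        if not self.name:
            raise InputError(f"atom {self.serial}: empty atom name")

    @property
    def key(self) -> tuple:
        return (self.chain, self.res_id, self.name)


@dataclass
class Structure:
    """One conformer: an ordered atom list grouped by residue in chain order."""

    atoms: list[Atom]
    model_id: str = "1"

    def __len__(self) -> int:
        return len(self.atoms)

    def topology(self) -> list[tuple]:
        return [(a.chain, a.res_id, a.res_name, a.name) for a in self.atoms]

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def residue_index(self) -> dict[tuple[str, int], list[Atom]]:
        """Map (chain, res_id) -> atoms of that residue, preserving order."""
        index: dict[tuple[str, int], list[Atom]] = {}
        for atom in self.atoms:
            index.setdefault((atom.chain, atom.res_id), []).append(atom)
        return index


@dataclass
class ConformerEnsemble:
    """Ordered conformers sharing one topology (models of one protein)."""

    models: list[Structure]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.models:
            raise InputError("ensemble must contain at least one model")
        reference = self.models[0].topology()
        for model in self.models[1:]:
            topo = model.topology()
            if topo != reference:
                mismatch = _first_topology_mismatch(reference, topo)
                raise TopologyError(
                    f"model {model.model_id!r} does not match model "
                    f"{self.models[0].model_id!r}: first mismatch at {mismatch}"
                )

    def __len__(self) -> int:
        return len(self.models)

    def model_ids(self) -> list[str]:
        return [m.model_id for m in self.models]


def _first_topology_mismatch(a: list[tuple], b: list[tuple]) -> str:
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return f"atom index {i}: {x} vs {y}"
    return f"atom count {len(a)} vs {len(b)}"


@dataclass
class LoopSpec:
    """Declarative loop selection: chain, anchors and reference residues.

    The anchors are the loop attachment points — the residues connecting the
    loop to fixed secondary structure. By default the loop consists of the
    residues strictly between the anchors (the anchors are treated as fixed
    stems); set ``include_anchors_in_loop`` to count them as loop residues.
    ``reference_res_ids`` name one or more residues (e.g. a conserved
    active-site Trp) whose Cα centroid serves as the reference point for the
    loop-ref-min descriptor.
    """

    chain: str
    anchor_start: int
    anchor_end: int
    reference_res_ids: Sequence[int]
    include_anchors_in_loop: bool = False

    def __post_init__(self) -> None:
        if self.anchor_start >= self.anchor_end:
            raise InputError(
                f"anchor_start ({self.anchor_start}) must be < anchor_end ({self.anchor_end})"
            )
        self.reference_res_ids = list(self.reference_res_ids)
        if not self.reference_res_ids:
            raise InputError("at least one reference residue is required")
        inside = [
            r for r in self.reference_res_ids if self.anchor_start <= r <= self.anchor_end
        ]
        if inside:
            raise InputError(
                f"reference residues {inside} fall inside the anchor range "
                f"[{self.anchor_start}, {self.anchor_end}]"
            )

    def loop_res_ids(self) -> list[int]:
        if self.include_anchors_in_loop:
            return list(range(self.anchor_start, self.anchor_end + 1))
        return list(range(self.anchor_start + 1, self.anchor_end))


@dataclass
class LoopSelection:
    """Concrete coordinate sets for one conformer under a LoopSpec.

    ``loop_backbone`` holds per-residue (N, Cα, C) positions where present
    (``None`` for a missing backbone atom, as in Cα-trace models).
    ``protein_heavy`` may be empty for loop-only synthetic fixtures, in which
    case the loop–protein shortest-distance descriptor is undefined.
    """

    loop_ca: np.ndarray
    loop_backbone: list[tuple[Optional[np.ndarray], np.ndarray, Optional[np.ndarray]]]
    loop_heavy: np.ndarray
    anchor_ca: np.ndarray
    reference_centroid: np.ndarray
    protein_heavy: np.ndarray
    loop_res_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.loop_ca = np.asarray(self.loop_ca, dtype=float)
        self.anchor_ca = np.asarray(self.anchor_ca, dtype=float)
        self.reference_centroid = np.asarray(self.reference_centroid, dtype=float)
        self.loop_heavy = np.asarray(self.loop_heavy, dtype=float).reshape(-1, 3)
        self.protein_heavy = np.asarray(self.protein_heavy, dtype=float).reshape(-1, 3)
        if self.loop_ca.shape[0] < 3:
            raise InputError(f"loop must contain at least 3 residues, got {self.loop_ca.shape[0]}")
        if self.anchor_ca.shape != (2, 3):
            raise InputError("anchor_ca must hold exactly the two anchor Cα positions")


@dataclass
class ScoreRecord:
    """Per-model DOPE and SOAP scores (unitless pseudo-energies, lower = better)."""

    model_id: str
    dope: float
    soap: float


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------


def _model_serials(lines: list[str]) -> list[str]:
    serials = []
    for line in lines:
        if line.startswith("MODEL"):
            parts = line.split()
            serials.append(parts[1] if len(parts) > 1 else str(len(serials) + 1))
    return serials


def _locate_bad_atom_line(lines: list[str]) -> Optional[int]:
    for lineno, line in enumerate(lines, start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                return lineno
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                int(line[6:11])
            except ValueError:
                return lineno
    return None


def read_ensemble(
    path: str | Path,
    format: str = "pdb",
    include_het: bool = False,
    keep_hydrogens: bool = False,
) -> ConformerEnsemble:
    """Read a multi-model PDB file into a :class:`ConformerEnsemble`.

    A file with no MODEL records is treated as a single-model ensemble with
    model id "1"; otherwise model ids are the MODEL record serial numbers.
    HETATM records and waters are excluded unless ``include_het`` is set;
    hydrogens are dropped unless ``keep_hydrogens`` is set.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if format != "pdb":
        raise InputError(f"unsupported format {format!r}; only 'pdb' is supported")
    if not path.exists():
        raise InputError(f"file not found: {path}")

    pdb_file = PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(
            model=None, altloc="occupancy", extra_fields=["atom_id"]
        )
    except Exception as exc:  # diagnose: bad record vs inconsistent topology
        bad_line = _locate_bad_atom_line(pdb_file.lines)
        if bad_line is not None:
            raise FormatError(f"{path}: unparsable ATOM record at line {bad_line}") from exc
        raise TopologyError(
            f"{path}: models do not share one topology ({exc})"
        ) from exc

    serials = _model_serials(pdb_file.lines)
    n_models = stack.stack_depth()
    if len(serials) != n_models:
        serials = [str(i + 1) for i in range(n_models)]

    keep = np.ones(stack.array_length(), dtype=bool)
    if not keep_hydrogens:
        keep &= ~np.isin(stack.element, list(_HYDROGEN))
    if not include_het:
        keep &= ~stack.hetero
        keep &= ~np.isin(stack.res_name, list(_WATER_RES))
    else:
        keep &= ~np.isin(stack.res_name, list(_WATER_RES))
    stack = stack[:, keep]

    ins = (
        stack.ins_code
        if "ins_code" in stack.get_annotation_categories()
        else np.full(stack.array_length(), "")
    )
    models = []
    for m in range(n_models):
        coords = stack.coord[m]
        atoms = [
            Atom(
                serial=int(stack.atom_id[i]),
                name=str(stack.atom_name[i]),
                res_name=str(stack.res_name[i]),
                res_id=int(stack.res_id[i]),
                chain=str(stack.chain_id[i]),
                element=str(stack.element[i]),
                xyz=coords[i],
                ins_code=str(ins[i]).strip(),
            )
            for i in range(stack.array_length())
        ]
        models.append(Structure(atoms=atoms, model_id=serials[m]))
    return ConformerEnsemble(models=models, source=str(path))


def write_ensemble(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL per conformer)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    first = ensemble.models[0]
    n_atoms = len(first)
    coords = np.stack([m.coords() for m in ensemble.models])
    if np.any(np.abs(coords) >= 10000.0):
        raise FormatError(
            "coordinate magnitude >= 10000 Å cannot be represented in PDB %8.3f columns"
        )

    stack = struc.AtomArrayStack(len(ensemble.models), n_atoms)
    stack.coord = coords
    stack.chain_id = np.array([a.chain for a in first.atoms])
    stack.res_id = np.array([a.res_id for a in first.atoms])
    stack.res_name = np.array([a.res_name for a in first.atoms])
    stack.atom_name = np.array([a.name for a in first.atoms])
    stack.element = np.array([a.element for a in first.atoms])
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    stack.set_annotation("atom_id", np.array([a.serial for a in first.atoms]))

    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    lines = list(pdb_file.lines)
    if not any(l.startswith("MODEL") for l in lines):
        # a 1-conformer ensemble still gets an explicit MODEL/ENDMDL pair
        body = [l for l in lines if l.strip() and not l.startswith("END")]
        lines = ["MODEL        1", *body, "ENDMDL", "END"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_scores(path: str | Path) -> list[ScoreRecord]:
    """Read a TSV score table with columns model_id, dope, soap (any case)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str)
    table.columns = [c.strip().lower() for c in table.columns]
    missing = {"model_id", "dope", "soap"} - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    records = []
    for i, row in enumerate(table.itertuples(index=False)):
        try:
            dope = float(getattr(row, "dope"))
            soap = float(getattr(row, "soap"))
        except (TypeError, ValueError) as exc:
            # +2: one for the header row, one for 1-based numbering
            raise FormatError(f"{path}: non-numeric score at row {i + 2}") from exc
        if not (math.isfinite(dope) and math.isfinite(soap)):
            raise FormatError(f"{path}: non-finite score at row {i + 2}")
        records.append(ScoreRecord(model_id=str(getattr(row, "model_id")), dope=dope, soap=soap))
    return records


def write_scores(records: Sequence[ScoreRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "model_id": [r.model_id for r in records],
            "dope": [r.dope for r in records],
            "soap": [r.soap for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Loop resolution
# ---------------------------------------------------------------------------


def _ca_of(atoms: list[Atom]) -> Optional[Atom]:
    for atom in atoms:
        if atom.name == "CA":
            return atom
    return None


def _named(atoms: list[Atom], name: str) -> Optional[Atom]:
    for atom in atoms:
        if atom.name == name:
            return atom
    return None


def resolve_loop(spec: LoopSpec, model: Structure) -> LoopSelection:
    """Resolve a :class:`LoopSpec` against one conformer.

    Loop residues are those strictly between the anchors (plus the anchors
    when the spec says so); the reference centroid is the mean Cα position of
    the reference residues; ``protein_heavy`` covers every residue outside
    loop ∪ anchors so that the loop–protein shortest distance never reports a
    trivially bonded anchor contact.
    """
    index = model.residue_index()
    chain = spec.chain

    def residue(res_id: int, role: str) -> list[Atom]:
        atoms = index.get((chain, res_id))
        if not atoms:
            raise ResolutionError(
                f"{role} residue {res_id} absent on chain {chain!r} "
                f"(model {model.model_id!r})"
            )
        return atoms

    anchor_ca = []
    for res_id in (spec.anchor_start, spec.anchor_end):
        ca = _ca_of(residue(res_id, "anchor"))
        if ca is None:
            raise ResolutionError(f"anchor residue {res_id} has no Cα atom")
        anchor_ca.append(ca.xyz)

    loop_ids = spec.loop_res_ids()
    loop_ca, loop_backbone, loop_heavy = [], [], []
    for res_id in loop_ids:
        atoms = residue(res_id, "loop")
        ca = _ca_of(atoms)
        if ca is None:
            raise ResolutionError(f"loop residue {res_id} has no Cα atom")
        if any(a.ins_code for a in atoms):
            raise ResolutionError(
                f"loop residue {res_id} carries an insertion code (unsupported)"
            )
        n_atom, c_atom = _named(atoms, "N"), _named(atoms, "C")
        loop_ca.append(ca.xyz)
        loop_backbone.append(
            (
                n_atom.xyz if n_atom is not None else None,
                ca.xyz,
                c_atom.xyz if c_atom is not None else None,
            )
        )
        loop_heavy.extend(a.xyz for a in atoms if a.element not in _HYDROGEN)

    ref_ca = []
    for res_id in spec.reference_res_ids:
        ca = _ca_of(residue(res_id, "reference"))
        if ca is None:
            raise ResolutionError(f"reference residue {res_id} has no Cα atom")
        ref_ca.append(ca.xyz)
    reference_centroid = np.mean(np.asarray(ref_ca, dtype=float), axis=0)

    excluded = set(loop_ids) | {spec.anchor_start, spec.anchor_end}
    protein_heavy = [
        a.xyz
        for a in model.atoms
        if not (a.chain == chain and a.res_id in excluded) and a.element not in _HYDROGEN
    ]

    return LoopSelection(
        loop_ca=np.asarray(loop_ca, dtype=float),
        loop_backbone=loop_backbone,
        loop_heavy=np.asarray(loop_heavy, dtype=float),
        anchor_ca=np.asarray(anchor_ca, dtype=float),
        reference_centroid=reference_centroid,
        protein_heavy=np.asarray(protein_heavy, dtype=float).reshape(-1, 3),
        loop_res_ids=loop_ids,
    )
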