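from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from loopshape import LoopSelection


def random_selection(rng: np.random.Generator) -> LoopSelection:
    """A random but structurally valid loop selection (backbone included)."""
    L = int(rng.integers(4, 11))
    loop_ca = rng.uniform(-10.0, 10.0, size=(L, 3))
    backbone = []
    heavy = []
    for i in range(L):
        n = loop_ca[i] + rng.normal(0.0, 1.0, size=3)
        c = loop_ca[i] + rng.normal(0.0, 1.0, size=3)
        backbone.append((n, loop_ca[i], c))
        heavy.extend([n, loop_ca[i], c])
    return LoopSelection(
        loop_ca=loop_ca,
        loop_backbone=backbone,
        loop_heavy=np.asarray(heavy),
        anchor_ca=rng.uniform(-10.0, 10.0, size=(2, 3)),
        reference_centroid=rng.uniform(-10.0, 10.0, size=3),
        protein_heavy=rng.uniform(-20.0, 20.0, size=(int(rng.integers(5, 30)), 3)),
    )


def transform_selection(sel: LoopSelection, rot: Rotation, shift: np.ndarray) -> LoopSelection:
    """Apply one rigid motion to every coordinate set of a selection."""

    def t(x):
        return rot.apply(np.atleast_2d(np.asarray(x, dtype=float))) + shift

    return LoopSelection(
        loop_ca=t(sel.loop_ca),
        loop_backbone=[
            (
                t(n)[0] if n is not None else None,
                t(ca)[0],
                t(c)[0] if c is not None else None,
            )
            for n, ca, c in sel.loop_backbone
        ],
        loop_heavy=t(sel.loop_heavy),
        anchor_ca=t(sel.anchor_ca),
        reference_centroid=t(sel.reference_centroid)[0],
        protein_heavy=t(sel.protein_heavy),
    )


def scale_selection(sel: LoopSelection, c: float) -> LoopSelection:
    return LoopSelection(
        loop_ca=c * sel.loop_ca,
        loop_backbone=[
            (c * n if n is not None else None, c * ca, c * cc if cc is not None else None)
            for n, ca, cc in sel.loop_backbone
        ],
        loop_heavy=c * sel.loop_heavy,
        anchor_ca=c * sel.anchor_ca,
        reference_centroid=c * sel.reference_centroid,
        protein_heavy=c * sel.protein_heavy,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_static_ensemble():
    from loopshape import generate_loop_ensemble, static_regime

    return generate_loop_ensemble(static_regime(n_models=20, seed=11, context="shell"))
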