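"""Static-vs-flexible loop classification from descriptor dispersion.

Over a large ensemble of loop models, a flexible solvent-exposed loop shows
wide dispersion of the arch-shape parameters (loop_anchor_mean,
loop_ref_min, loop_max_distance, ach_ach_dist), whereas a static loop —
whose position is constrained by neighbouring secondary structure — varies
mainly in the anchor separation (ach_ach_dist) while keeping its overall
shape. Dispersion is measured as the relative standard deviation
(RSD = 100 · sd / mean, in percent) of each descriptor column.

The decision rule operationalized here: a loop is called *flexible* when at
least two of {loop_anchor_mean, loop_ref_min, loop_max_distance} have
RSD above the threshold (default 8%), *static* when none do, and
*indeterminate* when exactly one does. ach_ach_dist is excluded from the
decision set — it is widely dispersed for both loop types — but its RSD is
always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import ARCH_PARAMETERS, DESCRIPTOR_NAMES, SCORE_NAMES
from .errors import InputError

#: Arch parameters that enter the static/flexible decision.
DECISION_SET = ("loop_anchor_mean", "loop_ref_min", "loop_max_distance")

DEFAULT_RSD_THRESHOLD_PCT = 8.0


@dataclass
class RSDProfile:
    """Per-descriptor relative standard deviation (percent) over an ensemble."""

    rsd: dict[str, float]
    n_models: int

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise InputError("RSD needs at least 2 models")


@dataclass
class FlexibilityCall:
    """The static/flexible verdict with the RSD evidence behind it."""

    verdict: str  # "static" | "flexible" | "indeterminate"
    threshold_pct: float
    arch_parameters_over_threshold: list[str]
    profile: RSDProfile
    decision_set: tuple[str, ...] = DECISION_SET

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "threshold_pct": self.threshold_pct,
            "decision_set": list(self.decision_set),
            "arch_parameters_over_threshold": list(self.arch_parameters_over_threshold),
            "rsd_pct": {k: float(v) for k, v in self.profile.rsd.items()},
            "n_models": self.profile.n_models,
        }


def rsd_profile(matrix: pd.DataFrame) -> RSDProfile:
    """RSD (100 · sample sd / mean, percent) per geometric descriptor column.

    Score columns (dope/soap — signed pseudo-energies for which RSD is
    meaningless) are excluded, as are all-NaN columns of undefined
    descriptors. A defined descriptor column with non-positive mean is an
    error: RSD is only meaningful on positive scales.
    """
    if len(matrix) < 2:
        raise InputError("RSD profile needs at least 2 models")
    rsd: dict[str, float] = {}
    for col in matrix.columns:
        if col in SCORE_NAMES or col not in DESCRIPTOR_NAMES:
            continue
        values = matrix[col].to_numpy(dtype=float)
        if np.isnan(values).all():
            continue
        if np.isnan(values).any():
            raise InputError(f"column {col!r} mixes defined and missing values")
        mean = values.mean()
        if mean <= 0.0:
            raise InputError(f"column {col!r} has non-positive mean; RSD undefined")
        rsd[col] = 100.0 * values.std(ddof=1) / mean
    return RSDProfile(rsd=rsd, n_models=len(matrix))


def classify_loop(
    profile: RSDProfile, threshold_pct: float = DEFAULT_RSD_THRESHOLD_PCT
) -> FlexibilityCall:
    """Issue the static/flexible verdict from an RSD profile.

    Requires all four arch parameters in the profile; the verdict depends
    only on the three-member decision set (see module docstring).
    """
    missing = [p for p in ARCH_PARAMETERS if p not in profile.rsd]
    if missing:
        raise InputError(f"profile lacks arch parameter(s) {missing}")
    over = [p for p in DECISION_SET if profile.rsd[p] > threshold_pct]
    if len(over) >= 2:
        verdict = "flexible"
    elif len(over) == 0:
        verdict = "static"
    else:
        verdict = "indeterminate"
    return FlexibilityCall(
        verdict=verdict,
        threshold_pct=threshold_pct,
        arch_parameters_over_threshold=over,
        profile=profile,
    )
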