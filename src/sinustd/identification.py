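"""Baseline standardisation, Total Difference scoring, and candidate ranking.

The Total Difference (TD) between two sinus profiles is the sum over the
ray-fan angles of the absolute differences of their baseline-standardised
line lengths, s_theta = L_theta / B. A matching antemortem/postmortem pair
should attain the lowest TD in a candidate array, with the value approaching
zero for a true match. TD is a pseudometric: nonnegative, symmetric, zero on
identical profiles, and satisfies the triangle inequality.

By convention the standardising divisor is the *total* baseline length B.
Scoring can also be run on raw millimetre lengths (``raw_profile``), since
comparisons of unstandardised profiles are occasionally wanted when all
images share one calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ComparisonError, GeometryError
from .geometry import SinusProfile


@dataclass(frozen=True)
class StandardizedProfile:
    """Dimensionless per-angle values s_theta = L_theta / B for one outline.

    (Raw-mm vectors are carried in the same container when standardisation is
    deliberately skipped.)
    """

    outline_id: str
    angles: tuple
    s: tuple

    def __post_init__(self) -> None:
        if len(self.angles) != len(self.s):
            raise ComparisonError("angle and value arrays differ in length")
        if any(v < 0.0 for v in self.s):
            raise ComparisonError("standardized lengths must be nonnegative")

    def values(self) -> np.ndarray:
        return np.asarray(self.s, dtype=float)


@dataclass(frozen=True)
class TotalDifferenceResult:
    """Per-angle absolute differences and their sum for one profile pair."""

    id_A: str
    id_B: str
    per_angle_abs_diff: tuple
    TD: float


def standardize_profile(profile: SinusProfile) -> StandardizedProfile:
    """Divide every line length by the total baseline length B."""
    B = profile.baseline.length_B
    if B <= 0.0:
        raise GeometryError("degenerate baseline: B must be > 0")
    return StandardizedProfile(outline_id=profile.outline_id,
                               angles=tuple(profile.angles.tolist()),
                               s=tuple((profile.lengths / B).tolist()))


def raw_profile(profile: SinusProfile) -> StandardizedProfile:
    """Carry raw millimetre line lengths, skipping baseline standardisation."""
    return StandardizedProfile(outline_id=profile.outline_id,
                               angles=tuple(profile.angles.tolist()),
                               s=tuple(profile.lengths.tolist()))


def total_difference(a: StandardizedProfile, b: StandardizedProfile) -> TotalDifferenceResult:
    """TD = sum over angles of |s_theta^a - s_theta^b|; symmetric in its arguments."""
    if len(a.s) != len(b.s) or not np.allclose(a.angles, b.angles):
        raise ComparisonError(
            f"profiles {a.outline_id!r} and {b.outline_id!r} have mismatched angle sets")
    diff = np.abs(a.values() - b.values())
    return TotalDifferenceResult(id_A=a.outline_id, id_B=b.outline_id,
                                 per_angle_abs_diff=tuple(diff.tolist()),
                                 TD=float(diff.sum()))


def rank_candidates(pm: StandardizedProfile,
                    am_array: Sequence[StandardizedProfile]) -> list[TotalDifferenceResult]:
    """Rank antemortem candidates against a postmortem profile, ascending by TD.

    The sort is stable, so candidates with tied TD keep their input order;
    the first entry (rank 1) is the proposed match.
    """
    if len(am_array) == 0:
        raise ComparisonError("candidate array is empty")
    results = [total_difference(pm, am) for am in am_array]
    return sorted(results, key=lambda r: r.TD)


def ranking_frame(ranking: Sequence[TotalDifferenceResult]) -> pd.DataFrame:
    """Tabulate a ranking as (candidate_id, TD, rank), rank 1 = proposed match."""
    return pd.DataFrame({
        "candidate_id": [r.id_B for r in ranking],
        "TD": [r.TD for r in ranking],
        "rank": np.arange(1, len(ranking) + 1),
    })
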