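"""k-dominance (abundance-biomass comparison) curves and stress classes.

A k-dominance curve ranks taxa by a quantity in descending order and
plots the cumulative percentage of the total against rank.  Comparing
the biomass curve with the abundance curve of the same community (ABC
method) classifies its condition:

* **unstressed** -- the biomass curve lies above the abundance curve
  (a few large-bodied taxa dominate the biomass while numbers are
  spread more evenly);
* **moderately stressed** -- the curves intersect;
* **heavily stressed** -- the abundance curve lies above the biomass
  curve (numerically dominant small-bodied taxa).

Each curve is ranked by its own variable.  The comparison runs over
ranks 1..R-1; the terminal rank, where both curves equal 100 %, is
vacuous and excluded.  Exact equality of the two curves over all
compared ranks counts as the intersecting (moderate) case, since
neither curve lies above the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CommunityTable, HabitatPartition, ValidationError

__all__ = [
    "StressState",
    "DominanceCurveSet",
    "k_dominance_curve",
    "classify_abc",
    "abc_analysis",
]

_TOL = 1e-9  # on the cumulative-percentage scale


class StressState(str, Enum):
    UNSTRESSED = "unstressed"
    MODERATELY_STRESSED = "moderately_stressed"
    HEAVILY_STRESSED = "heavily_stressed"


def k_dominance_curve(values: Sequence[float]) -> np.ndarray:
    """Cumulative percentage against descending rank.

    Ties keep the stable order of the input; zero entries trail at
    100 %.  The curve is invariant under positive rescaling of the
    input.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError("expected a non-empty 1-D vector")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValidationError("quantities must be finite and non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValidationError("k-dominance curve undefined for an all-zero vector")
    order = np.argsort(-arr, kind="stable")
    return np.cumsum(arr[order]) / total * 100.0


@dataclass
class DominanceCurveSet:
    biomass_curve: np.ndarray
    abundance_curve: np.ndarray
    classification: StressState
    crossing_ranks: list[int]

    def to_frame(self) -> pd.DataFrame:
        r = np.arange(1, len(self.biomass_curve) + 1)
        return pd.DataFrame(
            {
                "rank": r,
                "cum_biomass_pct": self.biomass_curve,
                "cum_abundance_pct": self.abundance_curve,
            }
        )


def classify_abc(
    biomass: Sequence[float], abundance: Sequence[float]
) -> tuple[StressState, list[int]]:
    """ABC stress classification from paired biomass/abundance vectors.

    Both vectors cover the same taxon set; each curve is ranked by its
    own variable.  ``crossing_ranks`` lists the (1-based) ranks at
    which the sign of (biomass - abundance) changes.  Swapping the two
    vectors maps unstressed <-> heavily stressed and fixes the
    moderate class.
    """
    b = np.asarray(biomass, dtype=float)
    a = np.asarray(abundance, dtype=float)
    if b.shape != a.shape:
        raise ValidationError("biomass and abundance must cover the same taxa")
    if b.size < 2:
        raise ValidationError("ABC classification needs at least two taxa")
    cb = k_dominance_curve(b)
    ca = k_dominance_curve(a)
    diff = cb - ca

    crossings: list[int] = []
    last_sign = 0
    for r, d in enumerate(diff, start=1):
        sign = 0 if abs(d) <= _TOL else (1 if d > 0 else -1)
        if sign != 0:
            if last_sign != 0 and sign != last_sign:
                crossings.append(r)
            last_sign = sign

    inner = diff[:-1]  # terminal rank (both 100 %) excluded
    above = inner > _TOL
    below = inner < -_TOL
    if above.any() and not below.any():
        state = StressState.UNSTRESSED
    elif below.any() and not above.any():
        state = StressState.HEAVILY_STRESSED
    else:
        state = StressState.MODERATELY_STRESSED
    return state, crossings


def abc_analysis(
    table: CommunityTable, partition: HabitatPartition
) -> dict[str, DominanceCurveSet]:
    """Per-habitat ABC curves; replicate samples are pooled (summed) first."""
    if table.abundance is None:
        raise ValidationError("ABC analysis requires an abundance matrix")
    out: dict[str, DominanceCurveSet] = {}
    for hab, sids in partition.groups.items():
        b = table.biomass[list(sids)].sum(axis=1).to_numpy()
        a = table.abundance[list(sids)].sum(axis=1).to_numpy()
        state, crossings = classify_abc(b, a)
        out[hab] = DominanceCurveSet(
            biomass_curve=k_dominance_curve(b),
            abundance_curve=k_dominance_curve(a),
            classification=state,
            crossing_ranks=crossings,
        )
    return out
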