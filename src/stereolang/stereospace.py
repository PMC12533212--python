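"""Competence–warmth geometry: 4D stereotype points and distance contrasts.

Each social group (and the AI category itself) is placed in a 4-dimensional
space whose axes are its association effects with high-vs-low competence and
high-vs-low warmth under two independent attribute dictionaries
(competence_A, warmth_A, competence_B, warmth_B). The Euclidean distance from
the AI point to each group's point measures how similar the group's stereotype
profile is to AI's; regressing distance on the group's advantaged /
disadvantaged status (with a fixed effect for the measurement method) tests
whether AI sits closer to advantaged groups. Status is coded
disadvantaged = 1, so a positive slope means disadvantaged groups lie farther
from AI.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .effects import EffectEstimate
from .errors import ComparabilityError, DesignError, SchemaError

Method = Literal["scweat", "fmat"]
Status = Literal["advantaged", "disadvantaged", "none"]

#: Canonical axis order of the 4D space.
DIMENSION_LABELS = ("competence_a", "warmth_a", "competence_b", "warmth_b")


@dataclass(frozen=True)
class StereotypePoint:
    """A group's coordinates in the 4D competence–warmth space."""

    group: str
    method: Method
    coords: tuple[float, float, float, float]
    status: Status = "none"

    def __post_init__(self):
        if len(self.coords) != 4 or not all(np.isfinite(self.coords)):
            raise SchemaError(f"point for '{self.group}' needs 4 finite coordinates")


@dataclass(frozen=True)
class DistanceRecord:
    """Distance from the AI point to one group's point, by one method."""

    group: str
    method: Method
    distance: float
    status: Status

    def __post_init__(self):
        if self.distance < 0:
            raise SchemaError("distance must be non-negative")


def build_point(group: str, assoc: Mapping[str, float], method: Method = "scweat",
                status: Status = "none") -> StereotypePoint:
    """Assemble a point from a map of exactly the four labeled effects.

    Keys must be exactly :data:`DIMENSION_LABELS` (any order); coordinates are
    stored in canonical order.
    """
    keys = set(assoc)
    expected = set(DIMENSION_LABELS)
    if keys != expected:
        missing, extra = expected - keys, keys - expected
        parts = []
        if missing:
            parts.append(f"missing {sorted(missing)}")
        if extra:
            parts.append(f"unexpected {sorted(extra)}")
        raise SchemaError(f"point for '{group}': " + "; ".join(parts))
    coords = tuple(float(assoc[k]) for k in DIMENSION_LABELS)
    return StereotypePoint(group=group, method=method, coords=coords, status=status)


def euclidean_distance(a: StereotypePoint, b: StereotypePoint) -> float:
    """Euclidean distance between two same-method points."""
    if a.method != b.method:
        raise ComparabilityError(
            f"cannot compare points measured by different methods "
            f"({a.method} vs {b.method})")
    return float(np.linalg.norm(np.asarray(a.coords) - np.asarray(b.coords)))


def distances_from(anchor: StereotypePoint,
                   points: Sequence[StereotypePoint]) -> list[DistanceRecord]:
    """Distance records from an anchor (the AI point) to each group point."""
    return [
        DistanceRecord(group=p.group, method=p.method,
                       distance=euclidean_distance(anchor, p), status=p.status)
        for p in points
    ]


def advantaged_contrast(records: Sequence[DistanceRecord],
                        source: dict | None = None) -> EffectEstimate:
    """OLS of distance on status (disadvantaged = 1) with method fixed effects.

    The method dummies absorb any additive scale offset between the embedding
    and fill-mask branches; the returned slope is the extra distance of
    disadvantaged groups from AI, in the distance units of the 4D space.
    """
    statuses = {r.status for r in records}
    if not {"advantaged", "disadvantaged"} <= statuses:
        raise DesignError("both advantaged and disadvantaged records are required")
    y = np.array([r.distance for r in records], dtype=np.float64)
    status = np.array([1.0 if r.status == "disadvantaged" else 0.0 for r in records])
    methods = sorted({r.method for r in records})
    cols = [status]
    for m in methods[1:]:  # first method is the reference level
        cols.append(np.array([1.0 if r.method == m else 0.0 for r in records]))
    X = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return EffectEstimate(
        estimate=float(fit.params[1]), se=float(fit.bse[1]),
        ci_low=float(ci[1][0]), ci_high=float(ci[1][1]),
        p=float(fit.pvalues[1]), n_obs=len(records),
        source=source or {"method": "stereospace"},
    )
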