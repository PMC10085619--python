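"""Bench-side study formulas: co-culture proliferation rate and caliper
tumor volume.

Both are trivial arithmetic, but implementing them once, with validated
inputs and a tidy-table helper, keeps the experimental computations
reproducible from tabulated measurements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

__all__ = [
    "CocultureCounts",
    "TumorMeasurement",
    "relative_proliferation_rate",
    "tumor_volume",
    "add_tumor_volumes",
]


@dataclass(frozen=True)
class CocultureCounts:
    """Cell counts from one co-culture field vs its control field.

    ``co_total`` is the total cell count in the co-culture field and
    ``co_marker`` the marker-positive (therapeutic) cells in the same field,
    so the target-cell count in co-culture is ``co_total - co_marker``.
    The control well is seeded with twice the target cells, hence the
    factor 2 in the rate formula.
    """

    co_total: int
    co_marker: int
    control_count: int

    def __post_init__(self) -> None:
        if self.co_total < 0 or self.co_marker < 0:
            raise ValidationError("cell counts must be non-negative")
        if self.co_marker > self.co_total:
            raise ValidationError(
                f"marker-positive count {self.co_marker} exceeds total {self.co_total}"
            )
        if self.control_count <= 0:
            raise ValidationError("control_count must be positive")


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper width and length in mm; width is the smaller axis.

    If supplied reversed the axes are swapped with a warning — the volume
    formula is not symmetric in its arguments.
    """

    width: float
    length: float

    def __post_init__(self) -> None:
        w, l = float(self.width), float(self.length)
        if not (math.isfinite(w) and math.isfinite(l) and w > 0 and l > 0):
            raise ValidationError(
                f"tumor dimensions must be positive and finite, got ({w!r}, {l!r})"
            )
        if w > l:
            warnings.warn(
                f"width {w} > length {l}: swapping (width is the smaller axis)",
                stacklevel=2,
            )
            w, l = l, w
        object.__setattr__(self, "width", w)
        object.__setattr__(self, "length", l)


def relative_proliferation_rate(counts: CocultureCounts) -> float:
    """Target-cell proliferation in co-culture relative to control, in %.

    ``((co_total - co_marker) * 2 / control_count) * 100`` — the factor 2
    compensates for the control well being seeded at double density.
    """
    return (counts.co_total - counts.co_marker) * 2 / counts.control_count * 100.0


def tumor_volume(m: TumorMeasurement) -> float:
    """Ellipsoid-style caliper volume in mm^3: width^2 * length * 0.5."""
    return m.width ** 2 * m.length * 0.5


def add_tumor_volumes(measurements: pd.DataFrame) -> pd.DataFrame:
    """Append a ``volume_mm3`` column to a tidy measurements table.

    Expects columns ``width_mm`` and ``length_mm``; other columns
    (animal_id, day, body_weight_g, group, ...) pass through untouched.
    """
    missing = {"width_mm", "length_mm"} - set(measurements.columns)
    if missing:
        raise ValidationError(f"measurements table missing columns: {sorted(missing)}")
    out = measurements.copy()
    out["volume_mm3"] = [
        tumor_volume(TumorMeasurement(w, l))
        for w, l in zip(out["width_mm"], out["length_mm"])
    ]
    return out
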