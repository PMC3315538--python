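"""Turn fitted interval weights into the clinician-facing integer score chart.

The chart lists, per variable, its intervals and integer points.  The
reference interval (leftmost interval, reference level, or binary value 0)
always earns 0 points and is omitted from rendered questions; all other
points are obtained by normalising the anchored weights so the smallest
non-zero magnitude becomes 1 and rounding to the nearest integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .optimizer import IntervalWeights
from .variables import (
    InputError,
    ThresholdGrid,
    VariableSpec,
    interval_bounds,
    is_missing,
)

__all__ = ["ScoreEntry", "ScoreTable", "anchor_weights", "normalize_and_round", "score_patient"]


@dataclass
class ScoreEntry:
    """One chart row: an interval (or level) of a variable and its points."""

    points: int
    lower: float | None = None  # continuous: half-open [lower, upper)
    upper: float | None = None
    level: object = None  # categorical/binary: the level this row matches

    def contains(self, value) -> bool:
        if self.level is not None:
            return value == self.level or str(value) == str(self.level)
        lo_ok = self.lower is None or value >= self.lower
        hi_ok = self.upper is None or value < self.upper
        return lo_ok and hi_ok

    def describe(self, unit: str = "") -> str:
        u = f" {unit}" if unit else ""
        if self.level is not None:
            return f"equal to {self.level}"
        if self.lower is None and self.upper is None:
            return "any value"
        if self.lower is None:
            return f"less than {self.upper:g}{u}"
        if self.upper is None:
            return f"{self.lower:g}{u} or more (included)"
        return f"between {self.lower:g} (included) and {self.upper:g}{u}"


@dataclass
class ScoreTable:
    """Integer points per (variable, interval): the printable chart itself."""

    variables: list  # display order
    entries: dict  # variable -> ordered list[ScoreEntry], reference first
    kinds: dict = field(default_factory=dict)  # variable -> kind
    units: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def is_empty(self) -> bool:
        return all(all(e.points == 0 for e in rows) for rows in self.entries.values())

    def selected_variables(self) -> list:
        return [v for v in self.variables if any(e.points != 0 for e in self.entries[v])]

    def score_range(self):
        """(min, max) attainable total score."""
        lo = sum(min(e.points for e in rows) for rows in self.entries.values())
        hi = sum(max(e.points for e in rows) for rows in self.entries.values())
        return int(lo), int(hi)


def anchor_weights(w: IntervalWeights) -> IntervalWeights:
    """Shift each variable block so its reference interval has weight 0.

    The subtracted amounts are folded into the intercept, so f(x) is
    unchanged for every input; idempotent.
    """
    values = w.values.copy()
    b = w.intercept
    for var, sl in w.blocks.items():
        ref = values[sl.start]
        if ref != 0.0:
            values[sl] -= ref
            b += ref
    return IntervalWeights(values=values, intercept=float(b), columns=list(w.columns), blocks=dict(w.blocks))


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def normalize_and_round(
    w: IntervalWeights,
    specs: dict | None = None,
    grids: dict | None = None,
    zero_tol: float = 1e-8,
    metadata: dict | None = None,
) -> ScoreTable:
    """Normalise anchored weights (smallest non-zero magnitude -> 1), round
    to nearest integer (ties away from zero), and merge adjacent intervals
    whose rounded points coincide.

    ``specs``/``grids`` attach interval bounds and level labels; without them
    entries carry only points in interval order.
    """
    w = anchor_weights(w)
    mags = np.abs(w.values)
    # absolute floor plus a relative guard against solver dust
    if mags.max() > 0:
        zero_tol = max(zero_tol, 1e-3 * mags.max())
    nonzero = mags[mags > zero_tol]
    variables = list(w.blocks.keys())

    def spec_of(var):
        if specs and var in specs:
            return specs[var]
        return None

    entries: dict = {}
    if nonzero.size == 0:
        table = ScoreTable(variables=[], entries={}, metadata=metadata or {})
        return table

    m = float(nonzero.min())
    kinds, units = {}, {}
    for var in variables:
        sl = w.blocks[var]
        pts = [
            0 if mags[c] <= zero_tol else _round_half_away(w.values[c] / m)
            for c in range(sl.start, sl.stop)
        ]
        s = spec_of(var)
        kind = s.kind if s else "continuous"
        kinds[var] = kind
        units[var] = s.unit if s else ""
        rows: list[ScoreEntry] = []
        if kind == "continuous":
            grid = grids.get(var) if grids else None
            for j, p in enumerate(pts):
                if grid is not None:
                    lo, hi = interval_bounds(grid, j)
                else:
                    lo, hi = float(j), float(j + 1)  # positional placeholder
                if rows and rows[-1].points == p:
                    rows[-1].upper = hi  # merge fused neighbours
                else:
                    rows.append(ScoreEntry(points=p, lower=lo, upper=hi))
            if grid is None:
                rows[0].lower, rows[-1].upper = None, None
        else:
            levels = s.levels if s else list(range(len(pts)))
            rows = [ScoreEntry(points=p, level=lev) for p, lev in zip(pts, levels)]
        entries[var] = rows

    return ScoreTable(
        variables=variables, entries=entries, kinds=kinds, units=units, metadata=metadata or {}
    )


def score_patient(record, table: ScoreTable) -> int:
    """Total integer score: sum of the points of the interval containing each
    covariate value; missing values earn 0 points."""
    total = 0
    for var in table.variables:
        value = record.get(var) if hasattr(record, "get") else record[var]
        if is_missing(value):
            continue
        rows = table.entries[var]
        if table.kinds.get(var, "continuous") == "continuous":
            value = float(value)
        hit = next((e for e in rows if e.contains(value)), None)
        if hit is None:
            raise InputError(f"value {value!r} outside declared intervals/levels of {var!r}")
        total += hit.points
    return int(total)
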