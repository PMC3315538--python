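"""Variable declarations, candidate threshold grids and interval-indicator encoding.

An interval-coded model represents each covariate by a block of binary
indicators, one per interval (continuous), per level (categorical) or per
value (binary).  Within a block the indicators partition the domain: every
patient activates exactly one column of every block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VariableSpec",
    "ThresholdGrid",
    "IndicatorMatrix",
    "InputError",
    "is_missing",
    "build_threshold_grid",
    "interval_of",
    "encode_dataset",
    "n_intervals",
    "interval_bounds",
]

#: Recognised missing markers in raw tabular input.
MISSING_MARKERS = {"", "NA", "NaN", "nan", None}


class InputError(ValueError):
    """Raised on malformed patient data (bad type, unknown category level)."""


def is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() in MISSING_MARKERS:
        return True
    return False


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one covariate.

    Parameters
    ----------
    name : unique identifier (CSV column name).
    kind : ``"continuous"``, ``"categorical"`` or ``"binary"``.
    levels : ordered category labels; required for categorical variables.
        Binary variables always use levels ``(0, 1)``.
    unit : free-text display unit (years, mm, ...).
    """

    name: str
    kind: str
    levels: tuple = ()
    unit: str = ""

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical", "binary"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "categorical":
            if len(self.levels) < 2:
                raise ValueError(f"categorical variable {self.name!r} needs >=2 levels")
            object.__setattr__(self, "levels", tuple(self.levels))
        elif self.kind == "binary":
            object.__setattr__(self, "levels", (0, 1))
        else:
            object.__setattr__(self, "levels", ())


@dataclass(frozen=True)
class ThresholdGrid:
    """Ordered candidate cut points for one continuous variable.

    ``K`` thresholds define ``K + 1`` half-open intervals
    ``(-inf, t1), [t1, t2), ..., [tK, +inf)`` — lower bounds included,
    upper bounds excluded.  An empty grid means the variable cannot be
    split and contributes a single interval.
    """

    variable: str
    thresholds: tuple = ()

    def __post_init__(self):
        t = tuple(float(x) for x in self.thresholds)
        if any(a >= b for a, b in zip(t, t[1:])):
            raise ValueError(f"thresholds for {self.variable!r} must be strictly increasing")
        object.__setattr__(self, "thresholds", t)


def build_threshold_grid(
    values,
    variable: str = "x",
    strategy: str = "quantile",
    max_cuts: int = 20,
    precision: int | None = None,
) -> ThresholdGrid:
    """Construct a dense candidate grid from observed values.

    ``strategy="unique"`` uses every distinct observed value except the
    minimum as a cut (thinned evenly if more than ``max_cuts``);
    ``strategy="quantile"`` places ``max_cuts`` equally spaced empirical
    quantiles and de-duplicates.  Missing values are ignored.  The
    optimizer is expected to fuse most candidate cuts away, so grids err
    on the dense side.
    """
    vals = [v for v in values if not is_missing(v)]
    if not vals:
        raise InputError(f"no non-missing values for variable {variable!r}")
    try:
        arr = np.asarray(vals, dtype=float)
    except (TypeError, ValueError) as exc:
        raise InputError(f"non-numeric value for continuous variable {variable!r}") from exc
    if np.isnan(arr).any():
        arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise InputError(f"no non-missing values for variable {variable!r}")
    if max_cuts < 1:
        raise ValueError("max_cuts must be >= 1")

    lo = arr.min()
    if strategy == "unique":
        cuts = np.unique(arr)
        cuts = cuts[cuts > lo]
        if cuts.size > max_cuts:
            idx = np.linspace(0, cuts.size - 1, max_cuts).round().astype(int)
            cuts = cuts[np.unique(idx)]
    elif strategy == "quantile":
        qs = np.arange(1, max_cuts + 1) / (max_cuts + 1)
        cuts = np.quantile(arr, qs)
        cuts = np.unique(cuts)
        cuts = cuts[cuts > lo]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    if precision is not None:
        cuts = np.unique(np.round(cuts, precision))
        cuts = cuts[cuts > lo]
    return ThresholdGrid(variable=variable, thresholds=tuple(cuts.tolist()))


def interval_of(value, grid: ThresholdGrid) -> int:
    """0-based index of the half-open interval containing ``value``.

    Lower bounds are included, upper bounds excluded: with thresholds
    ``[40, 60]``, a value of 40 or 56 falls in interval 1 and 60 in
    interval 2.
    """
    if is_missing(value):
        raise InputError("interval_of: value is missing; handle missing upstream")
    return int(np.searchsorted(grid.thresholds, float(value), side="right"))


def n_intervals(spec: VariableSpec, grid: ThresholdGrid | None) -> int:
    """Number of indicator columns of a variable's block."""
    if spec.kind == "continuous":
        k = len(grid.thresholds) if grid is not None else 0
        return k + 1
    return len(spec.levels)


def interval_bounds(grid: ThresholdGrid, j: int):
    """(lower, upper) of interval ``j``; ``None`` encodes an infinite bound."""
    t = grid.thresholds
    lo = t[j - 1] if j >= 1 else None
    hi = t[j] if j < len(t) else None
    return lo, hi


@dataclass
class IndicatorMatrix:
    """Binary interval-indicator design matrix with one-hot variable blocks.

    Attributes
    ----------
    X : (n, m) float array of 0/1 indicators.
    y : (n,) array of labels in {-1, +1}.
    columns : list of (variable name, interval/level index) per column.
    blocks : variable name -> slice of its column range.
    specs, grids : the declarations the matrix was built from.
    """

    X: np.ndarray
    y: np.ndarray
    columns: list
    blocks: dict
    specs: dict = field(default_factory=dict)
    grids: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]


def _encode_value(spec: VariableSpec, grid: ThresholdGrid | None, value) -> int:
    """Column index within the variable's block; missing maps to the reference."""
    if is_missing(value):
        return 0
    if spec.kind == "continuous":
        try:
            return interval_of(float(value), grid)
        except (TypeError, ValueError) as exc:
            raise InputError(
                f"non-numeric value {value!r} for continuous variable {spec.name!r}"
            ) from exc
    if spec.kind == "binary":
        iv = int(float(value))
        if iv not in (0, 1):
            raise InputError(f"binary variable {spec.name!r} got value {value!r}")
        return iv
    # categorical
    try:
        return spec.levels.index(value)
    except ValueError:
        # tolerate numeric-vs-string level representations from CSV round-trips
        for i, lev in enumerate(spec.levels):
            if str(lev) == str(value):
                return i
        raise InputError(
            f"unknown level {value!r} for categorical variable {spec.name!r} "
            f"(levels: {list(spec.levels)})"
        ) from None


def encode_dataset(records, specs, grids, outcomes) -> IndicatorMatrix:
    """Expand raw patient records into the one-hot interval representation.

    ``records`` is a sequence of mappings variable name -> raw value;
    ``grids`` a mapping or sequence of :class:`ThresholdGrid` covering the
    continuous variables; ``outcomes`` labels in {-1, +1}.
    """
    if not isinstance(grids, dict):
        grids = {g.variable: g for g in grids}
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate variable names")

    y = np.asarray(outcomes, dtype=float)
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise InputError("outcome labels must be in {-1, +1}")

    columns, blocks = [], {}
    for s in specs:
        g = grids.get(s.name) if s.kind == "continuous" else None
        if s.kind == "continuous" and g is None:
            raise ValueError(f"missing threshold grid for continuous variable {s.name!r}")
        start = len(columns)
        columns.extend((s.name, j) for j in range(n_intervals(s, g)))
        blocks[s.name] = slice(start, len(columns))

    X = np.zeros((len(records), len(columns)))
    for i, rec in enumerate(records):
        for s in specs:
            if s.name not in rec:
                raise InputError(f"row {i}: missing variable {s.name!r}")
            g = grids.get(s.name) if s.kind == "continuous" else None
            try:
                j = _encode_value(s, g, rec[s.name])
            except InputError as exc:
                raise InputError(f"row {i}: {exc}") from None
            X[i, blocks[s.name].start + j] = 1.0

    return IndicatorMatrix(
        X=X,
        y=y,
        columns=columns,
        blocks=blocks,
        specs={s.name: s for s in specs},
        grids=grids,
    )
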