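"""JSON (de)serialization of charts, risk tables and fitted models.

The model JSON schema (version 1) bundles the variable declarations, the
integer score chart, the score-to-risk table, the link knots and fit
metadata.  Numbers are written at full precision with sorted keys so that
identical fits serialize byte-identically.
"""

from __future__ import annotations

import json

from .calibration import LinkFunction, RiskTable
from .scorechart import ScoreEntry, ScoreTable
from .variables import ThresholdGrid, VariableSpec

SCHEMA_VERSION = 1

__all__ = [
    "score_table_to_dict",
    "score_table_from_dict",
    "risk_table_to_dict",
    "risk_table_from_dict",
    "link_to_dict",
    "link_from_dict",
    "dumps",
]


def dumps(obj) -> str:
    return json.dumps(obj, indent=1, sort_keys=True, allow_nan=False)


def score_table_to_dict(table: ScoreTable) -> dict:
    return {
        "variables": list(table.variables),
        "kinds": dict(table.kinds),
        "units": dict(table.units),
        "entries": {
            var: [
                {"points": e.points, "lower": e.lower, "upper": e.upper, "level": e.level}
                for e in rows
            ]
            for var, rows in table.entries.items()
        },
        "metadata": dict(table.metadata),
    }


def score_table_from_dict(d: dict) -> ScoreTable:
    entries = {
        var: [
            ScoreEntry(
                points=int(r["points"]),
                lower=r.get("lower"),
                upper=r.get("upper"),
                level=r.get("level"),
            )
            for r in rows
        ]
        for var, rows in d["entries"].items()
    }
    return ScoreTable(
        variables=list(d["variables"]),
        entries=entries,
        kinds=dict(d.get("kinds", {})),
        units=dict(d.get("units", {})),
        metadata=dict(d.get("metadata", {})),
    )


def risk_table_to_dict(rt: RiskTable) -> dict:
    return {"rows": [dict(row) for row in rt.rows]}


def risk_table_from_dict(d: dict) -> RiskTable:
    return RiskTable(rows=[dict(row) for row in d["rows"]])


def link_to_dict(link: LinkFunction) -> dict:
    return {
        "method": link.method,
        "knots": [[float(s), float(r)] for s, r in link.knots],
        "clip": list(link.clip),
    }


def link_from_dict(d: dict) -> LinkFunction:
    return LinkFunction(
        method=d["method"],
        knots=[(float(s), float(r)) for s, r in d["knots"]],
        clip=tuple(d["clip"]),
    )


def spec_to_dict(spec: VariableSpec) -> dict:
    return {"name": spec.name, "kind": spec.kind, "levels": list(spec.levels), "unit": spec.unit}


def spec_from_dict(d: dict) -> VariableSpec:
    kwargs = {"name": d["name"], "kind": d["kind"], "unit": d.get("unit", "")}
    if d["kind"] == "categorical":
        kwargs["levels"] = tuple(d["levels"])
    return VariableSpec(**kwargs)


def grid_to_dict(grid: ThresholdGrid) -> dict:
    return {"variable": grid.variable, "thresholds": list(grid.thresholds)}


def grid_from_dict(d: dict) -> ThresholdGrid:
    return ThresholdGrid(variable=d["variable"], thresholds=tuple(d["thresholds"]))
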