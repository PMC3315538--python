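"""Clinician-facing renderings: yes/no questionnaire, bar charts, color bars.

The questionnaire lists one yes/no question per non-reference interval with
its points, followed by the score-to-risk lookup.  The bar rendering draws
one horizontal bar per variable segmented by interval; in color mode the
segments use a diverging blue (protective) / white (neutral) / red (risk)
scale symmetric about zero points.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import Normalize
from matplotlib.patches import Rectangle

from .calibration import RiskTable
from .scorechart import ScoreTable

__all__ = ["render_questionnaire", "render_bars"]


def _question_text(table: ScoreTable, var: str, entry) -> str:
    unit = table.units.get(var, "")
    kind = table.kinds.get(var, "continuous")
    if kind == "continuous":
        return f"Is {var} {entry.describe(unit)}?"
    if kind == "binary":
        return f"Is {var} present?"
    return f"Is {var} {entry.describe()}?"


def _rows(table: ScoreTable):
    for var in table.variables:
        for e in table.entries[var]:
            if e.points != 0:
                yield var, e


def render_questionnaire(table: ScoreTable, risks: RiskTable, format: str = "text") -> str:
    """Render the chart and risk lookup as text, markdown or HTML."""
    if format not in ("text", "markdown", "html"):
        raise ValueError(f"unknown format {format!r}")
    if table.is_empty():
        return "no variables selected"

    qa = [(_question_text(table, var, e), e.points) for var, e in _rows(table)]
    risk_rows = [
        (
            f"{r['lo']}" if r["lo"] == r["hi"] else f"{r['lo']} to {r['hi']}",
            r.get("display", f"{r['risk']:.2f}"),
        )
        for r in risks.rows
    ]

    if format == "text":
        width = max(len(q) for q, _ in qa)
        lines = ["Question".ljust(width) + "  Points"]
        lines += [q.ljust(width) + f"  {p:+d}".replace("+", " ") if p > 0 else q.ljust(width) + f"  {p:d}" for q, p in qa]
        lines.append("")
        lines.append("Score -> Risk")
        lines += [f"  {rng:<10} {disp}" for rng, disp in risk_rows]
        return "\n".join(lines)
    if format == "markdown":
        lines = ["| Question | Points |", "| --- | --- |"]
        lines += [f"| {q} | {p} |" for q, p in qa]
        lines += ["", "| Score | Risk |", "| --- | --- |"]
        lines += [f"| {rng} | {disp} |" for rng, disp in risk_rows]
        return "\n".join(lines)
    # html
    body = ["<table><tr><th>Question</th><th>Points</th></tr>"]
    body += [f"<tr><td>{q}</td><td>{p}</td></tr>" for q, p in qa]
    body.append("</table>")
    body.append("<table><tr><th>Score</th><th>Risk</th></tr>")
    body += [f"<tr><td>{rng}</td><td>{disp}</td></tr>" for rng, disp in risk_rows]
    body.append("</table>")
    return "\n".join(body)


def _segment_color(points: int, max_abs: int, color: bool):
    if not color:
        return "#d9d9d9"
    cmap = plt.get_cmap("RdBu_r")
    norm = Normalize(vmin=-max_abs, vmax=max_abs)
    return cmap(norm(points))


def render_bars(table: ScoreTable, risks: RiskTable, color: bool = False, file: str = "bars.svg"):
    """Draw the bar-chart representation and save it to ``file``.

    One horizontal bar per variable, segmented by interval and labelled
    with points; a bottom bar maps total score ranges to risks.  Styling is
    pinned (including the SVG hash salt) so repeated renders of the same
    model are byte-stable.
    """
    if table.is_empty():
        raise ValueError("cannot render an empty score table")
    plt.rcParams["svg.hashsalt"] = "icscore"

    variables = table.variables
    max_abs = max(
        (abs(e.points) for rows in table.entries.values() for e in rows), default=1
    )
    max_abs = max(max_abs, 1)

    fig, ax = plt.subplots(figsize=(8, 0.6 * (len(variables) + 2)))
    yticks, ylabels = [], []
    for row_i, var in enumerate(variables):
        rows = table.entries[var]
        n_seg = len(rows)
        y = len(variables) - row_i
        for seg_i, e in enumerate(rows):
            x0 = seg_i / n_seg
            ax.add_patch(
                Rectangle(
                    (x0, y - 0.35),
                    1.0 / n_seg,
                    0.7,
                    facecolor=_segment_color(e.points, max_abs, color),
                    edgecolor="black",
                    linewidth=0.8,
                )
            )
            ax.text(
                x0 + 0.5 / n_seg, y, f"{e.points:d}", ha="center", va="center", fontsize=9
            )
        yticks.append(y)
        ylabels.append(var)

    # bottom bar: score ranges -> risk
    n_r = len(risks.rows)
    for i, r in enumerate(risks.rows):
        x0 = i / n_r
        ax.add_patch(
            Rectangle(
                (x0, -0.35),
                1.0 / n_r,
                0.7,
                facecolor=_segment_color(0, 1, False),
                edgecolor="black",
                linewidth=0.8,
            )
        )
        rng = f"{r['lo']}" if r["lo"] == r["hi"] else f"{r['lo']}..{r['hi']}"
        ax.text(x0 + 0.5 / n_r, 0.12, rng, ha="center", va="center", fontsize=6)
        ax.text(
            x0 + 0.5 / n_r,
            -0.15,
            r.get("display", str(r["risk"])),
            ha="center",
            va="center",
            fontsize=6,
        )
    yticks.append(0)
    ylabels.append("score -> risk")

    ax.set_xlim(0, 1)
    ax.set_ylim(-0.8, len(variables) + 0.8)
    ax.set_yticks(yticks)
    ax.set_yticklabels(ylabels)
    ax.set_xticks([])
    for spine in ax.spines.values():
        spine.set_visible(False)
    fig.tight_layout()
    fig.savefig(file, metadata={"Date": None} if str(file).endswith(".svg") else None)
    plt.close(fig)
    return file
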