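"""Report rendering for portfolio results.

Three deterministic serialisations of a :class:`~lifeyears.model.PortfolioResults`:

* ``"table"`` — a human-readable plain-text layout with a per-row gains
  table, a durations/life-years-lost table, the counterfactual-savings
  table, and a summary block with both median conventions labelled;
* ``"delimited"`` — CSV with full-precision columns alongside
  presentation-rounded ones;
* ``"json"`` — a JSON document that reparses to equal values.
"""

from __future__ import annotations

import io
import json
from typing import Dict, List

from ._rounding import round_half_away
from .model import PortfolioResults

__all__ = ["REPORT_FORMATS", "render_report"]

REPORT_FORMATS = ("table", "delimited", "json")

_SHORT = {"north_america": "na", "worldwide": "ww"}


def _row_records(result: PortfolioResults) -> List[Dict]:
    records = []
    for r in result.rows:
        rec: Dict = {
            "drug": r.key[0],
            "site": r.key[1],
            "subgroup": r.key[2],
            "duration_years": r.duration_years,
        }
        for region in result.config.regions:
            s = _SHORT[region]
            rec[f"per_year_{s}"] = r.per_year[region]
            rec[f"life_years_lost_{s}"] = r.life_years_lost[region]
            rec[f"scenario_saved_{s}"] = r.scenario_saved[region]
        records.append(rec)
    return records


def _render_json(result: PortfolioResults) -> str:
    doc = {
        "provenance": result.provenance,
        "config": {
            "target_years": result.config.target_years,
            "treated_fraction": result.config.treated_fraction,
            "median_convention": result.config.median_convention,
            "regions": list(result.config.regions),
            "rounding": result.config.rounding,
        },
        "rows": _row_records(result),
        "summaries": {
            f"{metric}[{region}]": {
                "n": s.n,
                "median_standard": s.median_standard,
                "median_paper": s.median_paper,
                "minimum": s.minimum,
                "maximum": s.maximum,
                "cumulative": s.cumulative,
            }
            for (metric, region), s in result.summaries.items()
        },
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def _render_delimited(result: PortfolioResults) -> str:
    records = _row_records(result)
    value_cols = [c for c in records[0] if c not in ("drug", "site", "subgroup")]
    header = ["drug", "site", "subgroup"]
    for c in value_cols:
        header += [c, f"{c}_rounded"]
    out = io.StringIO()
    out.write(",".join(header) + "\n")
    for rec in records:
        cells = [rec["drug"], rec["site"], rec["subgroup"]]
        for c in value_cols:
            v = rec[c]
            cells.append(repr(float(v)))
            nd = 1 if c == "duration_years" else 0
            cells.append(str(round_half_away(v, nd)))
        out.write(",".join(cells) + "\n")
    return out.getvalue()


def _render_table(result: PortfolioResults) -> str:
    cfg = result.config
    regions = cfg.regions
    lines: List[str] = []
    name_w = max(
        [len(f"{r.key[0]} ({r.key[1]}, {r.key[2]})") for r in result.rows] + [24]
    )

    def fmt_i(x: float) -> str:
        return f"{round_half_away(x):,}"

    lines.append("Life-years potentially gained per year of accelerated approval")
    head = f"{'scenario':<{name_w}}"
    for region in regions:
        head += f"{_SHORT[region]:>14}"
    lines.append(head)
    for r in result.rows:
        name = f"{r.key[0]} ({r.key[1]}, {r.key[2]})"
        line = f"{name:<{name_w}}"
        for region in regions:
            line += f"{fmt_i(r.per_year[region]):>14}"
        lines.append(line)
    lines.append("")

    lines.append("Development interval and life-years lost from discovery to approval")
    head = f"{'scenario':<{name_w}}{'years':>8}"
    for region in regions:
        head += f"{'lost_' + _SHORT[region]:>16}"
    lines.append(head)
    for r in result.rows:
        name = f"{r.key[0]} ({r.key[1]}, {r.key[2]})"
        line = f"{name:<{name_w}}{r.duration_years:>8.1f}"
        for region in regions:
            line += f"{fmt_i(r.life_years_lost[region]):>16}"
        lines.append(line)
    lines.append("")

    lines.append(
        f"Life-years saved had discovery-to-approval taken "
        f"{cfg.target_years:g} years"
    )
    head = f"{'scenario':<{name_w}}"
    for region in regions:
        head += f"{'saved_' + _SHORT[region]:>16}"
    lines.append(head)
    for r in result.rows:
        name = f"{r.key[0]} ({r.key[1]}, {r.key[2]})"
        line = f"{name:<{name_w}}"
        for region in regions:
            line += f"{fmt_i(r.scenario_saved[region]):>16}"
        lines.append(line)
    lines.append("")
    lines.append(result.summary())
    lines.append("")
    lines.append(f"provenance: {result.provenance}")
    return "\n".join(lines) + "\n"


def render_report(result: PortfolioResults, format: str = "table") -> str:
    """Serialise a portfolio result; pure and deterministic.

    Raises
    ------
    ValueError
        On an unknown format name.
    """
    if format not in REPORT_FORMATS:
        raise ValueError(
            f"unknown report format {format!r}; valid: {REPORT_FORMATS}"
        )
    if format == "json":
        return _render_json(result)
    if format == "delimited":
        return _render_delimited(result)
    return _render_table(result)
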