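"""Side-by-side significance grid comparing ANOVA and ALT conclusions.

Rows are factors (and interactions); columns are the mixed-ANOVA
between-subjects test, the ANOVA factor × day within test, and the ALT
paths onto the intercept and the slope.  Cells carry the underlying p
plus a label from a significance ladder (default 0.05 / 0.001, the
starring convention of the source tables).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .anova import AnovaResult
from .sem_core import FitResult

__all__ = ["ComparisonGrid", "comparison_report", "significance_label",
           "validate_json", "FIT_RESULT_SCHEMA", "COMPARISON_SCHEMA"]

DEFAULT_LADDER = (0.05, 0.001)

GAP = "(not fitted)"

COLUMNS = ("ANOVA between", "ANOVA within x day", "ALT intercept",
           "ALT slope")


def significance_label(p: float | None,
                       ladder: Sequence[float] = DEFAULT_LADDER) -> str:
    """Label ``p`` with the smallest ladder threshold it beats, else "ns"."""
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return GAP
    label = "ns"
    for threshold in sorted(ladder, reverse=True):
        if p < threshold:
            label = f"p < {threshold:g}"
    return label


@dataclass
class ComparisonGrid:
    rows: list[str]
    columns: tuple[str, ...]
    cells: dict[str, dict[str, dict]]  # row -> column -> {p, label}
    ladder: tuple[float, ...]

    def to_dict(self) -> dict:
        return {"columns": list(self.columns),
                "ladder": list(self.ladder),
                "rows": [{"factor": r, **{c: self.cells[r][c]
                                          for c in self.columns}}
                         for r in self.rows]}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_markdown(self) -> str:
        head = "| Factor | " + " | ".join(self.columns) + " |"
        sep = "|" + "---|" * (len(self.columns) + 1)
        lines = [head, sep]
        for r in self.rows:
            cells = [self.cells[r][c]["label"] for c in self.columns]
            lines.append("| " + " | ".join([r, *cells]) + " |")
        return "\n".join(lines)


def _cell(p: float | None, ladder: Sequence[float]) -> dict:
    return {"p": None if p is None or (isinstance(p, float) and math.isnan(p))
            else float(p),
            "label": significance_label(p, ladder)}


def comparison_report(anova: AnovaResult | None,
                      alt_fits: Mapping[str, FitResult],
                      alpha_ladder: Sequence[float] = DEFAULT_LADDER
                      ) -> ComparisonGrid:
    """Assemble the comparison grid.

    ``alt_fits`` maps a factor (or interaction, e.g. ``"stress_x_genotype"``)
    to the single-factor ALT fit whose parameter table contains
    ``<factor>_to_icept`` / ``<factor>_to_slope`` paths.  Rows missing from
    either side get an explicit gap marker, never a silent omission.
    """
    rows: list[str] = []
    if anova is not None:
        rows.extend(e for e in anova.between["effect"] if e != "Error")
    for f in alt_fits:
        name = f.replace("_x_", " * ")
        if name not in rows and f not in rows:
            rows.append(f)
    ladder = tuple(alpha_ladder)

    cells: dict[str, dict[str, dict]] = {}
    for row in rows:
        anova_key = row.replace("_x_", " * ")
        fit_key = row if row in alt_fits else row.replace(" * ", "_x_")
        entry: dict[str, dict] = {}
        p_bs = p_ws = None
        if anova is not None:
            try:
                p_bs = float(anova.effect(anova_key, "between")["p"])
            except KeyError:
                p_bs = None
            try:
                p_ws = float(anova.effect(f"{anova_key} * day", "within")["p_hf"])
            except KeyError:
                p_ws = None
        entry[COLUMNS[0]] = _cell(p_bs, ladder)
        entry[COLUMNS[1]] = _cell(p_ws, ladder)
        p_i = p_s = None
        fit = alt_fits.get(fit_key)
        if fit is not None:
            base = fit_key
            try:
                p_i = float(fit.parameter(f"{base}_to_icept")["p"])
                p_s = float(fit.parameter(f"{base}_to_slope")["p"])
            except KeyError:
                p_i = p_s = None
        entry[COLUMNS[2]] = _cell(p_i, ladder)
        entry[COLUMNS[3]] = _cell(p_s, ladder)
        cells[row] = entry
    return ComparisonGrid(rows=rows, columns=COLUMNS, cells=cells,
                          ladder=ladder)


# ---------------------------------------------------------------------------
# Output schemas (shipped, machine-checkable with validate_json)
# ---------------------------------------------------------------------------

FIT_RESULT_SCHEMA = {
    "type": "object",
    "required": ["parameters", "fit", "r2", "converged"],
    "properties": {
        "parameters": {"type": "array", "items": {
            "type": "object",
            "required": ["label", "estimate", "se", "cr", "p"],
        }},
        "fit": {"type": "object",
                "required": ["chi2", "df", "p", "cfi", "tli", "rmsea",
                             "rmsea_ci", "pclose"]},
        "r2": {"type": "object"},
        "converged": {"type": "boolean"},
    },
}

COMPARISON_SCHEMA = {
    "type": "object",
    "required": ["columns", "ladder", "rows"],
    "properties": {
        "columns": {"type": "array"},
        "ladder": {"type": "array"},
        "rows": {"type": "array", "items": {"type": "object",
                                            "required": ["factor"]}},
    },
}

_TYPES = {"object": dict, "array": list, "boolean": bool, "number": (int, float),
          "string": str}


def validate_json(obj, schema: dict, path: str = "$") -> list[str]:
    """Minimal structural validation against the shipped schema dialect
    (type + required + properties/items).  Returns a list of problems;
    empty means valid."""
    problems: list[str] = []
    t = schema.get("type")
    if t and not isinstance(obj, _TYPES[t]):
        return [f"{path}: expected {t}, got {type(obj).__name__}"]
    if isinstance(obj, dict):
        for key in schema.get("required", []):
            if key not in obj:
                problems.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                problems.extend(validate_json(obj[key], sub, f"{path}.{key}"))
    if isinstance(obj, list) and "items" in schema:
        for i, item in enumerate(obj):
            problems.extend(validate_json(item, schema["items"],
                                          f"{path}[{i}]"))
    return problems
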