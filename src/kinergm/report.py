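"""Human-readable summaries of a selected dyad model.

One row per non-intercept coefficient: the variable, the level (or level
pair) it refers to, the fold-increase in connection probability at the
fitted baseline, the Wald p-value, and the term family (Match / Diff /
Mix / Cov).  Non-significant rows are flagged; p-values below 1e-4 print
as "<1e-04".
"""

from __future__ import annotations

import math

import pandas as pd

from .fit import FitResult
from .select import SelectionResult

__all__ = ["summary_table", "format_table"]

_TYPE_LABEL = {
    "nodematch": "Match",
    "nodematch_diff": "Diff",
    "nodemix": "Mix",
    "edgecov": "Cov",
}

P_FLOOR = 1e-4


def _format_p(p: float) -> str:
    if not math.isfinite(p):
        return "NA"
    if p < P_FLOOR:
        return "<1e-04"
    return f"{p:.3f}"


def summary_table(result: SelectionResult | FitResult,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Table-style per-coefficient summary of a (chosen) fitted model."""
    fit = result.chosen_fit if isinstance(result, SelectionResult) else result
    rows = []
    for j, col in enumerate(fit.columns):
        if col == "edges":
            continue
        parts = col.split(".")
        kind = parts[0]
        variable = parts[1] if len(parts) > 1 else col
        level = "/".join(parts[2:]) if len(parts) > 2 else ""
        fold = fit.fold[j]
        p = fit.pvalues[j]
        rows.append(
            {
                "variable": variable,
                "level": level,
                "fold": math.inf if fit.separated[j] else round(float(fold), 2),
                "p_value": _format_p(p),
                "type": _TYPE_LABEL.get(kind, kind),
                "significant": bool(math.isfinite(p) and p <= alpha),
            }
        )
    return pd.DataFrame(rows,
                        columns=["variable", "level", "fold", "p_value",
                                 "type", "significant"])


def format_table(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of :func:`summary_table` output."""
    return table.to_string(index=False)
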