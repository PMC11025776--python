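"""Skim-style per-variable summary of a cleaned herd table.

One row per variable, grouped into sections by variable type (numeric,
factor, date, text), in schema order.  Quantiles use linear interpolation
(type 7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SummaryReport:
    """Sections keyed by variable type; each a DataFrame, one row per variable."""

    n_rows: int
    sections: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [f"rows: {self.n_rows}"]
        for kind, frame in self.sections.items():
            if frame.empty:
                continue
            lines.append("")
            lines.append(f"-- {kind} ({len(frame)} variables) --")
            lines.append(frame.to_string())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "sections": {k: v.reset_index().to_dict(orient="records") for k, v in self.sections.items()},
        }


def _base_stats(s: pd.Series) -> dict:
    n = len(s)
    n_missing = int(s.isna().sum())
    return {
        "n": n,
        "n_missing": n_missing,
        "complete_rate": (n - n_missing) / n if n else np.nan,
    }


def skim(table) -> SummaryReport:
    """Summarise every column of a (cleaned) herd table."""
    frame = getattr(table, "frame", table)
    numeric, factor, dates, text = [], [], [], []
    for col in frame.columns:
        s = frame[col]
        row = {"variable": col, **_base_stats(s)}
        vals = s.dropna()
        if isinstance(s.dtype, pd.CategoricalDtype):
            counts = vals.astype(str).value_counts()
            top = counts.head(5)
            row["n_levels"] = int(counts.size)
            row["top_counts"] = ", ".join(f"{k}: {v}" for k, v in top.items())
            factor.append(row)
        elif pd.api.types.is_datetime64_any_dtype(s):
            row["min"] = vals.min().date() if len(vals) else None
            row["max"] = vals.max().date() if len(vals) else None
            dates.append(row)
        elif pd.api.types.is_numeric_dtype(s):
            x = vals.astype(float).to_numpy()
            if len(x):
                q = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation
                row.update(
                    mean=float(np.mean(x)),
                    sd=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                    min=float(np.min(x)), p25=float(q[0]), p50=float(q[1]),
                    p75=float(q[2]), max=float(np.max(x)),
                )
            numeric.append(row)
        else:
            row["n_unique"] = int(vals.astype(str).nunique())
            text.append(row)

    def to_frame(rows):
        return (
            pd.DataFrame(rows).set_index("variable")
            if rows
            else pd.DataFrame(columns=["n", "n_missing", "complete_rate"])
        )

    return SummaryReport(
        n_rows=len(frame),
        sections={
            "numeric": to_frame(numeric),
            "factor": to_frame(factor),
            "date": to_frame(dates),
            "text": to_frame(text),
        },
    )
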