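"""Two-way categorical analysis: frequency tables and odds ratios.

The odds ratio table comes from a baseline-category multinomial logit of the
column variable on the row variable (fitted with statsmodels' MNLogit).  For
an all-positive 2x2 table the maximum-likelihood point estimate equals the
cross-product ratio (ad)/(bc) and the Wald interval equals
exp(log OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)); the model-based route
generalises this to RxC tables with one contrast per non-reference
(row level, column level) pair.  Cells of zero make a contrast non-estimable
and are reported as such rather than forced through a diverging fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import AnalysisError

__all__ = ["PivotTable", "crosstab", "fit_multinomial_or", "PivotOddsRatio"]


@dataclass
class PivotTable:
    """Two-way frequency table with margins and declared reference levels."""

    row_var: str
    col_var: str
    counts: pd.DataFrame  # index = row levels, columns = col levels (declared order)
    row_ref: str
    col_ref: str
    n_excluded_missing: int = 0

    @property
    def row_levels(self) -> list:
        return list(self.counts.index)

    @property
    def col_levels(self) -> list:
        return list(self.counts.columns)

    @property
    def row_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def with_margins(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["Total"] = self.row_sums
        total_row = out.sum(axis=0)
        total_row.name = "Total"
        return pd.concat([out, total_row.to_frame().T])


def _levels_of(series: pd.Series) -> list[str]:
    if isinstance(series.dtype, pd.CategoricalDtype):
        return [str(c) for c in series.cat.categories]
    vals = series.dropna().astype(str)
    if set(vals.unique()) <= {"0", "1"}:
        return ["0", "1"]
    freq = vals.value_counts()
    return sorted(freq.index, key=lambda lv: (freq[lv], lv))


def crosstab(table, row_var: str, col_var: str, row_ref=None, col_ref=None) -> PivotTable:
    """Two-way frequency table of two factor columns.

    Rows missing either variable are excluded (pairwise complete case) and
    counted on the result.  Level order follows the factors' declared order;
    the reference level defaults to the first level of each.
    """
    frame = getattr(table, "frame", table)
    for v in (row_var, col_var):
        if v not in frame.columns:
            raise AnalysisError(f"unknown variable {v!r}")
    if row_var == col_var:
        raise AnalysisError("row and column variable must differ")
    sub = frame[[row_var, col_var]].dropna()
    n_excl = len(frame) - len(sub)
    row_levels = _levels_of(frame[row_var])
    col_levels = _levels_of(frame[col_var])
    for name, lv in ((row_var, row_levels), (col_var, col_levels)):
        if len(lv) < 2:
            raise AnalysisError(
                f"variable {name!r} has a single level and cannot be tabulated"
            )
    counts = pd.crosstab(sub[row_var].astype(str), sub[col_var].astype(str))
    counts = counts.reindex(index=row_levels, columns=col_levels, fill_value=0)
    counts.index.name = row_var
    counts.columns.name = col_var
    row_ref = str(row_ref) if row_ref is not None else row_levels[0]
    col_ref = str(col_ref) if col_ref is not None else col_levels[0]
    for ref, lv, what in ((row_ref, row_levels, "row"), (col_ref, col_levels, "column")):
        if ref not in lv:
            raise AnalysisError(f"{what} reference level {ref!r} not among levels {lv}")
    return PivotTable(
        row_var=row_var, col_var=col_var, counts=counts.astype(int),
        row_ref=row_ref, col_ref=col_ref, n_excluded_missing=n_excl,
    )


def _mnlogit_or(counts: np.ndarray, conf_level: float) -> tuple[np.ndarray, np.ndarray]:
    """Fit the baseline-category logit on an all-positive R x C count matrix.

    Row 0 / column 0 are the reference levels.  Returns ``(log_or, se)`` of
    shape (R-1, C-1)."""
    R, C = counts.shape
    total = int(counts.sum())
    y = np.zeros(total, dtype=int)
    X = np.zeros((total, R), dtype=float)
    X[:, 0] = 1.0
    pos = 0
    for r in range(R):
        for c in range(C):
            k = int(counts[r, c])
            if k == 0:
                continue
            y[pos : pos + k] = c
            if r > 0:
                X[pos : pos + k, r] = 1.0
            pos += k
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MNLogit(y, X).fit(method="newton", maxiter=200, disp=0)
    params = np.asarray(res.params)  # (R, C-1); column j is level j+1 vs level 0
    bse = np.asarray(res.bse)
    return params[1:, :], bse[1:, :]


def fit_multinomial_or(pivot: PivotTable, conf_level: float = 0.95) -> pd.DataFrame:
    """Odds-ratio table for every non-reference (row, column) level pair.

    Returns a frame with columns row_level, col_level, log_or, se, or_point,
    ci_low, ci_high, estimable.  Contrasts whose 2x2 sub-table contains a
    zero cell are flagged non-estimable with a warning.
    """
    if not 0 < conf_level < 1:
        raise AnalysisError("conf_level must be in (0, 1)")
    counts = pivot.counts.copy()
    row_order = [pivot.row_ref] + [l for l in pivot.row_levels if l != pivot.row_ref]
    col_order = [pivot.col_ref] + [l for l in pivot.col_levels if l != pivot.col_ref]
    counts = counts.loc[row_order, col_order]
    mat = counts.to_numpy(dtype=float)
    R, C = mat.shape
    z = stats.norm.ppf(0.5 + conf_level / 2.0)

    log_or = np.full((R - 1, C - 1), np.nan)
    se = np.full((R - 1, C - 1), np.nan)
    estimable = np.zeros((R - 1, C - 1), dtype=bool)

    if (mat > 0).all():
        log_or, se = _mnlogit_or(mat, conf_level)
        estimable[:] = True
    else:
        warnings.warn(
            f"{pivot.row_var} x {pivot.col_var}: zero cells present; "
            "contrasts touching them are reported as non-estimable",
            stacklevel=2,
        )
        for r in range(1, R):
            for c in range(1, C):
                sub = mat[np.ix_([0, r], [0, c])]
                if (sub > 0).all():
                    lo, s = _mnlogit_or(sub, conf_level)
                    log_or[r - 1, c - 1] = lo[0, 0]
                    se[r - 1, c - 1] = s[0, 0]
                    estimable[r - 1, c - 1] = True

    rows = []
    for r in range(1, R):
        for c in range(1, C):
            lo, s, ok = log_or[r - 1, c - 1], se[r - 1, c - 1], estimable[r - 1, c - 1]
            rows.append(
                {
                    "row_level": row_order[r],
                    "col_level": col_order[c],
                    "log_or": lo if ok else np.nan,
                    "se": s if ok else np.nan,
                    "or_point": np.exp(lo) if ok else np.nan,
                    "ci_low": np.exp(lo - z * s) if ok else np.nan,
                    "ci_high": np.exp(lo + z * s) if ok else np.nan,
                    "estimable": bool(ok),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["conf_level"] = conf_level
    out.attrs["row_ref"] = pivot.row_ref
    out.attrs["col_ref"] = pivot.col_ref
    return out


class PivotOddsRatio(BaseEstimator):
    """Two-way pivot + odds-ratio analysis as a fit-shaped estimator.

    Parameters
    ----------
    row, col : str
        Factor column names for tabulation.
    row_ref, col_ref : str, optional
        Reference levels; default to the first declared level.
    conf_level : float, default 0.95
        Confidence level for the Wald intervals.

    After ``fit(table)``: ``pivot_`` (the :class:`PivotTable`),
    ``or_table_`` (the odds-ratio frame) and ``n_excluded_`` are available.
    """

    def __init__(self, row=None, col=None, row_ref=None, col_ref=None, conf_level=0.95):
        self.row = row
        self.col = col
        self.row_ref = row_ref
        self.col_ref = col_ref
        self.conf_level = conf_level

    def fit(self, X, y=None):
        if self.row is None or self.col is None:
            raise AnalysisError("row and col variables must be set before fit")
        self.pivot_ = crosstab(X, self.row, self.col, self.row_ref, self.col_ref)
        self.or_table_ = fit_multinomial_or(self.pivot_, self.conf_level)
        self.n_excluded_ = self.pivot_.n_excluded_missing
        return self
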