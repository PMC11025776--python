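"""Auto-detected linear / logistic / multinomial regression with sequential ANOVA.

The response type picks the model: numeric -> ordinary least squares,
two-level factor -> logistic, more levels -> baseline-category multinomial.
Categorical predictors enter as treatment-coded dummies against their
declared reference level (first category, i.e. '0' for binary indicators).
The ANOVA table is sequential (Type I, terms in user-entry order): sums of
squares for the linear model, likelihood-ratio analysis of deviance for the
others.  Wald confidence intervals are reported at 95%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import linalg as sla
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import AnalysisError

__all__ = ["detect_model_kind", "RegressionResult", "AutoRegression", "fit"]

#: |coefficient| beyond which a logistic term is treated as separated
_SEPARATION_BOUND = 15.0


def detect_model_kind(response: pd.Series) -> str:
    """Classify a response column: numeric -> 'linear', 2-level factor ->
    'logistic', >2 levels -> 'multinomial'.  A constant response is an error."""
    if pd.api.types.is_numeric_dtype(response):
        if response.dropna().nunique() <= 1:
            raise AnalysisError("response is constant; nothing to model")
        return "linear"
    n_levels = response.dropna().astype(str).nunique()
    if n_levels <= 1:
        raise AnalysisError("response is constant; nothing to model")
    return "logistic" if n_levels == 2 else "multinomial"


@dataclass
class RegressionResult:
    """Fitted model kind plus coefficient and sequential-ANOVA tables."""

    kind: str
    coef: pd.DataFrame
    anova: pd.DataFrame
    n_used: int
    n_dropped_missing: int
    converged: bool = True
    warnings: list = field(default_factory=list)


def _formula(response: str, predictors) -> str:
    rhs = " + ".join(f'Q("{p}")' for p in predictors)
    return f'Q("{response}") ~ {rhs}'


def _clean_names(names) -> list[str]:
    out = []
    for n in names:
        while 'Q("' in n:
            i = n.index('Q("')
            j = n.index('")', i)
            n = n[:i] + n[i + 3 : j] + n[j + 2 :]
        out.append(n)
    return out


def _check_rank(design: pd.DataFrame) -> None:
    X = np.asarray(design, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = sla.qr(X, mode="economic", pivoting=True)
        aliased = [design.columns[i] for i in piv[rank:]]
        raise AnalysisError(
            f"design matrix is rank deficient; aliased terms: {_clean_names(aliased)}"
        )


def _response_codes(series: pd.Series) -> pd.Series:
    """Factor response -> integer codes with the reference level as 0."""
    if isinstance(series.dtype, pd.CategoricalDtype):
        cat = series
    else:
        levels = sorted(series.dropna().astype(str).unique())
        cat = pd.Categorical(series.astype(str), categories=levels)
        cat = pd.Series(cat, index=series.index)
    return pd.Series(pd.Categorical(cat).codes, index=series.index).astype(int)


def _fit_mle(model):
    """MLE fit with a quasi-Newton fallback for separated/singular cases."""
    try:
        return model.fit(disp=0, maxiter=200), False
    except Exception:
        return model.fit(method="bfgs", disp=0, maxiter=500), True


def _deviance_anova(kind, work, response, predictors, formula_env):
    """Sequential likelihood-ratio analysis of deviance for GLM-like fits."""
    rows = []
    prev_llf = None
    prev_df = None
    for k in range(len(predictors) + 1):
        terms = predictors[:k]
        fml = (
            f'Q("{response}") ~ 1'
            if not terms
            else _formula(response, terms)
        )
        model = smf.logit(fml, data=work) if kind == "logistic" else smf.mnlogit(fml, data=work)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res, _ = _fit_mle(model)
        if prev_llf is not None:
            df = res.df_model - prev_df
            lr = 2.0 * (res.llf - prev_llf)
            rows.append(
                {
                    "term": predictors[k - 1],
                    "df": int(df),
                    "deviance": lr,
                    "p_value": stats.chi2.sf(lr, df) if df > 0 else np.nan,
                }
            )
        prev_llf, prev_df = res.llf, res.df_model
    rows.append(
        {
            "term": "Residual",
            "df": int(res.df_resid),
            "deviance": -2.0 * res.llf,
            "p_value": np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("term")


class AutoRegression(BaseEstimator):
    """Regression with automatic linear/logistic/multinomial detection.

    Parameters
    ----------
    response : str
        Name of the response column.
    predictors : sequence of str
        Explanatory variable names, in the order they should enter the
        sequential ANOVA.
    conf_level : float, default 0.95
        Level of the Wald confidence intervals in the coefficient table.

    After ``fit(table)``: ``kind_``, ``result_`` (a
    :class:`RegressionResult`), ``coef_table_``, ``anova_table_``,
    ``n_used_``.
    """

    def __init__(self, response=None, predictors=None, conf_level=0.95):
        self.response = response
        self.predictors = predictors
        self.conf_level = conf_level

    def fit(self, X, y=None):
        frame = getattr(X, "frame", X)
        if self.response is None or not self.predictors:
            raise AnalysisError("response and predictors must be set before fit")
        predictors = list(self.predictors)
        if self.response in predictors:
            raise AnalysisError("response cannot also be a predictor")
        missing = [v for v in [self.response] + predictors if v not in frame.columns]
        if missing:
            raise AnalysisError(f"unknown variables: {missing}")

        work = frame[[self.response] + predictors].dropna().copy()
        n_dropped = len(frame) - len(work)
        kind = detect_model_kind(work[self.response])

        warns: list[str] = []
        if kind != "linear":
            work[self.response] = _response_codes(work[self.response])

        fml = _formula(self.response, predictors)
        if kind == "linear":
            model = smf.ols(fml, data=work)
        elif kind == "logistic":
            model = smf.logit(fml, data=work)
        else:
            model = smf.mnlogit(fml, data=work)
        _check_rank(model.data.orig_exog)
        n_params = model.data.orig_exog.shape[1]
        if len(work) <= n_params:
            raise AnalysisError(
                f"{len(work)} usable rows for {n_params} parameters; not enough data"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if kind == "linear":
                res = model.fit()
                fit_failed = False
            else:
                # Newton blows up under (quasi-)complete separation; the
                # quasi-Newton fallback still yields a usable, flaggable fit.
                res, fit_failed = _fit_mle(model)

        converged = not fit_failed and bool(
            getattr(res, "mle_retvals", {}).get("converged", True)
        )
        alpha = 1.0 - self.conf_level
        params = res.params
        if kind == "multinomial":
            # one block of rows per non-baseline response level
            conf = res.conf_int(alpha)
            blocks = []
            for j, col in enumerate(params.columns):
                blk = pd.DataFrame(
                    {
                        "term": _clean_names(params.index),
                        "response_level": j + 1,
                        "estimate": params[col].to_numpy(),
                        "std_error": res.bse[col].to_numpy(),
                        "statistic": res.tvalues[col].to_numpy(),
                        "p_value": res.pvalues[col].to_numpy(),
                    }
                )
                blocks.append(blk)
            coef = pd.concat(blocks, ignore_index=True)
            coef["ci_low"] = coef["estimate"] - stats.norm.ppf(1 - alpha / 2) * coef["std_error"]
            coef["ci_high"] = coef["estimate"] + stats.norm.ppf(1 - alpha / 2) * coef["std_error"]
        else:
            ci = res.conf_int(alpha)
            coef = pd.DataFrame(
                {
                    "term": _clean_names(params.index),
                    "estimate": params.to_numpy(),
                    "std_error": res.bse.to_numpy(),
                    "statistic": res.tvalues.to_numpy(),
                    "p_value": res.pvalues.to_numpy(),
                    "ci_low": ci.iloc[:, 0].to_numpy(),
                    "ci_high": ci.iloc[:, 1].to_numpy(),
                }
            )
        if kind != "linear":
            separated = np.abs(coef["estimate"]) > _SEPARATION_BOUND
            if not converged or separated.any():
                warns.append(
                    "possible separation / non-convergence; flagged terms are non-estimable"
                )
                warnings.warn(warns[-1], stacklevel=2)
            coef["estimable"] = ~separated & converged

        if kind == "linear":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                anova = sm.stats.anova_lm(res, typ=1)
            anova = anova.rename(
                columns={"PR(>F)": "p_value", "F": "F"}
            )
            anova["mean_sq"] = anova["sum_sq"] / anova["df"]
            anova = anova[["df", "sum_sq", "mean_sq", "F", "p_value"]]
            anova.index = _clean_names(anova.index)
        else:
            anova = _deviance_anova(kind, work, self.response, predictors, None)

        self.kind_ = kind
        self.result_ = RegressionResult(
            kind=kind,
            coef=coef,
            anova=anova,
            n_used=len(work),
            n_dropped_missing=n_dropped,
            converged=converged,
            warnings=warns,
        )
        self.coef_table_ = coef
        self.anova_table_ = anova
        self.n_used_ = len(work)
        self._res = res
        return self


def fit(table, response: str, predictors, conf_level: float = 0.95) -> RegressionResult:
    """Functional wrapper over :class:`AutoRegression`."""
    est = AutoRegression(response=response, predictors=list(predictors), conf_level=conf_level)
    est.fit(table)
    return est.result_
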