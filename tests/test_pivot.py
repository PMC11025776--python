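import numpy as np
import pandas as pd
import pytest
from scipy import stats

from herdtools import AnalysisError, PivotOddsRatio, PivotTable, crosstab, fit_multinomial_or


def _pivot_from_counts(mat, row_levels, col_levels, row_ref=None, col_ref=None):
    counts = pd.DataFrame(mat, index=row_levels, columns=col_levels)
    return PivotTable(
        row_var="R", col_var="C", counts=counts,
        row_ref=row_ref or row_levels[0], col_ref=col_ref or col_levels[0],
    )


def closed_form_2x2(a, b, c, d, conf=0.95):
    """Independent oracle: cross-product OR with the Wald interval."""
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + conf / 2)
    return np.exp(log_or), np.exp(log_or - z * se), np.exp(log_or + z * se)


# ---------------------------------------------------------------------------
# crosstab

def test_crosstab_enumeration():
    df = pd.DataFrame({"R": ["A", "A", "B", "B"], "C": ["0", "1", "0", "0"]})
    pv = crosstab(df, "R", "C")
    assert pv.counts.loc["A"].tolist() == [1, 1]
    assert pv.counts.loc["B"].tolist() == [2, 0]
    assert pv.row_sums.tolist() == [2, 2]
    assert pv.col_sums.tolist() == [3, 1]
    assert pv.grand_total == 4


def test_crosstab_single_row_table():
    df = pd.DataFrame({"R": ["A"], "C": ["0"]})
    # declare a second level through categoricals so the variables are factors
    df["R"] = pd.Categorical(df["R"], categories=["A", "B"])
    df["C"] = pd.Categorical(df["C"], categories=["0", "1"])
    pv = crosstab(df, "R", "C")
    assert pv.grand_total == 1
    assert pv.counts.loc["A", "0"] == 1


def test_crosstab_missing_rows_excluded_and_counted():
    df = pd.DataFrame({"R": ["A", "B", None, "A"], "C": ["0", None, "1", "1"]})
    pv = crosstab(df, "R", "C")
    assert pv.grand_total == 2
    assert pv.n_excluded_missing == 2


def test_crosstab_errors():
    df = pd.DataFrame({"R": ["A", "B"], "C": ["0", "1"], "K": ["x", "x"]})
    with pytest.raises(AnalysisError, match="unknown variable"):
        crosstab(df, "R", "NOPE")
    with pytest.raises(AnalysisError, match="single level"):
        crosstab(df, "R", "K")
    with pytest.raises(AnalysisError, match="reference"):
        crosstab(df, "R", "C", row_ref="Z")


def test_margin_conservation(case_study):
    _, result = case_study
    pv = crosstab(result.frame, "LCTGP", "REMVD", row_ref="1", col_ref="0")
    assert pv.counts.shape == (3, 2)
    assert pv.row_sums.sum() == pv.col_sums.sum() == pv.grand_total
    assert pv.counts.to_numpy().sum() == pv.grand_total
    assert pv.grand_total == len(result.frame)  # both factors complete here


# ---------------------------------------------------------------------------
# odds ratios

def test_or_matches_cross_product_example():
    pv = _pivot_from_counts([[10, 20], [5, 40]], ["r0", "r1"], ["c0", "c1"])
    t = fit_multinomial_or(pv).iloc[0]
    point, lo, hi = closed_form_2x2(10, 20, 5, 40)
    assert t["or_point"] == pytest.approx(4.0, rel=1e-6)
    assert t["or_point"] == pytest.approx(point, rel=1e-6)
    assert t["ci_low"] == pytest.approx(lo, rel=1e-4)
    assert t["ci_high"] == pytest.approx(hi, rel=1e-4)


def test_or_identical_rows_is_one():
    pv = _pivot_from_counts([[7, 7], [7, 7]], ["r0", "r1"], ["c0", "c1"])
    t = fit_multinomial_or(pv).iloc[0]
    assert t["or_point"] == pytest.approx(1.0, abs=1e-8)


def test_or_reference_swap_inverts():
    pv = _pivot_from_counts([[10, 20], [5, 40]], ["r0", "r1"], ["c0", "c1"])
    base = fit_multinomial_or(pv).iloc[0]["or_point"]
    flipped = _pivot_from_counts(
        [[10, 20], [5, 40]], ["r0", "r1"], ["c0", "c1"], row_ref="r1"
    )
    inv = fit_multinomial_or(flipped).iloc[0]["or_point"]
    assert inv == pytest.approx(1.0 / base, rel=1e-6)


def test_or_transpose_invariant_2x2():
    pv = _pivot_from_counts([[10, 20], [5, 40]], ["r0", "r1"], ["c0", "c1"])
    tpv = _pivot_from_counts([[10, 5], [20, 40]], ["c0", "c1"], ["r0", "r1"])
    assert fit_multinomial_or(pv).iloc[0]["or_point"] == pytest.approx(
        fit_multinomial_or(tpv).iloc[0]["or_point"], rel=1e-6
    )


def test_or_rxc_contrasts_match_2x2_collapse():
    mat = [[30, 10], [25, 20], [15, 35]]
    pv = _pivot_from_counts(mat, ["1", "2", "3"], ["0", "1"])
    t = fit_multinomial_or(pv)
    for row_level, (c, d) in (("2", mat[1]), ("3", mat[2])):
        a, b = mat[0]
        expected = (a * d) / (b * c)
        got = t[t["row_level"] == row_level].iloc[0]["or_point"]
        assert got == pytest.approx(expected, rel=1e-4)


def test_or_zero_cell_non_estimable():
    pv = _pivot_from_counts([[10, 20], [5, 0], [4, 8]], ["r0", "r1", "r2"], ["c0", "c1"])
    with pytest.warns(UserWarning, match="zero cells"):
        t = fit_multinomial_or(pv)
    bad = t[t["row_level"] == "r1"].iloc[0]
    good = t[t["row_level"] == "r2"].iloc[0]
    assert not bad["estimable"] and np.isnan(bad["or_point"])
    assert good["estimable"]
    assert good["or_point"] == pytest.approx((10 * 8) / (20 * 4), rel=1e-4)


def test_or_confidence_level_configurable():
    pv = _pivot_from_counts([[10, 20], [5, 40]], ["r0", "r1"], ["c0", "c1"])
    t95 = fit_multinomial_or(pv, 0.95).iloc[0]
    t80 = fit_multinomial_or(pv, 0.80).iloc[0]
    assert t80["ci_low"] > t95["ci_low"] and t80["ci_high"] < t95["ci_high"]
    _, lo80, hi80 = closed_form_2x2(10, 20, 5, 40, conf=0.80)
    assert t80["ci_low"] == pytest.approx(lo80, rel=1e-4)
    assert t80["ci_high"] == pytest.approx(hi80, rel=1e-4)


def test_or_table_invariants(case_study):
    _, result = case_study
    est = PivotOddsRatio(row="LCTGP", col="TWINS", row_ref="1", col_ref="0").fit(result.frame)
    t = est.or_table_
    assert (t["ci_low"] <= t["or_point"]).all() and (t["or_point"] <= t["ci_high"]).all()
    assert (t["or_point"] > 0).all()
    assert np.allclose(t["or_point"], np.exp(t["log_or"]))
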