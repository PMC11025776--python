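import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdtools import (
    CleanConfig,
    ConfigError,
    DerivedVariableRule,
    HerdCleaner,
    compile_pipeline,
    normalize_events,
    order_factors,
    rolling_filter,
    write_clean_table,
)
from herdtools.cleaning import apply_rolling_filter, filter_valid

from conftest import mdy, raw_from_records


# ---------------------------------------------------------------------------
# rolling de-duplication filter

def _rolling_oracle(dims, lag):
    """Independent recursive statement of the rule: keep the first
    observation, then recurse on everything at least `lag` days later."""
    if not dims:
        return []
    rest = [d for d in dims[1:] if d - dims[0] >= lag]
    return [dims[0]] + _rolling_oracle(rest, lag)


@pytest.mark.parametrize(
    "dims,kept",
    [
        ([1, 2, 4], [1, 4]),  # milk fever at 1, 2, 4 DIM keeps 1 and 4
        ([7], [7]),
        ([1, 3, 4, 8], [1, 4, 8]),
        ([0, 1, 2, 3, 4, 5, 6], [0, 3, 6]),
        ([10, 10], [10]),
    ],
)
def test_rolling_filter_examples(dims, kept):
    assert rolling_filter(dims, 3) == kept


@settings(max_examples=200, deadline=None)
@given(
    dims=st.lists(st.integers(0, 400), min_size=1, max_size=30),
    lag=st.integers(1, 10),
)
def test_rolling_filter_matches_recursive_oracle(dims, lag):
    dims = sorted(dims)
    kept = rolling_filter(dims, lag)
    assert kept == _rolling_oracle(dims, lag)
    assert kept[0] == dims[0]                       # first observation survives
    assert set(kept) <= set(dims)                   # output is a subsequence
    assert rolling_filter(kept, lag) == kept        # idempotent
    assert all(b - a >= lag for a, b in zip(kept, kept[1:]))


def test_rolling_filter_on_dates():
    days = [dt.date(2022, 1, 2), dt.date(2022, 1, 3), dt.date(2022, 1, 6)]
    assert rolling_filter(days, 3) == [dt.date(2022, 1, 2), dt.date(2022, 1, 6)]


# ---------------------------------------------------------------------------
# event normalisation

def _one_cow(events, lact="1", fresh=(2022, 1, 1)):
    rec = {"ID": "7", "LACT": lact, "BDAT": mdy(2019, 5, 1),
           "FDAT": mdy(*fresh), "FCDAT": mdy(*fresh)}
    for i, (name, date, remark) in enumerate(events, start=1):
        rec[f"EVT{i}"] = name
        rec[f"DAT{i}"] = mdy(*date) if date else ""
        rec[f"REM{i}"] = remark
    return raw_from_records([rec])


def test_normalize_events_renames_and_drops_blanks():
    raw = _one_cow([
        ("SCOURS", (2022, 3, 1), "tx A"),
        ("", (2022, 3, 5), "orphan date"),
        ("ODDEVT", (2022, 3, 9), ""),
    ])
    events, stats = normalize_events(raw)
    assert list(events["EVENT"]) == ["DIARRHEA", "ODDEVT"]
    assert events.iloc[0]["DATE"] == pd.Timestamp(2022, 3, 1)
    assert events.iloc[0]["REMARK"] == "tx A"
    assert stats["dropped_blank"] == 1
    assert stats["unknown_names"] == ["ODDEVT"]


def test_normalize_events_merges_remark_and_protocol():
    raw = _one_cow([("MAST", (2022, 2, 1), "LF")])
    raw.frame["PRO1"] = "CEFTIOFUR"
    events, _ = normalize_events(raw)
    assert events.iloc[0]["REMARK"] == "LF | CEFTIOFUR"


def test_normalize_events_drops_unparseable_dates():
    raw = _one_cow([("MAST", None, "no date")])
    raw.frame.loc[0, "DAT1"] = "02/30/22"
    events, stats = normalize_events(raw)
    assert events.empty
    assert stats["dropped_missing_date"] == 1


# ---------------------------------------------------------------------------
# widening, placeholders, removal

def _compiled(events, **cow_kw):
    return compile_pipeline(_one_cow(events, **cow_kw), CleanConfig())


def test_number_and_widen_orders_occurrences():
    res = _compiled([
        ("MAST", (2022, 2, 10), "second"),
        ("MAST", (2022, 1, 11), "first"),
    ])
    row = res.frame.iloc[0]
    assert row["MAST_1_DATE"] == pd.Timestamp(2022, 1, 11)
    assert row["MAST_1_REMARK"] == "first"
    assert row["MAST_2_DATE"] == pd.Timestamp(2022, 2, 10)
    assert row["MAST_N"] == 2


def test_required_event_placeholders_created():
    res = _compiled([])
    row = res.frame.iloc[0]
    assert "MLK_FVR_1_DATE" in res.frame.columns
    assert pd.isna(row["MLK_FVR_1_DATE"])
    assert row["MLK_FVR_N"] == 0


def test_wide_columns_recover_long_event_set(small_herd):
    herd, result = small_herd
    cfg = CleanConfig()
    events, _ = normalize_events(herd.raw, cfg)
    events, _ = apply_rolling_filter(events, cfg.lag_days)
    long_expected = {
        (r.ID, int(r.LACT), r.EVENT, r.DATE) for r in events.itertuples()
    }
    long_back = set()
    frame = result.frame
    for col in frame.columns:
        if col.endswith("_DATE") and col != "REMVD_DATE":
            event, _, _ = col.rsplit("_", 2)
            sub = frame[["ID", "LACT", col]].dropna()
            for r in sub.itertuples(index=False):
                long_back.add((r[0], int(r[1]), event, pd.Timestamp(r[2])))
    # compiled table covers only retained rows; restrict expectation the same way
    kept_keys = set(zip(frame["ID"], frame["LACT"].astype(int)))
    long_expected = {t for t in long_expected if (t[0], t[1]) in kept_keys}
    assert long_back == long_expected


@pytest.mark.parametrize(
    "events,remvd,date",
    [
        ([("SOLD", (2022, 5, 1), "DAIRY")], "1", pd.Timestamp(2022, 5, 1)),
        ([], "0", pd.NaT),
        (
            [("DIED", (2022, 4, 1), ""), ("SOLD", (2022, 5, 1), "")],
            "1",
            pd.Timestamp(2022, 4, 1),  # earlier event wins
        ),
    ],
)
def test_derive_removal(events, remvd, date):
    row = _compiled(events).frame.iloc[0]
    assert str(row["REMVD"]) == remvd
    if pd.isna(date):
        assert pd.isna(row["REMVD_DATE"])
    else:
        assert row["REMVD_DATE"] == date


def test_derive_removal_notes_both_events():
    row = _compiled(
        [("DIED", (2022, 4, 1), "ACUTE"), ("SOLD", (2022, 5, 1), "X")]
    ).frame.iloc[0]
    assert "DIED" in row["REMVD_REMARK"] and "SOLD" in row["REMVD_REMARK"]


# ---------------------------------------------------------------------------
# row filtering

def _core(lact, bdat, fdat, fcdat):
    return pd.DataFrame(
        {
            "ID": ["1"],
            "LACT": pd.array([lact], dtype="Int64"),
            "BDAT": [pd.Timestamp(bdat) if bdat else pd.NaT],
            "FDAT": [pd.Timestamp(fdat) if fdat else pd.NaT],
            "FCDAT": [pd.Timestamp(fcdat) if fcdat else pd.NaT],
        }
    )


def test_filter_valid_rules():
    window = (dt.date(2021, 1, 1), dt.date(2022, 1, 1))
    kept, counts = filter_valid(_core(0, "2019-01-01", "2021-05-01", "2021-05-01"), window)
    assert len(kept) == 0 and counts["lactation_not_started"] == 1
    kept, counts = filter_valid(_core(1, None, "2021-05-01", "2021-05-01"), window)
    assert len(kept) == 0 and counts["invalid_or_missing_dates"] == 1
    kept, counts = filter_valid(_core(1, "2019-01-01", "2022-05-01", "2022-05-01"), window)
    assert len(kept) == 0 and counts["fresh_date_outside_window"] == 1
    kept, counts = filter_valid(_core(1, "2019-01-01", "2021-05-01", "2021-05-01"), window)
    assert len(kept) == 1 and sum(counts.values()) == 0


def test_filter_valid_window_endpoints_inclusive():
    window = (dt.date(2021, 1, 1), dt.date(2022, 1, 1))
    for d in ("2021-01-01", "2022-01-01"):
        kept, _ = filter_valid(_core(1, "2019-01-01", d, d), window)
        assert len(kept) == 1


def test_filter_valid_bookkeeping(case_study):
    _, result = case_study
    r = result.report
    assert r.rows_in == r.rows_out + sum(r.exclusions.values())


# ---------------------------------------------------------------------------
# derived variables

@pytest.mark.parametrize("lact,lctgp", [(1, "1"), (2, "2"), (3, "3"), (5, "3")])
def test_lactation_group(lact, lctgp):
    res = _compiled([], lact=str(lact))
    assert str(res.frame.iloc[0]["LCTGP"]) == lctgp


def test_milk_fever_cutoff_indicator():
    # first occurrence at DIM 5 (fresh Jan 1, event Jan 6)
    row = _compiled([("MF", (2022, 1, 6), "")]).frame.iloc[0]
    assert str(row["MLK_FVR<=7"]) == "1"
    assert row["MLK_FVR_FDIM"] == 5
    row = _compiled([("MF", (2022, 1, 20), "")]).frame.iloc[0]
    assert str(row["MLK_FVR<=7"]) == "0"
    row = _compiled([]).frame.iloc[0]
    assert str(row["MLK_FVR<=7"]) == "0"
    assert pd.isna(row["MLK_FVR_FDIM"])


def test_pre_fresh_events_outside_lactation_period():
    # event before the fresh date has negative DIM: not a lactation occurrence
    row = _compiled([("MF", (2021, 12, 20), "")]).frame.iloc[0]
    assert str(row["MLK_FVR"]) == "0"
    assert pd.isna(row["MLK_FVR_FDIM"])


def test_cutoff_implies_occurrence(case_study):
    _, result = case_study
    f = result.frame
    hit = f["MLK_FVR<=7"].astype(str) == "1"
    assert (f.loc[hit, "MLK_FVR"].astype(str) == "1").all()
    flag0 = f["MLK_FVR"].astype(str) == "0"
    assert f.loc[flag0, "MLK_FVR_FDIM"].isna().all()
    assert f.loc[~flag0, "MLK_FVR_FDIM"].notna().all()


def test_unknown_rule_event_rejected():
    cfg = CleanConfig(
        rules=[DerivedVariableRule(output_name="X", event="NOSUCH", kind="occurrence_flag")]
    )
    with pytest.raises(ConfigError, match="NOSUCH"):
        compile_pipeline(_one_cow([]), cfg)


# ---------------------------------------------------------------------------
# factor ordering

def test_order_factors_binary_and_multinomial():
    df = pd.DataFrame(
        {
            "REMVD": ["0"] * 9 + ["1"],
            "GRP": ["B"] * 5 + ["C"] * 3 + ["A"] * 2,
        }
    )
    out, levels = order_factors(df, ["REMVD", "GRP"])
    assert levels["REMVD"] == ["0", "1"]
    assert levels["GRP"] == ["A", "C", "B"]  # ascending frequency


def test_order_factors_tie_breaks_alphabetical():
    df = pd.DataFrame({"GRP": ["B", "A", "C", "A", "B", "C"]})
    _, levels = order_factors(df, ["GRP"])
    assert levels["GRP"] == ["A", "B", "C"]


# ---------------------------------------------------------------------------
# orchestration

def test_compile_deterministic_bytes(tmp_path, small_herd):
    herd, _ = small_herd
    paths = []
    for i in range(2):
        res = compile_pipeline(herd.raw, CleanConfig())
        p = tmp_path / f"out{i}.csv"
        write_clean_table(res, p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_compile_empty_raw_keeps_schema():
    res = compile_pipeline(raw_from_records([]), CleanConfig())
    assert len(res.frame) == 0
    for col in ("ID", "LACT", "LCTGP", "REMVD", "MLK_FVR_1_DATE", "MLK_FVR<=7"):
        assert col in res.frame.columns


def test_herd_cleaner_estimator(small_herd):
    herd, result = small_herd
    cleaner = HerdCleaner(config=CleanConfig())
    frame = cleaner.fit_transform(herd.raw)
    assert cleaner.n_rows_out_ == len(frame) == len(result.frame)
    assert cleaner.factor_levels_["REMVD"] == ["0", "1"]
    assert "config" in cleaner.get_params()
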