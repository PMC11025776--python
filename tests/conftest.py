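import datetime as dt

import pandas as pd
import pytest

from herdtools import (
    CleanConfig,
    RawHerdTable,
    case_study_config,
    compile_pipeline,
    generate,
    read_raw_export,
    write_raw_csv,
)

RAW_COLUMNS = [
    "ID", "LACT", "BDAT", "FDAT", "FCDAT", "FSTBF",
    "EVT1", "DAT1", "REM1", "EVT2", "DAT2", "REM2", "EVT3", "DAT3", "REM3",
]


def mdy(y, m, d):
    return f"{m:02d}/{d:02d}/{y % 100:02d}"


def raw_from_records(records, columns=None):
    """Build a RawHerdTable from dicts of strings; absent keys become blank."""
    columns = columns or RAW_COLUMNS
    rows = [{c: str(r.get(c, "")) for c in columns} for r in records]
    return RawHerdTable(frame=pd.DataFrame(rows, columns=columns, dtype=object))


@pytest.fixture(scope="session")
def analysis_window():
    return (dt.date(2020, 10, 12), dt.date(2023, 10, 12))


@pytest.fixture(scope="session")
def case_study(tmp_path_factory, analysis_window):
    """Synthetic stand-in for the example herd, compiled through a real CSV
    round trip (export -> file -> ingest -> pipeline)."""
    herd = generate(case_study_config(), seed=1)
    path = tmp_path_factory.mktemp("case") / "synthetic_raw.csv"
    write_raw_csv(herd, path)
    raw = read_raw_export(path)
    cfg = CleanConfig(fresh_window=analysis_window)
    result = compile_pipeline(raw, cfg)
    return herd, result


@pytest.fixture(scope="session")
def small_herd():
    """A 300-row clean-config herd (no invalid rows) with its manifest."""
    cfg = case_study_config(
        n_rows=300, heifer_rows=0, invalid_date_rows=0, out_of_window_rows=0
    )
    herd = generate(cfg, seed=11)
    result = compile_pipeline(herd.raw, CleanConfig())
    return herd, result
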