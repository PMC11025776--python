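"""Reading and writing the CSV dialects the tool touches.

The raw export is a header-first CSV whose cells are all text; dates come in
short month/day/two-digit-year form.  Cleaned tables are written back as
UTF-8 CSV with ISO-8601 dates so they re-import unambiguously.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CleanConfig, IngestConfig
from .errors import IngestError, SchemaError

log = logging.getLogger("herdtools.ingest")

_ISO_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


@dataclass
class RawHerdTable:
    """A raw export: all cells kept as text, row order preserved."""

    frame: pd.DataFrame
    n_malformed: int = 0
    malformed_rows: list[int] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def __len__(self) -> int:
        return len(self.frame)


def read_raw_export(path, config: IngestConfig | None = None) -> RawHerdTable:
    """Read a raw herd export CSV into a :class:`RawHerdTable`.

    The first row is taken verbatim as the variable names.  A data row whose
    width differs from the header is handled per ``config.malformed_policy``:
    ``fail`` raises an :class:`IngestError` naming the 1-based file row,
    ``drop`` logs and skips it (the skip is counted on the returned table).
    """
    config = config or IngestConfig()
    try:
        fh = open(path, "r", encoding="utf-8-sig", newline="")
    except FileNotFoundError as exc:
        raise IngestError(f"input file not found: {path}") from exc
    with fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise IngestError(f"{path}: file is empty") from None
        header = [h.strip() for h in header]
        rows: list[list[str]] = []
        malformed: list[int] = []
        for i, row in enumerate(reader, start=2):  # file row number, 1-based
            if not row:
                continue
            if len(row) != len(header):
                if config.malformed_policy == "fail":
                    raise IngestError(
                        f"{path}: row {i} has {len(row)} fields, expected {len(header)}"
                    )
                malformed.append(i)
                continue
            rows.append(row)
    if malformed:
        log.warning("%s: dropped %d malformed rows: %s", path, len(malformed), malformed)
    frame = pd.DataFrame(rows, columns=header, dtype=object)
    missing_id = frame[config.id_col].str.strip() == "" if config.id_col in frame else None
    if missing_id is not None and missing_id.any():
        log.warning("%s: %d rows have an empty %s", path, int(missing_id.sum()), config.id_col)
    return RawHerdTable(frame=frame, n_malformed=len(malformed), malformed_rows=malformed)


def parse_dc_date(text, fmt: str = "%m/%d/%y", pivot: int = 1970):
    """Parse a short herd-management date; invalid or blank text maps to None.

    Two-digit years are resolved against ``pivot``: years below
    ``pivot % 100`` land in the 2000s, the rest in the 1900s (herd records
    span roughly the 1990s–2020s).  ISO ``YYYY-MM-DD`` strings are accepted
    as a fallback so cleaned output re-imports.  Never raises.
    """
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return None
    s = str(text).strip()
    if not s:
        return None
    try:
        parsed = dt.datetime.strptime(s, fmt).date()
    except ValueError:
        if _ISO_RE.match(s):
            try:
                return dt.date.fromisoformat(s)
            except ValueError:
                return None
        return None
    if "%y" in fmt:
        yy = parsed.year % 100
        century = 2000 if yy < pivot % 100 else 1900
        try:
            parsed = parsed.replace(year=century + yy)
        except ValueError:
            return None  # e.g. Feb 29 in a non-leap resolved year
    return parsed


def parse_date_series(series: pd.Series, fmt: str = "%m/%d/%y", pivot: int = 1970) -> pd.Series:
    """Vectorised :func:`parse_dc_date`; returns datetime64[ns] with NaT."""
    parsed = [parse_dc_date(v, fmt, pivot) for v in series]
    return pd.to_datetime(pd.Series(parsed, index=series.index), errors="coerce")


# ---------------------------------------------------------------------------
# cleaned-table round trip

_EVENT_COL_RE = re.compile(r"^(?P<event>.+)_(?P<n>\d+)_(?P<what>DATE|REMARK)$")

CORE_CLEAN_COLS = ("ID", "LACT", "BDAT", "FDAT", "FCDAT")
REMOVAL_COLS = ("REMVD", "REMVD_DATE", "REMVD_REMARK")


def _clean_roster(config: CleanConfig) -> dict[str, str]:
    """Map known cleaned-table columns (beyond event patterns) to kinds."""
    roster: dict[str, str] = {
        "ID": "id", "LACT": "int", "BDAT": "date", "FDAT": "date", "FCDAT": "date",
        "LCTGP": "factor", "REMVD": "factor", "REMVD_DATE": "date",
        "REMVD_REMARK": "text",
    }
    for c in config.ingest.item_cols:
        roster[c] = "numeric"
    for rule in config.rules:
        roster[rule.output_name] = "int" if rule.kind == "first_dim" else "factor"
    return roster


def write_clean_table(table, path, config: CleanConfig | None = None) -> None:
    """Serialise a cleaned table to CSV (ISO dates, UTF-8, stable column order)."""
    frame = getattr(table, "frame", table).copy()
    for col in frame.columns:
        s = frame[col]
        if pd.api.types.is_datetime64_any_dtype(s):
            frame[col] = s.dt.strftime("%Y-%m-%d")
        elif isinstance(s.dtype, pd.CategoricalDtype):
            frame[col] = s.astype(object)
    frame.to_csv(path, index=False, encoding="utf-8")


def read_clean_table(path, config: CleanConfig | None = None) -> pd.DataFrame:
    """Re-import a cleaned CSV, restoring types and factor level order.

    Unknown extra columns load as text with a warning listing them; missing
    core columns raise :class:`SchemaError`.
    """
    from .cleaning import order_factors  # local import to avoid a cycle

    config = config or CleanConfig()
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8-sig")
    except FileNotFoundError as exc:
        raise IngestError(f"input file not found: {path}") from exc
    frame = frame.mask(frame == "")
    roster = _clean_roster(config)
    missing = [c for c in ("ID", "LACT") if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: not a cleaned herd table, missing columns {missing}", missing=missing
        )
    unknown = []
    factor_cols = []
    for col in frame.columns:
        kind = roster.get(col)
        m = _EVENT_COL_RE.match(col) if kind is None else None
        if kind is None and m:
            kind = "date" if m.group("what") == "DATE" else "text"
        if kind is None and col.endswith("_N"):
            kind = "int"
        if kind is None:
            unknown.append(col)
            continue
        if kind == "date":
            frame[col] = pd.to_datetime(frame[col], format="%Y-%m-%d", errors="coerce")
        elif kind == "int":
            frame[col] = pd.to_numeric(frame[col], errors="coerce").astype("Int64")
        elif kind == "numeric":
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
        elif kind == "factor":
            factor_cols.append(col)
    if unknown:
        warnings.warn(f"{path}: unknown columns kept as text: {unknown}", stacklevel=2)
    frame, _ = order_factors(frame, factor_cols)
    return frame
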