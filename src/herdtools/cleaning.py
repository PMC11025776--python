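"""Compilation of raw herd exports into one-row-per-cow-lactation tables.

The pipeline mirrors how herd-management event logs are prepared for
epidemiological analysis:

1. event triples are melted to a long stream, aliases renamed to canonical
   labels (e.g. SCOURS -> DIARRHEA), blank events and unparseable dates
   dropped with counts, remark and protocol text merged;
2. a rolling de-duplication filter removes re-recordings of the same event
   closer than ``lag_days`` (default 3) days to the last kept observation —
   milk fever recorded at 1, 2 and 4 DIM keeps only the 1- and 4-DIM entries;
3. occurrences are numbered per (cow, lactation, event) and widened to
   ``{EVENT}_{n}_DATE`` / ``{EVENT}_{n}_REMARK`` columns, with placeholder
   first-occurrence columns for required events;
4. herd removal (REMVD) is derived from the sold/died events;
5. rows are excluded for lactation < 1, invalid/missing birth, fresh or
   first-calving dates, or a fresh date outside the analysis window;
6. derived indicators are computed from a rule set (occurrence flags,
   first-occurrence DIM, cutoff-DIM indicators such as milk fever within
   7 DIM) plus the lactation group LCTGP = min(LACT, 3);
7. factor levels are ordered: binary factors with '0' (reference) first,
   multinomial factors by ascending frequency.

Every drop is counted in a :class:`CompileReport`; identical input and
configuration produce byte-identical output.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import CleanConfig
from .errors import ConfigError
from .ingest import RawHerdTable, parse_date_series

log = logging.getLogger("herdtools.cleaning")

_CMP = {
    "<=": np.less_equal,
    "<": np.less,
    ">=": np.greater_equal,
    ">": np.greater,
}


@dataclass
class CompileReport:
    """Row/event bookkeeping for one compilation run."""

    rows_in: int = 0
    rows_out: int = 0
    exclusions: dict = field(default_factory=dict)
    events_in: int = 0
    events_dropped_blank: int = 0
    events_dropped_missing_date: int = 0
    events_dropped_rolling: int = 0
    unknown_event_names: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"rows in:  {self.rows_in}",
            f"rows out: {self.rows_out}",
        ]
        for reason, n in self.exclusions.items():
            lines.append(f"  excluded ({reason}): {n}")
        lines += [
            f"event triples read: {self.events_in}",
            f"  dropped blank/missing event: {self.events_dropped_blank}",
            f"  dropped unparseable date:    {self.events_dropped_missing_date}",
            f"  dropped by rolling filter:   {self.events_dropped_rolling}",
        ]
        if self.unknown_event_names:
            lines.append(f"  unmapped event names passed through: {sorted(self.unknown_event_names)}")
        return "\n".join(lines)


@dataclass
class CleanHerdTable:
    """One row per (cow, lactation), with factor metadata and a run report."""

    frame: pd.DataFrame
    factor_levels: dict
    report: CompileReport

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# long event stream

def _text(series_or_none, index) -> pd.Series:
    if series_or_none is None:
        return pd.Series("", index=index, dtype=object)
    return series_or_none.fillna("").astype(str).str.strip()


def parse_core(raw, config: CleanConfig) -> pd.DataFrame:
    """Typed per-row core: id, lactation, the three dates and item columns.

    Item columns missing from the file are created as all-missing
    placeholders so downstream analyses see a stable schema."""
    ic = config.ingest
    df = getattr(raw, "frame", raw)
    core = pd.DataFrame(index=df.index)
    core["ID"] = _text(df.get(ic.id_col), df.index)
    core["LACT"] = pd.to_numeric(df.get(ic.lact_col), errors="coerce").astype("Int64")
    for out, col in (("BDAT", ic.birth_col), ("FDAT", ic.fresh_col), ("FCDAT", ic.calving_col)):
        src = df.get(col)
        if src is None:
            core[out] = pd.NaT
        else:
            core[out] = parse_date_series(src, ic.date_format, ic.pivot_year)
    for item in ic.item_cols:
        core[item] = pd.to_numeric(df.get(item), errors="coerce")
    return core


def normalize_events(raw, config: CleanConfig | None = None):
    """Melt event/date/remark triples into a long stream of event records.

    Returns ``(events, stats)`` where ``events`` has columns ID, LACT, FDAT,
    EVENT (canonical), DATE, REMARK, DIM, sorted by cow, lactation, event and
    date.  Blank event names and unparseable dates are dropped and counted;
    names absent from the rename map pass through unchanged with a log note;
    remark and protocol text are merged with ``" | "``.
    """
    config = config or CleanConfig()
    ic = config.ingest
    df = getattr(raw, "frame", raw)
    pat = re.compile(rf"^{re.escape(ic.event_prefix)}(\d+)$")
    slots = sorted(int(m.group(1)) for c in df.columns if (m := pat.match(str(c))))
    core = pd.DataFrame(index=df.index)
    core["ID"] = _text(df.get(ic.id_col), df.index)
    core["LACT"] = pd.to_numeric(df.get(ic.lact_col), errors="coerce").astype("Int64")
    core["FDAT"] = (
        parse_date_series(df[ic.fresh_col], ic.date_format, ic.pivot_year)
        if ic.fresh_col in df
        else pd.NaT
    )

    parts = []
    for i in slots:
        part = core.copy()
        part["EVENT"] = _text(df.get(f"{ic.event_prefix}{i}"), df.index).str.upper()
        part["DATE_RAW"] = _text(df.get(f"{ic.date_prefix}{i}"), df.index)
        remark = _text(df.get(f"{ic.remark_prefix}{i}"), df.index)
        protocol = _text(df.get(f"{ic.protocol_prefix}{i}"), df.index)
        both = remark.str.len().gt(0) & protocol.str.len().gt(0)
        merged = remark.where(remark.str.len() > 0, protocol)
        merged = merged.mask(both, remark + " | " + protocol)
        part["REMARK"] = merged.mask(merged.str.len() == 0, None)
        parts.append(part)

    stats = {
        "events_in": 0,
        "dropped_blank": 0,
        "dropped_missing_date": 0,
        "unknown_names": [],
    }
    if not parts:
        empty = pd.DataFrame(
            columns=["ID", "LACT", "FDAT", "EVENT", "DATE", "REMARK", "DIM"]
        )
        return empty, stats

    events = pd.concat(parts, ignore_index=True)
    stats["events_in"] = int((events["EVENT"].str.len() > 0).sum()) + int(
        ((events["EVENT"].str.len() == 0) & (events["DATE_RAW"].str.len() > 0)).sum()
    )
    blank = events["EVENT"].str.len() == 0
    stats["dropped_blank"] = int((blank & (events["DATE_RAW"].str.len() > 0)).sum())
    events = events[~blank].copy()

    rename = {k.upper(): v for k, v in config.rename_map.items()}
    canonical = (
        set(rename.values())
        | set(config.required_events)
        | {r.event for r in config.rules}
    )
    unknown = sorted(set(events["EVENT"]) - set(rename) - canonical)
    if unknown:
        log.info("event names not in rename map, passed through: %s", unknown)
    stats["unknown_names"] = unknown
    events["EVENT"] = events["EVENT"].map(lambda e: rename.get(e, e))

    events["DATE"] = parse_date_series(events["DATE_RAW"], ic.date_format, ic.pivot_year)
    bad_date = events["DATE"].isna()
    stats["dropped_missing_date"] = int(bad_date.sum())
    events = events[~bad_date].drop(columns="DATE_RAW")

    events["DIM"] = (events["DATE"] - events["FDAT"]).dt.days.astype("Int64")
    events = events.sort_values(
        ["ID", "LACT", "EVENT", "DATE", "REMARK"], kind="mergesort"
    ).reset_index(drop=True)
    return events, stats


# ---------------------------------------------------------------------------
# rolling de-duplication filter

def rolling_filter(values, lag_days: int = 3) -> list:
    """Keep-first rolling filter over an ascending sequence of DIMs or dates.

    The first observation is always kept; a subsequent one is dropped iff its
    gap to the last *kept* observation is below ``lag_days`` days.  Output is
    a subsequence of the input and the filter is idempotent.
    """
    kept: list = []
    last = None
    for v in values:
        day = v.toordinal() if isinstance(v, (dt.date, dt.datetime)) else v
        if last is None or day - last >= lag_days:
            kept.append(v)
            last = day
    return kept


def _rolling_keep_mask(days: np.ndarray, groups: np.ndarray, lag_days: int) -> np.ndarray:
    keep = np.ones(len(days), dtype=bool)
    current = None
    last = 0
    for i in range(len(days)):
        g = groups[i]
        if g != current:
            current = g
            last = days[i]
            continue
        if days[i] - last < lag_days:
            keep[i] = False
        else:
            last = days[i]
    return keep


def apply_rolling_filter(events: pd.DataFrame, lag_days: int = 3):
    """Apply :func:`rolling_filter` per (cow, lactation, event) group.

    ``events`` must be sorted ascending by date within each group (as
    :func:`normalize_events` returns it).  Returns ``(filtered, n_dropped)``.
    """
    if events.empty:
        return events, 0
    groups, _ = pd.factorize(
        pd.MultiIndex.from_frame(events[["ID", "LACT", "EVENT"]]).to_flat_index()
    )
    days = events["DATE"].map(pd.Timestamp.toordinal).to_numpy()
    keep = _rolling_keep_mask(days, groups, lag_days)
    return events[keep].reset_index(drop=True), int((~keep).sum())


# ---------------------------------------------------------------------------
# wide layout

def number_and_widen(events: pd.DataFrame, required_events=()) -> pd.DataFrame:
    """Number occurrences and widen to {EVENT}_{n}_DATE/_REMARK columns.

    Also emits a ``{EVENT}_N`` occurrence count per event, and placeholder
    first-occurrence columns for every required event never observed.
    Returns a frame indexed by (ID, LACT).
    """
    if events.empty:
        wide = pd.DataFrame(
            index=pd.MultiIndex.from_arrays(
                [pd.Index([], dtype=object), pd.Index([], dtype="Int64")],
                names=["ID", "LACT"],
            )
        )
    else:
        ev = events.copy()
        ev["OCC"] = ev.groupby(["ID", "LACT", "EVENT"], sort=False).cumcount() + 1
        ev["_D"] = ev["EVENT"] + "_" + ev["OCC"].astype(str) + "_DATE"
        ev["_R"] = ev["EVENT"] + "_" + ev["OCC"].astype(str) + "_REMARK"
        dates = ev.set_index(["ID", "LACT", "_D"])["DATE"].unstack()
        remarks = ev.set_index(["ID", "LACT", "_R"])["REMARK"].unstack()
        counts = ev.groupby(["ID", "LACT", "EVENT"]).size().unstack(fill_value=0)
        counts.columns = [f"{c}_N" for c in counts.columns]
        wide = dates.join(remarks).join(counts)

    for e in required_events:
        for col, filler in ((f"{e}_1_DATE", pd.NaT), (f"{e}_1_REMARK", None)):
            if col not in wide.columns:
                wide[col] = filler
        if f"{e}_N" not in wide.columns:
            wide[f"{e}_N"] = 0

    def sort_key(col):
        m = re.match(r"^(.+)_(\d+)_(DATE|REMARK)$", col)
        if m:
            return (m.group(1), int(m.group(2)), 0 if m.group(3) == "DATE" else 1, 0)
        return (col[:-2], 0, 2, 0)  # *_N counts sort after their event columns

    ordered = sorted(wide.columns, key=sort_key)
    wide = wide[ordered]
    for c in wide.columns:
        if c.endswith("_DATE"):
            wide[c] = pd.to_datetime(wide[c])
        elif c.endswith("_N"):
            wide[c] = wide[c].fillna(0).astype("Int64")
    return wide


def derive_removal(wide: pd.DataFrame) -> pd.DataFrame:
    """Derive REMVD (removed from herd) from the sold and died events.

    REMVD='1' with the sold-or-died date if either exists (the earlier of the
    two if both, with both noted in the remark); otherwise REMVD='0'.
    """
    wide = wide.copy()
    sold_d = wide.get("SOLD_1_DATE", pd.Series(pd.NaT, index=wide.index))
    died_d = wide.get("DIED_1_DATE", pd.Series(pd.NaT, index=wide.index))
    sold_r = wide.get("SOLD_1_REMARK", pd.Series(None, index=wide.index, dtype=object))
    died_r = wide.get("DIED_1_REMARK", pd.Series(None, index=wide.index, dtype=object))
    both = pd.concat([pd.to_datetime(sold_d), pd.to_datetime(died_d)], axis=1)
    removal_date = both.min(axis=1)

    def _remark(i):
        pieces = []
        for name, d, r in (("SOLD", sold_d.loc[i], sold_r.loc[i]), ("DIED", died_d.loc[i], died_r.loc[i])):
            if pd.notna(d):
                txt = f"{name}: {r}" if r else name
                pieces.append((pd.Timestamp(d), txt))
        return " | ".join(t for _, t in sorted(pieces, key=lambda p: p[0])) or None

    removed = removal_date.notna()
    wide["REMVD"] = np.where(removed, "1", "0")
    wide["REMVD_DATE"] = removal_date
    wide["REMVD_REMARK"] = [
        _remark(i) if rem else None for i, rem in zip(wide.index, removed)
    ]
    return wide


# ---------------------------------------------------------------------------
# row filters and derived variables

def filter_valid(table: pd.DataFrame, window=None):
    """Exclude pre-first-lactation rows, invalid dates and out-of-window rows.

    Exclusion reasons are exclusive and checked in order (lactation, dates,
    window) so that ``rows_in == rows_out + sum(counts)``.  The fresh-date
    window is a closed interval.
    """
    bad_lact = table["LACT"].isna() | (table["LACT"] < 1)
    bad_dates = ~bad_lact & (
        table["BDAT"].isna() | table["FDAT"].isna() | table["FCDAT"].isna()
    )
    if window is not None:
        lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        out_win = ~bad_lact & ~bad_dates & ~table["FDAT"].between(lo, hi)
    else:
        out_win = pd.Series(False, index=table.index)
    counts = {
        "lactation_not_started": int(bad_lact.sum()),
        "invalid_or_missing_dates": int(bad_dates.sum()),
        "fresh_date_outside_window": int(out_win.sum()),
    }
    kept = table[~(bad_lact | bad_dates | out_win)].reset_index(drop=True)
    return kept, counts


def derive_variables(table: pd.DataFrame, events: pd.DataFrame, config: CleanConfig) -> pd.DataFrame:
    """Compute LCTGP and the rule-driven derived columns.

    Only occurrences inside the lactation period (DIM >= 0) count toward
    occurrence flags, first-occurrence DIM and cutoff indicators; a cutoff
    indicator is '0' whenever the event never occurred.
    """
    table = table.copy()
    table["LCTGP"] = np.minimum(table["LACT"].astype("float"), 3).astype("Int64").astype(str)

    if events.empty:
        first_dim = pd.DataFrame()
    else:
        in_lact = events[events["DIM"].notna() & (events["DIM"] >= 0)]
        first_dim = in_lact.groupby(["ID", "LACT", "EVENT"])["DIM"].min().unstack()
    key = pd.MultiIndex.from_frame(table[["ID", "LACT"]])

    def first_dim_of(event: str) -> pd.Series:
        if event == "REMVD":
            fd = (table["REMVD_DATE"] - table["FDAT"]).dt.days
            return fd.where(fd >= 0).astype("Int64")
        if event in first_dim.columns:
            vals = first_dim[event].reindex(key)
            return pd.Series(vals.to_numpy(), index=table.index).astype("Int64")
        return pd.Series(pd.NA, index=table.index, dtype="Int64")

    for rule in config.rules:
        fd = first_dim_of(rule.event)
        if rule.kind == "occurrence_flag":
            table[rule.output_name] = np.where(fd.notna(), "1", "0")
        elif rule.kind == "first_dim":
            table[rule.output_name] = fd
        else:  # cutoff_indicator
            hit = _CMP[rule.comparison](fd.to_numpy(dtype="float", na_value=np.nan), rule.cutoff_dim)
            table[rule.output_name] = np.where(np.nan_to_num(hit, nan=0.0) > 0, "1", "0")
    return table


def order_factors(table: pd.DataFrame, factor_cols):
    """Order factor levels: binary '0' (reference) first; multinomial by
    ascending observed frequency with alphabetical tie-break.

    Returns ``(table, levels)`` where ``levels`` maps column -> ordered list.
    """
    table = table.copy()
    levels: dict[str, list[str]] = {}
    for col in factor_cols:
        if col not in table.columns:
            continue
        vals = table[col].dropna().astype(str)
        observed = set(vals.unique())
        if observed <= {"0", "1"}:
            order = ["0", "1"]
        else:
            freq = vals.value_counts()
            order = sorted(observed, key=lambda lv: (freq[lv], lv))
        table[col] = pd.Categorical(table[col].astype(object), categories=order)
        levels[col] = order
    return table, levels


# ---------------------------------------------------------------------------
# orchestration

def compile_pipeline(raw, config: CleanConfig | None = None) -> CleanHerdTable:
    """Run the full cleaning pipeline on a raw export.

    Deterministic: identical input and configuration yield a byte-identical
    cleaned CSV.  Returns the cleaned table together with factor-level
    metadata and a :class:`CompileReport`.
    """
    config = config or CleanConfig()
    frame = getattr(raw, "frame", raw)
    report = CompileReport(rows_in=len(frame))

    core = parse_core(raw, config)
    events, stats = normalize_events(raw, config)
    report.events_in = stats["events_in"]
    report.events_dropped_blank = stats["dropped_blank"]
    report.events_dropped_missing_date = stats["dropped_missing_date"]
    report.unknown_event_names = stats["unknown_names"]

    known = set(config.rename_map.values()) | set(config.required_events)
    if not events.empty:
        known |= set(events["EVENT"].unique())
    config.validate_rules(known)

    events, n_rolled = apply_rolling_filter(events, config.lag_days)
    report.events_dropped_rolling = n_rolled

    wide = number_and_widen(events, config.required_events)
    wide = derive_removal(wide)
    table = core.merge(wide, how="left", left_on=["ID", "LACT"], right_index=True)
    for c in table.columns:
        if c.endswith("_N"):
            table[c] = table[c].fillna(0).astype("Int64")
        elif c.endswith("_DATE") and c != "REMVD_DATE":
            table[c] = pd.to_datetime(table[c])
    table["REMVD"] = table["REMVD"].fillna("0")
    table["REMVD_DATE"] = pd.to_datetime(table["REMVD_DATE"])

    table, exclusions = filter_valid(table, config.fresh_window)
    report.exclusions = exclusions
    table = derive_variables(table, events, config)

    factor_cols = ["LCTGP", "REMVD"] + [
        r.output_name for r in config.rules if r.kind != "first_dim"
    ]
    table, levels = order_factors(table, factor_cols)

    for c in table.columns:
        if table[c].dtype == object:
            table[c] = table[c].where(table[c].notna(), np.nan)

    event_cols = [c for c in table.columns if re.match(r"^.+_(\d+)_(DATE|REMARK)$", c) or c.endswith("_N")]
    rule_cols = [r.output_name for r in config.rules]
    front = ["ID", "LACT", "BDAT", "FDAT", "FCDAT"] + list(config.ingest.item_cols) + ["LCTGP"]
    back = ["REMVD", "REMVD_DATE", "REMVD_REMARK"] + rule_cols
    ordered = front + event_cols + back
    table = table[[c for c in ordered if c in table.columns]]

    report.rows_out = len(table)
    log.info("compiled %d -> %d rows\n%s", report.rows_in, report.rows_out, report.summary())
    return CleanHerdTable(frame=table, factor_levels=levels, report=report)


class HerdCleaner(TransformerMixin, BaseEstimator):
    """Transformer wrapping :func:`compile_pipeline`.

    Parameters mirror :class:`~herdtools.config.CleanConfig`; ``transform``
    maps a :class:`~herdtools.ingest.RawHerdTable` (or raw frame) to the
    cleaned one-row-per-cow-lactation frame.  After fitting,
    ``factor_levels_`` and ``report_`` describe the compiled table.
    """

    def __init__(self, config: CleanConfig | None = None):
        self.config = config

    def _compile(self, X) -> CleanHerdTable:
        return compile_pipeline(X, self.config or CleanConfig())

    def fit(self, X, y=None):
        result = self._compile(X)
        self.factor_levels_ = result.factor_levels
        self.report_ = result.report
        self.n_rows_out_ = result.report.rows_out
        return self

    def transform(self, X) -> pd.DataFrame:
        return self._compile(X).frame

    def fit_transform(self, X, y=None, **kwargs):
        result = self._compile(X)
        self.factor_levels_ = result.factor_levels
        self.report_ = result.report
        self.n_rows_out_ = result.report.rows_out
        return result.frame
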