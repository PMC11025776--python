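"""Configuration objects for ingest and compilation.

Herd-management exports carry no embedded schema: the first row is a plain
header and every farm's "protocol" command can name columns differently.  All
naming conventions therefore live in :class:`IngestConfig` (column map) and
:class:`CleanConfig` (event rename map, derived-variable rules, filters), with
defaults matching the layout the bundled synthetic generator emits:

* core columns ``ID, LACT, BDAT, FDAT, FCDAT`` (id, lactation number, birth,
  fresh and first-calving dates),
* item columns such as ``FSTBF`` (first-test butterfat, percent),
* repeated event triples ``EVT1,DAT1,REM1,EVT2,DAT2,REM2,...``.

Both configs are pydantic models, so a YAML/JSON mapping loaded from disk
validates on construction.
"""

from __future__ import annotations

import datetime as dt
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigError

#: Events renamed to canonical labels during compilation.  Only the
#: SCOURS -> DIARRHEA pair is universal; the rest are common shorthand seen in
#: herd-management exports.  Unknown names pass through unchanged.
DEFAULT_RENAME_MAP: dict[str, str] = {
    "SCOURS": "DIARRHEA",
    "MF": "MLK_FVR",
    "MILKFEVER": "MLK_FVR",
    "KETOSIS": "KET",
    "RETPLA": "RP",
    "TWINS": "TWIN",
}

#: Events for which first-occurrence placeholder columns are always created,
#: even when a herd never recorded them.
DEFAULT_REQUIRED_EVENTS: tuple[str, ...] = (
    "TWIN",
    "RP",
    "KET",
    "MLK_FVR",
    "MAST",
    "DIARRHEA",
    "SOLD",
    "DIED",
)


class DerivedVariableRule(BaseModel):
    """One derived column computed from an event's occurrences in a lactation.

    kind:
        ``occurrence_flag`` — '1' if the event occurred at DIM >= 0, else '0'.
        ``first_dim`` — days in milk of the first occurrence (missing if none).
        ``cutoff_indicator`` — '1' if the first-occurrence DIM satisfies
        ``comparison cutoff_dim``, else '0' (including when the event never
        occurred).
    """

    output_name: str
    event: str
    kind: Literal["occurrence_flag", "first_dim", "cutoff_indicator"]
    cutoff_dim: Optional[int] = None
    comparison: Literal["<=", "<", ">=", ">"] = "<="

    @model_validator(mode="after")
    def _cutoff_needs_value(self):
        if self.kind == "cutoff_indicator" and self.cutoff_dim is None:
            raise ValueError(f"rule {self.output_name!r}: cutoff_indicator needs cutoff_dim")
        return self


def default_rules() -> list[DerivedVariableRule]:
    """Derived-variable roster for transition-cow health analysis.

    Occurrence flags for the main health events, first-occurrence DIM for
    each, the milk-fever-within-7-DIM transition indicator, and removal
    before 60 DIM (strict: "before").
    """
    rules: list[DerivedVariableRule] = []
    flags = {
        "TWINS": "TWIN",
        "RP": "RP",
        "KET": "KET",
        "MLK_FVR": "MLK_FVR",
        "MAST": "MAST",
        "DIARRHEA": "DIARRHEA",
    }
    for out, ev in flags.items():
        rules.append(DerivedVariableRule(output_name=out, event=ev, kind="occurrence_flag"))
        rules.append(
            DerivedVariableRule(output_name=f"{ev}_FDIM", event=ev, kind="first_dim")
        )
    rules.append(
        DerivedVariableRule(
            output_name="MLK_FVR<=7", event="MLK_FVR", kind="cutoff_indicator",
            cutoff_dim=7, comparison="<=",
        )
    )
    rules.append(
        DerivedVariableRule(
            output_name="REMVD<60", event="REMVD", kind="cutoff_indicator",
            cutoff_dim=60, comparison="<",
        )
    )
    return rules


class IngestConfig(BaseModel):
    """Column map and dialect of the raw export."""

    id_col: str = "ID"
    lact_col: str = "LACT"
    birth_col: str = "BDAT"
    fresh_col: str = "FDAT"
    calving_col: str = "FCDAT"
    item_cols: list[str] = Field(default_factory=lambda: ["FSTBF"])
    event_prefix: str = "EVT"
    date_prefix: str = "DAT"
    remark_prefix: str = "REM"
    protocol_prefix: str = "PRO"
    date_format: str = "%m/%d/%y"
    #: two-digit years below ``pivot_year % 100`` map to 20xx, others to 19xx
    pivot_year: int = 1970
    #: 'fail' raises on a width-mismatched row; 'drop' logs and skips it
    malformed_policy: Literal["fail", "drop"] = "fail"

    @property
    def core_cols(self) -> list[str]:
        return [self.id_col, self.lact_col, self.birth_col, self.fresh_col, self.calving_col]


class CleanConfig(BaseModel):
    """Everything the compilation pipeline needs beyond the raw table."""

    ingest: IngestConfig = Field(default_factory=IngestConfig)
    rename_map: dict[str, str] = Field(default_factory=lambda: dict(DEFAULT_RENAME_MAP))
    required_events: list[str] = Field(default_factory=lambda: list(DEFAULT_REQUIRED_EVENTS))
    rules: list[DerivedVariableRule] = Field(default_factory=default_rules)
    #: minimum day gap for the rolling de-duplication filter; an observation
    #: closer than this to the last kept one is discarded
    lag_days: int = 3
    fresh_window: Optional[tuple[dt.date, dt.date]] = None
    farm_name: Optional[str] = None
    extraction_date: Optional[dt.date] = None

    @field_validator("lag_days")
    @classmethod
    def _positive_lag(cls, v):
        if v < 1:
            raise ValueError("lag_days must be >= 1")
        return v

    @model_validator(mode="after")
    def _validate(self):
        if self.fresh_window is not None and self.fresh_window[0] > self.fresh_window[1]:
            raise ValueError("fresh_window start must not exceed end")
        seen = set()
        for r in self.rules:
            if r.output_name in seen:
                raise ValueError(f"duplicate derived-variable output {r.output_name!r}")
            seen.add(r.output_name)
        return self

    def validate_rules(self, known_events: set[str]) -> None:
        """Raise :class:`ConfigError` if a rule references an unknown event.

        ``REMVD`` is always known (derived from SOLD/DIED)."""
        known = set(known_events) | {"REMVD"}
        bad = [f"{r.output_name} (event {r.event!r})" for r in self.rules if r.event not in known]
        if bad:
            raise ConfigError(f"rules reference unknown events: {bad}")


def load_config(path) -> CleanConfig:
    """Load a :class:`CleanConfig` from a YAML (or JSON) mapping file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    try:
        return CleanConfig(**data)
    except ValueError as exc:  # pydantic ValidationError subclasses ValueError
        raise ConfigError(str(exc)) from exc
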