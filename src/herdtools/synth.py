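"""Synthetic herd-export generator with a ground-truth manifest.

Emits raw event-export tables in the same layout the ingest module reads
(core columns ``ID, LACT, BDAT, FDAT, FCDAT``, a first-test butterfat item
``FSTBF`` and interleaved ``EVT/DAT/REM`` triples) together with a per-row
manifest of the true simulated state, so every pipeline stage and both
analysis engines can be checked against known answers.

The default configuration emulates the compiled example herd the package's
worked analyses refer to: a roughly 1000-cow dairy observed over a two-year
fresh-date window (2020-10-12 .. 2023-10-12) yielding exactly 2106 valid
cow-lactation rows, with injected associations

* odds of a twin birth vs lactation group: OR 1.7 (group 2 vs 1) and 4.6
  (group 3+ vs 1) on a 2.5% first-lactation twinning rate;
* odds of removal before 60 DIM vs twinning: OR 3.4;
* first-test butterfat: direct twin effect −0.28 percentage points with
  small lactation-group offsets sized so the unadjusted effect is ≈ −0.30.

Because these files stand in for a real herd export that is not
redistributable, everything generated here is explicitly synthetic; event
incidences are plausible but not biologically calibrated.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy.special import expit, logit

from .config import CleanConfig
from .errors import ConfigError
from .ingest import RawHerdTable

__all__ = [
    "FstbfModel", "HerdSimConfig", "SyntheticHerd",
    "generate", "inject_association", "case_study_config", "sample_twin_lctgp",
    "write_raw_csv",
]

#: canonical event name -> name written in the raw export (exercises renaming)
RAW_EVENT_NAMES = {
    "TWIN": "TWIN",
    "RP": "RP",
    "MLK_FVR": "MF",
    "KET": "KETOSIS",
    "MAST": "MAST",
    "DIARRHEA": "SCOURS",
    "SOLD": "SOLD",
    "DIED": "DIED",
}

_REMARKS = {
    "MAST": ("LF", "RF", "LR", "RR"),
    "KET": ("KETO TX", ""),
    "MLK_FVR": ("CMPK", ""),
    "DIARRHEA": ("",),
    "RP": ("LUTALYSE", ""),
    "TWIN": ("",),
    "SOLD": ("DAIRY", "BEEF"),
    "DIED": ("ACUTE", ""),
}


class FstbfModel(BaseModel):
    """Linear model generating first-test butterfat (percent)."""

    base: float = 4.2
    lctgp_offsets: dict[str, float] = Field(
        default_factory=lambda: {"1": 0.0, "2": -0.04, "3": -0.07}
    )
    beta_twin: float = -0.28
    beta_ket: float = 0.0
    sd: float = 0.55
    decimals: int = 1
    #: first test happens around 30 DIM; cows removed earlier have no value
    missing_if_removed_before: int = 30


class HerdSimConfig(BaseModel):
    """Simulation parameters; probabilities are per cow-lactation."""

    n_rows: int = 2106           # valid, in-window cow-lactation rows
    heifer_rows: int = 54        # lactation 0, filtered out downstream
    invalid_date_rows: int = 38  # one corrupted/missing core date each
    out_of_window_rows: int = 77  # fresh date before the analysis window
    window: tuple[dt.date, dt.date] = (dt.date(2020, 10, 12), dt.date(2023, 10, 12))
    lact_probs: dict[int, float] = Field(
        default_factory=lambda: {1: 0.38, 2: 0.27, 3: 0.15, 4: 0.10, 5: 0.07, 6: 0.03}
    )
    #: fraction of valid rows emitted as same-cow consecutive-lactation pairs
    multi_lact_frac: float = 0.15
    twin_base_p: float = 0.025
    twin_or: dict[str, float] = Field(default_factory=lambda: {"2": 1.7, "3": 4.6})
    rem60_base_p: float = 0.035
    rem60_or_twin: float = 3.4
    late_removal_p: dict[str, float] = Field(
        default_factory=lambda: {"1": 0.15, "2": 0.17, "3": 0.28}
    )
    sold_frac: float = 0.7
    mlk_fvr_p: dict[str, float] = Field(
        default_factory=lambda: {"1": 0.01, "2": 0.03, "3": 0.08}
    )
    ket_p: dict[str, float] = Field(
        default_factory=lambda: {"1": 0.04, "2": 0.06, "3": 0.09}
    )
    rp_p: float = 0.06
    mast_p: float = 0.12
    mast_second_p: float = 0.30
    scours_p: float = 0.03
    #: probability a disease event is re-recorded 1-2 days later (exercises
    #: the rolling de-duplication filter)
    duplicate_p: float = 0.15
    duplicate_lags: tuple[int, ...] = (1, 2)
    fstbf: FstbfModel = Field(default_factory=FstbfModel)

    @field_validator(
        "twin_base_p", "rem60_base_p", "rp_p", "mast_p", "mast_second_p",
        "scours_p", "duplicate_p", "multi_lact_frac",
    )
    @classmethod
    def _prob(cls, v):
        if not 0.0 <= v <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        return v

    def twin_p(self, lctgp: str) -> float:
        odds = self.twin_base_p / (1.0 - self.twin_base_p)
        odds *= self.twin_or.get(lctgp, 1.0)
        return odds / (1.0 + odds)


@dataclass
class SyntheticHerd:
    """Raw export plus the ground truth that produced it."""

    raw: RawHerdTable
    manifest: pd.DataFrame
    truth: dict


def case_study_config(**overrides) -> HerdSimConfig:
    """The default study-condition configuration (see module docstring)."""
    return HerdSimConfig(**overrides)


def inject_association(
    config: HerdSimConfig,
    kind: Literal["odds_ratio", "linear_effect"],
    spec: dict,
) -> HerdSimConfig:
    """Return a config whose generated population carries a requested truth.

    ``odds_ratio``: ``{"pair": ("TWIN", "LCTGP"), "level": "3", "value": 4.0}``
    or ``{"pair": ("REMVD<60", "TWIN"), "value": 3.4}``.
    ``linear_effect``: ``{"item": "FSTBF", "predictor": "TWIN"|"KET",
    "value": -0.3}``.  Infeasible requests (probability pushed outside (0,1),
    non-positive OR) raise :class:`ConfigError`.
    """
    cfg = config.model_copy(deep=True)
    if kind == "odds_ratio":
        value = float(spec["value"])
        if value <= 0:
            raise ConfigError("odds ratio must be positive")
        pair = tuple(spec["pair"])
        if pair == ("TWIN", "LCTGP"):
            base = cfg.twin_base_p
            if not 0 < base < 1:
                raise ConfigError("twin_base_p must be inside (0, 1) to scale odds")
            cfg.twin_or[str(spec["level"])] = value
        elif pair in (("REMVD<60", "TWIN"), ("TWIN", "REMVD<60")):
            if not 0 < cfg.rem60_base_p < 1:
                raise ConfigError("rem60_base_p must be inside (0, 1) to scale odds")
            cfg.rem60_or_twin = value
        else:
            raise ConfigError(f"no odds-ratio hook for pair {pair}")
    elif kind == "linear_effect":
        pred = spec["predictor"]
        if spec.get("item", "FSTBF") != "FSTBF":
            raise ConfigError("only FSTBF carries a linear-effect hook")
        if pred == "TWIN":
            cfg.fstbf.beta_twin = float(spec["value"])
        elif pred == "KET":
            cfg.fstbf.beta_ket = float(spec["value"])
        else:
            raise ConfigError(f"no linear-effect hook for predictor {pred}")
    else:
        raise ConfigError(f"unknown association kind {kind}")
    return cfg


def sample_twin_lctgp(n: int, config: HerdSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Fast draw of (LCTGP, TWIN) pairs under the configured odds ratios.

    Used by coverage simulations that do not need the full export layout."""
    lacts = rng.choice(
        list(config.lact_probs), size=n, p=list(config.lact_probs.values())
    )
    lctgp = np.minimum(lacts, 3).astype(str)
    p = np.array([config.twin_p(g) for g in lctgp])
    twin = (rng.random(n) < p).astype(int).astype(str)
    out = pd.DataFrame(
        {
            "LCTGP": pd.Categorical(lctgp, categories=["1", "2", "3"]),
            "TWIN": pd.Categorical(twin, categories=["0", "1"]),
        }
    )
    return out


def _fmt_date(d) -> str:
    return d.strftime("%m/%d/%y")


def generate(config: HerdSimConfig | None = None, seed: int = 0) -> SyntheticHerd:
    """Generate a synthetic raw export and its ground-truth manifest.

    Deterministic in ``(config, seed)``; the same pair yields byte-identical
    CSV output.  The manifest's ``reason`` column mirrors the compilation
    pipeline's exclusion categories, so ``reason == "ok"`` rows are exactly
    the rows a default-configured compile retains.
    """
    config = config or HerdSimConfig()
    rng = np.random.default_rng(seed)
    w0, w1 = config.window
    span = (w1 - w0).days
    if span < 500:
        raise ConfigError("window must cover at least 500 days")

    n_v = config.n_rows
    lact_values = np.array(list(config.lact_probs))
    lact_weights = np.array(list(config.lact_probs.values()), dtype=float)
    lact_weights = lact_weights / lact_weights.sum()
    lacts = rng.choice(lact_values, size=n_v, p=lact_weights)

    fresh = np.array([w0 + dt.timedelta(days=int(d)) for d in rng.integers(0, span + 1, n_v)])
    cow_ids = np.arange(1, n_v + 1)

    # same-cow consecutive-lactation pairs
    n_pairs = int(config.multi_lact_frac * n_v / 2)
    for k in range(n_pairs):
        a, b = 2 * k, 2 * k + 1
        cow_ids[b] = cow_ids[a]
        lacts[b] = lacts[a] + 1
        fa = w0 + dt.timedelta(days=int(rng.integers(0, max(span - 450, 1))))
        fresh[a] = fa
        fresh[b] = fa + dt.timedelta(days=int(380 + rng.integers(0, 61)))

    lctgp = np.minimum(lacts, 3).astype(str)
    p_twin = np.array([config.twin_p(g) for g in lctgp])
    twin = rng.random(n_v) < p_twin
    ket = rng.random(n_v) < np.array([config.ket_p[g] for g in lctgp])
    rp = rng.random(n_v) < config.rp_p
    mlk_fvr = rng.random(n_v) < np.array([config.mlk_fvr_p[g] for g in lctgp])
    mast = rng.random(n_v) < config.mast_p
    mast2 = mast & (rng.random(n_v) < config.mast_second_p)
    scours = rng.random(n_v) < config.scours_p

    mf_dim = np.minimum(rng.geometric(0.25, n_v) - 1, 14)
    ket_dim = rng.integers(3, 26, n_v)
    rp_dim = rng.integers(0, 3, n_v)
    mast_dim = rng.integers(4, 251, n_v)
    mast2_dim = np.minimum(mast_dim + rng.integers(10, 101, n_v), 305)
    scours_dim = rng.integers(2, 31, n_v)

    rem60 = rng.random(n_v) < expit(
        logit(config.rem60_base_p) + np.log(config.rem60_or_twin) * twin
    )
    rem60_dim = rng.integers(3, 60, n_v)
    late_p = np.array([config.late_removal_p[g] for g in lctgp])
    late = ~rem60 & (rng.random(n_v) < late_p)
    late_dim = rng.integers(60, 331, n_v)
    removed = rem60 | late
    rem_dim = np.where(rem60, rem60_dim, late_dim)
    sold = removed & (rng.random(n_v) < config.sold_frac)

    # events after removal cannot have been recorded
    horizon = np.where(removed, rem_dim, 10_000)
    ket &= ket_dim <= horizon
    rp &= rp_dim <= horizon
    mlk_fvr &= mf_dim <= horizon
    mast &= mast_dim <= horizon
    mast2 &= mast & (mast2_dim <= horizon)
    scours &= scours_dim <= horizon

    fm = config.fstbf
    offsets = np.array([fm.lctgp_offsets[g] for g in lctgp])
    fstbf_true = (
        fm.base + offsets + fm.beta_twin * twin + fm.beta_ket * ket
        + rng.normal(0.0, fm.sd, n_v)
    )
    fstbf = np.round(fstbf_true, fm.decimals)
    fstbf_missing = removed & (rem_dim < fm.missing_if_removed_before)

    dup_draw = rng.random((n_v, 6))
    dup_lag = rng.choice(config.duplicate_lags, size=(n_v, 6))
    remark_pick = rng.integers(0, 4, (n_v, 8))

    def remark(event, i, slot):
        pool = _REMARKS[event]
        return pool[remark_pick[i, slot] % len(pool)]

    rows = []
    manifest_rows = []
    for i in range(n_v):
        fd = fresh[i]
        evs: list[tuple[dt.date, str, str]] = []

        def add(event, dim, slot, dup_slot=None):
            evs.append((fd + dt.timedelta(days=int(dim)), RAW_EVENT_NAMES[event], remark(event, i, slot)))
            if dup_slot is not None and dup_draw[i, dup_slot] < config.duplicate_p:
                evs.append(
                    (fd + dt.timedelta(days=int(dim + dup_lag[i, dup_slot])),
                     RAW_EVENT_NAMES[event], "RECHECK")
                )

        if twin[i]:
            add("TWIN", 0, 0)
        if rp[i]:
            add("RP", rp_dim[i], 1, dup_slot=0)
        if mlk_fvr[i]:
            add("MLK_FVR", mf_dim[i], 2, dup_slot=1)
        if ket[i]:
            add("KET", ket_dim[i], 3, dup_slot=2)
        if mast[i]:
            add("MAST", mast_dim[i], 4, dup_slot=3)
        if mast2[i]:
            add("MAST", mast2_dim[i], 5, dup_slot=4)
        if scours[i]:
            add("DIARRHEA", scours_dim[i], 6, dup_slot=5)
        if removed[i]:
            add("SOLD" if sold[i] else "DIED", rem_dim[i], 7)
        evs.sort(key=lambda e: (e[0], e[1]))

        lact = int(lacts[i])
        fcdat = fd if lact == 1 else fd - dt.timedelta(days=int((lact - 1) * 385 + rng.integers(0, 61)))
        bdat = fcdat - dt.timedelta(days=int(730 + rng.integers(-30, 31)))
        rows.append(
            {
                "ID": str(cow_ids[i]),
                "LACT": str(lact),
                "BDAT": _fmt_date(bdat),
                "FDAT": _fmt_date(fd),
                "FCDAT": _fmt_date(fcdat),
                "FSTBF": "" if fstbf_missing[i] else f"{fstbf[i]:.{fm.decimals}f}",
                "_events": evs,
            }
        )
        manifest_rows.append(
            {
                "ID": str(cow_ids[i]), "LACT": lact, "reason": "ok",
                "LCTGP": lctgp[i], "TWIN": int(twin[i]), "KET": int(ket[i]),
                "RP": int(rp[i]), "MLK_FVR": int(mlk_fvr[i]),
                "MLK_FVR_DIM": int(mf_dim[i]) if mlk_fvr[i] else None,
                "MAST_N": int(mast[i]) + int(mast2[i]),
                "DIARRHEA": int(scours[i]),
                "REMVD": int(removed[i]),
                "REM_DIM": int(rem_dim[i]) if removed[i] else None,
                "REM60": int(rem60[i]),
                "FSTBF": None if fstbf_missing[i] else float(f"{fstbf[i]:.{fm.decimals}f}"),
            }
        )

    next_id = n_v + 1

    def blank_manifest(cow, lact, reason):
        return {
            "ID": str(cow), "LACT": lact, "reason": reason,
            "LCTGP": str(min(lact, 3)) if lact >= 1 else None,
            "TWIN": 0, "KET": 0, "RP": 0, "MLK_FVR": 0, "MLK_FVR_DIM": None,
            "MAST_N": 0, "DIARRHEA": 0, "REMVD": 0, "REM_DIM": None,
            "REM60": 0, "FSTBF": None,
        }

    for _ in range(config.heifer_rows):
        b = w0 - dt.timedelta(days=int(rng.integers(300, 700)))
        rows.append(
            {"ID": str(next_id), "LACT": "0", "BDAT": _fmt_date(b), "FDAT": "",
             "FCDAT": "", "FSTBF": "", "_events": []}
        )
        manifest_rows.append(blank_manifest(next_id, 0, "lactation_not_started"))
        next_id += 1

    corrupt_field = rng.integers(0, 3, config.invalid_date_rows)
    for j in range(config.invalid_date_rows):
        lact = int(rng.choice(lact_values, p=lact_weights))
        fd = w0 + dt.timedelta(days=int(rng.integers(0, span + 1)))
        fcdat = fd if lact == 1 else fd - dt.timedelta(days=int((lact - 1) * 385))
        bdat = fcdat - dt.timedelta(days=730)
        row = {
            "ID": str(next_id), "LACT": str(lact), "BDAT": _fmt_date(bdat),
            "FDAT": _fmt_date(fd), "FCDAT": _fmt_date(fcdat),
            "FSTBF": f"{fm.base:.{fm.decimals}f}", "_events": [],
        }
        row[["BDAT", "FDAT", "FCDAT"][corrupt_field[j]]] = ["", "02/30/22", "N/A"][
            int(rng.integers(0, 3))
        ]
        rows.append(row)
        manifest_rows.append(blank_manifest(next_id, lact, "invalid_or_missing_dates"))
        next_id += 1

    for _ in range(config.out_of_window_rows):
        lact = int(rng.choice(lact_values, p=lact_weights))
        fd = w0 - dt.timedelta(days=int(rng.integers(30, 400)))
        fcdat = fd if lact == 1 else fd - dt.timedelta(days=int((lact - 1) * 385))
        bdat = fcdat - dt.timedelta(days=730)
        rows.append(
            {"ID": str(next_id), "LACT": str(lact), "BDAT": _fmt_date(bdat),
             "FDAT": _fmt_date(fd), "FCDAT": _fmt_date(fcdat),
             "FSTBF": f"{fm.base:.{fm.decimals}f}", "_events": []}
        )
        manifest_rows.append(blank_manifest(next_id, lact, "fresh_date_outside_window"))
        next_id += 1

    max_ev = max((len(r["_events"]) for r in rows), default=0)
    records = []
    for r in rows:
        rec = {k: v for k, v in r.items() if k != "_events"}
        for j in range(max_ev):
            if j < len(r["_events"]):
                d, name, rem = r["_events"][j]
                rec[f"EVT{j + 1}"], rec[f"DAT{j + 1}"], rec[f"REM{j + 1}"] = name, _fmt_date(d), rem
            else:
                rec[f"EVT{j + 1}"] = rec[f"DAT{j + 1}"] = rec[f"REM{j + 1}"] = ""
        records.append(rec)

    columns = ["ID", "LACT", "BDAT", "FDAT", "FCDAT", "FSTBF"]
    for j in range(max_ev):
        columns += [f"EVT{j + 1}", f"DAT{j + 1}", f"REM{j + 1}"]
    frame = pd.DataFrame(records, columns=columns).astype(object)
    manifest = pd.DataFrame(manifest_rows)

    truth = {
        "seed": seed,
        "expected_rows": int(n_v),
        "or_twin_lctgp": dict(config.twin_or),
        "or_rem60_twin": config.rem60_or_twin,
        "beta_twin_fstbf": config.fstbf.beta_twin,
        "beta_ket_fstbf": config.fstbf.beta_ket,
    }
    return SyntheticHerd(raw=RawHerdTable(frame=frame), manifest=manifest, truth=truth)


def write_raw_csv(herd: SyntheticHerd, path) -> None:
    """Write the synthetic raw export exactly as an on-farm export would look."""
    herd.raw.frame.to_csv(path, index=False, encoding="utf-8")
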