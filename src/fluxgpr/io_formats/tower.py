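"""Tower-table reading/writing.

Tower tables are CSV files with one row per site-day: ``site_id``, ISO-8601
``date``, optional ``vegetation_class``, the predictor columns named exactly
as in the schema (FLUXNET-style aliases such as ``SW_IN`` or ``TA_F`` can be
renamed through an alias map), and any subset of the flux columns GPP, RECO,
NEE in micromol CO2 m-2 s-1.

Sign convention: records always store NEE as *positive = atmosphere-to-
biosphere* (uptake).  Micrometeorological files use the opposite sign
(positive = release); pass ``nee_sign="release_positive"`` to flip on read.

The reader is total: malformed rows never crash it — each one produces a
located diagnostic on the returned table and is skipped (bad dates) or
flagged (out-of-range values).  Soil variables missing deeper depths are
filled by copying the deepest available measurement, with a fill flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path

import pandas as pd

from ..schema import FLUX_VARIABLES, PredictorSchema, VEGETATION_CLASSES

__all__ = ["TowerRecord", "TowerTable", "SchemaError", "read_tower_table",
           "write_tower_table"]

NEE_SIGN_UPTAKE = "uptake_positive"
NEE_SIGN_RELEASE = "release_positive"

# FLUXNET-style column aliases, user-overridable via the alias_map argument.
DEFAULT_ALIASES = {
    "SW_IN": "SW", "SW_IN_F": "SW",
    "TA_F": "TA", "TA_F_MDS": "TA",
    "P_F": "P", "WS_F": "WS", "VPD_F": "VPD",
    "TS_F_MDS_1": "TS_1", "TS_F_MDS_2": "TS_2", "TS_F_MDS_3": "TS_3",
    "SWC_F_MDS_1": "SWC_1", "SWC_F_MDS_2": "SWC_2", "SWC_F_MDS_3": "SWC_3",
    "H_F_MDS": "H", "LE_F_MDS": "LE",
    "GPP_NT_VUT_REF": "GPP", "RECO_NT_VUT_REF": "RECO", "NEE_VUT_REF": "NEE",
    "IGBP": "vegetation_class", "SITE_ID": "site_id", "TIMESTAMP": "date",
}

# Deeper soil depths may be absent at a tower; they are filled from the
# deepest available measurement rather than treated as missing.
_FILLABLE = {
    "TS_2": ["TS_1"], "TS_3": ["TS_2", "TS_1"],
    "SWC_2": ["SWC_1"], "SWC_3": ["SWC_2", "SWC_1"],
}


class SchemaError(ValueError):
    """A table is structurally incompatible with the predictor schema."""


@dataclass
class TowerRecord:
    """One site-day of predictors and fluxes."""

    site_id: str
    date: Date
    vegetation_class: str | None
    predictors: dict[str, float]
    fluxes: dict[str, float] = field(default_factory=dict)
    flags: dict[str, list[str]] = field(default_factory=dict)
    metadata: dict[str, object] = field(default_factory=dict)
    nee_sign: str = NEE_SIGN_UPTAKE


class TowerTable(list):
    """List of TowerRecord with row-level diagnostics from parsing."""

    def __init__(self, records=(), diagnostics=None):
        super().__init__(records)
        self.diagnostics: list[str] = list(diagnostics or [])


def read_tower_table(
    path: str | Path,
    schema: PredictorSchema,
    alias_map: dict[str, str] | None = None,
    nee_sign: str = NEE_SIGN_UPTAKE,
) -> TowerTable:
    """Parse a CSV tower table against a predictor schema.

    Raises SchemaError if a mandatory column (site_id, date, or a
    non-fillable predictor) is absent; all row-level problems become
    diagnostics instead of exceptions.
    """
    if nee_sign not in (NEE_SIGN_UPTAKE, NEE_SIGN_RELEASE):
        raise ValueError(f"unknown NEE sign convention {nee_sign!r}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    aliases = dict(DEFAULT_ALIASES)
    aliases.update(alias_map or {})
    df = df.rename(columns={c: aliases.get(c, c) for c in df.columns})

    for col in ("site_id", "date"):
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col}")
    for p in schema:
        if p.name not in df.columns and p.name not in _FILLABLE:
            raise SchemaError(f"missing mandatory column: {p.name}")

    known = {"site_id", "date", "vegetation_class", *schema.names,
             *FLUX_VARIABLES}
    extra_cols = [c for c in df.columns if c not in known]

    records: list[TowerRecord] = []
    diagnostics: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            day = pd.Timestamp(str(row["date"]).strip()).date()
        except (ValueError, TypeError):
            diagnostics.append(
                f"line {line}: unparseable date {row['date']!r}; row skipped"
            )
            continue

        flags: dict[str, list[str]] = {}
        preds: dict[str, float] = {}
        missing: list[str] = []
        for p in schema:
            val = _parse_float(row.get(p.name))
            if val is None:
                missing.append(p.name)
                continue
            preds[p.name] = val
            if not p.in_range(val):
                flags.setdefault("out_of_range", []).append(p.name)
        # fill absent deeper soil depths from the deepest available
        for name in list(missing):
            for source in _FILLABLE.get(name, []):
                if source in preds:
                    preds[name] = preds[source]
                    flags.setdefault("filled", []).append(name)
                    missing.remove(name)
                    break
        if missing:
            flags["missing"] = missing

        fluxes: dict[str, float] = {}
        for fv in FLUX_VARIABLES:
            val = _parse_float(row.get(fv))
            if val is not None:
                if fv == "NEE" and nee_sign == NEE_SIGN_RELEASE:
                    val = -val
                fluxes[fv] = val

        veg = row.get("vegetation_class")
        veg = str(veg).strip() if veg is not None and str(veg).strip() else None
        if veg is not None and veg not in VEGETATION_CLASSES:
            flags.setdefault("unknown_vegetation_class", []).append(veg)

        records.append(
            TowerRecord(
                site_id=str(row["site_id"]).strip(),
                date=day,
                vegetation_class=veg,
                predictors=preds,
                fluxes=fluxes,
                flags=flags,
                metadata={c: row[c] for c in extra_cols},
            )
        )
    return TowerTable(records, diagnostics)


def write_tower_table(path: str | Path, records: list[TowerRecord],
                      schema: PredictorSchema) -> None:
    rows = []
    for r in records:
        row = {"site_id": r.site_id, "date": r.date.isoformat(),
               "vegetation_class": r.vegetation_class or ""}
        for p in schema:
            row[p.name] = r.predictors.get(p.name, "")
        for fv in FLUX_VARIABLES:
            if fv in r.fluxes:
                row[fv] = r.fluxes[fv]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _parse_float(raw) -> float | None:
    if raw is None:
        return None
    s = str(raw).strip()
    if not s or s.upper() in ("NA", "NAN", "-9999", "-9999.0"):
        return None
    try:
        v = float(s)
    except ValueError:
        return None
    return v if math.isfinite(v) else None
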