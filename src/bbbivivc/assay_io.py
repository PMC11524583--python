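"""Tabular I/O: read and validate assay CSVs, serve the packaged 18-drug
reference table, and write result tables.

All readers validate row-by-row into the typed records of
:mod:`bbbivivc.records` and report the offending CSV row on failure.
Thousands separators ("13,716.00") are accepted on read since published
tables often carry them; output is always machine-clean.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pydantic import ValidationError

from .records import DrugRecord, IvivcResult, TeerRecord, TransportRecord

__all__ = [
    "SchemaError",
    "UnitError",
    "RowValidationError",
    "FixtureIntegrityError",
    "read_transport_table",
    "read_teer_table",
    "read_drugs_table",
    "write_results_table",
    "load_table1_fixture",
    "table1_dataframe",
    "TABLE1_SHA256",
]


class SchemaError(ValueError):
    """A required column is absent from the input table."""


class UnitError(ValueError):
    """A declared unit is unknown or unsupported."""


class RowValidationError(ValueError):
    """A row failed validation; carries the 1-based data row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class FixtureIntegrityError(RuntimeError):
    """The packaged reference table does not match its frozen checksum."""


# concentration units convertible to the internal µmol/L
_CONC_FACTORS = {
    "uM": 1.0,
    "umol/L": 1.0,
    "µM": 1.0,
    "µmol/L": 1.0,
    "nmol/mL": 1.0,  # numerically identical to µmol/L
    "mM": 1000.0,
    "mmol/L": 1000.0,
    "nM": 1e-3,
    "nmol/L": 1e-3,
}

_TRANSPORT_COLUMNS = {
    "drug_id": "drug_id",
    "model_id": "model_id",
    "replicate": "replicate",
    "t_sample": "t_sample_s",
    "c0_donor": "C0_uM",
    "c_receiver": "C_receiver_uM",
    "v_receiver": "V_receiver_mL",
    "v_donor": "V_donor_mL",
    "membrane_area": "area_cm2",
}

_TEER_COLUMNS = {
    "insert_id": "insert_id",
    "model_id": "model_id",
    "day": "day",
    "resistance_raw": "resistance_ohm",
    "is_blank": "is_blank",
    "membrane_area": "area_cm2",
}

_DRUG_COLUMNS = {
    "drug_id": "drug_id",
    "fu_brain": "fu_brain",
    "ps_obs": "ps_obs_ul_min_g",
    "ps_obs_source": "source",
}

TABLE1_SHA256 = "d037c3eb4a9344ee60d81bd3dbe8c37f0fcf5b3c4f586900eaa6fbf8a09ed6da"


def _clean_numeric(value):
    """Strip thousands separators from a printed number; pass floats through."""
    if isinstance(value, str):
        return value.replace(",", "").strip()
    return value


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, dtype=object, keep_default_na=False, na_values=[""])


def _require_columns(df: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")


def concentration_factor(unit: str) -> float:
    """Multiplier converting the declared concentration unit to µmol/L."""
    try:
        return _CONC_FACTORS[unit]
    except KeyError:
        raise UnitError(
            f"unknown concentration unit {unit!r}; supported: {sorted(_CONC_FACTORS)}"
        ) from None


def read_transport_table(
    path: str | Path,
    schema_config: Mapping[str, str] | None = None,
    concentration_unit: str = "uM",
) -> list[TransportRecord]:
    """Parse a transport CSV into validated :class:`TransportRecord` rows.

    ``schema_config`` remaps logical field names to CSV column names;
    ``concentration_unit`` declares the unit of both concentration columns
    and is converted to µmol/L on read.
    """
    colmap = dict(_TRANSPORT_COLUMNS)
    if schema_config:
        colmap.update(schema_config)
    factor = concentration_factor(concentration_unit)

    df = _read_csv(path)
    _require_columns(df, colmap.values())

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw = {field: _clean_numeric(getattr(row, col)) for field, col in colmap.items()}
        try:
            rec = TransportRecord(
                drug_id=str(raw["drug_id"]),
                model_id=str(raw["model_id"]),
                replicate=int(raw["replicate"]),
                t_sample=float(raw["t_sample"]),
                c0_donor=float(raw["c0_donor"]) * factor,
                c_receiver=float(raw["c_receiver"]) * factor,
                v_receiver=float(raw["v_receiver"]),
                v_donor=float(raw["v_donor"]),
                membrane_area=float(raw["membrane_area"]),
            )
        except (TypeError, ValueError, ValidationError) as exc:
            raise RowValidationError(i, str(exc)) from exc
        records.append(rec)
    return records


def read_teer_table(
    path: str | Path, schema_config: Mapping[str, str] | None = None
) -> list[TeerRecord]:
    """Parse a TEER CSV (one resistance reading per insert per day)."""
    colmap = dict(_TEER_COLUMNS)
    if schema_config:
        colmap.update(schema_config)
    df = _read_csv(path)
    _require_columns(df, colmap.values())

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw = {field: _clean_numeric(getattr(row, col)) for field, col in colmap.items()}
        try:
            rec = TeerRecord(
                insert_id=str(raw["insert_id"]),
                model_id=str(raw["model_id"]),
                day=int(raw["day"]),
                resistance_raw=float(raw["resistance_raw"]),
                is_blank=str(raw["is_blank"]).strip().lower() in {"true", "1", "yes"},
                membrane_area=float(raw["membrane_area"]),
            )
        except (TypeError, ValueError, ValidationError) as exc:
            raise RowValidationError(i, str(exc)) from exc
        records.append(rec)
    return records


def read_drugs_table(
    path: str | Path, schema_config: Mapping[str, str] | None = None
) -> list[DrugRecord]:
    """Parse a drug table CSV (fu_brain and observed in vivo PS per drug)."""
    colmap = dict(_DRUG_COLUMNS)
    if schema_config:
        colmap.update(schema_config)
    df = _read_csv(path)
    required = [colmap[f] for f in ("drug_id", "fu_brain", "ps_obs")]
    _require_columns(df, required)
    has_source = colmap["ps_obs_source"] in df.columns

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = DrugRecord(
                drug_id=str(getattr(row, colmap["drug_id"])),
                fu_brain=float(_clean_numeric(getattr(row, colmap["fu_brain"]))),
                ps_obs=float(_clean_numeric(getattr(row, colmap["ps_obs"]))),
                ps_obs_source=str(getattr(row, colmap["ps_obs_source"])) if has_source else "",
            )
        except (TypeError, ValueError, ValidationError) as exc:
            raise RowValidationError(i, str(exc)) from exc
        records.append(rec)
    return records


def write_results_table(
    results: Sequence[IvivcResult], path: str | Path, precision: int = 2
) -> Path:
    """Write IVIVC results to CSV with deterministic column order.

    Floats are rounded to ``precision`` decimals (default 2, matching the
    published-table style); values round-trip through :func:`pandas.read_csv`
    losslessly at that precision.
    """
    if not results:
        raise ValueError("refusing to write an empty results table")
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "drug_id": r.drug_id,
                "model_id": r.model_id,
                "ps_pre_ul_min_g": round(r.ps_pre, precision),
                "ps_obs_ul_min_g": round(r.ps_obs, precision),
                "fold_ratio": round(r.fold_ratio, max(precision, 3)),
                "within_2fold": r.within_2fold,
            }
            for r in results
        ]
    )
    df.to_csv(path, index=False)
    return path


def _fixture_bytes() -> bytes:
    return resources.files("bbbivivc.data").joinpath("table1.csv").read_bytes()


def table1_dataframe() -> pd.DataFrame:
    """The packaged 18-drug reference table as a DataFrame, checksum-verified.

    Columns: fu_brain, observed PS (µL/min/g), per-model mean ± SEM Papp on
    the ×10⁻⁶ cm/s display scale, and the published predicted-PS values
    retained for cross-checking recomputation.
    """
    raw = _fixture_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise FixtureIntegrityError(
            f"reference table checksum mismatch: {digest} != {TABLE1_SHA256}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_table1_fixture() -> tuple[list[DrugRecord], dict[str, dict[str, float]]]:
    """Load the packaged reference table.

    Returns the 18 :class:`DrugRecord` entries and a mapping
    ``drug_id -> {"mono": papp_cm_s, "triple": papp_cm_s, ...}`` of mean
    apparent permeabilities converted from the ×10⁻⁶ display scale to cm/s.
    """
    df = table1_dataframe()
    drugs = [
        DrugRecord(
            drug_id=row.drug_id,
            fu_brain=row.fu_brain,
            ps_obs=row.ps_obs_ul_min_g,
            ps_obs_source="published reference table",
        )
        for row in df.itertuples(index=False)
    ]
    papp = {
        row.drug_id: {
            "mono": row.papp_mono_mean_1e6_cm_s * 1e-6,
            "mono_sem": row.papp_mono_sem_1e6_cm_s * 1e-6,
            "triple": row.papp_triple_mean_1e6_cm_s * 1e-6,
            "triple_sem": row.papp_triple_sem_1e6_cm_s * 1e-6,
        }
        for row in df.itertuples(index=False)
    }
    return drugs, papp
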