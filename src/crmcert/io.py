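"""Validated readers and writers for the long-format study tables.

Every stage of the certification pipeline consumes a "measurement table": a
long-format :class:`pandas.DataFrame` with one row per individual result
(mass fraction in µg/kg) and study-specific grouping columns.  Three study
kinds are supported:

====================  =====================================================
kind                  columns
====================  =====================================================
``homogeneity``       ``analyte, bottle, replicate, value``
``stability``         ``analyte, temperature_C, time_months, unit, value``
``characterisation``  ``analyte, workplace, unit, replicate, value``
====================  =====================================================

Files use UTF-8, comma delimiter, period decimal separator and a header row.
A generic interchange layout ``analyte,group1,group2,replicate,value,
unit_of_measure`` (with a sidecar JSON documenting the group semantics) is
also accepted and written by the simulator CLI.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .exceptions import ValidationError

#: canonical column sets per study kind
STUDY_SCHEMAS: dict[str, list[str]] = {
    "homogeneity": ["analyte", "bottle", "replicate", "value"],
    "stability": ["analyte", "temperature_C", "time_months", "unit", "value"],
    "characterisation": ["analyte", "workplace", "unit", "replicate", "value"],
}

GENERIC_COLUMNS = ["analyte", "group1", "group2", "replicate", "value", "unit_of_measure"]

#: mapping generic -> kind-specific column names (None drops the column)
_GENERIC_MAPS: dict[str, dict[str, str | None]] = {
    "homogeneity": {"group1": "bottle", "group2": None, "replicate": "replicate"},
    "stability": {"group1": "temperature_C", "group2": "time_months", "replicate": "unit"},
    "characterisation": {"group1": "workplace", "group2": "unit", "replicate": "replicate"},
}

_DECIMAL_COMMA = re.compile(r"^\s*-?\d+,\d+\s*$")


def _key_columns(kind: str) -> list[str]:
    cols = STUDY_SCHEMAS[kind]
    return [c for c in cols if c != "value"]


def validate_measurements(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Validate a measurement table against the schema for *kind*.

    Checks column presence, finite numeric values and key uniqueness.
    Returns a copy with the canonical column order.  Raises
    :class:`ValidationError` listing offending rows (0-based data rows).
    """
    if kind not in STUDY_SCHEMAS:
        raise ValidationError(f"unknown study kind {kind!r}; expected one of {sorted(STUDY_SCHEMAS)}")
    expected = STUDY_SCHEMAS[kind]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(f"{kind} table is missing required columns {missing}; found {list(df.columns)}")
    out = df.loc[:, expected].copy()
    if len(out) == 0:
        raise ValidationError(f"{kind} table contains no data rows")

    if out["value"].dtype == object:
        commas = [i for i, v in enumerate(out["value"]) if isinstance(v, str) and _DECIMAL_COMMA.match(v)]
        if commas:
            raise ValidationError(
                "decimal-comma values are not accepted (use a period decimal separator); "
                f"offending rows: {commas[:10]}"
            )
    values = pd.to_numeric(out["value"], errors="coerce")
    bad = values.index[~values.apply(lambda v: pd.notna(v) and abs(v) != float("inf"))].tolist()
    if bad:
        raise ValidationError(f"non-numeric or non-finite values in rows {bad[:10]}")
    out["value"] = values.astype(float)

    keys = _key_columns(kind)
    dup_mask = out.duplicated(subset=keys, keep=False)
    if dup_mask.any():
        first = out.loc[dup_mask, keys].iloc[0].to_dict()
        raise ValidationError(f"duplicate measurement key {first} in {kind} table")
    return out


def read_measurements(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate a long-format study CSV.

    Accepts both the kind-specific header and the generic
    ``analyte,group1,group2,...`` interchange layout.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"value": str})
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty file: {path}") from None
    if set(GENERIC_COLUMNS[:5]).issubset(df.columns):
        mapping = _GENERIC_MAPS[kind] if kind in _GENERIC_MAPS else {}
        renamed = {}
        for generic, specific in mapping.items():
            if specific is not None:
                renamed[generic] = specific
        df = df.rename(columns=renamed)
    return validate_measurements(df, kind)


def write_measurements(df: pd.DataFrame, kind: str, path: str | Path) -> None:
    """Write a validated table in the generic interchange layout.

    A sidecar ``<path>.meta.json`` documents what ``group1``/``group2`` mean
    for this study kind.
    """
    df = validate_measurements(df, kind)
    mapping = _GENERIC_MAPS[kind]
    out = pd.DataFrame({"analyte": df["analyte"]})
    inverse = {v: k for k, v in mapping.items() if v is not None}
    semantics: dict[str, str] = {}
    for generic in ("group1", "group2", "replicate"):
        specific = mapping.get(generic)
        if specific is None:
            out[generic] = ""
            semantics[generic] = "(unused)"
        else:
            out[generic] = df[specific]
            semantics[generic] = specific
    out["value"] = df["value"]
    out["unit_of_measure"] = "ug/kg"
    path = Path(path)
    out.to_csv(path, index=False)
    meta = {"kind": kind, "group_semantics": semantics, "value_unit": "ug/kg"}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))
    _ = inverse  # documented mapping retained for symmetry


@dataclass
class PipelineConfig:
    """Configuration of a full certification run.

    Parameters mirror the statistical choices of the certification procedure:
    ``alpha`` for all significance screens, ``m_tests`` for the Bonferroni
    multiplier (None: number of analytes present), ``t_sl`` the shelf-life
    horizon in months, ``ref_temp`` the storage temperature whose regression
    feeds the stability contribution, ``k`` the coverage factor and
    ``u_pur_r`` the per-analyte relative calibrant-purity uncertainty.
    """

    homogeneity_path: str | None = None
    stability_path: str | None = None
    characterisation_path: str | None = None
    u_pur_r: Mapping[str, float] | float = 0.0
    alpha: float = 0.05
    m_tests: int | None = None
    t_sl: float = 36.0
    ref_temp: float = -20.0
    k: float = 2.0
    precision_map: Mapping[str, int] = field(default_factory=dict)
    isomer_sum_analytes: tuple[str, ...] = ("PFOA", "PFHxS", "PFOS")
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.k <= 0:
            raise ValidationError(f"coverage factor k must be > 0, got {self.k}")
        if self.t_sl <= 0:
            raise ValidationError(f"shelf life t_sl must be > 0 months, got {self.t_sl}")
        if self.m_tests is not None and self.m_tests < 1:
            raise ValidationError(f"m_tests must be >= 1, got {self.m_tests}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "precision_map" in raw and raw["precision_map"] is None:
            raw["precision_map"] = {}
        if "isomer_sum_analytes" in raw:
            raw["isomer_sum_analytes"] = tuple(raw["isomer_sum_analytes"])
        return cls(**raw)

    def u_pur_for(self, analyte: str) -> float:
        if isinstance(self.u_pur_r, Mapping):
            if analyte not in self.u_pur_r:
                raise ValidationError(f"no calibrant-purity uncertainty configured for analyte {analyte!r}")
            value = float(self.u_pur_r[analyte])
        else:
            value = float(self.u_pur_r)
        if value < 0:
            raise ValidationError(f"u_pur_r for {analyte!r} must be >= 0, got {value}")
        return value
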