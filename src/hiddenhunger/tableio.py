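"""Reading and writing the delimited country / DALY tables.

Tables are UTF-8 delimited text (comma by default, tab accepted). An
empty cell means missing. Unparseable numeric cells are demoted to
missing with a logged warning; structural problems (duplicate iso3,
absent mandatory columns) are hard errors.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .records import (
    AgeGroup,
    ConversionPolicy,
    CountryRecord,
    DalyRecord,
    PrevalenceEstimate,
    Provenance,
    WHORegion,
)

logger = logging.getLogger(__name__)

COUNTRY_COLUMNS = [
    "iso3", "name", "who_region", "ssa_member", "hdi_2007", "lei_2007",
    "gdp_2005", "population_2009", "under5_population", "malaria_endemic",
    "stunting", "stunting_prov", "anemia", "anemia_prov",
    "vad", "vad_prov", "id", "id_prov",
]
MANDATORY_COUNTRY_COLUMNS = ("iso3", "name", "who_region")

DALY_COLUMNS = [
    "iso3", "daly_iron", "daly_zinc", "daly_vita", "daly_iodine",
    "total_all_cause_dalys", "population",
]

_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n", ""}


def _detect_sep(path: Path, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    if path.suffix.lower() in {".tsv", ".tab"}:
        return "\t"
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header and "," not in header else ","


def _cell(row: pd.Series, col: str) -> str:
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    return str(v).strip()


def _num(row: pd.Series, col: str, context: str) -> Optional[float]:
    raw = _cell(row, col)
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        logger.warning("unparseable %s=%r for %s; treated as missing", col, raw, context)
        return None


def _boolean(row: pd.Series, col: str, context: str) -> bool:
    raw = _cell(row, col).lower()
    if raw in _TRUE:
        return True
    if raw in _FALSE:
        return False
    logger.warning("unparseable %s=%r for %s; treated as False", col, raw, context)
    return False


def _prevalence(row: pd.Series, col: str, age_group: AgeGroup, context: str) -> PrevalenceEstimate:
    value = _num(row, col, context)
    if value is None:
        return PrevalenceEstimate(None, age_group, Provenance.MISSING)
    raw_prov = _cell(row, f"{col}_prov")
    if raw_prov == "":
        prov = Provenance.NATIONAL_SURVEY  # unannotated values default to survey data
    else:
        try:
            prov = Provenance(raw_prov)
        except ValueError:
            logger.warning(
                "unknown provenance %r for %s %s; defaulting to national_survey",
                raw_prov, context, col,
            )
            prov = Provenance.NATIONAL_SURVEY
    if prov is Provenance.MISSING:
        prov = Provenance.NATIONAL_SURVEY
    return PrevalenceEstimate(value, age_group, prov)


def read_country_table(
    path: str | Path,
    schema: Sequence[str] = MANDATORY_COUNTRY_COLUMNS,
    sep: Optional[str] = None,
) -> list[CountryRecord]:
    """Read a country indicator table into :class:`CountryRecord` rows.

    Raises ``ValueError`` on duplicate iso3 codes or missing mandatory
    columns; malformed numeric cells become missing with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep), dtype=str, keep_default_na=False)
    missing_cols = [c for c in schema if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing mandatory columns {missing_cols}")

    records: list[CountryRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        iso3 = _cell(row, "iso3").upper()
        if not iso3:
            raise ValueError(f"{path}: row with empty iso3")
        if iso3 in seen:
            raise ValueError(f"{path}: duplicate iso3 {iso3!r}")
        seen.add(iso3)
        region = _cell(row, "who_region").upper()
        try:
            who_region = WHORegion(region)
        except ValueError as exc:
            raise ValueError(f"{path}: unknown WHO region {region!r} for {iso3}") from exc
        records.append(
            CountryRecord(
                iso3=iso3,
                name=_cell(row, "name"),
                who_region=who_region,
                ssa_member=_boolean(row, "ssa_member", iso3),
                hdi_2007=_num(row, "hdi_2007", iso3),
                lei_2007=_num(row, "lei_2007", iso3),
                gdp_2005=_num(row, "gdp_2005", iso3),
                population_2009=_num(row, "population_2009", iso3),
                under5_population=_num(row, "under5_population", iso3),
                malaria_endemic=_boolean(row, "malaria_endemic", iso3),
                stunting=_prevalence(row, "stunting", AgeGroup.PRESCHOOL, iso3),
                anemia=_prevalence(row, "anemia", AgeGroup.PRESCHOOL, iso3),
                vad=_prevalence(row, "vad", AgeGroup.PRESCHOOL, iso3),
                id=_prevalence(row, "id", AgeGroup.SCHOOL_AGE, iso3),
            )
        )
    return records


def read_daly_table(path: str | Path, sep: Optional[str] = None) -> list[DalyRecord]:
    """Read the per-country micronutrient DALY table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep), dtype=str, keep_default_na=False)
    if "iso3" not in df.columns:
        raise ValueError(f"{path}: missing mandatory column 'iso3'")
    records: list[DalyRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        iso3 = _cell(row, "iso3").upper()
        if iso3 in seen:
            raise ValueError(f"{path}: duplicate iso3 {iso3!r}")
        seen.add(iso3)
        records.append(
            DalyRecord(
                iso3=iso3,
                daly_iron=_num(row, "daly_iron", iso3),
                daly_zinc=_num(row, "daly_zinc", iso3),
                daly_vita=_num(row, "daly_vita", iso3),
                daly_iodine=_num(row, "daly_iodine", iso3),
                total_all_cause_dalys=_num(row, "total_all_cause_dalys", iso3),
                population=_num(row, "population", iso3),
            )
        )
    return records


def _fmt(x: Optional[float]) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return str(x).lower()
    if float(x) == int(x) and abs(x) < 1e15:
        return str(int(x))
    return format(float(x), ".6g")


def country_frame(records: Iterable[CountryRecord]) -> pd.DataFrame:
    """Records as a DataFrame in the canonical column order."""
    rows = []
    for r in records:
        row = {
            "iso3": r.iso3,
            "name": r.name,
            "who_region": r.who_region.value,
            "ssa_member": str(r.ssa_member).lower(),
            "hdi_2007": _fmt(r.hdi_2007),
            "lei_2007": _fmt(r.lei_2007),
            "gdp_2005": _fmt(r.gdp_2005),
            "population_2009": _fmt(r.population_2009),
            "under5_population": _fmt(r.under5_population),
            "malaria_endemic": str(r.malaria_endemic).lower(),
        }
        for f in ("stunting", "anemia", "vad", "id"):
            est: PrevalenceEstimate = getattr(r, f)
            row[f] = _fmt(est.value)
            row[f"{f}_prov"] = "" if est.is_missing else est.provenance.value
        rows.append(row)
    return pd.DataFrame(rows, columns=COUNTRY_COLUMNS)


def daly_frame(records: Iterable[DalyRecord]) -> pd.DataFrame:
    rows = [
        {
            "iso3": r.iso3,
            "daly_iron": _fmt(r.daly_iron),
            "daly_zinc": _fmt(r.daly_zinc),
            "daly_vita": _fmt(r.daly_vita),
            "daly_iodine": _fmt(r.daly_iodine),
            "total_all_cause_dalys": _fmt(r.total_all_cause_dalys),
            "population": _fmt(r.population),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=DALY_COLUMNS)


def write_country_table(records: Iterable[CountryRecord], path: str | Path, sep: str = ",") -> None:
    country_frame(records).to_csv(path, sep=sep, index=False)


def write_daly_table(records: Iterable[DalyRecord], path: str | Path, sep: str = ",") -> None:
    daly_frame(records).to_csv(path, sep=sep, index=False)


def write_exclusion_report(
    exclusions: Iterable[tuple[CountryRecord, str]], path: str | Path, sep: str = ","
) -> None:
    """Write the (iso3, reason) exclusion report."""
    df = pd.DataFrame(
        [{"iso3": r.iso3, "name": r.name, "reason": reason} for r, reason in exclusions],
        columns=["iso3", "name", "reason"],
    )
    df.to_csv(path, sep=sep, index=False)
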