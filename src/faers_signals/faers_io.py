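"""Reading and writing FAERS-style quarterly ASCII packages.

A quarterly package is a directory of $-delimited text files, one per table
(DEMO, DRUG, REAC, INDI, OUTC, THER), plus an optional deleted-case list
(one CASEID per line; distributed with quarters from 2019Q1 onward). Fields
are unquoted, the first line is a header, and the files are decoded as
Latin-1 with undecodable bytes replaced, matching the public FAERS archive
convention.

Dates are distributed as YYYYMMDD integers and are frequently partial:

* ``YYYYMMDD`` parses to a calendar date;
* ``YYYYMM`` is imputed to day 15 (flagged in a ``*_imputed`` column) so
  interval arithmetic stays possible but auditable;
* ``YYYY`` is unusable for arithmetic — the parsed date is missing but the
  year is retained in a ``*_year`` column for binning;
* anything else is missing, with a logged warning.

Every parsed date column ``col`` therefore travels with ``col_imputed``
(bool) and ``col_year`` (nullable int).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of each table in the ASCII dialect
TABLE_COLUMNS: dict[str, list[str]] = {
    "demo": [
        "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
        "wt", "wt_cod", "sex", "occ_cod", "occr_country",
    ],
    "drug": ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai", "route"],
    "reac": ["primaryid", "pt"],
    "indi": ["primaryid", "indi_drug_seq", "indi_pt"],
    "outc": ["primaryid", "outc_cod"],
    "ther": ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"],
}

DATE_COLUMNS: dict[str, list[str]] = {
    "demo": ["fda_dt", "event_dt"],
    "ther": ["start_dt", "end_dt"],
}

INT_COLUMNS: dict[str, list[str]] = {
    "demo": ["primaryid", "caseid"],
    "drug": ["primaryid", "drug_seq"],
    "reac": ["primaryid"],
    "indi": ["primaryid", "indi_drug_seq"],
    "outc": ["primaryid"],
    "ther": ["primaryid", "dsg_drug_seq"],
}

FLOAT_COLUMNS: dict[str, list[str]] = {"demo": ["age", "wt"]}

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

_QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")

#: pound-to-kilogram conversion factor
LBS_TO_KG = 0.45359237

AGE_UNIT_FACTORS = {"YR": 1.0, "DEC": 10.0, "MON": 1.0 / 12.0, "DY": 1.0 / 365.25}


class FaersFormatError(ValueError):
    """Raised for structurally unreadable quarterly files."""


def parse_quarter_label(label: str) -> tuple[int, int]:
    """Return (year, quarter) from a label like ``"2021Q1"``."""
    m = _QUARTER_RE.match(label)
    if not m:
        raise ValueError(f"not a quarter label: {label!r}")
    return int(m.group(1)), int(m.group(2))


def quarter_bounds(label: str) -> tuple[pd.Timestamp, pd.Timestamp]:
    """First and last calendar day of a quarter."""
    year, q = parse_quarter_label(label)
    start = pd.Timestamp(year=year, month=3 * (q - 1) + 1, day=1)
    end = start + pd.offsets.QuarterEnd(startingMonth=3)
    return start, end


@dataclass
class RawQuarter:
    """One quarterly package parsed into typed tables.

    Invariant: every PRIMARYID in the satellite tables exists in ``demo``
    (orphans are dropped with a warning at read time).
    """

    quarter_label: str
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    indi: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    deleted_case_ids: set[int] = field(default_factory=set)

    @property
    def manifest(self) -> dict[str, int]:
        """Row counts per table plus deleted-list size."""
        counts = {name: len(getattr(self, name)) for name in TABLE_COLUMNS}
        counts["deleted"] = len(self.deleted_case_ids)
        return counts

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_COLUMNS}


def parse_faers_dates(raw: pd.Series) -> pd.DataFrame:
    """Parse a series of FAERS date strings into (date, imputed, year).

    Returns a frame with columns ``date`` (datetime64), ``imputed`` (bool)
    and ``year`` (Int32), following the partial-date convention described in
    the module docstring.
    """
    s = raw.astype("string").str.strip()
    s = s.where(s.notna() & (s != ""), other=pd.NA)

    date = pd.Series(pd.NaT, index=raw.index, dtype="datetime64[ns]")
    imputed = pd.Series(False, index=raw.index)
    year = pd.Series(pd.NA, index=raw.index, dtype="Int32")

    full = s.str.fullmatch(r"\d{8}").fillna(False).astype(bool)
    ym = s.str.fullmatch(r"\d{6}").fillna(False).astype(bool)
    y_only = s.str.fullmatch(r"\d{4}").fillna(False).astype(bool)

    if full.any():
        parsed = pd.to_datetime(s[full], format="%Y%m%d", errors="coerce")
        date.loc[full] = parsed
        year.loc[full] = parsed.dt.year.astype("Int32")
        bad_cal = full & date.isna()  # e.g. 20210230
        if bad_cal.any():
            logger.warning("%d date value(s) are not valid calendar dates; set missing",
                           int(bad_cal.sum()))
            year.loc[bad_cal] = pd.NA
    if ym.any():
        parsed = pd.to_datetime(s[ym] + "15", format="%Y%m%d", errors="coerce")
        date.loc[ym] = parsed
        imputed.loc[ym] = parsed.notna()
        year.loc[ym] = parsed.dt.year.astype("Int32")
    if y_only.any():
        year.loc[y_only] = s[y_only].astype(int)

    junk = s.notna() & ~(full | ym | y_only)
    if junk.any():
        logger.warning("%d unparseable date value(s) set to missing (e.g. %r)",
                       int(junk.sum()), s[junk].iloc[0])
    return pd.DataFrame({"date": date, "imputed": imputed, "year": year})


def normalize_age(age: float | None, age_cod: str | None) -> float:
    """Convert a reported age to years.

    Years pass through, decades are multiplied by 10, months divided by 12,
    days by 365.25. A missing unit with a plausible value (0-120) is assumed
    to be years (the dominant FAERS convention), with a warning. Unknown
    units and negative ages yield NaN.
    """
    if age is None or (isinstance(age, float) and np.isnan(age)):
        return float("nan")
    if age < 0:
        logger.warning("negative age %r set to missing", age)
        return float("nan")
    unit = (age_cod or "").strip().upper()
    if unit in AGE_UNIT_FACTORS:
        return float(age) * AGE_UNIT_FACTORS[unit]
    if unit == "":
        if 0 <= age <= 120:
            logger.warning("age %r has no unit; assumed years", age)
            return float(age)
        return float("nan")
    return float("nan")


def normalize_age_series(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    """Vectorized :func:`normalize_age` over aligned series."""
    a = pd.to_numeric(age, errors="coerce")
    unit = age_cod.astype("string").str.strip().str.upper().fillna("")
    factor = unit.map(AGE_UNIT_FACTORS).astype(float)
    out = a * factor
    assumed = unit.eq("") & a.between(0, 120)
    if assumed.any():
        logger.warning("%d age(s) with no unit assumed to be years", int(assumed.sum()))
        out[assumed] = a[assumed]
    negative = a < 0
    if negative.any():
        logger.warning("%d negative age(s) set to missing", int(negative.sum()))
        out[negative] = np.nan
    return out.astype(float)


def normalize_weight(wt: float | None, wt_cod: str | None) -> float:
    """Convert a reported weight to kilograms (kg unchanged, lbs converted)."""
    if wt is None or (isinstance(wt, float) and np.isnan(wt)):
        return float("nan")
    if wt < 0:
        logger.warning("negative weight %r set to missing", wt)
        return float("nan")
    unit = (wt_cod or "").strip().upper()
    if unit == "KG":
        return float(wt)
    if unit == "LBS":
        return float(wt) * LBS_TO_KG
    return float("nan")


def normalize_weight_series(wt: pd.Series, wt_cod: pd.Series) -> pd.Series:
    """Vectorized :func:`normalize_weight` over aligned series."""
    w = pd.to_numeric(wt, errors="coerce")
    unit = wt_cod.astype("string").str.strip().str.upper().fillna("")
    factor = unit.map({"KG": 1.0, "LBS": LBS_TO_KG}).astype(float)
    out = w * factor
    negative = w < 0
    if negative.any():
        logger.warning("%d negative weight(s) set to missing", int(negative.sum()))
        out[negative] = np.nan
    return out.astype(float)


def _table_path(directory: Path, table: str, quarter_label: str) -> Path:
    return directory / f"{table.upper()}{quarter_label}.txt"


def _deleted_path(directory: Path, quarter_label: str) -> Path:
    return directory / f"DELETED{quarter_label}.txt"


def _read_table(path: Path, table: str, strict: bool) -> pd.DataFrame:
    expected = TABLE_COLUMNS[table]
    if not path.exists():
        raise FileNotFoundError(f"mandatory table file missing: {path}")
    with open(path, encoding="latin-1", errors="replace") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
    cols = [c.strip().lower() for c in header.split("$")]
    if cols[: len(expected)] != expected:
        raise FaersFormatError(
            f"{path} line 1: malformed header {cols!r}, expected {expected!r}")
    if len(cols) > len(expected):
        msg = f"{path}: {len(cols) - len(expected)} unexpected extra column(s)"
        if strict:
            raise FaersFormatError(msg)
        logger.warning("%s; ignored", msg)

    df = pd.read_csv(path, sep="$", dtype=str, encoding="latin-1",
                     encoding_errors="replace", keep_default_na=False,
                     engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    df = df[expected]
    df = df.where(df != "", other=np.nan)

    for col in INT_COLUMNS.get(table, []):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    for col in FLOAT_COLUMNS.get(table, []):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in DATE_COLUMNS.get(table, []):
        parsed = parse_faers_dates(df[col])
        df[col] = parsed["date"]
        df[f"{col}_imputed"] = parsed["imputed"]
        df[f"{col}_year"] = parsed["year"]
    return df


def read_quarter(directory_path: str | Path, quarter_label: str,
                 strict: bool = False) -> RawQuarter:
    """Read one quarterly package from a directory.

    Missing mandatory table files raise :class:`FileNotFoundError`; a
    malformed header raises :class:`FaersFormatError` with the file and
    line. The deleted-case list is optional (absent before 2019Q1).
    Satellite rows whose PRIMARYID does not appear in DEMO are dropped
    with a warning so referential integrity holds on the result.
    """
    parse_quarter_label(quarter_label)
    directory = Path(directory_path)
    tables = {t: _read_table(_table_path(directory, t, quarter_label), t, strict)
              for t in TABLE_COLUMNS}

    known = set(tables["demo"]["primaryid"].dropna().astype(int))
    for name in ("drug", "reac", "indi", "outc", "ther"):
        df = tables[name]
        mask = df["primaryid"].isin(known)
        if (~mask).any():
            logger.warning("%s%s: dropped %d orphan row(s) with PRIMARYID not in DEMO",
                           name.upper(), quarter_label, int((~mask).sum()))
            tables[name] = df[mask].reset_index(drop=True)

    deleted: set[int] = set()
    dpath = _deleted_path(directory, quarter_label)
    if dpath.exists():
        for line in dpath.read_text(encoding="latin-1").splitlines():
            line = line.strip()
            if line:
                deleted.add(int(line))

    quarter = RawQuarter(quarter_label=quarter_label, deleted_case_ids=deleted,
                         **tables)
    logger.info("loaded %s: %s", quarter_label, quarter.manifest)
    return quarter


def _format_dates(df: pd.DataFrame, col: str) -> pd.Series:
    """Serialize a (date, imputed, year) triple back to FAERS strings."""
    out = pd.Series("", index=df.index, dtype=object)
    date = df[col]
    imputed = df.get(f"{col}_imputed", pd.Series(False, index=df.index))
    year = df.get(f"{col}_year", pd.Series(pd.NA, index=df.index, dtype="Int32"))
    has_date = date.notna()
    out[has_date & ~imputed] = date[has_date & ~imputed].dt.strftime("%Y%m%d")
    out[has_date & imputed] = date[has_date & imputed].dt.strftime("%Y%m")
    year_only = ~has_date & year.notna()
    out[year_only] = year[year_only].astype(int).astype(str)
    return out


def _format_value(v) -> str:
    if pd.isna(v):
        return ""
    if isinstance(v, (float, np.floating)):
        return f"{v:g}"
    return str(v)


def write_quarter(quarter: RawQuarter, directory_path: str | Path) -> list[Path]:
    """Write a quarter back to the $-delimited dialect.

    Inverse of :func:`read_quarter`: re-reading the written directory
    reproduces the quarter field-for-field, including partial-date
    precision and missingness. Returns the written file paths.
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for table, cols in TABLE_COLUMNS.items():
        df = getattr(quarter, table).copy()
        for col in DATE_COLUMNS.get(table, []):
            if col in df.columns and len(df):
                df[col] = _format_dates(df, col)
        path = _table_path(directory, table, quarter.quarter_label)
        with open(path, "w", encoding="latin-1", errors="replace", newline="\n") as fh:
            fh.write("$".join(cols) + "\n")
            for row in df[cols].itertuples(index=False):
                fh.write("$".join(_format_value(v) for v in row) + "\n")
        written.append(path)
    if quarter.deleted_case_ids:
        path = _deleted_path(directory, quarter.quarter_label)
        path.write_text("\n".join(str(i) for i in sorted(quarter.deleted_case_ids)) + "\n",
                        encoding="latin-1")
        written.append(path)
    return written


def combine_quarters(quarters: list[RawQuarter]) -> dict[str, object]:
    """Concatenate quarters into one corpus.

    Returns a dict of the six concatenated tables plus ``deleted_case_ids``
    (the union across quarters — a case deleted in any quarter is deleted).
    """
    if not quarters:
        raise ValueError("no quarters to combine")
    corpus: dict[str, object] = {}
    for name in TABLE_COLUMNS:
        corpus[name] = pd.concat([getattr(q, name) for q in quarters],
                                 ignore_index=True)
    corpus["deleted_case_ids"] = set().union(*(q.deleted_case_ids for q in quarters))
    return corpus
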