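"""Reader/writer for FAERS-dialect quarterly ASCII tables.

The FDA Adverse Event Reporting System distributes each quarter as a set of
dollar-sign-delimited text tables (DEMO, DRUG, REAC, INDI, THER, ...) with a
single header row and no quoting.  This module loads the five tables the
disproportionality pipeline needs into a :class:`QuarterDataset` of pandas
DataFrames, applying light validation:

* rows with the wrong number of fields are skipped and counted;
* rows in DRUG/REAC/INDI/THER whose ``primaryid`` does not appear in DEMO are
  excluded as *orphans* and counted;
* unknown columns are preserved untouched.

Only the modern (primaryid-keyed, 2012Q4+) layout is supported; the legacy
ISR-keyed layout is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger(__name__)

DELIMITER = "$"

#: canonical (lower-case) column names per table; extra columns are preserved.
TABLE_COLUMNS: dict[str, list[str]] = {
    "demo": [
        "primaryid",
        "caseid",
        "fda_dt",
        "event_dt",
        "age",
        "age_cod",
        "sex",
        "occp_cod",
        "reporter_country",
    ],
    "drug": ["primaryid", "drug_seq", "role_cod", "drugname"],
    "reac": ["primaryid", "pt"],
    "indi": ["primaryid", "indi_drug_seq", "indi_pt"],
    "ther": ["primaryid", "dsg_drug_seq", "start_dt"],
}

#: columns that must be present for the table to be usable at all.
MANDATORY_COLUMNS: dict[str, list[str]] = {
    "demo": ["primaryid", "caseid"],
    "drug": ["primaryid"],
    "reac": ["primaryid"],
    "indi": ["primaryid"],
    "ther": ["primaryid"],
}

TABLE_NAMES = tuple(TABLE_COLUMNS)

#: multiplicative factors decoding FAERS age units to years.
AGE_UNIT_TO_YEARS: dict[str, float] = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.14,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


# ---------------------------------------------------------------------------
# dates


@dataclass(frozen=True)
class FaersDate:
    """A possibly partial FAERS date (``YYYYMMDD``, ``YYYYMM``, ``YYYY`` or empty).

    ``precision`` is one of ``"day"``, ``"month"``, ``"year"``, ``"missing"``.
    """

    year: int | None = None
    month: int | None = None
    day: int | None = None

    @property
    def precision(self) -> str:
        if self.year is None:
            return "missing"
        if self.month is None:
            return "year"
        if self.day is None:
            return "month"
        return "day"

    @property
    def is_full(self) -> bool:
        return self.precision == "day"

    def to_date(self) -> date | None:
        """Calendar date for full-precision values, else ``None``."""
        if not self.is_full:
            return None
        return date(self.year, self.month, self.day)  # type: ignore[arg-type]


def parse_faers_date(raw: object) -> FaersDate:
    """Parse a FAERS date string; total — invalid input maps to missing.

    Length-8 strings are full dates, length-6 year-month partials, length-4
    year partials, anything else (including calendar-invalid values such as
    ``20230230``) is missing with a logged warning.
    """
    if raw is None:
        return FaersDate()
    s = str(raw).strip()
    if s in ("", "nan", "<NA>", "None"):
        return FaersDate()
    if not s.isdigit() or len(s) not in (4, 6, 8):
        log.warning("unparseable date %r treated as missing", raw)
        return FaersDate()
    year = int(s[:4])
    if len(s) == 4:
        return FaersDate(year=year)
    month = int(s[4:6])
    if not 1 <= month <= 12:
        log.warning("invalid calendar month in date %r treated as missing", raw)
        return FaersDate()
    if len(s) == 6:
        return FaersDate(year=year, month=month)
    day = int(s[6:8])
    try:
        date(year, month, day)
    except ValueError:
        log.warning("invalid calendar day in date %r treated as missing", raw)
        return FaersDate()
    return FaersDate(year=year, month=month, day=day)


def date_sort_key(raw: object) -> str:
    """Chronological sort key for possibly-partial date strings.

    Missing/invalid dates sort before every real date (an undated report
    version never beats a dated one during deduplication); partial dates are
    zero-padded to 8 digits.
    """
    d = parse_faers_date(raw)
    if d.precision == "missing":
        return "00000000"
    return f"{d.year:04d}{d.month or 0:02d}{d.day or 0:02d}"


def age_to_years(age: object, age_cod: object) -> float:
    """Decode an (age, unit-code) pair to years; NaN when undecodable.

    A present age with a missing unit code is assumed to already be in years
    (logged); an unknown unit code yields NaN.
    """
    try:
        value = float(age)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return float("nan")
    if value != value:  # NaN
        return float("nan")
    code = str(age_cod).strip().upper() if age_cod is not None else ""
    if code in ("", "NAN", "<NA>", "NONE"):
        log.warning("age %s without unit code: assuming years", value)
        return value
    factor = AGE_UNIT_TO_YEARS.get(code)
    if factor is None:
        log.warning("unknown age unit %r: age treated as missing", age_cod)
        return float("nan")
    return value * factor


# ---------------------------------------------------------------------------
# dataset container


@dataclass
class TableCounts:
    """Row accounting for one table: read = kept + skipped + orphans."""

    read: int = 0
    kept: int = 0
    skipped: int = 0
    orphans: int = 0


@dataclass
class QuarterDataset:
    """The five FAERS tables of one or more quarters as pandas DataFrames.

    Column names are lower-case; every ``primaryid`` occurring in the child
    tables is guaranteed to exist in ``demo``.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    indi: pd.DataFrame
    ther: pd.DataFrame
    provenance: dict[str, list[str]] = field(default_factory=dict)
    counts: dict[str, TableCounts] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    def validate(self) -> None:
        if self.demo["primaryid"].duplicated().any():
            raise ValueError("duplicate primaryid in demo table")
        if (self.demo["caseid"].astype(str).str.strip() == "").any():
            raise ValueError("empty caseid in demo table")
        ids = set(self.demo["primaryid"])
        for name in ("drug", "reac", "indi", "ther"):
            tab = self.table(name)
            if len(tab) and not set(tab["primaryid"]).issubset(ids):
                raise ValueError(f"orphan primaryid in {name} table")


def _empty_frame(name: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=str) for c in TABLE_COLUMNS[name]})


def _read_table(path: Path, name: str) -> tuple[pd.DataFrame, TableCounts]:
    counts = TableCounts()
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\r\n")
        if not header_line:
            raise ValueError(f"{path}: empty file (no header row)")
        columns = [c.strip().lower() for c in header_line.split(DELIMITER)]
        for col in MANDATORY_COLUMNS[name]:
            if col not in columns:
                raise ValueError(f"{path}: mandatory column {col!r} missing from {name} table")
        ncol = len(columns)
        rows: list[list[str]] = []
        for line in fh:
            line = line.rstrip("\r\n")
            if line == "":
                continue
            fields = line.split(DELIMITER)
            counts.read += 1
            if len(fields) != ncol:
                counts.skipped += 1
                continue
            rows.append(fields)
    frame = pd.DataFrame(rows, columns=columns, dtype=str)
    for col in TABLE_COLUMNS[name]:
        if col not in frame.columns:
            frame[col] = ""
    counts.kept = len(frame)
    return frame, counts


def read_quarter(paths: Mapping[str, str | Path] | str | Path) -> QuarterDataset:
    """Load one quarter's DEMO/DRUG/REAC/INDI/THER files.

    ``paths`` is either a mapping from table name to file path or a directory
    containing files named ``demo.txt`` ... ``ther.txt`` (case-insensitive).
    Child-table rows whose ``primaryid`` is absent from DEMO are excluded and
    counted as orphans.
    """
    if isinstance(paths, (str, Path)):
        root = Path(paths)
        resolved: dict[str, Path] = {}
        for name in TABLE_NAMES:
            matches = [p for p in root.iterdir() if p.name.lower() == f"{name}.txt"]
            if not matches:
                raise FileNotFoundError(f"{root}: no {name}.txt file")
            resolved[name] = matches[0]
    else:
        resolved = {name: Path(p) for name, p in paths.items()}
        for name in TABLE_NAMES:
            if name not in resolved:
                raise FileNotFoundError(f"no path given for {name} table")

    frames: dict[str, pd.DataFrame] = {}
    counts: dict[str, TableCounts] = {}
    for name in TABLE_NAMES:
        frames[name], counts[name] = _read_table(resolved[name], name)

    demo = frames["demo"]
    if demo["primaryid"].duplicated().any():
        raise ValueError(f"{resolved['demo']}: duplicate primaryid values in demo table")
    known = set(demo["primaryid"])
    for name in ("drug", "reac", "indi", "ther"):
        tab = frames[name]
        mask = tab["primaryid"].isin(known)
        counts[name].orphans = int((~mask).sum())
        counts[name].kept = int(mask.sum())
        frames[name] = tab[mask].reset_index(drop=True)

    for name in TABLE_NAMES:
        c = counts[name]
        log.info(
            "read table=%s file=%s rows_read=%d rows_kept=%d rows_skipped=%d orphans=%d",
            name, resolved[name], c.read, c.kept, c.skipped, c.orphans,
        )

    return QuarterDataset(
        demo=frames["demo"],
        drug=frames["drug"],
        reac=frames["reac"],
        indi=frames["indi"],
        ther=frames["ther"],
        provenance={name: [str(resolved[name])] for name in TABLE_NAMES},
        counts=counts,
    )


def write_quarter(dataset: QuarterDataset, out: Mapping[str, str | Path] | str | Path) -> dict[str, Path]:
    """Write a dataset back to FAERS-dialect files (inverse of :func:`read_quarter`).

    The dialect has no quoting, so any literal ``$`` inside a field is
    stripped on write; apart from that, read(write(d)) == d field-for-field.
    """
    if isinstance(out, (str, Path)):
        root = Path(out)
        root.mkdir(parents=True, exist_ok=True)
        resolved = {name: root / f"{name}.txt" for name in TABLE_NAMES}
    else:
        resolved = {name: Path(p) for name, p in out.items()}

    for name in TABLE_NAMES:
        frame = dataset.table(name)
        cols = list(frame.columns)
        with open(resolved[name], "w", encoding="utf-8") as fh:
            fh.write(DELIMITER.join(cols) + "\n")
            if len(frame):
                body = frame.astype(str).replace({"nan": "", "<NA>": "", "None": ""})
                for row in body.itertuples(index=False):
                    fh.write(DELIMITER.join(v.replace(DELIMITER, "") for v in row) + "\n")
        log.info("wrote table=%s file=%s rows=%d", name, resolved[name], len(frame))
    return resolved


def concat_quarters(datasets: Iterable[QuarterDataset]) -> QuarterDataset:
    """Concatenate several quarters into one dataset.

    A ``primaryid`` occurring in more than one quarter (a resubmitted report
    version) keeps only its last occurrence; the per-case version choice is
    the deduplication step's job, this merely restores primaryid uniqueness.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no datasets to concatenate")
    frames = {name: pd.concat([d.table(name) for d in datasets], ignore_index=True) for name in TABLE_NAMES}
    demo = frames["demo"]
    dup = demo["primaryid"].duplicated(keep="last")
    if dup.any():
        log.info("concat: dropped %d repeated primaryid rows from demo", int(dup.sum()))
        frames["demo"] = demo[~dup].reset_index(drop=True)
        for name in ("drug", "reac", "indi", "ther"):
            frames[name] = frames[name].drop_duplicates().reset_index(drop=True)
    provenance: dict[str, list[str]] = {name: [] for name in TABLE_NAMES}
    for d in datasets:
        for name in TABLE_NAMES:
            provenance[name].extend(d.provenance.get(name, []))
    return QuarterDataset(provenance=provenance, **frames)
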