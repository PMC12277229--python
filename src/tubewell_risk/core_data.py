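"""Domain types, guideline registry, validation and tabular I/O.

The package models school tubewell water records from a four-union study
area (Bagoan, Dariapur, Mohajanpur, Monakhali): location, tubewell depth,
field physicochemistry (pH, EC, TDS, temperature, salinity) and the two
analytes of health concern, iron and arsenic.  Concentrations come from
field kits with hard instrument ranges: an iron colorimeter reading
0.00-5.00 mg/L at 0.01 mg/L resolution, and a dual-range arsenic test kit
whose primary range is 0.00-0.5 mg/L.  Those ranges are enforced as type
invariants here so every downstream stage can assume physically readable
values.

Guideline limits (WHO, US EPA and the Bangladesh Drinking Water Standard)
ship as a structured registry; exceedance semantics are explicit per rule
(one-sided upper bound vs. acceptable range).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "UNIONS",
    "UNION_ALIASES",
    "FE_KIT_MAX",
    "AS_KIT_MAX",
    "AS_EXTENDED_MAX",
    "COLUMNS",
    "WaterSample",
    "GuidelineRule",
    "Dataset",
    "ValidationIssue",
    "ValidationReport",
    "LoadError",
    "load_guidelines",
    "load_samples",
    "write_samples",
    "validate_dataset",
    "export_geojson",
]

# ---------------------------------------------------------------------------
# Constants

UNIONS: tuple[str, ...] = ("Bagoan", "Dariapur", "Mohajanpur", "Monakhali")

# Union names appear under variant spellings in field records; canonical
# spelling is applied on load.
UNION_ALIASES: dict[str, str] = {
    "Baguan": "Bagoan",
    "Moahajanpur": "Mohajanpur",
    "Mahajanpur": "Mohajanpur",
}

FE_KIT_MAX = 5.00   # mg/L, iron colorimeter full scale
AS_KIT_MAX = 0.5    # mg/L, arsenic kit primary detection range
# The arsenic tester's extended scale runs to 5 mg/L; readings in
# (0.5, 5] are flagged as suspect rather than rejected.
AS_EXTENDED_MAX = 5.0

#: Canonical column order for the tabular representation.
COLUMNS: tuple[str, ...] = (
    "sample_id", "school", "union", "longitude", "latitude", "depth",
    "ph", "ec", "tds", "temperature", "salinity", "fe", "as",
)

_NUMERIC_COLUMNS = COLUMNS[3:]
_OPTIONAL_COLUMNS = frozenset({"longitude", "latitude", "temperature", "salinity", "school"})

# Accepted header aliases (lower-cased) -> canonical column name.
_COLUMN_ALIASES: dict[str, str] = {
    "sample_id": "sample_id", "id": "sample_id", "sample": "sample_id",
    "school": "school", "school_name": "school",
    "union": "union", "union_name": "union",
    "longitude": "longitude", "lon": "longitude", "long": "longitude",
    "latitude": "latitude", "lat": "latitude",
    "depth": "depth", "depth_ft": "depth", "depth_feet": "depth",
    "ph": "ph",
    "ec": "ec", "ec_uscm": "ec", "conductivity": "ec",
    "tds": "tds", "tds_mgl": "tds",
    "temperature": "temperature", "temp": "temperature", "temperature_c": "temperature",
    "salinity": "salinity", "sal": "salinity",
    "fe": "fe", "iron": "fe", "fe_mgl": "fe",
    "as": "as", "arsenic": "as", "as_conc": "as", "as_mgl": "as",
}


# ---------------------------------------------------------------------------
# Domain types

@dataclass(frozen=True)
class WaterSample:
    """One school tubewell record.

    Concentrations are mg/L; depth is feet; EC is µS/cm; coordinates are
    WGS84 decimal degrees (may be NaN when not recorded).
    """

    sample_id: str
    school: str
    union: str
    longitude: float
    latitude: float
    depth: float
    ph: float
    ec: float
    tds: float
    temperature: float
    salinity: float
    fe: float
    as_conc: float

    def invariant_violations(self) -> list[str]:
        """Hard invariant violations (reasons to reject the record)."""
        bad: list[str] = []
        if self.union not in UNIONS:
            bad.append(f"union {self.union!r} not one of {UNIONS}")
        if not (self.depth > 0):
            bad.append(f"depth {self.depth} must be > 0")
        if not (0 <= self.ph <= 14):
            bad.append(f"ph {self.ph} out of [0, 14]")
        if not (self.ec >= 0):
            bad.append(f"ec {self.ec} must be >= 0")
        if not (self.tds >= 0):
            bad.append(f"tds {self.tds} must be >= 0")
        if not (0 <= self.fe <= FE_KIT_MAX):
            bad.append(f"fe {self.fe} out of colorimeter range [0, {FE_KIT_MAX}]")
        if not (0 <= self.as_conc <= AS_EXTENDED_MAX):
            bad.append(f"as {self.as_conc} out of [0, {AS_EXTENDED_MAX}]")
        return bad

    def invariant_flags(self) -> list[str]:
        """Soft warnings (record kept, value suspect)."""
        if AS_KIT_MAX < self.as_conc <= AS_EXTENDED_MAX:
            return [
                f"as {self.as_conc} above primary kit range {AS_KIT_MAX} "
                f"(extended-scale reading, flagged)"
            ]
        return []


@dataclass(frozen=True)
class GuidelineRule:
    """One (authority, parameter) drinking-water limit.

    ``exceed_mode`` fixes the exceedance semantics: ``above_upper`` counts a
    sample only when the value is strictly above ``upper``; ``outside_range``
    counts values below ``lower`` or above ``upper``.
    """

    authority: str            # WHO | USEPA | BDWS
    parameter: str            # ph | ec | tds | fe | as
    lower: float | None
    upper: float | None
    exceed_mode: str          # above_upper | outside_range

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise ValueError("rule needs at least one of lower/upper")
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError("lower > upper")
        if self.exceed_mode not in ("above_upper", "outside_range"):
            raise ValueError(f"unknown exceed_mode {self.exceed_mode!r}")

    def exceeded_by(self, value: float) -> bool:
        """True iff ``value`` violates this rule (NaN is never an exceedance)."""
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return False
        if self.exceed_mode == "above_upper":
            return value > self.upper
        return (self.lower is not None and value < self.lower) or (
            self.upper is not None and value > self.upper
        )


@dataclass
class Dataset:
    """Ordered collection of tubewell records with provenance.

    ``df`` carries the canonical tabular form (columns :data:`COLUMNS`);
    missing optional fields are NaN, never zero.  ``rejected`` holds
    row-indexed diagnostics for records dropped on load.
    """

    df: pd.DataFrame
    provenance: str = ""
    rejected: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"Dataset frame missing columns: {missing}")
        self.df = self.df.loc[:, list(COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[WaterSample]:
        out = []
        for row in self.df.itertuples(index=False):
            d = dict(zip(COLUMNS, row))
            d["as_conc"] = d.pop("as")
            out.append(WaterSample(**d))
        return out

    @classmethod
    def from_samples(cls, samples: Iterable[WaterSample], provenance: str = "") -> "Dataset":
        rows = []
        for s in samples:
            d = {c: getattr(s, c) for c in COLUMNS if c != "as"}
            d["as"] = s.as_conc
            rows.append(d)
        df = pd.DataFrame(rows, columns=list(COLUMNS))
        return cls(df=df, provenance=provenance)


# ---------------------------------------------------------------------------
# Guideline registry

def load_guidelines(path: str | Path | None = None) -> list[GuidelineRule]:
    """Load the guideline registry (packaged WHO/USEPA/BDWS table by default)."""
    if path is None:
        text = resources.files("tubewell_risk").joinpath("data/guidelines.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return [
        GuidelineRule(
            authority=r["authority"],
            parameter=r["parameter"],
            lower=r.get("lower"),
            upper=r.get("upper"),
            exceed_mode=r["exceed_mode"],
        )
        for r in raw
    ]


# ---------------------------------------------------------------------------
# Tabular I/O

class LoadError(ValueError):
    """Structural problem in an input table (bad header, value or label)."""


def _canon_header(names: Sequence[str], extra_aliases: Mapping[str, str] | None) -> dict[str, str]:
    table = dict(_COLUMN_ALIASES)
    if extra_aliases:
        table.update({k.lower(): v for k, v in extra_aliases.items()})
    out: dict[str, str] = {}
    for name in names:
        key = name.strip().lower()
        if key in table:
            out[name] = table[key]
    return out


def load_samples(
    path: str | Path,
    *,
    delimiter: str = ",",
    union_aliases: Mapping[str, str] | None = None,
    column_aliases: Mapping[str, str] | None = None,
) -> Dataset:
    """Read a delimited sample table into a :class:`Dataset`.

    Header names are matched case-insensitively with configurable aliases.
    Rows violating hard type invariants are rejected with row-indexed
    diagnostics (kept on ``Dataset.rejected``); structurally unparseable
    values (unknown union label, non-numeric concentration) raise
    :class:`LoadError` naming the row and column.  Missing optional fields
    become NaN, never zeros.
    """
    path = Path(path)
    if not path.is_file():
        raise LoadError(f"no such file: {path}")
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    rename = _canon_header(list(df.columns), column_aliases)
    df = df.rename(columns=rename)
    required = set(COLUMNS) - _OPTIONAL_COLUMNS
    missing = sorted(required - set(df.columns))
    if missing:
        raise LoadError(f"header missing required columns: {missing}")
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = ""

    aliases = dict(UNION_ALIASES)
    if union_aliases:
        aliases.update(union_aliases)

    kept: list[dict] = []
    rejected: list[str] = []
    flags: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        rec: dict = dict(zip(df.columns, row))
        union = rec["union"].strip()
        union = aliases.get(union, union)
        if union not in UNIONS:
            raise LoadError(f"row {i}: unknown union label {rec['union']!r}")
        parsed: dict = {"sample_id": rec["sample_id"].strip(),
                        "school": rec["school"].strip(), "union": union}
        for col in _NUMERIC_COLUMNS:
            text = str(rec[col]).strip()
            if text == "":
                if col in _OPTIONAL_COLUMNS:
                    parsed[col] = float("nan")
                    continue
                raise LoadError(f"row {i}, column {col!r}: required value missing")
            try:
                parsed[col] = float(text)
            except ValueError:
                raise LoadError(f"row {i}, column {col!r}: non-numeric value {text!r}") from None
        sample = WaterSample(**{("as_conc" if k == "as" else k): v for k, v in parsed.items()})
        bad = sample.invariant_violations()
        if bad:
            rejected.append(f"row {i} (sample_id={sample.sample_id!r}): " + "; ".join(bad))
            continue
        for w in sample.invariant_flags():
            flags.append(f"row {i} (sample_id={sample.sample_id!r}): {w}")
        kept.append(parsed)

    out = pd.DataFrame(kept, columns=list(COLUMNS)) if kept else pd.DataFrame(
        {c: pd.Series(dtype=(object if c in ("sample_id", "school", "union") else float))
         for c in COLUMNS})
    return Dataset(df=out, provenance=str(path), rejected=tuple(rejected), flags=tuple(flags))


def write_samples(dataset: Dataset, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a Dataset back to delimited text (empty cells for missing)."""
    df = dataset.df.copy()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(COLUMNS)
        for row in df.itertuples(index=False):
            out = []
            for col, v in zip(COLUMNS, row):
                if isinstance(v, float) and math.isnan(v):
                    out.append("")
                elif isinstance(v, float):
                    out.append(repr(v))
                else:
                    out.append(str(v))
            writer.writerow(out)


# ---------------------------------------------------------------------------
# Validation

@dataclass(frozen=True)
class ValidationIssue:
    row: int | None           # 0-based row index in Dataset.df, None for dataset-level
    field: str
    message: str


@dataclass
class ValidationReport:
    n: int
    issues: list[ValidationIssue] = field(default_factory=list)
    missing_counts: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.issues

    @property
    def empty(self) -> bool:
        return self.n == 0


def validate_dataset(dataset: Dataset) -> ValidationReport:
    """Pure invariant audit: per-field violations, duplicate ids, missing counts."""
    df = dataset.df
    report = ValidationReport(n=len(df))
    if len(df) == 0:
        return report

    dupes = df["sample_id"][df["sample_id"].duplicated()].unique()
    for d in dupes:
        report.issues.append(ValidationIssue(None, "sample_id", f"duplicate id {d!r}"))

    for i, sample in enumerate(dataset.samples):
        for msg in sample.invariant_violations():
            fieldname = msg.split()[0]
            report.issues.append(ValidationIssue(i, fieldname, msg))

    for col in _NUMERIC_COLUMNS:
        report.missing_counts[col] = int(df[col].isna().sum())
    return report


# ---------------------------------------------------------------------------
# GeoJSON export

def export_geojson(
    df: pd.DataFrame,
    path: str | Path,
    *,
    lon_col: str = "longitude",
    lat_col: str = "latitude",
) -> None:
    """Write point features (WGS84 lon/lat order) with all other columns as
    properties; rows without coordinates are skipped."""
    features = []
    prop_cols = [c for c in df.columns if c not in (lon_col, lat_col)]
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        lon, lat = rec.get(lon_col), rec.get(lat_col)
        if lon is None or lat is None or (isinstance(lon, float) and math.isnan(lon)) \
                or (isinstance(lat, float) and math.isnan(lat)):
            continue
        props = {}
        for c in prop_cols:
            v = rec[c]
            if isinstance(v, float) and math.isnan(v):
                v = None
            elif isinstance(v, (np.floating, np.integer)):
                v = v.item()
            elif isinstance(v, float) and math.isinf(v):
                v = None
            props[c] = v
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(lon), float(lat)]},
            "properties": props,
        })
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
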