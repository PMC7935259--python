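"""Reading, validating, cleaning and filtering sampling-inspection records.

A record is one sampled food item with a qualification status (qualified or
substandard) and the free-text addresses of its manufacturer and distributor.
Cleaning removes records that cannot be placed on a circulation route
(missing either party's address) and collapses exact duplicates; the
downstream networks are built from the substandard subset only, while
qualified totals are kept for circulation-intensity denominators.
"""

from __future__ import annotations

import datetime as _dt
import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

QUALIFIED = "qualified"
SUBSTANDARD = "substandard"

#: canonical column order for cleaned-record CSV output
CANONICAL_COLUMNS = [
    "record_id",
    "status",
    "manufacturer_address",
    "distributor_address",
    "food_name",
    "sample_date",
]

# accepted spellings for the two status values (Chinese source data uses
# 合格 / 不合格); matching is case-insensitive after normalization
_STATUS_ALIASES = {
    "qualified": QUALIFIED,
    "pass": QUALIFIED,
    "合格": QUALIFIED,
    "substandard": SUBSTANDARD,
    "unqualified": SUBSTANDARD,
    "fail": SUBSTANDARD,
    "不合格": SUBSTANDARD,
}


def normalize_text(value) -> str:
    """NFKC-normalize (full-width → half-width) and collapse whitespace.

    Returns "" for missing values, so emptiness checks see blank and absent
    addresses the same way.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    text = unicodedata.normalize("NFKC", str(value))
    return " ".join(text.split())


class ConfigurationError(ValueError):
    """A column map or config names something the source does not have."""


@dataclass(frozen=True)
class InspectionRecord:
    """One sampled food item."""

    record_id: str
    status: str
    manufacturer_address: str
    distributor_address: str
    food_name: str | None = None
    sample_date: _dt.date | None = None

    def __post_init__(self):
        if self.status not in (QUALIFIED, SUBSTANDARD):
            raise ValueError(f"status must be {QUALIFIED!r} or {SUBSTANDARD!r}, got {self.status!r}")


@dataclass
class RecordSet:
    """An ordered collection of inspection records with provenance.

    Internally a pandas DataFrame in canonical column order; `records`
    materialises `InspectionRecord` objects on demand. Operations never
    mutate their input RecordSet — each returns a new one.
    """

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in CANONICAL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"RecordSet frame missing columns: {missing}")
        self.frame = self.frame[CANONICAL_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def counts(self) -> dict:
        n_sub = int((self.frame["status"] == SUBSTANDARD).sum())
        total = len(self.frame)
        return {"total": total, "qualified": total - n_sub, "substandard": n_sub}

    @property
    def records(self) -> list[InspectionRecord]:
        out = []
        for row in self.frame.itertuples(index=False):
            out.append(
                InspectionRecord(
                    record_id=row.record_id,
                    status=row.status,
                    manufacturer_address=row.manufacturer_address,
                    distributor_address=row.distributor_address,
                    food_name=row.food_name if pd.notna(row.food_name) else None,
                    sample_date=row.sample_date if pd.notna(row.sample_date) else None,
                )
            )
        return out

    def copy(self) -> "RecordSet":
        return RecordSet(self.frame.copy(), dict(self.provenance))

    def to_csv(self, path) -> None:
        """Write records in the canonical column order (UTF-8 CSV)."""
        self.frame.to_csv(path, index=False)


def _parse_status(value) -> str | None:
    key = normalize_text(value).lower()
    return _STATUS_ALIASES.get(key)


def _parse_date(value):
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    ts = pd.to_datetime(value, errors="coerce")
    return None if pd.isna(ts) else ts.date()


def load_records(
    path,
    format_hint: str = "auto",
    column_map: Mapping[str, str] | None = None,
    encoding: str = "utf-8",
) -> RecordSet:
    """Load inspection records from a CSV or XLSX table.

    Parameters
    ----------
    path
        Source file. Must exist.
    format_hint
        One of ``csv``, ``xlsx``, ``auto`` (by extension). Legacy binary
        ``.xls`` is not supported; convert to ``.xlsx`` or CSV first.
    column_map
        Mapping of logical field name (``status``, ``manufacturer_address``,
        ``distributor_address``, optionally ``record_id``, ``food_name``,
        ``sample_date``) to the source column name. Defaults to identity.
    encoding
        Text encoding for CSV sources (legacy exports are often GBK).

    Rows whose status cannot be parsed are dropped and counted in
    ``provenance["coercion_failures"]``, never silently discarded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"record file not found: {path}")
    fmt = format_hint
    if fmt == "auto":
        suffix = path.suffix.lower().lstrip(".")
        fmt = suffix if suffix in ("csv", "xlsx", "xls") else "csv"
    if fmt == "xls":
        raise ConfigurationError(
            "legacy binary .xls is not supported; convert the table to .xlsx or CSV"
        )
    if fmt == "xlsx":
        raw = pd.read_excel(path, dtype=object)
    elif fmt == "csv":
        raw = pd.read_csv(path, dtype=object, encoding=encoding)
    else:
        raise ConfigurationError(f"unknown format hint {format_hint!r}")

    column_map = dict(column_map or {})
    required = ["status", "manufacturer_address", "distributor_address"]
    for logical in required:
        column_map.setdefault(logical, logical)
    missing = [src for src in column_map.values() if src not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"column_map names columns absent from {path.name}: {missing}; "
            f"available: {list(raw.columns)}"
        )

    n_raw = len(raw)
    statuses = raw[column_map["status"]].map(_parse_status)
    bad_status = statuses.isna()
    n_bad = int(bad_status.sum())
    if n_bad:
        logger.warning("dropped %d rows with unparseable status while loading %s", n_bad, path.name)
    kept = raw.loc[~bad_status]

    def _col(logical, default=None):
        src = column_map.get(logical)
        if src is not None and src in kept.columns:
            return kept[src]
        return pd.Series([default] * len(kept), index=kept.index, dtype=object)

    frame = pd.DataFrame(
        {
            "record_id": _col("record_id"),
            "status": statuses.loc[kept.index],
            "manufacturer_address": _col("manufacturer_address").map(normalize_text),
            "distributor_address": _col("distributor_address").map(normalize_text),
            "food_name": _col("food_name").map(lambda v: normalize_text(v) or None),
            "sample_date": _col("sample_date").map(_parse_date),
        }
    )
    if frame["record_id"].isna().all():
        frame["record_id"] = [f"R{i:07d}" for i in range(len(frame))]
    else:
        frame["record_id"] = frame["record_id"].map(normalize_text)

    provenance = {
        "source": str(path),
        "loaded_at": _dt.datetime.now().isoformat(timespec="seconds"),
        "rows_in_source": n_raw,
        "coercion_failures": n_bad,
    }
    rs = RecordSet(frame, provenance)
    logger.info("loaded %d records from %s (%d coercion failures)", len(rs), path.name, n_bad)
    return rs


def from_frame(frame: pd.DataFrame, provenance: dict | None = None) -> RecordSet:
    """Build a RecordSet from an in-memory DataFrame with canonical columns."""
    return RecordSet(frame.copy(), dict(provenance or {}))


def clean_records(rs: RecordSet) -> tuple[RecordSet, dict]:
    """Drop records missing either party's address; collapse exact duplicates.

    A duplicate is an exact match on the tuple (status, manufacturer_address,
    distributor_address, food_name, sample_date) after whitespace/width
    normalization; the first occurrence is kept. Returns the cleaned set and
    a report ``{"missing_party": n, "duplicates": n, "retained": n}``.
    Idempotent: cleaning a cleaned set removes nothing.
    """
    frame = rs.frame.copy()
    for col in ("manufacturer_address", "distributor_address"):
        frame[col] = frame[col].map(normalize_text)

    has_parties = (frame["manufacturer_address"] != "") & (frame["distributor_address"] != "")
    n_missing = int((~has_parties).sum())
    frame = frame.loc[has_parties]

    dup_key = ["status", "manufacturer_address", "distributor_address", "food_name", "sample_date"]
    dup_mask = frame.duplicated(subset=dup_key, keep="first")
    n_dup = int(dup_mask.sum())
    frame = frame.loc[~dup_mask]

    report = {"missing_party": n_missing, "duplicates": n_dup, "retained": len(frame)}
    if len(frame) == 0:
        logger.warning("cleaning removed every record (report: %s)", report)
    provenance = dict(rs.provenance)
    provenance["cleaning_report"] = report
    return RecordSet(frame.reset_index(drop=True), provenance), report


def filter_substandard(rs: RecordSet) -> RecordSet:
    """Keep substandard records only; preserve qualified totals in provenance.

    The circulation networks are built from substandard flows, but the
    qualified counts (overall and per distributor address) stay available
    for circulation-intensity denominators.
    """
    counts = rs.counts
    sub = rs.frame.loc[rs.frame["status"] == SUBSTANDARD]
    if len(sub) == 0:
        logger.warning("no substandard records present after filtering")
    provenance = dict(rs.provenance)
    provenance["qualified_total"] = counts["qualified"]
    provenance["prefilter_total"] = counts["total"]
    return RecordSet(sub.reset_index(drop=True), provenance)
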