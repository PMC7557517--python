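"""Record schema, CSV I/O, exclusion filtering, and the 9-to-4 location recode.

One row is one emergency-department visit for a nonfatal gunshot wound:
a free-text coder narrative, the survey design fields (year, hospital PSU,
stratum, case weight), demographics, intent, disposition, body part, and a
possibly-missing coded injury location.  Source data carry nine location
codes; analysis collapses them to four classes (home, street/highway,
other public place, other) because the rarer codes are individually too
sparse to predict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "MISSING"

#: Reporting order of the four analysis location classes; fixed everywhere
#: (argmax tie-breaks, confusion-matrix axes, output tables).
LOCATION_CLASSES: tuple[str, ...] = ("HOME", "STREET", "PUBLIC", "OTHER")
UNKNOWN = "UNKNOWN"

RAW_LOCATIONS: tuple[str, ...] = (
    "home", "apartment", "mobile_home", "farm", "street_highway",
    "other_public", "recreation", "industry", "school",
)

STRATA: tuple[str, ...] = ("small", "medium", "large", "very_large", "childrens")
SEXES: tuple[str, ...] = ("male", "female", "unknown")
RACES: tuple[str, ...] = ("white", "black", "other", "not_stated")
AGE_GROUPS: tuple[str, ...] = (
    "0-14", "15-24", "25-34", "35-44", "45-54", "55-64", "65+",
)
INTENTS: tuple[str, ...] = ("assault", "unintentional", "self_harm", "unknown")
DISPOSITIONS: tuple[str, ...] = (
    "treated_released", "transferred_released", "transferred_hospital",
    "hospitalized", "observation",
)
BODY_PARTS: tuple[str, ...] = (
    "head_neck", "upper_trunk", "lower_trunk", "arm_hand", "leg_foot", "other",
)

#: Default collapse of the nine source location codes onto the four
#: analysis classes.  Farm goes to OTHER (it is too rare to predict and has
#: no residential semantics); mobile home goes to HOME.  Both are
#: overridable through ``schema_config["recode"]``.
DEFAULT_RECODE: dict[str, str] = {
    "home": "HOME",
    "apartment": "HOME",
    "mobile_home": "HOME",
    "street_highway": "STREET",
    "other_public": "PUBLIC",
    "recreation": "OTHER",
    "industry": "OTHER",
    "school": "OTHER",
    "farm": "OTHER",
}

#: Mandatory CSV columns, in canonical order.
COLUMNS: tuple[str, ...] = (
    "record_id", "year", "hospital_id", "stratum", "weight", "narrative",
    "sex", "race", "age_group", "intent", "disposition", "body_part",
    "raw_location", "is_bb_or_nongsw",
)

_ENUM_DOMAINS = {
    "stratum": set(STRATA),
    "sex": set(SEXES),
    "race": set(RACES),
    "age_group": set(AGE_GROUPS),
    "intent": set(INTENTS),
    "disposition": set(DISPOSITIONS),
    "body_part": set(BODY_PARTS),
    "raw_location": set(RAW_LOCATIONS) | {MISSING},
}


class SchemaError(ValueError):
    """A mandatory column is absent or the file cannot be interpreted."""


class ValidationError(ValueError):
    """One or more rows violate record invariants; offending ids attached."""

    def __init__(self, message: str, record_ids: list[str]):
        super().__init__(message)
        self.record_ids = record_ids


@dataclass
class RecordSet:
    """An ordered collection of injury records backed by a DataFrame.

    Record ids are unique; ``provenance`` is a free-text label describing
    where the set came from (file path, generator config, filter step).
    """

    records: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.records["record_id"].duplicated().any():
            dupes = self.records.loc[
                self.records["record_id"].duplicated(), "record_id"
            ].tolist()
            raise ValidationError(f"duplicate record_ids: {dupes[:5]}", dupes)

    def __len__(self) -> int:
        return len(self.records)

    def copy(self, provenance: str | None = None) -> "RecordSet":
        return RecordSet(self.records.copy(), provenance or self.provenance)


def _validate_rows(df: pd.DataFrame) -> pd.Series:
    """Return a Series of per-row problem strings ('' where the row is fine)."""
    problems = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, msg: str) -> None:
        problems[mask] += msg + ";"

    flag(~(pd.to_numeric(df["weight"], errors="coerce") > 0), "non-positive weight")
    flag(pd.to_numeric(df["year"], errors="coerce").isna(), "non-integer year")
    narratives = df["narrative"].astype(str)
    flag(narratives.str.strip() == "", "empty narrative")
    flag(narratives.str.contains("\n"), "newline in narrative")
    for col, domain in _ENUM_DOMAINS.items():
        flag(~df[col].astype(str).isin(domain), f"invalid {col}")
    return problems


def read_records(
    path,
    schema_config: dict | None = None,
    on_invalid: str = "raise",
    error_report_path=None,
) -> RecordSet:
    """Read a record CSV into a :class:`RecordSet`.

    Parameters
    ----------
    path
        CSV file with a header row containing every column in
        :data:`COLUMNS` (extra columns are preserved).
    schema_config
        Optional overrides, e.g. ``{"columns": {...renames...}}``.
    on_invalid
        ``"raise"`` (default) aborts with a :class:`ValidationError`
        listing offending record ids; ``"collect"`` drops invalid rows into
        a sidecar error report (``error_report_path``, default
        ``<path>.rejects.csv``) and keeps going.
    """
    schema_config = schema_config or {}
    try:
        df = pd.read_csv(path, dtype={"record_id": str, "hospital_id": str},
                         float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"cannot parse {path}: {exc}") from exc

    renames = schema_config.get("columns", {})
    if renames:
        df = df.rename(columns=renames)
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing_cols)}")

    df["raw_location"] = df["raw_location"].fillna(MISSING).astype(str)
    problems = _validate_rows(df)
    bad = problems != ""
    if bad.any():
        bad_ids = df.loc[bad, "record_id"].astype(str).tolist()
        if on_invalid == "raise":
            detail = "; ".join(
                f"{rid}: {msg}" for rid, msg in
                zip(bad_ids[:10], problems[bad].head(10))
            )
            raise ValidationError(
                f"{bad.sum()} invalid row(s): {detail}", bad_ids
            )
        report = df.loc[bad].copy()
        report["problems"] = problems[bad]
        sidecar = error_report_path or f"{path}.rejects.csv"
        report.to_csv(sidecar, index=False)
        logger.warning("rejected %d rows; report at %s", bad.sum(), sidecar)
        df = df.loc[~bad].reset_index(drop=True)

    df["year"] = df["year"].astype(int)
    df["weight"] = df["weight"].astype(float)
    df["is_bb_or_nongsw"] = df["is_bb_or_nongsw"].astype(bool)
    return RecordSet(df[list(COLUMNS) + [c for c in df.columns if c not in COLUMNS]],
                     provenance=str(path))


def write_records(rs: RecordSet, path) -> None:
    """Write a RecordSet to CSV.

    Weights are written with ``repr`` precision so a read round-trip
    reproduces them bit-for-bit; narratives must not contain newlines
    (validated at read time).
    """
    df = rs.records.copy()
    df["weight"] = df["weight"].map(lambda v: repr(float(v)))
    df.to_csv(path, index=False)


def apply_exclusions(rs: RecordSet) -> RecordSet:
    """Drop BB-gun and non-gunshot records (``is_bb_or_nongsw`` flag)."""
    keep = ~rs.records["is_bb_or_nongsw"].astype(bool)
    n_excluded = int((~keep).sum())
    if n_excluded == len(rs):
        logger.warning("exclusion filter removed every record")
    logger.info("excluded %d of %d records (BB gun / non-GSW)", n_excluded, len(rs))
    return RecordSet(rs.records.loc[keep].reset_index(drop=True),
                     provenance=f"{rs.provenance} [excl {n_excluded}]")


def recode_location(raw_location: str, recode_map: dict[str, str] | None = None) -> str:
    """Collapse one source location code to a four-class label.

    MISSING passes through; an unrecognized code is an error rather than a
    silent OTHER bucket.
    """
    if raw_location == MISSING:
        return MISSING
    mapping = recode_map or DEFAULT_RECODE
    try:
        return mapping[raw_location]
    except KeyError:
        raise ValueError(f"unknown source location code: {raw_location!r}") from None


def recode_records(rs: RecordSet, recode_map: dict[str, str] | None = None) -> RecordSet:
    """Add a ``location4`` column holding the four-class recode (or MISSING)."""
    df = rs.records.copy()
    df["location4"] = [
        recode_location(v, recode_map) for v in df["raw_location"].astype(str)
    ]
    return RecordSet(df, provenance=rs.provenance)


def partition_by_missingness(rs: RecordSet) -> tuple[RecordSet, RecordSet]:
    """Split into (missing-location, nonmissing-location) record sets.

    The partition is disjoint and exhaustive; sizes always sum to the input
    size.  Requires :func:`recode_records` to have been applied.
    """
    if "location4" not in rs.records.columns:
        raise ValueError("recode_records must be applied before partitioning")
    is_missing = rs.records["location4"] == MISSING
    missing = RecordSet(rs.records.loc[is_missing].reset_index(drop=True),
                        provenance=f"{rs.provenance} [missing]")
    nonmissing = RecordSet(rs.records.loc[~is_missing].reset_index(drop=True),
                           provenance=f"{rs.provenance} [nonmissing]")
    return missing, nonmissing
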