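"""Tabular data model for individual reproductive records and group metadata.

The atom of every skew computation is one individual's count of surviving
offspring (``rs``) together with their exposure to the risk of reproduction
(years at risk, or age at census for completed-fertility data).  Groups carry
categorical metadata — taxon, mating system (nonhuman mammals), marriage
system and subsistence mode (humans) — that drive all downstream
comparisons.  Everything is plain CSV: comma-separated UTF-8 with a header,
decimal point ``.``, missing values as empty strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("repskew")

__all__ = [
    "Sex",
    "Taxon",
    "MatingSystem",
    "MarriageSystem",
    "Subsistence",
    "PublishedSkewStat",
    "SchemaError",
    "ValidationError",
    "Crosstab",
    "read_records",
    "write_records",
    "validate_records",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "read_published_stats",
    "validate_published_stats",
    "crosstab_metadata",
]


class SchemaError(ValueError):
    """A required column is missing or unparseable."""


class ValidationError(ValueError):
    """A row violates a data-model invariant."""


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Taxon(str, Enum):
    HUMAN = "human"
    NONHUMAN_MAMMAL = "nonhuman_mammal"


class MatingSystem(str, Enum):
    MONOGAMOUS = "monogamous"
    POLYGYNOUS = "polygynous"


class MarriageSystem(str, Enum):
    NORMATIVE_MONOGAMY = "normative_monogamy"
    POLYGYNY_TOLERATED = "polygyny_tolerated"
    NORMATIVE_POLYGYNY = "normative_polygyny"


class Subsistence(str, Enum):
    FORAGING = "foraging"
    HORTICULTURE = "horticulture"
    AGROPASTORALISM = "agropastoralism"
    AGRICULTURE = "agriculture"
    MARKET = "market"


RECORD_COLUMNS = ["individual_id", "group_id", "sex", "rs", "exposure"]

METADATA_COLUMNS = [
    "group_id",
    "taxon",
    "species_name",
    "is_primate",
    "mating_system",
    "marriage_system",
    "subsistence",
    "pct_female_polygyny",
    "high_quality_demography",
]

PUBLISHED_STAT_COLUMNS = ["group_id", "sex", "stat_type", "value", "mean_rs", "n"]

STAT_TYPES = {"variance", "sd", "cv", "opportunity_I", "nonacs_B", "M"}


@dataclass(frozen=True)
class PublishedSkewStat:
    """A published summary statistic of reproductive success for one group-sex.

    ``mean_rs`` is required whenever the conversion to the multinomial index
    needs the mean reproductive success (all types except ``M`` and
    ``nonacs_B``); ``n`` is the number of sampled individuals.
    """

    group_id: str
    sex: str
    stat_type: str
    value: float
    n: int
    mean_rs: float | None = None

    def __post_init__(self) -> None:
        if self.stat_type not in STAT_TYPES:
            raise ValidationError(
                f"unknown stat_type {self.stat_type!r}; allowed: {sorted(STAT_TYPES)}"
            )
        if self.sex not in (Sex.MALE.value, Sex.FEMALE.value):
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.n < 2:
            raise ValidationError(f"n must be >= 2, got {self.n}")
        if self.stat_type in ("variance", "sd", "cv") and self.value < 0:
            raise ValidationError(f"{self.stat_type} must be >= 0, got {self.value}")
        if self.mean_rs is not None and self.mean_rs <= 0:
            raise ValidationError(f"mean_rs must be > 0, got {self.mean_rs}")


# ---------------------------------------------------------------------------
# Individual records
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a records table in place and return it.

    Enforces: non-negative integral ``rs``, strictly positive ``exposure``,
    a known ``sex`` label, and uniqueness of (individual_id, group_id).
    Row numbers in error messages are 0-based positions in the table.
    """
    _require_columns(df, RECORD_COLUMNS, "records table")
    rs = pd.to_numeric(df["rs"], errors="coerce")
    if rs.isna().any():
        row = int(np.flatnonzero(rs.isna().to_numpy())[0])
        raise ValidationError(f"row {row}: rs is not numeric")
    if (rs < 0).any():
        row = int(np.flatnonzero((rs < 0).to_numpy())[0])
        raise ValidationError(f"row {row}: rs must be >= 0 (got {rs.iloc[row]})")
    if (rs != np.floor(rs)).any():
        row = int(np.flatnonzero((rs != np.floor(rs)).to_numpy())[0])
        raise ValidationError(f"row {row}: rs must be an integer (got {rs.iloc[row]})")
    exposure = pd.to_numeric(df["exposure"], errors="coerce")
    if exposure.isna().any() or (exposure <= 0).any():
        bad = exposure.isna() | (exposure <= 0)
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"row {row}: exposure must be a positive number (got {df['exposure'].iloc[row]!r})"
        )
    sex = df["sex"].astype(str).str.strip().str.lower()
    allowed = {s.value for s in Sex}
    if (~sex.isin(allowed)).any():
        row = int(np.flatnonzero((~sex.isin(allowed)).to_numpy())[0])
        raise ValidationError(
            f"row {row}: unknown sex {df['sex'].iloc[row]!r}; allowed: {sorted(allowed)}"
        )
    dup = df.duplicated(subset=["individual_id", "group_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"row {row}: duplicate (individual_id, group_id) = "
            f"({df['individual_id'].iloc[row]!r}, {df['group_id'].iloc[row]!r})"
        )
    df = df.copy()
    df["rs"] = rs.astype(int)
    df["exposure"] = exposure.astype(float)
    df["sex"] = sex
    df["individual_id"] = df["individual_id"].astype(str)
    df["group_id"] = df["group_id"].astype(str)
    return df


def read_records(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate an individual-level records CSV.

    Parameters
    ----------
    path
        CSV with columns ``individual_id, group_id, sex, rs, exposure``.
    column_map
        Optional mapping from nonstandard file headers to the standard
        column names, e.g. ``{"ID": "individual_id"}``.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "group_id": str})
    if column_map:
        df = df.rename(columns=column_map)
    df = validate_records(df)
    logger.info("read %d records from %s (%d groups)", len(df), path, df["group_id"].nunique())
    return df


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    validate_records(df)[RECORD_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Group metadata
# ---------------------------------------------------------------------------


def _parse_enum(series: pd.Series, enum_cls, col: str) -> pd.Series:
    """Case-insensitive parse of a controlled-vocabulary column; blanks -> NA."""
    raw = series.astype("string").str.strip().str.lower().str.replace(" ", "_")
    raw = raw.replace({"": pd.NA, "na": pd.NA, "nan": pd.NA, "none": pd.NA})
    allowed = {e.value for e in enum_cls}
    bad = raw.dropna()[~raw.dropna().isin(allowed)]
    if len(bad):
        raise ValidationError(
            f"unknown {col} value {bad.iloc[0]!r}; allowed: {sorted(allowed)}"
        )
    return raw


def _parse_flag(series: pd.Series) -> pd.Series:
    raw = series.astype("string").str.strip().str.lower()
    mapping = {"true": True, "1": True, "yes": True, "false": False, "0": False,
               "no": False, "": pd.NA, "na": pd.NA, "nan": pd.NA}
    out = raw.map(mapping)
    unknown = raw.dropna()[~raw.dropna().isin(mapping)]
    if len(unknown):
        raise ValidationError(f"unparseable boolean flag {unknown.iloc[0]!r}")
    return out.astype("boolean")


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a group-metadata table.

    Humans carry ``marriage_system`` and ``subsistence``; nonhuman mammals
    carry ``mating_system``; the inapplicable fields must be missing.
    """
    _require_columns(df, ["group_id", "taxon"], "metadata table")
    df = df.copy()
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df["group_id"] = df["group_id"].astype(str)
    df["taxon"] = _parse_enum(df["taxon"], Taxon, "taxon")
    if df["taxon"].isna().any():
        row = int(np.flatnonzero(df["taxon"].isna().to_numpy())[0])
        raise ValidationError(f"row {row}: taxon is required")
    df["mating_system"] = _parse_enum(df["mating_system"], MatingSystem, "mating_system")
    df["marriage_system"] = _parse_enum(df["marriage_system"], MarriageSystem, "marriage_system")
    df["subsistence"] = _parse_enum(df["subsistence"], Subsistence, "subsistence")
    df["is_primate"] = _parse_flag(df["is_primate"])
    df["high_quality_demography"] = _parse_flag(df["high_quality_demography"])
    df["pct_female_polygyny"] = pd.to_numeric(df["pct_female_polygyny"], errors="coerce")

    human = df["taxon"] == Taxon.HUMAN.value
    if (human & df["mating_system"].notna()).any():
        row = int(np.flatnonzero((human & df["mating_system"].notna()).to_numpy())[0])
        raise ValidationError(
            f"row {row}: mating_system is inapplicable to human groups (use marriage_system)"
        )
    if (~human & (df["marriage_system"].notna() | df["subsistence"].notna())).any():
        bad = ~human & (df["marriage_system"].notna() | df["subsistence"].notna())
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"row {row}: marriage_system/subsistence are inapplicable to nonhuman groups"
        )
    pct = df["pct_female_polygyny"]
    if ((pct < 0) | (pct > 100)).any():
        row = int(np.flatnonzero(((pct < 0) | (pct > 100)).to_numpy())[0])
        raise ValidationError(f"row {row}: pct_female_polygyny must lie in [0, 100]")
    if (~human & pct.notna()).any():
        row = int(np.flatnonzero((~human & pct.notna()).to_numpy())[0])
        raise ValidationError(f"row {row}: pct_female_polygyny applies to human groups only")
    if df["group_id"].duplicated().any():
        row = int(np.flatnonzero(df["group_id"].duplicated().to_numpy())[0])
        raise ValidationError(f"row {row}: duplicate group_id {df['group_id'].iloc[row]!r}")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = validate_metadata(pd.read_csv(path, dtype={"group_id": str}))
    logger.info("read metadata for %d groups from %s", len(df), path)
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(df)[METADATA_COLUMNS].to_csv(path, index=False)


def check_groups_covered(records: pd.DataFrame, metadata: pd.DataFrame) -> None:
    """Raise if any record's group_id is absent from the metadata table."""
    missing = set(records["group_id"]) - set(metadata["group_id"])
    if missing:
        raise ValidationError(
            f"{len(missing)} record group_id(s) missing from metadata, e.g. "
            f"{sorted(missing)[:3]}"
        )


# ---------------------------------------------------------------------------
# Published summary statistics
# ---------------------------------------------------------------------------


def validate_published_stats(df: pd.DataFrame) -> list[PublishedSkewStat]:
    _require_columns(df, ["group_id", "sex", "stat_type", "value", "n"], "published stats table")
    stats = []
    for i, row in df.reset_index(drop=True).iterrows():
        mean_rs = row.get("mean_rs")
        if mean_rs is not None and pd.isna(mean_rs):
            mean_rs = None
        try:
            stats.append(
                PublishedSkewStat(
                    group_id=str(row["group_id"]),
                    sex=str(row["sex"]).strip().lower(),
                    stat_type=str(row["stat_type"]).strip(),
                    value=float(row["value"]),
                    n=int(row["n"]),
                    mean_rs=None if mean_rs is None else float(mean_rs),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return stats


def read_published_stats(path: str | Path) -> list[PublishedSkewStat]:
    stats = validate_published_stats(pd.read_csv(path, dtype={"group_id": str}))
    logger.info("read %d published skew statistics from %s", len(stats), path)
    return stats


# ---------------------------------------------------------------------------
# Cross-tabulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Crosstab:
    """A contingency table of group counts with row-wise proportions."""

    counts: pd.DataFrame
    row_proportions: pd.DataFrame

    @property
    def n_groups(self) -> int:
        return int(self.counts.to_numpy().sum())


def crosstab_metadata(meta: pd.DataFrame, rows: str, cols: str) -> Crosstab:
    """Cross-tabulate two categorical metadata fields.

    Rows with a missing value in either field are excluded.  Cell counts sum
    to the number of groups with both fields present; each row of
    ``row_proportions`` sums to 1.
    """
    for col in (rows, cols):
        if col not in meta.columns:
            raise SchemaError(f"metadata has no column {col!r}")
    sub = meta[[rows, cols]].dropna()
    if sub.empty:
        raise ValidationError(f"no groups with both {rows!r} and {cols!r} present")
    counts = pd.crosstab(sub[rows], sub[cols])
    props = counts.div(counts.sum(axis=1), axis=0)
    return Crosstab(counts=counts, row_proportions=props)
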