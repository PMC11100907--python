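"""Tabular data model and readers/writers for the analysis pipeline.

The pipeline starts at per-cell coordinate tables (one row per segmented
cell), not at images.  Coordinates are micrometres with an arbitrary origin
and the image convention that y increases downward; every spatial statistic
in the package is invariant to origin and axis orientation, so the
convention is documentation only.

Cell tables are CSV files with required columns ``sample``, ``x``, ``y``;
optional columns ``compartment``, ``region_class``, ``region_id``; marker
intensity columns prefixed ``int_``; and bare-named boolean phenotype
columns (accepted values: 0, 1, TRUE, FALSE, true, false — anything else is
an error, never silently coerced).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

COMPARTMENTS = ("duct", "stroma", "unknown")
REGION_CLASSES = ("normal", "ADH", "DCIS", "stroma", "unknown")
CLINICAL_EVENTS = ("none", "DCIS", "invasive")
HORMONE_STATUS = ("pos", "neg")

#: region classes whose cells carry no region id
_REGIONLESS_CLASSES = ("stroma", "unknown")

CELL_META_COLUMNS = ("sample", "x", "y", "compartment", "region_class", "region_id")
INTENSITY_PREFIX = "int_"

_TRUE_TOKENS = {"1", "TRUE", "true", "True"}
_FALSE_TOKENS = {"0", "FALSE", "false", "False"}


# ---------------------------------------------------------------------------
# domain records


@dataclass(frozen=True)
class Cell:
    """A single segmented cell."""

    sample_id: str
    x: float
    y: float
    intensities: Mapping[str, float]
    phenotypes: Mapping[str, bool]
    compartment: str = "unknown"
    region_class: str = "unknown"
    region_id: str | None = None


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-sample risk factors, follow-up and recurrence outcome.

    ``followup_time`` is the time to event when ``event != 'none'`` and the
    censoring time otherwise, in years.
    """

    sample_id: str
    age: float
    grade: int
    hr: str
    her2: str
    comedo: bool
    palpable: bool
    path_mass: bool
    followup_time: float
    event: str

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3):
            raise ValidationError(f"grade must be 1, 2 or 3, got {self.grade!r}")
        if self.hr not in HORMONE_STATUS:
            raise ValidationError(f"HR must be pos/neg, got {self.hr!r}")
        if self.her2 not in HORMONE_STATUS:
            raise ValidationError(f"HER2 must be pos/neg, got {self.her2!r}")
        if self.event not in CLINICAL_EVENTS:
            raise ValidationError(f"event must be one of {CLINICAL_EVENTS}, got {self.event!r}")
        if not (self.followup_time >= 0):
            raise ValidationError(f"followup_time must be >= 0, got {self.followup_time!r}")


@dataclass(frozen=True)
class SegmentRecord:
    """A copy-number segment; 1-based inclusive coordinates (SEG convention)."""

    chrom: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"segment end < start on {self.chrom}: {self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class VariantRecord:
    """A called variant with its ClinVar significance and allele frequency."""

    gene: str
    clinvar: str
    vaf: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf <= 1.0):
            raise ValidationError(f"VAF must be in [0, 1], got {self.vaf!r}")


# ---------------------------------------------------------------------------
# cell table container


class CellTable:
    """Ordered collection of cells for one or more samples.

    Backed by a :class:`pandas.DataFrame` with the canonical columns of
    :data:`CELL_META_COLUMNS`, boolean phenotype columns, and float
    ``int_<marker>`` intensity columns.  Phenotype columns are recognised by
    boolean dtype.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        for col, default in (
            ("compartment", "unknown"),
            ("region_class", "unknown"),
            ("region_id", None),
        ):
            if col not in df.columns:
                df[col] = default
        # normalise missing region ids to NaN so tables compare equal after
        # a CSV round trip
        df["region_id"] = pd.Series(
            [np.nan if pd.isna(v) else str(v) for v in df["region_id"]],
            index=df.index, dtype=object,
        )
        self.df = df.reset_index(drop=True)
        if validate:
            self.validate()

    # -- construction helpers

    @classmethod
    def from_records(cls, cells: Iterable[Cell]) -> "CellTable":
        rows = []
        for c in cells:
            row = {
                "sample": c.sample_id,
                "x": c.x,
                "y": c.y,
                "compartment": c.compartment,
                "region_class": c.region_class,
                "region_id": c.region_id,
            }
            row.update({INTENSITY_PREFIX + m: v for m, v in c.intensities.items()})
            row.update(c.phenotypes)
            rows.append(row)
        df = pd.DataFrame(rows)
        for col in df.columns:
            if col not in CELL_META_COLUMNS and not col.startswith(INTENSITY_PREFIX):
                df[col] = df[col].fillna(False).astype(bool)
        return cls(df)

    # -- accessors

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_cells(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.df["sample"]))

    @property
    def phenotypes(self) -> list[str]:
        return [c for c in self.df.columns if self.df[c].dtype == bool]

    @property
    def intensity_markers(self) -> list[str]:
        return [
            c[len(INTENSITY_PREFIX):]
            for c in self.df.columns
            if c.startswith(INTENSITY_PREFIX)
        ]

    def positive(self, phenotype: str) -> np.ndarray:
        """Boolean mask over rows for a named phenotype column."""
        if phenotype not in self.df.columns or self.df[phenotype].dtype != bool:
            raise SchemaError(f"phenotype column {phenotype!r} not present")
        return self.df[phenotype].to_numpy()

    def coords(self, mask: np.ndarray | None = None) -> np.ndarray:
        xy = self.df[["x", "y"]].to_numpy(dtype=float)
        return xy if mask is None else xy[mask]

    def for_sample(self, sample_id: str) -> "CellTable":
        sub = self.df[self.df["sample"] == sample_id]
        return CellTable(sub, validate=False)

    def cells(self) -> Iterator[Cell]:
        int_cols = [c for c in self.df.columns if c.startswith(INTENSITY_PREFIX)]
        phe_cols = self.phenotypes
        for _, r in self.df.iterrows():
            yield Cell(
                sample_id=r["sample"],
                x=float(r["x"]),
                y=float(r["y"]),
                intensities={c[len(INTENSITY_PREFIX):]: float(r[c]) for c in int_cols},
                phenotypes={c: bool(r[c]) for c in phe_cols},
                compartment=r["compartment"],
                region_class=r["region_class"],
                region_id=None if pd.isna(r["region_id"]) else r["region_id"],
            )

    # -- validation

    def validate(self) -> None:
        df = self.df
        for col in ("sample", "x", "y"):
            if col not in df.columns:
                raise SchemaError(f"cell table is missing mandatory column {col!r}")
        if len(df) == 0:
            return
        if df["sample"].isna().any() or (df["sample"].astype(str) == "").any():
            raise ValidationError("sample id must be nonempty for every cell")
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            bad = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
            raise ValidationError(f"non-finite coordinate at row {bad}")
        bad_comp = set(df["compartment"].dropna()) - set(COMPARTMENTS)
        if bad_comp:
            raise ValidationError(f"unknown compartment value(s): {sorted(bad_comp)}")
        bad_rc = set(df["region_class"].dropna()) - set(REGION_CLASSES)
        if bad_rc:
            raise ValidationError(f"unknown region_class value(s): {sorted(bad_rc)}")
        regionless = df["region_class"].isin(_REGIONLESS_CLASSES)
        has_id = df["region_id"].notna()
        if (regionless & has_id).any():
            raise ValidationError("cells in stroma/unknown regions must have null region_id")
        if ((~regionless) & (~has_id)).any():
            raise ValidationError(
                "cells in normal/ADH/DCIS regions must carry a region_id"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CellTable):
            return NotImplemented
        a, b = self.df, other.df
        if sorted(a.columns) != sorted(b.columns):
            return False
        return a[sorted(a.columns)].equals(b[sorted(a.columns)])


# ---------------------------------------------------------------------------
# region tables

REGION_COLUMNS = ("sample", "region_id", "region_class", "area")


def validate_region_table(regions: pd.DataFrame) -> pd.DataFrame:
    """Check a region table (sample, region_id, region_class, area in μm²)."""
    for col in REGION_COLUMNS:
        if col not in regions.columns:
            raise SchemaError(f"region table is missing column {col!r}")
    if len(regions):
        if (regions["area"].to_numpy(dtype=float) <= 0).any():
            raise ValidationError("region areas must be > 0")
        bad = set(regions["region_class"]) - set(REGION_CLASSES)
        if bad:
            raise ValidationError(f"unknown region_class value(s): {sorted(bad)}")
        if regions.duplicated(["sample", "region_id"]).any():
            raise ValidationError("(sample, region_id) pairs must be unique")
    return regions


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_bool_column(s: pd.Series, name: str) -> pd.Series:
    if s.dtype == bool:
        return s
    out = np.empty(len(s), dtype=bool)
    for i, v in enumerate(s):
        if isinstance(v, (bool, np.bool_)):
            out[i] = bool(v)
        elif isinstance(v, (int, np.integer)) and v in (0, 1):
            out[i] = bool(v)
        elif isinstance(v, (float, np.floating)) and v in (0.0, 1.0):
            out[i] = bool(v)
        elif isinstance(v, str) and v.strip() in _TRUE_TOKENS:
            out[i] = True
        elif isinstance(v, str) and v.strip() in _FALSE_TOKENS:
            out[i] = False
        else:
            raise ValidationError(
                f"phenotype column {name!r} has non-boolean value {v!r} at row {i}"
            )
    return pd.Series(out, index=s.index)


# ---------------------------------------------------------------------------
# readers / writers


def read_cell_table(path: str | os.PathLike, schema: Mapping | None = None) -> CellTable:
    """Read a per-cell CSV into a :class:`CellTable`.

    ``schema`` optionally maps canonical column names (``sample``, ``x``,
    ``y``, ``compartment``, ``region_class``, ``region_id``) to the file's
    column names and may list ``phenotypes`` (file columns to parse as
    boolean phenotype flags).  Without an explicit phenotype list, every
    column that is neither canonical nor ``int_``-prefixed is treated as a
    phenotype.  With an explicit list, unmapped phenotype columns are
    ignored.
    """
    schema = dict(schema or {})
    raw = pd.read_csv(path)
    rename = {}
    for canonical in CELL_META_COLUMNS:
        src = schema.get(canonical, canonical)
        if src in raw.columns:
            rename[src] = canonical
        elif canonical in ("sample", "x", "y"):
            raise SchemaError(f"cell table {path} is missing mandatory column {src!r}")
    df = raw.rename(columns=rename)

    for col in ("x", "y"):
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"non-numeric {col} coordinate at row {row}")
        if num.isna().any():
            row = int(np.flatnonzero(num.isna().to_numpy())[0])
            raise SchemaError(f"missing {col} coordinate at row {row}")
        df[col] = num.astype(float)

    meta = [c for c in CELL_META_COLUMNS if c in df.columns]
    int_cols = [c for c in df.columns if c.startswith(INTENSITY_PREFIX)]
    if "phenotypes" in schema:
        phe_cols = list(schema["phenotypes"])
        missing = [c for c in phe_cols if c not in df.columns]
        if missing:
            raise SchemaError(f"phenotype column(s) not in file: {missing}")
    else:
        phe_cols = [c for c in df.columns if c not in meta and c not in int_cols]
    for c in phe_cols:
        df[c] = _parse_bool_column(df[c], c)
    for c in int_cols:
        df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
    keep = meta + int_cols + phe_cols
    return CellTable(df[keep])


def write_cell_table(table: CellTable, path: str | os.PathLike, overwrite: bool = False) -> None:
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True")
    table.df.to_csv(path, index=False)


def read_region_table(path: str | os.PathLike) -> pd.DataFrame:
    regions = pd.read_csv(path)
    return validate_region_table(regions)


def write_region_table(regions: pd.DataFrame, path: str | os.PathLike, overwrite: bool = False) -> None:
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True")
    validate_region_table(regions).to_csv(path, index=False)


_CLINICAL_COLUMNS = (
    "sample", "age", "grade", "HR", "HER2", "comedo", "palpable",
    "path_mass", "followup_time", "event",
)


def read_clinical_table(path: str | os.PathLike) -> list[ClinicalRecord]:
    """Read the clinical CSV; one validated record per sample."""
    df = pd.read_csv(path)
    missing = [c for c in _CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table is missing column(s): {missing}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValidationError(f"duplicate sample id {dup!r} in clinical table")
    records = []
    for i, r in df.iterrows():
        try:
            grade = int(r["grade"])
        except (TypeError, ValueError):
            raise ValidationError(f"non-integer grade {r['grade']!r} at row {i}")
        try:
            records.append(
                ClinicalRecord(
                    sample_id=str(r["sample"]),
                    age=float(r["age"]),
                    grade=grade,
                    hr=str(r["HR"]),
                    her2=str(r["HER2"]),
                    comedo=bool(_parse_bool_column(pd.Series([r["comedo"]]), "comedo")[0]),
                    palpable=bool(_parse_bool_column(pd.Series([r["palpable"]]), "palpable")[0]),
                    path_mass=bool(_parse_bool_column(pd.Series([r["path_mass"]]), "path_mass")[0]),
                    followup_time=float(r["followup_time"]),
                    event=str(r["event"]),
                )
            )
        except ValidationError as e:
            raise ValidationError(f"row {i}: {e}") from None
    return records


def clinical_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a DataFrame indexed by sample id."""
    df = pd.DataFrame(
        {
            "sample": [r.sample_id for r in records],
            "age": [r.age for r in records],
            "grade": [r.grade for r in records],
            "HR": [r.hr for r in records],
            "HER2": [r.her2 for r in records],
            "comedo": [r.comedo for r in records],
            "palpable": [r.palpable for r in records],
            "path_mass": [r.path_mass for r in records],
            "followup_time": [r.followup_time for r in records],
            "event": [r.event for r in records],
        }
    )
    return df.set_index("sample")


def write_clinical_table(records: Sequence[ClinicalRecord], path, overwrite: bool = False) -> None:
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True")
    clinical_frame(records).reset_index().to_csv(path, index=False)


def read_segments(path: str | os.PathLike) -> list[SegmentRecord]:
    """Read a SEG-like TSV (chrom, start, end, log2_ratio)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("chrom", "start", "end", "log2_ratio") if c not in df.columns]
    if missing:
        raise SchemaError(f"segment table is missing column(s): {missing}")
    out = []
    for i, r in df.iterrows():
        try:
            out.append(
                SegmentRecord(
                    chrom=str(r["chrom"]),
                    start=int(r["start"]),
                    end=int(r["end"]),
                    log2_ratio=float(r["log2_ratio"]),
                )
            )
        except ValidationError as e:
            raise ValidationError(f"row {i}: {e}") from None
    return out


def read_variants(path: str | os.PathLike) -> list[VariantRecord]:
    """Read a variant TSV (gene, clinvar, vaf)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "clinvar", "vaf") if c not in df.columns]
    if missing:
        raise SchemaError(f"variant table is missing column(s): {missing}")
    out = []
    for i, r in df.iterrows():
        try:
            out.append(VariantRecord(str(r["gene"]), str(r["clinvar"]), float(r["vaf"])))
        except ValidationError as e:
            raise ValidationError(f"row {i}: {e}") from None
    return out


def write_variants(variants: Sequence[VariantRecord], path, overwrite: bool = False) -> None:
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True")
    pd.DataFrame(
        {"gene": [v.gene for v in variants],
         "clinvar": [v.clinvar for v in variants],
         "vaf": [v.vaf for v in variants]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature matrices

# A SampleFeatureMatrix is a DataFrame: rows = samples, columns = features,
# NaN = missing. Serialised as CSV with empty fields for missing values.


def write_feature_matrix(matrix: pd.DataFrame, path, overwrite: bool = False) -> None:
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValidationError("refusing to write an empty feature matrix")
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True")
    out = matrix.copy()
    out.index.name = "sample"
    out.to_csv(path, na_rep="")


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample")
    df.index = df.index.astype(str)
    return df
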