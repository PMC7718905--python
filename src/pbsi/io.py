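"""Reading, validating and writing the tabular formats of the PBSI pipeline.

The universal input is a *morphometry table*: one row per subject with
``subject_id``, ``group``, ``site``, ``sex``, ``age``, optional numeric
covariates, and one numeric column per regional measure.  Region columns are
tagged with their modality by a column-name prefix — ``ct__`` for cortical
thickness (mm) and ``sv__`` for subcortical volume (mm^3) — or by an explicit
YAML schema file declaring modality membership and canonical region order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CT = "CT"
SV = "SV"
MODALITIES = (CT, SV)

#: column-name prefixes tagging region columns with a modality
PREFIX = {CT: "ct__", SV: "sv__"}

MANDATORY_COLUMNS = ("subject_id", "group", "site", "sex", "age")


class MorphometryError(ValueError):
    """Base class for morphometry-table validation failures."""


class SchemaError(MorphometryError):
    """Mandatory columns missing or region schema inconsistent."""


class ParseError(MorphometryError):
    """A region cell could not be coerced to a number."""


class EmptyInputError(MorphometryError):
    """No usable subjects remain after filtering."""


@dataclass(frozen=True)
class RegionSet:
    """An ordered list of region labels of one modality.

    Ordering is the canonical profile order: profiles are compared
    position-wise, so it must be identical for every subject.
    """

    modality: str
    region_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise SchemaError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if len(self.region_ids) < 2:
            raise SchemaError(
                f"{self.modality} region set needs >= 2 regions, got {len(self.region_ids)}"
            )
        if len(set(self.region_ids)) != len(self.region_ids):
            dupes = sorted({r for r in self.region_ids if list(self.region_ids).count(r) > 1})
            raise SchemaError(f"duplicated region ids in {self.modality} set: {dupes}")
        object.__setattr__(self, "region_ids", tuple(self.region_ids))

    def __len__(self) -> int:
        return len(self.region_ids)

    @property
    def columns(self) -> list[str]:
        """Region labels as prefixed table column names."""
        pre = PREFIX[self.modality]
        return [r if r.startswith(pre) else pre + r for r in self.region_ids]


@dataclass(frozen=True)
class MorphometrySchema:
    """The CT/SV region-set pair describing one table layout."""

    ct: RegionSet
    sv: RegionSet

    def region_set(self, modality: str) -> RegionSet:
        if modality == CT:
            return self.ct
        if modality == SV:
            return self.sv
        raise SchemaError(f"unknown modality {modality!r}")

    @property
    def region_columns(self) -> list[str]:
        return self.ct.columns + self.sv.columns

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MorphometrySchema":
        """Load ``{ct: [...], sv: [...]}`` from a YAML schema file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("ct", "sv"):
            if key not in raw:
                raise SchemaError(f"schema file {path} missing key {key!r}")
        return cls(
            ct=RegionSet(CT, tuple(str(r) for r in raw["ct"])),
            sv=RegionSet(SV, tuple(str(r) for r in raw["sv"])),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"ct": list(self.ct.region_ids), "sv": list(self.sv.region_ids)},
                fh,
                sort_keys=False,
            )


# Desikan-atlas cortical parcels, bilateral (32 per hemisphere = 64 columns),
# and the common bilateral subcortical segmentation labels (9 per hemisphere
# = 18 columns).  This is the documented default layout; any schema with >= 2
# regions per modality is accepted.
_DESIKAN_32 = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal",
    "transversetemporal", "insula",
)
_SUBCORTICAL_9 = (
    "thalamus", "caudate", "putamen", "pallidum", "hippocampus",
    "amygdala", "accumbens", "ventraldc", "lateralventricle",
)


def default_schema() -> MorphometrySchema:
    """The default 64 CT + 18 SV region schema (bilateral Desikan labels)."""
    ct = tuple(f"{h}_{r}" for h in ("lh", "rh") for r in _DESIKAN_32)
    sv = tuple(f"{h}_{r}" for h in ("lh", "rh") for r in _SUBCORTICAL_9)
    return MorphometrySchema(ct=RegionSet(CT, ct), sv=RegionSet(SV, sv))


def infer_schema(columns: Iterable[str]) -> MorphometrySchema:
    """Infer the region schema from ``ct__`` / ``sv__`` prefixed column names.

    Column order in the file defines the canonical profile order.
    """
    ct = tuple(c[len(PREFIX[CT]):] for c in columns if c.startswith(PREFIX[CT]))
    sv = tuple(c[len(PREFIX[SV]):] for c in columns if c.startswith(PREFIX[SV]))
    if len(ct) < 2 or len(sv) < 2:
        raise SchemaError(
            "could not infer a region schema: need >= 2 'ct__' and >= 2 'sv__' "
            f"columns, found {len(ct)} CT and {len(sv)} SV"
        )
    return MorphometrySchema(ct=RegionSet(CT, ct), sv=RegionSet(SV, sv))


@dataclass
class MorphometryTable:
    """A validated subjects-by-measures table plus its region schema."""

    data: pd.DataFrame
    schema: MorphometrySchema
    n_dropped: int = 0
    dropped_subjects: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        validate_table(self.data, self.schema)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def profiles(self, modality: str) -> pd.DataFrame:
        """Subjects x regions matrix for one modality, canonical order."""
        cols = self.schema.region_set(modality).columns
        mat = self.data[cols].copy()
        mat.index = self.data["subject_id"].to_numpy()
        return mat

    def cells(self) -> list[tuple[str, str]]:
        """All observed (group, site) strata, in first-appearance order."""
        seen = self.data[["group", "site"]].drop_duplicates()
        return list(seen.itertuples(index=False, name=None))


def validate_table(data: pd.DataFrame, schema: MorphometrySchema) -> None:
    missing = [c for c in MANDATORY_COLUMNS if c not in data.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    missing_regions = [c for c in schema.region_columns if c not in data.columns]
    if missing_regions:
        raise SchemaError(f"missing region columns: {missing_regions[:8]}"
                          + ("..." if len(missing_regions) > 8 else ""))
    ids = data["subject_id"]
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique().tolist())
        raise SchemaError(f"duplicated subject_id values: {dupes}")
    region = data[schema.region_columns]
    bad = [c for c in region.columns if not pd.api.types.is_numeric_dtype(region[c])]
    if bad:
        raise ParseError(f"non-numeric region columns after coercion: {bad}")
    if not np.isfinite(region.to_numpy(dtype=float)).all():
        raise ParseError("region columns contain non-finite values")
    if len(data) == 0:
        raise EmptyInputError("zero subjects in table")


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_morphometry(path: str | Path, schema: MorphometrySchema | None = None) -> MorphometryTable:
    """Read and validate a morphometry CSV/TSV.

    The delimiter is auto-detected from the header.  Region columns are
    coerced to numeric; a cell that is neither numeric nor a recognized
    missing-value marker raises :class:`ParseError` with its row and column.
    Subjects with any missing region value are dropped (a profile with holes
    breaks position-wise rank correlation) and the count is logged.

    Parameters
    ----------
    path
        CSV or TSV file with a header row.
    schema
        Region schema; when ``None`` it is inferred from ``ct__``/``sv__``
        column prefixes, with file column order as the canonical order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    if schema is None:
        schema = infer_schema(data.columns)

    missing = [c for c in MANDATORY_COLUMNS if c not in data.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    missing_regions = [c for c in schema.region_columns if c not in data.columns]
    if missing_regions:
        raise SchemaError(f"missing region columns: {missing_regions}")

    data = data.copy()
    data["subject_id"] = data["subject_id"].astype(str)
    for col in schema.region_columns:
        raw = data[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        newly_bad = coerced.isna() & raw.notna()
        if newly_bad.any():
            row = int(np.flatnonzero(newly_bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric region value {raw.iloc[row]!r} at row {row}, column {col!r}"
            )
        data[col] = coerced

    incomplete = data[schema.region_columns].isna().any(axis=1)
    dropped = tuple(data.loc[incomplete, "subject_id"])
    if incomplete.any():
        logger.warning(
            "dropping %d subject(s) with missing region values: %s",
            len(dropped), ", ".join(dropped),
        )
        data = data.loc[~incomplete].reset_index(drop=True)
    if len(data) == 0:
        raise EmptyInputError(f"zero usable subjects in {path}")
    return MorphometryTable(data=data, schema=schema,
                            n_dropped=len(dropped), dropped_subjects=dropped)


def write_table(table: MorphometryTable, path: str | Path) -> Path:
    """Write the table as CSV (lossless for finite doubles)."""
    path = Path(path)
    table.data.to_csv(path, index=False)
    return path


def write_results(frame: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy results frame as CSV with full float precision.

    Floats are written with Python's shortest round-trip repr, so reading
    the file back reproduces every value exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path
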