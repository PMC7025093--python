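"""Domain types, feature-table I/O, derived features and the phenotype taxonomy.

A :class:`FeatureTable` is the universal currency of the pipeline: one row per
segmented cell, a fixed block of metadata columns (plate, well, field, strain,
allele, marker, screen type, condition), a ``qc_status`` column, and named
numeric morphology features following the naming style CellProfiler emits
(``<object>_<category>_<measure>``, objects being the whole cell, the screened
compartment and the cytoplasm).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from phenoscreen.errors import DataError, EmptyTableError, SchemaError

logger = logging.getLogger(__name__)

REQUIRED_META = (
    "plate_id",
    "well_id",
    "field_id",
    "strain_id",
    "allele_id",
    "marker",
    "screen_type",
    "condition",
)

#: qc_status values; only "good" cells enter downstream statistics.
QC_GOOD = "good"
QC_BAD_SHAPE = "bad_shape"
QC_BAD_IMAGE = "bad_image"
QC_BAD_WELL = "bad_well"
QC_ARTIFACT = "artifact_class"
QC_STATUSES = (QC_GOOD, QC_BAD_SHAPE, QC_BAD_IMAGE, QC_BAD_WELL, QC_ARTIFACT)

COMPARTMENT_TAGS = ("cell", "compartment", "cytoplasm")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names plus their compartment grouping.

    Parameters
    ----------
    feature_names
        Ordered, unique feature identifiers.
    groups
        Map feature -> one of ``{"cell", "compartment", "cytoplasm"}``.
    """

    feature_names: tuple[str, ...]
    groups: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(self.feature_names)
        if len(set(names)) != len(names):
            raise SchemaError("feature names must be unique")
        object.__setattr__(self, "feature_names", names)
        for feat, tag in self.groups.items():
            if tag not in COMPARTMENT_TAGS:
                raise SchemaError(
                    f"group tag {tag!r} for feature {feat!r} is not one of "
                    f"{COMPARTMENT_TAGS}"
                )

    def __len__(self) -> int:
        return len(self.feature_names)

    @property
    def required_meta(self) -> tuple[str, ...]:
        return REQUIRED_META


def default_schema() -> FeatureSchema:
    """A representative ~90-feature CellProfiler-like schema.

    Ten area/shape, six intensity and fourteen texture measures for each of
    the three segmented objects. The exact feature list of any given
    CellProfiler run is configurable; downstream statistics only require
    named numeric columns.
    """
    shape = (
        "areashape_area",
        "areashape_perimeter",
        "areashape_eccentricity",
        "areashape_formfactor",
        "areashape_solidity",
        "areashape_extent",
        "areashape_maxferetdiameter",
        "areashape_minferetdiameter",
        "areashape_majoraxislength",
        "areashape_minoraxislength",
    )
    intensity = (
        "intensity_meanintensity",
        "intensity_medianintensity",
        "intensity_maxintensity",
        "intensity_minintensity",
        "intensity_stdintensity",
        "intensity_integratedintensity",
    )
    texture = tuple(
        f"texture_{m}"
        for m in (
            "angularsecondmoment",
            "contrast",
            "correlation",
            "variance",
            "inversedifferencemoment",
            "sumaverage",
            "sumvariance",
            "sumentropy",
            "entropy",
            "differencevariance",
            "differenceentropy",
            "infomeas1",
            "infomeas2",
            "gabor",
        )
    )
    names: list[str] = []
    groups: dict[str, str] = {}
    for obj in COMPARTMENT_TAGS:
        for meas in shape + intensity + texture:
            name = f"{obj}_{meas}"
            names.append(name)
            groups[name] = obj
    return FeatureSchema(tuple(names), groups)


class FeatureTable:
    """Per-cell feature rows sharing one :class:`FeatureSchema`.

    Backed by a :class:`pandas.DataFrame` with columns
    ``cell_id`` + required metadata + ``qc_status`` + schema features.
    """

    def __init__(self, schema: FeatureSchema, data: pd.DataFrame):
        missing_meta = [c for c in ("cell_id", *REQUIRED_META) if c not in data.columns]
        if missing_meta:
            raise SchemaError(f"missing required metadata columns: {missing_meta}")
        missing_feat = [f for f in schema.feature_names if f not in data.columns]
        if missing_feat:
            raise SchemaError(f"missing feature columns: {missing_feat[:5]}...")
        data = data.copy()
        if "qc_status" not in data.columns:
            data["qc_status"] = QC_GOOD
        ordered = ["cell_id", *REQUIRED_META, "qc_status", *schema.feature_names]
        extra = [c for c in data.columns if c not in ordered]
        self.schema = schema
        self.data = data[ordered + extra].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.schema, self.data)

    @property
    def good_mask(self) -> pd.Series:
        return self.data["qc_status"] == QC_GOOD

    def good_cells(self) -> pd.DataFrame:
        """Rows passing all QC filters (the only rows statistics may use)."""
        return self.data[self.good_mask]

    def features(self, good_only: bool = False) -> pd.DataFrame:
        rows = self.good_cells() if good_only else self.data
        return rows[list(self.schema.feature_names)]

    def feature_matrix(self, good_only: bool = True) -> np.ndarray:
        return self.features(good_only=good_only).to_numpy(dtype=float)

    def with_extra_features(self, extra: pd.DataFrame) -> "FeatureTable":
        """Return a new table whose schema is extended by ``extra``'s columns."""
        new_names = self.schema.feature_names + tuple(extra.columns)
        groups = dict(self.schema.groups)
        data = pd.concat([self.data, extra.reset_index(drop=True)], axis=1)
        return FeatureTable(FeatureSchema(new_names, groups), data)


@dataclass(frozen=True)
class PhenotypeTaxonomy:
    """Markers and their ordered phenotype classes.

    Each marker has exactly one wild-type class; the remaining classes
    describe aberrant compartment morphologies. The default taxonomy covers
    the four endocytic compartment markers with 4 wild-type and 17 aberrant
    classes (21 total).
    """

    markers: tuple[str, ...]
    classes_per_marker: Mapping[str, tuple[str, ...]]
    wild_type_class: Mapping[str, str]

    def __post_init__(self) -> None:
        for m in self.markers:
            classes = self.classes_per_marker[m]
            if len(set(classes)) != len(classes):
                raise SchemaError(f"duplicate class names for marker {m!r}")
            if self.wild_type_class[m] not in classes:
                raise SchemaError(f"wild-type class of marker {m!r} not in its class list")

    @property
    def aberrant_classes(self) -> tuple[str, ...]:
        """Flattened ordered list of non-wild-type classes across markers."""
        out: list[str] = []
        for m in self.markers:
            wt = self.wild_type_class[m]
            out.extend(c for c in self.classes_per_marker[m] if c != wt)
        return tuple(out)

    @property
    def all_classes(self) -> tuple[str, ...]:
        out: list[str] = []
        for m in self.markers:
            out.extend(self.classes_per_marker[m])
        return tuple(out)

    def classes_of(self, marker: str) -> tuple[str, ...]:
        return tuple(self.classes_per_marker[marker])


def default_taxonomy() -> PhenotypeTaxonomy:
    """Default endocytosis taxonomy: 4 markers, 21 classes (4 WT + 17 aberrant).

    Aberrant class counts per compartment module: actin patch 4, coat patch 4,
    late endosome 3, vacuole 6.
    """
    classes = {
        "actin": (
            "wt_actin",
            "actin_depolarized",
            "actin_patch_enlarged",
            "actin_clumped",
            "actin_reduced",
        ),
        "coat": (
            "wt_coat",
            "coat_patch_enlarged",
            "coat_patch_bright",
            "coat_clumped",
            "coat_reduced",
        ),
        "late_endosome": (
            "wt_late_endosome",
            "le_enlarged",
            "le_fragmented",
            "le_class_e",
        ),
        "vacuole": (
            "wt_vacuole",
            "vac_enlarged",
            "vac_fragmented",
            "vac_multilobed",
            "vac_condensed",
            "vac_vph1_mislocalized",
            "vac_class_e",
        ),
    }
    markers = ("actin", "coat", "late_endosome", "vacuole")
    wt = {m: classes[m][0] for m in markers}
    return PhenotypeTaxonomy(markers, classes, wt)


@dataclass(frozen=True)
class PlateLayout:
    """Well-to-strain map of one plate plus its wild-type control wells."""

    plate_id: str
    well_to_strain: Mapping[str, str]
    control_wells: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "control_wells", frozenset(self.control_wells))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def infer_schema(path: str | Path) -> FeatureSchema:
    """Build a schema from a table's header: every non-metadata column is a feature."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise EmptyTableError(f"{path} is empty")
    sep = _sniff_sep(path)
    with open(path, "r") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    reserved = {"cell_id", "qc_status", *REQUIRED_META}
    features = tuple(c for c in header if c not in reserved)
    if not features:
        raise SchemaError(f"{path}: no feature columns found")
    groups = {
        f: tag
        for f in features
        for tag in COMPARTMENT_TAGS
        if f.startswith(f"{tag}_")
    }
    return FeatureSchema(features, groups)


def read_feature_table(path: str | Path, schema: FeatureSchema) -> FeatureTable:
    """Read a delimited-text feature table conforming to ``schema``.

    Tab-delimited by default, comma accepted; one header row; column names
    case-sensitive. Rows with unparseable numeric feature values are rejected
    and their row indices logged.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise EmptyTableError(f"{path} is empty")
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if raw.empty:
        raise EmptyTableError(f"{path} has a header but no data rows")
    missing = [c for c in ("cell_id", *REQUIRED_META) if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required metadata columns {missing}")
    missing_f = [f for f in schema.feature_names if f not in raw.columns]
    if missing_f:
        raise SchemaError(f"{path}: missing feature columns {missing_f[:5]}")
    feats = raw[list(schema.feature_names)].apply(pd.to_numeric, errors="coerce")
    # a feature cell that is textually present but unparseable becomes NaN
    # where the raw string was non-empty -> reject that row
    was_text = raw[list(schema.feature_names)].notna()
    bad_rows = (feats.isna() & was_text).any(axis=1)
    if bad_rows.any():
        idx = list(raw.index[bad_rows])
        logger.warning("rejected %d rows with unparseable numerics: %s", len(idx), idx)
        warnings.warn(f"rejected rows with unparseable numerics: {idx}")
    keep = ~bad_rows
    data = raw.loc[keep, ["cell_id", *REQUIRED_META]].copy()
    if "qc_status" in raw.columns:
        data["qc_status"] = raw.loc[keep, "qc_status"]
    # exact per-element float() parse: to_numeric's fast path can be 1 ulp off
    data[list(schema.feature_names)] = raw.loc[keep, list(schema.feature_names)].astype(float)
    return FeatureTable(schema, data)


def write_feature_table(table: FeatureTable, path: str | Path, sep: str = "\t") -> None:
    """Write a feature table as delimited text (full float precision)."""
    cols = ["cell_id", *REQUIRED_META, "qc_status", *table.schema.feature_names]
    table.data[cols].to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Derived features
# ---------------------------------------------------------------------------

def add_derived_features(
    table: FeatureTable,
    compartment_area: str = "compartment_areashape_area",
    cell_area: str = "cell_areashape_area",
    max_feret: str = "compartment_areashape_maxferetdiameter",
    min_feret: str = "compartment_areashape_minferetdiameter",
) -> FeatureTable:
    """Append the two compartment-geometry features derived from raw measures.

    ``area_fraction`` is the fraction of the cell occupied by the screened
    compartment (compartment area / cell area); ``diameter_ratio`` is the
    compartment max/min Feret diameter ratio. Records with a zero denominator
    get a missing value and are flagged ``bad_shape``.
    """
    for col in (compartment_area, cell_area, max_feret, min_feret):
        if col not in table.data.columns:
            raise SchemaError(f"required raw feature {col!r} not in table")
    d = table.data
    cell_a = d[cell_area].to_numpy(dtype=float)
    comp_a = d[compartment_area].to_numpy(dtype=float)
    mx = d[max_feret].to_numpy(dtype=float)
    mn = d[min_feret].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        area_fraction = np.where(cell_a != 0, comp_a / cell_a, np.nan)
        diameter_ratio = np.where(mn != 0, mx / mn, np.nan)
    extra = pd.DataFrame(
        {"area_fraction": area_fraction, "diameter_ratio": diameter_ratio}
    )
    out = table.with_extra_features(extra)
    flagged = (cell_a == 0) | (mn == 0)
    if flagged.any():
        good = out.data["qc_status"] == QC_GOOD
        out.data.loc[flagged & good, "qc_status"] = QC_BAD_SHAPE
        logger.warning("flagged %d cells with zero-denominator derived features", int(flagged.sum()))
    return out


def taxonomy_counts(tax: PhenotypeTaxonomy) -> tuple[int, int, int]:
    """Return (total classes, aberrant classes, unordered aberrant pairs)."""
    n_total = len(tax.all_classes)
    n_aberrant = len(tax.aberrant_classes)
    n_pairs = n_aberrant * (n_aberrant - 1) // 2
    return n_total, n_aberrant, n_pairs
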