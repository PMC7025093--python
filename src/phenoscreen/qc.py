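"""Per-plate standardization against wild-type controls and QC filters.

Features are z-scored per plate using the mean and standard deviation of the
wild-type (negative control) cells of that plate, so that one control SD is
the unit of every downstream threshold. Quality-control filters only mark
``qc_status``; nothing is deleted, and downstream statistics consume
``qc_status == "good"`` rows exclusively.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from phenoscreen.core_data import (
    QC_ARTIFACT,
    QC_BAD_IMAGE,
    QC_BAD_SHAPE,
    QC_BAD_WELL,
    QC_GOOD,
    FeatureTable,
    PlateLayout,
)
from phenoscreen.errors import ConfigurationError, InsufficientDataError

logger = logging.getLogger(__name__)


def _default_bounds() -> dict[str, tuple[float, float]]:
    # +/- 6 control SDs on cell size and segmentation-channel intensity;
    # applies after per-plate standardization (units = control SD).
    return {
        "cell_areashape_area": (-6.0, 6.0),
        "cell_intensity_meanintensity": (-6.0, 6.0),
    }


@dataclass
class QcConfig:
    """Quality-control thresholds.

    Defaults: images with fewer than 5 cells are discarded, wells with fewer
    than 2 good fields (of the 3 acquired) are discarded, and cells whose mean
    artifact-class probability across the ensemble is >= 0.85 are excluded.
    """

    min_cells_per_image: int = 5
    min_good_fields_per_well: int = 2
    artifact_prob_threshold: float = 0.85
    feature_bounds: dict[str, tuple[float, float]] = field(default_factory=_default_bounds)

    def __post_init__(self) -> None:
        if not 0.0 <= self.artifact_prob_threshold <= 1.0:
            raise ConfigurationError("artifact_prob_threshold must be in [0, 1]")
        if self.min_cells_per_image < 0 or self.min_good_fields_per_well < 0:
            raise ConfigurationError("QC counts must be non-negative")


@dataclass
class PlateStats:
    """Audit record of one plate's control-based standardization."""

    plate_id: str
    mean: pd.Series
    sd: pd.Series
    n_control_cells: int
    dropped_features: tuple[str, ...] = ()


def standardize_per_plate(
    table: FeatureTable,
    layouts: Mapping[str, PlateLayout] | Sequence[PlateLayout],
) -> tuple[FeatureTable, list[PlateStats]]:
    """Z-score every feature per plate against that plate's control cells.

    Control statistics use good cells in the layout's control wells only
    (unbiased SD, ddof=1). A feature whose control SD is zero on a plate is
    dropped for that plate (values set to missing) with a warning.
    """
    if not isinstance(layouts, Mapping):
        layouts = {lay.plate_id: lay for lay in layouts}
    out = table.copy()
    feats = list(table.schema.feature_names)
    stats: list[PlateStats] = []
    for plate_id, plate_rows in out.data.groupby("plate_id", sort=False):
        if plate_id not in layouts:
            raise ConfigurationError(f"no layout for plate {plate_id!r}")
        control_wells = layouts[plate_id].control_wells
        ctrl = plate_rows[
            plate_rows["well_id"].isin(control_wells)
            & (plate_rows["qc_status"] == QC_GOOD)
        ]
        if len(ctrl) == 0:
            raise InsufficientDataError(f"plate {plate_id!r} has no good control cells")
        mean = ctrl[feats].mean()
        sd = ctrl[feats].std(ddof=1)
        if len(ctrl) == 1:
            sd = pd.Series(0.0, index=mean.index)
        dropped = tuple(sd.index[(sd == 0) | sd.isna()])
        if dropped:
            warnings.warn(
                f"plate {plate_id!r}: dropping {len(dropped)} constant control "
                f"feature(s): {list(dropped)[:5]}"
            )
        z = (plate_rows[feats] - mean) / sd.replace(0.0, np.nan)
        z[list(dropped)] = np.nan
        out.data.loc[plate_rows.index, feats] = z
        stats.append(
            PlateStats(
                plate_id=str(plate_id),
                mean=mean,
                sd=sd,
                n_control_cells=len(ctrl),
                dropped_features=dropped,
            )
        )
    return out, stats


def apply_hard_filters(table: FeatureTable, cfg: QcConfig | None = None) -> FeatureTable:
    """Mark cells failing shape/size/intensity bounds, sparse images, bad wells.

    Order of application: per-feature bounds -> per-image minimum cell count
    -> per-well minimum count of good fields. Filters mark ``qc_status`` and
    are idempotent.
    """
    cfg = cfg or QcConfig()
    out = table.copy()
    d = out.data

    # 1. per-feature bounds (interpreted in the table's current units)
    good = d["qc_status"] == QC_GOOD
    bad_bounds = pd.Series(False, index=d.index)
    for feat, (lo, hi) in cfg.feature_bounds.items():
        if feat not in d.columns:
            continue
        vals = d[feat].astype(float)
        bad_bounds |= (vals < lo) | (vals > hi)
    d.loc[good & bad_bounds, "qc_status"] = QC_BAD_SHAPE

    # 2. images (plate/well/field) with too few cells
    good = d["qc_status"] == QC_GOOD
    img_keys = ["plate_id", "well_id", "field_id"]
    img_counts = d[good].groupby(img_keys).size()
    sparse = img_counts[img_counts < cfg.min_cells_per_image].index
    if len(sparse) > 0:
        bad_img = d.set_index(img_keys).index.isin(sparse)
        d.loc[bad_img & good.to_numpy(), "qc_status"] = QC_BAD_IMAGE

    # 3. wells with too few good fields
    good = d["qc_status"] == QC_GOOD
    well_keys = ["plate_id", "well_id"]
    good_fields = (
        d[good].groupby(well_keys)["field_id"].nunique()
        if good.any()
        else pd.Series(dtype=int)
    )
    bad_wells = good_fields[good_fields < cfg.min_good_fields_per_well].index
    if len(bad_wells) > 0:
        in_bad_well = d.set_index(well_keys).index.isin(bad_wells)
        d.loc[in_bad_well & good.to_numpy(), "qc_status"] = QC_BAD_WELL
    return out


ARTIFACT_CLASSES = ("small_bud", "bad")
ARTIFACT_MODEL_CLASSES = ("wild_type", "small_bud", "bad")


def artifact_filter(table: FeatureTable, model, cfg: QcConfig | None = None) -> FeatureTable:
    """Mark segmentation artifacts using the 3-class quality-control ensemble.

    ``model`` is an :class:`~phenoscreen.classify.EnsemblePhenotypeClassifier`
    trained on {wild_type, small_bud, bad}. A good cell whose mean ensemble
    probability for either artifact class reaches ``artifact_prob_threshold``
    (inclusive) is marked ``artifact_class``.
    """
    cfg = cfg or QcConfig()
    if set(model.classes) != set(ARTIFACT_MODEL_CLASSES):
        raise ConfigurationError(
            f"artifact model must have classes {ARTIFACT_MODEL_CLASSES}, "
            f"got {tuple(model.classes)}"
        )
    out = table.copy()
    good = out.data["qc_status"] == QC_GOOD
    if not good.any():
        return out
    X = out.data.loc[good, list(out.schema.feature_names)].to_numpy(dtype=float)
    probs = model.predict_proba(X)
    cols = {c: i for i, c in enumerate(model.classes)}
    artifact_prob = np.maximum(
        probs[:, cols["small_bud"]], probs[:, cols["bad"]]
    )
    is_artifact = artifact_prob >= cfg.artifact_prob_threshold
    idx = out.data.index[good][is_artifact]
    out.data.loc[idx, "qc_status"] = QC_ARTIFACT
    logger.info("artifact filter excluded %d of %d good cells", len(idx), int(good.sum()))
    return out


def qc_report(table: FeatureTable) -> pd.DataFrame:
    """Counts of cells per qc_status per plate (for the QC report file)."""
    return (
        table.data.groupby(["plate_id", "qc_status"])
        .size()
        .rename("n_cells")
        .reset_index()
    )
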