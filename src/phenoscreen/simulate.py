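"""Synthetic screens with planted ground truth.

The generator emulates the data model of an imaging screen: 384-well plates
(16 x 24) with wild-type controls at the 76 border wells, three imaged
fields per well, per-cell feature vectors drawn from per-class multivariate
Gaussians (spherical by default, heavy-tailed optional) whose aberrant-class
means sit a configurable number of control SDs away from the wild-type
mean, additive per-plate batch shifts, and per-strain phenotype mixtures
with known penetrance. It also fabricates labeled training sets (with
optional planted label swaps) and toy annotation standards whose terms are
planted gene groups, so that classifier, calling and enrichment stages can
be tested against known truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from phenoscreen.classify import TrainingSet
from phenoscreen.core_data import (
    REQUIRED_META,
    FeatureSchema,
    FeatureTable,
    PhenotypeTaxonomy,
    PlateLayout,
    default_taxonomy,
)
from phenoscreen.errors import ConfigurationError

PLATE_ROWS = 16
PLATE_COLS = 24


def plate_wells() -> list[str]:
    return [
        f"{chr(ord('A') + r)}{c + 1:02d}"
        for r in range(PLATE_ROWS)
        for c in range(PLATE_COLS)
    ]


def border_wells() -> list[str]:
    """The 76 border wells of a 384-well plate (wild-type control positions)."""
    out = []
    for r in range(PLATE_ROWS):
        for c in range(PLATE_COLS):
            if r in (0, PLATE_ROWS - 1) or c in (0, PLATE_COLS - 1):
                out.append(f"{chr(ord('A') + r)}{c + 1:02d}")
    return out


@dataclass
class StrainSpec:
    """One mutant strain: identity plus its true phenotype-class mixture."""

    gene_id: str
    allele_id: str
    mixture: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"strain {self.gene_id}/{self.allele_id}: mixture sums to {total}"
            )

    @property
    def strain_id(self) -> str:
        return f"{self.gene_id}-{self.allele_id}"

    def true_penetrance(self, wild_type_class: str) -> float:
        return 100.0 * (1.0 - self.mixture.get(wild_type_class, 0.0))


@dataclass
class GeneratorConfig:
    """Study conditions of a synthetic screen."""

    seed: int
    strains: list[StrainSpec] = field(default_factory=list)
    marker: str = "vacuole"
    taxonomy: PhenotypeTaxonomy = field(default_factory=default_taxonomy)
    n_features: int = 20
    separation: float = 6.0          # aberrant-class mean offset, control SD units
    batch_shift_sd: float = 0.5      # per-plate additive shift per feature
    fields_per_well: int = 3
    cells_per_field_mean: float = 20.0
    n_replicates: int = 1
    control_strain: str = "WT"
    screen_type: str = "genome_wide"
    condition: str = "30C"
    heavy_tailed: bool = False
    t_df: float = 5.0

    @property
    def wild_type_class(self) -> str:
        return self.taxonomy.wild_type_class[self.marker]


@dataclass
class GroundTruth:
    """Planted truth of a generated screen, aligned to the emitted table."""

    cell_truth: pd.DataFrame     # cell_id, true_class, is_aberrant
    strain_truth: pd.DataFrame   # strain_id, gene_id, allele_id, true_penetrance, ...
    plate_shifts: dict[str, np.ndarray]
    class_means: dict[str, np.ndarray]


def _schema(n_features: int) -> FeatureSchema:
    # generic numeric features; first four carry the names the derived-feature
    # step expects so generated tables exercise the full core_data surface
    base = [
        "cell_areashape_area",
        "compartment_areashape_area",
        "compartment_areashape_maxferetdiameter",
        "compartment_areashape_minferetdiameter",
        "cell_intensity_meanintensity",
    ]
    names = base[:n_features] + [f"feature_{i:03d}" for i in range(max(0, n_features - len(base)))]
    groups = {n: ("cell" if n.startswith("cell") else "compartment") for n in names}
    return FeatureSchema(tuple(names[:n_features]), groups)


def class_mean(name: str, cfg: GeneratorConfig) -> np.ndarray:
    """Deterministic class mean: wild-type at the origin, aberrant classes at
    ``separation`` control SDs along a class-specific random direction."""
    if name in {cfg.taxonomy.wild_type_class[m] for m in cfg.taxonomy.markers} or name == "wild_type":
        return np.zeros(cfg.n_features)
    key = (zlib.crc32(name.encode()) ^ (cfg.seed & 0x7FFFFFFF)) & 0x7FFFFFFF
    rng = np.random.default_rng(key)
    direction = rng.standard_normal(cfg.n_features)
    direction /= np.linalg.norm(direction)
    return cfg.separation * direction


def _draw_noise(rng: np.random.Generator, n: int, cfg: GeneratorConfig) -> np.ndarray:
    if cfg.heavy_tailed:
        scale = np.sqrt((cfg.t_df - 2) / cfg.t_df)  # unit variance
        return rng.standard_t(cfg.t_df, size=(n, cfg.n_features)) * scale
    return rng.standard_normal((n, cfg.n_features))


def generate_screen(
    cfg: GeneratorConfig,
) -> tuple[FeatureTable, dict[str, PlateLayout], GroundTruth]:
    """Generate one screen: feature table, plate layouts and ground truth.

    Mutant strains fill the non-border wells plate by plate; every border
    well carries the wild-type control strain. Each replicate regenerates
    the full plate set with fresh plates (and fresh batch shifts).
    """
    rng = np.random.default_rng(cfg.seed)
    schema = _schema(cfg.n_features)
    wt_class = cfg.wild_type_class
    classes = cfg.taxonomy.classes_of(cfg.marker)
    means = {c: class_mean(c, cfg) for c in classes}
    borders = border_wells()
    inner = [w for w in plate_wells() if w not in set(borders)]
    wt_spec = StrainSpec(cfg.control_strain, "wt", {wt_class: 1.0})

    n_plates_per_rep = max(1, int(np.ceil(len(cfg.strains) / len(inner))))
    records: list[dict] = []
    truth_rows: list[dict] = []
    layouts: dict[str, PlateLayout] = {}
    plate_shifts: dict[str, np.ndarray] = {}
    feats_blocks: list[np.ndarray] = []
    cell_counter = 0

    for rep in range(cfg.n_replicates):
        for p in range(n_plates_per_rep):
            plate_id = f"rep{rep + 1}_plate{p + 1:02d}"
            shift = rng.normal(0.0, cfg.batch_shift_sd, size=cfg.n_features)
            plate_shifts[plate_id] = shift
            strains_here = cfg.strains[p * len(inner) : (p + 1) * len(inner)]
            well_to_strain = {w: cfg.control_strain for w in borders}
            specs: list[tuple[str, StrainSpec]] = [(w, wt_spec) for w in borders]
            for w, spec in zip(inner, strains_here):
                well_to_strain[w] = spec.strain_id
                specs.append((w, spec))
            layouts[plate_id] = PlateLayout(
                plate_id=plate_id,
                well_to_strain=well_to_strain,
                control_wells=frozenset(borders),
            )
            for well, spec in specs:
                mix_classes = list(spec.mixture)
                mix_p = np.array([spec.mixture[c] for c in mix_classes])
                for f in range(cfg.fields_per_well):
                    n_cells = rng.poisson(cfg.cells_per_field_mean)
                    if n_cells == 0:
                        continue
                    draw = rng.choice(len(mix_classes), size=n_cells, p=mix_p)
                    noise = _draw_noise(rng, n_cells, cfg)
                    mu = np.stack([means[mix_classes[i]] for i in draw])
                    feats_blocks.append(mu + noise + shift)
                    for i in range(n_cells):
                        cid = f"cell{cell_counter:08d}"
                        cell_counter += 1
                        true_class = mix_classes[draw[i]]
                        records.append(
                            {
                                "cell_id": cid,
                                "plate_id": plate_id,
                                "well_id": well,
                                "field_id": f"f{f + 1}",
                                "strain_id": spec.strain_id if spec is not wt_spec else cfg.control_strain,
                                "allele_id": spec.allele_id,
                                "marker": cfg.marker,
                                "screen_type": cfg.screen_type,
                                "condition": cfg.condition,
                            }
                        )
                        truth_rows.append(
                            {
                                "cell_id": cid,
                                "true_class": true_class,
                                "is_aberrant": true_class != wt_class,
                            }
                        )

    data = pd.DataFrame(records)
    feats = np.concatenate(feats_blocks) if feats_blocks else np.empty((0, cfg.n_features))
    data[list(schema.feature_names)] = feats
    # cell/compartment geometry columns must be positive for derived features:
    # shift the two area and two Feret columns to a positive regime
    for col, offset in (
        ("cell_areashape_area", 100.0),
        ("compartment_areashape_area", 25.0),
        ("compartment_areashape_maxferetdiameter", 20.0),
        ("compartment_areashape_minferetdiameter", 15.0),
    ):
        if col in data.columns:
            data[col] = data[col] + offset
    table = FeatureTable(schema, data)

    strain_truth = pd.DataFrame(
        [
            {
                "strain_id": s.strain_id,
                "gene_id": s.gene_id,
                "allele_id": s.allele_id,
                "true_penetrance": s.true_penetrance(wt_class),
                **{f"true_frac_{c}": s.mixture.get(c, 0.0) for c in classes},
            }
            for s in cfg.strains
        ]
    )
    truth = GroundTruth(
        cell_truth=pd.DataFrame(truth_rows),
        strain_truth=strain_truth,
        plate_shifts=plate_shifts,
        class_means=means,
    )
    return table, layouts, truth


def random_strains(
    n_strains: int,
    cfg_seed: int,
    classes: Sequence[str],
    wild_type_class: str,
    penetrance_range: tuple[float, float] = (20.0, 95.0),
    n_alleles: int = 1,
) -> list[StrainSpec]:
    """Random mutant strain specs: each strain mixes wild-type cells with one
    aberrant class at a penetrance drawn uniformly from ``penetrance_range``."""
    rng = np.random.default_rng(cfg_seed + 777)
    aberrant = [c for c in classes if c != wild_type_class]
    out = []
    for i in range(n_strains):
        cls = aberrant[rng.integers(len(aberrant))]
        pen = rng.uniform(*penetrance_range) / 100.0
        for a in range(n_alleles):
            out.append(
                StrainSpec(
                    gene_id=f"gene{i:04d}",
                    allele_id=f"a{a + 1}",
                    mixture={wild_type_class: 1.0 - pen, cls: pen},
                )
            )
    return out


def generate_training_set(
    cfg: GeneratorConfig,
    n_per_class: int,
    classes: Sequence[str] | None = None,
    swap_fraction: float = 0.0,
) -> tuple[TrainingSet, np.ndarray]:
    """Labeled cells drawn from the per-class generators.

    ``classes`` defaults to the marker's taxonomy classes; arbitrary extra
    class names (e.g. the quality-control classes ``small_bud``/``bad``) get
    their own deterministic class means. With ``swap_fraction`` > 0 that
    fraction of cells receives a wrong label (planted mislabels); the second
    return value holds the true labels.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    classes = tuple(classes) if classes is not None else cfg.taxonomy.classes_of(cfg.marker)
    means = {c: class_mean(c, cfg) for c in classes}
    X = np.concatenate(
        [means[c] + _draw_noise(rng, n_per_class, cfg) for c in classes]
    )
    true_labels = np.repeat(np.array(classes, dtype=object), n_per_class)
    labels = true_labels.copy()
    n = len(labels)
    if swap_fraction > 0:
        n_swap = int(round(swap_fraction * n))
        idx = rng.choice(n, size=n_swap, replace=False)
        for i in idx:
            others = [c for c in classes if c != true_labels[i]]
            labels[i] = others[rng.integers(len(others))]
    ids = np.array([f"train{i:06d}" for i in range(n)])
    ts = TrainingSet(
        X=X,
        labels=labels,
        cell_ids=ids,
        classes=classes,
        marker=cfg.marker,
        screen_type=cfg.screen_type,
    )
    return ts, true_labels


def generate_standards(
    genes: Sequence[str],
    planted_groups: Sequence[Sequence[str]] = (),
    n_decoys: int = 20,
    decoy_size: tuple[int, int] = (4, 10),
    seed: int = 0,
) -> dict[str, dict[str, set]]:
    """Toy complex/pathway/GO-slim standards with planted groups as terms.

    Each planted gene group becomes one term in every standard; decoy terms
    are random gene subsets sharing no planted structure beyond chance.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    standards: dict[str, dict[str, set]] = {}
    for kind in ("complex", "pathway", "go_slim"):
        terms: dict[str, set] = {}
        for i, grp in enumerate(planted_groups):
            terms[f"{kind}_planted_{i}"] = set(grp)
        for j in range(n_decoys):
            size = rng.integers(decoy_size[0], decoy_size[1] + 1)
            terms[f"{kind}_decoy_{j}"] = set(rng.choice(genes, size=size, replace=False))
        standards[kind] = terms
    return standards


def simulate_intensity_linked_outliers(
    n: int,
    base_rate: float,
    slope: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell covariate intensity with a logistic link to outlier probability.

    Intensity is log-normal; P(outlier | intensity) = sigmoid(a + slope * z)
    where z is the standardized log intensity and the intercept a is solved
    so the marginal outlier rate equals ``base_rate``. ``slope = 0`` gives
    independence.
    """
    rng = np.random.default_rng(seed)
    log_i = rng.normal(0.0, 0.5, size=n)
    z = (log_i - log_i.mean()) / log_i.std()

    def marginal(a: float) -> float:
        return float(expit(a + slope * z).mean()) - base_rate

    a = brentq(marginal, -30.0, 30.0)
    p = expit(a + slope * z)
    flags = rng.random(n) < p
    return np.exp(log_i), flags
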