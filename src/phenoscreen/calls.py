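"""Strain-level penetrance statistics and mutant calling.

Penetrance is 100 x (1 - fraction of wild-type-classified cells). Thresholds
are calibrated from the wild-type replicate distribution: the
specific-phenotype threshold is the 98th percentile of WT phenotype
fractions (floored at 0.05) with a stringent variant
str = (max - thr) * 0.25 + thr, and the penetrance-mutant threshold is the
95th percentile of WT penetrances. Calls additionally require cell-count
support (>= 50 good cells; >= 10 cells of the phenotype) and, for penetrance
mutants, a Bonferroni-corrected hypergeometric p < 0.05. Gene-level
consensus calls require half or more of a gene's alleles to qualify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from phenoscreen.classify import NONE_CLASS
from phenoscreen.errors import ConfigurationError, DataError, InsufficientDataError
from phenoscreen.outliers import penetrance_significance


@dataclass
class StrainSummary:
    """Class fractions, counts and penetrance of one strain in one screen."""

    strain_id: str
    allele_id: str
    marker: str
    condition: str
    screen_type: str
    n_good_cells: int
    class_fractions: dict[str, float]
    class_counts: dict[str, int]
    penetrance: float
    n_replicates: int = 1

    def fraction(self, cls: str) -> float:
        return self.class_fractions.get(cls, 0.0)

    def count(self, cls: str) -> int:
        return self.class_counts.get(cls, 0)


@dataclass
class SpmThresholds:
    phenotype: str
    condition: str
    thr: float
    max_observed: float
    stringent: float


@dataclass
class PenetranceThreshold:
    marker: str
    condition: str
    value: float


@dataclass
class CallConfig:
    min_good_cells: int = 50
    min_phenotype_cells: int = 10
    alpha: float = 0.05
    consensus_rule: float = 0.5
    bin_high: float = 75.0
    bin_intermediate: float = 50.0

    def penetrance_bin(self, penetrance: float) -> str:
        if penetrance >= self.bin_high:
            return "high"
        if penetrance >= self.bin_intermediate:
            return "intermediate"
        return "low"


@dataclass
class ReplicateMetrics:
    TP: int
    TN: int
    FP: int
    FN: int
    penetrance_diffs: np.ndarray

    @property
    def accuracy(self) -> float:
        total = self.TP + self.TN + self.FP + self.FN
        return (self.TP + self.TN) / total if total else float("nan")

    @property
    def fpr(self) -> float:
        denom = self.FP + self.TN
        return self.FP / denom if denom else float("nan")

    @property
    def fnr(self) -> float:
        denom = self.FN + self.TP
        return self.FN / denom if denom else float("nan")

    @property
    def mean_diff(self) -> float:
        return float(np.mean(self.penetrance_diffs)) if len(self.penetrance_diffs) else float("nan")

    @property
    def frac_diff_gt30(self) -> float:
        d = self.penetrance_diffs
        return float(np.mean(d > 30)) if len(d) else float("nan")


@dataclass
class BootstrapConfig:
    """Two sampling grids (fine 10..100 by 10, coarse 125..1000 by 25)."""

    small_grid: tuple[int, ...] = tuple(range(10, 101, 10))
    large_grid: tuple[int, ...] = tuple(range(125, 1001, 25))
    n_samplings: int = 100
    rel_sd_threshold: float = 0.2
    seed: int = 0

    @property
    def grid(self) -> tuple[int, ...]:
        g = tuple(self.small_grid) + tuple(self.large_grid)
        if any(b <= a for a, b in zip(g, g[1:])):
            raise ConfigurationError("bootstrap grids must be sorted ascending")
        return g


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_strain(
    assigned: Sequence[str] | pd.Series,
    wild_type_class: str,
    meta: Mapping[str, str],
) -> StrainSummary | None:
    """Class fractions (including "None") and penetrance of one strain.

    ``assigned`` are the per-good-cell class assignments; returns None when
    the strain has zero good cells.
    """
    assigned = pd.Series(list(assigned))
    n = len(assigned)
    if n == 0:
        return None
    counts = assigned.value_counts().to_dict()
    fractions = {c: k / n for c, k in counts.items()}
    penetrance = 100.0 * (1.0 - fractions.get(wild_type_class, 0.0))
    return StrainSummary(
        strain_id=str(meta.get("strain_id", "")),
        allele_id=str(meta.get("allele_id", "")),
        marker=str(meta.get("marker", "")),
        condition=str(meta.get("condition", "")),
        screen_type=str(meta.get("screen_type", "")),
        n_good_cells=n,
        class_fractions=fractions,
        class_counts={c: int(k) for c, k in counts.items()},
        penetrance=penetrance,
    )


def combine_replicates(summaries: Sequence[StrainSummary]) -> StrainSummary:
    """Replicate-number-weighted mean of per-screen-type strain summaries.

    Fractions and penetrance are combined as
    sum(value_i * n_replicates_i) / sum(n_replicates_i); cell counts add.
    """
    if not summaries:
        raise InsufficientDataError("no summaries to combine")
    if len(summaries) == 1:
        return summaries[0]
    w = np.array([s.n_replicates for s in summaries], dtype=float)
    wsum = w.sum()
    classes = sorted({c for s in summaries for c in s.class_fractions})
    fractions = {
        c: float(sum(s.fraction(c) * wi for s, wi in zip(summaries, w)) / wsum)
        for c in classes
    }
    counts = {c: int(sum(s.count(c) for s in summaries)) for c in classes}
    penetrance = float(sum(s.penetrance * wi for s, wi in zip(summaries, w)) / wsum)
    first = summaries[0]
    return StrainSummary(
        strain_id=first.strain_id,
        allele_id=first.allele_id,
        marker=first.marker,
        condition=first.condition,
        screen_type="combined",
        n_good_cells=int(sum(s.n_good_cells for s in summaries)),
        class_fractions=fractions,
        class_counts=counts,
        penetrance=penetrance,
        n_replicates=int(wsum),
    )


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------

def _wt_values(
    wt_summaries: Sequence[StrainSummary] | Sequence[float] | np.ndarray,
    getter,
) -> np.ndarray:
    if len(wt_summaries) == 0:
        raise InsufficientDataError("no wild-type replicate summaries")
    first = wt_summaries[0]
    if isinstance(first, StrainSummary):
        vals = np.array([getter(s) for s in wt_summaries], dtype=float)
    else:
        vals = np.asarray(wt_summaries, dtype=float)
    if len(vals) < 20:
        warnings.warn(f"only {len(vals)} wild-type replicates; calibration is noisy")
    return vals


def calibrate_spm_thresholds(
    wt_summaries: Sequence[StrainSummary] | Sequence[float],
    phenotype: str,
    condition: str = "",
    max_observed: float | None = None,
    floor: float = 0.05,
    percentile: float = 98.0,
) -> SpmThresholds:
    """Specific-phenotype threshold: 98th percentile of WT fractions, floored.

    ``max_observed`` is the highest observed fraction of this phenotype
    across all strains of the run; the stringent threshold interpolates a
    quarter of the way from thr to it.
    """
    vals = _wt_values(wt_summaries, lambda s: s.fraction(phenotype))
    thr = max(float(np.percentile(vals, percentile)), floor)
    if max_observed is None:
        max_observed = float(vals.max())
    stringent = (max_observed - thr) * 0.25 + thr if max_observed > thr else thr
    return SpmThresholds(
        phenotype=phenotype,
        condition=condition,
        thr=thr,
        max_observed=float(max_observed),
        stringent=float(stringent),
    )


def calibrate_penetrance_threshold(
    wt_summaries: Sequence[StrainSummary] | Sequence[float],
    marker: str = "",
    condition: str = "",
    percentile: float = 95.0,
) -> PenetranceThreshold:
    """Penetrance-mutant threshold: 95th percentile of WT replicate penetrances."""
    vals = _wt_values(wt_summaries, lambda s: s.penetrance)
    return PenetranceThreshold(
        marker=marker, condition=condition, value=float(np.percentile(vals, percentile))
    )


# ---------------------------------------------------------------------------
# Calls
# ---------------------------------------------------------------------------

def call_spm(
    summary: StrainSummary,
    thresholds: SpmThresholds,
    cfg: CallConfig | None = None,
) -> tuple[bool, bool]:
    """(is_spm, is_stringent_spm) for one strain and one phenotype.

    Requires: fraction >= threshold (stringent threshold for the stringent
    call), >= min_good_cells good cells, and >= min_phenotype_cells cells
    assigned to the phenotype.
    """
    cfg = cfg or CallConfig()
    frac = summary.fraction(thresholds.phenotype)
    support = (
        summary.n_good_cells >= cfg.min_good_cells
        and summary.count(thresholds.phenotype) >= cfg.min_phenotype_cells
    )
    is_spm = support and frac >= thresholds.thr
    is_stringent = support and frac >= thresholds.stringent
    return bool(is_spm), bool(is_spm and is_stringent)


def call_penetrance_mutant(
    summary: StrainSummary,
    threshold: PenetranceThreshold,
    cfg: CallConfig | None = None,
    wt_background: tuple[int, int] | None = None,
    m_tests: int = 1,
    wild_type_class: str | None = None,
) -> dict:
    """Penetrance-mutant call for one strain against one marker's threshold.

    The significance test treats any cell not assigned the wild-type class
    ("None" included) as an outlier and compares the strain's outlier count
    against the pooled wild-type background ``(k_wt, n_wt)`` with a
    hypergeometric test; p is Bonferroni-corrected by ``m_tests``.
    """
    cfg = cfg or CallConfig()
    if wild_type_class is None:
        wt_classes = [c for c in summary.class_counts if c.startswith("wt_")]
        if len(wt_classes) != 1:
            raise DataError("cannot infer wild-type class; pass wild_type_class")
        wild_type_class = wt_classes[0]
    k_mut = summary.n_good_cells - summary.count(wild_type_class)
    p = float("nan")
    p_bonf = float("nan")
    if wt_background is not None:
        k_wt, n_wt = wt_background
        p = penetrance_significance(k_mut, summary.n_good_cells, k_wt, n_wt)
        p_bonf = min(1.0, p * m_tests)
    is_mutant = (
        summary.penetrance >= threshold.value
        and summary.n_good_cells >= cfg.min_good_cells
        and (wt_background is None or p_bonf < cfg.alpha)
    )
    return {
        "is_penetrance_mutant": bool(is_mutant),
        "p": p,
        "p_bonferroni": p_bonf,
        "penetrance_bin": cfg.penetrance_bin(summary.penetrance) if is_mutant else "",
        "penetrance": summary.penetrance,
        "n_good_cells": summary.n_good_cells,
    }


def consensus_gene_calls(
    allele_calls: pd.DataFrame,
    cfg: CallConfig | None = None,
    flag_columns: Sequence[str] = ("is_spm", "is_stringent_spm", "is_penetrance_mutant"),
) -> pd.DataFrame:
    """Aggregate allele-level calls to gene level by the half-or-more rule.

    ``allele_calls`` needs a ``gene_id`` column, flag columns and a
    ``penetrance`` column. The consensus gene penetrance is the maximum over
    the alleles that qualified (for the penetrance-mutant flag).
    """
    cfg = cfg or CallConfig()
    rows = []
    for gene, grp in allele_calls.groupby("gene_id"):
        row: dict = {"gene_id": gene, "n_alleles": len(grp)}
        for col in flag_columns:
            if col in grp.columns:
                row[f"consensus_{col}"] = bool(
                    grp[col].mean() >= cfg.consensus_rule
                )
        qual = grp[grp.get("is_penetrance_mutant", pd.Series(False, index=grp.index))]
        if "penetrance" in grp.columns:
            row["penetrance"] = (
                float(qual["penetrance"].max()) if len(qual) else float("nan")
            )
            if row.get("consensus_is_penetrance_mutant") and len(qual):
                row["penetrance_bin"] = cfg.penetrance_bin(row["penetrance"])
            else:
                row["penetrance_bin"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def replicate_metrics(
    pairs: Iterable[tuple[tuple[bool, float], tuple[bool, float]]]
) -> ReplicateMetrics:
    """Reproducibility confusion counts and penetrance differences over replicate pairs.

    Each pair is ((call_ref, penetrance_ref), (call_other, penetrance_other)).
    TP = both replicates satisfy the mutant criteria, TN = neither. For
    discordant pairs the first replicate is the reference: reference positive
    with the other negative counts as a false negative, reference negative
    with the other positive as a false positive.
    """
    TP = TN = FP = FN = 0
    diffs = []
    for (call_a, pen_a), (call_b, pen_b) in pairs:
        if call_a and call_b:
            TP += 1
        elif not call_a and not call_b:
            TN += 1
        elif call_a and not call_b:
            FN += 1
        else:
            FP += 1
        diffs.append(abs(pen_a - pen_b))
    return ReplicateMetrics(TP=TP, TN=TN, FP=FP, FN=FN, penetrance_diffs=np.array(diffs))


@dataclass
class BootstrapResult:
    table: pd.DataFrame  # columns: n, mean_penetrance, sd, rel_sd
    min_n: int | None


def bootstrap_min_cells(
    population: np.ndarray | float,
    cfg: BootstrapConfig | None = None,
) -> BootstrapResult:
    """Minimum cell count for a stable penetrance estimate, by bootstrap.

    ``population`` is either an array of per-cell outlier flags (sampled with
    replacement) or a generative outlier probability p (samples drawn
    binomially). For each grid size n the mean and SD of penetrance over
    ``n_samplings`` draws are recorded; ``min_n`` is the first grid n whose
    relative SD (SD/mean) falls below ``rel_sd_threshold``. Grid sizes with
    zero mean penetrance are skipped with a warning.
    """
    cfg = cfg or BootstrapConfig()
    rng = np.random.default_rng(cfg.seed)
    generative = np.isscalar(population)
    if not generative:
        population = np.asarray(population, dtype=bool)
        if population.size < cfg.grid[-1]:
            raise InsufficientDataError(
                f"population ({population.size}) smaller than largest grid n "
                f"({cfg.grid[-1]}); use generative mode or a smaller grid"
            )
    rows = []
    min_n = None
    for n in cfg.grid:
        if generative:
            pens = 100.0 * rng.binomial(n, float(population), size=cfg.n_samplings) / n
        else:
            draws = rng.choice(population, size=(cfg.n_samplings, n), replace=True)
            pens = 100.0 * draws.mean(axis=1)
        mean, sd = float(pens.mean()), float(pens.std(ddof=1))
        if mean == 0:
            warnings.warn(f"n={n}: mean penetrance 0, relative SD undefined; skipped")
            rows.append({"n": n, "mean_penetrance": mean, "sd": sd, "rel_sd": np.nan})
            continue
        rel = sd / mean
        rows.append({"n": n, "mean_penetrance": mean, "sd": sd, "rel_sd": rel})
        if min_n is None and rel < cfg.rel_sd_threshold:
            min_n = n
    return BootstrapResult(table=pd.DataFrame(rows), min_n=min_n)
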