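"""Single-cell covariate analyses of incomplete penetrance.

Two follow-up analyses of why only part of an isogenic mutant population
shows a phenotype: replicative-age binning by bud-scar (WGA) staining
intensity with a six-bin halving scheme (50%, 25%, 12.5%, 6.25%, 3.125%,
3.125% of cells from youngest to oldest), and stress-response binning of
size-normalized reporter intensity into 10 equal-count bins with k-means
clustering of the resulting per-strain penetrance profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from phenoscreen.errors import ConfigurationError, DataError, InsufficientDataError

DEFAULT_AGE_FRACTIONS = (0.50, 0.25, 0.125, 0.0625, 0.03125, 0.03125)


@dataclass
class AgeBinScheme:
    """Ordered population fractions per replicative-age bin (youngest first)."""

    fractions: tuple[float, ...] = DEFAULT_AGE_FRACTIONS

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigurationError("age bin fractions must sum to 1")

    @property
    def n_bins(self) -> int:
        return len(self.fractions)

    def bin_sizes(self, n: int) -> np.ndarray:
        """Cumulative-fraction cut with floor; remainder goes to the final bin."""
        edges = np.floor(np.cumsum(self.fractions) * n).astype(int)
        edges[-1] = n
        return np.diff(np.concatenate([[0], edges]))


def bin_share_percent(scheme: "AgeBinScheme", n: int, bin_index: int = -1, decimals: int = 2) -> float:
    """Percentage of the population in one age bin, rounded half-up.

    Half-up rounding matches how such shares are conventionally printed
    (3.125% of a 32-divisible population -> 3.13).
    """
    from decimal import ROUND_HALF_UP, Decimal

    sizes = scheme.bin_sizes(n)
    pct = Decimal(int(sizes[bin_index])) * 100 / Decimal(int(n))
    return float(pct.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def bin_by_age(
    intensity: Sequence[float],
    outlier_flags: Sequence[bool],
    scheme: AgeBinScheme | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign cells to replicative-age bins and compute per-bin outlier fractions.

    Cells are sorted ascending by bud-scar intensity and cut at the scheme's
    cumulative fractions. Returns (bin assignment per cell, per-bin outlier
    fraction, per-bin cell count).
    """
    scheme = scheme or AgeBinScheme()
    intensity = np.asarray(intensity, dtype=float)
    flags = np.asarray(outlier_flags, dtype=bool)
    n = intensity.size
    if n < scheme.n_bins:
        raise InsufficientDataError(f"need at least {scheme.n_bins} cells, got {n}")
    if flags.size != n:
        raise DataError("intensity and outlier flags must align")
    order = np.argsort(intensity, kind="stable")
    sizes = scheme.bin_sizes(n)
    assignment = np.empty(n, dtype=int)
    assignment[order] = np.repeat(np.arange(scheme.n_bins), sizes)
    fractions = np.array(
        [flags[assignment == b].mean() for b in range(scheme.n_bins)]
    )
    return assignment, fractions, sizes


def relative_outlier_ratio(
    mutant_fractions: Sequence[float], wt_fractions: Sequence[float]
) -> np.ndarray:
    """Per-bin ratio of mutant to wild-type outlier fractions.

    Bins where the wild-type fraction is 0 return a missing value.
    """
    m = np.asarray(mutant_fractions, dtype=float)
    w = np.asarray(wt_fractions, dtype=float)
    if m.shape != w.shape:
        raise DataError("mutant and wild-type bin schemes differ")
    zero = w == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} bin(s) with wild-type fraction 0; ratio missing")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(zero, np.nan, m / w)
    return ratio


def stress_penetrance_profiles(
    reporter_intensity: Sequence[float],
    cell_area: Sequence[float],
    outlier_flags: Sequence[bool],
    n_bins: int = 10,
) -> np.ndarray:
    """Per-bin outlier fraction over equal-count bins of size-normalized stress signal.

    Reporter intensity is divided by cell area to normalize for cell size;
    cells with zero area are dropped. Cells are sorted by normalized
    intensity and split into ``n_bins`` bins of (near-)equal cell number.
    """
    rep = np.asarray(reporter_intensity, dtype=float)
    area = np.asarray(cell_area, dtype=float)
    flags = np.asarray(outlier_flags, dtype=bool)
    keep = area != 0
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} cell(s) with zero area")
    rep, area, flags = rep[keep], area[keep], flags[keep]
    if rep.size < n_bins:
        raise InsufficientDataError(f"need at least {n_bins} cells, got {rep.size}")
    norm = rep / area
    order = np.argsort(norm, kind="stable")
    chunks = np.array_split(order, n_bins)
    return np.array([flags[idx].mean() for idx in chunks])


def cluster_stress_profiles(
    profiles: np.ndarray | pd.DataFrame, k: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """k-means clustering of per-strain stress-penetrance profiles.

    Returns (labels, centroids). k defaults elsewhere to the number of
    distinct response shapes expected per marker; here it is a free
    parameter.
    """
    X = np.asarray(profiles, dtype=float)
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if len(X) < k:
        raise InsufficientDataError(f"need at least k={k} profiles, got {len(X)}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    return labels, km.cluster_centers_
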