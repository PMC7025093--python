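"""Unsupervised morphological outlier detection.

PCA reduces the standardized feature space to the minimal number of
components explaining at least 80% of the variance of the complete data
(controls plus mutants). A one-class SVM (RBF kernel, nu = 0.5,
gamma = 1/n_PCs) is fitted on wild-type control cells; signed distances to
its decision boundary are thresholded at the 20th percentile of the control
distances, so cells strictly below the threshold are outliers and, by
construction, 20% of the calibration controls are flagged. Unsupervised
penetrance is the percentage of outlier cells in a strain, and its
significance comes from a hypergeometric (one-sided Fisher) test against the
pooled wild-type background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.svm import OneClassSVM

from phenoscreen.core_data import FeatureTable
from phenoscreen.errors import ConfigurationError, DataError, InsufficientDataError


@dataclass
class OutlierDetectorConfig:
    variance_target: float = 0.80
    nu: float = 0.5
    control_percentile: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.variance_target <= 1:
            raise ConfigurationError("variance_target must be in (0, 1]")
        if not 0 < self.nu <= 1:
            raise ConfigurationError("nu must be in (0, 1]")
        if not 0 <= self.control_percentile < 100:
            raise ConfigurationError("control_percentile must be in [0, 100)")


@dataclass
class PcaProjection:
    """Fitted PCA truncated at the minimal component count reaching the target."""

    pca: PCA
    n_pcs: int
    n_features: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.n_features:
            raise DataError(
                f"feature count mismatch: expected {self.n_features}, got {X.shape[1]}"
            )
        return self.pca.transform(X)[:, : self.n_pcs]


@dataclass
class OutlierDetectorModel:
    projection: PcaProjection
    boundary: OneClassSVM
    distance_threshold: float
    config: OutlierDetectorConfig

    @property
    def n_pcs(self) -> int:
        return self.projection.n_pcs

    def decision_distances(self, X: np.ndarray) -> np.ndarray:
        return self.boundary.decision_function(self.projection.transform(X))


def _as_matrix(data: FeatureTable | np.ndarray) -> np.ndarray:
    if isinstance(data, FeatureTable):
        return data.feature_matrix(good_only=True)
    return np.asarray(data, dtype=float)


def min_components_for_variance(variance_shares: Sequence[float], target: float) -> int:
    """Minimal number of leading components whose variance shares reach ``target``."""
    cum = np.cumsum(np.asarray(variance_shares, dtype=float))
    n = int(np.searchsorted(cum, target - 1e-12) + 1)
    return min(n, len(cum))


def fit_pca(data: FeatureTable | np.ndarray, cfg: OutlierDetectorConfig | None = None) -> PcaProjection:
    """Fit PCA and keep the minimal number of PCs reaching ``variance_target``.

    Degenerate covariance is handled naturally: the number of retained PCs
    never exceeds the matrix rank.
    """
    cfg = cfg or OutlierDetectorConfig()
    X = _as_matrix(data)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise InsufficientDataError("PCA needs at least 2 cells and 2 features")
    pca = PCA(svd_solver="full", random_state=cfg.seed)
    pca.fit(X)
    n_pcs = min_components_for_variance(pca.explained_variance_ratio_, cfg.variance_target)
    return PcaProjection(pca=pca, n_pcs=n_pcs, n_features=X.shape[1])


def fit_outlier_detector(
    controls: FeatureTable | np.ndarray,
    cfg: OutlierDetectorConfig | None = None,
    projection: PcaProjection | None = None,
) -> OutlierDetectorModel:
    """Fit the one-class SVM on wild-type controls and calibrate the threshold.

    ``projection`` should be a PCA fitted on the complete data of the screen;
    when omitted it is fitted on the controls themselves. The distance
    threshold is the ``control_percentile``-th percentile (linear
    interpolation) of the signed decision distances of the control cells.
    """
    cfg = cfg or OutlierDetectorConfig()
    X = _as_matrix(controls)
    if projection is None:
        projection = fit_pca(X, cfg)
    if X.shape[0] < projection.n_pcs + 1:
        raise InsufficientDataError(
            f"need more control cells ({X.shape[0]}) than retained PCs "
            f"({projection.n_pcs}) to fit the boundary"
        )
    Z = projection.transform(X)
    svm = OneClassSVM(kernel="rbf", nu=cfg.nu, gamma=1.0 / projection.n_pcs)
    svm.fit(Z)
    dist = svm.decision_function(Z)
    threshold = float(np.percentile(dist, cfg.control_percentile))
    return OutlierDetectorModel(
        projection=projection, boundary=svm, distance_threshold=threshold, config=cfg
    )


def detect_outliers(
    data: FeatureTable | np.ndarray, model: OutlierDetectorModel
) -> np.ndarray | pd.Series:
    """Flag cells as outliers (decision distance strictly below the threshold).

    For a :class:`FeatureTable`, returns a boolean Series indexed by the good
    rows of the table; for a plain matrix, a boolean array.
    """
    if isinstance(data, FeatureTable):
        X = data.feature_matrix(good_only=True)
        flags = model.decision_distances(X) < model.distance_threshold
        return pd.Series(flags, index=data.good_cells().index, name="is_outlier")
    X = np.asarray(data, dtype=float)
    return model.decision_distances(X) < model.distance_threshold


def unsupervised_penetrance(flags: Sequence[bool] | np.ndarray | pd.Series) -> float:
    """Percentage of outlier cells among the good cells of one strain."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return float("nan")
    return 100.0 * float(flags.mean())


def penetrance_significance(k_mut: int, n_mut: int, k_wt: int, n_wt: int) -> float:
    """One-tailed p-value for outlier enrichment in a mutant vs the WT background.

    Hypergeometric upper tail P(X >= k_mut) with the mutant and background
    populations pooled — identical to a one-sided Fisher's exact test on the
    2x2 table [[k_mut, n_mut - k_mut], [k_wt, n_wt - k_wt]].
    """
    if n_mut == 0:
        return float("nan")
    if k_mut > n_mut or k_wt > n_wt:
        raise DataError("outlier count exceeds population size")
    return float(stats.hypergeom.sf(k_mut - 1, n_mut + n_wt, k_mut + k_wt, n_mut))


def strain_outlier_table(
    flags: pd.Series,
    strain_ids: pd.Series,
    wt_strain_id: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-strain unsupervised-penetrance table with Bonferroni-corrected p.

    The background is the pooled wild-type cell population of the run.
    """
    df = pd.DataFrame({"strain_id": strain_ids.loc[flags.index], "is_outlier": flags})
    wt = df[df["strain_id"] == wt_strain_id]
    k_wt, n_wt = int(wt["is_outlier"].sum()), len(wt)
    rows = []
    mutants = df[df["strain_id"] != wt_strain_id]
    m_tests = mutants["strain_id"].nunique()
    for strain, grp in mutants.groupby("strain_id"):
        k, n = int(grp["is_outlier"].sum()), len(grp)
        p = penetrance_significance(k, n, k_wt, n_wt)
        rows.append(
            {
                "strain_id": strain,
                "n_cells": n,
                "n_outliers": k,
                "unsupervised_penetrance": unsupervised_penetrance(grp["is_outlier"]),
                "p": p,
                "p_bonferroni": min(1.0, p * m_tests) if np.isfinite(p) else p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["significant"] = out["p_bonferroni"] < alpha
    return out
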