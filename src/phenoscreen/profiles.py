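"""Phenotype-profile construction and functional mining.

A gene's phenotype profile is its vector of 17 aberrant-class fractions
(allele-averaged, all four markers required). Profiles are mined by Pearson
correlation, average-linkage hierarchical clustering on correlation
distance, pairwise SPM-set overlap tests (one-sided Fisher + BH FDR),
randomized-network enrichment of protein complexes and pathways, GO-slim
hypergeometric enrichment, gene-feature panels (one-sided Mann-Whitney for
numeric, one-sided Fisher for binary), and category-wise profile-similarity
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from phenoscreen.calls import StrainSummary
from phenoscreen.core_data import PhenotypeTaxonomy, default_taxonomy
from phenoscreen.errors import DataError, InsufficientDataError


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def build_profiles(
    summaries: Iterable[StrainSummary],
    gene_of_allele: Mapping[str, str] | None = None,
    taxonomy: PhenotypeTaxonomy | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Allele-averaged aberrant-fraction profiles per gene.

    ``summaries`` are combined per-strain summaries across the four markers.
    Genes missing any marker are excluded (returned as the second element).
    ``gene_of_allele`` maps strain_id -> gene_id; identity when omitted.
    """
    taxonomy = taxonomy or default_taxonomy()
    aberrant = list(taxonomy.aberrant_classes)
    marker_of_class = {
        c: m for m in taxonomy.markers for c in taxonomy.classes_of(m)
    }
    rows = []
    for s in summaries:
        gene = gene_of_allele.get(s.strain_id, s.strain_id) if gene_of_allele else s.strain_id
        for c in taxonomy.classes_of(s.marker):
            if c == taxonomy.wild_type_class[s.marker]:
                continue
            rows.append({"gene_id": gene, "class": c, "fraction": s.fraction(c), "marker": s.marker})
    if not rows:
        raise InsufficientDataError("no summaries provided")
    df = pd.DataFrame(rows)
    # mean across alleles per gene and class
    prof = df.groupby(["gene_id", "class"])["fraction"].mean().unstack("class")
    markers_seen = df.groupby("gene_id")["marker"].nunique()
    complete = markers_seen[markers_seen == len(taxonomy.markers)].index
    incomplete = sorted(set(prof.index) - set(complete))
    prof = prof.loc[complete].reindex(columns=aberrant)
    return prof, incomplete


def profile_correlations(profiles: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix across gene profiles (unit diagonal).

    Zero-variance profiles get missing correlations with a warning.
    """
    if len(profiles) < 2:
        raise InsufficientDataError("need at least 2 complete profiles")
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance profile(s); correlations set to missing"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = np.corrcoef(X)
    pcc[flat, :] = np.nan
    pcc[:, flat] = np.nan
    np.fill_diagonal(pcc, 1.0)
    return pd.DataFrame(pcc, index=profiles.index, columns=profiles.index)


def cluster_profiles(pcc: pd.DataFrame, n_clusters: int | None = None):
    """Average-linkage hierarchical clustering on correlation distance (1 - PCC).

    Returns (linkage matrix, labels). Labels are flat-cluster assignments when
    ``n_clusters`` is given, else None.
    """
    d = 1.0 - pcc.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    if len(pcc) == 1:
        return np.empty((0, 4)), np.array([1])
    condensed = d[np.triu_indices_from(d, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    labels = hierarchy.fcluster(Z, n_clusters, criterion="maxclust") if n_clusters else None
    return Z, labels


def linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return str(leaf_names[node.id])
        left, right = rec(node.left), rec(node.right)
        return f"({left}:{node.dist - node.left.dist:.6g},{right}:{node.dist - node.right.dist:.6g})"

    return rec(tree) + ";"


# ---------------------------------------------------------------------------
# Set-overlap and enrichment tests
# ---------------------------------------------------------------------------

def fisher_overlap(set_a: set, set_b: set, universe: set) -> tuple[float, float]:
    """One-sided (enrichment) Fisher's exact test on the overlap of two gene sets.

    Returns (odds ratio, p).
    """
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


def phenotype_pair_overlap(
    spm_sets: Mapping[str, set],
    universe: set,
    alpha: float = 0.05,
    fdr_threshold: float = 0.2,
) -> pd.DataFrame:
    """Do two phenotypes share more causative mutants than chance?

    One-sided Fisher tests on all unordered phenotype pairs with non-empty
    SPM sets, Benjamini-Hochberg q-values, significance at p < alpha and
    q < fdr_threshold.
    """
    phens = [p for p in spm_sets if len(spm_sets[p]) > 0]
    rows = []
    for i, p1 in enumerate(phens):
        for p2 in phens[i + 1 :]:
            odds, p = fisher_overlap(spm_sets[p1], spm_sets[p2], universe)
            rows.append(
                {
                    "phenotype_a": p1,
                    "phenotype_b": p2,
                    "n_shared": len(spm_sets[p1] & spm_sets[p2]),
                    "odds_ratio": odds,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = (out["p"] < alpha) & (out["q"] < fdr_threshold)
    return out


@dataclass
class RandomizedEnrichmentRecord:
    phenotype: str
    term: str
    P1: int
    p_greater: float
    rnd_p95: float
    significant: bool


def randomized_enrichment(
    hit_sets: Mapping[str, set],
    standard: Mapping[str, set],
    universe: set,
    n_rand: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    scheme: str = "label_permutation",
    pair_mode: bool = False,
    pair_alpha: float = 0.01,
    min_shared: int = 2,
) -> pd.DataFrame:
    """Term enrichment of per-phenotype hit sets against a randomized null.

    For each (phenotype, term): P1 is the observed overlap, p_greater the
    one-sided Fisher p, and the null distribution of overlaps comes from
    ``n_rand`` randomizations of the phenotype-gene associations (default:
    per-phenotype hit sets redrawn uniformly from the universe, preserving
    set sizes; ``scheme="degree_preserving"`` shuffles the bipartite
    association lists jointly, preserving per-gene phenotype counts too).
    A record is significant when p_greater < alpha and P1 exceeds the 95th
    percentile of the null overlaps; in ``pair_mode`` (shared-SPM sets of a
    phenotype pair) the rule is p < pair_alpha and P1 >= min_shared plus the
    null-percentile condition.
    """
    rng = np.random.default_rng(seed)
    universe_list = sorted(universe)
    terms = {t: set(g) & universe for t, g in standard.items()}
    phens = list(hit_sets)

    def overlaps(hits_by_phen: Mapping[str, set]) -> dict[tuple[str, str], int]:
        return {
            (ph, t): len(hits_by_phen[ph] & genes)
            for ph in phens
            for t, genes in terms.items()
        }

    obs = overlaps(hit_sets)
    null_counts: dict[tuple[str, str], list[int]] = {k: [] for k in obs}

    if scheme == "degree_preserving":
        # flatten associations, permute the gene ends jointly
        assoc_ph = [ph for ph in phens for _ in hit_sets[ph]]
        assoc_gene = [g for ph in phens for g in sorted(hit_sets[ph])]
    for _ in range(n_rand):
        if scheme == "label_permutation":
            rnd = {
                ph: set(rng.choice(universe_list, size=len(hit_sets[ph]), replace=False))
                for ph in phens
            }
        elif scheme == "degree_preserving":
            perm = rng.permutation(len(assoc_gene))
            rnd = {ph: set() for ph in phens}
            for ph, gi in zip(assoc_ph, perm):
                rnd[ph].add(assoc_gene[gi])
        else:
            raise DataError(f"unknown randomization scheme {scheme!r}")
        for k, v in overlaps(rnd).items():
            null_counts[k].append(v)

    rows = []
    for (ph, t), p1 in obs.items():
        _, p = fisher_overlap(hit_sets[ph], terms[t], universe)
        rnd_p95 = float(np.percentile(null_counts[(ph, t)], 95))
        if pair_mode:
            sig = p < pair_alpha and p1 >= min_shared and p1 > rnd_p95
        else:
            sig = p < alpha and p1 > rnd_p95
        rows.append(
            {
                "phenotype": ph,
                "term": t,
                "P1": p1,
                "p_greater": p,
                "rnd_p95": rnd_p95,
                "significant": bool(sig),
            }
        )
    return pd.DataFrame(rows)


def go_enrichment(
    hits: set, standard: Mapping[str, set], universe: set
) -> pd.DataFrame:
    """Hypergeometric GO-slim enrichment with Bonferroni correction.

    Fold enrichment = (mutants in term / all mutants) / (term size / background).
    Terms with no members in the universe are skipped.
    """
    hits = set(hits) & universe
    N, n = len(universe), len(hits)
    rows = []
    for term, genes in standard.items():
        members = set(genes) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(hits & members)
        fold = (k / n) / (K / N) if n else float("nan")
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "fold": fold, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out


# ---------------------------------------------------------------------------
# Gene-feature panels
# ---------------------------------------------------------------------------

def gene_feature_tests(
    hits: Sequence[str],
    nonhits: Sequence[str],
    numeric_panels: Mapping[str, Mapping[str, float]] | None = None,
    binary_panels: Mapping[str, Mapping[str, bool]] | None = None,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Compare hit and non-hit genes against numeric/binary gene-feature panels.

    Numeric features: one-sided Mann-Whitney U, plus the median z of the hits
    under a robust normalization using the median and SD of the non-hits
    (so non-hit median z is 0 by construction). Binary features: one-sided
    Fisher's exact test, with fold enrichment log(f_hits / f_nonhits).
    """
    hits, nonhits = list(hits), list(nonhits)
    rows = []
    for name, panel in (numeric_panels or {}).items():
        hv = np.array([panel[g] for g in hits if g in panel and np.isfinite(panel[g])])
        nv = np.array([panel[g] for g in nonhits if g in panel and np.isfinite(panel[g])])
        if len(hv) == 0 or len(nv) == 0:
            warnings.warn(f"numeric feature {name!r}: no data; skipped")
            continue
        sd = nv.std(ddof=1)
        med_z = float((np.median(hv) - np.median(nv)) / sd) if sd > 0 else float("nan")
        _, p = stats.mannwhitneyu(hv, nv, alternative=alternative)
        rows.append(
            {"feature": name, "kind": "numeric", "statistic": med_z, "p": float(p)}
        )
    for name, panel in (binary_panels or {}).items():
        hv = np.array([bool(panel[g]) for g in hits if g in panel])
        nv = np.array([bool(panel[g]) for g in nonhits if g in panel])
        if len(hv) == 0 or len(nv) == 0:
            warnings.warn(f"binary feature {name!r}: no data; skipped")
            continue
        f_hits, f_nonhits = hv.mean(), nv.mean()
        table = [
            [int(hv.sum()), int((~hv).sum())],
            [int(nv.sum()), int((~nv).sum())],
        ]
        _, p = stats.fisher_exact(table, alternative=alternative)
        log_fold = (
            float(np.log(f_hits / f_nonhits)) if f_hits > 0 and f_nonhits > 0 else float("nan")
        )
        rows.append(
            {"feature": name, "kind": "binary", "statistic": log_fold, "p": float(p)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Category-wise profile-similarity comparison
# ---------------------------------------------------------------------------

def category_pcc_comparison(
    pcc: pd.DataFrame,
    pair_categories: Mapping[str, Iterable[tuple[str, str]]],
    alternative: str = "greater",
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Group profile correlations by pair category and test category differences.

    ``pair_categories`` maps a category name (e.g. direct contact / indirect
    contact / different complex, or co-complex / co-pathway / co-expressed)
    to gene pairs. Returns the per-category PCC values and a table of
    pairwise one-sided Mann-Whitney U tests (category A vs category B).
    Categories with fewer than 2 scorable pairs are skipped with a warning.
    """
    values: dict[str, np.ndarray] = {}
    for cat, pairs in pair_categories.items():
        vals = [
            pcc.at[a, b]
            for a, b in pairs
            if a in pcc.index and b in pcc.columns and np.isfinite(pcc.at[a, b])
        ]
        if len(vals) < 2:
            warnings.warn(f"category {cat!r} has < 2 scorable pairs; skipped")
            continue
        values[cat] = np.asarray(vals, dtype=float)
    cats = list(values)
    rows = []
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            _, p = stats.mannwhitneyu(values[a], values[b], alternative=alternative)
            rows.append(
                {
                    "category_a": a,
                    "category_b": b,
                    "median_a": float(np.median(values[a])),
                    "median_b": float(np.median(values[b])),
                    "p": float(p),
                }
            )
    return values, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Annotation standards I/O
# ---------------------------------------------------------------------------

def load_term_standard(path: str | Path, sep: str = "\t") -> dict[str, set]:
    """Load a (term, gene) two-column delimited file as term -> gene set."""
    df = pd.read_csv(path, sep=sep, header=None, names=["term", "gene"], dtype=str)
    return {t: set(g["gene"]) for t, g in df.groupby("term")}


def load_value_standard(path: str | Path, sep: str = "\t") -> dict[str, float]:
    """Load a (gene, value) two-column delimited file as gene -> value."""
    df = pd.read_csv(path, sep=sep, header=None, names=["gene", "value"], dtype=str)
    return {g: float(v) for g, v in zip(df["gene"], df["value"])}
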