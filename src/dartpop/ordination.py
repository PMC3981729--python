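"""Jaccard distances, ordination (PCoA / PCA), outlier flagging and
per-marker group association for dominant marker panels.

Jaccard dissimilarity ignores shared absences, which for dominant markers
cannot be told apart from missing data: d = (M01 + M10) / (M01 + M10 + M11)
over markers scored in both genotypes.  PCoA is classical scaling of the
distance matrix; PCA runs on centred (unscaled) 0/1 columns with
band-frequency imputation of missing calls.  The "GLM" confirmation of
group-separating markers reduces, for a binary marker and a binary group
label, to a 2x2 association test: chi-square with continuity correction,
falling back to Fisher's exact test for sparse tables, with
Benjamini-Hochberg q-values across markers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA
from statsmodels.stats.multitest import multipletests

from .io import MISSING, MarkerMatrix

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "jaccard_distance",
    "pcoa",
    "pca",
    "flag_outliers",
    "top_loading_markers",
    "marker_group_association",
]


@dataclass
class DistanceMatrix:
    genotype_ids: list[str]
    values: np.ndarray             # symmetric, zero diagonal, NaN = undefined

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.genotype_ids),) * 2:
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genotype_ids, columns=self.genotype_ids)


@dataclass
class OrdinationResult:
    method: str                    # "PCoA" | "PCA"
    ids: list[str]
    coordinates: np.ndarray        # n x axes
    explained_fraction: np.ndarray
    loadings: np.ndarray | None = None      # markers x axes (PCA only)
    marker_ids: list[str] | None = None


def jaccard_distance(matrix: MarkerMatrix) -> DistanceMatrix:
    """Pairwise Jaccard dissimilarities, complete-case per genotype pair.

    Pairs with no comparable informative marker (denominator zero) get a
    missing (NaN) distance and a warning.
    """
    if matrix.n_genotypes < 2:
        raise ValueError("need at least 2 genotypes")
    present = ((matrix.scores == 1)).astype(float)
    absent = ((matrix.scores == 0)).astype(float)
    m11 = present @ present.T
    m10 = present @ absent.T        # i has band, j does not
    mism = m10 + m10.T
    denom = m11 + mism
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, mism / denom, np.nan)
    np.fill_diagonal(d, 0.0)
    n_undef = int(np.isnan(d[np.triu_indices_from(d, k=1)]).sum())
    if n_undef:
        warnings.warn(f"{n_undef} genotype pair(s) share no informative marker")
    return DistanceMatrix(list(matrix.genotype_ids), d)


def pcoa(dist: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Missing entries are imputed by the mean of the defined off-diagonal
    distances (with a warning).  Negative eigenvalues (non-Euclidean input)
    are dropped from both the axes and the explained-fraction denominator.
    """
    d = dist.values.copy()
    off = ~np.eye(len(d), dtype=bool)
    if np.isnan(d[off]).any():
        fill = np.nanmean(d[off])
        warnings.warn("imputing missing distances by the matrix mean")
        d[np.isnan(d)] = fill
        np.fill_diagonal(d, 0.0)
    d2 = d * d
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    total = evals[pos].sum()
    k = min(n_axes, int(pos.sum()))
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    explained = evals[:k] / total if total > 0 else np.zeros(k)
    return OrdinationResult(
        method="PCoA",
        ids=list(dist.genotype_ids),
        coordinates=coords,
        explained_fraction=explained,
    )


def _impute_band_freq(matrix: MarkerMatrix) -> np.ndarray:
    x = matrix.scores.astype(float)
    x[matrix.scores == MISSING] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)   # all-missing column -> 0
    idx = np.where(np.isnan(x))
    x[idx] = col_mean[idx[1]]
    return x


def pca(matrix: MarkerMatrix, n_axes: int = 2) -> OrdinationResult:
    """PCA of the genotype x marker 0/1 matrix (centred, unscaled columns).

    Missing calls are imputed with the marker's band frequency.  Loadings
    are the principal-axis coefficients per marker; a constant column has
    loading 0 on every axis.
    """
    if matrix.n_genotypes < 2 or matrix.n_markers < 2:
        raise ValueError("need at least 2 genotypes and 2 markers")
    x = _impute_band_freq(matrix)
    k = min(n_axes, matrix.n_genotypes - 1, matrix.n_markers)
    fit = _SkPCA(n_components=k, svd_solver="full").fit(x)
    scores = fit.transform(x)
    return OrdinationResult(
        method="PCA",
        ids=list(matrix.genotype_ids),
        coordinates=scores,
        explained_fraction=fit.explained_variance_ratio_,
        loadings=fit.components_.T,
        marker_ids=list(matrix.marker_ids),
    )


def flag_outliers(
    ord_result: OrdinationResult, k_sd: float = 4.0, n_neighbors: int = 3
) -> list[str]:
    """Flag isolated genotypes on the first two ordination axes.

    A genotype is flagged when the log of its distance to its
    ``n_neighbors``-th nearest neighbour exceeds the panel median of that
    quantity by more than ``k_sd`` robust standard deviations, with the
    spread taken from the right tail ((Q90 - median) / 1.2816, the normal
    consistency factor) because nearest-neighbour distances are
    right-skewed.  Isolation — not distance from the overall centroid — is
    the criterion, so members of a compact minority subpopulation are not
    flagged while a genotype whose assay failed (far from everything) is.
    Removal is left to the caller.
    """
    n = len(ord_result.ids)
    if n < 3:
        raise ValueError("need at least 3 genotypes")
    xy = ord_result.coordinates[:, : min(2, ord_result.coordinates.shape[1])]
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    k = min(n_neighbors, n - 1)
    knn = np.log(np.maximum(np.sort(d, axis=1)[:, k - 1], 1e-300))
    med = np.median(knn)
    spread = (np.quantile(knn, 0.9) - med) / 1.2816
    if spread <= 0:
        return []
    cutoff = med + k_sd * spread
    return [g for g, ki in zip(ord_result.ids, knn) if ki > cutoff]


def top_loading_markers(
    ord_result: OrdinationResult, fraction: float = 0.05, axis: int = 1
) -> pd.DataFrame:
    """Markers with the largest |loading| on a 1-based ordination axis.

    Returns the top ceil(fraction * n_markers) markers with rank and signed
    loading, largest magnitude first.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if ord_result.loadings is None or ord_result.marker_ids is None:
        raise ValueError("ordination result carries no loadings (need PCA)")
    if not 1 <= axis <= ord_result.loadings.shape[1]:
        raise ValueError(f"axis {axis} out of range")
    load = ord_result.loadings[:, axis - 1]
    n_top = math.ceil(fraction * len(load))
    order = np.argsort(-np.abs(load), kind="stable")[:n_top]
    return pd.DataFrame(
        {
            "marker_id": [ord_result.marker_ids[i] for i in order],
            "loading": load[order],
            "rank": np.arange(1, n_top + 1),
        }
    )


def marker_group_association(
    matrix: MarkerMatrix, labels: dict[str, int | str]
) -> pd.DataFrame:
    """Per-marker band x group association for a two-group split.

    Each marker yields a 2x2 table of band presence against group over
    non-missing calls, scored by chi-square with continuity correction, or
    Fisher's exact test when any expected cell is below 5.  Raw p-values and
    Benjamini-Hochberg q-values are reported with the band-frequency
    difference (group A minus group B) as effect direction.
    """
    groups = sorted({labels[g] for g in matrix.genotype_ids}, key=str)
    if len(groups) != 2:
        raise ValueError(
            f"{len(groups)} groups given; this test is two-group only — run "
            "one-vs-rest for multi-group panels"
        )
    lab = np.array([labels[g] == groups[0] for g in matrix.genotype_ids])
    rows = []
    for j, m in enumerate(matrix.marker_ids):
        x = matrix.scores[:, j]
        obs = x != MISSING
        a = int(((x == 1) & lab & obs).sum())
        b = int(((x == 1) & ~lab & obs).sum())
        c = int(((x == 0) & lab & obs).sum())
        d = int(((x == 0) & ~lab & obs).sum())
        table = np.array([[a, b], [c, d]])
        n1, n2 = a + c, b + d
        f1 = a / n1 if n1 else np.nan
        f2 = b / n2 if n2 else np.nan
        if min(a + b, c + d) == 0 or min(n1, n2) == 0:
            p, test = 1.0, "none"
        else:
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            if (expected < 5).any():
                p = float(stats.fisher_exact(table).pvalue)
                test = "fisher"
            else:
                p = float(stats.chi2_contingency(table, correction=True).pvalue)
                test = "chi2"
        rows.append((m, a, b, c, d, f1, f2, (f1 - f2) if n1 and n2 else np.nan, test, p))
    df = pd.DataFrame(
        rows,
        columns=[
            "marker_id", "present_g1", "present_g2", "absent_g1", "absent_g2",
            "freq_g1", "freq_g2", "freq_diff", "test", "p_value",
        ],
    )
    df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df
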