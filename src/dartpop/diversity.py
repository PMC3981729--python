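"""Gene diversity and AMOVA-based differentiation for dominant markers.

Gene diversity per marker is h = 2 f (1 - f) with f the band frequency among
non-missing calls; the reported H is the mean over the marker set.  The
AMOVA partitions squared Euclidean distances between 0/1 band profiles into
among- and within-group components (the standard distance-based
decomposition for binary data), yielding Phi_PT — the dominant-marker
analogue of F_ST — with a label-permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MarkerMatrix

__all__ = [
    "DiversityReport",
    "AmovaResult",
    "gene_diversity",
    "squared_distance_matrix",
    "amova",
    "phi_pt",
    "pairwise_phi",
]


@dataclass
class DiversityReport:
    per_group: pd.DataFrame        # group, n, n_markers, mean_H
    total_H: float
    n_total: int


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    sigma2_among_raw: float        # can be negative; clamped value used for Phi
    sigma2_among: float
    sigma2_within: float
    n0: float
    phi_pt: float                  # from clamped sigma2_among
    phi_pt_raw: float
    percent_among: float
    p_value: float | None
    n_permutations: int


def _group_freqs(scores: np.ndarray) -> np.ndarray:
    obs = scores >= 0
    n = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, ((scores == 1) & obs).sum(axis=0) / np.maximum(n, 1), np.nan)


def gene_diversity(
    matrix: MarkerMatrix, labels: dict[str, int | str] | None = None
) -> DiversityReport:
    """Mean gene diversity H = mean over markers of 2 f (1 - f).

    Computed for the pooled panel and, when labels are given, per group;
    groups of fewer than two genotypes are excluded with a warning.  Markers
    with no non-missing call in a stratum are excluded from that stratum's
    mean.
    """
    f_tot = _group_freqs(matrix.scores)
    total_h = float(np.nanmean(2.0 * f_tot * (1.0 - f_tot)))
    rows = []
    if labels is not None:
        unlabeled = [g for g in matrix.genotype_ids if g not in labels]
        if unlabeled:
            raise ValueError(f"unlabeled genotype(s): {unlabeled[:5]}")
        lab = np.array([labels[g] for g in matrix.genotype_ids], dtype=object)
        for g in sorted(set(lab), key=str):
            sel = lab == g
            if sel.sum() < 2:
                warnings.warn(f"group {g!r} has fewer than 2 genotypes; skipped")
                continue
            f = _group_freqs(matrix.scores[sel])
            rows.append(
                {
                    "group": g,
                    "n": int(sel.sum()),
                    "n_markers": int(np.isfinite(f).sum()),
                    "mean_H": float(np.nanmean(2.0 * f * (1.0 - f))),
                }
            )
    per_group = pd.DataFrame(rows, columns=["group", "n", "n_markers", "mean_H"])
    return DiversityReport(per_group=per_group, total_H=total_h, n_total=matrix.n_genotypes)


def squared_distance_matrix(matrix: MarkerMatrix) -> np.ndarray:
    """Pairwise squared Euclidean distances of 0/1 profiles.

    Missing calls are handled pairwise-complete: the mismatch count over
    markers scored in both genotypes is rescaled by
    (total markers / comparable markers).
    """
    present = (matrix.scores == 1).astype(float)
    absent = (matrix.scores == 0).astype(float)
    obs = (matrix.scores >= 0).astype(float)
    mism = present @ absent.T
    mism = mism + mism.T
    comparable = obs @ obs.T
    if (comparable[~np.eye(len(comparable), dtype=bool)] == 0).any():
        raise ValueError("some genotype pair shares no scored marker")
    return mism * (matrix.n_markers / comparable)


def _ss_within(d2: np.ndarray, lab: np.ndarray, groups: list) -> float:
    ssw = 0.0
    for g in groups:
        sel = lab == g
        ssw += d2[np.ix_(sel, sel)].sum() / (2.0 * sel.sum())
    return ssw


def amova(
    matrix: MarkerMatrix,
    labels: dict[str, int | str],
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """One-level AMOVA on squared profile distances with a permutation test.

    SS_total = sum_{i<j} d²_ij / N; SS_within sums the analogous quantity per
    group; variance components follow the distance-based decomposition with
    the unequal-size coefficient n0 = (N - sum n_g²/N)/(G-1).  Phi_PT is
    sigma²_among / (sigma²_among + sigma²_within) with sigma²_among clamped
    at zero (the raw value is also reported).  p is the +1-corrected
    fraction of label permutations whose (raw) Phi meets or exceeds the
    observed one; ``n_perm = 0`` skips the test (p is None).
    """
    unlabeled = [g for g in matrix.genotype_ids if g not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled genotype(s): {unlabeled[:5]}")
    lab = np.array([labels[g] for g in matrix.genotype_ids], dtype=object)
    groups = sorted(set(lab), key=str)
    sizes = np.array([(lab == g).sum() for g in groups])
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        small = [g for g, s in zip(groups, sizes) if s < 2]
        raise ValueError(f"singleton group(s): {small}")

    d2 = squared_distance_matrix(matrix)
    n = len(lab)
    g_count = len(groups)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, lab, groups)
    ss_among = ss_total - ss_within
    df_among = g_count - 1
    df_within = n - g_count
    sigma_w = ss_within / df_within
    n0 = (n - (sizes**2).sum() / n) / df_among
    sigma_a_raw = (ss_among / df_among - sigma_w) / n0
    sigma_a = max(sigma_a_raw, 0.0)
    phi_raw = sigma_a_raw / (sigma_a_raw + sigma_w)
    phi = sigma_a / (sigma_a + sigma_w) if (sigma_a + sigma_w) > 0 else 0.0

    p_value: float | None = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        codes = np.array([groups.index(v) for v in lab])
        perm_codes = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
        ssw_p = np.zeros(n_perm)
        for gi, size in enumerate(sizes):
            b = (perm_codes == gi).astype(float)
            ssw_p += np.einsum("pi,ij,pj->p", b, d2, b) / (2.0 * size)
        sw = ssw_p / df_within
        sa = ((ss_total - ssw_p) / df_among - sw) / n0
        phi_p = sa / (sa + sw)
        count = int((phi_p >= phi_raw - 1e-12).sum())
        p_value = (1.0 + count) / (1.0 + n_perm)

    return AmovaResult(
        df_among=df_among,
        df_within=df_within,
        ss_among=float(ss_among),
        ss_within=float(ss_within),
        sigma2_among_raw=float(sigma_a_raw),
        sigma2_among=float(sigma_a),
        sigma2_within=float(sigma_w),
        n0=float(n0),
        phi_pt=float(phi),
        phi_pt_raw=float(phi_raw),
        percent_among=float(100.0 * phi),
        p_value=p_value,
        n_permutations=n_perm,
    )


def phi_pt(matrix: MarkerMatrix, labels: dict[str, int | str]) -> float:
    """Point estimate of Phi_PT (no permutation test)."""
    return amova(matrix, labels, n_perm=0).phi_pt


def pairwise_phi(
    matrix: MarkerMatrix,
    labels: dict[str, int | str],
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phi_PT (and p-values) for every group pair; symmetric, zero diagonal."""
    lab = {g: labels[g] for g in matrix.genotype_ids}
    groups = sorted(set(lab.values()), key=str)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    phi = pd.DataFrame(0.0, index=groups, columns=groups)
    pval = pd.DataFrame(np.nan, index=groups, columns=groups)
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            keep = [g for g in matrix.genotype_ids if lab[g] in (ga, gb)]
            sub = matrix.select_genotypes(keep)
            res = amova(sub, lab, n_perm=n_perm, seed=seed)
            phi.loc[ga, gb] = phi.loc[gb, ga] = res.phi_pt
            pval.loc[ga, gb] = pval.loc[gb, ga] = res.p_value
    return phi, pval
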