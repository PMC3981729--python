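"""Intra-chromosomal linkage disequilibrium: pairwise r², permutation
significance, unlinked background threshold, degree-2 loess decay curve.

r² between two dominant markers is the squared Pearson correlation of their
0/1 band vectors over genotypes observed at both loci.  Under the
homozygosity assumption the band vector *is* the allele vector, so this
equals the classical squared allele-frequency correlation
D² / (p_A p_a p_B p_b).  Significance is assessed per pair by permuting one
marker's calls; the background LD level is the 95th percentile of r² among
effectively unlinked pairs (same chromosome, > 50 cM apart); the decay
distance is where a tricube-weighted local quadratic (loess, degree 2)
smooth of the significant pairs first drops to the background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneticMap, MarkerMatrix

__all__ = [
    "LDPairs",
    "LDDecayResult",
    "pair_r2",
    "background_ld",
    "fit_decay",
    "ld_summaries",
    "loess_quadratic",
    "permutation_r2_test",
    "UNLINKED_CM",
]

#: Same-chromosome pairs farther apart than this are treated as unlinked.
UNLINKED_CM: float = 50.0

_PAIR_COLUMNS = [
    "marker_a",
    "marker_b",
    "chromosome",
    "distance_cM",
    "r2",
    "p_perm",
    "significant",
    "unlinked",
]


@dataclass
class LDPairs:
    """All computed intra-chromosomal pairs plus a count of skipped ones."""

    table: pd.DataFrame
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class LDDecayResult:
    background_r2: float
    loess_curve: pd.DataFrame          # distance_cM, r2_fit
    decay_cM: float | None             # None == "no intercept"
    terminal_extent_cM: float
    span: float

    @property
    def no_intercept(self) -> bool:
        return self.decay_cM is None


def _complete_case(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = (xa >= 0) & (xb >= 0)
    return xa[ok].astype(float), xb[ok].astype(float)


def _r2(xa: np.ndarray, xb: np.ndarray) -> float | None:
    """Squared Pearson correlation; None when either vector is constant."""
    va = xa.var()
    vb = xb.var()
    if va == 0.0 or vb == 0.0:
        return None
    cov = ((xa - xa.mean()) * (xb - xb.mean())).mean()
    return float(cov * cov / (va * vb))


def permutation_r2_test(
    xa: np.ndarray,
    xb: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    min_n: int = 4,
) -> tuple[float, float] | None:
    """(r², permutation p) on the complete-case subset, or None when undefined.

    One marker's calls are permuted; because every permutation of a vector
    has the same mean and sum of squares, each permuted r² reduces to a dot
    product, so all ``n_perm`` replicates are evaluated in one matmul.
    p carries the +1 correction: p = (1 + #{r²_perm >= r²_obs}) / (1 + n_perm).
    """
    a, b = _complete_case(np.asarray(xa), np.asarray(xb))
    if a.size < min_n:
        return None
    r2_obs = _r2(a, b)
    if r2_obs is None:
        return None
    ac = a - a.mean()
    bc = b - b.mean()
    ssa = float(ac @ ac)
    ssb = float(bc @ bc)
    perms = rng.permuted(np.tile(ac, (n_perm, 1)), axis=1)
    dots = perms @ bc
    r2_perm = (dots * dots) / (ssa * ssb)
    p = (1.0 + int((r2_perm >= r2_obs - 1e-15).sum())) / (1.0 + n_perm)
    return r2_obs, p


def pair_r2(
    matrix: MarkerMatrix,
    gmap: GeneticMap,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    min_n: int = 4,
) -> LDPairs:
    """r² and permutation significance for every same-chromosome marker pair.

    Distances come from the genetic map; only mapped markers present in the
    matrix are used.  Pairs whose complete-case data are too small or
    monomorphic are skipped and counted.  Each pair draws its permutations
    from a seed derived from the master seed and the two marker indices, so
    results are independent of traversal order.
    """
    col_of = {m: j for j, m in enumerate(matrix.marker_ids)}
    records: list[tuple] = []
    n_skipped = 0
    for chrom, sub in gmap.by_chromosome().items():
        ids = [m for m in sub["marker_id"] if m in col_of]
        pos = {m: p for m, p in zip(sub["marker_id"], sub["position_cM"])}
        for i in range(len(ids)):
            xa = matrix.scores[:, col_of[ids[i]]]
            for j in range(i + 1, len(ids)):
                xb = matrix.scores[:, col_of[ids[j]]]
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, col_of[ids[i]], col_of[ids[j]]])
                )
                res = permutation_r2_test(xa, xb, n_perm, rng, min_n=min_n)
                if res is None:
                    n_skipped += 1
                    continue
                r2, p = res
                d = abs(pos[ids[j]] - pos[ids[i]])
                records.append(
                    (ids[i], ids[j], chrom, d, r2, p, p < alpha, d > UNLINKED_CM)
                )
    table = pd.DataFrame(records, columns=_PAIR_COLUMNS)
    return LDPairs(table=table, n_skipped=n_skipped)


def background_ld(pairs: LDPairs | pd.DataFrame, min_pairs: int = 20) -> float:
    """95th percentile (linear interpolation) of r² among unlinked pairs."""
    table = pairs.table if isinstance(pairs, LDPairs) else pairs
    unlinked = table.loc[table["unlinked"], "r2"].to_numpy()
    if unlinked.size < min_pairs:
        raise ValueError(
            f"only {unlinked.size} unlinked (> {UNLINKED_CM} cM) pairs; "
            "use a longer map or pool chromosomes"
        )
    return float(np.percentile(unlinked, 95))


def loess_quadratic(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    span: float = 0.5,
) -> np.ndarray:
    """Tricube-weighted local quadratic regression evaluated on ``grid``.

    At each grid point the ``ceil(span * n)`` nearest observations get
    tricube weights on distance scaled by the neighbourhood radius, and a
    weighted degree-2 polynomial is fitted; the fitted value at the grid
    point is returned.  Degenerate local fits fall back to the weighted mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points for a local quadratic")
    k = max(3, int(np.ceil(span * n)))
    out = np.empty(grid.size)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    for gi, x0 in enumerate(grid):
        d = np.abs(xs - x0)
        idx = np.argpartition(d, min(k, n) - 1)[:k]
        h = d[idx].max()
        if h == 0.0:
            out[gi] = ys[idx].mean()
            continue
        w = (1.0 - np.minimum(d[idx] / h, 1.0) ** 3) ** 3
        u = xs[idx] - x0
        sw = np.sqrt(w)
        A = np.column_stack([np.ones_like(u), u, u * u]) * sw[:, None]
        b = ys[idx] * sw
        coef, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
        if rank < 3:
            out[gi] = float(np.average(ys[idx], weights=w)) if w.sum() > 0 else ys[idx].mean()
        else:
            out[gi] = coef[0]
    return out


def fit_decay(
    pairs: LDPairs | pd.DataFrame,
    background: float,
    span: float = 0.5,
    grid_step: float = 0.5,
    min_pairs: int = 30,
) -> LDDecayResult:
    """Loess decay curve over significant pairs and its background crossing.

    The degree-2 loess smooth of r² against distance is evaluated on a
    ``grid_step`` cM grid from 0 to the largest pair distance; the decay
    distance is the smallest grid point where the curve is at or below the
    background.  When the curve stays above the background everywhere the
    result records "no intercept" and the curve's terminal extent.
    """
    table = pairs.table if isinstance(pairs, LDPairs) else pairs
    if "significant" in table.columns:
        table = table[table["significant"]]
    if len(table) < min_pairs:
        raise ValueError(f"only {len(table)} significant pairs (< {min_pairs})")
    x = table["distance_cM"].to_numpy(dtype=float)
    y = table["r2"].to_numpy(dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError("all pair distances equal; loess fit is degenerate")
    grid = np.arange(0.0, x.max() + grid_step, grid_step)
    fitted = loess_quadratic(x, y, grid, span=span)
    curve = pd.DataFrame({"distance_cM": grid, "r2_fit": fitted})
    below = np.nonzero(fitted <= background)[0]
    decay = float(grid[below[0]]) if below.size else None
    return LDDecayResult(
        background_r2=float(background),
        loess_curve=curve,
        decay_cM=decay,
        terminal_extent_cM=float(grid[-1]),
        span=span,
    )


def ld_summaries(pairs: LDPairs | pd.DataFrame, gmap: GeneticMap) -> dict[str, pd.DataFrame]:
    """Mean r² per chromosome / genome / whole genome, and adjacent-pair profiles.

    Chromosomes on the map with fewer than two scored markers appear with
    missing means.  The adjacent-pair profile pairs each marker with its map
    successor; the value is plotted at the proximal (smaller-position) locus.
    """
    table = pairs.table if isinstance(pairs, LDPairs) else pairs

    def _stratum(sub: pd.DataFrame) -> dict:
        sig = sub[sub["significant"]]
        return {
            "n_pairs": len(sub),
            "n_significant": len(sig),
            "n_unlinked": int(sub["unlinked"].sum()),
            "mean_r2_all": sub["r2"].mean() if len(sub) else np.nan,
            "mean_r2_significant": sig["r2"].mean() if len(sig) else np.nan,
        }

    chrom_rows = []
    for chrom in sorted(set(gmap.entries["chromosome"])):
        sub = table[table["chromosome"] == chrom]
        chrom_rows.append({"chromosome": chrom, **_stratum(sub)})
    per_chromosome = pd.DataFrame(chrom_rows)

    genome_rows = []
    for g in "ABD":
        sub = table[table["chromosome"].str[-1] == g]
        genome_rows.append({"genome": g, **_stratum(sub)})
    per_genome = pd.DataFrame(genome_rows)

    overall = pd.DataFrame([{"stratum": "whole_genome", **_stratum(table)}])

    pair_index = {}
    for row in table.itertuples(index=False):
        pair_index[(row.marker_a, row.marker_b)] = row.r2
        pair_index[(row.marker_b, row.marker_a)] = row.r2
    adj_rows = []
    for chrom, sub in gmap.by_chromosome().items():
        ids = sub["marker_id"].tolist()
        pos = sub["position_cM"].tolist()
        for a, b, pa in zip(ids[:-1], ids[1:], pos[:-1]):
            r2 = pair_index.get((a, b))
            if r2 is not None:
                adj_rows.append((chrom, a, b, pa, r2))
    adjacent = pd.DataFrame(
        adj_rows, columns=["chromosome", "marker_a", "marker_b", "position_cM", "r2"]
    )
    return {
        "per_chromosome": per_chromosome,
        "per_genome": per_genome,
        "overall": overall,
        "adjacent": adjacent,
    }
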