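"""Bayesian admixture clustering for haploid-scored dominant markers.

The model is the classical admixture mixture: each genotype i has membership
proportions q_i ~ Dirichlet(alpha, ..., alpha) over K source populations,
each population k has a band frequency p_{k,l} ~ Beta(1, 1) at every marker
l, and each observed call x_{i,l} arises from a latent origin
z_{i,l} ~ Categorical(q_i) with x | z=k ~ Bernoulli(p_{k,l}).  Because the
varieties are homozygous, a single Bernoulli draw per genotype per marker is
the full likelihood — no diploid dominance masking is involved; this is the
largest modelling decision in the package and is discussed in the methods
documentation.

Inference is by Gibbs sampling (z, p, q) with a Metropolis random walk on
the shared Dirichlet concentration alpha (uniform prior on (0, 10]).  The
model evidence ln Pr(X|K) is estimated from the recorded post-burn-in data
log-likelihoods as mean - variance/2, and the number of subpopulations is
chosen by the Evanno delta-K statistic over replicate runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import GeneticMap, MarkerMatrix
from .ld import permutation_r2_test

__all__ = [
    "StructureFit",
    "DeltaKTable",
    "run_admixture",
    "select_k_evanno",
    "evanno_table",
    "assign_groups",
    "align_runs",
    "mean_aligned_q",
    "prune_by_ld",
]

_ALPHA_PROPOSAL_SD = 0.25
_ALPHA_MAX = 10.0
_P_EPS = 1e-12


@dataclass
class StructureFit:
    K: int
    genotype_ids: list[str]
    q: np.ndarray                  # genotypes x K, rows sum to 1
    p: np.ndarray                  # K x markers, posterior means
    alpha_trace: np.ndarray
    loglik_samples: np.ndarray
    ln_evidence: float
    seed: int


@dataclass
class DeltaKTable:
    table: pd.DataFrame            # K, n_runs, mean_lnl, sd_lnl, l_prime, l_second, delta_k
    best_k: int | None


def _sample_z(
    x: np.ndarray, mask: np.ndarray, q: np.ndarray, p: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample latent origins for all cells at once; returns (z, lik_cube).

    ``lik_cube[i, k, l]`` is Bernoulli(p_{k,l}) evaluated at x_{i,l}; z at
    missing cells is set to -1 and never used.
    """
    pc = np.clip(p, _P_EPS, 1.0 - _P_EPS)
    lik = np.where(x[:, None, :] == 1, pc[None, :, :], 1.0 - pc[None, :, :])
    w = q[:, :, None] * lik
    c = np.cumsum(w, axis=1)
    u = rng.random((x.shape[0], 1, x.shape[1])) * c[:, -1:, :]
    z = (u > c).sum(axis=1).astype(np.int16)
    z[~mask] = -1
    return z, lik


def _update_alpha(
    alpha: float, q: np.ndarray, rng: np.random.Generator
) -> float:
    n, K = q.shape
    sum_log_q = float(np.log(np.clip(q, 1e-300, None)).sum())

    def log_target(a: float) -> float:
        return n * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * sum_log_q

    prop = alpha + rng.normal(0.0, _ALPHA_PROPOSAL_SD)
    prop = abs(prop)  # reflect at 0
    if prop == 0.0 or prop > _ALPHA_MAX:
        return alpha
    if np.log(rng.random() + 1e-300) < log_target(prop) - log_target(alpha):
        return prop
    return alpha


def run_admixture(
    matrix: MarkerMatrix,
    K: int,
    burnin: int = 9999,
    iters: int = 9999,
    seed: int = 0,
    thin: int = 10,
) -> StructureFit:
    """Fit the K-population admixture model by Gibbs sampling.

    Every ``thin``-th post-burn-in iteration is recorded; reported q and p
    are means over recorded iterations, ln_evidence is mean - var/2 of the
    recorded data log-likelihoods log Pr(X | Q, P) (latent origins summed
    out).  Missing cells contribute no likelihood and are skipped in the
    z updates.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > matrix.n_genotypes:
        raise ValueError(f"K={K} exceeds the {matrix.n_genotypes} genotypes")
    if burnin <= 0 or iters <= 0:
        raise ValueError("burnin and iters must be positive")
    rng = np.random.default_rng(seed)
    x = matrix.scores.astype(np.int8)
    mask = x >= 0
    n, L = x.shape
    is1 = x == 1
    is0 = x == 0

    if K == 1:
        return _run_single_population(matrix, burnin, iters, rng, thin, seed)

    p = rng.random((K, L))
    q = rng.dirichlet(np.ones(K), size=n)
    alpha = 1.0

    q_acc = np.zeros_like(q)
    p_acc = np.zeros_like(p)
    ll_samples: list[float] = []
    alpha_trace: list[float] = []
    n_rec = 0

    total = burnin + iters
    for it in range(total):
        z, lik = _sample_z(x, mask, q, p, rng)
        # p | z, x
        for k in range(K):
            sel = z == k
            n1 = (sel & is1).sum(axis=0)
            n0 = (sel & is0).sum(axis=0)
            p[k] = rng.beta(1.0 + n1, 1.0 + n0)
        # q | z
        counts = np.stack([(z == k).sum(axis=1) for k in range(K)], axis=1)
        g = rng.gamma(alpha + counts)
        q = g / g.sum(axis=1, keepdims=True)
        alpha = _update_alpha(alpha, q, rng)

        if it >= burnin and (it - burnin) % thin == 0:
            # marginal data log-likelihood log Pr(X | Q, P) at the current
            # state (latent origins summed out, as in the classical
            # admixture-model evidence estimate)
            pc = np.clip(p, _P_EPS, 1.0 - _P_EPS)
            lik_now = np.where(x[:, None, :] == 1, pc[None], 1.0 - pc[None])
            mix = np.einsum("ik,ikl->il", q, lik_now)
            ll_samples.append(float(np.log(mix[mask]).sum()))
            alpha_trace.append(alpha)
            q_acc += q
            p_acc += p
            n_rec += 1

    ll = np.asarray(ll_samples)
    ln_ev = float(ll.mean() - ll.var(ddof=1) / 2.0) if ll.size > 1 else float(ll.mean())
    return StructureFit(
        K=K,
        genotype_ids=list(matrix.genotype_ids),
        q=q_acc / n_rec,
        p=p_acc / n_rec,
        alpha_trace=np.asarray(alpha_trace),
        loglik_samples=ll,
        ln_evidence=ln_ev,
        seed=seed,
    )


def _run_single_population(
    matrix: MarkerMatrix,
    burnin: int,
    iters: int,
    rng: np.random.Generator,
    thin: int,
    seed: int,
) -> StructureFit:
    """Degenerate K=1 sampler: only p is latent; q is a column of ones."""
    x = matrix.scores
    mask = x >= 0
    n1 = ((x == 1)).sum(axis=0)
    n0 = ((x == 0)).sum(axis=0)
    L = x.shape[1]
    p_acc = np.zeros(L)
    ll_samples: list[float] = []
    n_rec = 0
    total = burnin + iters
    for it in range(total):
        p = rng.beta(1.0 + n1, 1.0 + n0)
        if it >= burnin and (it - burnin) % thin == 0:
            pc = np.clip(p, _P_EPS, 1.0 - _P_EPS)
            ll = float(n1 @ np.log(pc) + n0 @ np.log(1.0 - pc))
            ll_samples.append(ll)
            p_acc += p
            n_rec += 1
    ll = np.asarray(ll_samples)
    ln_ev = float(ll.mean() - ll.var(ddof=1) / 2.0) if ll.size > 1 else float(ll.mean())
    return StructureFit(
        K=1,
        genotype_ids=list(matrix.genotype_ids),
        q=np.ones((x.shape[0], 1)),
        p=(p_acc / n_rec)[None, :],
        alpha_trace=np.asarray([]),
        loglik_samples=ll,
        ln_evidence=ln_ev,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Evanno delta-K


def evanno_table(lnl_by_k: Mapping[int, Sequence[float]]) -> DeltaKTable:
    """Evanno statistics from replicate ln Pr(X|K) values per K.

    L'(K) = L(K) - L(K-1) and L''(K) = L'(K+1) - L'(K) on the replicate
    means; delta K = |L''(K)| / sd(L(K)) for interior K.  K with zero
    replicate spread get an undefined delta K and are excluded from the
    argmax.
    """
    ks = sorted(lnl_by_k)
    if len(ks) < 3:
        raise ValueError("need runs for at least 3 consecutive K values")
    for k in ks:
        if len(lnl_by_k[k]) < 3:
            raise ValueError(f"need >= 3 replicate runs per K (K={k})")
    mean = {k: float(np.mean(lnl_by_k[k])) for k in ks}
    sd = {k: float(np.std(lnl_by_k[k], ddof=1)) for k in ks}
    rows = []
    for i, k in enumerate(ks):
        lp = mean[k] - mean[ks[i - 1]] if i > 0 else np.nan
        if 0 < i < len(ks) - 1:
            ls = (mean[ks[i + 1]] - mean[k]) - (mean[k] - mean[ks[i - 1]])
            dk = abs(ls) / sd[k] if sd[k] > 0 else np.nan
        else:
            ls, dk = np.nan, np.nan
        rows.append(
            {
                "K": k,
                "n_runs": len(lnl_by_k[k]),
                "mean_lnl": mean[k],
                "sd_lnl": sd[k],
                "l_prime": lp,
                "l_second": ls,
                "delta_k": dk,
            }
        )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["delta_k"])
    best = int(valid.loc[valid["delta_k"].idxmax(), "K"]) if len(valid) else None
    return DeltaKTable(table=table, best_k=best)


def select_k_evanno(fits: Sequence[StructureFit]) -> DeltaKTable:
    """Evanno delta-K from a collection of replicate :class:`StructureFit`."""
    lnl: dict[int, list[float]] = {}
    for fit in fits:
        lnl.setdefault(fit.K, []).append(fit.ln_evidence)
    return evanno_table(lnl)


# ---------------------------------------------------------------------------
# assignment and run alignment


def assign_groups(
    q: np.ndarray,
    genotype_ids: Sequence[str] | None = None,
    admixed_threshold: float = 0.6,
) -> pd.DataFrame:
    """Hard group labels from a membership matrix.

    Label is the argmax membership (ties go to the lowest group index); a
    genotype whose top membership is below ``admixed_threshold`` is flagged
    admixed but still assigned.
    """
    q = np.asarray(q, dtype=float)
    if genotype_ids is None:
        genotype_ids = [f"g{i}" for i in range(q.shape[0])]
    group = q.argmax(axis=1)
    max_q = q.max(axis=1)
    return pd.DataFrame(
        {
            "genotype": list(genotype_ids),
            "group": group,
            "max_membership": max_q,
            "admixed": max_q < admixed_threshold,
        }
    )


def align_runs(fits: Sequence[StructureFit]) -> list[StructureFit]:
    """Resolve label switching across replicate runs of the same K.

    Each run's q columns are greedily matched to the first run's by column
    dot product; q and p are permuted accordingly.  ln_evidence is
    label-invariant and untouched.
    """
    if not fits:
        return []
    ref = fits[0]
    aligned = [ref]
    for fit in fits[1:]:
        if fit.K != ref.K:
            raise ValueError("align_runs requires equal K across runs")
        sim = ref.q.T @ fit.q               # ref-col x run-col overlaps
        perm = np.full(fit.K, -1)
        taken: set[int] = set()
        for _ in range(fit.K):
            i, j = np.unravel_index(np.argmax(sim), sim.shape)
            perm[i] = j
            taken.add(j)
            sim[i, :] = -np.inf
            sim[:, j] = -np.inf
        aligned.append(
            StructureFit(
                K=fit.K,
                genotype_ids=fit.genotype_ids,
                q=fit.q[:, perm],
                p=fit.p[perm, :],
                alpha_trace=fit.alpha_trace,
                loglik_samples=fit.loglik_samples,
                ln_evidence=fit.ln_evidence,
                seed=fit.seed,
            )
        )
    return aligned


def mean_aligned_q(fits: Sequence[StructureFit]) -> np.ndarray:
    """Average membership matrix over label-aligned replicate runs."""
    aligned = align_runs(fits)
    return np.mean([f.q for f in aligned], axis=0)


# ---------------------------------------------------------------------------
# LD-based marker thinning


def prune_by_ld(
    matrix: MarkerMatrix,
    gmap: GeneticMap,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[str]:
    """Greedy LD thinning: keep markers not in significant LD with kept ones.

    Markers are scanned in (chromosome, position) order; a marker enters the
    retained set iff its permutation r² test against every already-retained
    marker on the same chromosome is non-significant at ``alpha``.  Unmapped
    markers are excluded.  Pairs whose r² is undefined (too few shared
    calls, monomorphic overlap) cannot be significant and do not block
    retention.  The per-pair permutation stream is derived from the master
    seed and the two marker column indices, so the test outcome for a pair
    does not depend on scan history.
    """
    if len(gmap) == 0:
        raise ValueError("empty genetic map")
    col_of = {m: j for j, m in enumerate(matrix.marker_ids)}
    retained: list[str] = []
    for chrom, sub in gmap.by_chromosome().items():
        kept_cols: list[int] = []
        for m in sub["marker_id"]:
            if m not in col_of:
                continue
            col = col_of[m]
            x = matrix.scores[:, col]
            ok = True
            for other in kept_cols:
                rng = np.random.default_rng(np.random.SeedSequence([seed, col, other]))
                res = permutation_r2_test(x, matrix.scores[:, other], n_perm, rng)
                if res is not None and res[1] < alpha:
                    ok = False
                    break
            if ok:
                retained.append(m)
                kept_cols.append(col)
    return retained
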