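"""End-to-end orchestration of the panel analysis.

The workflow mirrors a standard diversity study of a dominant-marker panel:
polymorphic-marker filtering, one outlier-screening ordination pass with a
single exclusion round, LD-based marker thinning, admixture clustering over
a K range with Evanno delta-K selection, hard group assignment, PCoA/PCA
with loading-based marker detection and marker-group association, gene
diversity and AMOVA on the thinned set, and LD-decay analysis for the full
panel and per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import diversity, ld, ordination, structure, summary
from .io import GeneticMap, MarkerMatrix, TraitTable, write_results
from .simulate import SimulationConfig, simulate_panel

__all__ = ["PipelineConfig", "PipelineResult", "run_full", "crosstab_trait_groups"]


@dataclass
class PipelineConfig:
    k_min: int = 1
    k_max: int = 10
    reps: int = 10
    burnin: int = 9999
    iters: int = 9999
    prune_alpha: float = 0.05
    prune_n_perm: int = 200
    pca_axes: int = 2
    pca_fraction: float = 0.05
    pca_axis: int = 1
    amova_n_perm: int = 999
    ld_n_perm: int = 1000
    ld_span: float = 0.5
    outlier_k_sd: float = 4.0
    seed: int = 0
    out_dir: str | Path | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    outliers: list[str]
    pruned_marker_ids: list[str]
    delta_k: structure.DeltaKTable
    best_k: int
    labels: dict[str, int]
    amova: diversity.AmovaResult
    diversity: diversity.DiversityReport
    ld_decay: dict[str, ld.LDDecayResult]
    manifest: list[str] = field(default_factory=list)
    report: str = ""


def _polymorphic_subset(matrix: MarkerMatrix) -> MarkerMatrix:
    stats_ = summary.marker_statistics(matrix)
    poly = stats_.per_marker.loc[stats_.per_marker["polymorphic"], "marker_id"]
    return matrix.select_markers(poly.tolist())


def _ld_stage(
    matrix: MarkerMatrix, gmap: GeneticMap, cfg: PipelineConfig, seed: int
) -> tuple[ld.LDPairs, ld.LDDecayResult | None, dict[str, pd.DataFrame]]:
    pairs = ld.pair_r2(matrix, gmap, n_perm=cfg.ld_n_perm, seed=seed)
    decay = None
    try:
        bg = ld.background_ld(pairs)
        decay = ld.fit_decay(pairs, bg, span=cfg.ld_span)
    except ValueError:
        pass  # too few unlinked or significant pairs; summaries still useful
    return pairs, decay, ld.ld_summaries(pairs, gmap)


def run_full(
    matrix: MarkerMatrix,
    gmap: GeneticMap,
    config: PipelineConfig,
    trait: TraitTable | None = None,
) -> PipelineResult:
    """Run the whole analysis; returns all result tables plus a text report.

    Genotypes flagged as ordination outliers in a screening pass are dropped
    once and every stage runs on the retained panel (a single exclusion
    round, not iterated).  The admixture/AMOVA/diversity stages use the
    LD-thinned marker set; ordination and LD analysis use all polymorphic
    mapped markers.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    stage_seeds = {name: int(s) for name, s in zip(
        ("prune", "structure", "amova", "ld", "ld_g"),
        rng.integers(0, 2**31 - 1, size=5),
    )}

    # outlier screening pass on all polymorphic markers
    poly = _polymorphic_subset(matrix)
    screen = ordination.pcoa(ordination.jaccard_distance(poly), n_axes=2)
    outliers = ordination.flag_outliers(screen, k_sd=cfg.outlier_k_sd)
    if outliers:
        keep = [g for g in matrix.genotype_ids if g not in set(outliers)]
        matrix = matrix.select_genotypes(keep)
        poly = _polymorphic_subset(matrix)

    mapped = [m for m in poly.marker_ids if m in gmap]
    poly_mapped = poly.select_markers(mapped)
    gmap_poly = gmap.subset(mapped)

    # LD thinning and admixture clustering
    pruned_ids = structure.prune_by_ld(
        poly_mapped, gmap_poly, alpha=cfg.prune_alpha,
        n_perm=cfg.prune_n_perm, seed=stage_seeds["prune"],
    )
    pruned = poly_mapped.select_markers(pruned_ids)

    fits: list[structure.StructureFit] = []
    run_seed = np.random.default_rng(stage_seeds["structure"])
    for k in range(cfg.k_min, cfg.k_max + 1):
        for _ in range(cfg.reps):
            fits.append(
                structure.run_admixture(
                    pruned, k, burnin=cfg.burnin, iters=cfg.iters,
                    seed=int(run_seed.integers(0, 2**31 - 1)),
                )
            )
    dk = structure.select_k_evanno(fits)
    best_k = dk.best_k if dk.best_k is not None else 2
    best_fits = [f for f in fits if f.K == best_k]
    q_mean = structure.mean_aligned_q(best_fits)
    assignment = structure.assign_groups(q_mean, matrix.genotype_ids)
    labels = dict(zip(assignment["genotype"], assignment["group"].astype(int)))

    # ordination + marker detection on all polymorphic markers
    dist = ordination.jaccard_distance(poly)
    pcoa_res = ordination.pcoa(dist, n_axes=2)
    pca_res = ordination.pca(poly, n_axes=cfg.pca_axes)
    top = ordination.top_loading_markers(pca_res, cfg.pca_fraction, cfg.pca_axis)
    n_groups = len(set(labels.values()))
    assoc = overlap = None
    if n_groups == 2:
        assoc = ordination.marker_group_association(poly, labels)
        n_top = len(top)
        assoc_top = assoc.nsmallest(n_top, "p_value")["marker_id"]
        overlap = len(set(top["marker_id"]) & set(assoc_top)) / n_top if n_top else np.nan

    # diversity / AMOVA on the thinned set
    div = diversity.gene_diversity(pruned, labels)
    amova_res = diversity.amova(
        pruned, labels, n_perm=cfg.amova_n_perm, seed=stage_seeds["amova"]
    )
    phi_mat, phi_p = diversity.pairwise_phi(
        pruned, labels, n_perm=cfg.amova_n_perm, seed=stage_seeds["amova"]
    )

    # LD decay: full panel and per group
    decays: dict[str, ld.LDDecayResult] = {}
    pairs_all, decay_all, summaries = _ld_stage(poly_mapped, gmap_poly, cfg, stage_seeds["ld"])
    if decay_all is not None:
        decays["total"] = decay_all
    group_tables = {}
    for g in sorted(set(labels.values())):
        members = [gid for gid, gg in labels.items() if gg == g]
        if len(members) < 4:
            continue
        sub = poly_mapped.select_genotypes(members)
        _, decay_g, summ_g = _ld_stage(sub, gmap_poly, cfg, stage_seeds["ld_g"] + g)
        if decay_g is not None:
            decays[f"group{g}"] = decay_g
        group_tables[f"ld_summary_group{g}"] = summ_g["overall"]

    # assemble tables
    cov = summary.summarize_coverage(gmap_poly)
    mstats = summary.marker_statistics(poly)
    tables: dict[str, pd.DataFrame] = {
        "q_matrix": pd.DataFrame(
            q_mean, index=matrix.genotype_ids,
            columns=[f"Q{k + 1}" for k in range(best_k)],
        ),
        "group_labels": assignment,
        "delta_k": dk.table,
        "diversity": div.per_group,
        "amova": pd.DataFrame([amova_res.__dict__]),
        "pairwise_phi": phi_mat,
        "pcoa_coords": pd.DataFrame(
            pcoa_res.coordinates, index=pcoa_res.ids,
            columns=[f"axis{i + 1}" for i in range(pcoa_res.coordinates.shape[1])],
        ),
        "pca_coords": pd.DataFrame(
            pca_res.coordinates, index=pca_res.ids,
            columns=[f"PC{i + 1}" for i in range(pca_res.coordinates.shape[1])],
        ),
        "pca_explained": pd.DataFrame({
            "axis": np.arange(1, len(pca_res.explained_fraction) + 1),
            "explained_fraction": pca_res.explained_fraction,
        }),
        "pca_top_loadings": top,
        "marker_summary": mstats.per_marker,
        "coverage_gaps": cov.gaps,
        "ld_pairs": pairs_all.table,
        "ld_summary": summaries["overall"],
        "ld_summary_chromosome": summaries["per_chromosome"],
        "ld_summary_genome": summaries["per_genome"],
        "adjacent_profile": summaries["adjacent"],
        **group_tables,
    }
    if assoc is not None:
        tables["marker_association"] = assoc
    decay_rows = []
    for name, dres in decays.items():
        decay_rows.append(
            {
                "stratum": name,
                "background_r2": dres.background_r2,
                "decay_cM": np.nan if dres.decay_cM is None else dres.decay_cM,
                "no_intercept": dres.no_intercept,
                "terminal_extent_cM": dres.terminal_extent_cM,
                "span": dres.span,
            }
        )
    tables["ld_decay"] = pd.DataFrame(decay_rows)

    if trait is not None:
        ct, ct_p, ct_test = crosstab_trait_groups(labels, trait)
        tables["trait_crosstab"] = ct.assign(p_value=ct_p, test=ct_test)

    sizes = assignment.groupby("group").size().to_dict()
    report_lines = [
        "# Panel analysis report",
        f"- genotypes retained: {matrix.n_genotypes} (outliers removed: {outliers or 'none'})",
        f"- polymorphic markers: {poly.n_markers}; mapped: {poly_mapped.n_markers}; "
        f"LD-thinned set: {pruned.n_markers}",
        f"- delta-K best K: {best_k}; group sizes: "
        + ", ".join(f"Gr{g + 1}={n}" for g, n in sorted(sizes.items())),
        f"- mean gene diversity (pooled): {div.total_H:.3f}",
        f"- Phi_PT: {amova_res.phi_pt:.3f} (p = {amova_res.p_value}); "
        f"{amova_res.percent_among:.1f}% of variance among groups",
        f"- PC1/PC2 explained: "
        + "/".join(f"{100 * v:.1f}%" for v in pca_res.explained_fraction[:2]),
    ]
    if overlap is not None:
        report_lines.append(
            f"- top-loading vs association marker overlap: {100 * overlap:.0f}%"
        )
    for name, dres in decays.items():
        if dres.no_intercept:
            report_lines.append(
                f"- LD decay ({name}): no intercept; loess curve extends to "
                f"{dres.terminal_extent_cM:.0f} cM (background r² {dres.background_r2:.3f})"
            )
        else:
            report_lines.append(
                f"- LD decay ({name}): {dres.decay_cM:.1f} cM "
                f"(background r² {dres.background_r2:.3f})"
            )
    report = "\n".join(report_lines) + "\n"

    manifest: list[str] = []
    if cfg.out_dir is not None:
        manifest = write_results(tables, cfg.out_dir, config=cfg.to_dict(), seed=cfg.seed)
        Path(cfg.out_dir, "report.md").write_text(report)
        manifest.append("report.md")

    return PipelineResult(
        tables=tables,
        outliers=outliers,
        pruned_marker_ids=pruned_ids,
        delta_k=dk,
        best_k=best_k,
        labels=labels,
        amova=amova_res,
        diversity=div,
        ld_decay=decays,
        manifest=manifest,
        report=report,
    )


def crosstab_trait_groups(
    labels: Mapping[str, int | str],
    trait: TraitTable,
    n_mc: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, str]:
    """Group x trait-category contingency table with an association test.

    2x2 tables with small expected counts use Fisher's exact test; larger
    sparse tables use a Monte-Carlo permutation chi-square; otherwise the
    chi-square test (no continuity correction beyond 2x2 defaults) applies.
    """
    observed = trait.observed()
    common = [g for g in observed if g in labels]
    if not common:
        raise ValueError("trait table shares no genotypes with the labels")
    cats = sorted({observed[g] for g in common})
    if len(cats) < 2:
        raise ValueError("need at least 2 trait categories with carriers")
    groups = sorted({labels[g] for g in common}, key=str)
    table = pd.DataFrame(0, index=groups, columns=cats)
    for g in common:
        table.loc[labels[g], observed[g]] += 1
    arr = table.to_numpy()
    expected = np.outer(arr.sum(1), arr.sum(0)) / arr.sum()
    if (expected < 5).any():
        if arr.shape == (2, 2):
            p = float(stats.fisher_exact(arr).pvalue)
            test = "fisher"
        else:
            chi_obs = stats.chi2_contingency(arr, correction=False).statistic
            rng = np.random.default_rng(seed)
            lab_vec = np.array([labels[g] for g in common], dtype=object)
            cat_vec = np.array([observed[g] for g in common], dtype=object)
            count = 0
            for _ in range(n_mc):
                perm = rng.permutation(len(lab_vec))
                t = pd.crosstab(lab_vec, cat_vec[perm]).reindex(
                    index=groups, columns=cats, fill_value=0
                )
                chi = stats.chi2_contingency(t.to_numpy(), correction=False).statistic
                if chi >= chi_obs - 1e-12:
                    count += 1
            p = (1.0 + count) / (1.0 + n_mc)
            test = "mc_chi2"
    else:
        correction = arr.shape == (2, 2)
        p = float(stats.chi2_contingency(arr, correction=correction).pvalue)
        test = "chi2"
    table.index.name = "group"
    return table, p, test
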