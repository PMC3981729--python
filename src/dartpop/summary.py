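"""Descriptive statistics of a dominant-marker panel and its genetic map.

Covers map coverage (per-genome marker counts, inter-marker gaps), per-marker
band frequency, polymorphism, PIC, and rare/private alleles.  PIC for a
dominant biallelic marker under the homozygosity assumption is the gene
diversity 2 f (1 - f), where f is the band frequency among non-missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneticMap, MarkerMatrix

__all__ = [
    "CoverageSummary",
    "MarkerStats",
    "summarize_coverage",
    "marker_statistics",
    "private_markers_by_group",
]


@dataclass
class CoverageSummary:
    genome_counts: dict[str, int]
    genome_fractions: dict[str, float]
    chromosome_counts: dict[str, int]
    gaps: pd.DataFrame            # chromosome, start_cM, end_cM, gap_cM; sorted desc
    n_gaps_gt10: int
    n_gaps_gt50: int
    fraction_intervals_le10: float


@dataclass
class MarkerStats:
    per_marker: pd.DataFrame      # marker_id, n_calls, n_present, band_freq, polymorphic, pic
    rare_markers: list[str]
    private_markers: list[str]
    unassessable_markers: list[str]


def summarize_coverage(gmap: GeneticMap) -> CoverageSummary:
    """Per-genome tallies and inter-marker gap statistics of a genetic map.

    Gaps are successive position differences per chromosome (positions
    sorted); chromosomes with fewer than two markers contribute no gaps.
    """
    if len(gmap) == 0:
        raise ValueError("empty genetic map")
    ent = gmap.entries
    chrom_counts = ent["chromosome"].value_counts().to_dict()
    genomes = ent["chromosome"].str[-1]
    genome_counts = {g: int((genomes == g).sum()) for g in "ABD"}
    total = len(ent)
    genome_fracs = {g: c / total for g, c in genome_counts.items()}

    rows = []
    for chrom, sub in gmap.by_chromosome().items():
        pos = sub["position_cM"].to_numpy()
        for a, b in zip(pos[:-1], pos[1:]):
            rows.append((chrom, float(a), float(b), float(b - a)))
    gaps = pd.DataFrame(rows, columns=["chromosome", "start_cM", "end_cM", "gap_cM"])
    gaps = gaps.sort_values("gap_cM", ascending=False, kind="stable").reset_index(drop=True)
    n_intervals = len(gaps)
    frac_le10 = float((gaps["gap_cM"] <= 10.0).mean()) if n_intervals else float("nan")
    return CoverageSummary(
        genome_counts=genome_counts,
        genome_fractions=genome_fracs,
        chromosome_counts={str(c): int(n) for c, n in chrom_counts.items()},
        gaps=gaps,
        n_gaps_gt10=int((gaps["gap_cM"] > 10.0).sum()),
        n_gaps_gt50=int((gaps["gap_cM"] > 50.0).sum()),
        fraction_intervals_le10=frac_le10,
    )


def marker_statistics(matrix: MarkerMatrix, rare_threshold: int = 5) -> MarkerStats:
    """Band frequency, polymorphism flag, PIC and rare/private lists per marker.

    A marker is *rare* when 1..rare_threshold genotypes carry the band and
    *private* when exactly one does; both are computed on non-missing calls.
    Markers with no non-missing calls are flagged unassessable and excluded.
    """
    if matrix.n_genotypes < 2:
        raise ValueError("need at least 2 genotypes")
    obs = matrix.observed
    n_calls = obs.sum(axis=0)
    n_present = ((matrix.scores == 1) & obs).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_calls > 0, n_present / np.maximum(n_calls, 1), np.nan)
    poly = (n_present > 0) & (n_present < n_calls)
    pic = 2.0 * freq * (1.0 - freq)

    df = pd.DataFrame(
        {
            "marker_id": matrix.marker_ids,
            "n_calls": n_calls,
            "n_present": n_present,
            "band_freq": freq,
            "polymorphic": poly,
            "pic": pic,
        }
    )
    assessable = df["n_calls"] > 0
    unassessable = df.loc[~assessable, "marker_id"].tolist()
    rare = df.loc[
        assessable & (df["n_present"] >= 1) & (df["n_present"] <= rare_threshold),
        "marker_id",
    ].tolist()
    private = df.loc[assessable & (df["n_present"] == 1), "marker_id"].tolist()
    return MarkerStats(
        per_marker=df[assessable].reset_index(drop=True),
        rare_markers=rare,
        private_markers=private,
        unassessable_markers=unassessable,
    )


def private_markers_by_group(
    matrix: MarkerMatrix, labels: dict[str, int | str]
) -> dict:
    """Count markers whose band occurs only in one group.

    A marker is private to group g when at least one genotype carries the
    band and every carrier (among non-missing calls) belongs to g.
    """
    unlabeled = [g for g in matrix.genotype_ids if g not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled genotype(s): {unlabeled[:5]}")
    groups = sorted({labels[g] for g in matrix.genotype_ids}, key=str)
    carrier = (matrix.scores == 1) & matrix.observed
    lab_arr = np.array([labels[g] for g in matrix.genotype_ids], dtype=object)
    counts = {}
    for g in groups:
        in_g = lab_arr == g
        carried = carrier.any(axis=0)
        only_g = carried & ~carrier[~in_g].any(axis=0)
        counts[g] = int(only_g.sum())
    return counts
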