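"""Synthetic dominant-marker panels with controlled population structure.

Two generators are provided.  :func:`simulate_panel` draws a panel of
homozygous (haploid-scored) genotypes from the Balding-Nichols F-model:
each marker has an ancestral band frequency, each subpopulation perturbs it
with a Beta distribution whose variance is set by ``fst``, and each genotype
is a Bernoulli draw from its group's frequency.  :func:`simulate_ld_block`
instead generates distance-dependent linkage along a chromosome with a
stationary two-state Markov walk, as a controlled fixture for the LD-decay
estimator; it is a testing device, not a model of real haplotype structure.

The default configuration emulates the kind of panel this pipeline targets:
92 winter-wheat genotypes in two subpopulations of 26 and 66, ~1,400 mapped
dominant markers spread over 21 chromosomes with more markers on the B than
the A than the D genome, genome-wide differentiation F_ST = 0.13, one
strongly differentiated block on chromosome 2D (a dwarfing-locus analogue),
one >50 cM map gap on 4D, and a few percent missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import CHROMOSOMES, MISSING, GeneticMap, MarkerMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticPanel",
    "default_config",
    "simulate_panel",
    "simulate_ld_block",
    "ld_decay_rate",
    "expected_decay_distance",
]


class ConfigError(ValueError):
    """Raised for an inconsistent simulation configuration."""


@dataclass
class SelectedBlock:
    """A chromosome interval whose markers get fixed per-group band frequencies."""

    chromosome: str
    start_cM: float
    end_cM: float
    group_frequencies: tuple[float, ...]


@dataclass
class SimulationConfig:
    group_sizes: tuple[int, ...] = (26, 66)
    markers_per_chromosome: Mapping[str, int] = field(default_factory=dict)
    chromosome_lengths_cM: Mapping[str, float] = field(default_factory=dict)
    fst: float = 0.13
    selected_block: SelectedBlock | None = None
    missing_rate: float = 0.03
    seed: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    def validate(self) -> None:
        if sum(self.group_sizes) < 2:
            raise ConfigError("need at least 2 genotypes in total")
        if not 0.0 <= self.fst < 1.0:
            raise ConfigError("fst must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        for chrom in self.markers_per_chromosome:
            if chrom not in CHROMOSOMES:
                raise ConfigError(f"unknown chromosome {chrom!r}")
        blk = self.selected_block
        if blk is not None:
            if len(blk.group_frequencies) != self.n_groups:
                raise ConfigError("block needs one band frequency per group")
            if any(not 0.0 <= f <= 1.0 for f in blk.group_frequencies):
                raise ConfigError("block group frequencies must lie in [0, 1]")
            length = self.chromosome_lengths_cM.get(blk.chromosome, 0.0)
            if not 0.0 <= blk.start_cM <= blk.end_cM <= length:
                raise ConfigError("block interval must lie within its chromosome")


@dataclass
class SyntheticPanel:
    """A simulated panel together with its generating truth."""

    matrix: MarkerMatrix
    map: GeneticMap
    truth_labels: dict[str, int]
    truth_frequencies: np.ndarray  # markers x groups


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-scale default: 26+66 genotypes, ~1,400 markers, F_ST 0.13.

    Per-genome marker totals follow the B > A > D asymmetry typical of wheat
    DArT maps (66/chromosome on A, 96 on B, 38 on D -> 33%/48%/19% of 1,400),
    chromosomes are 150 cM, and 4D carries a 67 cM marker desert.  The 2D
    block at 10-30 cM gets group band frequencies (0.9, 0.1).
    """
    per_genome = {"A": 66, "B": 96, "D": 38}
    markers = {c: per_genome[c[-1]] for c in CHROMOSOMES}
    lengths = {c: 150.0 for c in CHROMOSOMES}
    cfg = SimulationConfig(
        markers_per_chromosome=markers,
        chromosome_lengths_cM=lengths,
        selected_block=SelectedBlock("2D", 10.0, 30.0, (0.9, 0.1)),
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def _positions_for_chromosome(
    chrom: str, count: int, length: float, rng: np.random.Generator
) -> np.ndarray:
    if chrom == "4D" and length > 110.0 and count >= 2:
        # leave a 67 cM desert in the middle of 4D
        lo, hi = 40.0, 107.0
        left = max(1, int(round(count * lo / (length - (hi - lo)))))
        pos = np.concatenate(
            [
                rng.uniform(0.0, lo, size=left),
                rng.uniform(hi, length, size=count - left),
            ]
        )
    else:
        pos = rng.uniform(0.0, length, size=count)
    return np.sort(pos)


def _build_map(config: SimulationConfig, rng: np.random.Generator) -> GeneticMap:
    rows = []
    for chrom in CHROMOSOMES:
        count = int(config.markers_per_chromosome.get(chrom, 0))
        if count == 0:
            continue
        length = float(config.chromosome_lengths_cM.get(chrom, 100.0))
        for k, pos in enumerate(_positions_for_chromosome(chrom, count, length, rng)):
            rows.append((f"m_{chrom}_{k:04d}", chrom, round(float(pos), 4)))
    import pandas as pd

    return GeneticMap(
        pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_cM"])
    )


def _apply_missing(
    scores: np.ndarray, missing_rate: float, rng: np.random.Generator
) -> np.ndarray:
    if missing_rate > 0:
        mask = rng.random(scores.shape) < missing_rate
        scores = scores.copy()
        scores[mask] = MISSING
    return scores


def simulate_panel(config: SimulationConfig) -> SyntheticPanel:
    """Draw a Balding-Nichols panel of dominant markers.

    For each marker an ancestral band frequency ``p ~ U(0.05, 0.95)`` is
    drawn; each group's frequency comes from ``Beta`` with mean ``p`` and
    variance ``p (1-p) fst`` (``fst = 0`` collapses to identical group
    frequencies).  Band calls are haploid Bernoulli draws; markers inside the
    selected block override group frequencies with the configured values;
    missing calls are dropped in independently at ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    map_rng, freq_rng, geno_rng, miss_rng = rng.spawn(4)

    gmap = _build_map(config, map_rng)
    n_markers = len(gmap)
    n_groups = config.n_groups

    p_anc = freq_rng.uniform(0.05, 0.95, size=n_markers)
    if config.fst > 0:
        scale = (1.0 - config.fst) / config.fst
        freqs = freq_rng.beta(
            p_anc[:, None] * scale, (1.0 - p_anc[:, None]) * scale,
            size=(n_markers, n_groups),
        )
    else:
        freqs = np.repeat(p_anc[:, None], n_groups, axis=1)

    blk = config.selected_block
    if blk is not None:
        ent = gmap.entries
        in_block = (
            (ent["chromosome"] == blk.chromosome)
            & (ent["position_cM"] >= blk.start_cM)
            & (ent["position_cM"] <= blk.end_cM)
        ).to_numpy()
        freqs[in_block] = np.asarray(blk.group_frequencies)[None, :]

    group_of = np.repeat(np.arange(n_groups), config.group_sizes)
    n = group_of.size
    scores = (geno_rng.random((n, n_markers)) < freqs[:, group_of].T).astype(np.int8)
    scores = _apply_missing(scores, config.missing_rate, miss_rng)

    genotype_ids = [f"g{i:03d}" for i in range(n)]
    matrix = MarkerMatrix(genotype_ids, gmap.marker_ids, scores)
    labels = {g: int(k) for g, k in zip(genotype_ids, group_of)}
    return SyntheticPanel(matrix, gmap, labels, freqs)


# ---------------------------------------------------------------------------
# LD fixture


def ld_decay_rate(block_r2: float, reference_cM: float = 10.0) -> float:
    """Exponential rate c such that expected r² at distance d is exp(-c d).

    Calibrated so that r² equals ``block_r2`` at ``reference_cM``.  For the
    symmetric two-state walk used below, state correlation at distance d is
    exp(-2 theta d), hence r² = exp(-4 theta d) and c = 4 theta.
    """
    if not 0.0 < block_r2 <= 1.0:
        raise ConfigError("block_r2 must be in (0, 1]")
    c = -np.log(block_r2) / reference_cM
    if not np.isfinite(c):
        raise ConfigError("non-finite LD calibration")
    return float(c)


def expected_decay_distance(c: float, background_r2: float, n_genotypes: int) -> float:
    """Distance where the expected *sample* r² falls to the background level.

    The sample r² of two weakly correlated binary vectors is inflated by
    roughly (1 - rho²)² / n, so the crossing solves
    exp(-c d) + 1/n = background (no solution -> inf).
    """
    target = background_r2 - 1.0 / n_genotypes
    if target <= 0 or c <= 0:
        return float("inf")
    return float(-np.log(target) / c)


def simulate_ld_block(
    config: SimulationConfig,
    block_r2: float,
    reference_cM: float = 10.0,
    switch_probability: float | None = None,
) -> SyntheticPanel:
    """Generate distance-dependent LD with a stationary two-state Markov walk.

    Along each chromosome (markers in map order), a genotype's band at the
    first marker is Bernoulli(1/2); at each subsequent marker the state flips
    with probability ``(1 - exp(-2 theta d)) / 2`` for inter-marker distance
    ``d``, giving expected r² ≈ exp(-c d) with ``c = 4 theta`` calibrated
    from ``block_r2`` at ``reference_cM``.  Passing ``switch_probability``
    overrides the calibration with a fixed per-step flip probability.

    All genotypes are independent walks, so the panel carries no group
    structure regardless of ``config.group_sizes``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    map_rng, walk_rng, miss_rng = rng.spawn(3)
    gmap = _build_map(config, map_rng)
    n = sum(config.group_sizes)

    theta = None
    if switch_probability is None:
        theta = ld_decay_rate(block_r2, reference_cM) / 4.0

    cols: list[np.ndarray] = []
    marker_order: list[str] = []
    for chrom, sub in gmap.by_chromosome().items():
        pos = sub["position_cM"].to_numpy()
        state = (walk_rng.random(n) < 0.5).astype(np.int8)
        cols.append(state.copy())
        marker_order.append(sub["marker_id"].iloc[0])
        for j in range(1, len(pos)):
            d = pos[j] - pos[j - 1]
            if switch_probability is not None:
                flip_p = switch_probability
            else:
                flip_p = 0.5 * (1.0 - np.exp(-2.0 * theta * d))
            flips = walk_rng.random(n) < flip_p
            state = np.where(flips, 1 - state, state).astype(np.int8)
            cols.append(state.copy())
            marker_order.append(sub["marker_id"].iloc[j])
    scores = np.column_stack(cols)
    scores = _apply_missing(scores, config.missing_rate, miss_rng)

    genotype_ids = [f"g{i:03d}" for i in range(n)]
    matrix = MarkerMatrix(genotype_ids, marker_order, scores)
    gmap = gmap.subset(marker_order)
    labels = {g: 0 for g in genotype_ids}
    n_markers = len(marker_order)
    freqs = np.full((n_markers, 1), 0.5)
    return SyntheticPanel(matrix, gmap, labels, freqs)
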