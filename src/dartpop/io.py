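"""Reading, writing and validation of the tabular formats the pipeline touches.

Dominant-marker score sheets come as wide tables (genotypes x markers) of
presence/absence calls with assorted missing-value spellings; genetic maps are
long tables of marker, chromosome, position (cM).  Everything is normalised
into three domain containers: :class:`MarkerMatrix`, :class:`GeneticMap` and
:class:`TraitTable`.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "CHROMOSOMES",
    "FormatError",
    "MarkerMatrix",
    "GeneticMap",
    "TraitTable",
    "read_marker_table",
    "write_marker_table",
    "read_map_table",
    "write_map_table",
    "write_results",
]

#: Integer code for a missing call in ``MarkerMatrix.scores``.
MISSING: int = -1

#: The 21 bread-wheat chromosome names, grouped by genome.
CHROMOSOMES: tuple[str, ...] = tuple(f"{i}{g}" for g in "ABD" for i in range(1, 8))

_PRESENT_TOKENS = {"1"}
_ABSENT_TOKENS = {"0"}
_MISSING_TOKENS = {"x", "-", "na", "", "nan"}


class FormatError(ValueError):
    """Raised when an input table violates the expected format."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class MarkerMatrix:
    """Genotypes x markers presence/absence/missing score matrix.

    ``scores`` holds one row per genotype and one column per marker with
    values 1 (band present), 0 (band absent) or :data:`MISSING`.  Varieties
    are assumed homozygous, so a single band call per genotype per marker is
    the complete score.
    """

    genotype_ids: list[str]
    marker_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int8)
        if self.scores.ndim != 2:
            raise FormatError("scores must be a 2-D matrix")
        n, m = self.scores.shape
        if n != len(self.genotype_ids):
            raise FormatError(
                f"{n} score rows but {len(self.genotype_ids)} genotype ids"
            )
        if m != len(self.marker_ids):
            raise FormatError(f"{m} score columns but {len(self.marker_ids)} marker ids")
        _check_unique(self.genotype_ids, "genotype")
        _check_unique(self.marker_ids, "marker")
        bad = ~np.isin(self.scores, (0, 1, MISSING))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"invalid score {self.scores[i, j]} at genotype "
                f"{self.genotype_ids[i]!r}, marker {self.marker_ids[j]!r}"
            )

    # -- convenience ----------------------------------------------------
    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.scores != MISSING

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, index=self.genotype_ids, columns=self.marker_ids)
        df.index.name = "genotype"
        return df

    def select_markers(self, marker_ids: Iterable[str]) -> "MarkerMatrix":
        wanted = list(marker_ids)
        pos = {m: j for j, m in enumerate(self.marker_ids)}
        missing = [m for m in wanted if m not in pos]
        if missing:
            raise KeyError(f"unknown marker ids: {missing[:5]}")
        cols = [pos[m] for m in wanted]
        return MarkerMatrix(list(self.genotype_ids), wanted, self.scores[:, cols])

    def select_genotypes(self, genotype_ids: Iterable[str]) -> "MarkerMatrix":
        wanted = list(genotype_ids)
        pos = {g: i for i, g in enumerate(self.genotype_ids)}
        missing = [g for g in wanted if g not in pos]
        if missing:
            raise KeyError(f"unknown genotype ids: {missing[:5]}")
        rows = [pos[g] for g in wanted]
        return MarkerMatrix(wanted, list(self.marker_ids), self.scores[rows])


@dataclass
class GeneticMap:
    """Marker -> (chromosome, position in cM) lookup.

    Chromosome names are validated against the 21-name wheat alphabet
    (1A..7D).  The map may cover only a subset of a panel's markers.
    """

    entries: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.entries)
        required = {"marker_id", "chromosome", "position_cM"}
        if not required.issubset(df.columns):
            raise FormatError(f"map table needs columns {sorted(required)}")
        df = df[["marker_id", "chromosome", "position_cM"]].copy()
        df["marker_id"] = df["marker_id"].astype(str)
        df["chromosome"] = df["chromosome"].astype(str)
        df["position_cM"] = df["position_cM"].astype(float)
        if df["marker_id"].duplicated().any():
            dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise FormatError(f"marker {dup!r} mapped more than once")
        unknown = set(df["chromosome"]) - set(CHROMOSOMES)
        if unknown:
            raise FormatError(f"unknown chromosome label(s): {sorted(unknown)}")
        if not np.isfinite(df["position_cM"]).all() or (df["position_cM"] < 0).any():
            raise FormatError("map positions must be finite and non-negative")
        self.entries = df.reset_index(drop=True)

    @staticmethod
    def genome(chromosome: str) -> str:
        """Genome letter (A, B or D) of a chromosome name."""
        return chromosome[-1]

    @property
    def marker_ids(self) -> list[str]:
        return self.entries["marker_id"].tolist()

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in set(self.entries["marker_id"])

    def position(self, marker_id: str) -> tuple[str, float]:
        row = self.entries.loc[self.entries["marker_id"] == marker_id]
        if row.empty:
            raise KeyError(marker_id)
        r = row.iloc[0]
        return str(r["chromosome"]), float(r["position_cM"])

    def subset(self, marker_ids: Iterable[str]) -> "GeneticMap":
        wanted = set(marker_ids)
        return GeneticMap(self.entries[self.entries["marker_id"].isin(wanted)])

    def by_chromosome(self) -> dict[str, pd.DataFrame]:
        """Chromosome -> entries sorted by position (stable on ties)."""
        out: dict[str, pd.DataFrame] = {}
        for chrom, sub in self.entries.groupby("chromosome", sort=True):
            out[str(chrom)] = sub.sort_values(
                "position_cM", kind="stable"
            ).reset_index(drop=True)
        return out


@dataclass
class TraitTable:
    """Genotype -> categorical trait label (e.g. a diagnostic band size class)."""

    labels: dict[str, str | None]
    alphabet: tuple[str, ...]

    def __post_init__(self) -> None:
        allowed = set(self.alphabet)
        for g, lab in self.labels.items():
            if lab is not None and lab not in allowed:
                raise FormatError(
                    f"trait label {lab!r} for genotype {g!r} outside alphabet {sorted(allowed)}"
                )

    def observed(self) -> dict[str, str]:
        return {g: v for g, v in self.labels.items() if v is not None}


# ---------------------------------------------------------------------------
# readers / writers


def _decode_cell(token: str, row: str, col: str) -> int:
    t = token.strip().lower()
    if t in _PRESENT_TOKENS:
        return 1
    if t in _ABSENT_TOKENS:
        return 0
    if t in _MISSING_TOKENS:
        return MISSING
    raise FormatError(
        f"invalid score {token!r} at genotype {row!r}, marker {col!r} "
        "(expected 0, 1, X, -, NA or empty)"
    )


def read_marker_table(
    path: str | Path,
    dialect: str = "wide_tsv",
    transpose: bool = False,
) -> MarkerMatrix:
    """Read a wide score sheet into a :class:`MarkerMatrix`.

    The header row carries marker ids and the first column genotype ids
    (swapped when ``transpose`` is set, for sheets exported markers-as-rows).
    Cells may be ``0``, ``1`` or any of the missing spellings ``X``, ``-``,
    ``NA``, empty.
    """
    sep = {"wide_tsv": "\t", "wide_csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    _check_unique(header, "marker" if not transpose else "genotype")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if transpose:
        df = df.T
    genotype_ids = [str(g) for g in df.index]
    marker_ids = [str(m) for m in df.columns]
    _check_unique(genotype_ids, "genotype")
    _check_unique(marker_ids, "marker")
    scores = np.empty(df.shape, dtype=np.int8)
    values = df.to_numpy(dtype=str)
    for i, g in enumerate(genotype_ids):
        for j, m in enumerate(marker_ids):
            scores[i, j] = _decode_cell(values[i, j], g, m)
    return MarkerMatrix(genotype_ids, marker_ids, scores)


def write_marker_table(matrix: MarkerMatrix, path: str | Path, dialect: str = "wide_tsv") -> None:
    """Write a score sheet readable by :func:`read_marker_table` (missing as ``X``)."""
    sep = {"wide_tsv": "\t", "wide_csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = matrix.to_dataframe().astype(object)
    df = df.where(df != MISSING, "X")
    df.to_csv(path, sep=sep)


def read_map_table(path: str | Path, sep: str | None = None) -> GeneticMap:
    """Read a marker_id / chromosome / position_cM table into a :class:`GeneticMap`."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"marker_id": str, "chromosome": str})
    return GeneticMap(df)


def write_map_table(gmap: GeneticMap, path: str | Path, sep: str = "\t") -> None:
    gmap.entries.to_csv(path, sep=sep, index=False)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> list[str]:
    """Write one TSV per result table plus a ``run_log.txt`` with config and seed.

    Returns the manifest (list of file names written).  Floats are printed
    with ``repr`` round-tripping precision so identical results are
    byte-identical across runs.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        manifest: list[str] = []
        for name, table in tables.items():
            fname = f"{name}.tsv"
            table.to_csv(out / fname, sep="\t", float_format="%.12g")
            manifest.append(fname)
        log_lines = [f"seed: {seed}"]
        for key, value in sorted((config or {}).items()):
            log_lines.append(f"{key}: {value}")
        log_lines.append(f"tables: {', '.join(manifest) if manifest else '(none)'}")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        manifest.append("run_log.txt")
    except OSError as exc:
        raise OSError(f"cannot write results to {out}: {exc}") from exc
    return manifest


def _timestamp() -> str:  # pragma: no cover - used by CLI logging only
    return datetime.datetime.now().isoformat(timespec="seconds")
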