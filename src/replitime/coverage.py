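"""Sliding-window read quantification and depth normalization.

The genome is tiled into fixed-size windows (default 100 kb) advanced by a
fixed step (default 10 kb, i.e. overlapping windows); reads passing the
mapping-quality filter (MAPQ > 10, strict) are counted into every window
containing their position, and counts are converted to reads-per-million
(RPM) using the per-sample retained-read total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeDefinition
from .simulate import ReadSet

logger = logging.getLogger(__name__)


@dataclass(eq=False, frozen=True)
class WindowGrid:
    """Ordered fixed-size windows over a genome.

    Windows on each chromosome start at ``0, step, 2*step, ...`` for as long
    as ``start + size <= chromosome length``; trailing partial windows are
    dropped so every window has exactly ``size`` bp.
    """

    size: int
    step: int
    windows: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self) -> None:
        if not (self.size >= self.step > 0):
            raise ValueError("window size must satisfy size >= step > 0")
        w = self.windows
        if not {"chrom", "start", "end"}.issubset(w.columns):
            raise ValueError("windows frame needs chrom/start/end columns")
        if len(w) and ((w["end"] - w["start"]) != self.size).any():
            raise ValueError("all windows must have length == size")

    def __len__(self) -> int:
        return len(self.windows)

    def __eq__(self, other) -> bool:
        if not isinstance(other, WindowGrid):
            return NotImplemented
        return (
            self.size == other.size
            and self.step == other.step
            and len(self.windows) == len(other.windows)
            and self.windows[["chrom", "start"]].equals(
                other.windows[["chrom", "start"]].set_axis(self.windows.index)
            )
        )

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.windows["start"] + self.windows["end"]) // 2).to_numpy()

    def chrom_rows(self, chrom: str) -> slice:
        """Row range of a chromosome's windows (windows are chrom-contiguous)."""
        idx = np.flatnonzero((self.windows["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    @property
    def chrom_extents(self) -> dict:
        """chrom -> furthest covered coordinate (max window end)."""
        if not len(self.windows):
            return {}
        return self.windows.groupby("chrom", sort=False)["end"].max().to_dict()


def make_windows(genome: GenomeDefinition, size: int = 100_000, step: int = 10_000) -> WindowGrid:
    """Tile every chromosome with sliding windows.

    A chromosome shorter than ``size`` contributes zero windows (not an
    error).  Ordering is deterministic: genome chromosome order, then start.
    """
    if not (size >= step > 0):
        raise ValueError("window size must satisfy size >= step > 0")
    chroms, starts = [], []
    for name, length in genome.chromosomes:
        n = (length - size) // step + 1 if length >= size else 0
        if n > 0:
            starts.append(np.arange(n, dtype=np.int64) * step)
            chroms.append(np.full(n, name, dtype=object))
    if chroms:
        start = np.concatenate(starts)
        windows = pd.DataFrame(
            {"chrom": np.concatenate(chroms), "start": start, "end": start + size}
        )
    else:
        windows = pd.DataFrame(
            {"chrom": pd.Series(dtype=object),
             "start": pd.Series(dtype=np.int64),
             "end": pd.Series(dtype=np.int64)}
        )
    return WindowGrid(size, step, windows)


@dataclass
class CountColumn:
    """Per-window counts for one sample plus filter bookkeeping."""

    counts: np.ndarray
    retained: int
    skipped: int


def count_reads(
    reads: ReadSet,
    grid: WindowGrid,
    mapq_min: int = 10,
    inclusive: bool = False,
) -> CountColumn:
    """Count retained reads into every overlapping window.

    A read is a point at its position ``p`` and contributes to each window
    with ``start <= p < end`` (overlapping windows each count it).  Reads
    with ``mapq <= mapq_min`` are excluded from counts and from the retained
    total (``inclusive=True`` relaxes the filter to ``mapq >= mapq_min``).
    Reads on chromosomes absent from the grid are skipped with a logged count.
    """
    rec = reads.records
    keep = rec["mapq"].to_numpy() >= mapq_min if inclusive else rec["mapq"].to_numpy() > mapq_min
    rec = rec.loc[keep]
    retained = int(len(rec))
    counts = np.zeros(len(grid), dtype=np.int64)
    grid_chroms = set(grid.windows["chrom"].unique())
    skipped = 0
    for chrom, sub in rec.groupby("chrom", sort=False):
        if chrom not in grid_chroms:
            skipped += len(sub)
            continue
        rows = grid.chrom_rows(chrom)
        pos = np.sort(sub["pos"].to_numpy())
        starts = grid.windows["start"].to_numpy()[rows]
        counts[rows] = (
            np.searchsorted(pos, starts + grid.size, side="left")
            - np.searchsorted(pos, starts, side="left")
        )
    if skipped:
        logger.warning(
            "sample %s: skipped %d reads on chromosomes absent from the grid",
            reads.sample_id, skipped,
        )
    return CountColumn(counts, retained, skipped)


def rpm_normalize(counts: np.ndarray, total: int) -> np.ndarray:
    """Reads-per-million: ``count * 1e6 / total retained reads``."""
    if total <= 0:
        raise ValueError("cannot RPM-normalize with zero retained reads")
    return np.asarray(counts, dtype=float) * 1e6 / total


@dataclass(eq=False)
class CoverageTable:
    """Window x sample read counts with per-sample metadata.

    ``counts`` columns are sample ids; ``meta`` is indexed by sample id with
    columns condition / phase / replicate / retained / skipped.  ``rpm``
    divides each column by its retained total (x 1e6).
    """

    grid: WindowGrid
    counts: pd.DataFrame
    meta: pd.DataFrame

    @classmethod
    def from_read_sets(
        cls,
        read_sets: Iterable[ReadSet],
        grid: WindowGrid,
        mapq_min: int = 10,
        inclusive: bool = False,
    ) -> "CoverageTable":
        cols, meta_rows = {}, []
        for rs in read_sets:
            if rs.sample_id in cols:
                raise ValueError(f"duplicate sample id {rs.sample_id!r}")
            col = count_reads(rs, grid, mapq_min=mapq_min, inclusive=inclusive)
            cols[rs.sample_id] = col.counts
            meta_rows.append(
                {
                    "sample": rs.sample_id,
                    "condition": rs.condition,
                    "phase": rs.phase,
                    "replicate": rs.replicate,
                    "retained": col.retained,
                    "skipped": col.skipped,
                }
            )
        meta = pd.DataFrame(meta_rows).set_index("sample")
        return cls(grid, pd.DataFrame(cols), meta)

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    def samples_where(self, phase: Optional[str] = None, condition: Optional[str] = None) -> list:
        m = self.meta
        sel = pd.Series(True, index=m.index)
        if phase is not None:
            sel &= m["phase"] == phase
        if condition is not None:
            sel &= m["condition"] == condition
        return list(m.index[sel])

    @property
    def rpm(self) -> pd.DataFrame:
        out = {}
        for s in self.counts.columns:
            out[s] = rpm_normalize(self.counts[s].to_numpy(), int(self.meta.loc[s, "retained"]))
        return pd.DataFrame(out, index=self.counts.index)


def coverage_ratio(
    table_a: CoverageTable,
    table_b: CoverageTable,
    pseudo: float = 0.01,
    samples_a: Optional[Sequence[str]] = None,
    samples_b: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Per-window log2 RPM ratio between two coverage tables.

    RPM is averaged over the selected samples (all, by default) on each side;
    the pseudo-count keeps zero-coverage windows finite.  Used for
    copy-number comparisons between two S fractions, e.g. to assess
    underreplication.
    """
    if table_a.grid != table_b.grid:
        raise ValueError("coverage tables are on different window grids")
    rpm_a = table_a.rpm[list(samples_a) if samples_a else table_a.samples].mean(axis=1)
    rpm_b = table_b.rpm[list(samples_b) if samples_b else table_b.samples].mean(axis=1)
    return np.log2((rpm_a.to_numpy() + pseudo) / (rpm_b.to_numpy() + pseudo))


def windows_in_annotation(
    grid: WindowGrid,
    genome: GenomeDefinition,
    label: str,
    min_frac: float = 0.5,
) -> np.ndarray:
    """Boolean mask of windows with >= ``min_frac`` of their length inside
    the (merged) annotation intervals of ``label``."""
    intervals = genome.annotation(label)
    if not intervals:
        raise ValueError(f"annotation {label!r} is empty")
    mask = np.zeros(len(grid), dtype=bool)
    w = grid.windows
    for chrom in w["chrom"].unique():
        rows = grid.chrom_rows(chrom)
        ivs = [(s, e) for c, s, e in intervals if c == chrom]
        if not ivs:
            continue
        starts = w["start"].to_numpy()[rows]
        ends = w["end"].to_numpy()[rows]
        overlap = np.zeros(len(starts), dtype=np.int64)
        for s, e in ivs:
            overlap += np.clip(np.minimum(ends, e) - np.maximum(starts, s), 0, None)
        mask[rows] = overlap >= min_frac * grid.size
    return mask
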