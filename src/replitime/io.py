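"""Plain-text file formats: chrom.sizes, BED, bedGraph, TSV.

All coordinates are 0-based half-open.  Writers can prepend ``#`` header
lines (version / config hash / thresholds); readers skip them.  Reading
then writing canonical records round-trips exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from . import __version__
from .coverage import WindowGrid
from .genome import GenomeDefinition
from .simulate import ReadSet

PathLike = Union[str, Path]


def output_header(**fields) -> str:
    parts = [f"replitime v{__version__}"] + [f"{k}={v}" for k, v in fields.items()]
    return "# " + " ".join(parts)


# -- chrom.sizes -----------------------------------------------------------

def read_chrom_sizes(path: PathLike) -> list:
    """``name<TAB>length`` pairs; duplicates and bad lengths are errors."""
    out, seen = [], set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected 'name length', got {line!r}")
        name = parts[0]
        if name in seen:
            raise ValueError(f"{path}:{ln}: duplicate chromosome {name!r}")
        seen.add(name)
        try:
            length = int(parts[1])
        except ValueError:
            raise ValueError(f"{path}:{ln}: non-integer length {parts[1]!r}") from None
        out.append((name, length))
    return out


def write_chrom_sizes(chromosomes: Iterable[Tuple[str, int]], path: PathLike) -> None:
    Path(path).write_text("".join(f"{n}\t{l}\n" for n, l in chromosomes))


def genome_from_files(
    chrom_sizes: PathLike,
    annotation_beds: Optional[Mapping[str, PathLike]] = None,
) -> GenomeDefinition:
    chroms = read_chrom_sizes(chrom_sizes)
    lengths = dict(chroms)
    annotations = {}
    for label, bed in (annotation_beds or {}).items():
        df = read_bed(bed, chrom_lengths=lengths)
        annotations[label] = list(zip(df["chrom"], df["start"], df["end"]))
    return GenomeDefinition(tuple(chroms), annotations)


# -- BED -------------------------------------------------------------------

def read_bed(path: PathLike, chrom_lengths: Optional[Mapping[str, int]] = None) -> pd.DataFrame:
    """BED3+ into a frame (chrom, start, end [, name, score]).

    Malformed lines (start >= end, bad integers) raise with the line
    number; with ``chrom_lengths`` coordinates are bounds-checked.
    """
    rows = []
    n_extra = 0
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
        chrom = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise ValueError(f"{path}:{ln}: non-integer coordinates") from None
        if start < 0 or start >= end:
            raise ValueError(f"{path}:{ln}: invalid interval {chrom}:{start}-{end}")
        if chrom_lengths is not None:
            if chrom not in chrom_lengths:
                raise ValueError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            if end > chrom_lengths[chrom]:
                raise ValueError(
                    f"{path}:{ln}: interval end {end} beyond chromosome "
                    f"length {chrom_lengths[chrom]}"
                )
        row = [chrom, start, end] + parts[3:5]
        n_extra = max(n_extra, len(parts[3:5]))
        rows.append(row)
    cols = ["chrom", "start", "end"] + ["name", "score"][:n_extra]
    rows = [r + [None] * (3 + n_extra - len(r)) for r in rows]
    return pd.DataFrame(rows, columns=cols)


def write_bed(df: pd.DataFrame, path: PathLike, header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        cols = [c for c in ("chrom", "start", "end", "name", "score") if c in df.columns]
        for row in df[cols].itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


def write_bedgraph(
    windows: pd.DataFrame,
    values: Sequence[float],
    path: PathLike,
    header: Optional[str] = None,
) -> None:
    """Four-column bedGraph (chrom, start, end, value)."""
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        for (chrom, start, end), v in zip(
            zip(windows["chrom"], windows["start"], windows["end"]), values
        ):
            fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


# -- read sets -------------------------------------------------------------

def write_reads_bed(reads: ReadSet, path: PathLike, header: Optional[str] = None) -> None:
    """One line per read: chrom, pos, pos+1, sample id, MAPQ."""
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        sid = reads.sample_id
        for chrom, pos, mapq in zip(
            reads.records["chrom"], reads.records["pos"], reads.records["mapq"]
        ):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{sid}\t{mapq}\n")


def read_reads_bed(
    path: PathLike,
    sample_id: str,
    condition: str,
    phase: str,
    replicate: int,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> ReadSet:
    df = read_bed(path, chrom_lengths=chrom_lengths)
    records = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(object),
            "pos": df["start"].astype("int64"),
            "mapq": pd.to_numeric(df["score"], errors="raise").astype("int16")
            if "score" in df.columns
            else 60,
        }
    )
    return ReadSet(sample_id, condition, phase, replicate, records)


# -- window grids and tables ----------------------------------------------

def write_grid_bed(grid: WindowGrid, path: PathLike, header: Optional[str] = None) -> None:
    write_bed(grid.windows, path, header=header)


def grid_from_bed(path: PathLike, size: int, step: int) -> WindowGrid:
    df = read_bed(path)
    return WindowGrid(size, step, df[["chrom", "start", "end"]].astype(
        {"start": "int64", "end": "int64"}))


def write_tsv(df: pd.DataFrame, path: PathLike, header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
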