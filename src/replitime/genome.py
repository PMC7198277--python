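"""Genome coordinate bookkeeping shared by every stage of the pipeline.

A :class:`GenomeDefinition` is a lightweight stand-in for a reference
assembly: an ordered list of chromosome lengths plus named interval
annotations (e.g. ``"pericentric"``).  All coordinates are 0-based
half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Tuple

Interval = Tuple[str, int, int]


def merge_intervals(intervals: Iterable[Sequence]) -> Tuple[Interval, ...]:
    """Sort intervals and merge any that overlap, per chromosome.

    Adjacent-but-touching intervals are merged as well, so the result is a
    canonical non-overlapping set.
    """
    out: list[list] = []
    for chrom, start, end in sorted((c, int(s), int(e)) for c, s, e in intervals):
        if start >= end:
            raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            out[-1][2] = max(out[-1][2], end)
        else:
            out.append([chrom, start, end])
    return tuple((c, s, e) for c, s, e in out)


@dataclass(frozen=True)
class GenomeDefinition:
    """Chromosome sizes plus labelled annotation interval sets.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.  Order is preserved and defines
        the canonical sort order of every downstream table.
    annotations
        Mapping ``label -> iterable of (chrom, start, end)``.  Intervals are
        normalized (sorted, merged) on construction and validated against the
        chromosome bounds.
    """

    chromosomes: Tuple[Tuple[str, int], ...]
    annotations: Mapping[str, Tuple[Interval, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        if not chroms:
            raise ValueError("genome must contain at least one chromosome")
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        lengths = dict(chroms)
        anns = {}
        for label, ivs in dict(self.annotations).items():
            merged = merge_intervals(ivs)
            for chrom, start, end in merged:
                if chrom not in lengths:
                    raise ValueError(f"annotation {label!r} names unknown chromosome {chrom!r}")
                if start < 0 or end > lengths[chrom]:
                    raise ValueError(
                        f"annotation {label!r} interval {chrom}:{start}-{end} "
                        f"outside chromosome bounds [0, {lengths[chrom]})"
                    )
            anns[str(label)] = merged
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "annotations", anns)

    # -- accessors ---------------------------------------------------------

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def chrom_length(self, name: str) -> int:
        try:
            return self.lengths[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def annotation(self, label: str) -> Tuple[Interval, ...]:
        try:
            return self.annotations[label]
        except KeyError:
            raise KeyError(
                f"unknown annotation {label!r}; available: {sorted(self.annotations)}"
            ) from None
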