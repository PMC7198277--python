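"""Replication-domain segmentation of smoothed RT profiles.

Domains are delimited by the coordinates halfway between each peak and
valley of the smoothed profile; the distance from one halfway point to the
next is the domain size.  Peak/valley detection (a prominence threshold on
the LOESS profile, with enforced peak/valley alternation) is this package's
deterministic rule; each domain contains exactly one extremum and is classed
early (peak) or late (valley).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .rtprofile import SmoothProfile

PEAK = "peak"
VALLEY = "valley"


def find_extrema(profile: SmoothProfile, min_prominence: float = 0.1) -> pd.DataFrame:
    """Alternating peaks and valleys of a smoothed profile.

    Local maxima/minima with prominence >= ``min_prominence`` (log2 units)
    are detected per chromosome; where two same-type extrema remain
    adjacent (their separating extremum fell below the prominence cut), the
    lesser one (lower peak / higher valley) is discarded until the sequence
    alternates.  Plateau extrema take the plateau's midpoint.  Chromosomes
    with fewer than 3 profile points yield no extrema.
    """
    rows = []
    for chrom, sub in profile.data.groupby("chrom", sort=False):
        y = sub["value"].to_numpy(dtype=float)
        pos = sub["pos"].to_numpy()
        if len(y) < 3:
            continue
        found = []
        for sign, kind in ((1.0, PEAK), (-1.0, VALLEY)):
            idx, props = find_peaks(sign * y, prominence=min_prominence,
                                    plateau_size=(1, None))
            mid = (props["left_edges"] + props["right_edges"]) // 2
            found.extend((int(i), kind) for i in mid)
        found.sort()
        # enforce alternation: of two same-type neighbours keep the stronger
        changed = True
        while changed:
            changed = False
            for k in range(len(found) - 1):
                i, kind_i = found[k]
                j, kind_j = found[k + 1]
                if kind_i != kind_j:
                    continue
                if kind_i == PEAK:
                    drop = k if y[i] < y[j] else k + 1
                else:
                    drop = k if y[i] > y[j] else k + 1
                del found[drop]
                changed = True
                break
        for i, kind in found:
            rows.append({"chrom": chrom, "pos": int(pos[i]), "kind": kind,
                         "value": float(y[i])})
    return pd.DataFrame(rows, columns=["chrom", "pos", "kind", "value"])


@dataclass
class DomainSet:
    """Segmentation result: extrema, boundaries, and classed domains.

    ``domains`` columns: chrom, start, end, cls (early/late), size,
    clipped (terminal half-domains cut at chromosome ends).
    """

    extrema: pd.DataFrame
    boundaries: pd.DataFrame   # chrom, pos
    domains: pd.DataFrame

    def sizes(self, include_clipped: bool = False) -> np.ndarray:
        d = self.domains
        if not include_clipped:
            d = d[~d["clipped"].astype(bool)]
        return d["size"].to_numpy()


def domain_sizes(
    extrema: pd.DataFrame,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> DomainSet:
    """Boundaries at the arithmetic midpoint between adjacent extrema;
    domains span consecutive boundaries.

    Terminal domains are clipped at the chromosome ends (coordinate 0 and,
    when ``chrom_lengths`` is given, the chromosome length — otherwise the
    last extremum's coordinate), flagged ``clipped``, and excluded from
    :meth:`DomainSet.sizes` by default.  Chromosomes with fewer than two
    extrema contribute no domains.
    """
    b_rows, d_rows = [], []
    for chrom, sub in extrema.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        kinds = sub["kind"].to_numpy()
        if len(pos) < 2:
            continue
        bounds = (pos[:-1] + pos[1:]) // 2
        for b in bounds:
            b_rows.append({"chrom": chrom, "pos": int(b)})
        end_coord = (
            int(chrom_lengths[chrom]) if chrom_lengths is not None else int(pos[-1])
        )
        edges = np.concatenate(([0], bounds, [end_coord]))
        for k in range(len(pos)):
            start, end = int(edges[k]), int(edges[k + 1])
            d_rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "cls": "early" if kinds[k] == PEAK else "late",
                    "size": end - start,
                    "clipped": k == 0 or k == len(pos) - 1,
                }
            )
    return DomainSet(
        extrema,
        pd.DataFrame(b_rows, columns=["chrom", "pos"]),
        pd.DataFrame(d_rows, columns=["chrom", "start", "end", "cls", "size", "clipped"]),
    )


def segment(
    profile: SmoothProfile,
    min_prominence: float = 0.1,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> DomainSet:
    """Convenience: extrema detection followed by boundary placement."""
    return domain_sizes(find_extrema(profile, min_prominence), chrom_lengths)
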