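"""Replication-timing values from window coverage.

RT at a window is the log2 ratio of S-phase to G1-phase RPM: larger values
indicate earlier replication.  Per-replicate columns are averaged within a
condition; quantile normalization equalizes the dynamic range of RT values
across samples before any between-sample comparison; tricube local-linear
(LOESS) smoothing turns the window series into the profile used for domain
segmentation and display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .coverage import CoverageTable, WindowGrid

logger = logging.getLogger(__name__)


@dataclass(eq=False)
class RTTable:
    """Window x S-replicate log2(S/G1) values.

    ``values`` is indexed by row position into ``grid.windows`` (windows
    masked during construction are simply absent) with one column per
    S-phase replicate; ``conditions`` maps each column to its condition
    label; ``normalized`` records whether quantile normalization has been
    applied (``"raw"`` or ``"quantile"``).
    """

    grid: WindowGrid
    values: pd.DataFrame
    conditions: Mapping[str, str]
    normalized: str = "raw"
    n_masked: int = 0

    @property
    def windows(self) -> pd.DataFrame:
        """Window coordinates for the retained rows."""
        return self.grid.windows.iloc[self.values.index.to_numpy()]

    def replicate_columns(self, condition: str) -> list:
        cols = [s for s, c in self.conditions.items() if c == condition]
        if not cols:
            raise KeyError(f"no replicate columns for condition {condition!r}")
        return cols

    def condition_mean(self, condition: str) -> np.ndarray:
        return self.values[self.replicate_columns(condition)].mean(axis=1).to_numpy()

    def condition_means(self) -> pd.DataFrame:
        conds = sorted(set(self.conditions.values()))
        return pd.DataFrame(
            {c: self.condition_mean(c) for c in conds}, index=self.values.index
        )

    def quantile_normalized(self) -> "RTTable":
        return RTTable(
            self.grid,
            quantile_normalize(self.values),
            dict(self.conditions),
            normalized="quantile",
            n_masked=self.n_masked,
        )


def pooled_g1_pairing(cov: CoverageTable) -> dict:
    """Map every S sample to the tuple of all G1 samples (pooled control).

    Pooling the G1 replicates into one shared denominator mirrors a single
    copy-number control used for all samples and keeps the two-sample
    moderated t calibrated: a shared denominator cancels from between-
    condition mean differences and never enters within-condition variances.
    """
    g1 = tuple(cov.samples_where(phase="G1"))
    if not g1:
        raise ValueError("coverage table contains no G1 samples")
    return {s: g1 for s in cov.samples_where(phase="S")}


def rt_values(
    cov: CoverageTable,
    pairing: Mapping[str, Union[str, Sequence[str]]],
    pseudo: float = 0.0,
    mask_zero: bool = True,
) -> RTTable:
    """Per-replicate log2(S/G1) RPM ratios on the coverage grid.

    ``pairing`` assigns each S sample its G1 control: either a single G1
    sample id or a sequence of ids whose RPM is averaged (pooled control).
    Windows where any participating column has zero RPM are masked (removed
    from all columns, logged) unless a positive ``pseudo`` count is supplied;
    with ``mask_zero=False`` and ``pseudo=0`` zero coverage is an error.
    """
    rpm = cov.rpm
    s_samples = cov.samples_where(phase="S")
    missing = [s for s in s_samples if s not in pairing]
    if missing:
        raise ValueError(f"no G1 pairing for S samples: {missing}")
    g1_cols = {}
    for s in s_samples:
        g1 = pairing[s]
        g1_list = [g1] if isinstance(g1, str) else list(g1)
        for g in g1_list:
            if g not in rpm.columns:
                raise ValueError(f"pairing for {s!r} names unknown sample {g!r}")
            if cov.meta.loc[g, "phase"] != "G1":
                raise ValueError(f"pairing for {s!r} names non-G1 sample {g!r}")
        g1_cols[s] = rpm[g1_list].mean(axis=1).to_numpy()

    zero = np.zeros(len(rpm), dtype=bool)
    if pseudo == 0.0:
        for s in s_samples:
            zero |= rpm[s].to_numpy() == 0
            zero |= g1_cols[s] == 0
    if zero.any():
        if not mask_zero:
            raise ValueError(
                f"{int(zero.sum())} windows have zero RPM in a participating "
                "column; supply a pseudo-count or enable masking"
            )
        logger.info("masking %d windows with zero coverage", int(zero.sum()))
    keep = ~zero

    values = {}
    for s in s_samples:
        values[s] = np.log2(
            (rpm[s].to_numpy()[keep] + pseudo) / (g1_cols[s][keep] + pseudo)
        )
    frame = pd.DataFrame(values, index=np.flatnonzero(keep))
    conditions = {s: cov.meta.loc[s, "condition"] for s in s_samples}
    return RTTable(cov.grid, frame, conditions, normalized="raw", n_masked=int(zero.sum()))


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Force identical value distributions across columns.

    Each column's rank r is replaced by the mean across columns of the r-th
    order statistics; tied values receive the mean of the reference values
    over the tied rank span, so within-column rank order is preserved and
    the operation is idempotent.
    """
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 columns")
    arr = df.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("quantile normalization requires finite values "
                         "(remove missing-data windows first)")
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        idx = np.argsort(arr[:, j], kind="stable")
        s = arr[idx, j]
        run_starts = np.r_[0, np.flatnonzero(s[1:] != s[:-1]) + 1]
        run_lengths = np.diff(np.r_[run_starts, n])
        run_means = np.add.reduceat(ref, run_starts) / run_lengths
        out[idx, j] = np.repeat(run_means, run_lengths)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


@dataclass
class SmoothProfile:
    """LOESS-smoothed RT profile: one value per window midpoint.

    ``data`` has columns chrom / pos / value, ordered like the source grid.
    """

    data: pd.DataFrame
    bandwidth: int

    def chrom(self, name: str) -> pd.DataFrame:
        return self.data[self.data["chrom"] == name]

    def plot(self, ax=None, **kwargs):  # pragma: no cover - convenience only
        """Quick profile plot (one panel per chromosome)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, sub in self.data.groupby("chrom", sort=False):
            ax.plot(sub["pos"] / 1e6, sub["value"], label=str(name), **kwargs)
        ax.set_xlabel("position (Mb)")
        ax.set_ylabel("RT  log2(S/G1)")
        ax.legend()
        return ax


def _loess_1d(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray, bandwidth: float) -> np.ndarray:
    """Tricube-weighted local linear regression at each evaluation point.

    Points farther than ``bandwidth`` get zero weight; if fewer than two
    points carry weight at some evaluation point, the three nearest points
    are used unweighted (degenerate chromosome ends).  Output is clipped to
    the data range.
    """
    out = np.empty(len(x_eval))
    for k, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        w = np.clip(1.0 - (d / bandwidth) ** 3, 0.0, None) ** 3
        use = w > 0
        if use.sum() < 2:
            use = np.argsort(d)[:3]
            w_use = np.ones(len(use))
            xs, ys = x[use], y[use]
        else:
            w_use = w[use]
            xs, ys = x[use], y[use]
        sw = w_use.sum()
        xm = (w_use * xs).sum() / sw
        ym = (w_use * ys).sum() / sw
        sxx = (w_use * (xs - xm) ** 2).sum()
        beta = (w_use * (xs - xm) * (ys - ym)).sum() / sxx if sxx > 0 else 0.0
        out[k] = ym + beta * (x0 - xm)
    return np.clip(out, y.min(), y.max())


def loess_profile(
    rt: RTTable,
    column: Optional[str] = None,
    condition: Optional[str] = None,
    bandwidth: int = 250_000,
) -> SmoothProfile:
    """Smooth one RT column (or a condition average) along each chromosome.

    ``bandwidth`` is the tricube half-width in bp of genomic distance and
    must be at least the grid step; every chromosome needs >= 2 retained
    windows.
    """
    if bandwidth < rt.grid.step:
        raise ValueError("LOESS bandwidth must be >= the grid step")
    if (column is None) == (condition is None):
        raise ValueError("pass exactly one of column= or condition=")
    y_all = rt.values[column].to_numpy() if column else rt.condition_mean(condition)
    win = rt.windows
    mid_all = ((win["start"] + win["end"]) // 2).to_numpy()
    chroms_all = win["chrom"].to_numpy()
    rows = []
    for name in pd.unique(chroms_all):
        m = chroms_all == name
        if m.sum() < 2:
            logger.warning(
                "chromosome %r has fewer than 2 windows; excluded from the profile",
                name,
            )
            continue
        x = mid_all[m].astype(float)
        smoothed = _loess_1d(x, y_all[m], x, float(bandwidth))
        rows.append(pd.DataFrame({"chrom": name, "pos": mid_all[m], "value": smoothed}))
    if not rows:
        raise ValueError("no chromosome has >= 2 windows to smooth")
    return SmoothProfile(pd.concat(rows, ignore_index=True), bandwidth)


def correlation_matrix(
    values: Union[RTTable, pd.DataFrame],
    include: Optional[np.ndarray] = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Pairwise correlation of RT columns over included windows.

    ``include`` is an optional boolean mask over rows (e.g. the complement
    of a pericentric-annotation mask, to exclude late-replicating
    heterochromatin).  Pearson by default; ``method="spearman"`` available.
    """
    df = values.values if isinstance(values, RTTable) else values
    if include is not None:
        df = df.loc[np.asarray(include, dtype=bool)]
    if len(df) < 3:
        raise ValueError("need >= 3 included windows for a correlation matrix")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    return df.corr(method=method)
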