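"""Differential replication timing between two conditions.

The central object is :class:`DifferentialRTModel`: built from the
quantile-normalized per-replicate RT columns of two conditions, its
``fit()`` applies the empirical-Bayes moderated t (scaled inverse-chi-square
variance prior) per window and returns a :class:`DifferentialRTResults`
carrying fold changes, moderated statistics, BH-adjusted p-values and the
advanced / delayed / ns classification at the strict thresholds
(adjusted p < 0.01, |log2 FC| > 0.1 at 100-kb windows; p < 0.05 after the
median down-mapping to 10-kb windows).

Window-set overlap follows bedtools ``intersect -f 0.5 -u`` semantics:
a query window is reported (once) if any single subject window covers at
least half of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._stats import ModeratedTResult, bh_adjust, moderated_t
from .coverage import WindowGrid, windows_in_annotation
from .genome import GenomeDefinition
from .rtprofile import RTTable

CALL_ADVANCED = "advanced"   # significantly earlier in condition A
CALL_DELAYED = "delayed"     # significantly earlier in condition B
CALL_NS = "ns"


def call_windows(
    log_fc: np.ndarray,
    p_adj: np.ndarray,
    alpha: float = 0.01,
    lfc: float = 0.1,
) -> np.ndarray:
    """Classify windows with strict thresholds, exactly as printed:
    significant iff ``p_adj < alpha`` AND ``|log_fc| > lfc``; the sign of
    the fold change partitions advanced (earlier in A) from delayed."""
    log_fc = np.asarray(log_fc, dtype=float)
    p_adj = np.asarray(p_adj, dtype=float)
    sig = (p_adj < alpha) & (np.abs(log_fc) > lfc)
    out = np.full(len(log_fc), CALL_NS, dtype=object)
    out[sig & (log_fc > 0)] = CALL_ADVANCED
    out[sig & (log_fc < 0)] = CALL_DELAYED
    return out


def call_summary(calls: np.ndarray, n_total: Optional[int] = None) -> dict:
    """Counts and percentages of advanced / delayed / ns calls.

    ``n_total`` defaults to the number of calls; pass the full grid size to
    report percentages over all windows when some were masked.
    """
    calls = np.asarray(calls)
    n_total = int(n_total if n_total is not None else len(calls))
    out = {}
    for label in (CALL_ADVANCED, CALL_DELAYED, CALL_NS):
        k = int((calls == label).sum())
        out[f"n_{label}"] = k
        out[f"pct_{label}"] = 100.0 * k / n_total if n_total else 0.0
    out["n_total"] = n_total
    return out


class DifferentialRTModel:
    """Per-window two-condition comparison of replicate RT values.

    Parameters
    ----------
    values_a, values_b
        Window x replicate matrices of (quantile-normalized) log2(S/G1)
        values, one per condition; equal row counts, >= 2 columns each.
    grid, window_index
        Optional window grid and the row positions of the values within it
        (carried into the results for coordinate-aware downstream steps).
    conditions
        Labels for the two conditions (A, B); the fold change is A - B, so
        positive log FC means earlier replication in A.
    """

    def __init__(
        self,
        values_a,
        values_b,
        grid: Optional[WindowGrid] = None,
        window_index: Optional[np.ndarray] = None,
        conditions: Tuple[str, str] = ("A", "B"),
    ) -> None:
        self.values_a = np.atleast_2d(np.asarray(values_a, dtype=float))
        self.values_b = np.atleast_2d(np.asarray(values_b, dtype=float))
        if self.values_a.shape[0] != self.values_b.shape[0]:
            raise ValueError("conditions have different numbers of windows")
        if self.values_a.shape[1] < 2 or self.values_b.shape[1] < 2:
            raise ValueError("need >= 2 replicates per condition")
        self.grid = grid
        self.window_index = (
            np.asarray(window_index)
            if window_index is not None
            else np.arange(self.values_a.shape[0])
        )
        self.conditions = tuple(conditions)

    @classmethod
    def from_rt_table(
        cls, rt: RTTable, condition_a: str, condition_b: str
    ) -> "DifferentialRTModel":
        """Build the model from an :class:`RTTable`'s replicate columns."""
        a = rt.values[rt.replicate_columns(condition_a)].to_numpy()
        b = rt.values[rt.replicate_columns(condition_b)].to_numpy()
        return cls(
            a, b,
            grid=rt.grid,
            window_index=rt.values.index.to_numpy(),
            conditions=(condition_a, condition_b),
        )

    def fit(self, df_prior: Optional[float] = None) -> "DifferentialRTResults":
        """Estimate the variance prior across windows and apply the
        moderated t per window; ``df_prior`` overrides the estimate (0 =
        ordinary t, inf = fully pooled)."""
        res = moderated_t(self.values_a, self.values_b, df_prior=df_prior)
        return DifferentialRTResults(self, res)


class DifferentialRTResults:
    """Fitted differential-RT comparison.

    Exposes per-window estimates (``frame``), the shrinkage diagnostics
    (``df_prior``, ``s2_prior``), classification (:meth:`calls`), the
    10-kb median down-mapping (:meth:`map_to_fine`) and a text
    :meth:`summary`.
    """

    def __init__(self, model: DifferentialRTModel, res: ModeratedTResult) -> None:
        self.model = model
        self._res = res
        self.df_prior = res.df_prior
        self.s2_prior = res.s2_prior
        self.df_residual = res.df_residual
        self.df_total = res.df_total
        self.p_adj = bh_adjust(res.p)

        data = {
            "mean_a": res.mean_a,
            "mean_b": res.mean_b,
            "log_fc": res.log_fc,
            "s2": res.s2,
            "s2_post": res.s2_post,
            "t": res.t,
            "p": res.p,
            "p_adj": self.p_adj,
        }
        if model.grid is not None:
            win = model.grid.windows.iloc[model.window_index]
            frame = win[["chrom", "start", "end"]].reset_index(drop=True)
            for k, v in data.items():
                frame[k] = v
        else:
            frame = pd.DataFrame(data)
        self.frame = frame

    @property
    def log_fc(self) -> np.ndarray:
        return self._res.log_fc

    @property
    def p(self) -> np.ndarray:
        return self._res.p

    @property
    def t(self) -> np.ndarray:
        return self._res.t

    def calls(self, alpha: float = 0.01, lfc: float = 0.1) -> np.ndarray:
        return call_windows(self.log_fc, self.p_adj, alpha=alpha, lfc=lfc)

    def call_summary(self, alpha: float = 0.01, lfc: float = 0.1) -> dict:
        n_total = len(self.model.grid.windows) if self.model.grid is not None else None
        return call_summary(self.calls(alpha, lfc), n_total=n_total)

    def called_windows(self, alpha: float = 0.01, lfc: float = 0.1,
                       direction: Optional[str] = None) -> pd.DataFrame:
        """Coordinate frame of significant windows (optionally one direction)."""
        calls = self.calls(alpha, lfc)
        keep = calls != CALL_NS if direction is None else calls == direction
        return self.frame.loc[keep].reset_index(drop=True)

    def map_to_fine(
        self, alpha: float = 0.05, lfc: float = 0.1
    ) -> "FineGrainResult":
        return map_to_fine(self, alpha=alpha, lfc=lfc)

    def summary(self, alpha: float = 0.01, lfc: float = 0.1) -> str:
        a, b = self.model.conditions
        cs = self.call_summary(alpha, lfc)
        lines = [
            "Differential replication timing (moderated t)",
            "=" * 54,
            f"conditions:        {a} vs {b}   (log FC = {a} - {b})",
            f"windows tested:    {len(self.frame)}",
            f"replicates:        {self.model.values_a.shape[1]} vs {self.model.values_b.shape[1]}",
            f"residual df:       {self.df_residual:g}",
            f"prior df (d0):     {self.df_prior:g}",
            f"prior scale s0^2:  {self.s2_prior:.4g}",
            f"total df:          {self.df_total:g}",
            f"thresholds:        adj. p < {alpha:g}, |log2 FC| > {lfc:g} (strict)",
            "-" * 54,
            f"advanced (earlier in {a}): {cs['n_advanced']:6d}  ({cs['pct_advanced']:.1f}%)",
            f"delayed  (earlier in {b}): {cs['n_delayed']:6d}  ({cs['pct_delayed']:.1f}%)",
            f"not significant:           {cs['n_ns']:6d}  ({cs['pct_ns']:.1f}%)",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# 100-kb -> 10-kb median down-mapping
# ---------------------------------------------------------------------------

@dataclass
class FineGrainResult:
    """Median RT statistics on the fine (step-sized) tiling.

    Each fine window takes the median of every coarse window fully
    containing it (<= size/step of them); fine windows contained in zero
    coarse windows are absent.
    """

    frame: pd.DataFrame  # chrom start end n_coarse mean_a mean_b log_fc p_adj call
    alpha: float
    lfc: float

    def call_summary(self) -> dict:
        return call_summary(self.frame["call"].to_numpy())


def map_to_fine(
    results: DifferentialRTResults,
    alpha: float = 0.05,
    lfc: float = 0.1,
) -> FineGrainResult:
    """Down-map coarse sliding-window statistics to step-sized fine windows.

    Requires the coarse grid's step to equal the fine window size (the
    sliding tiling makes each fine window a constituent of up to
    ``size/step`` coarse windows).  Medians use mean-of-middle-two for even
    counts; the significance threshold is re-applied at the fine scale
    (default adjusted p < 0.05, |log2 FC| > 0.1).
    """
    if results.model.grid is None:
        raise ValueError("fine mapping requires a window grid")
    return map_frame_to_fine(results.frame, results.model.grid, alpha=alpha, lfc=lfc)


def map_frame_to_fine(
    frame: pd.DataFrame,
    grid: WindowGrid,
    alpha: float = 0.05,
    lfc: float = 0.1,
) -> FineGrainResult:
    """Frame-level core of :func:`map_to_fine` (coarse statistics table +
    grid in, fine medians out)."""
    fine_size = grid.step
    frame = frame.sort_values(["chrom", "start"], kind="stable")
    out_rows = []
    for chrom, extent in grid.chrom_extents.items():
        sub = frame[frame["chrom"] == chrom]
        starts = sub["start"].to_numpy()
        cols = {k: sub[k].to_numpy() for k in ("mean_a", "mean_b", "log_fc", "p_adj")}
        fine_starts = np.arange(0, extent - fine_size + 1, fine_size)
        for fs in fine_starts:
            fe = fs + fine_size
            lo = np.searchsorted(starts, fe - grid.size, side="left")
            hi = np.searchsorted(starts, fs, side="right")
            if hi <= lo:
                continue  # fine window covered by no retained coarse window
            med = {k: float(np.median(v[lo:hi])) for k, v in cols.items()}
            out_rows.append(
                {"chrom": chrom, "start": int(fs), "end": int(fe),
                 "n_coarse": int(hi - lo), **med}
            )
    fine = pd.DataFrame(
        out_rows,
        columns=["chrom", "start", "end", "n_coarse",
                 "mean_a", "mean_b", "log_fc", "p_adj"],
    )
    fine["call"] = call_windows(
        fine["log_fc"].to_numpy(), fine["p_adj"].to_numpy(), alpha=alpha, lfc=lfc
    )
    return FineGrainResult(fine, alpha, lfc)


# ---------------------------------------------------------------------------
# window-set overlap and enrichment
# ---------------------------------------------------------------------------

def intersect_windows(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    f: float = 0.5,
    unique: bool = True,
) -> np.ndarray:
    """bedtools ``intersect -f F [-u]`` semantics on interval frames.

    Returns a boolean mask over the rows of ``set_a`` marking windows for
    which some single window of ``set_b`` covers at least ``f`` of the A
    window's length (boundary inclusive: exactly ``f`` qualifies).  With
    ``unique`` each A window is reported at most once (the mask form).
    """
    if not unique:
        raise NotImplementedError("only the -u (unique) reporting mode is supported")
    mask = np.zeros(len(set_a), dtype=bool)
    a_idx = np.arange(len(set_a))
    for chrom in pd.unique(set_a["chrom"]):
        am = (set_a["chrom"] == chrom).to_numpy()
        bm = (set_b["chrom"] == chrom).to_numpy()
        if not bm.any():
            continue
        b_starts = set_b["start"].to_numpy()[bm]
        b_ends = set_b["end"].to_numpy()[bm]
        order = np.argsort(b_starts)
        b_starts, b_ends = b_starts[order], b_ends[order]
        for i, (s, e) in zip(
            a_idx[am],
            zip(set_a["start"].to_numpy()[am], set_a["end"].to_numpy()[am]),
        ):
            hi = np.searchsorted(b_starts, e, side="left")
            if hi == 0:
                continue
            ov = np.minimum(b_ends[:hi], e) - np.maximum(b_starts[:hi], s)
            if ov.size and ov.max() >= f * (e - s):
                mask[i] = True
    return mask


def venn_counts(set_a: pd.DataFrame, set_b: pd.DataFrame, f: float = 0.5) -> dict:
    """Two-set overlap summary (|A only|, |B only|, |A and B|).

    The shared count is taken from the A perspective (A windows overlapped
    by B at fraction ``f``); for same-size grid windows the B perspective
    is symmetric.
    """
    a_hit = intersect_windows(set_a, set_b, f=f)
    b_hit = intersect_windows(set_b, set_a, f=f)
    return {
        "a_only": int((~a_hit).sum()),
        "b_only": int((~b_hit).sum()),
        "a_and_b": int(a_hit.sum()),
        "b_and_a": int(b_hit.sum()),
    }


def annotation_enrichment(
    grid: WindowGrid,
    called: np.ndarray,
    genome: GenomeDefinition,
    label: str,
    min_frac: float = 0.5,
) -> dict:
    """How calls distribute relative to an annotation (e.g. pericentric).

    ``called`` is a boolean mask over the grid's windows.  A window counts
    as annotated when >= ``min_frac`` of it lies inside the annotation.
    Returns the fraction of annotated windows that are called and the
    fraction of calls lying in the annotation, with the underlying counts.
    """
    called = np.asarray(called, dtype=bool)
    if len(called) != len(grid):
        raise ValueError("call mask length does not match the grid")
    annotated = windows_in_annotation(grid, genome, label, min_frac=min_frac)
    n_ann = int(annotated.sum())
    n_called = int(called.sum())
    n_both = int((annotated & called).sum())
    return {
        "n_annotated": n_ann,
        "n_called": n_called,
        "n_called_in_annotation": n_both,
        "frac_annotated_called": n_both / n_ann if n_ann else 0.0,
        "frac_calls_in_annotation": n_both / n_called if n_called else 0.0,
    }


def moderated_t_test(
    values_a,
    values_b,
    grid: Optional[WindowGrid] = None,
    window_index: Optional[np.ndarray] = None,
    df_prior: Optional[float] = None,
) -> DifferentialRTResults:
    """Functional wrapper: fit :class:`DifferentialRTModel` in one call."""
    return DifferentialRTModel(
        values_a, values_b, grid=grid, window_index=window_index
    ).fit(df_prior=df_prior)
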