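"""Transcript-level expression integrated with window-level RT.

Differential expression uses the same moderated-t engine as the RT caller,
applied to log2-CPM (counts per million with a pseudo-count); significance
follows the raw p < 0.01 convention.  Expression presence is TPM-based:
a transcript is expressed in a condition iff its mean TPM there is > 0,
giving the shared / A-specific / B-specific / silent classification.
Transcript statistics are carried onto fine (10-kb) windows by one of three
assignment schemes, and cross-tabulated against differential-RT calls.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._stats import bh_adjust, moderated_t
from .coverage import WindowGrid

SCHEMES = ("mean_lfc", "lowest_p", "max_abs_lfc")


def tpm(counts: pd.DataFrame, lengths: Sequence[float]) -> pd.DataFrame:
    """Transcripts-per-million from raw counts and transcript lengths.

    Each column sums to 1e6 (samples with zero counts raise).
    """
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("transcript lengths must be positive")
    rate = counts.to_numpy(dtype=float) / lengths[:, None]
    colsum = rate.sum(axis=0)
    if np.any(colsum == 0):
        raise ValueError("sample with zero total counts")
    return pd.DataFrame(rate / colsum * 1e6, index=counts.index, columns=counts.columns)


def differential_expression(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    pseudo: float = 0.5,
) -> pd.DataFrame:
    """Per-transcript moderated-t differential expression on log2 CPM.

    Returns log_fc (log2 CPM, A - B), t, p, p_adj.  Library sizes of zero
    are an error.
    """
    if len(counts_a) != len(counts_b):
        raise ValueError("count matrices differ in transcript count")
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")

    def log_cpm(df: pd.DataFrame) -> np.ndarray:
        arr = df.to_numpy(dtype=float)
        lib = arr.sum(axis=0)
        if np.any(lib == 0):
            raise ValueError("sample with zero library size")
        return np.log2((arr + pseudo) / (lib + 2 * pseudo)[None, :] * 1e6)

    res = moderated_t(log_cpm(counts_a), log_cpm(counts_b))
    return pd.DataFrame(
        {
            "log_fc": res.log_fc,
            "t": res.t,
            "p": res.p,
            "p_adj": bh_adjust(res.p),
        },
        index=counts_a.index,
    )


def classify_expression(
    tpm_a: pd.DataFrame,
    tpm_b: pd.DataFrame,
    labels: Tuple[str, str] = ("A", "B"),
) -> pd.Series:
    """Expression class per transcript from mean TPM per condition.

    Expressed in a condition iff mean TPM > 0 there; shared = both,
    ``{A}_specific`` / ``{B}_specific`` = one side only, silent = neither.
    """
    a = tpm_a.mean(axis=1).to_numpy() > 0
    b = tpm_b.mean(axis=1).to_numpy() > 0
    la, lb = labels
    out = np.where(
        a & b, "shared",
        np.where(a, f"{la}_specific", np.where(b, f"{lb}_specific", "silent")),
    )
    return pd.Series(out, index=tpm_a.index, name="expression_class")


def assign_to_windows(
    transcripts: pd.DataFrame,
    grid: WindowGrid,
    scheme: str = "mean_lfc",
) -> pd.DataFrame:
    """Summarize transcript statistics per (fine) window.

    ``transcripts`` needs chrom/start/end plus log_fc, p, p_adj columns
    (and transcript_id for deterministic tie-breaks).  A transcript overlaps
    a window if their intervals intersect by >= 1 bp.  Schemes:

    * ``mean_lfc``   - mean log FC and mean adjusted p of all overlapping
      transcripts;
    * ``lowest_p``   - the log FC (and p) of the overlapping transcript with
      the smallest raw p;
    * ``max_abs_lfc`` - the log FC of the transcript with the largest
      |log FC| (ties: smaller raw p, then transcript id).

    Windows overlapped by no transcript are absent from the output.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    w = grid.windows
    rows = []
    tx_sorted = transcripts.sort_values(["chrom", "start"], kind="stable")
    for chrom, sub in tx_sorted.groupby("chrom", sort=False):
        sel = grid.chrom_rows(chrom)
        w_start = w["start"].to_numpy()[sel]
        w_end = w["end"].to_numpy()[sel]
        base = sel.start
        t_start = sub["start"].to_numpy()
        t_end = sub["end"].to_numpy()
        for k in range(len(w_start)):
            hit = (t_start < w_end[k]) & (t_end > w_start[k])
            if not hit.any():
                continue
            g = sub.loc[hit]
            if scheme == "mean_lfc":
                rows.append(
                    {"window": base + k, "n_transcripts": len(g),
                     "log_fc": float(g["log_fc"].mean()),
                     "p": float(g["p"].mean()),
                     "p_adj": float(g["p_adj"].mean())}
                )
            else:
                if scheme == "lowest_p":
                    order = g.sort_values(["p", "transcript_id"], kind="stable")
                else:
                    order = g.assign(_abs=-(g["log_fc"].abs())).sort_values(
                        ["_abs", "p", "transcript_id"], kind="stable"
                    )
                top = order.iloc[0]
                rows.append(
                    {"window": base + k, "n_transcripts": len(g),
                     "log_fc": float(top["log_fc"]),
                     "p": float(top["p"]),
                     "p_adj": float(top["p_adj"])}
                )
    out = pd.DataFrame(rows, columns=["window", "n_transcripts", "log_fc", "p", "p_adj"])
    if len(out):
        coords = w.iloc[out["window"].to_numpy()][["chrom", "start", "end"]].reset_index(drop=True)
        out = pd.concat([coords, out.reset_index(drop=True)], axis=1)
    return out


def rt_expression_concordance(
    transcripts: pd.DataFrame,
    fine_frame: pd.DataFrame,
    p_threshold: float = 0.01,
    grid: Optional[WindowGrid] = None,
) -> dict:
    """Cross-tabulate RT calls against significant expression changes.

    For each fine window the RT call (advanced / delayed / ns, log FC
    oriented A - B) is paired with whether any overlapping transcript shows
    a significant (raw p < ``p_threshold``) abundance increase in the
    direction of the RT change (up in A for advanced windows, up in B for
    delayed).  Also reports the Pearson correlation between the mean
    transcript log FC and the RT log FC over windows containing >= 1
    transcript.
    """
    required = {"chrom", "start", "end", "log_fc", "call"}
    if not required.issubset(fine_frame.columns):
        raise ValueError(f"fine frame needs columns {sorted(required)}")
    sig_up = transcripts[(transcripts["p"] < p_threshold) & (transcripts["log_fc"] > 0)]
    sig_down = transcripts[(transcripts["p"] < p_threshold) & (transcripts["log_fc"] < 0)]

    def window_has(tx: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(fine_frame), dtype=bool)
        for chrom, sub in tx.groupby("chrom", sort=False):
            m = (fine_frame["chrom"] == chrom).to_numpy()
            ws = fine_frame["start"].to_numpy()[m]
            we = fine_frame["end"].to_numpy()[m]
            ts = sub["start"].to_numpy()
            te = sub["end"].to_numpy()
            hit = np.zeros(len(ws), dtype=bool)
            for s, e in zip(ts, te):
                hit |= (ws < e) & (we > s)
            out[np.flatnonzero(m)] = hit
        return out

    has_any = window_has(transcripts)
    has_up = window_has(sig_up)
    has_down = window_has(sig_down)
    calls = fine_frame["call"].to_numpy()

    crosstab = {}
    for label, concordant in (("advanced", has_up), ("delayed", has_down)):
        m = calls == label
        n = int(m.sum())
        n_with = int((m & concordant).sum())
        crosstab[label] = {
            "n_windows": n,
            "with_concordant_up": n_with,
            "without_concordant_up": n - n_with,
            "frac_without": (n - n_with) / n if n else np.nan,
        }

    mean_assigned = fine_frame.merge(
        # mean transcript log FC per window for the correlation
        _mean_lfc_by_window(transcripts, fine_frame),
        on=["chrom", "start"], how="inner",
    )
    if (
        len(mean_assigned) >= 3
        and mean_assigned["expr_log_fc"].std() > 0
        and mean_assigned["log_fc"].std() > 0
    ):
        r = float(np.corrcoef(mean_assigned["expr_log_fc"], mean_assigned["log_fc"])[0, 1])
    else:
        r = np.nan
    return {
        "crosstab": crosstab,
        "n_windows_with_transcript": int(has_any.sum()),
        "correlation": r,
    }


def _mean_lfc_by_window(transcripts: pd.DataFrame, fine_frame: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for chrom, sub in transcripts.groupby("chrom", sort=False):
        m = (fine_frame["chrom"] == chrom).to_numpy()
        ws = fine_frame["start"].to_numpy()[m]
        we = fine_frame["end"].to_numpy()[m]
        ts = sub["start"].to_numpy()
        te = sub["end"].to_numpy()
        lfc = sub["log_fc"].to_numpy()
        for k in range(len(ws)):
            hit = (ts < we[k]) & (te > ws[k])
            if hit.any():
                rows.append({"chrom": chrom, "start": int(ws[k]),
                             "expr_log_fc": float(lfc[hit].mean())})
    return pd.DataFrame(rows, columns=["chrom", "start", "expr_log_fc"])
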