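"""In-silico contamination (spike-in) sensitivity analysis.

A sorted cell population is rarely pure: a FACS gate intended to capture one
population can contain cells of another (for the ovarian follicle-cell gate,
up to half the "mitotic" 2C-4C population can be first-endocycle cells,
because an egg chamber completes its mitotic divisions at 2^10 = 1024
cells).  To measure how such impurity masks or mimics differential RT, reads
from a contaminating condition are mixed into a base condition's S-phase
replicates at known fractions (1%, 5%, 10%, 25%, 50% of a fixed total,
3 x 10^7 reads at full scale), the differential-RT pipeline is re-run on
each mixture against the pure base, and sensitivity against the known
truth set is reported per fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .coverage import CoverageTable, WindowGrid
from .differential import CALL_NS, DifferentialRTModel
from .rtprofile import pooled_g1_pairing, rt_values
from .simulate import ReadSet


@dataclass
class SpikeInDesign:
    """Mixing design for the contamination analysis.

    ``total`` reads per mixed replicate, of which ``round(fraction * total)``
    (round-half-even) come from the contaminating condition and the rest
    from the base condition, both sampled uniformly without replacement.
    """

    total: int = 30_000_000
    fractions: Tuple[float, ...] = (0.01, 0.05, 0.10, 0.25, 0.50)
    base: str = "base"
    contaminant: str = "contaminant"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total reads per replicate must be > 0")
        for f in self.fractions:
            if not 0.0 < f < 1.0:
                raise ValueError(f"impurity fraction {f} outside (0, 1)")

    def contaminant_reads(self, fraction: float) -> int:
        """Contaminating read count at a fraction (round-half-even)."""
        return round(fraction * self.total)


def _sample_records(rec: pd.DataFrame, n: int, rng, origin: str) -> pd.DataFrame:
    if len(rec) < n:
        raise ValueError(
            f"source replicate has {len(rec)} reads, {n} required "
            f"(shortfall {n - len(rec)}) for origin {origin!r}"
        )
    take = rng.choice(len(rec), size=n, replace=False)
    out = rec.iloc[np.sort(take)].copy()
    out["origin"] = origin
    return out


def mix_reads(
    base: Sequence[ReadSet],
    contaminant: Sequence[ReadSet],
    design: SpikeInDesign,
) -> dict:
    """Mixed read sets per impurity fraction.

    Replicates are paired by list position; every mixed replicate has
    exactly ``design.total`` reads, each carrying an ``origin`` provenance
    tag ("base" / "contaminant").  Deterministic under ``design.seed``.
    """
    if len(base) != len(contaminant):
        raise ValueError("base and contaminant replicate lists differ in length")
    rng = np.random.default_rng(design.seed)
    mixtures: dict = {}
    for frac in design.fractions:
        n_cont = design.contaminant_reads(frac)
        n_base = design.total - n_cont
        reps = []
        for b, c in zip(base, contaminant):
            take_b = _sample_records(b.records, n_base, rng, "base")
            take_c = _sample_records(c.records, n_cont, rng, "contaminant")
            rec = pd.concat([take_b, take_c], ignore_index=True)
            rec = rec.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
            reps.append(
                ReadSet(
                    f"mix{frac:g}_{b.phase}_{b.replicate}",
                    f"{design.base}+{design.contaminant}@{frac:g}",
                    b.phase,
                    b.replicate,
                    rec,
                )
            )
        mixtures[frac] = reps
    return mixtures


@dataclass
class SpikeInReport:
    """Sensitivity and false-call counts per impurity fraction.

    ``frame`` columns: fraction, n_called, n_true_called, sensitivity,
    false_calls, fdr.  ``null_called_fraction`` is the called fraction of
    the zero-impurity self-comparison (a pure-subsample of the base against
    the base itself), the analysis' empirical null.
    """

    frame: pd.DataFrame
    truth_definition: str
    null_called_fraction: Optional[float] = None


def _run_caller(
    test_sets: Sequence[ReadSet],
    base_sets: Sequence[ReadSet],
    g1_sets: Sequence[ReadSet],
    grid: WindowGrid,
    mapq_min: int,
    quantile: bool,
    alpha: float,
    lfc: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """coverage -> RT -> differential on (test vs base); returns the boolean
    called mask over grid windows and the retained window index."""
    relabel = []
    for rs in test_sets:
        relabel.append(ReadSet(f"T_S_{rs.replicate}", "T", "S", rs.replicate, rs.records))
    for rs in base_sets:
        relabel.append(ReadSet(f"B_S_{rs.replicate}", "B", "S", rs.replicate, rs.records))
    for rs in g1_sets:
        relabel.append(ReadSet(f"G_G1_{rs.replicate}", "G", "G1", rs.replicate, rs.records))
    cov = CoverageTable.from_read_sets(relabel, grid, mapq_min=mapq_min)
    rt = rt_values(cov, pooled_g1_pairing(cov))
    if quantile:
        rt = rt.quantile_normalized()
    res = DifferentialRTModel.from_rt_table(rt, "T", "B").fit()
    calls = res.calls(alpha=alpha, lfc=lfc)
    mask = np.zeros(len(grid), dtype=bool)
    mask[res.model.window_index] = calls != CALL_NS
    return mask, res.model.window_index


def spikein_sensitivity(
    base: Sequence[ReadSet],
    contaminant: Sequence[ReadSet],
    g1: Sequence[ReadSet],
    grid: WindowGrid,
    truth: np.ndarray,
    design: SpikeInDesign,
    alpha: float = 0.01,
    lfc: float = 0.1,
    mapq_min: int = 10,
    quantile: bool = True,
    include_null: bool = True,
    truth_definition: str = "planted",
) -> SpikeInReport:
    """Sensitivity/FDR of the differential caller under gate impurity.

    For each fraction the mixture replicates are compared against the pure
    base replicates (shared pooled G1 control); sensitivity is the share of
    ``truth`` windows called, false calls are called windows outside the
    truth set.  With ``include_null`` a zero-impurity subsample of the base
    is compared against the base itself and its called fraction recorded.
    """
    truth = np.asarray(truth, dtype=bool)
    if len(truth) != len(grid):
        raise ValueError("truth mask length does not match the grid")
    mixtures = mix_reads(base, contaminant, design)
    rows = []
    n_truth = int(truth.sum())
    for frac in design.fractions:
        called, _ = _run_caller(
            mixtures[frac], base, g1, grid, mapq_min, quantile, alpha, lfc
        )
        n_called = int(called.sum())
        n_true_called = int((called & truth).sum())
        false_calls = int((called & ~truth).sum())
        rows.append(
            {
                "fraction": frac,
                "n_called": n_called,
                "n_true_called": n_true_called,
                "sensitivity": n_true_called / n_truth if n_truth else np.nan,
                "false_calls": false_calls,
                "fdr": false_calls / n_called if n_called else 0.0,
            }
        )
    report = SpikeInReport(pd.DataFrame(rows), truth_definition)
    if include_null:
        rng = np.random.default_rng(design.seed + 1)
        null_sets = [
            ReadSet(
                f"null_S_{b.replicate}", "null", "S", b.replicate,
                _sample_records(b.records, design.total, rng, "base").drop(columns="origin"),
            )
            for b in base
        ]
        called, _ = _run_caller(null_sets, base, g1, grid, mapq_min, quantile, alpha, lfc)
        report.null_called_fraction = float(called.sum()) / len(grid)
    return report


def cells_after_divisions(n_divisions: int = 10) -> int:
    """Cells descended from one founder after ``n_divisions`` synchronous
    mitotic divisions (2^n); an egg chamber's follicle epithelium completes
    10 divisions, hence 1024 cells."""
    if n_divisions < 0:
        raise ValueError("division count must be non-negative")
    return 2 ** n_divisions


def contamination_bound(mitotic: float, endocycle: float) -> float:
    """Maximal contaminating percentage of a sorted gate containing
    ``mitotic`` target cells and ``endocycle`` contaminating cells:
    ``100 * endocycle / (mitotic + endocycle)``."""
    if mitotic < 0 or endocycle < 0:
        raise ValueError("cell counts must be non-negative")
    if mitotic + endocycle == 0:
        raise ValueError("cell counts must not both be zero")
    return 100.0 * endocycle / (mitotic + endocycle)
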