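"""Simulation studies that validate the pipeline by parameter recovery.

Each study plants a known RT program, runs the full pipeline
(reads -> coverage -> RT -> differential / domains / spike-in) and measures
how well the planted truth is recovered.  Problem sizes are scaled to run
on a single CPU in seconds-to-minutes while keeping per-window read depths
representative (hundreds to thousands of reads per 100-kb window, the
regime where log-ratio noise is dominated by the replicate noise model
rather than counting noise).

All randomness flows through the ``seed`` argument; derived seeds stay
below 2^31.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sp_stats

from .coverage import CoverageTable, make_windows
from .differential import CALL_NS, DifferentialRTModel
from .domains import segment
from .genome import GenomeDefinition
from .rtprofile import loess_profile, pooled_g1_pairing, rt_values
from .simulate import RTProgram, SimulationConfig, simulate_reads
from .spikein import SpikeInDesign, spikein_sensitivity


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31 - 1))


def _pipeline_rt(genome, programs, config_by_condition, g1_condition,
                 window, step, quantile=True):
    """simulate -> coverage -> (quantile-normalized) RT for >= 1 conditions.

    G1 replicates are taken from ``g1_condition`` only (shared pooled
    copy-number control); the other conditions contribute S replicates.
    """
    read_sets = []
    for prog in programs:
        phases = ("G1", "S") if prog.condition == g1_condition else ("S",)
        read_sets.extend(
            simulate_reads(genome, prog, config_by_condition[prog.condition],
                           phases=phases)
        )
    grid = make_windows(genome, window, step)
    cov = CoverageTable.from_read_sets(read_sets, grid)
    rt = rt_values(cov, pooled_g1_pairing(cov))
    if quantile:
        rt = rt.quantile_normalized()
    return rt


def null_comparison_study(
    seed: int,
    n_seeds: int = 20,
    n_windows: int = 2000,
    window: int = 100_000,
    library_size: int = 1_000_000,
    replicates: int = 3,
    alpha: float = 0.01,
    lfc: float = 0.1,
) -> dict:
    """Type-I error of the caller when the two conditions share one program.

    Two sets of S replicates are simulated from identical RT programs
    (random 100-kb blocks) with default noise and compared; reported are
    the pooled fraction of raw p-values below 0.05 and the fraction of
    windows called significant at the strict thresholds.
    """
    n_p05 = n_tests = n_called = 0
    for k in range(n_seeds):
        s = _sub_seed(seed, k)
        genome = GenomeDefinition((("chr1", n_windows * window),))
        program = RTProgram.random_blocks(genome, window, seed=s, low=0.2, high=0.8,
                                          condition="A")
        program_b = RTProgram("B", program.segments)
        cfg_a = SimulationConfig(library_size=library_size, replicates=replicates,
                                 seed=_sub_seed(s, 1))
        cfg_b = SimulationConfig(library_size=library_size, replicates=replicates,
                                 seed=_sub_seed(s, 2))
        rt = _pipeline_rt(genome, [program, program_b],
                          {"A": cfg_a, "B": cfg_b}, "A", window, window)
        res = DifferentialRTModel.from_rt_table(rt, "A", "B").fit()
        n_p05 += int((res.p < 0.05).sum())
        n_tests += len(res.p)
        n_called += int((res.calls(alpha=alpha, lfc=lfc) != CALL_NS).sum())
    return {
        "raw_p_lt_05_fraction": n_p05 / n_tests,
        "called_fraction": n_called / n_tests,
        "n_tests": n_tests,
    }


def planted_recovery_study(
    seed: int,
    n_windows: int = 500,
    frac_shifted: float = 0.15,
    delta_rt: float = 0.3,
    window: int = 100_000,
    library_size: int = 2_000_000,
    replicates: int = 3,
    alpha: float = 0.01,
    lfc: float = 0.1,
) -> dict:
    """Sensitivity and FDR on a planted differential design.

    15% of windows (by default) receive an RT shift of exactly
    ``delta_rt`` log2 units (random sign) in condition B; the timing values
    are chosen so the latent log2 copy ratio moves by precisely the target
    (t maps to copy 2 - t, so t_B = 2 - (2 - t_A) * 2^(-+delta)).
    """
    rng = np.random.default_rng(_sub_seed(seed, 0))
    genome = GenomeDefinition((("chr1", n_windows * window),))
    # base timing spans (nearly) the full range, as real genomes do; the
    # shift direction per window is whichever keeps t_B inside [0, 1]
    t_a = rng.uniform(0.05, 0.95, n_windows)
    program_a = RTProgram.from_block_values(genome, window, {"chr1": t_a}, "A")
    shifted = rng.choice(n_windows, size=int(round(frac_shifted * n_windows)),
                         replace=False)
    regions = []
    for i in shifted:
        options = []
        for sgn in (-1.0, 1.0):
            t_b = 2.0 - (2.0 - t_a[i]) * 2.0 ** (sgn * delta_rt)
            if 0.0 <= t_b <= 1.0:
                options.append(t_b)
        t_b = float(options[rng.integers(len(options))])
        regions.append(("chr1", i * window, (i + 1) * window, t_b))
    program_b = program_a.override(regions, condition="B")

    cfg_a = SimulationConfig(library_size=library_size, replicates=replicates,
                             seed=_sub_seed(seed, 1))
    cfg_b = SimulationConfig(library_size=library_size, replicates=replicates,
                             seed=_sub_seed(seed, 2))
    rt = _pipeline_rt(genome, [program_a, program_b],
                      {"A": cfg_a, "B": cfg_b}, "A", window, window)
    res = DifferentialRTModel.from_rt_table(rt, "A", "B").fit()
    called = res.calls(alpha=alpha, lfc=lfc) != CALL_NS
    truth = np.zeros(n_windows, dtype=bool)
    truth[shifted] = True
    truth = truth[res.model.window_index]
    n_called = int(called.sum())
    n_true_called = int((called & truth).sum())
    return {
        "sensitivity": n_true_called / int(truth.sum()),
        "fdr": (n_called - n_true_called) / n_called if n_called else 0.0,
        "n_truth": int(truth.sum()),
        "n_called": n_called,
    }


def rt_fidelity_study(
    seed: int,
    genome_mb: int = 8,
    depth_per_mb: int = 1_000_000,
    block: int = 100_000,
    window: int = 100_000,
    step: int = 10_000,
    replicates: int = 3,
) -> dict:
    """Spearman correlation between estimated RT and the planted timing.

    Timing is random per 100-kb block; estimated RT (replicate-averaged,
    quantile-normalized) should decrease in t, so the reported correlation
    is between RT and ``-t``.
    """
    length = genome_mb * 1_000_000
    genome = GenomeDefinition((("chr1", length),))
    program = RTProgram.random_blocks(genome, block, seed=_sub_seed(seed, 0),
                                      condition="A")
    cfg = SimulationConfig(library_size=genome_mb * depth_per_mb,
                           replicates=replicates, seed=_sub_seed(seed, 1))
    rt = _pipeline_rt(genome, [program], {"A": cfg}, "A", window, step)
    est = rt.condition_mean("A")
    truth = program.t_at_windows(rt.windows)
    rho = sp_stats.spearmanr(est, -truth).statistic
    return {"spearman": float(rho), "n_windows": len(est)}


def domain_recovery_study(
    seed: int,
    domain_size: int = 400_000,
    genome_mb: int = 8,
    library_size: int = 2_000_000,
    replicates: int = 3,
    bandwidth: int = 100_000,
    min_prominence: float = 0.1,
    window: int = 100_000,
    step: int = 10_000,
) -> dict:
    """Domain-size recovery on a square-wave RT program.

    The LOESS bandwidth is set to a quarter of the planted domain size (the
    regime where the segmentation rule is expected to resolve domains).
    Clipped terminal domains are excluded from the size distribution.
    """
    length = genome_mb * 1_000_000
    genome = GenomeDefinition((("chr1", length),))
    program = RTProgram.square_wave(genome, domain_size, condition="A")
    cfg = SimulationConfig(library_size=library_size, replicates=replicates,
                           seed=_sub_seed(seed, 1))
    rt = _pipeline_rt(genome, [program], {"A": cfg}, "A", window, step)
    profile = loess_profile(rt, condition="A", bandwidth=bandwidth)
    doms = segment(profile, min_prominence=min_prominence,
                   chrom_lengths=genome.lengths)
    sizes = doms.sizes()
    median = float(np.median(sizes)) if len(sizes) else float("nan")
    return {
        "median_size": median,
        "relative_error": abs(median - domain_size) / domain_size,
        "n_domains": int(len(sizes)),
    }


def spikein_study(
    seed: int,
    n_seeds: int = 5,
    fractions: Tuple[float, ...] = (0.01, 0.05, 0.10, 0.25, 0.50),
    n_windows: int = 100,
    frac_diff: float = 0.3,
    window: int = 100_000,
    total: int = 300_000,
    source_library: int = 600_000,
    replicates: int = 3,
    alpha: float = 0.01,
    lfc: float = 0.1,
) -> dict:
    """Spike-in sensitivity curve averaged over seeds.

    The contaminating condition differs from the base in a planted set of
    strongly-shifted windows (early <-> late); mixtures at each impurity
    fraction are called against the pure base and sensitivity is measured
    against the planted set.  Also returns the zero-impurity null call
    fraction (averaged).
    """
    sens = np.zeros((n_seeds, len(fractions)))
    null_frac = np.zeros(n_seeds)
    for k in range(n_seeds):
        s = _sub_seed(seed, 100 + k)
        rng = np.random.default_rng(s)
        genome = GenomeDefinition((("chr1", n_windows * window),))
        t_base = rng.uniform(0.05, 0.95, n_windows)
        program_base = RTProgram.from_block_values(genome, window, {"chr1": t_base},
                                                   "base")
        diff_idx = rng.choice(n_windows, size=int(round(frac_diff * n_windows)),
                              replace=False)
        regions = [("chr1", i * window, (i + 1) * window,
                    0.9 if t_base[i] < 0.5 else 0.1) for i in diff_idx]
        program_cont = program_base.override(regions, condition="contaminant")

        cfg_base = SimulationConfig(library_size=source_library, replicates=replicates,
                                    seed=_sub_seed(s, 1))
        cfg_cont = SimulationConfig(library_size=source_library, replicates=replicates,
                                    seed=_sub_seed(s, 2))
        base_sets = simulate_reads(genome, program_base, cfg_base, phases=("G1", "S"))
        g1 = [r for r in base_sets if r.phase == "G1"]
        base_s = [r for r in base_sets if r.phase == "S"]
        cont_s = simulate_reads(genome, program_cont, cfg_cont, phases=("S",))

        grid = make_windows(genome, window, window)
        truth = np.zeros(n_windows, dtype=bool)
        truth[diff_idx] = True
        design = SpikeInDesign(total=total, fractions=tuple(fractions),
                               base="base", contaminant="contaminant",
                               seed=_sub_seed(s, 3))
        report = spikein_sensitivity(base_s, cont_s, g1, grid, truth, design,
                                     alpha=alpha, lfc=lfc)
        sens[k] = report.frame["sensitivity"].to_numpy()
        null_frac[k] = report.null_called_fraction
    return {
        "fractions": list(fractions),
        "mean_sensitivity": sens.mean(axis=0).tolist(),
        "per_seed_sensitivity": sens.tolist(),
        "null_called_fraction": float(null_frac.mean()),
    }
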