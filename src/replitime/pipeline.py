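"""End-to-end pipeline driver: stages, on-disk artifacts, run summary.

Stage order: simulate (optional) -> coverage -> rt -> differential ->
fine mapping -> domains -> spike-in (optional) -> rna (optional).  Every
output file carries a ``#`` header with version, config hash and the
thresholds in force; all randomness flows through the config seed, so a
run is reproducible from its config file alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import io as rio
from .config import RunConfig, build_genome, build_programs
from .coverage import CoverageTable, make_windows
from .differential import (
    CALL_NS,
    DifferentialRTModel,
    map_frame_to_fine,
)
from .domains import segment
from .genome import GenomeDefinition
from .rtprofile import (
    RTTable,
    correlation_matrix,
    loess_profile,
    pooled_g1_pairing,
    rt_values,
)
from .simulate import ReadSet, SimulationConfig, TranscriptExpressionSpec, simulate_reads, simulate_transcripts
from .spikein import SpikeInDesign, spikein_sensitivity
from .transcription import differential_expression, rt_expression_concordance

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


class PipelineRun:
    """Mutable run state shared between stages."""

    def __init__(self, config: RunConfig) -> None:
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.header = rio.output_header(
            config=config.hash(), seed=config.seed,
            alpha=config.alpha, alpha_fine=config.alpha_fine, lfc=config.lfc,
        )
        self.genome: Optional[GenomeDefinition] = None
        self.programs: dict = {}
        self.read_sets: List[ReadSet] = []
        self.cov: Optional[CoverageTable] = None
        self.rt: Optional[RTTable] = None
        self.results = None
        self.summary: dict = {"config_hash": config.hash(), "seed": config.seed,
                              "thresholds": {"alpha": config.alpha,
                                             "alpha_fine": config.alpha_fine,
                                             "lfc": config.lfc,
                                             "mapq_min": config.mapq_min}}

        log_path = self.outdir / "run.log"
        handler = logging.FileHandler(log_path, mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logging.getLogger("replitime").addHandler(handler)
        self._log_handler = handler

    def close(self) -> None:
        logging.getLogger("replitime").removeHandler(self._log_handler)
        self._log_handler.close()


def _resolve_genome(run: PipelineRun) -> GenomeDefinition:
    cfg = run.config
    if cfg.simulate is not None:
        return build_genome(cfg.simulate["genome"])
    ann = {
        label: path
        for label, path in (cfg.genome_files.get("annotations") or {}).items()
    }
    return rio.genome_from_files(cfg.genome_files["chrom_sizes"], ann)


def stage_simulate(run: PipelineRun) -> None:
    cfg = run.config
    sim = cfg.simulate
    run.genome = _resolve_genome(run)
    run.programs = build_programs(run.genome, sim["programs"], cfg.seed)
    g1_condition = cfg.g1_condition or next(iter(run.programs))
    read_sets: List[ReadSet] = []
    for k, (name, program) in enumerate(run.programs.items()):
        contamination = sim.get("contamination", 0.0)
        if sim.get("contaminating_condition") == name:
            contamination = 0.0  # the contaminating population itself is pure
        sim_cfg = SimulationConfig(
            library_size=sim.get("library_size", 1_000_000),
            replicates=sim.get("replicates", 3),
            noise_sd=sim.get("noise_sd", 0.06),
            noise_window=sim.get("noise_window", 100_000),
            contamination=contamination,
            contaminating_condition=sim.get("contaminating_condition"),
            underreplication=sim.get("underreplication", {}).get(name, {}),
            lowmap_label=sim.get("lowmap_label"),
            seed=cfg.seed * 1000 + k,
        )
        contaminating = None
        if sim_cfg.contamination > 0:
            contaminating = run.programs[sim_cfg.contaminating_condition]
        phases = ("G1", "S") if name == g1_condition else ("S",)
        read_sets.extend(
            simulate_reads(run.genome, program, sim_cfg,
                           contaminating_program=contaminating, phases=phases)
        )
    run.read_sets = read_sets
    reads_dir = run.outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    rio.write_chrom_sizes(run.genome.chromosomes, run.outdir / "genome.chrom.sizes")
    for label, ivs in run.genome.annotations.items():
        rio.write_bed(pd.DataFrame(ivs, columns=["chrom", "start", "end"]),
                      run.outdir / f"annotation_{label}.bed", header=run.header)
    for rs in read_sets:
        rio.write_reads_bed(rs, reads_dir / f"{rs.sample_id}.bed", header=run.header)
    run.summary["samples"] = [rs.sample_id for rs in read_sets]


def stage_load_samples(run: PipelineRun) -> None:
    cfg = run.config
    run.genome = _resolve_genome(run)
    lengths = run.genome.lengths
    run.read_sets = [
        rio.read_reads_bed(s.path, s.id, s.condition, s.phase, s.replicate,
                           chrom_lengths=lengths)
        for s in cfg.samples
    ]
    run.summary["samples"] = [rs.sample_id for rs in run.read_sets]


def stage_coverage(run: PipelineRun) -> None:
    cfg = run.config
    grid = make_windows(run.genome, cfg.window_size, cfg.window_step)
    run.cov = CoverageTable.from_read_sets(run.read_sets, grid,
                                           mapq_min=cfg.mapq_min)
    out = run.cov.grid.windows.copy()
    for s in run.cov.samples:
        out[s] = run.cov.counts[s].to_numpy()
    rio.write_tsv(out, run.outdir / "coverage.tsv", header=run.header)
    rio.write_tsv(run.cov.meta.reset_index(), run.outdir / "coverage_meta.tsv",
                  header=run.header)
    run.summary["retained_reads"] = run.cov.meta["retained"].to_dict()
    run.summary["skipped_reads"] = int(run.cov.meta["skipped"].sum())


def _pairing(run: PipelineRun) -> dict:
    cfg = run.config
    if cfg.samples is not None:
        explicit = {s.id: s.g1 for s in cfg.samples if s.phase == "S" and s.g1}
        default = tuple(run.cov.samples_where(phase="G1"))
        return {
            s: tuple(explicit.get(s, default))
            for s in run.cov.samples_where(phase="S")
        }
    return pooled_g1_pairing(run.cov)


def stage_rt(run: PipelineRun) -> None:
    cfg = run.config
    rt = rt_values(run.cov, _pairing(run), pseudo=cfg.pseudo)
    if cfg.quantile:
        rt = rt.quantile_normalized()
    run.rt = rt
    out = rt.windows.reset_index(drop=True)
    out = pd.concat([out, rt.values.reset_index(drop=True)], axis=1)
    means = rt.condition_means()
    for cond in means.columns:
        out[f"mean_{cond}"] = means[cond].to_numpy()
        rio.write_bedgraph(rt.windows, means[cond].to_numpy(),
                           run.outdir / f"rt_{cond}.bedgraph", header=run.header)
    rio.write_tsv(out, run.outdir / "rt.tsv", header=run.header)
    run.summary["n_windows"] = len(rt.grid)
    run.summary["n_masked_windows"] = rt.n_masked
    run.summary["normalization"] = rt.normalized
    if rt.values.shape[1] >= 2:
        corr = correlation_matrix(rt)
        run.summary["correlation_matrix"] = {
            "samples": list(corr.columns),
            "values": corr.round(4).to_numpy().tolist(),
        }


def stage_differential(run: PipelineRun) -> None:
    cfg = run.config
    a, b = cfg.compare
    res = DifferentialRTModel.from_rt_table(run.rt, a, b).fit()
    run.results = res
    frame = res.frame.copy()
    frame["call"] = res.calls(alpha=cfg.alpha, lfc=cfg.lfc)
    rio.write_tsv(frame, run.outdir / "differential.tsv", header=run.header)
    run.summary["differential"] = res.call_summary(alpha=cfg.alpha, lfc=cfg.lfc)
    run.summary["differential"]["df_prior"] = res.df_prior
    run.summary["differential"]["s2_prior"] = res.s2_prior
    (run.outdir / "differential_summary.txt").write_text(
        res.summary(alpha=cfg.alpha, lfc=cfg.lfc) + "\n"
    )


def stage_fine(run: PipelineRun) -> None:
    cfg = run.config
    fine = run.results.map_to_fine(alpha=cfg.alpha_fine, lfc=cfg.lfc)
    rio.write_tsv(fine.frame, run.outdir / "fine.tsv", header=run.header)
    run.summary["fine"] = fine.call_summary()
    run._fine = fine


def stage_domains(run: PipelineRun) -> None:
    cfg = run.config
    conds = cfg.compare or sorted(set(run.rt.conditions.values()))
    dom_stats = {}
    frames, bounds = [], []
    for cond in conds:
        profile = loess_profile(run.rt, condition=cond,
                                bandwidth=cfg.loess_bandwidth)
        doms = segment(profile, min_prominence=cfg.min_prominence,
                       chrom_lengths=run.genome.lengths)
        d = doms.domains.copy()
        d["name"] = cond + "_" + d["cls"]
        frames.append(d)
        bd = doms.boundaries.copy()
        bd["name"] = cond
        bounds.append(bd)
        sizes = doms.sizes()
        dom_stats[cond] = {
            "n_domains": int(len(sizes)),
            "median_size": float(np.median(sizes)) if len(sizes) else None,
        }
    if frames:
        all_d = pd.concat(frames, ignore_index=True)
        all_d["score"] = 0
        rio.write_bed(all_d, run.outdir / "domains.bed", header=run.header)
        all_b = pd.concat(bounds, ignore_index=True)
        all_b = pd.DataFrame({"chrom": all_b["chrom"], "start": all_b["pos"],
                              "end": all_b["pos"] + 1, "name": all_b["name"]})
        rio.write_bed(all_b, run.outdir / "boundaries.bed", header=run.header)
    run.summary["domains"] = dom_stats


def stage_spikein(run: PipelineRun) -> None:
    cfg = run.config
    if cfg.simulate is None:
        raise ValueError("spike-in stage requires a simulate-mode run")
    sp = cfg.spikein
    base_cond = sp.get("base", cfg.compare[0] if cfg.compare else None)
    cont_cond = sp.get("contaminant", cfg.compare[1] if cfg.compare else None)
    base_s = [r for r in run.read_sets if r.condition == base_cond and r.phase == "S"]
    cont_s = [r for r in run.read_sets if r.condition == cont_cond and r.phase == "S"]
    g1 = [r for r in run.read_sets if r.phase == "G1"]
    design = SpikeInDesign(
        total=sp.get("total", 30_000_000),
        fractions=tuple(sp.get("fractions", (0.01, 0.05, 0.10, 0.25, 0.50))),
        base=base_cond, contaminant=cont_cond, seed=cfg.seed + 7,
    )
    # truth: the pure A-vs-B call set at the configured thresholds
    truth = np.zeros(len(run.cov.grid), dtype=bool)
    truth[run.results.model.window_index] = (
        run.results.calls(alpha=cfg.alpha, lfc=cfg.lfc) != CALL_NS
    )
    report = spikein_sensitivity(base_s, cont_s, g1, run.cov.grid, truth, design,
                                 alpha=cfg.alpha, lfc=cfg.lfc,
                                 mapq_min=cfg.mapq_min, quantile=cfg.quantile,
                                 truth_definition="pure-comparison calls")
    rio.write_tsv(report.frame, run.outdir / "spikein.tsv", header=run.header)
    run.summary["spikein"] = {
        "fractions": report.frame["fraction"].tolist(),
        "sensitivity": report.frame["sensitivity"].tolist(),
        "null_called_fraction": report.null_called_fraction,
    }


def stage_rna(run: PipelineRun) -> None:
    cfg = run.config
    if cfg.simulate is None:
        raise ValueError("rna stage requires a simulate-mode run")
    rna = cfg.rna or {}
    spec = TranscriptExpressionSpec(**rna.get("expression", {}))
    a, b = cfg.compare
    sim_cfg = SimulationConfig(
        replicates=cfg.simulate.get("replicates", 3), seed=cfg.seed + 13
    )
    transcripts, counts = simulate_transcripts(run.genome, spec, sim_cfg,
                                               conditions=(a, b))
    cols_a = [c for c in counts.columns if c.startswith(f"{a}_")]
    cols_b = [c for c in counts.columns if c.startswith(f"{b}_")]
    de = differential_expression(counts[cols_a], counts[cols_b])
    tx = pd.concat([transcripts.reset_index(drop=True), de.reset_index(drop=True)],
                   axis=1)
    rio.write_tsv(tx, run.outdir / "rna.tsv", header=run.header)
    fine = run._fine.frame
    conc = rt_expression_concordance(tx, fine)
    run.summary["rna"] = {
        "n_transcripts": len(tx),
        "n_de_p01": int((de["p"] < 0.01).sum()),
        "concordance": conc["crosstab"],
        "rt_expression_correlation": conc["correlation"],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the summary dict (also
    written to ``summary.json``).  A stage failure aborts with the stage
    name; outputs written before the failure are flagged partial."""
    run = PipelineRun(config)
    stages = [("simulate" if config.simulate is not None else "load_samples",
               stage_simulate if config.simulate is not None else stage_load_samples),
              ("coverage", stage_coverage),
              ("rt", stage_rt)]
    if config.compare is not None:
        stages += [("differential", stage_differential), ("fine", stage_fine)]
    stages.append(("domains", stage_domains))
    if config.spikein is not None:
        stages.append(("spikein", stage_spikein))
    if config.rna is not None:
        stages.append(("rna", stage_rna))
    try:
        for name, fn in stages:
            logger.info("stage %s", name)
            try:
                fn(run)
            except Exception as exc:
                run.summary["failed_stage"] = name
                (run.outdir / "summary.json").write_text(
                    json.dumps(run.summary, indent=2, default=str) + "\n"
                )
                raise PipelineError(name, exc) from exc
        (run.outdir / "summary.json").write_text(
            json.dumps(run.summary, indent=2, default=str) + "\n"
        )
        return run.summary
    finally:
        run.close()
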