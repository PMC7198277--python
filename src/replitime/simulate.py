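"""Synthetic read populations with a planted replication-timing program.

The S/G1 method rests on one premise: within a sorted S-phase population,
early-replicating DNA is over-represented relative to late-replicating DNA,
because a cell that has progressed a fraction *f* through S phase carries two
copies of every locus whose timing value *t* is below *f* and one copy of
every later locus.  The generator makes that premise literal: each condition
carries a latent timing track ``t(w) in [0, 1]`` (0 = earliest, 1 = latest),
and read positions are drawn with density proportional to the expected
relative copy number implied by *t*, the cell-cycle phase, and the S-phase
progression distribution.

On top of the copy-number signal the generator layers the nuisance structure
the downstream analysis must survive:

* window-level multiplicative replicate noise (log-normal in log2 units),
* FACS-gate contamination (a fraction of reads drawn from a second
  condition's timing program),
* underreplication (annotation-scoped copy-number reduction, as seen in
  pericentric heterochromatin of endocycling cells), and
* an optional low-mappability annotation whose reads receive MAPQ <= 10 so
  the mapping-quality filter is exercised.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeDefinition

logger = logging.getLogger(__name__)

PHASES = ("G1", "S")


# ---------------------------------------------------------------------------
# latent timing program
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RTProgram:
    """Piecewise-constant timing track for one condition.

    ``segments`` is a tuple of ``(chrom, start, end, t)`` that must tile each
    chromosome exactly (contiguous from 0, no gaps or overlaps), with
    ``t in [0, 1]``; 0 replicates earliest, 1 latest.
    """

    condition: str
    segments: Tuple[Tuple[str, int, int, float], ...]

    def __post_init__(self) -> None:
        segs = tuple((str(c), int(s), int(e), float(t)) for c, s, e, t in self.segments)
        if not segs:
            raise ValueError("timing program has no segments")
        last: dict = {}
        for chrom, start, end, t in segs:
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"timing value {t} outside [0, 1] at {chrom}:{start}-{end}")
            if start >= end:
                raise ValueError(f"empty segment {chrom}:{start}-{end}")
            expect = last.get(chrom, 0)
            if start != expect:
                raise ValueError(
                    f"segments do not tile {chrom}: expected start {expect}, got {start}"
                )
            last[chrom] = end
        object.__setattr__(self, "segments", segs)

    def validate_against(self, genome: GenomeDefinition) -> None:
        ends: dict = {}
        for chrom, _, end, _ in self.segments:
            if chrom not in genome.lengths:
                raise ValueError(f"program names unknown chromosome {chrom!r}")
            ends[chrom] = end
        for name, length in genome.chromosomes:
            if ends.get(name) != length:
                raise ValueError(
                    f"program does not tile chromosome {name!r} "
                    f"(covers up to {ends.get(name)}, length {length})"
                )

    # -- constructors ------------------------------------------------------

    @classmethod
    def constant(cls, genome: GenomeDefinition, t: float, condition: str = "cond") -> "RTProgram":
        return cls(condition, tuple((n, 0, l, t) for n, l in genome.chromosomes))

    @classmethod
    def from_block_values(
        cls,
        genome: GenomeDefinition,
        block_size: int,
        values: Mapping[str, Sequence[float]],
        condition: str = "cond",
    ) -> "RTProgram":
        """One t value per ``block_size`` block, per chromosome; the trailing
        partial block (if any) extends the last value to the chromosome end."""
        segs = []
        for name, length in genome.chromosomes:
            vals = list(values[name])
            n_blocks = max(1, -(-length // block_size))
            if len(vals) != n_blocks:
                raise ValueError(f"{name}: expected {n_blocks} block values, got {len(vals)}")
            for i, t in enumerate(vals):
                start = i * block_size
                end = min(length, (i + 1) * block_size)
                segs.append((name, start, end, t))
        return cls(condition, tuple(segs))

    @classmethod
    def random_blocks(
        cls,
        genome: GenomeDefinition,
        block_size: int,
        seed: int = 0,
        low: float = 0.0,
        high: float = 1.0,
        condition: str = "cond",
    ) -> "RTProgram":
        rng = np.random.default_rng(seed)
        values = {}
        for name, length in genome.chromosomes:
            n_blocks = max(1, -(-length // block_size))
            values[name] = rng.uniform(low, high, n_blocks)
        return cls.from_block_values(genome, block_size, values, condition)

    @classmethod
    def square_wave(
        cls,
        genome: GenomeDefinition,
        domain_size: int,
        t_early: float = 0.15,
        t_late: float = 0.85,
        condition: str = "cond",
    ) -> "RTProgram":
        """Alternating early/late domains of fixed size (replication-domain
        recovery benchmark)."""
        segs = []
        for name, length in genome.chromosomes:
            pos, i = 0, 0
            while pos < length:
                end = min(length, pos + domain_size)
                segs.append((name, pos, end, t_early if i % 2 == 0 else t_late))
                pos, i = end, i + 1
        return cls(condition, tuple(segs))

    # -- derivation and lookup --------------------------------------------

    def override(
        self, regions: Iterable[Tuple[str, int, int, float]], condition: Optional[str] = None
    ) -> "RTProgram":
        """Return a copy with ``t`` replaced inside the given regions.

        Used to plant differential-RT windows: the returned program is
        identical to ``self`` outside ``regions``.
        """
        overrides = [(str(c), int(s), int(e), float(t)) for c, s, e, t in regions]
        by_chrom: dict = {}
        for c, s, e, t in overrides:
            by_chrom.setdefault(c, []).append((s, e, t))
        segs = []
        for chrom, start, end, t in self.segments:
            cuts = {start, end}
            for s, e, _ in by_chrom.get(chrom, ()):
                if s < end and e > start:
                    cuts.add(max(s, start))
                    cuts.add(min(e, end))
            edges = sorted(cuts)
            for a, b in zip(edges[:-1], edges[1:]):
                t_here = t
                for s, e, t_new in by_chrom.get(chrom, ()):
                    if s <= a and b <= e:
                        t_here = t_new
                segs.append((chrom, a, b, t_here))
        return RTProgram(condition or self.condition, tuple(segs))

    def t_at_windows(self, windows: pd.DataFrame) -> np.ndarray:
        """Length-weighted mean timing value per window.

        ``windows`` needs ``chrom``, ``start``, ``end`` columns.  This is the
        ground truth against which estimated RT is compared in recovery tests.
        """
        by_chrom: dict = {}
        for chrom, start, end, t in self.segments:
            by_chrom.setdefault(chrom, []).append((start, end, t))
        out = np.empty(len(windows), dtype=float)
        for i, (chrom, start, end) in enumerate(
            zip(windows["chrom"], windows["start"], windows["end"])
        ):
            segs = by_chrom.get(chrom)
            if segs is None:
                raise ValueError(f"window on chromosome {chrom!r} absent from program")
            acc = w = 0.0
            for s, e, t in segs:
                ov = min(e, end) - max(s, start)
                if ov > 0:
                    acc += ov * t
                    w += ov
            out[i] = acc / w
        return out


# ---------------------------------------------------------------------------
# configuration and read containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Knobs of the read generator.

    Parameters
    ----------
    library_size
        Expected number of reads per sample (the realized total is Poisson
        around this value).
    replicates
        Replicates per condition and phase.
    noise_sd
        Window-level multiplicative replicate noise, log-normal with this
        standard deviation in log2 units.  The default (0.06) is calibrated so
        that default simulations reproduce inter-replicate RT correlations of
        roughly 0.9-0.95, as observed for real replicate pairs.
    noise_window
        Granularity (bp) at which the replicate noise is drawn.
    progression
        S-phase progression distribution: ``"uniform"`` or any frozen
        distribution with a ``cdf`` method supported on [0, 1].
    contamination
        FACS-gate impurity fraction pi in [0, 1]: this share of each sample's
        reads follows the contaminating condition's timing program.
    underreplication
        Mapping annotation label -> factor ``u in (0, 1]`` multiplying the
        copy number inside that annotation (both phases; underreplication is
        a property of the tissue's genome, not of the sorting gate).
    lowmap_label
        Optional annotation label inside which simulated reads get
        MAPQ <= 10, exercising the mapping-quality filter.
    """

    library_size: int = 1_000_000
    replicates: int = 3
    noise_sd: float = 0.06
    noise_window: int = 100_000
    progression: object = "uniform"
    contamination: float = 0.0
    contaminating_condition: Optional[str] = None
    underreplication: Mapping[str, float] = field(default_factory=dict)
    lowmap_label: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError("contamination fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_window <= 0:
            raise ValueError("noise_window must be > 0")
        for label, u in dict(self.underreplication).items():
            if not 0.0 < u <= 1.0:
                raise ValueError(f"underreplication factor for {label!r} must be in (0, 1]")


@dataclass
class ReadSet:
    """Aligned-read records for one sample.

    ``records`` holds one row per read with columns ``chrom`` (str),
    ``pos`` (0-based position, int) and ``mapq`` (int); extra columns (e.g.
    ``origin`` provenance tags from spike-in mixing) are preserved.
    """

    sample_id: str
    condition: str
    phase: str
    replicate: int
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        required = {"chrom", "pos", "mapq"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(required)}")

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# the generative model
# ---------------------------------------------------------------------------

def expected_relative_copy_number(t, phase: str, progression: object = "uniform"):
    """Expected copy number of a locus, relative to the G1 (2C) baseline.

    A G1 cell carries one relative copy of every locus.  A sorted S-phase
    cell at progression fraction ``f`` carries two relative copies of a locus
    with timing ``t`` iff ``f > t``, so the expectation over the gate is
    ``1 + P(f > t)``; with uniform progression that is ``2 - t``.

    Accepts scalars or arrays; returns the matching shape.
    """
    scalar = np.isscalar(t)
    t_arr = np.asarray(t, dtype=float)
    if np.any((t_arr < 0.0) | (t_arr > 1.0)):
        raise ValueError("timing values must lie in [0, 1]")
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}, got {phase!r}")
    if phase == "G1":
        out = np.ones_like(t_arr)
    else:
        if isinstance(progression, str):
            if progression != "uniform":
                raise ValueError(f"unknown progression {progression!r}")
            cdf = t_arr
        else:
            cdf = np.asarray(progression.cdf(t_arr), dtype=float)
        out = 2.0 - cdf
    return float(out) if scalar else out


def _atomize(
    genome: GenomeDefinition,
    program: RTProgram,
    config: SimulationConfig,
    contaminating: Optional[RTProgram],
):
    """Split the genome into atomic intervals of constant generative rate.

    Returns parallel arrays: chrom index, start, end, t (main program),
    t_contaminant, underreplication factor, low-mappability flag, and a
    global noise-window index.
    """
    def bounds(prog):
        d: dict = {}
        if prog is not None:
            for chrom, start, end, t in prog.segments:
                d.setdefault(chrom, []).append((start, end, t))
        return d

    main = bounds(program)
    cont = bounds(contaminating)
    under_ivs = {
        label: genome.annotation(label) for label in config.underreplication
    }
    lowmap_ivs = genome.annotation(config.lowmap_label) if config.lowmap_label else ()

    cols: dict = {k: [] for k in
                  ("ci", "start", "end", "t", "t_cont", "u", "lowmap", "noise_idx")}
    noise_offset = 0
    for ci, (name, length) in enumerate(genome.chromosomes):
        cuts = {0, length}
        cuts.update(range(config.noise_window, length, config.noise_window))
        for s, e, _ in main.get(name, ()):
            cuts.update((s, e))
        for s, e, _ in cont.get(name, ()):
            cuts.update((s, e))
        for ivs in under_ivs.values():
            cuts.update(x for c, s, e in ivs if c == name for x in (s, e))
        cuts.update(x for c, s, e in lowmap_ivs if c == name for x in (s, e))
        edges = sorted(c for c in cuts if 0 <= c <= length)

        def lookup(d, pos):
            for s, e, t in d.get(name, ()):
                if s <= pos < e:
                    return t
            raise ValueError(f"position {name}:{pos} not covered by program")

        for a, b in zip(edges[:-1], edges[1:]):
            mid = a  # atoms never straddle a boundary, left edge identifies them
            u = 1.0
            for label, ivs in under_ivs.items():
                if any(c == name and s <= mid < e for c, s, e in ivs):
                    u *= config.underreplication[label]
            cols["ci"].append(ci)
            cols["start"].append(a)
            cols["end"].append(b)
            cols["t"].append(lookup(main, mid))
            cols["t_cont"].append(lookup(cont, mid) if cont else 0.0)
            cols["u"].append(u)
            cols["lowmap"].append(
                any(c == name and s <= mid < e for c, s, e in lowmap_ivs)
            )
            cols["noise_idx"].append(noise_offset + a // config.noise_window)
        noise_offset += -(-length // config.noise_window)
    arrays = {k: np.asarray(v) for k, v in cols.items()}
    arrays["n_noise"] = noise_offset
    return arrays


def simulate_reads(
    genome: GenomeDefinition,
    program: RTProgram,
    config: SimulationConfig,
    contaminating_program: Optional[RTProgram] = None,
    phases: Sequence[str] = PHASES,
) -> list:
    """Draw G1 and S read populations for one condition.

    Per sample, the read count in each atomic interval is Poisson with mean
    proportional to ``interval length x expected copy number x
    underreplication x 2^(window noise)``, scaled so the expected total is
    ``config.library_size``; positions are uniform within the interval.
    Reruns with the same seed produce identical read sets.
    """
    program.validate_against(genome)
    if config.contamination > 0 and contaminating_program is None:
        raise ValueError(
            "contamination fraction > 0 requires a contaminating timing program"
        )
    if contaminating_program is not None:
        contaminating_program.validate_against(genome)
    atoms = _atomize(genome, program, config, contaminating_program)
    rng = np.random.default_rng(config.seed)
    names = genome.names
    lengths = atoms["end"] - atoms["start"]
    pi = config.contamination

    read_sets = []
    for phase in phases:
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}")
        for rep in range(1, config.replicates + 1):
            eps = rng.normal(0.0, config.noise_sd, atoms["n_noise"])
            copy = expected_relative_copy_number(atoms["t"], phase, config.progression)
            if pi > 0:
                copy_c = expected_relative_copy_number(
                    atoms["t_cont"], phase, config.progression
                )
                copy = (1.0 - pi) * copy + pi * copy_c
            rate = lengths * copy * atoms["u"] * np.exp2(eps[atoms["noise_idx"]])
            lam = config.library_size * rate / rate.sum()
            counts = rng.poisson(lam)
            pos_parts, chrom_parts, mapq_parts = [], [], []
            for i in np.flatnonzero(counts):
                c = counts[i]
                pos_parts.append(rng.integers(atoms["start"][i], atoms["end"][i], c))
                chrom_parts.append(np.full(c, atoms["ci"][i], dtype=np.int32))
                if atoms["lowmap"][i]:
                    mapq_parts.append(rng.integers(0, 11, c).astype(np.int16))
                else:
                    mapq_parts.append(np.full(c, 60, dtype=np.int16))
            if pos_parts:
                pos = np.concatenate(pos_parts)
                ci = np.concatenate(chrom_parts)
                mapq = np.concatenate(mapq_parts)
                order = np.lexsort((pos, ci))
                records = pd.DataFrame(
                    {
                        "chrom": np.asarray(names, dtype=object)[ci[order]],
                        "pos": pos[order].astype(np.int64),
                        "mapq": mapq[order],
                    }
                )
            else:
                records = pd.DataFrame(
                    {"chrom": pd.Series(dtype=object),
                     "pos": pd.Series(dtype=np.int64),
                     "mapq": pd.Series(dtype=np.int16)}
                )
            sample_id = f"{program.condition}_{phase}_{rep}"
            read_sets.append(
                ReadSet(sample_id, program.condition, phase, rep, records)
            )
    logger.info(
        "simulated %d samples for condition %r (library ~%d reads)",
        len(read_sets), program.condition, config.library_size,
    )
    return read_sets


# ---------------------------------------------------------------------------
# transcript counterpart
# ---------------------------------------------------------------------------

@dataclass
class TranscriptExpressionSpec:
    """Design of the synthetic transcript population.

    A fraction of transcripts is condition-specific (mean 0 in the other
    condition), a fraction is differentially expressed between conditions at
    ``de_log2fc`` with random sign, and the rest share a common mean.  Counts
    are negative binomial with the given dispersion.
    """

    n_transcripts: int = 500
    log2_mean_low: float = 3.0
    log2_mean_high: float = 9.0
    dispersion: float = 0.1
    frac_a_specific: float = 0.05
    frac_b_specific: float = 0.05
    frac_de: float = 0.10
    de_log2fc: float = 2.0
    length_low: int = 500
    length_high: int = 5_000

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.frac_a_specific + self.frac_b_specific + self.frac_de > 1:
            raise ValueError("class fractions exceed 1")


def simulate_transcripts(
    genome: GenomeDefinition,
    spec: TranscriptExpressionSpec,
    config: SimulationConfig,
    conditions: Tuple[str, str] = ("A", "B"),
):
    """Negative-binomial transcript counts with retained truth labels.

    Returns ``(transcripts, counts)``: a transcript table (coordinates,
    length, truth class in {shared, A_specific, B_specific, shared_de} and
    true log2 fold change A vs B) and a replicate count matrix whose columns
    are ``{condition}_rna_{replicate}``.
    """
    rng = np.random.default_rng(config.seed)
    n = spec.n_transcripts
    cond_a, cond_b = conditions

    n_a = int(round(spec.frac_a_specific * n))
    n_b = int(round(spec.frac_b_specific * n))
    n_de = int(round(spec.frac_de * n))
    classes = np.array(
        ["A_specific"] * n_a + ["B_specific"] * n_b + ["shared_de"] * n_de
        + ["shared"] * (n - n_a - n_b - n_de)
    )
    rng.shuffle(classes)

    base = np.exp2(rng.uniform(spec.log2_mean_low, spec.log2_mean_high, n))
    mean_a = base.copy()
    mean_b = base.copy()
    mean_b[classes == "A_specific"] = 0.0
    mean_a[classes == "B_specific"] = 0.0
    signs = rng.choice([-1.0, 1.0], n)
    de = classes == "shared_de"
    mean_b[de] = base[de] * np.exp2(-signs[de] * spec.de_log2fc)

    with np.errstate(divide="ignore"):
        true_lfc = np.log2(mean_a) - np.log2(mean_b)

    chrom_names = genome.names
    chrom_lengths = np.array([genome.chrom_length(c) for c in chrom_names], dtype=float)
    ci = rng.choice(len(chrom_names), n, p=chrom_lengths / chrom_lengths.sum())
    lengths = rng.integers(spec.length_low, spec.length_high + 1, n)
    starts = np.empty(n, dtype=np.int64)
    for i in range(n):
        max_start = max(1, int(chrom_lengths[ci[i]]) - int(lengths[i]))
        starts[i] = rng.integers(0, max_start)

    transcripts = pd.DataFrame(
        {
            "transcript_id": [f"tx{i:05d}" for i in range(n)],
            "chrom": np.asarray(chrom_names, dtype=object)[ci],
            "start": starts,
            "end": starts + lengths,
            "length": lengths,
            "true_class": classes,
            "true_log2fc": true_lfc,
        }
    )

    r = 1.0 / spec.dispersion
    counts = {}
    for cond, means in ((cond_a, mean_a), (cond_b, mean_b)):
        for rep in range(1, config.replicates + 1):
            col = np.zeros(n, dtype=np.int64)
            pos = means > 0
            p = r / (r + means[pos])
            col[pos] = rng.negative_binomial(r, p)
            counts[f"{cond}_rna_{rep}"] = col
    counts_df = pd.DataFrame(counts, index=transcripts["transcript_id"])
    return transcripts, counts_df
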