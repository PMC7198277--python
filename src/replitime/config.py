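"""Run configuration: YAML schema, validation, hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Mapping, Optional, Tuple

import yaml

from .genome import GenomeDefinition
from .simulate import RTProgram


@dataclass
class SampleEntry:
    """One manifest row: an aligned-read BED file plus sample metadata."""

    id: str
    path: str
    condition: str
    phase: str
    replicate: int
    g1: Optional[List[str]] = None  # G1 sample id(s); None -> pooled default


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML.

    Exactly one of ``simulate`` (generator-driven run) or ``samples``
    (manifest of read BED files; needs ``genome_files``) must be present.
    """

    outdir: str = "replitime_out"
    seed: int = 0
    window_size: int = 100_000
    window_step: int = 10_000
    mapq_min: int = 10
    quantile: bool = True
    pseudo: float = 0.0
    alpha: float = 0.01
    alpha_fine: float = 0.05
    lfc: float = 0.1
    loess_bandwidth: int = 250_000
    min_prominence: float = 0.1
    compare: Optional[Tuple[str, str]] = None
    g1_condition: Optional[str] = None
    simulate: Optional[dict] = None
    samples: Optional[List[SampleEntry]] = None
    genome_files: Optional[dict] = None  # {chrom_sizes: path, annotations: {label: bed}}
    spikein: Optional[dict] = None
    rna: Optional[dict] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Mapping, base_dir: Optional[Path] = None) -> "RunConfig":
        raw = dict(raw)
        samples = raw.pop("samples", None)
        entries = None
        if samples is not None:
            entries = []
            for s in samples:
                s = dict(s)
                g1 = s.get("g1")
                if isinstance(g1, str):
                    s["g1"] = [g1]
                if base_dir is not None and not Path(s["path"]).is_absolute():
                    s["path"] = str(base_dir / s["path"])
                entries.append(SampleEntry(**s))
        compare = raw.pop("compare", None)
        cfg = cls(samples=entries,
                  compare=tuple(compare) if compare else None,
                  **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if (self.simulate is None) == (self.samples is None):
            raise ValueError("config needs exactly one of 'simulate' or 'samples'")
        if not (self.window_size >= self.window_step > 0):
            raise ValueError("window_size must satisfy size >= step > 0")
        if self.samples is not None:
            if self.genome_files is None or "chrom_sizes" not in self.genome_files:
                raise ValueError("manifest mode requires genome_files.chrom_sizes")
            ids = [s.id for s in self.samples]
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate sample ids in manifest")
            by_id = {s.id: s for s in self.samples}
            g1_ids = [s.id for s in self.samples if s.phase == "G1"]
            for s in self.samples:
                if s.phase not in ("G1", "S"):
                    raise ValueError(f"sample {s.id!r}: phase must be G1 or S")
                if not Path(s.path).exists():
                    raise ValueError(f"sample {s.id!r}: missing input file {s.path}")
                if s.phase == "S":
                    pairing = s.g1 if s.g1 is not None else g1_ids
                    if not pairing:
                        raise ValueError(
                            f"S sample {s.id!r} has no G1 pairing and the "
                            "manifest contains no G1 samples"
                        )
                    for g in pairing:
                        if g not in by_id or by_id[g].phase != "G1":
                            raise ValueError(
                                f"S sample {s.id!r}: G1 pairing {g!r} is not a "
                                "G1 sample in the manifest"
                            )
        if self.simulate is not None:
            if "genome" not in self.simulate or "programs" not in self.simulate:
                raise ValueError("simulate section needs 'genome' and 'programs'")
        if self.compare is not None and len(self.compare) != 2:
            raise ValueError("compare must list exactly two conditions")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if v is not None}
        if self.samples is not None:
            d["samples"] = [s.__dict__ for s in self.samples]
        if self.compare is not None:
            d["compare"] = list(self.compare)
        return d

    def hash(self) -> str:
        """Digest of the analysis-defining fields (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.md5(blob.encode()).hexdigest()[:12]


def build_genome(spec: Mapping) -> GenomeDefinition:
    """Genome from the config's inline ``simulate.genome`` mapping:
    ``{chromosomes: {name: length}, annotations: {label: [[chrom, s, e]]}}``."""
    chroms = tuple(spec["chromosomes"].items())
    annotations = {
        label: [tuple(iv) for iv in ivs]
        for label, ivs in (spec.get("annotations") or {}).items()
    }
    return GenomeDefinition(chroms, annotations)


def build_programs(genome: GenomeDefinition, spec: Mapping, seed: int) -> dict:
    """Timing programs from the config's ``simulate.programs`` mapping.

    Supported kinds: ``constant`` (t), ``random_blocks`` (block_size, low,
    high), ``square_wave`` (domain_size, t_early, t_late) and ``derive``
    (from: <condition>, regions: [[chrom, start, end, t]]) which overrides
    another program inside the listed regions.
    """
    programs: dict = {}
    pending = dict(spec)
    guard = 0
    while pending:
        guard += 1
        if guard > 100:
            raise ValueError("circular 'derive' references in programs")
        for name in list(pending):
            p = dict(pending[name])
            kind = p.pop("kind", "random_blocks")
            if kind == "derive":
                src = p["from"]
                if src not in programs:
                    continue
                regions = [tuple(r) for r in p["regions"]]
                programs[name] = programs[src].override(regions, condition=name)
            elif kind == "constant":
                programs[name] = RTProgram.constant(genome, p["t"], condition=name)
            elif kind == "random_blocks":
                programs[name] = RTProgram.random_blocks(
                    genome, p.get("block_size", 100_000),
                    seed=seed + p.get("seed_offset", 0),
                    low=p.get("low", 0.0), high=p.get("high", 1.0),
                    condition=name,
                )
            elif kind == "square_wave":
                programs[name] = RTProgram.square_wave(
                    genome, p["domain_size"],
                    t_early=p.get("t_early", 0.15), t_late=p.get("t_late", 0.85),
                    condition=name,
                )
            else:
                raise ValueError(f"unknown program kind {kind!r}")
            del pending[name]
    return programs
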