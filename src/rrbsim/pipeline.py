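"""Experiment orchestration: configuration, staged execution, reports.

A single :class:`PipelineConfig` (YAML-loadable) describes one library —
RRBS (digest + size selection) or WGBS (sonication) — and the full run
executes simulate -> fragment -> reads -> trim -> map -> call -> coverage
(-> saturation), writing TSV/JSON reports plus a machine-readable manifest.
All stage randomness derives deterministically from one global seed, so an
identical config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .align import (MapperConfig, alignments_to_frame, build_index, map_pairs,
                    mapping_efficiency)
from .calls import call_methylation, conversion_qc, mean_methylation
from .coverage import (CoverageThresholds, count_cpg_coverage, feature_coverage,
                       saturation_analysis)
from .fragments import MSPI, Enzyme, Fragment, SizeWindow, rrbs_library, sonicate
from .genome import (GenomeConfig, MethylomeParams, ReferenceGenome,
                     simulate_genome, simulate_methylome, write_reference)
from .reads import (ConversionParams, QualityModel, TrimConfig, trim_pairs,
                    write_fastq_pairs)

__all__ = [
    "SonicationParams",
    "PipelineConfig",
    "ConfigError",
    "StageError",
    "validate_config",
    "config_from_dict",
    "derive_seed",
    "run_experiment",
    "compare_runs",
]

logger = logging.getLogger("rrbsim")


class ConfigError(ValueError):
    """Invalid pipeline configuration; carries the full error list."""

    def __init__(self, errors: List[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SonicationParams:
    length_mean: float = 350.0
    length_sd: float = 50.0
    window: SizeWindow = field(default_factory=lambda: SizeWindow(300, 400))

    def validate(self) -> List[str]:
        errors = []
        if self.length_mean <= 0 or self.length_sd <= 0:
            errors.append("sonication: length_mean and length_sd must be > 0")
        return errors


@dataclass
class PipelineConfig:
    """Everything one experiment needs, with field-level defaults matching
    a directional 100 bp paired-end HiSeq-style design."""

    library_type: str = "rrbs"  # rrbs | wgbs
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    methylome: MethylomeParams = field(default_factory=MethylomeParams)
    enzyme: Enzyme = MSPI
    size_window: SizeWindow = field(default_factory=lambda: SizeWindow(150, 250))
    sonication: SonicationParams = field(default_factory=SonicationParams)
    read_length: int = 100
    n_read_pairs: Optional[int] = None
    target_depth: float = 20.0
    conversion: ConversionParams = field(default_factory=ConversionParams)
    quality: QualityModel = field(default_factory=QualityModel)
    trim: Optional[TrimConfig] = None   # filled in __post_init__ from library type
    mapper: Optional[MapperConfig] = None  # insert window derived from size window
    thresholds: CoverageThresholds = field(default_factory=CoverageThresholds)
    saturation_fractions: Tuple[float, ...] = ()
    full_gb: float = 30.0
    output_dir: str = "rrbsim_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trim is None:
            self.trim = TrimConfig(rrbs_mode=self.library_type == "rrbs")
        if self.mapper is None:
            window = (self.size_window if self.library_type == "rrbs"
                      else self.sonication.window)
            # "appropriate insert size": the selection window widened by 20 bp
            self.mapper = MapperConfig(
                insert_min_bp=max(1, window.min_insert_bp - 20),
                insert_max_bp=window.max_insert_bp + 20,
            )

    def validate(self) -> List[str]:
        errors = []
        if self.library_type not in ("rrbs", "wgbs"):
            errors.append("library_type: must be 'rrbs' or 'wgbs'")
        errors += [f"genome.{e}" for e in self.genome.validate()]
        errors += [f"methylome.{e}" for e in self.methylome.validate()]
        errors += [f"conversion.{e}" for e in self.conversion.validate()]
        errors += [f"trim.{e}" for e in self.trim.validate()]
        errors += [f"mapper.{e}" for e in self.mapper.validate()]
        errors += [f"thresholds.{e}" for e in self.thresholds.validate()]
        if self.library_type == "wgbs":
            errors += [f"sonication.{e}" for e in self.sonication.validate()]
        if self.read_length < 1:
            errors.append("read_length: must be >= 1")
        if self.n_read_pairs is not None and self.n_read_pairs < 1:
            errors.append("n_read_pairs: must be >= 1")
        if self.n_read_pairs is None and self.target_depth <= 0:
            errors.append("target_depth: must be > 0")
        if any(not 0 < f <= 1 for f in self.saturation_fractions):
            errors.append("saturation_fractions: must be in (0, 1]")
        if self.full_gb <= 0:
            errors.append("full_gb: must be > 0")
        return errors


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

_NESTED = {
    "genome": GenomeConfig,
    "methylome": MethylomeParams,
    "conversion": ConversionParams,
    "quality": QualityModel,
    "trim": TrimConfig,
    "mapper": MapperConfig,
    "thresholds": CoverageThresholds,
    "sonication": SonicationParams,
}


def _build(cls, data: Dict[str, Any], path: str, errors: List[str]):
    known = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in known:
            errors.append(f"{path}.{key}: unknown field")
    kwargs = {k: v for k, v in data.items() if k in known}
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{path}: {exc}")
        return cls()


def config_from_dict(data: Dict[str, Any]) -> PipelineConfig:
    """Build a validated PipelineConfig; raises ConfigError listing every
    problem at once with its field path."""
    errors: List[str] = []
    data = dict(data)
    kwargs: Dict[str, Any] = {}
    for key, cls in _NESTED.items():
        if key in data:
            sub = data.pop(key)
            if key == "sonication" and isinstance(sub, dict) and "window" in sub:
                w = sub.pop("window")
                sub = dict(sub)
                try:
                    sub["window"] = SizeWindow(**w)
                except (TypeError, ValueError) as exc:
                    errors.append(f"sonication.window: {exc}")
            if not isinstance(sub, dict):
                errors.append(f"{key}: must be a mapping")
            else:
                kwargs[key] = _build(cls, sub, key, errors)
    for simple_key, cls in (("size_window", SizeWindow), ("enzyme", Enzyme)):
        if simple_key in data:
            try:
                kwargs[simple_key] = cls(**data.pop(simple_key))
            except (TypeError, ValueError) as exc:
                errors.append(f"{simple_key}: {exc}")
    if "saturation_fractions" in data:
        data["saturation_fractions"] = tuple(data["saturation_fractions"])
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key in data:
        if key not in known:
            errors.append(f"{key}: unknown field")
    kwargs.update({k: v for k, v in data.items() if k in known})
    try:
        config = PipelineConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(str(exc))
        config = None
    if config is not None:
        errors.extend(config.validate())
    if errors:
        raise ConfigError(errors)
    return config


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config file (all violations reported at once)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])
    return config_from_dict(data)


def config_to_dict(config: PipelineConfig) -> Dict[str, Any]:
    return dataclasses.asdict(config)


# ---------------------------------------------------------------------------
# staged execution
# ---------------------------------------------------------------------------

def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of 'stage:global_seed' (< 2^31)."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) % (2 ** 31)


def pairs_for_depth(fragments: Sequence[Fragment], target_depth: float,
                    read_length: int, genome_bp: Optional[int] = None) -> int:
    """Read pairs needed for a mean per-base depth over the sequenced pool.

    For a digest/size-selected pool the molecule lands on one of the selected
    fragments, so depth concentrates on their bases; for sonication
    (genome_bp given) coverage spreads over the whole genome.
    """
    covered = np.array([min(f.length, 2 * read_length) for f in fragments], dtype=float)
    if genome_bp is not None:
        return int(math.ceil(target_depth * genome_bp / covered.mean()))
    insert = np.array([f.length for f in fragments], dtype=float)
    return int(math.ceil(target_depth * len(fragments) * insert.mean() / covered.mean()))


def make_fragments(config: PipelineConfig, genome: ReferenceGenome) -> List[Fragment]:
    """The library's fragment pool (RRBS: digest + size-select; WGBS: shear)."""
    if config.library_type == "rrbs":
        return rrbs_library(genome, config.size_window, config.enzyme)
    covered = min(config.sonication.length_mean, 2 * config.read_length)
    n = config.n_read_pairs or int(
        math.ceil(config.target_depth * genome.total_length / covered))
    return sonicate(genome, n, config.sonication.length_mean,
                    config.sonication.length_sd, config.sonication.window,
                    seed=derive_seed(config.seed, "sonicate"))


def write_fragments_table(fragments: Sequence[Fragment], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tsource\tfill_ins\tterminal\tend_extension\n")
        for f in fragments:
            fill = ",".join(str(p) for p in sorted(f.fill_in_positions)) or "."
            fh.write(f"{f.chrom}\t{f.insert_start}\t{f.insert_end}\t{f.source}"
                     f"\t{fill}\t{int(f.terminal)}\t{f.end_extension}\n")


def read_fragments_table(path: Path) -> List[Fragment]:
    out = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            continue
        chrom, s, e, source, fill, terminal, ext = line.split("\t")
        fills = frozenset(int(x) for x in fill.split(",")) if fill != "." else frozenset()
        out.append(Fragment(chrom, int(s), int(e), source, fills,
                            bool(int(terminal)), int(ext)))
    return out


def run_experiment(config: PipelineConfig) -> Dict[str, Any]:
    """Execute the full pipeline; returns the summary plus output paths.

    Any stage failure raises :class:`StageError` naming the stage.
    """
    errors = config.validate()
    if errors:
        raise ConfigError(errors)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Any] = {}

    def stage(name: str, fn):
        try:
            result = fn()
        except (ConfigError, StageError):
            raise
        except Exception as exc:  # surfaced with the stage name
            raise StageError(name, exc) from exc
        logger.info("stage %s done", name)
        return result

    genome_cfg = dataclasses.replace(
        config.genome, rng_seed=derive_seed(config.seed, "genome"))
    genome, features = stage("simulate_genome", lambda: simulate_genome(genome_cfg))
    methylome_params = dataclasses.replace(
        config.methylome, rng_seed=derive_seed(config.seed, "methylome"))
    methylome = stage("simulate_methylome",
                      lambda: simulate_methylome(genome, features, methylome_params))
    paths.update(stage("write_reference",
                       lambda: write_reference(genome, features, methylome, out)))

    fragments = stage("fragments", lambda: make_fragments(config, genome))
    if not fragments:
        raise StageError("fragments", RuntimeError("empty fragment pool"))
    write_fragments_table(fragments, out / "fragments.tsv")
    paths["fragments"] = out / "fragments.tsv"
    logger.info("fragments: %d (library=%s)", len(fragments), config.library_type)

    if config.library_type == "wgbs":
        n_pairs = len(fragments)
    else:
        n_pairs = config.n_read_pairs or pairs_for_depth(
            fragments, config.target_depth, config.read_length)
    from .reads import generate_reads  # local import to keep module graph flat
    pairs = stage("generate_reads", lambda: generate_reads(
        fragments, genome, methylome, n_pairs, config.read_length,
        config.conversion, config.trim.adapter_sequence,
        seed=derive_seed(config.seed, "reads"), quality_model=config.quality))
    write_fastq_pairs(pairs, out / "reads_1.fastq", out / "reads_2.fastq")
    paths["reads"] = (out / "reads_1.fastq", out / "reads_2.fastq")

    trimmed = stage("trim", lambda: trim_pairs(pairs, config.trim))
    write_fastq_pairs(trimmed, out / "trimmed_1.fastq", out / "trimmed_2.fastq")
    paths["trimmed"] = (out / "trimmed_1.fastq", out / "trimmed_2.fastq")
    logger.info("trim: %d of %d pairs kept", len(trimmed), len(pairs))

    index = stage("index", lambda: build_index(genome, config.mapper.seed_length_bp))
    alignments = stage("map", lambda: map_pairs(trimmed, index, config.mapper))
    alignments_to_frame(alignments).to_csv(out / "alignments.tsv", sep="\t", index=False)
    paths["alignments"] = out / "alignments.tsv"
    status_counts = pd.Series([a.status for a in alignments]).value_counts().to_dict() \
        if alignments else {}
    logger.info("map: %s", status_counts)

    table = stage("call", lambda: call_methylation(alignments, trimmed, genome))
    table.to_frame().to_csv(out / "calls.tsv", sep="\t", index=False)
    merged = table.merged_cpg_frame()
    merged.to_csv(out / "merged_cpg.tsv", sep="\t", index=False)
    paths["calls"] = out / "calls.tsv"
    paths["merged_cpg"] = out / "merged_cpg.tsv"

    cov = stage("coverage", lambda: count_cpg_coverage(merged, config.thresholds))
    feats = stage("feature_coverage",
                  lambda: feature_coverage(merged, features, genome, config.thresholds))
    try:
        non_cpg_pct, efficiency = conversion_qc(table)
    except ValueError:
        non_cpg_pct = efficiency = float("nan")
    try:
        mean_meth = mean_methylation(table)
    except ValueError:
        mean_meth = float("nan")
    d_lo, d_hi = config.thresholds.depths[0], config.thresholds.depths[-1]
    summary = {
        "library_type": config.library_type,
        "n_read_pairs": len(pairs),
        "n_pairs_after_trim": len(trimmed),
        "alignment_status_counts": status_counts,
        "mapping_efficiency_pct": mapping_efficiency(alignments) if alignments else float("nan"),
        f"cpgs_{d_lo}x": cov[d_lo],
        f"cpgs_ge{d_hi}x": cov[d_hi],
        "mean_cpg_methylation_pct": mean_meth,
        "non_cpg_methylation_pct": non_cpg_pct,
        "implied_conversion_efficiency_pct": efficiency,
        "feature_coverage": feats,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    paths["summary"] = out / "summary.json"

    if config.saturation_fractions:
        sat = stage("saturation", lambda: saturation_analysis(
            trimmed, config.saturation_fractions, genome, index, config.mapper,
            config.thresholds, config.full_gb,
            seed=derive_seed(config.seed, "saturation")))
        sat.to_csv(out / "saturation.tsv", sep="\t", index=False)
        paths["saturation"] = out / "saturation.tsv"
        summary["saturation"] = sat.to_dict(orient="records")

    manifest = {
        "rrbsim_version": __version__,
        "seed": config.seed,
        "config": config_to_dict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    paths["manifest"] = out / "manifest.json"
    return {"summary": summary, "paths": paths}


def compare_runs(summary_paths: Sequence[str | Path]) -> pd.DataFrame:
    """Combine the summary.json files of several runs into one table."""
    rows = []
    for p in summary_paths:
        data = json.loads(Path(p).read_text())
        data.pop("saturation", None)
        feats = data.pop("feature_coverage", {})
        data.pop("alignment_status_counts", None)
        data.update({f"feature_{k}": v for k, v in feats.items()})
        data["run"] = str(Path(p).parent.name)
        rows.append(data)
    frame = pd.DataFrame(rows)
    cols = ["run"] + [c for c in frame.columns if c != "run"]
    return frame[cols]
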