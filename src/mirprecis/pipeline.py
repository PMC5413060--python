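"""End-to-end orchestration: simulate -> trim -> quantify -> diff -> precision.

The run configuration names every analysis constant (18-30 nt size window,
RPTM expression threshold 10, two-fold reduction, +/-2 nt precision
tolerance, >= 10 reads per replicate) as a config key defaulting to the
study value, so a default run is the reference analysis.  Identical config
and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import differential, precision, quantify, reads, simulate

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class GenotypeConfig:
    """Simulation settings for one genotype.

    ``reduced_loci`` lists the indices (into the locus panel) whose baseline
    abundance is scaled by ``multiplier`` in this genotype; all other loci
    keep multiplier 1.
    """

    replicates: int = 2
    misprocessing_rate: float = 0.05
    multiplier: float = 1.0
    reduced_loci: list[int] = field(default_factory=list)


@dataclass
class SimulationConfig:
    n_loci: int = 60
    n_chromosomes: int = 1
    chromosome_length: int = 50_000
    gc_fraction: float = 0.36
    depth: int = 200_000
    background_24nt_fraction: float = 0.70
    dispersion: float = 0.1
    baseline_abundance: float | None = None  # None -> depth*(1-bg)/n_loci
    mature_to_star_ratio: float = 4.0
    read_length: int = 50
    offset_magnitude_range: tuple[int, int] = (3, 5)
    benign_isomir_rate: float = 0.0

    def locus_baseline(self) -> float:
        if self.baseline_abundance is not None:
            return self.baseline_abundance
        return self.depth * (1.0 - self.background_24nt_fraction) / self.n_loci


def _default_genotypes() -> dict[str, GenotypeConfig]:
    # Default study layout: wild type, a hyl1-like processing mutant (strong
    # misprocessing plus reduced abundance at 15 loci) and a snrk2-like
    # abundance mutant (normal processing, reduced abundance at 15 loci,
    # 10 of them shared with the hyl1-like set).
    return {
        "WT": GenotypeConfig(),
        "hyl1_like": GenotypeConfig(
            misprocessing_rate=0.4, multiplier=0.4, reduced_loci=list(range(0, 15))
        ),
        "snrk2_like": GenotypeConfig(
            misprocessing_rate=0.05, multiplier=0.4, reduced_loci=list(range(5, 20))
        ),
    }


@dataclass
class RunConfig:
    out_dir: str = "mirprecis_run"
    seed: int = 0
    wt_label: str = "WT"
    genotypes: dict[str, GenotypeConfig] = field(default_factory=_default_genotypes)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    adapter: str = reads.DEFAULT_ADAPTER
    min_overlap: int = reads.DEFAULT_MIN_OVERLAP
    max_mismatch_rate: float = reads.DEFAULT_MAX_MISMATCH_RATE
    keep_untrimmed: bool = False
    min_len: int = reads.MIN_INSERT_LENGTH
    max_len: int = reads.MAX_INSERT_LENGTH
    expression_threshold: float = differential.DEFAULT_EXPRESSION_THRESHOLD_RPTM
    per_replicate_threshold: bool = False
    fold_threshold: float = differential.DEFAULT_FOLD_THRESHOLD
    fold_inclusive: bool = True
    tolerance_nt: int = precision.DEFAULT_TOLERANCE_NT
    min_reads_per_replicate: int = precision.DEFAULT_MIN_READS_PER_REPLICATE

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "genotypes" in data:
            data["genotypes"] = {
                name: GenotypeConfig(**g) if isinstance(g, dict) else g
                for name, g in data["genotypes"].items()
            }
        if isinstance(data.get("simulation"), dict):
            sim = dict(data["simulation"])
            if isinstance(sim.get("offset_magnitude_range"), list):
                sim["offset_magnitude_range"] = tuple(sim["offset_magnitude_range"])
            data["simulation"] = SimulationConfig(**sim)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def validate_config(config: RunConfig) -> list[str]:
    """Return the list of violations (empty means valid); never mutates."""
    violations: list[str] = []
    if config.wt_label not in config.genotypes:
        violations.append(f"wt_label {config.wt_label!r} not among genotypes")
    for name in ("expression_threshold", "fold_threshold", "tolerance_nt",
                 "min_reads_per_replicate", "min_overlap"):
        if getattr(config, name) < 0:
            violations.append(f"{name} must be non-negative")
    if config.fold_threshold == 0:
        violations.append("fold_threshold must be positive")
    if config.min_len > config.max_len:
        violations.append(f"min_len {config.min_len} > max_len {config.max_len}")
    if not 0 <= config.max_mismatch_rate < 1:
        violations.append("max_mismatch_rate must lie in [0, 1)")
    for name, genotype in config.genotypes.items():
        if genotype.replicates < 1:
            violations.append(f"genotype {name!r}: replicates must be >= 1")
        if not 0 <= genotype.misprocessing_rate <= 1:
            violations.append(f"genotype {name!r}: misprocessing_rate outside [0, 1]")
        if genotype.multiplier < 0:
            violations.append(f"genotype {name!r}: multiplier must be >= 0")
        if any(i < 0 or i >= config.simulation.n_loci for i in genotype.reduced_loci):
            violations.append(f"genotype {name!r}: reduced_loci index out of range")
    if config.simulation.depth < 1:
        violations.append("simulation depth must be >= 1")
    return violations


@dataclass
class RunReport:
    sections: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.sections, fh, indent=2, sort_keys=True, default=_jsonable)
            fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _library_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def build_specs(
    config: RunConfig,
) -> tuple[simulate.SyntheticGenomeSpec, list[simulate.SyntheticLocusSpec], list[simulate.LibrarySpec]]:
    """Expand the run configuration into simulator specs."""
    sim = config.simulation
    genome_spec = simulate.SyntheticGenomeSpec(
        n_chromosomes=sim.n_chromosomes,
        chromosome_length=sim.chromosome_length,
        gc_fraction=sim.gc_fraction,
        seed=_library_seed(config.seed, 0),
    )
    baseline = sim.locus_baseline()
    locus_specs = []
    for i in range(sim.n_loci):
        multipliers = {
            name: genotype.multiplier
            for name, genotype in config.genotypes.items()
            if i in genotype.reduced_loci
        }
        locus_specs.append(
            simulate.SyntheticLocusSpec(
                locus_id=f"syn-MIR{i + 1:03d}",
                baseline_abundance=baseline,
                mature_to_star_ratio=sim.mature_to_star_ratio,
                genotype_multipliers=multipliers,
            )
        )
    library_specs = []
    lib_index = 1
    for name in sorted(config.genotypes):
        genotype = config.genotypes[name]
        for rep in range(1, genotype.replicates + 1):
            library_specs.append(
                simulate.LibrarySpec(
                    genotype=name,
                    replicate=rep,
                    depth=sim.depth,
                    adapter=config.adapter,
                    read_length=sim.read_length,
                    misprocessing_rate=genotype.misprocessing_rate,
                    offset_magnitude_range=sim.offset_magnitude_range,
                    benign_isomir_rate=sim.benign_isomir_rate,
                    background_24nt_fraction=sim.background_24nt_fraction,
                    dispersion=sim.dispersion,
                    seed=_library_seed(config.seed, lib_index),
                )
            )
            lib_index += 1
    return genome_spec, locus_specs, library_specs


@dataclass
class PipelineResult:
    """In-memory results of a run, alongside the files written."""

    report: RunReport
    experiment: simulate.SimulatedExperiment
    collapsed: dict[str, reads.CollapsedReadSet]
    hits: dict[str, dict[str, list[quantify.AlignmentHit]]]
    matrix: quantify.NormalizedMatrix
    expression: list[differential.ExpressionRecord]
    reduced_sets: dict[str, set[str]]
    precision_records: pd.DataFrame
    precision_summary: precision.PrecisionSummary
    layout: dict[str, list[str]]


def run_pipeline(config: RunConfig, write_fastq: bool = True) -> PipelineResult:
    """Execute all stages on a simulated study and write every output.

    ``write_fastq`` controls whether the simulated FASTQ files themselves
    are written (they are the bulkiest artifact; the analysis consumes the
    in-memory records either way, and trimming results are identical).
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    report.sections["version"] = __version__
    report.sections["config"] = config.to_dict()
    stage = "simulate"
    try:
        genome_spec, locus_specs, library_specs = build_specs(config)
        experiment = simulate.simulate_experiment(genome_spec, locus_specs, library_specs)
        simulate.write_genome_fasta(experiment.genome, out_dir / "genome.fa")
        simulate.write_annotation_gff3(
            experiment.annotation, experiment.locus_specs, out_dir / "annotation.gff3"
        )
        simulate.write_mature_fasta(experiment.mature_catalog, out_dir / "mature.fa")
        simulate.write_truth_tsv(experiment.truth, out_dir / "truth.tsv")
        if write_fastq:
            for name, records in experiment.libraries.items():
                simulate.write_fastq(records, out_dir / f"lib_{name}.fastq")
        layout: dict[str, list[str]] = {}
        for lib in library_specs:
            layout.setdefault(lib.genotype, []).append(lib.name)
        logger.info("simulated %d libraries over %d loci",
                    len(library_specs), len(locus_specs))

        stage = "trim"
        collapsed: dict[str, reads.CollapsedReadSet] = {}
        accounting: dict[str, dict] = {}
        for name, records in experiment.libraries.items():
            raw = (reads.RawRead(rid, seq, qual) for rid, seq, qual in records)
            collapsed[name], acct = reads.process_library(
                raw,
                adapter=config.adapter,
                min_overlap=config.min_overlap,
                max_mismatch_rate=config.max_mismatch_rate,
                min_len=config.min_len,
                max_len=config.max_len,
                keep_untrimmed=config.keep_untrimmed,
            )
            accounting[name] = dataclasses.asdict(acct)
            reads.write_collapsed(
                collapsed[name],
                out_dir / f"collapsed_{name}.fa",
                out_dir / f"collapsed_{name}.tsv",
            )

        stage = "quantify"
        index = quantify.GenomeIndex(experiment.genome)
        catalog = quantify.MatureCatalog.from_dict(experiment.mature_catalog)
        hits: dict[str, dict[str, list[quantify.AlignmentHit]]] = {}
        per_lib_counts = {}
        per_lib_totals = {}
        mapped_sets: dict[str, reads.CollapsedReadSet] = {}
        for name, reads_set in collapsed.items():
            lib_hits = quantify.map_exact(reads_set, index)
            hits[name] = lib_hits
            total = quantify.genome_matched_total(reads_set, lib_hits)
            per_lib_totals[name] = total
            per_lib_counts[name] = quantify.quantify_mature(reads_set, catalog)
            accounting[name]["n_genome_matched"] = total
            mapped_sets[name] = reads.CollapsedReadSet(
                {seq: mult for seq, mult in reads_set.counts.items() if lib_hits.get(seq)}
            )
        matrix = quantify.build_matrices(per_lib_counts, per_lib_totals)
        quantify.write_matrices(matrix, out_dir / "counts.tsv", out_dir / "rptm.tsv")
        report.sections["libraries"] = accounting

        stage = "differential"
        expression = differential.filter_expressed(
            matrix.rptm, layout, config.wt_label,
            threshold=config.expression_threshold,
            per_replicate=config.per_replicate_threshold,
        )
        mutants = sorted(g for g in layout if g != config.wt_label)
        fold_table = differential.fold_change_table(
            expression, config.wt_label, mutants,
            fold=config.fold_threshold, inclusive=config.fold_inclusive,
        )
        differential.write_fold_changes(fold_table, out_dir / "fold_changes.tsv")
        reduced_sets = {
            mutant: differential.reduced_set(
                expression, config.wt_label, mutant,
                fold=config.fold_threshold, inclusive=config.fold_inclusive,
            )
            for mutant in mutants
        }
        overlaps = {}
        for i, mut_a in enumerate(mutants):
            for mut_b in mutants[i + 1 :]:
                overlap = differential.set_overlap(reduced_sets[mut_a], reduced_sets[mut_b])
                differential.write_overlap(
                    overlap, mut_a, mut_b, out_dir / f"overlap_{mut_a}_vs_{mut_b}.tsv"
                )
                overlaps[f"{mut_a}_vs_{mut_b}"] = dict(
                    zip(("only_a", "shared", "only_b"), overlap.counts)
                )
        profile = differential.size_class_profile(
            mapped_sets, min_len=config.min_len, max_len=config.max_len
        )
        profile.to_csv(out_dir / "size_profile.tsv", sep="\t", float_format="%.6g")
        report.sections["differential"] = {
            "n_expressed": len(expression),
            "reduced_set_sizes": {m: len(s) for m, s in reduced_sets.items()},
            "overlaps": overlaps,
        }

        stage = "precision"
        all_records = []
        for name, reads_set in collapsed.items():
            assignments = precision.assign_to_locus(hits[name], reads_set, experiment.annotation)
            all_records.extend(
                precision.locus_fraction(
                    assignments, experiment.annotation, name, config.tolerance_nt
                )
            )
        records_frame = precision.records_to_frame(all_records)
        summary = precision.genotype_precision_summary(
            records_frame, layout, config.wt_label,
            min_reads=config.min_reads_per_replicate,
        )
        precision.write_precision_tables(
            records_frame, summary,
            out_dir / "precision.tsv", out_dir / "precision_summary.tsv",
        )
        report.sections["precision"] = {
            "medians": {g: float(v) for g, v in summary.medians.items()},
            "tests": summary.tests.to_dict(orient="records"),
            "n_eligible_loci": int(summary.per_locus.shape[0]),
        }

        stage = "report"
        report.to_json(out_dir / "report.json")
    except Exception as exc:
        _retain_failed(out_dir)
        raise StageError(stage, exc) from exc
    return PipelineResult(
        report=report,
        experiment=experiment,
        collapsed=collapsed,
        hits=hits,
        matrix=matrix,
        expression=expression,
        reduced_sets=reduced_sets,
        precision_records=records_frame,
        precision_summary=summary,
        layout=layout,
    )


def _retain_failed(out_dir: Path) -> None:
    failed = out_dir / "failed"
    try:
        failed.mkdir(exist_ok=True)
        for item in list(out_dir.iterdir()):
            if item.name == "failed":
                continue
            shutil.move(str(item), str(failed / item.name))
    except OSError:  # best effort; the StageError is the primary signal
        logger.warning("could not move partial outputs to %s", failed)


def setup_logging(out_dir: str | Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(out_dir) / "run.log"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
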