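"""Synthetic small RNA sequencing data with recorded ground truth.

Generates a random genome with planted MIRNA hairpin loci (one mature and
one star species each), a miRBase-style annotation and mature catalog, and
FASTQ libraries whose statistical structure matches what the downstream
analysis assumes:

* per-locus insert counts are negative-binomial (Gamma-Poisson) around
  ``baseline_abundance x genotype_multiplier``; the ``dispersion`` parameter
  is the biological coefficient of variation of the Gamma mixture
  (NB size = 1/dispersion^2), so 0.1 means ~10% between-replicate
  biological variability;
* reads are drawn from the mature or star window per the mature:star ratio;
  with probability ``misprocessing_rate`` the whole window slides by >= 3 nt
  (a misprocessing product, imprecise under the +/-2 nt rule), and with an
  optional benign-isomiR rate it slides by 1-2 nt (still precise);
* a 24-nt siRNA-like background is sampled uniformly from sense-strand
  non-hairpin genome windows, Binomial(depth, background_24nt_fraction)
  reads in total;
* the emitted read is insert + 3' adapter truncated to the read length,
  with a constant quality string (the analysis ignores qualities).

Every read's genomic placement and precise/imprecise/background label is
recorded, so downstream estimates can be checked against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .precision import HairpinLocus
from .reads import DEFAULT_ADAPTER

BACKGROUND_READ_LENGTH = 24
# Mature/star windows start this far inside the hairpin so that slid
# (misprocessed) windows never cross the hairpin boundary at default
# offset magnitudes.
WINDOW_MARGIN = 10
CHROMOSOME_EDGE_MARGIN = 50
CONSTANT_QUALITY_CHAR = "I"


class PlacementError(ValueError):
    """Raised when the requested loci cannot be placed on the genome."""


class GenerationError(RuntimeError):
    """Raised when unique mature sequences cannot be generated."""


class SimulationConfigError(ValueError):
    """Raised for invalid library simulation settings."""


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    n_chromosomes: int = 1
    chromosome_length: int = 50_000
    gc_fraction: float = 0.36  # Arabidopsis-like
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chromosome_length < 1000:
            raise ValueError("chromosome_length must be >= 1000")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")


@dataclass(frozen=True)
class SyntheticLocusSpec:
    locus_id: str
    hairpin_length: int = 120
    mature_length: int = 21
    mature_arm: str = "5p"
    star_gap: int = 16
    baseline_abundance: float = 400.0
    mature_to_star_ratio: float = 4.0
    genotype_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 20 <= self.mature_length <= 22:
            raise ValueError(f"{self.locus_id}: mature_length must be in [20, 22]")
        if self.mature_arm not in ("5p", "3p"):
            raise ValueError(f"{self.locus_id}: mature_arm must be 5p or 3p")
        if self.star_gap < 0:
            raise ValueError(f"{self.locus_id}: star_gap must be >= 0")
        needed = 2 * WINDOW_MARGIN + 2 * self.mature_length + self.star_gap
        if self.hairpin_length < needed:
            raise ValueError(
                f"{self.locus_id}: hairpin_length {self.hairpin_length} < {needed} "
                "needed for mature + star windows with margins"
            )
        if self.baseline_abundance < 0:
            raise ValueError(f"{self.locus_id}: baseline_abundance must be >= 0")
        if self.mature_to_star_ratio <= 0:
            raise ValueError(f"{self.locus_id}: mature_to_star_ratio must be > 0")
        for genotype, mult in self.genotype_multipliers.items():
            if mult < 0:
                raise ValueError(f"{self.locus_id}: multiplier for {genotype} < 0")

    def multiplier(self, genotype: str) -> float:
        return self.genotype_multipliers.get(genotype, 1.0)


@dataclass(frozen=True)
class LibrarySpec:
    genotype: str
    replicate: int
    depth: int
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 50
    misprocessing_rate: float = 0.0
    offset_magnitude_range: tuple[int, int] = (3, 5)
    benign_isomir_rate: float = 0.0
    background_24nt_fraction: float = 0.70
    dispersion: float = 0.0
    seed: int = 0

    @property
    def name(self) -> str:
        return f"{self.genotype}_{self.replicate}"

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise SimulationConfigError("depth must be >= 0")
        if len(self.adapter) < 15 or set(self.adapter) - set("ACGT"):
            raise SimulationConfigError("adapter must be a DNA string of >= 15 nt")
        lo, hi = self.offset_magnitude_range
        if lo < 3 or hi < lo:
            raise SimulationConfigError(
                "offset_magnitude_range must be an increasing pair with minimum >= 3 "
                "(smaller offsets would blur the precise/imprecise boundary)"
            )
        for name in ("misprocessing_rate", "benign_isomir_rate", "background_24nt_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SimulationConfigError(f"{name} must lie in [0, 1]")
        if self.dispersion < 0:
            raise SimulationConfigError("dispersion must be >= 0")
        if self.read_length < BACKGROUND_READ_LENGTH:
            raise SimulationConfigError("read_length must cover a 24-nt insert")


@dataclass
class LibraryTruth:
    """Per-library simulation record: counts per locus plus per-read detail.

    ``reads`` holds one row per emitted read: read_id, label
    (precise/imprecise/background), locus, species (mature/star), and the
    genomic placement of the insert (chrom, start, end, strand; 0-based
    half-open).
    """

    library: str
    genotype: str
    replicate: int
    nominal_depth: int
    per_locus_true_counts: dict[str, int]
    n_background: int
    reads: pd.DataFrame

    @property
    def realized_depth(self) -> int:
        return len(self.reads)

    @property
    def read_labels(self) -> dict[str, str]:
        return dict(zip(self.reads["read_id"], self.reads["label"]))


@dataclass
class GroundTruth:
    """Merged truth across libraries, keyed the way the analysis reports.

    ``true_fold_changes`` maps (locus, genotype) to the abundance multiplier
    relative to the baseline genotype (multiplier 1.0), i.e. the true fold
    change a perfect analysis would recover.
    """

    per_locus_true_counts: dict[tuple[str, str], int]
    true_fold_changes: dict[tuple[str, str], float]
    libraries: dict[str, LibraryTruth]

    @property
    def read_labels(self) -> dict[str, str]:
        labels: dict[str, str] = {}
        for truth in self.libraries.values():
            labels.update(truth.read_labels)
        return labels

    def true_reduced_set(self, genotype: str, max_ratio: float = 0.5) -> set[str]:
        return {
            locus
            for (locus, g), ratio in self.true_fold_changes.items()
            if g == genotype and ratio <= max_ratio
        }


# --- genome construction -----------------------------------------------------


def _random_dna(rng: np.random.Generator, length: int, gc_fraction: float) -> str:
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length,
                       p=[at, gc, gc, at])
    return codes.tobytes().decode("ascii")


def _count_occurrences(haystack: str, needle: str) -> int:
    count = 0
    pos = haystack.find(needle)
    while pos >= 0:
        count += 1
        pos = haystack.find(needle, pos + 1)
    return count


def _genome_occurrences(genome: dict[str, str], query: str) -> int:
    """Occurrences of ``query`` on either strand across all chromosomes."""
    rc = reverse_complement(query)
    total = 0
    for seq in genome.values():
        total += _count_occurrences(seq, query)
        if rc != query:
            total += _count_occurrences(seq, rc)
    return total


def _windows(spec: SyntheticLocusSpec) -> tuple[tuple[int, int], tuple[int, int]]:
    """(mature, star) window offsets within the hairpin (half-open)."""
    first = (WINDOW_MARGIN, WINDOW_MARGIN + spec.mature_length)
    second_start = first[1] + spec.star_gap
    second = (second_start, second_start + spec.mature_length)
    return (first, second) if spec.mature_arm == "5p" else (second, first)


def build_genome(
    spec: SyntheticGenomeSpec,
    loci: list[SyntheticLocusSpec],
    max_retries: int = 50,
) -> tuple[dict[str, str], list[HairpinLocus], dict[str, str]]:
    """Random genome with planted hairpins, annotation and mature catalog.

    Hairpins are planted as literal random subsequences (no folding is
    enforced; the analysis consumes annotations, not structures), spaced
    evenly across the chromosomes.  Each locus's mature sequence is checked
    for genome-wide uniqueness (both strands) and the hairpin is regenerated
    on a collision.
    """
    if len({l.locus_id for l in loci}) != len(loci):
        raise ValueError("duplicate locus_id in locus specs")
    rng = np.random.default_rng(spec.seed)
    genome = {
        f"chr{i + 1}": _random_dna(rng, spec.chromosome_length, spec.gc_fraction)
        for i in range(spec.n_chromosomes)
    }
    # Round-robin placement, evenly spaced slots per chromosome.
    per_chrom: dict[str, list[SyntheticLocusSpec]] = {name: [] for name in genome}
    names = list(genome)
    for i, locus in enumerate(loci):
        per_chrom[names[i % len(names)]].append(locus)
    placements: dict[str, tuple[str, int]] = {}
    for chrom, chrom_loci in per_chrom.items():
        if not chrom_loci:
            continue
        usable = spec.chromosome_length - 2 * CHROMOSOME_EDGE_MARGIN
        slot = usable // len(chrom_loci)
        if any(slot < l.hairpin_length + 20 for l in chrom_loci):
            raise PlacementError(
                f"{len(chrom_loci)} loci do not fit on {chrom} "
                f"({spec.chromosome_length} nt) without overlap"
            )
        for j, locus in enumerate(chrom_loci):
            placements[locus.locus_id] = (chrom, CHROMOSOME_EDGE_MARGIN + j * slot)

    def plant(locus: SyntheticLocusSpec) -> None:
        chrom, start = placements[locus.locus_id]
        hairpin = _random_dna(rng, locus.hairpin_length, spec.gc_fraction)
        seq = genome[chrom]
        genome[chrom] = seq[:start] + hairpin + seq[start + locus.hairpin_length :]

    for locus in loci:
        plant(locus)
    # Uniqueness pass: regenerate any hairpin whose mature sequence is not
    # unique genome-wide.
    for locus in loci:
        chrom, start = placements[locus.locus_id]
        (m_off, m_end), _ = _windows(locus)
        for attempt in range(max_retries + 1):
            mature_seq = genome[chrom][start + m_off : start + m_end]
            if _genome_occurrences(genome, mature_seq) == 1:
                break
            if attempt == max_retries:
                raise GenerationError(
                    f"{locus.locus_id}: no unique mature sequence after "
                    f"{max_retries} retries"
                )
            plant(locus)

    annotation: list[HairpinLocus] = []
    catalog: dict[str, str] = {}
    for locus in loci:
        chrom, start = placements[locus.locus_id]
        (m_off, m_end), (s_off, s_end) = _windows(locus)
        mature_seq = genome[chrom][start + m_off : start + m_end]
        annotation.append(
            HairpinLocus(
                locus_id=locus.locus_id,
                chromosome=chrom,
                start=start,
                end=start + locus.hairpin_length,
                strand="+",
                mature_start=start + m_off,
                mature_end=start + m_end,
                star_start=start + s_off,
                star_end=start + s_end,
                mature_sequence=mature_seq,
            )
        )
        catalog[f"{locus.locus_id}-{locus.mature_arm}"] = mature_seq
    return genome, annotation, catalog


# --- library simulation ------------------------------------------------------


def _background_positions(
    genome: dict[str, str], annotation: list[HairpinLocus]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Sense-strand start positions whose 24-nt window avoids all hairpins.

    Returns (chrom names, window start offsets, cumulative counts) for
    uniform sampling.  Because mature sequences are unique genome-wide and
    confined to hairpins, windows sampled here can never collide with a
    mature sequence.
    """
    chroms: list[str] = []
    starts_per_chrom: list[np.ndarray] = []
    for chrom, seq in genome.items():
        mask = np.ones(len(seq) - BACKGROUND_READ_LENGTH + 1, dtype=bool)
        for locus in annotation:
            if locus.chromosome != chrom:
                continue
            lo = max(0, locus.start - BACKGROUND_READ_LENGTH + 1)
            hi = min(len(mask), locus.end)
            mask[lo:hi] = False
        chroms.append(chrom)
        starts_per_chrom.append(np.flatnonzero(mask))
    counts = np.array([len(s) for s in starts_per_chrom])
    if counts.sum() == 0:
        raise SimulationConfigError("no non-hairpin positions left for background reads")
    return chroms, np.concatenate(starts_per_chrom), np.cumsum(counts)


def simulate_library(
    genome: dict[str, str],
    annotation: list[HairpinLocus],
    lib: LibrarySpec,
    loci: list[SyntheticLocusSpec],
) -> tuple[list[tuple[str, str, str]], LibraryTruth]:
    """One FASTQ library plus its ground truth.

    Returns ``(records, truth)`` with ``records`` a list of
    (read_id, sequence, quality) tuples in randomized order.
    """
    rng = np.random.default_rng(lib.seed)
    ann_by_id = {l.locus_id: l for l in annotation}
    chrom_list: list[str] = []
    start_list: list[np.ndarray] = []
    meta: list[tuple[str, str, str, str]] = []  # (label, locus, species, chrom)
    lengths: list[np.ndarray] = []
    strands: list[str] = []
    per_locus_counts: dict[str, int] = {}

    for spec in loci:
        mean = spec.baseline_abundance * spec.multiplier(lib.genotype)
        if mean <= 0 or lib.depth == 0:
            per_locus_counts[spec.locus_id] = 0
            continue
        if lib.dispersion > 0:
            shape = 1.0 / lib.dispersion**2
            lam = rng.gamma(shape, mean / shape)
        else:
            lam = mean
        count = int(rng.poisson(lam))
        per_locus_counts[spec.locus_id] = count
        if count == 0:
            continue
        locus = ann_by_id[spec.locus_id]
        p_mature = spec.mature_to_star_ratio / (1.0 + spec.mature_to_star_ratio)
        is_mature = rng.random(count) < p_mature
        base_start = np.where(is_mature, locus.mature_start, locus.star_start)
        base_end = np.where(is_mature, locus.mature_end, locus.star_end)
        is_mis = rng.random(count) < lib.misprocessing_rate
        is_benign = (~is_mis) & (rng.random(count) < lib.benign_isomir_rate)
        lo, hi = lib.offset_magnitude_range
        magnitude = np.where(
            is_mis,
            rng.integers(lo, hi + 1, size=count),
            np.where(is_benign, rng.integers(1, 3, size=count), 0),
        )
        sign = rng.choice(np.array([-1, 1]), size=count)
        offset = magnitude * sign
        start = base_start + offset
        end = base_end + offset
        # Clip to the hairpin by flipping the slide direction (margins make
        # this a no-op at default settings).
        out = (start < locus.start) | (end > locus.end)
        start = np.where(out, base_start - offset, start)
        end = np.where(out, base_end - offset, end)
        for i in range(count):
            meta.append(
                (
                    "imprecise" if is_mis[i] else "precise",
                    spec.locus_id,
                    "mature" if is_mature[i] else "star",
                    locus.chromosome,
                )
            )
            strands.append(locus.strand)
        chrom_list.extend([locus.chromosome] * count)
        start_list.append(start.astype(np.int64))
        lengths.append((end - start).astype(np.int64))

    n_background = int(rng.binomial(lib.depth, lib.background_24nt_fraction)) if lib.depth else 0
    if n_background:
        bg_chroms, bg_starts, cum = _background_positions(genome, annotation)
        picks = rng.integers(0, cum[-1], size=n_background)
        chrom_idx = np.searchsorted(cum, picks, side="right")
        starts = bg_starts[picks]
        for i in range(n_background):
            meta.append(("background", "", "", bg_chroms[chrom_idx[i]]))
            strands.append("+")
        chrom_list.extend(bg_chroms[j] for j in chrom_idx)
        start_list.append(starts.astype(np.int64))
        lengths.append(np.full(n_background, BACKGROUND_READ_LENGTH, dtype=np.int64))

    if not meta:
        empty = pd.DataFrame(
            columns=["read_id", "label", "locus", "species", "chrom", "start", "end", "strand"]
        )
        truth = LibraryTruth(lib.name, lib.genotype, lib.replicate, lib.depth,
                             per_locus_counts, 0, empty)
        return [], truth

    starts = np.concatenate(start_list)
    ends = starts + np.concatenate(lengths)
    order = rng.permutation(len(meta))
    records: list[tuple[str, str, str]] = []
    rows = {k: [] for k in ("read_id", "label", "locus", "species", "chrom", "start", "end", "strand")}
    for out_i, i in enumerate(order):
        label, locus_id, species, chrom = meta[i]
        insert = genome[chrom][starts[i] : ends[i]]
        if strands[i] == "-":
            insert = reverse_complement(insert)
        read_seq = (insert + lib.adapter)[: lib.read_length]
        read_id = f"{lib.name}_{out_i:07d}"
        records.append((read_id, read_seq, CONSTANT_QUALITY_CHAR * len(read_seq)))
        rows["read_id"].append(read_id)
        rows["label"].append(label)
        rows["locus"].append(locus_id)
        rows["species"].append(species)
        rows["chrom"].append(chrom)
        rows["start"].append(int(starts[i]))
        rows["end"].append(int(ends[i]))
        rows["strand"].append(strands[i])
    reads_df = pd.DataFrame(rows)
    for col in ("label", "locus", "species", "chrom", "strand"):
        reads_df[col] = reads_df[col].astype("category")
    truth = LibraryTruth(
        library=lib.name,
        genotype=lib.genotype,
        replicate=lib.replicate,
        nominal_depth=lib.depth,
        per_locus_true_counts=per_locus_counts,
        n_background=n_background,
        reads=reads_df,
    )
    return records, truth


@dataclass
class SimulatedExperiment:
    genome: dict[str, str]
    annotation: list[HairpinLocus]
    mature_catalog: dict[str, str]
    libraries: dict[str, list[tuple[str, str, str]]]
    truth: GroundTruth
    locus_specs: list[SyntheticLocusSpec]
    library_specs: list[LibrarySpec]


def simulate_experiment(
    genome_spec: SyntheticGenomeSpec,
    loci: list[SyntheticLocusSpec],
    library_specs: list[LibrarySpec],
) -> SimulatedExperiment:
    """Full multi-library simulation with merged ground truth."""
    if len({lib.name for lib in library_specs}) != len(library_specs):
        raise SimulationConfigError("duplicate (genotype, replicate) in library specs")
    genome, annotation, catalog = build_genome(genome_spec, loci)
    libraries: dict[str, list[tuple[str, str, str]]] = {}
    lib_truths: dict[str, LibraryTruth] = {}
    per_locus: dict[tuple[str, str], int] = {}
    for lib in library_specs:
        records, truth = simulate_library(genome, annotation, lib, loci)
        libraries[lib.name] = records
        lib_truths[lib.name] = truth
        for locus_id, count in truth.per_locus_true_counts.items():
            per_locus[(locus_id, lib.name)] = count
    genotypes = sorted({lib.genotype for lib in library_specs})
    fold_changes = {
        (spec.locus_id, genotype): spec.multiplier(genotype)
        for spec in loci
        for genotype in genotypes
    }
    truth = GroundTruth(per_locus, fold_changes, lib_truths)
    return SimulatedExperiment(
        genome, annotation, catalog, libraries, truth, list(loci), list(library_specs)
    )


# --- writers -----------------------------------------------------------------


def write_genome_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_mature_fasta(catalog: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(catalog):
            fh.write(f">{name}\n{catalog[name]}\n")


def write_annotation_gff3(
    annotation: list[HairpinLocus],
    locus_specs: list[SyntheticLocusSpec],
    path: str | Path,
) -> None:
    """miRBase-dialect GFF3: hairpins as miRNA_primary_transcript, mature and
    star species as miRNA children (1-based inclusive coordinates)."""
    arm_by_id = {spec.locus_id: spec.mature_arm for spec in locus_specs}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in annotation:
            arm = arm_by_id[locus.locus_id]
            star_arm = "3p" if arm == "5p" else "5p"
            hid = f"MI_{locus.locus_id}"
            fh.write(
                f"{locus.chromosome}\t.\tmiRNA_primary_transcript\t"
                f"{locus.start + 1}\t{locus.end}\t.\t{locus.strand}\t.\t"
                f"ID={hid};Name={locus.locus_id};arm={arm}\n"
            )
            fh.write(
                f"{locus.chromosome}\t.\tmiRNA\t"
                f"{locus.mature_start + 1}\t{locus.mature_end}\t.\t{locus.strand}\t.\t"
                f"ID=MIMAT_{locus.locus_id};Name={locus.locus_id}-{arm};"
                f"Parent={hid};Derives_from={hid}\n"
            )
            if locus.has_star:
                fh.write(
                    f"{locus.chromosome}\t.\tmiRNA\t"
                    f"{locus.star_start + 1}\t{locus.star_end}\t.\t{locus.strand}\t.\t"
                    f"ID=MIMAT_{locus.locus_id}_star;Name={locus.locus_id}-{star_arm};"
                    f"Parent={hid};Derives_from={hid}\n"
                )


def write_fastq(records: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def write_truth_tsv(truth: GroundTruth, path: str | Path) -> None:
    frames = []
    for name in sorted(truth.libraries):
        df = truth.libraries[name].reads.copy()
        df.insert(0, "library", name)
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    merged.to_csv(path, sep="\t", index=False)


def write_simulation(experiment: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gff3",
        "mature": outdir / "mature.fa",
        "truth": outdir / "truth.tsv",
    }
    write_genome_fasta(experiment.genome, paths["genome"])
    write_annotation_gff3(experiment.annotation, experiment.locus_specs, paths["annotation"])
    write_mature_fasta(experiment.mature_catalog, paths["mature"])
    write_truth_tsv(experiment.truth, paths["truth"])
    for name, records in experiment.libraries.items():
        fq = outdir / f"lib_{name}.fastq"
        write_fastq(records, fq)
        paths[f"fastq_{name}"] = fq
    return paths
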