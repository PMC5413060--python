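"""Synthetic genome/library generation and its ground-truth guarantees."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import reverse_complement

from mirprecis.precision import classify_precise
from mirprecis.quantify import AlignmentHit
from mirprecis.simulate import (
    GenerationError,
    LibrarySpec,
    PlacementError,
    SimulationConfigError,
    SyntheticGenomeSpec,
    SyntheticLocusSpec,
    build_genome,
    simulate_library,
    write_annotation_gff3,
    write_fastq,
    write_genome_fasta,
)


def _loci(n, **kwargs):
    return [SyntheticLocusSpec(locus_id=f"L{i}", **kwargs) for i in range(n)]


class TestBuildGenome:
    def test_fixed_seed_is_deterministic(self):
        spec = SyntheticGenomeSpec(chromosome_length=5_000, seed=1)
        loci = _loci(3)
        g1, a1, c1 = build_genome(spec, loci)
        g2, a2, c2 = build_genome(spec, loci)
        assert g1 == g2 and a1 == a2 and c1 == c2

    def test_hairpins_disjoint_and_contained(self):
        spec = SyntheticGenomeSpec(chromosome_length=10_000, seed=2)
        _genome, annotation, _catalog = build_genome(spec, _loci(5))
        intervals = sorted((l.start, l.end) for l in annotation)
        assert all(0 <= s < e <= 10_000 for s, e in intervals)
        assert all(a_end <= b_start for (_, a_end), (b_start, _) in
                   zip(intervals, intervals[1:]))

    def test_mature_sequences_unique_by_brute_force_scan(self):
        spec = SyntheticGenomeSpec(chromosome_length=10_000, seed=3)
        genome, annotation, catalog = build_genome(spec, _loci(5))
        for locus in annotation:
            mature = locus.mature_sequence
            occurrences = 0
            for seq in genome.values():
                for query in {mature, reverse_complement(mature)}:
                    start = seq.find(query)
                    while start >= 0:
                        occurrences += 1
                        start = seq.find(query, start + 1)
            assert occurrences == 1
        assert set(catalog.values()) == {l.mature_sequence for l in annotation}

    def test_mature_and_star_windows_inside_hairpin(self):
        spec = SyntheticGenomeSpec(chromosome_length=5_000, seed=4)
        _genome, annotation, _catalog = build_genome(spec, _loci(2, mature_arm="3p"))
        for locus in annotation:
            assert locus.start < locus.mature_start < locus.mature_end < locus.end
            assert locus.start < locus.star_start < locus.star_end < locus.end

    def test_too_many_loci_raise_placement_error(self):
        spec = SyntheticGenomeSpec(chromosome_length=1_000, seed=5)
        with pytest.raises(PlacementError):
            build_genome(spec, _loci(10))

    def test_duplicate_locus_ids_rejected(self):
        spec = SyntheticGenomeSpec(chromosome_length=5_000, seed=6)
        with pytest.raises(ValueError, match="duplicate"):
            build_genome(spec, [SyntheticLocusSpec("L0"), SyntheticLocusSpec("L0")])


class TestSimulateLibrary:
    def test_fixed_seed_determinism_including_fastq_bytes(self, small_genome, tmp_path):
        genome, annotation, _catalog, loci = small_genome
        lib = LibrarySpec(genotype="WT", replicate=1, depth=2_000, seed=9,
                          misprocessing_rate=0.1, dispersion=0.1)
        r1, t1 = simulate_library(genome, annotation, lib, loci)
        r2, t2 = simulate_library(genome, annotation, lib, loci)
        assert r1 == r2
        pd.testing.assert_frame_equal(t1.reads, t2.reads)
        write_fastq(r1, tmp_path / "a.fastq")
        write_fastq(r2, tmp_path / "b.fastq")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_zero_misprocessing_labels_every_locus_read_precise(self, small_library):
        _lib, _records, truth = small_library
        locus_reads = truth.reads[truth.reads["label"] != "background"]
        assert (locus_reads["label"] == "precise").all()

    def test_background_fraction_within_binomial_99pct_bounds(self, small_genome):
        genome, annotation, _catalog, loci = small_genome
        depth, frac = 10_000, 0.2
        lib = LibrarySpec(genotype="WT", replicate=1, depth=depth, seed=33,
                          background_24nt_fraction=frac)
        _records, truth = simulate_library(genome, annotation, lib, loci)
        sd = np.sqrt(depth * frac * (1 - frac))
        assert abs(truth.n_background - depth * frac) <= 2.576 * sd

    def test_genotype_multiplier_halves_true_mean_counts(self, small_genome):
        genome, annotation, _catalog, _ = small_genome
        locus = [SyntheticLocusSpec("L0", baseline_abundance=400.0,
                                    genotype_multipliers={"mut": 0.5})]
        _g, ann, _c = build_genome(
            SyntheticGenomeSpec(chromosome_length=5_000, seed=8), locus
        )
        means = {}
        for genotype in ("WT", "mut"):
            counts = []
            for rep in range(30):
                lib = LibrarySpec(genotype=genotype, replicate=rep, depth=1_000,
                                  background_24nt_fraction=0.1, seed=100 + rep)
                _r, truth = simulate_library(_g, ann, lib, locus)
                counts.append(truth.per_locus_true_counts["L0"])
            means[genotype] = np.mean(counts)
        assert means["mut"] / means["WT"] == pytest.approx(0.5, abs=0.05)

    def test_read_count_bookkeeping_is_exact(self, small_library):
        _lib, records, truth = small_library
        assert len(records) == truth.realized_depth
        assert (sum(truth.per_locus_true_counts.values()) + truth.n_background
                == truth.realized_depth)

    def test_depth_zero_yields_empty_library_not_error(self, small_genome):
        genome, annotation, _catalog, loci = small_genome
        lib = LibrarySpec(genotype="WT", replicate=1, depth=0, seed=1)
        records, truth = simulate_library(genome, annotation, lib, loci)
        assert records == [] and truth.realized_depth == 0

    def test_offset_magnitudes_below_three_are_config_error(self):
        with pytest.raises(SimulationConfigError, match="blur"):
            LibrarySpec(genotype="WT", replicate=1, depth=10,
                        offset_magnitude_range=(2, 5))

    def test_short_adapter_rejected(self):
        with pytest.raises(SimulationConfigError, match="15"):
            LibrarySpec(genotype="WT", replicate=1, depth=10, adapter="ACGTACGT")

    def test_labels_consistent_with_rederived_end_offsets(self, small_genome):
        """Re-deriving each read's classification from its recorded genomic
        placement reproduces the precise/imprecise label exactly."""
        genome, annotation, _catalog, loci = small_genome
        by_id = {l.locus_id: l for l in annotation}
        lib = LibrarySpec(genotype="WT", replicate=1, depth=4_000, seed=17,
                          misprocessing_rate=0.3, benign_isomir_rate=0.1,
                          background_24nt_fraction=0.3)
        _records, truth = simulate_library(genome, annotation, lib, loci)
        locus_reads = truth.reads[truth.reads["label"] != "background"]
        assert {"precise", "imprecise"} == set(locus_reads["label"].unique())
        for row in locus_reads.itertuples():
            locus = by_id[row.locus]
            hit = AlignmentHit(row.chrom, row.start, row.end, row.strand)
            assert classify_precise(hit, locus, 2) == row.label

    def test_background_reads_avoid_hairpins(self, small_library):
        _lib, _records, truth = small_library
        bg = truth.reads[truth.reads["label"] == "background"]
        assert (bg["end"] - bg["start"] == 24).all()


class TestWriters:
    def test_genome_fasta_wrapped_and_annotation_coordinates_1based(
        self, small_genome, tmp_path
    ):
        genome, annotation, _catalog, loci = small_genome
        fa = tmp_path / "genome.fa"
        write_genome_fasta(genome, fa)
        lines = fa.read_text().splitlines()
        assert max(len(l) for l in lines if not l.startswith(">")) <= 80
        gff = tmp_path / "ann.gff3"
        write_annotation_gff3(annotation, loci, gff)
        body = [l.split("\t") for l in gff.read_text().splitlines()[1:]]
        hairpins = [f for f in body if f[2] == "miRNA_primary_transcript"]
        assert len(hairpins) == len(annotation)
        by_name = {l.locus_id: l for l in annotation}
        for fields in hairpins:
            name = dict(kv.split("=") for kv in fields[8].split(";"))["Name"]
            locus = by_name[name]
            assert int(fields[3]) == locus.start + 1
            assert int(fields[4]) == locus.end
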