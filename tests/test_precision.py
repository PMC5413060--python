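"""Hairpin read assignment and the +/-2 nt processing-precision statistic."""

import numpy as np
import pandas as pd
import pytest

from mirprecis.precision import (
    HairpinLocus,
    assign_to_locus,
    classify_precise,
    eligible_loci,
    genotype_precision_summary,
    locus_fraction,
    read_hairpin_annotation,
    records_to_frame,
)
from mirprecis.quantify import AlignmentHit
from mirprecis.reads import CollapsedReadSet
from mirprecis.simulate import write_annotation_gff3


@pytest.fixture
def locus_plus():
    return HairpinLocus(
        locus_id="L", chromosome="chr1", start=100, end=220, strand="+",
        mature_start=110, mature_end=131, star_start=147, star_end=168,
    )


@pytest.fixture
def locus_minus():
    return HairpinLocus(
        locus_id="Lm", chromosome="chr1", start=300, end=420, strand="-",
        mature_start=310, mature_end=331, star_start=347, star_end=368,
    )


class TestClassifyPrecise:
    def test_exact_mature_window_is_precise(self, locus_plus):
        hit = AlignmentHit("chr1", 110, 131, "+")
        assert classify_precise(hit, locus_plus) == "precise"

    def test_boundary_offsets_of_two_are_precise(self, locus_plus):
        # 5' end -2 and 3' end +2 relative to the mature window.
        hit = AlignmentHit("chr1", 108, 133, "+")
        assert classify_precise(hit, locus_plus, 2) == "precise"

    def test_offset_of_three_is_imprecise(self, locus_plus):
        hit = AlignmentHit("chr1", 107, 131, "+")
        assert classify_precise(hit, locus_plus, 2) == "imprecise"

    def test_star_window_also_counts_as_precise(self, locus_plus):
        hit = AlignmentHit("chr1", 146, 169, "+")
        assert classify_precise(hit, locus_plus, 2) == "precise"

    def test_no_star_annotation_evaluates_mature_only(self):
        locus = HairpinLocus(
            locus_id="L", chromosome="chr1", start=100, end=220, strand="+",
            mature_start=110, mature_end=131,
        )
        assert classify_precise(AlignmentHit("chr1", 147, 168, "+"), locus) == "imprecise"

    def test_minus_strand_offsets_follow_strand_orientation(self, locus_minus):
        # On '-' the genomic left edge is the 3' end; shifting start by -3
        # is a 3'-end offset of +3.
        assert classify_precise(AlignmentHit("chr1", 307, 331, "-"), locus_minus) == "imprecise"
        assert classify_precise(AlignmentHit("chr1", 308, 331, "-"), locus_minus) == "precise"

    def test_infinite_tolerance_makes_everything_precise(self, locus_plus):
        hit = AlignmentHit("chr1", 100, 125, "+")
        assert classify_precise(hit, locus_plus, 10**6) == "precise"

    def test_equivalence_with_offset_pair_enumeration(self, locus_plus):
        """Brute-force oracle: a window is precise iff it equals some
        (d5, d3)-shifted annotated window with |d5|, |d3| <= tol."""
        tol = 2
        precise_windows = set()
        for w_start, w_end in ((locus_plus.mature_start, locus_plus.mature_end),
                               (locus_plus.star_start, locus_plus.star_end)):
            for d5 in range(-tol, tol + 1):
                for d3 in range(-tol, tol + 1):
                    precise_windows.add((w_start + d5, w_end + d3))
        for start in range(locus_plus.start, locus_plus.end - 15):
            for end in range(start + 16, min(start + 32, locus_plus.end) + 1):
                expected = "precise" if (start, end) in precise_windows else "imprecise"
                hit = AlignmentHit("chr1", start, end, "+")
                assert classify_precise(hit, locus_plus, tol) == expected


class TestAssignment:
    def test_containment_same_strand_assigned(self, locus_plus):
        reads = CollapsedReadSet({"A" * 21: 7})
        hits = {"A" * 21: [AlignmentHit("chr1", 110, 131, "+")]}
        assigned = assign_to_locus(hits, reads, [locus_plus])
        assert assigned[("L", "A" * 21)][1] == 7

    def test_boundary_overhang_excluded(self, locus_plus):
        reads = CollapsedReadSet({"A" * 21: 7})
        hits = {"A" * 21: [AlignmentHit("chr1", 99, 120, "+")]}
        assert assign_to_locus(hits, reads, [locus_plus]) == {}

    def test_antisense_hit_excluded(self, locus_plus):
        reads = CollapsedReadSet({"A" * 21: 7})
        hits = {"A" * 21: [AlignmentHit("chr1", 110, 131, "-")]}
        assert assign_to_locus(hits, reads, [locus_plus]) == {}

    def test_simulated_antisense_background_never_assigned(self, locus_plus):
        rng = np.random.default_rng(3)
        reads = {}
        hits = {}
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=24))
            start = int(rng.integers(locus_plus.start, locus_plus.end - 24))
            reads[seq] = 1
            hits[seq] = [AlignmentHit("chr1", start, start + 24, "-")]
        assert assign_to_locus(hits, CollapsedReadSet(reads), [locus_plus]) == {}

    def test_overlapping_hairpins_warn_and_keep_both(self, locus_plus):
        other = HairpinLocus(
            locus_id="L2", chromosome="chr1", start=120, end=240, strand="+",
            mature_start=130, mature_end=151,
        )
        reads = CollapsedReadSet({"A" * 21: 3})
        hits = {"A" * 21: [AlignmentHit("chr1", 130, 151, "+")]}
        with pytest.warns(UserWarning, match="overlap"):
            assigned = assign_to_locus(hits, reads, [locus_plus, other])
        assert set(assigned) == {("L", "A" * 21), ("L2", "A" * 21)}


class TestLocusFraction:
    def test_fraction_arithmetic(self, locus_plus):
        assignments = {
            ("L", "s1"): (AlignmentHit("chr1", 110, 131, "+"), 7),   # precise
            ("L", "s2"): (AlignmentHit("chr1", 105, 131, "+"), 3),   # imprecise
        }
        (record,) = locus_fraction(assignments, [locus_plus], "lib1")
        assert record.n_assigned == 10
        assert record.n_imprecise == 3
        assert record.imprecise_fraction == pytest.approx(0.3)

    def test_zero_imprecise_and_empty_locus(self, locus_plus):
        assignments = {("L", "s1"): (AlignmentHit("chr1", 110, 131, "+"), 4)}
        (record,) = locus_fraction(assignments, [locus_plus], "lib1")
        assert record.imprecise_fraction == 0.0
        (empty,) = locus_fraction({}, [locus_plus], "lib1")
        assert not empty.evaluable and np.isnan(empty.imprecise_fraction)


class TestEligibility:
    def _records(self, counts):
        rows = []
        for (locus, lib), n in counts.items():
            rows.append({"locus_id": locus, "library": lib, "n_assigned": n,
                         "n_imprecise": 0, "imprecise_fraction": 0.0})
        return pd.DataFrame(rows)

    LAYOUT = {"WT": ["WT_1", "WT_2"], "mut": ["mut_1", "mut_2"]}

    def test_at_least_ten_in_each_replicate_required(self):
        records = self._records({
            ("a", "WT_1"): 12, ("a", "WT_2"): 11, ("a", "mut_1"): 10, ("a", "mut_2"): 10,
            ("b", "WT_1"): 12, ("b", "WT_2"): 9, ("b", "mut_1"): 50, ("b", "mut_2"): 50,
        })
        assert eligible_loci(records, self.LAYOUT, min_reads=10) == ["a"]

    def test_min_reads_zero_keeps_all_assigned_loci(self):
        records = self._records({
            ("a", "WT_1"): 1, ("a", "WT_2"): 0, ("a", "mut_1"): 2, ("a", "mut_2"): 3,
        })
        assert eligible_loci(records, self.LAYOUT, min_reads=0) == ["a"]


class TestGenotypeSummary:
    def test_median_of_per_locus_fractions(self):
        rows = []
        for locus, frac in zip("abc", (0.1, 0.2, 0.3)):
            for lib in ("WT_1", "WT_2"):
                rows.append({"locus_id": locus, "library": lib, "n_assigned": 100,
                             "n_imprecise": int(100 * frac),
                             "imprecise_fraction": frac})
        records = pd.DataFrame(rows)
        summary = genotype_precision_summary(records, {"WT": ["WT_1", "WT_2"]}, "WT")
        assert summary.medians["WT"] == pytest.approx(0.2)

    def test_identical_distributions_give_large_p(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(40):
            frac = float(rng.uniform(0.05, 0.3))
            for lib in ("WT_1", "mut_1"):
                rows.append({"locus_id": f"l{i:02d}", "library": lib,
                             "n_assigned": 200, "n_imprecise": int(200 * frac),
                             "imprecise_fraction": frac})
        records = pd.DataFrame(rows)
        summary = genotype_precision_summary(
            records, {"WT": ["WT_1"], "mut": ["mut_1"]}, "WT"
        )
        assert summary.tests.loc[0, "p_value"] > 0.9  # identical per-locus values

    def test_too_few_loci_skips_test(self):
        rows = [{"locus_id": "a", "library": lib, "n_assigned": 50,
                 "n_imprecise": 5, "imprecise_fraction": 0.1}
                for lib in ("WT_1", "mut_1")]
        summary = genotype_precision_summary(
            pd.DataFrame(rows), {"WT": ["WT_1"], "mut": ["mut_1"]}, "WT"
        )
        assert not summary.tests.loc[0, "tested"]
        assert np.isnan(summary.tests.loc[0, "p_value"])


class TestAnnotationRoundTrip:
    def test_gff3_round_trip_recovers_loci(self, small_genome, tmp_path):
        genome, annotation, catalog, loci = small_genome
        path = tmp_path / "ann.gff3"
        write_annotation_gff3(annotation, loci, path)
        recovered = read_hairpin_annotation(path, genome, set(catalog.values()))
        assert recovered == sorted(annotation, key=lambda l: (l.chromosome, l.start))

    def test_star_suffix_dialect(self, tmp_path):
        gff = tmp_path / "star.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\t.\tmiRNA_primary_transcript\t101\t220\t.\t+\t.\tID=MI1;Name=MIR1\n"
            "chr1\t.\tmiRNA\t111\t131\t.\t+\t.\tID=M1;Name=miR1;Parent=MI1\n"
            "chr1\t.\tmiRNA\t148\t168\t.\t+\t.\tID=M1s;Name=miR1*;Parent=MI1\n"
        )
        (locus,) = read_hairpin_annotation(gff)
        assert locus.mature_start == 110 and locus.star_start == 147
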