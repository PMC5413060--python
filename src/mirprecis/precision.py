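"""Per-locus miRNA processing-precision statistics.

A hairpin-assigned read is *precise* when both of its ends fall within a
tolerance (default +/-2 nt) of the annotated mature ends, or of the
annotated star (miRNA*) ends when a star species is annotated; otherwise it
is *imprecise* (a misprocessing product or shifted isomiR).  The per-locus
imprecise fraction, restricted to loci with enough reads in every replicate,
summarizes processing fidelity per genotype; genotypes are contrasted by the
median per-locus fraction and a two-sided Wilcoxon rank-sum test.

Assignment is sense-strand containment: a sequence belongs to a hairpin
when one of its exact placements lies entirely inside the hairpin interval
on the annotated strand.  Antisense placements are excluded (processing is
strand-defined) and logged separately.  A sequence may be assigned to
several overlapping/family loci and contributes its full multiplicity to
each, classified against each locus's own annotations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from scipy import stats

from .quantify import AlignmentHit
from .reads import CollapsedReadSet

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE_NT = 2
DEFAULT_MIN_READS_PER_REPLICATE = 10


@dataclass(frozen=True)
class HairpinLocus:
    """A MIRNA hairpin with its annotated mature (and optional star) windows.

    Coordinates are 0-based half-open on the forward strand; ``strand``
    orients the 5'/3' ends of the sub-features.
    """

    locus_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    mature_start: int
    mature_end: int
    star_start: int | None = None
    star_end: int | None = None
    mature_sequence: str = ""

    def __post_init__(self) -> None:
        if not (self.start <= self.mature_start < self.mature_end <= self.end):
            raise ValueError(f"{self.locus_id}: mature window outside hairpin")
        if (self.star_start is None) != (self.star_end is None):
            raise ValueError(f"{self.locus_id}: star window half-specified")
        if self.star_start is not None:
            if not (self.start <= self.star_start < self.star_end <= self.end):
                raise ValueError(f"{self.locus_id}: star window outside hairpin")
            lo, hi = sorted([(self.mature_start, self.mature_end), (self.star_start, self.star_end)])
            if lo[1] > hi[0]:
                raise ValueError(f"{self.locus_id}: mature and star windows overlap")

    @property
    def has_star(self) -> bool:
        return self.star_start is not None


@dataclass
class PrecisionRecord:
    locus_id: str
    library: str
    n_assigned: int
    n_imprecise: int

    @property
    def evaluable(self) -> bool:
        return self.n_assigned > 0

    @property
    def imprecise_fraction(self) -> float:
        if self.n_assigned == 0:
            return float("nan")
        return self.n_imprecise / self.n_assigned


def _oriented_ends(start: int, end: int, strand: str) -> tuple[int, int]:
    """(5' end, 3' end) genomic positions of a half-open interval."""
    return (start, end - 1) if strand == "+" else (end - 1, start)


def classify_precise(
    hit: AlignmentHit, locus: HairpinLocus, tolerance_nt: int = DEFAULT_TOLERANCE_NT
) -> str:
    """'precise' iff both read ends sit within the tolerance of the mature
    (or star) annotated ends, in strand orientation; else 'imprecise'."""
    if tolerance_nt < 0:
        raise ValueError("tolerance must be >= 0")
    hit5, hit3 = _oriented_ends(hit.start, hit.end, locus.strand)
    windows = [(locus.mature_start, locus.mature_end)]
    if locus.has_star:
        windows.append((locus.star_start, locus.star_end))
    for w_start, w_end in windows:
        ann5, ann3 = _oriented_ends(w_start, w_end, locus.strand)
        if abs(hit5 - ann5) <= tolerance_nt and abs(hit3 - ann3) <= tolerance_nt:
            return "precise"
    return "imprecise"


def assign_to_locus(
    hits: dict[str, list[AlignmentHit]],
    reads: CollapsedReadSet,
    loci: list[HairpinLocus],
) -> dict[tuple[str, str], tuple[AlignmentHit, int]]:
    """Assign sequences to hairpins by sense-strand containment.

    Returns {(locus_id, sequence): (hit, multiplicity)}.  Antisense
    placements inside a hairpin are counted and logged, never assigned.
    """
    by_chrom: dict[str, list[HairpinLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chromosome, []).append(locus)
    for chrom_loci in by_chrom.values():
        chrom_loci.sort(key=lambda l: l.start)
        for a, b in zip(chrom_loci, chrom_loci[1:]):
            if b.start < a.end:
                warnings.warn(
                    f"hairpins {a.locus_id} and {b.locus_id} overlap; "
                    "reads in the shared interval are assigned to both"
                )
    assigned: dict[tuple[str, str], tuple[AlignmentHit, int]] = {}
    n_antisense = 0
    for seq, seq_hits in hits.items():
        mult = reads.counts.get(seq, 0)
        if mult == 0:
            continue
        for hit in seq_hits:
            for locus in by_chrom.get(hit.chromosome, ()):
                if locus.start <= hit.start and hit.end <= locus.end:
                    if hit.strand != locus.strand:
                        n_antisense += mult
                        continue
                    assigned[(locus.locus_id, seq)] = (hit, mult)
    if n_antisense:
        logger.info("excluded %d antisense in-hairpin reads from assignment", n_antisense)
    return assigned


def locus_fraction(
    assignments: dict[tuple[str, str], tuple[AlignmentHit, int]],
    loci: list[HairpinLocus],
    library: str,
    tolerance_nt: int = DEFAULT_TOLERANCE_NT,
) -> list[PrecisionRecord]:
    """Per-locus assigned/imprecise totals for one library.

    Loci with no assigned reads yield a record with n_assigned = 0
    (not evaluable; fraction is NaN).
    """
    by_id = {locus.locus_id: locus for locus in loci}
    n_assigned: dict[str, int] = {lid: 0 for lid in by_id}
    n_imprecise: dict[str, int] = {lid: 0 for lid in by_id}
    for (locus_id, _seq), (hit, mult) in assignments.items():
        n_assigned[locus_id] += mult
        if classify_precise(hit, by_id[locus_id], tolerance_nt) == "imprecise":
            n_imprecise[locus_id] += mult
    return [
        PrecisionRecord(lid, library, n_assigned[lid], n_imprecise[lid])
        for lid in sorted(by_id)
    ]


def records_to_frame(records: list[PrecisionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": [r.locus_id for r in records],
            "library": [r.library for r in records],
            "n_assigned": [r.n_assigned for r in records],
            "n_imprecise": [r.n_imprecise for r in records],
            "imprecise_fraction": [r.imprecise_fraction for r in records],
        }
    )


def eligible_loci(
    records: pd.DataFrame,
    layout: dict[str, list[str]],
    genotypes: list[str] | None = None,
    min_reads: int = DEFAULT_MIN_READS_PER_REPLICATE,
) -> list[str]:
    """Loci with >= min_reads assigned in every replicate of every compared
    genotype (the depth filter for evaluating processing precision)."""
    genotypes = genotypes or sorted(layout)
    libraries = [lib for g in genotypes for lib in layout[g]]
    keep: list[str] = []
    for locus_id, group in records.groupby("locus_id"):
        per_lib = group.set_index("library")["n_assigned"]
        if all(per_lib.get(lib, 0) >= min_reads for lib in libraries):
            keep.append(str(locus_id))
    return sorted(keep)


@dataclass
class PrecisionSummary:
    per_locus: pd.DataFrame          # locus x genotype mean imprecise fraction
    medians: pd.Series               # per-genotype median of per-locus fractions
    tests: pd.DataFrame              # mutant vs WT rank-sum results (or empty)


def genotype_precision_summary(
    records: pd.DataFrame,
    layout: dict[str, list[str]],
    wt_label: str,
    genotypes: list[str] | None = None,
    min_reads: int = DEFAULT_MIN_READS_PER_REPLICATE,
    min_loci_for_test: int = 3,
) -> PrecisionSummary:
    """Genotype-level precision contrast over eligible loci.

    Replicate fractions are averaged per locus per genotype before medians;
    each mutant is compared to WT with a two-sided Wilcoxon rank-sum test
    over the per-locus fractions (reported, never thresholded).
    """
    genotypes = genotypes or sorted(layout)
    if wt_label not in genotypes:
        raise ValueError(f"wild-type label {wt_label!r} not in genotypes {genotypes}")
    eligible = eligible_loci(records, layout, genotypes, min_reads)
    sub = records[records["locus_id"].isin(eligible)]
    lib_to_genotype = {lib: g for g, libs in layout.items() for lib in libs}
    sub = sub.assign(genotype=sub["library"].map(lib_to_genotype))
    per_locus = (
        sub.groupby(["locus_id", "genotype"])["imprecise_fraction"]
        .mean()
        .unstack("genotype")
        .reindex(columns=genotypes)
    )
    medians = per_locus.median()
    rows = []
    for genotype in genotypes:
        if genotype == wt_label:
            continue
        if len(per_locus) < min_loci_for_test:
            rows.append({"genotype": genotype, "n_loci": len(per_locus),
                         "statistic": np.nan, "p_value": np.nan, "tested": False})
            continue
        res = stats.ranksums(
            per_locus[genotype].dropna(), per_locus[wt_label].dropna()
        )
        rows.append({"genotype": genotype, "n_loci": len(per_locus),
                     "statistic": res.statistic, "p_value": res.pvalue, "tested": True})
    tests = pd.DataFrame(rows, columns=["genotype", "n_loci", "statistic", "p_value", "tested"])
    return PrecisionSummary(per_locus=per_locus, medians=medians, tests=tests)


# --- annotation IO -----------------------------------------------------------

def read_hairpin_annotation(
    gff3_path: str | Path,
    genome: dict[str, str] | None = None,
    mature_sequences: set[str] | None = None,
) -> list[HairpinLocus]:
    """Load hairpin loci from a miRBase-dialect GFF3.

    ``miRNA_primary_transcript`` features are hairpins; child ``miRNA``
    features (linked by Parent/Derives_from) are the mature and star
    species.  The mature child is recognised, in order of preference, by
    membership of its spelled-out sequence in ``mature_sequences``, by the
    absence of a ``*`` suffix when its sibling has one, or by an arm suffix
    (-5p/-3p) matching the hairpin's ``arm`` attribute; with exactly one
    child, that child is the mature species and no star is recorded.
    """
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    loci: list[HairpinLocus] = []
    for hairpin in db.features_of_type("miRNA_primary_transcript"):
        children = []
        for child in db.features_of_type("miRNA"):
            parents = child.attributes.get("Parent", []) + child.attributes.get("Derives_from", [])
            if hairpin.id in parents or any(p == hairpin.id for p in parents):
                children.append(child)
        if not children:
            warnings.warn(f"hairpin {hairpin.id} has no miRNA children; skipped")
            continue
        mature_child, star_child = _split_mature_star(
            hairpin, children, genome, mature_sequences
        )
        mature_seq = ""
        if genome is not None:
            mature_seq = _feature_sequence(mature_child, genome)
        loci.append(
            HairpinLocus(
                locus_id=_feature_name(hairpin),
                chromosome=hairpin.seqid,
                start=hairpin.start - 1,
                end=hairpin.end,
                strand=hairpin.strand,
                mature_start=mature_child.start - 1,
                mature_end=mature_child.end,
                star_start=None if star_child is None else star_child.start - 1,
                star_end=None if star_child is None else star_child.end,
                mature_sequence=mature_seq,
            )
        )
    return sorted(loci, key=lambda l: (l.chromosome, l.start))


def _feature_name(feature) -> str:
    names = feature.attributes.get("Name", [])
    return names[0] if names else feature.id


def _feature_sequence(feature, genome: dict[str, str]) -> str:
    from Bio.Seq import reverse_complement

    seq = genome[feature.seqid][feature.start - 1 : feature.end].upper()
    return reverse_complement(seq) if feature.strand == "-" else seq


def _split_mature_star(hairpin, children, genome, mature_sequences):
    if len(children) == 1:
        return children[0], None
    if len(children) != 2:
        raise ValueError(
            f"hairpin {hairpin.id}: expected 1-2 miRNA children, got {len(children)}"
        )
    a, b = children
    if mature_sequences is not None and genome is not None:
        a_in = _feature_sequence(a, genome) in mature_sequences
        b_in = _feature_sequence(b, genome) in mature_sequences
        if a_in != b_in:
            return (a, b) if a_in else (b, a)
    a_star = _feature_name(a).endswith("*")
    b_star = _feature_name(b).endswith("*")
    if a_star != b_star:
        return (b, a) if a_star else (a, b)
    arm = (hairpin.attributes.get("arm", [None]) or [None])[0]
    if arm in ("5p", "3p"):
        for mature, star in ((a, b), (b, a)):
            if _feature_name(mature).endswith(f"-{arm}"):
                return mature, star
    raise ValueError(
        f"hairpin {hairpin.id}: cannot tell mature from star among "
        f"{[_feature_name(c) for c in children]}"
    )


def write_precision_tables(
    records: pd.DataFrame,
    summary: PrecisionSummary,
    precision_path: str | Path,
    summary_path: str | Path,
) -> None:
    records.to_csv(precision_path, sep="\t", index=False, float_format="%.6g")
    with open(summary_path, "w") as fh:
        fh.write("# per-genotype median imprecise fraction over eligible loci\n")
        summary.medians.rename("median_imprecise_fraction").to_csv(fh, sep="\t")
        fh.write("# mutant vs WT two-sided Wilcoxon rank-sum\n")
        summary.tests.to_csv(fh, sep="\t", index=False, float_format="%.6g")
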