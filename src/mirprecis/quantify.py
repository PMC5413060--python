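"""Exact-match genome mapping, mature miRNA identification and RPTM.

Collapsed reads are placed on the genome by perfect full-length matching on
both strands (mirroring an analysis in which only reads identical to
annotated mature miRNAs are counted).  Mature miRNAs are identified by
strict sequence identity to a miRBase-style catalog, and counts are
normalized to Reads Per Ten Million (RPTM):

    RPTM = raw count / (total genome-matched reads in the library) * 1e7

where a multi-locus sequence contributes its multiplicity once to the
genome-matched total (a read is one molecule regardless of placements).

Coordinates are 0-based half-open internally; anything written to GFF3 or
reports is 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .reads import CollapsedReadSet

RPTM_SCALE = 10_000_000


class NormalizationError(ValueError):
    """Raised when a library has no genome-matched reads to normalize by."""


@dataclass(frozen=True)
class AlignmentHit:
    chromosome: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("empty alignment interval")


class GenomeIndex:
    """Exact-match lookup over both strands of a genome.

    Forward-strand windows of each query length are indexed once per length
    (lazily); a query is looked up as itself (plus-strand hits) and as its
    reverse complement (reported as minus-strand hits on the same forward
    interval).  A palindromic query (equal to its own reverse complement)
    reports each genomic window once, as a plus-strand hit.
    """

    def __init__(self, genome: dict[str, str]):
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self._by_length: dict[int, dict[str, list[tuple[str, int]]]] = {}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not genome:
            raise ValueError(f"no sequences in {path}")
        return cls(genome)

    def _index_for(self, length: int) -> dict[str, list[tuple[str, int]]]:
        idx = self._by_length.get(length)
        if idx is None:
            idx = {}
            for chrom, seq in self.genome.items():
                for start in range(0, len(seq) - length + 1):
                    idx.setdefault(seq[start : start + length], []).append((chrom, start))
            self._by_length[length] = idx
        return idx

    def query(self, sequence: str) -> list[AlignmentHit]:
        sequence = sequence.upper()
        length = len(sequence)
        if length == 0:
            return []
        idx = self._index_for(length)
        hits = [
            AlignmentHit(chrom, start, start + length, "+")
            for chrom, start in idx.get(sequence, ())
        ]
        rc = reverse_complement(sequence)
        if rc != sequence:
            hits.extend(
                AlignmentHit(chrom, start, start + length, "-")
                for chrom, start in idx.get(rc, ())
            )
        return hits


def map_exact(reads: CollapsedReadSet, index: GenomeIndex) -> dict[str, list[AlignmentHit]]:
    """All perfect-match placements for every collapsed sequence.

    Sequences with no placement are kept with an empty hit list so that
    unmapped reads stay visible to the accounting.
    """
    return {seq: index.query(seq) for seq in reads.counts}


def genome_matched_total(reads: CollapsedReadSet, hits: dict[str, list[AlignmentHit]]) -> int:
    """Total multiplicity of sequences with >= 1 genomic placement.

    Each read counts once regardless of how many loci its sequence hits.
    """
    return sum(mult for seq, mult in reads.counts.items() if hits.get(seq))


@dataclass
class MatureCatalog:
    """Unique mature sequences -> sorted miRNA names sharing that sequence.

    miRNA families whose members share one mature sequence are merged into a
    single entry (strict identity cannot distinguish them); the merged row
    label joins the names with '/'.  RNA 'U' is normalized to 'T' on load.
    """

    entries: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MatureCatalog":
        entries: dict[str, list[str]] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper().replace("U", "T")
            entries.setdefault(seq, []).append(rec.id)
        return cls({seq: sorted(set(names)) for seq, names in entries.items()})

    @classmethod
    def from_dict(cls, name_to_seq: dict[str, str]) -> "MatureCatalog":
        entries: dict[str, list[str]] = {}
        for name, seq in name_to_seq.items():
            entries.setdefault(seq.upper().replace("U", "T"), []).append(name)
        return cls({seq: sorted(set(names)) for seq, names in entries.items()})

    def label(self, seq: str) -> str:
        return "/".join(self.entries[seq])

    @property
    def labels(self) -> list[str]:
        return sorted(self.label(seq) for seq in self.entries)


def quantify_mature(reads: CollapsedReadSet, catalog: MatureCatalog) -> pd.Series:
    """Raw mature counts by strict full-length identity to the catalog.

    IsomiRs (any end shift) and mismatched variants count 0 toward an entry.
    Catalog entries absent from the library get 0.
    """
    data = {
        catalog.label(seq): reads.counts.get(seq, 0) for seq in catalog.entries
    }
    return pd.Series(data, dtype="int64").sort_index()


def rptm(raw: float, genome_total: int, library: str = "") -> float:
    """Reads Per Ten Million: raw / genome_total * 1e7."""
    if genome_total <= 0:
        where = f" in library {library!r}" if library else ""
        raise NormalizationError(f"no genome-matched reads{where}; cannot compute RPTM")
    return raw / genome_total * RPTM_SCALE


@dataclass
class NormalizedMatrix:
    """Mature miRNA x library count and RPTM matrices."""

    counts: pd.DataFrame              # integer raw counts
    rptm: pd.DataFrame                # RPTM values
    genome_matched_total: pd.Series   # per-library normalizer


def build_matrices(
    per_library_counts: dict[str, pd.Series],
    per_library_totals: dict[str, int],
) -> NormalizedMatrix:
    """Assemble count and RPTM matrices from per-library mature counts."""
    counts = pd.DataFrame(per_library_counts).sort_index()
    totals = pd.Series(per_library_totals).reindex(counts.columns)
    for lib, total in totals.items():
        if total <= 0:
            raise NormalizationError(
                f"no genome-matched reads in library {lib!r}; cannot compute RPTM"
            )
    rptm_df = counts.div(totals, axis=1) * RPTM_SCALE
    return NormalizedMatrix(counts=counts, rptm=rptm_df, genome_matched_total=totals)


def write_matrices(matrix: NormalizedMatrix, counts_path: str | Path, rptm_path: str | Path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="mirna")
    matrix.rptm.round(3).to_csv(rptm_path, sep="\t", index_label="mirna", float_format="%.3f")
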