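"""Raw read clean-up for small RNA libraries.

Converts raw single-end FASTQ reads into collapsed, size-selected insert
sets.  Small RNA protocols read through the insert into the 3' adapter, so
the insert is recovered by locating the adapter and keeping the upstream
part of the read.  Reads in which no adapter is found are discarded by
default (an adapter-less read implies an insert longer than the read, i.e.
outside the small RNA size range).  Inserts are then filtered to the
18-30 nt window and collapsed to unique sequences with multiplicities,
the unit all downstream counting operates on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

# Illumina TruSeq small RNA 3' adapter; a configuration default, not a
# claim about any particular sequencing run.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

MIN_INSERT_LENGTH = 18
MAX_INSERT_LENGTH = 30

DEFAULT_MIN_OVERLAP = 6
DEFAULT_MAX_MISMATCH_RATE = 0.1


class AdapterConfigError(ValueError):
    """Raised for unusable adapter/overlap settings."""


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class CleanRead:
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CollapsedReadSet:
    """Unique clean-read sequences with per-library multiplicities."""

    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_clean_reads(self) -> int:
        return sum(self.counts.values())

    def expand(self) -> list[str]:
        """Inverse of :func:`collapse` (order: sorted sequences)."""
        out: list[str] = []
        for seq in sorted(self.counts):
            out.extend([seq] * self.counts[seq])
        return out


@dataclass
class ReadAccounting:
    """Per-library read bookkeeping along the clean-up stages."""

    n_raw: int = 0
    n_trimmed: int = 0
    n_untrimmed: int = 0
    n_with_n: int = 0
    n_size_kept: int = 0


def trim_adapter(
    sequence: str,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> str | None:
    """Locate the 3' adapter and return the upstream insert.

    Scans candidate trim positions left to right and accepts the first
    position where the read suffix matches a prefix of the adapter with
    overlap >= ``min_overlap`` and a mismatch fraction <= ``max_mismatch_rate``.
    A full internal adapter occurrence is therefore trimmed at its leftmost
    start.  Returns ``None`` when no acceptable match exists (read discarded
    upstream of size selection).
    """
    if not adapter:
        raise AdapterConfigError("adapter sequence is empty")
    if min_overlap < 5:
        raise AdapterConfigError(f"min_overlap must be >= 5, got {min_overlap}")
    if len(adapter) < min_overlap:
        raise AdapterConfigError(
            f"adapter ({len(adapter)} nt) shorter than min_overlap {min_overlap}"
        )
    n = len(sequence)
    m = len(adapter)
    if max_mismatch_rate <= 0.0:
        # Exact-match fast path: a full occurrence is always the leftmost
        # acceptable position; otherwise the longest exact suffix-prefix
        # overlap is.
        pos = sequence.find(adapter)
        if pos >= 0:
            return sequence[:pos]
        for ovl in range(min(m, n), min_overlap - 1, -1):
            if sequence.endswith(adapter[:ovl]):
                return sequence[: n - ovl]
        return None
    for i in range(0, n - min_overlap + 1):
        ovl = min(n - i, m)
        allowed = int(max_mismatch_rate * ovl)
        mismatches = 0
        ok = True
        for j in range(ovl):
            if sequence[i + j] != adapter[j]:
                mismatches += 1
                if mismatches > allowed:
                    ok = False
                    break
        if ok:
            return sequence[:i]
    return None


def filter_by_size(
    inserts: Iterable[str],
    min_len: int = MIN_INSERT_LENGTH,
    max_len: int = MAX_INSERT_LENGTH,
) -> list[CleanRead]:
    """Keep inserts with min_len <= length <= max_len (bounds inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [CleanRead(s) for s in inserts if min_len <= len(s) <= max_len]


def collapse(clean: Iterable[CleanRead | str]) -> CollapsedReadSet:
    """Collapse clean reads to unique sequences with multiplicities."""
    counter: Counter[str] = Counter(
        r.sequence if isinstance(r, CleanRead) else r for r in clean
    )
    return CollapsedReadSet(counts=dict(counter))


def iter_fastq(path: str | Path) -> Iterator[RawRead]:
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield RawRead(title.split()[0], seq.upper(), qual)


def process_library(
    reads: Iterable[RawRead] | str | Path,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    min_len: int = MIN_INSERT_LENGTH,
    max_len: int = MAX_INSERT_LENGTH,
    keep_untrimmed: bool = False,
) -> tuple[CollapsedReadSet, ReadAccounting]:
    """FASTQ -> trimmed, size-selected, collapsed read set with accounting.

    Identical raw sequences are trimmed once (the trim rule depends only on
    the sequence).  Inserts containing N are discarded: exact-match mapping
    downstream cannot place them.
    """
    if isinstance(reads, (str, Path)):
        reads = iter_fastq(reads)
    raw_counter: Counter[str] = Counter(r.sequence for r in reads)
    acct = ReadAccounting(n_raw=sum(raw_counter.values()))
    insert_counter: Counter[str] = Counter()
    for seq, mult in raw_counter.items():
        insert = trim_adapter(seq, adapter, min_overlap, max_mismatch_rate)
        if insert is None:
            acct.n_untrimmed += mult
            if keep_untrimmed:
                insert = seq
            else:
                continue
        else:
            acct.n_trimmed += mult
        if "N" in insert:
            acct.n_with_n += mult
            continue
        insert_counter[insert] += mult
    kept: dict[str, int] = {
        s: c for s, c in insert_counter.items() if min_len <= len(s) <= max_len
    }
    acct.n_size_kept = sum(kept.values())
    return CollapsedReadSet(counts=kept), acct


def write_collapsed(collapsed: CollapsedReadSet, fasta_path: str | Path, tsv_path: str | Path) -> None:
    """Write the collapsed set as `>seq<i>_x<count>` FASTA plus a TSV."""
    items = sorted(collapsed.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(fasta_path, "w") as fa:
        for i, (seq, count) in enumerate(items, start=1):
            fa.write(f">seq{i}_x{count}\n{seq}\n")
    with open(tsv_path, "w") as tsv:
        tsv.write("sequence\tlength\tcount\n")
        for seq, count in items:
            tsv.write(f"{seq}\t{len(seq)}\t{count}\n")


def read_collapsed_tsv(tsv_path: str | Path) -> CollapsedReadSet:
    counts: dict[str, int] = {}
    with open(tsv_path) as fh:
        header = fh.readline()
        if not header.startswith("sequence"):
            raise ValueError(f"{tsv_path}: expected a collapsed-read TSV header")
        for line in fh:
            seq, _length, count = line.rstrip("\n").split("\t")
            counts[seq] = int(count)
    return CollapsedReadSet(counts=counts)
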