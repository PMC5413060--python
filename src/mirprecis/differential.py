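"""Differential miRNA accumulation and size-class profiling.

Follows a pure fold-change design: miRNAs expressed above an RPTM threshold
in wild type are classified as reduced in a mutant when the mutant/WT ratio
of replicate-mean RPTM drops to the fold threshold (default two-fold,
boundary inclusive).  No dispersion-based test or multiple-testing
correction is applied.  Reduced sets from different mutants are compared as
a three-way partition (only-A / shared / only-B).  A per-length relative
abundance profile over the 18-30 nt window supports the 24-nt siRNA
size-class comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .quantify import NormalizationError
from .reads import MAX_INSERT_LENGTH, MIN_INSERT_LENGTH, CollapsedReadSet

DEFAULT_EXPRESSION_THRESHOLD_RPTM = 10.0
DEFAULT_FOLD_THRESHOLD = 2.0


class LayoutError(ValueError):
    """Raised when a genotype label is missing from the library layout."""


@dataclass
class ExpressionRecord:
    mirna: str
    genotype_means: dict[str, float]
    replicate_values: dict[tuple[str, str], float]  # (genotype, library) -> RPTM


@dataclass
class FoldChangeResult:
    mirna: str
    wt_mean: float
    mutant_mean: float
    ratio_mut_over_wt: float
    reduced_twofold: bool


@dataclass
class OverlapResult:
    only_a: list[str]
    shared: list[str]
    only_b: list[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.only_a), len(self.shared), len(self.only_b)


def _check_layout(rptm: pd.DataFrame, layout: dict[str, list[str]], labels: list[str]) -> None:
    for label in labels:
        if label not in layout:
            raise LayoutError(f"genotype {label!r} not in layout {sorted(layout)}")
        missing = [lib for lib in layout[label] if lib not in rptm.columns]
        if missing:
            raise LayoutError(f"libraries {missing} for genotype {label!r} not in matrix")


def filter_expressed(
    rptm: pd.DataFrame,
    layout: dict[str, list[str]],
    wt_label: str,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD_RPTM,
    per_replicate: bool = False,
) -> list[ExpressionRecord]:
    """Keep miRNAs whose WT mean RPTM (or, optionally, every WT replicate)
    reaches the expression threshold."""
    _check_layout(rptm, layout, [wt_label])
    wt_cols = layout[wt_label]
    if per_replicate:
        keep = (rptm[wt_cols] >= threshold).all(axis=1)
    else:
        keep = rptm[wt_cols].mean(axis=1) >= threshold
    records: list[ExpressionRecord] = []
    for mirna in rptm.index[keep]:
        means = {g: float(rptm.loc[mirna, libs].mean()) for g, libs in layout.items()}
        values = {
            (g, lib): float(rptm.loc[mirna, lib])
            for g, libs in layout.items()
            for lib in libs
        }
        records.append(ExpressionRecord(str(mirna), means, values))
    return records


def classify_reduced(
    record: ExpressionRecord,
    wt_label: str,
    mutant_label: str,
    fold: float = DEFAULT_FOLD_THRESHOLD,
    inclusive: bool = True,
) -> FoldChangeResult:
    """Mutant/WT ratio of replicate-mean RPTM and the fold-reduction call.

    ``inclusive`` reads the threshold as "at least a ``fold``-fold
    reduction" (ratio <= 1/fold); the strict variant requires
    ratio < 1/fold.  The WT mean is > 0 for any record that passed a
    positive expression filter.
    """
    if fold <= 0:
        raise ValueError("fold threshold must be > 0")
    wt_mean = record.genotype_means[wt_label]
    mut_mean = record.genotype_means[mutant_label]
    if wt_mean <= 0:
        raise ValueError(f"{record.mirna}: WT mean is 0; apply the expression filter first")
    ratio = mut_mean / wt_mean
    cutoff = 1.0 / fold
    reduced = ratio <= cutoff if inclusive else ratio < cutoff
    return FoldChangeResult(record.mirna, wt_mean, mut_mean, ratio, reduced)


def reduced_set(
    records: list[ExpressionRecord],
    wt_label: str,
    mutant_label: str,
    fold: float = DEFAULT_FOLD_THRESHOLD,
    inclusive: bool = True,
) -> set[str]:
    return {
        r.mirna
        for r in records
        if classify_reduced(r, wt_label, mutant_label, fold, inclusive).reduced_twofold
    }


def set_overlap(reduced_a: set[str], reduced_b: set[str]) -> OverlapResult:
    """Partition two reduced sets into only-A / shared / only-B."""
    return OverlapResult(
        only_a=sorted(reduced_a - reduced_b),
        shared=sorted(reduced_a & reduced_b),
        only_b=sorted(reduced_b - reduced_a),
    )


def size_class_profile(
    mapped_reads: dict[str, CollapsedReadSet],
    min_len: int = MIN_INSERT_LENGTH,
    max_len: int = MAX_INSERT_LENGTH,
) -> pd.DataFrame:
    """Per-length relative abundance of genome-matched reads per library.

    ``mapped_reads`` maps library name to its genome-matched collapsed set
    (apply a structural-RNA exclusion upstream for the "non-structural"
    variant).  Rows are lengths min_len..max_len; columns are libraries;
    each column sums to 1.
    """
    lengths = list(range(min_len, max_len + 1))
    data: dict[str, list[float]] = {}
    for library, reads in mapped_reads.items():
        total = reads.total_clean_reads
        if total == 0:
            raise NormalizationError(f"library {library!r} has no genome-matched reads")
        by_len = {length: 0 for length in lengths}
        for seq, mult in reads.counts.items():
            if min_len <= len(seq) <= max_len:
                by_len[len(seq)] += mult
        data[library] = [by_len[length] / total for length in lengths]
    return pd.DataFrame(data, index=pd.Index(lengths, name="length"))


def size_class_ratio(
    profile: pd.DataFrame,
    layout: dict[str, list[str]],
    wt_label: str,
    mutant_label: str,
    length: int = 24,
) -> float:
    """Mutant/WT ratio of the replicate-mean relative abundance at one size
    class (default the 24-nt siRNA class)."""
    for label in (wt_label, mutant_label):
        if label not in layout:
            raise LayoutError(f"genotype {label!r} not in layout {sorted(layout)}")
        missing = [lib for lib in layout[label] if lib not in profile.columns]
        if missing:
            raise LayoutError(f"libraries {missing} for genotype {label!r} not in profile")
    wt_frac = profile.loc[length, layout[wt_label]].mean()
    mut_frac = profile.loc[length, layout[mutant_label]].mean()
    if wt_frac == 0:
        raise NormalizationError(f"WT has no reads of length {length}")
    return float(mut_frac / wt_frac)


def fold_change_table(
    records: list[ExpressionRecord],
    wt_label: str,
    mutant_labels: list[str],
    fold: float = DEFAULT_FOLD_THRESHOLD,
    inclusive: bool = True,
) -> pd.DataFrame:
    rows = []
    for record in records:
        for mutant in mutant_labels:
            result = classify_reduced(record, wt_label, mutant, fold, inclusive)
            rows.append(
                {
                    "mirna": result.mirna,
                    "mutant": mutant,
                    "wt_mean_rptm": result.wt_mean,
                    "mutant_mean_rptm": result.mutant_mean,
                    "ratio": result.ratio_mut_over_wt,
                    "reduced": result.reduced_twofold,
                }
            )
    return pd.DataFrame(rows)


def write_fold_changes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_overlap(result: OverlapResult, label_a: str, label_b: str, path: str | Path) -> None:
    only_a, shared, only_b = result.counts
    with open(path, "w") as fh:
        fh.write("partition\tcount\tmirnas\n")
        fh.write(f"only_{label_a}\t{only_a}\t{','.join(result.only_a)}\n")
        fh.write(f"shared\t{shared}\t{','.join(result.shared)}\n")
        fh.write(f"only_{label_b}\t{only_b}\t{','.join(result.only_b)}\n")
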