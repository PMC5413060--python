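"""Relative quantification of qRT-PCR Ct tables by the 2^-ddCt method.

Per sample and biological replicate, dCt = Ct(target) - Ct(reference gene,
e.g. Actin for mRNAs or SnoR101 for small RNAs).  Each replicate's fold
change is 2^-(dCt - mean dCt of the calibrator sample), so the calibrator
(wild type / untreated) averages to 1 and its replicates scatter around 1.
Means and sample SDs are reported on the fold scale, matching
"mean +/- SD of three biological replicates" style error bars.
Amplification efficiency is fixed at 2 (no Pfaffl correction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CT_COLUMNS = ["sample", "gene", "role", "replicate", "ct"]


class QpcrConfigError(ValueError):
    """Raised when the Ct table cannot support the requested calibration."""


@dataclass
class RelativeExpression:
    sample: str
    gene: str
    per_replicate_fold: list[float]
    mean_fold: float
    sd_fold: float


def delta_ct(target_ct: float, reference_ct: float) -> float:
    """dCt = Ct(target) - Ct(reference) for one sample and replicate."""
    return target_ct - reference_ct


def read_ct_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise QpcrConfigError(f"Ct table {path} missing columns {missing}")
    return table


def _delta_ct_frame(table: pd.DataFrame, reference_gene: str | None = None) -> pd.DataFrame:
    """Per (sample, target gene, replicate) dCt values.

    The reference gene is taken from rows with role == 'reference' (or by
    name).  Replicates lacking a reference Ct are excluded with a warning.
    """
    if (table["ct"] <= 0).any():
        raise QpcrConfigError("Ct values must be positive cycle numbers")
    dup = table.duplicated(subset=["sample", "gene", "replicate"])
    if dup.any():
        raise QpcrConfigError("duplicate (sample, gene, replicate) rows in Ct table")
    if reference_gene is None:
        ref_rows = table[table["role"] == "reference"]
    else:
        ref_rows = table[table["gene"] == reference_gene]
    if ref_rows.empty:
        raise QpcrConfigError("no reference-gene rows in Ct table")
    # Mean over reference genes when more than one is supplied.
    ref = ref_rows.groupby(["sample", "replicate"])["ct"].mean()
    targets = table[~table.index.isin(ref_rows.index)]
    rows = []
    for record in targets.itertuples():
        key = (record.sample, record.replicate)
        if key not in ref.index:
            warnings.warn(
                f"no reference Ct for sample {record.sample!r} replicate "
                f"{record.replicate}; replicate excluded"
            )
            continue
        rows.append(
            {
                "sample": record.sample,
                "gene": record.gene,
                "replicate": record.replicate,
                "delta_ct": delta_ct(record.ct, float(ref.loc[key])),
            }
        )
    return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "delta_ct"])


def relative_expression(
    delta_cts: pd.DataFrame | list[float],
    calibrator_mean_delta_ct: float | None = None,
    sample: str = "",
    gene: str = "",
) -> RelativeExpression:
    """Fold changes for one (sample, gene) against a calibrator mean dCt.

    per-replicate fold = 2^-(dCt - calibrator mean dCt); the mean and the
    sample SD (ddof=1) are taken over replicates on the fold scale.
    """
    if calibrator_mean_delta_ct is None:
        raise QpcrConfigError("no calibrator data: calibrator mean delta-Ct required")
    if isinstance(delta_cts, pd.DataFrame):
        values = delta_cts["delta_ct"].to_numpy(dtype=float)
    else:
        values = np.asarray(delta_cts, dtype=float)
    if values.size == 0:
        raise QpcrConfigError(f"no replicates for sample {sample!r} gene {gene!r}")
    folds = np.power(2.0, -(values - calibrator_mean_delta_ct))
    if values.size == 1:
        warnings.warn(f"single replicate for ({sample!r}, {gene!r}); SD reported as 0")
        sd = 0.0
    else:
        sd = float(np.std(folds, ddof=1))
    return RelativeExpression(
        sample=sample,
        gene=gene,
        per_replicate_fold=[float(f) for f in folds],
        mean_fold=float(np.mean(folds)),
        sd_fold=sd,
    )


def quantify_table(
    table: pd.DataFrame,
    calibrator: str,
    reference_gene: str | None = None,
) -> list[RelativeExpression]:
    """2^-ddCt for every (sample, target gene) in a Ct table."""
    dcts = _delta_ct_frame(table, reference_gene)
    if dcts.empty:
        raise QpcrConfigError("no target dCt values could be computed")
    results: list[RelativeExpression] = []
    for gene, gene_dcts in dcts.groupby("gene", sort=True):
        calib = gene_dcts[gene_dcts["sample"] == calibrator]
        if calib.empty:
            raise QpcrConfigError(
                f"calibrator sample {calibrator!r} has no dCt values for gene {gene!r}"
            )
        calib_mean = float(calib["delta_ct"].mean())
        for sample, sample_dcts in gene_dcts.groupby("sample", sort=True):
            results.append(
                relative_expression(sample_dcts, calib_mean, str(sample), str(gene))
            )
    return results


def summarize(
    results: list[RelativeExpression], expected_replicates: int = 3
) -> pd.DataFrame:
    """One row per (sample, gene): mean fold +/- SD, replicate count."""
    rows = []
    for res in results:
        n = len(res.per_replicate_fold)
        if n != expected_replicates:
            warnings.warn(
                f"({res.sample!r}, {res.gene!r}): {n} replicates, "
                f"expected {expected_replicates}"
            )
        rows.append(
            {
                "sample": res.sample,
                "gene": res.gene,
                "n_replicates": n,
                "mean_fold": res.mean_fold,
                "sd_fold": res.sd_fold,
            }
        )
    return pd.DataFrame(rows, columns=["sample", "gene", "n_replicates", "mean_fold", "sd_fold"])


def ct_table_from_folds(
    folds: dict[tuple[str, str], list[float]],
    calibrator: str = "WT",
    reference_gene: str = "Actin",
    reference_ct: float = 20.0,
    calibrator_delta_ct: float = 5.0,
) -> pd.DataFrame:
    """Synthetic Ct table realizing given per-replicate fold changes.

    Inverts the 2^-ddCt arithmetic: Ct(target) = Ct(reference) +
    calibrator dCt - log2(fold).  The calibrator sample itself must be
    included in ``folds`` (its replicate folds determine its scatter; use
    all 1.0 for an exact calibrator).  Useful for round-trip validation.
    """
    if not any(sample == calibrator for sample, _gene in folds):
        raise QpcrConfigError(f"folds must include the calibrator sample {calibrator!r}")
    rows = []
    seen_refs: set[tuple[str, int]] = set()
    for (sample, gene), fold_values in sorted(folds.items()):
        # Calibrator folds must average 1 so its mean dCt equals the anchor
        # only when they do; shift them so the round trip is exact.
        values = list(fold_values)
        if sample == calibrator:
            log2s = [math.log2(v) for v in values]
            shift = sum(log2s) / len(log2s)
            values = [2.0 ** (l - shift) for l in log2s]
        for rep, fold in enumerate(values, start=1):
            if (sample, rep) not in seen_refs:
                rows.append(
                    {"sample": sample, "gene": reference_gene, "role": "reference",
                     "replicate": rep, "ct": reference_ct}
                )
                seen_refs.add((sample, rep))
            ct = reference_ct + calibrator_delta_ct - math.log2(fold)
            rows.append(
                {"sample": sample, "gene": gene, "role": "target",
                 "replicate": rep, "ct": ct}
            )
    return pd.DataFrame(rows, columns=CT_COLUMNS)


def write_relative_expression(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, sep="\t", index=False, float_format="%.6g")
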