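"""Unit conversion, normalisation and cross-cohort merging.

Produces the analysis-ready meta-cohort: cohorts are restricted to their
common gene space, concatenated column-wise and quantile-normalised against
a single reference distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "fpkm_to_tpm",
    "log2_transform",
    "quantile_normalize",
    "MetaCohort",
    "build_meta_cohort",
]


def fpkm_to_tpm(x: ExpressionMatrix) -> ExpressionMatrix:
    """Convert FPKM to TPM by per-sample renormalisation.

    tpm[g, s] = fpkm[g, s] / sum_g fpkm[g, s] * 1e6, so each sample column
    sums to one million.  The conversion is scale-invariant per sample.
    """
    if x.unit != "fpkm":
        raise ValueError(f"expected unit 'fpkm', got {x.unit!r}")
    colsums = x.values.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise FormatError(f"all-zero expression column(s): {zero.index.tolist()}")
    tpm = x.values.div(colsums, axis=1) * 1e6
    return ExpressionMatrix(tpm, "tpm")


def log2_transform(x: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount); the unit is updated to its log2 counterpart."""
    if (x.values.to_numpy() < 0).any():
        raise FormatError("log2_transform requires non-negative input")
    unit = {"tpm": "log2tpm", "fpkm": "log2tpm"}.get(x.unit, "log2intensity")
    return ExpressionMatrix(np.log2(x.values + pseudocount), unit)


def _quantile_normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise columns of ``df`` against the mean order statistics.

    Ties within a column receive the mean of the reference values across their
    rank span (the behaviour of limma's normalizeQuantiles with ties=TRUE).
    """
    arr = df.to_numpy(dtype=float)
    n_genes, n_samples = arr.shape
    # reference distribution: mean of sorted columns
    reference = np.sort(arr, axis=0).mean(axis=1)
    ref_cum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(arr)
    for j in range(n_samples):
        ranks = rankdata(arr[:, j], method="average")  # 1-based, ties averaged
        lo = rankdata(arr[:, j], method="min") - 1
        hi = rankdata(arr[:, j], method="max")
        # mean of reference[lo:hi] for each gene's tie span
        out[:, j] = (ref_cum[hi] - ref_cum[lo]) / (hi - lo)
        del ranks
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def quantile_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the across-sample mean distribution of order statistics."""
    if x.shape[1] == 1:
        logger.warning("quantile_normalize: single sample, returning input unchanged")
        return ExpressionMatrix(x.values.copy(), x.unit)
    return ExpressionMatrix(_quantile_normalize_frame(x.values), x.unit)


@dataclass
class MetaCohort:
    """Merged multi-cohort matrix restricted to the common gene space."""

    matrix: ExpressionMatrix
    cohort_of: pd.Series  # sample_id -> cohort label
    genes_common: list[str]

    def __post_init__(self) -> None:
        if set(self.cohort_of.index) != set(self.matrix.samples):
            raise ValueError("cohort labels do not cover the merged samples exactly")


def build_meta_cohort(
    cohorts: list[ExpressionMatrix],
    labels: list[str],
    normalize: bool = True,
) -> MetaCohort:
    """Intersect gene spaces, concatenate cohorts and quantile-normalise the merge.

    Normalisation is applied after merging so all samples share one reference
    distribution.  Gene-id namespaces must be harmonised upstream.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    if len(cohorts) != len(labels):
        raise ValueError("cohorts and labels differ in length")
    common = set(cohorts[0].genes)
    for c in cohorts[1:]:
        common &= set(c.genes)
    if not common:
        raise FormatError("empty gene intersection across cohorts")
    genes = sorted(common)
    logger.info("build_meta_cohort: %d common genes across %d cohorts", len(genes), len(cohorts))
    frames, cohort_of = [], {}
    for mat, label in zip(cohorts, labels):
        frames.append(mat.values.loc[genes])
        for s in mat.samples:
            cohort_of[s] = label
    merged = pd.concat(frames, axis=1)
    if merged.columns.duplicated().any():
        raise FormatError("sample ids collide across cohorts")
    unit = cohorts[0].unit if len({c.unit for c in cohorts}) == 1 else "log2intensity"
    matrix = ExpressionMatrix(merged, unit)
    if normalize and matrix.shape[1] > 1:
        matrix = quantile_normalize(matrix)
    return MetaCohort(matrix, pd.Series(cohort_of), genes)
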