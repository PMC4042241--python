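"""The regularized two-group statistic.

For SNP i and transcript j,

    Z_ij = (xbar_carrier - xbar_noncarrier) / (a0_i + S_ij)

where S_ij is the pooled-variance standard error of the mean difference,
sqrt(s2_pooled * (1/n1 + 1/n0)), and a0_i is a per-SNP "fudge factor"
set to the 90th percentile of that SNP's S_ij values.  Adding a0 to the
denominator stabilizes transcripts whose within-group variability is
tiny; with a0 = 0 and the pooled-SE reading of S, Z is exactly the
classical pooled two-sample t statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import (
    DegenerateGroupError,
    ExpressionMatrix,
    GenotypeTable,
    GroupAssignment,
    check_paired,
    dominant_groups,
)

__all__ = ["ZStatistics", "pair_scale", "compute_a0", "group_stats", "z_row", "z_matrix"]

A0_PERCENTILE = 90.0


@dataclass
class ZStatistics:
    """Regularized statistics for all SNP x transcript pairs."""

    z: np.ndarray          # I x J
    s: np.ndarray          # I x J pooled SEs
    a0: np.ndarray         # length I
    mean1: np.ndarray      # I x J carrier-group means
    mean0: np.ndarray      # I x J non-carrier means
    snp_ids: list[str]
    transcript_ids: list[str]


def group_stats(values: np.ndarray, groups: GroupAssignment) -> tuple[np.ndarray, ...]:
    """Per-row group means and pooled SEs for a J x n value block.

    Returns ``(mean1, mean0, s, diff)`` where ``s`` is the pooled-variance
    standard error of the mean difference and ``diff`` is ``mean1 - mean0``
    computed on centered data (immune to large common offsets).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    # center each row first: the statistic is shift-invariant and the
    # one-pass sum-of-squares loses precision under large common offsets
    offset = values.mean(axis=1, keepdims=True)
    values = values - offset
    lab = groups.labels.astype(float)
    n1, n0 = groups.n1, groups.n0
    sum1 = values @ lab
    sum0 = values.sum(axis=1) - sum1
    mean1 = sum1 / n1
    mean0 = sum0 / n0
    sq = values**2
    ss1 = sq @ lab - n1 * mean1**2
    ss0 = sq.sum(axis=1) - sq @ lab - n0 * mean0**2
    # clip tiny negatives from cancellation
    pooled = np.clip(ss1 + ss0, 0.0, None) / (n1 + n0 - 2)
    s = np.sqrt(pooled * (1.0 / n1 + 1.0 / n0))
    off = offset[:, 0]
    return mean1 + off, mean0 + off, s, mean1 - mean0


def pair_scale(expr_row: np.ndarray, groups: GroupAssignment) -> float:
    """Pooled-variance standard error of the group-mean difference for one transcript."""
    _, _, s, _ = group_stats(np.asarray(expr_row, dtype=float)[None, :], groups)
    return float(s[0])


def compute_a0(scales: np.ndarray) -> float:
    """90th percentile of a SNP's pair scales (linear-interpolation convention)."""
    scales = np.asarray(scales, dtype=float)
    if scales.size == 0:
        raise ValueError("cannot take a percentile of an empty scale vector")
    if np.any(scales < 0):
        raise ValueError("pair scales must be nonnegative")
    return float(np.percentile(scales, A0_PERCENTILE))


def z_row(
    values: np.ndarray, groups: GroupAssignment, a0: float | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Statistics for one SNP across all transcripts.

    When ``a0`` is None it is computed from this row's scales; passing a
    fixed value supports permutation nulls where a0 from the observed
    grouping is held constant.
    Returns ``(z, s, a0)``.
    """
    _, _, s, diff = group_stats(values, groups)
    if a0 is None:
        a0 = compute_a0(s)
    denom = a0 + s
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return z, s, float(a0)


def z_matrix(expr: ExpressionMatrix, genotypes: GenotypeTable) -> ZStatistics:
    """Z_ij for every SNP i (dominant grouping) and transcript j."""
    check_paired(expr, genotypes)
    I, J = genotypes.n_snps, expr.n_transcripts
    z = np.empty((I, J))
    s = np.empty((I, J))
    a0 = np.empty(I)
    mean1 = np.empty((I, J))
    mean0 = np.empty((I, J))
    for i in range(I):
        try:
            groups = dominant_groups(genotypes, i)
        except DegenerateGroupError:
            raise
        m1, m0, si, diff = group_stats(expr.values, groups)
        a0[i] = compute_a0(si)
        denom = a0[i] + si
        with np.errstate(invalid="ignore", divide="ignore"):
            z[i] = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
        s[i], mean1[i], mean0[i] = si, m1, m0
    return ZStatistics(z, s, a0, mean1, mean0, list(genotypes.snp_ids), list(expr.transcript_ids))
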