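"""Reading, writing and validating the matrices the screen operates on.

Expression matrices are transcripts x samples on a log scale; genotype
tables are SNPs x samples with codes counting copies of the minor allele
(0, 1, 2).  Both travel as plain TSV with a header row of sample IDs and
an ID first column.  Missing values are rejected rather than imputed:
every downstream statistic assumes complete matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GenotypeTable",
    "GroupAssignment",
    "ValidationError",
    "DegenerateGroupError",
    "read_expression",
    "write_expression",
    "read_genotypes",
    "write_genotypes",
    "dominant_groups",
]


class ValidationError(ValueError):
    """An input matrix violates a structural invariant."""


class DegenerateGroupError(ValidationError):
    """A genotype split leaves a group with fewer than two samples."""


def _check_ids(ids: list[str], kind: str) -> None:
    if any(not i for i in ids):
        raise ValidationError(f"empty {kind} ID")
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {kind} ID: {dup!r}")


@dataclass
class ExpressionMatrix:
    """Log-scale expression, one row per transcript, one column per sample."""

    transcript_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        j, n = self.values.shape
        if j != len(self.transcript_ids) or n != len(self.sample_ids):
            raise ValidationError("expression matrix shape does not match IDs")
        if j < 2 or n < 4:
            raise ValidationError(f"need at least 2 transcripts and 4 samples, got {j}x{n}")
        _check_ids(self.transcript_ids, "transcript")
        _check_ids(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            jj, ss = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression at transcript {self.transcript_ids[jj]!r}, "
                f"sample {self.sample_ids[ss]!r}"
            )

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class GenotypeTable:
    """Minor-allele dosage codes per SNP and sample, with per-SNP MAF.

    ``maf`` may be supplied (e.g. from a population reference); when it is
    omitted it is derived as the allele frequency implied by the codes.
    A supplied MAF is checked for consistency only when ``derived=True``.
    """

    snp_ids: list[str]
    sample_ids: list[str]
    codes: np.ndarray
    maf: np.ndarray | None = None
    derived: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        i, n = self.codes.shape
        if i != len(self.snp_ids) or n != len(self.sample_ids):
            raise ValidationError("genotype matrix shape does not match IDs")
        _check_ids(self.snp_ids, "SNP")
        _check_ids(self.sample_ids, "sample")
        if not np.issubdtype(self.codes.dtype, np.integer):
            flo = np.asarray(self.codes, dtype=float)
            if not np.all(np.isfinite(flo)) or np.any(flo != np.round(flo)):
                raise ValidationError("genotype codes must be integers in {0,1,2}")
            self.codes = flo.astype(np.int64)
        if self.codes.min() < 0 or self.codes.max() > 2:
            raise ValidationError("genotype codes must be in {0,1,2}")
        derived = self.codes.sum(axis=1) / (2.0 * n)
        if self.maf is None:
            self.maf = derived
            self.derived = True
        else:
            self.maf = np.asarray(self.maf, dtype=float)
            if self.maf.shape != (i,):
                raise ValidationError("maf length does not match number of SNPs")
            if self.derived and np.any(np.abs(self.maf - derived) >= 1e-9):
                raise ValidationError("stored MAF inconsistent with genotype codes")
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            raise ValidationError("MAF must lie in (0, 0.5]")

    @property
    def n_snps(self) -> int:
        return self.codes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[1]


@dataclass
class GroupAssignment:
    """A binary split of the samples (1 = minor-allele carrier)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1 or not np.all((self.labels == 0) | (self.labels == 1)):
            raise ValidationError("labels must be a flat 0/1 vector")
        if self.n1 < 2 or self.n0 < 2:
            raise DegenerateGroupError(
                f"each group needs >= 2 samples (got n1={self.n1}, n0={self.n0})"
            )

    @property
    def n1(self) -> int:
        return int(self.labels.sum())

    @property
    def n0(self) -> int:
        return int(len(self.labels) - self.labels.sum())


def _read_table(path: str | Path, kind: str) -> tuple[list[str], list[str], np.ndarray]:
    """Parse a TSV into (row IDs, column IDs, float matrix).

    Values are parsed with numpy's exact string conversion so shortest-
    repr output round-trips bit-for-bit; a failing cell is located by a
    per-cell rescan for the error message.
    """
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str, comment="#")
    raw = df.to_numpy()
    try:
        values = raw.astype(float)
    except ValueError:
        for (j, s), cell in np.ndenumerate(raw):
            try:
                float(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-numeric {kind} cell at row {df.index[j]!r}, "
                    f"column {df.columns[s]!r}"
                ) from None
        raise
    if np.isnan(values).any() and pd.isna(raw).any():
        j, s = np.argwhere(pd.isna(raw))[0]
        raise ValidationError(
            f"non-numeric {kind} cell at row {df.index[j]!r}, column {df.columns[s]!r}"
        )
    return [str(i) for i in df.index], [str(c) for c in df.columns], values


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a transcripts x samples TSV (header = sample IDs)."""
    rows, cols, values = _read_table(path, "expression")
    return ExpressionMatrix(rows, cols, values)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV; shortest-repr floats make the file
    round-trip bit-exactly through :func:`read_expression`."""
    df = pd.DataFrame(expr.values, index=expr.transcript_ids, columns=expr.sample_ids)
    df.to_csv(path, sep="\t", index_label="transcript_id")


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read a SNPs x samples TSV of 0/1/2 minor-allele counts."""
    rows, cols, values = _read_table(path, "genotype")
    return GenotypeTable(rows, cols, values)


def write_genotypes(geno: GenotypeTable, path: str | Path) -> None:
    df = pd.DataFrame(geno.codes, index=geno.snp_ids, columns=geno.sample_ids)
    df.to_csv(path, sep="\t", index_label="snp_id")


def check_paired(expr: ExpressionMatrix, geno: GenotypeTable) -> None:
    """Require identical sample IDs in identical order."""
    if expr.sample_ids != geno.sample_ids:
        raise ValidationError("expression and genotype sample IDs do not match")


def dominant_groups(genotypes: GenotypeTable, snp_index: int) -> GroupAssignment:
    """Dominant-model split: carriers of the minor allele (code >= 1) vs non-carriers.

    Raises :class:`DegenerateGroupError` when either group has fewer than
    two samples, since the two-group statistic is then undefined.
    """
    row = genotypes.codes[snp_index]
    labels = (row >= 1).astype(np.int8)
    try:
        return GroupAssignment(labels)
    except DegenerateGroupError as exc:
        raise DegenerateGroupError(
            f"SNP {genotypes.snp_ids[snp_index]!r}: {exc}"
        ) from None
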