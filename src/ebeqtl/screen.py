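"""Per-SNP screening pipeline: statistic -> permutation null -> mixture -> fdr.

Glue shared by the command-line ``fit`` entry point and the simulation
study.  All statistics for a SNP are standardized by the ML null scale
before the mixture (whose null component is pinned at location 0,
scale 1) is fitted; lfdr and thresholds therefore live on that
standardized scale, which is also the scale reported in results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import GroupAssignment
from .fdr_inference import DiscoverySet, NpebFit, lfdr_values, npeb_fdr, peb_discoveries, tail_fdr
from .null_model import NullFit, fit_null, null_statistics
from .peb_mixture import TMixtureParams, apply_pi0_cap, ecme_fit
from .zstats import z_row

__all__ = ["SnpFit", "fit_snp"]


@dataclass
class SnpFit:
    """Everything the screen learned about one SNP."""

    a0: float
    z: np.ndarray             # standardized statistics, length J
    null: NullFit
    params: TMixtureParams    # pi0-capped ECME fit
    trace: np.ndarray
    lfdr: np.ndarray

    def discoveries(self, alpha: float, side: str = "two_sided") -> DiscoverySet:
        return peb_discoveries(self.z, self.params, alpha, side=side)

    def pair_fdr(self) -> np.ndarray:
        """Two-sided tail FDR evaluated at each pair's own |z|."""
        return np.array([tail_fdr(abs(zz), self.params, "two_sided") for zz in self.z])

    def npeb(self, alpha: float, **kwargs) -> NpebFit:
        return npeb_fdr(self.z, self.null.standardize(self.null.z_null), alpha, **kwargs)


def fit_snp(
    values: np.ndarray,
    groups: GroupAssignment,
    n_perms: int = 40,
    n_swap: int | None = None,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> SnpFit:
    """Fit the full empirical-Bayes model for one SNP.

    ``values`` is the J x n expression block; ``n_swap`` defaults to
    round(n1 * n0 / n), the swap count that leaves each permuted group
    with the original carrier proportion so genuine group effects cancel
    (35 for two groups of 70; half the smaller group only when the
    groups are equal).
    """
    if n_swap is None:
        n = groups.n1 + groups.n0
        n_swap = round(groups.n1 * groups.n0 / n)
    z_raw, _, a0 = z_row(values, groups)
    z_null = null_statistics(values, groups, a0, n_swap, n_perms, seed)
    null = fit_null(z_null, n_perms=n_perms, n_swap=n_swap)
    z = null.standardize(z_raw)
    params, trace = ecme_fit(z, nu0=null.nu0, tol=tol, max_iter=max_iter)
    params = apply_pi0_cap(z, params)
    return SnpFit(
        a0=a0, z=z, null=null, params=params, trace=trace, lfdr=lfdr_values(z, params)
    )
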