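"""Permutation null distribution of the regularized statistic.

The null for each SNP is estimated by *balanced* permutations: a fixed
number of samples is swapped between the carrier and non-carrier groups
(the same number each way), which preserves group sizes and, crucially,
breaks genuine genotype-expression association even for differentially
expressed transcripts, because each permuted group becomes an even blend
of the original two.

Because the fudge factor a0 roughly doubles the denominator of the
statistic, the pooled permutation statistics concentrate on a scale well
below 1.  The null is therefore modelled as a *scaled* t: location 0,
scale sigma0, degrees of freedom nu0, both estimated by maximum
likelihood.  Dividing all statistics for a SNP by sigma0 puts them on
the standardized scale on which the mixture model pins its null
component at mu0 = 0, tau0^2 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .data_io import GroupAssignment
from .zstats import z_row

__all__ = [
    "NullFit",
    "DfFit",
    "balanced_permutations",
    "null_statistics",
    "fit_null_df",
    "fit_null",
    "qq_points",
]

DF_RANGE = (1.0, 200.0)


def balanced_permutations(
    groups: GroupAssignment,
    n_swap: int,
    n_perms: int,
    seed: int | np.random.Generator,
) -> list[GroupAssignment]:
    """Draw label permutations that swap exactly ``n_swap`` samples each way.

    Each permutation moves ``n_swap`` randomly chosen carriers to the
    non-carrier group and vice versa, so group sizes are preserved
    exactly.  Draws are independent (sampling with replacement from the
    set of balanced swaps); with ``n_swap = 0`` every draw is the
    original assignment.
    """
    if n_swap > min(groups.n1, groups.n0):
        raise ValueError(
            f"n_swap={n_swap} exceeds the smaller group size "
            f"(n1={groups.n1}, n0={groups.n0})"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx1 = np.flatnonzero(groups.labels == 1)
    idx0 = np.flatnonzero(groups.labels == 0)
    out = []
    for _ in range(n_perms):
        labels = groups.labels.copy()
        if n_swap > 0:
            swap_out = rng.choice(idx1, size=n_swap, replace=False)
            swap_in = rng.choice(idx0, size=n_swap, replace=False)
            labels[swap_out] = 0
            labels[swap_in] = 1
        out.append(GroupAssignment(labels))
    return out


def null_statistics(
    values: np.ndarray,
    groups: GroupAssignment,
    a0: float,
    n_swap: int,
    n_perms: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Pooled permutation statistics for one SNP.

    ``a0`` must come from the unpermuted data and is held fixed across
    permutations: the null has to describe the very statistic that is
    thresholded.  Returns a flat vector of length ``n_perms * J``.
    """
    perms = balanced_permutations(groups, n_swap, n_perms, seed)
    pooled = [z_row(values, p, a0=a0)[0] for p in perms]
    return np.concatenate(pooled)


@dataclass
class DfFit:
    """Degrees of freedom fitted by ML, with an endpoint warning flag."""

    nu: float
    at_bound: bool

    def __float__(self) -> float:
        return self.nu


def _t_loglik(z: np.ndarray, nu: float, sigma2: float = 1.0) -> float:
    n = z.size
    return float(
        n
        * (
            special.gammaln((nu + 1) / 2)
            - special.gammaln(nu / 2)
            - 0.5 * np.log(nu * np.pi * sigma2)
        )
        - (nu + 1) / 2 * np.log1p(z**2 / (nu * sigma2)).sum()
    )


def fit_null_df(z_null: np.ndarray, df_range: tuple[float, float] = DF_RANGE) -> DfFit:
    """ML degrees of freedom for the location-0, scale-1 t density.

    The profile likelihood is optimized over log(nu) on ``df_range``;
    ``at_bound`` flags an estimate within 1% of either endpoint
    (Gaussian-like data pushes nu to the upper bound, super-heavy tails
    to the lower one).
    """
    z_null = np.asarray(z_null, dtype=float)
    if z_null.size < 100:
        raise ValueError("need at least 100 null statistics to fit nu")
    lo, hi = df_range
    if not (0.5 < lo < hi <= 500):
        raise ValueError("df_range must lie within (0.5, 500]")
    res = optimize.minimize_scalar(
        lambda lognu: -_t_loglik(z_null, np.exp(lognu)),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    nu = float(np.exp(res.x))
    at_bound = nu <= lo * 1.01 or nu >= hi / 1.01
    return DfFit(nu=nu, at_bound=at_bound)


def _profile_sigma2(z2: np.ndarray, nu: float, tol: float = 1e-10) -> float:
    """ML scale^2 of a location-0 t(nu) by the standard EM fixed point."""
    s2 = max(float(z2.mean()), 1e-12)
    for _ in range(200):
        w = (nu + 1.0) / (nu + z2 / s2)
        new = float((w * z2).mean())
        if abs(new - s2) <= tol * max(s2, 1e-12):
            s2 = new
            break
        s2 = new
    return max(s2, 1e-12)


@dataclass
class NullFit:
    """Per-SNP null: scaled t with df ``nu0`` and scale ``sigma0``."""

    nu0: float
    sigma0: float
    z_null: np.ndarray
    n_perms: int
    n_swap: int
    at_bound: bool

    def standardize(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) / self.sigma0


def fit_null(
    z_null: np.ndarray,
    n_perms: int,
    n_swap: int,
    df_range: tuple[float, float] = DF_RANGE,
) -> NullFit:
    """Joint ML fit of (nu0, sigma0) for a location-0 scaled t null."""
    z_null = np.asarray(z_null, dtype=float)
    if z_null.size < 100:
        raise ValueError("need at least 100 null statistics to fit the null")
    z2 = z_null**2
    lo, hi = df_range

    def negll(lognu: float) -> float:
        nu = float(np.exp(lognu))
        s2 = _profile_sigma2(z2, nu)
        return -_t_loglik(z_null, nu, s2)

    res = optimize.minimize_scalar(
        negll, bounds=(np.log(lo), np.log(hi)), method="bounded", options={"xatol": 1e-6}
    )
    nu0 = float(np.exp(res.x))
    sigma0 = float(np.sqrt(_profile_sigma2(z2, nu0)))
    at_bound = nu0 <= lo * 1.01 or nu0 >= hi / 1.01
    return NullFit(
        nu0=nu0, sigma0=sigma0, z_null=z_null, n_perms=n_perms, n_swap=n_swap, at_bound=at_bound
    )


def qq_points(z_null: np.ndarray, nu: float) -> np.ndarray:
    """(theoretical, empirical) quantile pairs against the scale-1 t(nu).

    Theoretical quantiles are taken at the plotting positions
    (i - 0.5)/n; the caller decides whether and how to plot.
    """
    if nu <= 0:
        raise ValueError("nu must be positive")
    emp = np.sort(np.asarray(z_null, dtype=float))
    n = emp.size
    theo = stats.t.ppf((np.arange(1, n + 1) - 0.5) / n, df=nu)
    return np.column_stack([theo, emp])
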