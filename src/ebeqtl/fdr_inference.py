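"""From fitted mixtures to local and tail-area false discovery rates.

The local fdr of a pair is the posterior probability that it is null,

    lfdr(z) = pi0 f0(z) / f(z),

and the tail-area FDR of a rejection region R is the mixture-weighted
null fraction of R,

    FDR(R) = pi0 P0(R) / P(R),

which is exactly the conditional average of lfdr over R.  Discovery sets
are the largest regions whose estimated FDR stays at or below the
target.  Rejection regions default to two-sided {|z| >= c}: the mixture
model carries explicit positive- and negative-association components.
One-sided regions are retained mainly for checking the tail identity.

The nonparametric comparator (NPEB) replaces the parametric mixture by
a density-ratio estimate built from the pooled permutation statistics:
observed and permutation values are binned together, a smooth logistic
fit of the observed-vs-permutation log odds (with the sample-size
imbalance correction) gives f/f0, the min-ratio rule bounds pi0, and
tail FDRs use empirical tail counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import interpolate, stats

from .peb_mixture import TMixtureParams, mixture_pdf, t_pdf

__all__ = [
    "DiscoverySet",
    "NpebFit",
    "lfdr_values",
    "tail_fdr",
    "threshold_for_fdr",
    "peb_discoveries",
    "npeb_fdr",
]

SIDES = ("upper", "lower", "two_sided")


@dataclass
class DiscoverySet:
    """A thresholded rejection region and what it declares."""

    threshold: float
    side: str
    alpha: float
    mask: np.ndarray          # boolean over the scored statistics
    attained_fdr: float

    @property
    def n_discoveries(self) -> int:
        return int(self.mask.sum())


def lfdr_values(z: np.ndarray, params: TMixtureParams) -> np.ndarray:
    """lfdr(z) = pi0 f0(z) / f(z), clipped to [0, 1].

    With both alternative components pruned the mixture is purely null
    and lfdr is identically 1.
    """
    z = np.asarray(z, dtype=float)
    if params.pi[1] == 0 and params.pi[2] == 0:
        return np.ones_like(z)
    f = mixture_pdf(z, params)
    f0 = t_pdf(z, 0.0, 1.0, float(params.nu[0]))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = params.pi[0] * f0 / f
    return np.clip(np.where(np.isfinite(out), out, 1.0), 0.0, 1.0)


def _component_tail(c: float, mu: float, tau2: float, nu: float, side: str) -> float:
    scale = np.sqrt(tau2)
    if side == "upper":
        return float(stats.t.sf(c, df=nu, loc=mu, scale=scale))
    if side == "lower":
        return float(stats.t.cdf(c, df=nu, loc=mu, scale=scale))
    return float(
        stats.t.sf(abs(c), df=nu, loc=mu, scale=scale)
        + stats.t.cdf(-abs(c), df=nu, loc=mu, scale=scale)
    )


def tail_fdr(c: float, params: TMixtureParams, side: str = "two_sided") -> float:
    """FDR of the rejection region at cutoff ``c``.

    upper: {z >= c}; lower: {z <= c}; two_sided: {|z| >= c}.  A region
    of zero total probability returns 0 (no discoveries, no errors).
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    masses = [
        params.pi[k] * _component_tail(c, params.mu[k], params.tau2[k], params.nu[k], side)
        if params.pi[k] > 0
        else 0.0
        for k in range(3)
    ]
    total = sum(masses)
    if total <= 0:
        return 0.0
    return float(np.clip(masses[0] / total, 0.0, 1.0))


def threshold_for_fdr(
    params: TMixtureParams,
    alpha: float,
    side: str = "two_sided",
    c_max: float = 1e6,
) -> float:
    """Smallest two-sided cutoff (largest region) with tail FDR <= alpha.

    The tail FDR is typically decreasing in the cutoff, but when an
    alternative component has lighter far tails than the null it can
    rise again beyond the alternative's reach, so the first crossing is
    located on a dense grid and then refined by bisection to 1e-6.
    Returns +inf when no cutoff achieves the target (e.g. a pure-null
    fit with small alpha).  For one-sided regions the cutoff applies to
    z (upper) or -z (lower).
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if side == "lower":
        flipped = TMixtureParams(
            pi=params.pi[[0, 2, 1]],
            mu=np.array([0.0, -params.mu[2], -params.mu[1]]),
            tau2=params.tau2[[0, 2, 1]],
            nu=params.nu[[0, 2, 1]],
        )
        return threshold_for_fdr(flipped, alpha, side="upper", c_max=c_max)
    start = 0.0 if side == "two_sided" else -c_max
    if tail_fdr(start, params, side) <= alpha:
        return start
    reach = max(10.0, float(np.max(np.abs(params.mu) + 20 * np.sqrt(params.tau2))))
    grid = np.concatenate(
        [np.linspace(max(start, -reach), reach, 4001), np.geomspace(reach, c_max, 200)]
    )
    grid = grid[grid >= start]
    below = None
    prev = start
    for c in grid:
        if tail_fdr(float(c), params, side) <= alpha:
            below = float(c)
            break
        prev = float(c)
    if below is None:
        return np.inf
    lo, hi = prev, below
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if tail_fdr(mid, params, side) > alpha:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    return float(hi)


def peb_discoveries(
    z: np.ndarray, params: TMixtureParams, alpha: float, side: str = "two_sided"
) -> DiscoverySet:
    """Declare pairs whose statistic falls in the FDR-controlled region."""
    z = np.asarray(z, dtype=float)
    c = threshold_for_fdr(params, alpha, side=side)
    if side == "upper":
        mask = z >= c
    elif side == "lower":
        mask = z <= -c if np.isfinite(c) else np.zeros_like(z, bool)
    else:
        mask = np.abs(z) >= c
    attained = tail_fdr(c, params, side=side) if np.isfinite(c) else 0.0
    return DiscoverySet(threshold=float(c), side=side, alpha=alpha, mask=mask, attained_fdr=attained)


# ---------------------------------------------------------------------------
# Nonparametric empirical Bayes comparator


@dataclass
class NpebFit:
    """Nonparametric density-ratio fit of the two-groups model."""

    pi0: float
    lfdr: np.ndarray          # per observed statistic
    discoveries: DiscoverySet
    bin_centers: np.ndarray
    log_ratio: np.ndarray     # log f/f0 at bin centers


def _spline_basis(pooled_t: np.ndarray, degree: int):
    """Cubic B-spline basis on the asinh scale with quantile knots.

    Interior knots sit at quantiles of the pooled sample (so resolution
    follows the data) plus a few evenly spaced knots across any long
    stretch between the bulk and far-outlying signal; a local basis
    keeps the fit near the null bulk decoupled from a distant signal
    cluster, which a global polynomial cannot do.
    """
    lo, hi = float(pooled_t.min()) - 1e-9, float(pooled_t.max()) + 1e-9
    qs = np.quantile(pooled_t, [0.02, 0.10, 0.30, 0.50, 0.70, 0.90, 0.98])
    bulk_hi = float(np.quantile(pooled_t, 0.999))
    extra = (
        np.linspace(bulk_hi, hi, 4)[1:-1] if hi - bulk_hi > 0.5 else np.array([])
    )
    interior = np.unique(np.round(np.concatenate([qs, extra]), 6))
    interior = interior[(interior > lo) & (interior < hi)]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])

    def basis(tq: np.ndarray) -> np.ndarray:
        tq = np.clip(np.asarray(tq, float), lo, hi)
        return interpolate.BSpline.design_matrix(tq, knots, degree).toarray()

    return basis


def _smooth_log_ratio(
    z_obs: np.ndarray, z_null: np.ndarray, n_bins: int, degree: int, min_count: int
):
    """Binned logistic estimate of log f/f0 with sampling-SE access.

    Binning and the B-spline basis live on the asinh(z/2) scale, which
    compresses far-outlying statistics so the smooth fit is not starved
    of resolution where the null mass sits.
    """
    t_obs, t_null = np.arcsinh(z_obs / 2.0), np.arcsinh(z_null / 2.0)
    pooled = np.concatenate([t_obs, t_null])
    edges = np.linspace(pooled.min(), pooled.max() + 1e-12, n_bins + 1)
    obs_counts, _ = np.histogram(t_obs, bins=edges)
    null_counts, _ = np.histogram(t_null, bins=edges)
    centers_t = 0.5 * (edges[:-1] + edges[1:])
    # bins too sparse to carry ratio information (the near-empty stretch
    # between the null bulk and far-outlying signal) are excluded from
    # the fit: a smooth local basis chasing a handful of one-sample
    # counts there rings violently through the null's shoulder
    keep = obs_counts + null_counts >= min_count
    if keep.sum() < 8:
        keep = obs_counts + null_counts > 0
    basis = _spline_basis(pooled, degree)

    fit = sm.GLM(
        np.column_stack([obs_counts, null_counts])[keep],
        basis(centers_t[keep]),
        family=sm.families.Binomial(),
    ).fit()
    imbalance = np.log(len(z_null) / len(z_obs))

    def log_ratio(zq: np.ndarray, se: bool = False):
        bq = basis(np.arcsinh(np.asarray(zq, float) / 2.0))
        eta = bq @ fit.params + imbalance  # log f/f0
        if not se:
            return eta
        eta_se = np.sqrt(np.einsum("ij,jk,ik->i", bq, fit.cov_params(), bq))
        return eta, eta_se

    centers = 2.0 * np.sinh(centers_t[keep])
    return centers, log_ratio(centers), log_ratio


def npeb_fdr(
    z_obs: np.ndarray,
    z_null: np.ndarray,
    alpha: float,
    n_bins: int = 60,
    degree: int = 3,
    min_count: int = 5,
    side: str = "two_sided",
) -> NpebFit:
    """Nonparametric EB screen against a pooled permutation null.

    The marginal-to-null density ratio is estimated by a smooth logistic
    fit on binned counts of the pooled observed + permutation values
    (corrected for the size imbalance of the two samples); pi0 is the
    min-ratio bound; lfdr = min(1, pi0 f0/f); and the FDR-controlled
    region uses the empirical tail-count estimate

        FDR(c) = pi0 * (null tail fraction) / (observed tail fraction),

    taking the smallest cutoff whose estimate stays at or below alpha.
    Bins too sparse to inform the ratio (fewer than ``min_count`` pooled
    values) are excluded from the smooth fit.
    """
    z_obs = np.asarray(z_obs, dtype=float)
    z_null = np.asarray(z_null, dtype=float)
    if z_obs.size == 0 or z_null.size == 0:
        raise ValueError("observed and null statistics must be non-empty")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    centers, log_ratio_centers, log_ratio = _smooth_log_ratio(
        z_obs, z_null, n_bins, degree, min_count
    )
    # pi0 bound from the central mass, where the ratio estimate is stable;
    # minimizing a noisy curve is biased low, so the pointwise +1 SE
    # envelope is minimized instead
    central = np.abs(centers - np.median(z_null)) <= np.quantile(
        np.abs(z_null - np.median(z_null)), 0.995
    )
    if not central.any():
        central = np.ones_like(centers, dtype=bool)
    eta_c, se_c = log_ratio(centers[central], se=True)
    pi0 = float(np.clip(np.exp((eta_c + se_c).min()), 0.0, 1.0))
    lfdr = np.clip(pi0 * np.exp(-log_ratio(z_obs)), 0.0, 1.0)

    if side == "two_sided":
        score_obs, score_null = np.abs(z_obs), np.abs(z_null)
    elif side == "upper":
        score_obs, score_null = z_obs, z_null
    else:
        score_obs, score_null = -z_obs, -z_null
    order = np.sort(score_obs)
    null_sorted = np.sort(score_null)
    n_obs, n_null = score_obs.size, score_null.size
    candidates = np.unique(order)
    obs_tail = (n_obs - np.searchsorted(order, candidates, side="left")) / n_obs
    null_tail = (n_null - np.searchsorted(null_sorted, candidates, side="left")) / n_null
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_hat = np.where(obs_tail > 0, pi0 * null_tail / obs_tail, 0.0)
    ok = np.flatnonzero(fdr_hat <= alpha)
    if ok.size:
        c = float(candidates[ok[0]])
        mask = score_obs >= c
        attained = float(min(fdr_hat[ok[0]], 1.0))
    else:
        c, mask, attained = np.inf, np.zeros_like(score_obs, dtype=bool), 0.0
    disc = DiscoverySet(threshold=c, side=side, alpha=alpha, mask=mask, attained_fdr=attained)
    return NpebFit(
        pi0=pi0, lfdr=lfdr, discoveries=disc, bin_centers=centers, log_ratio=log_ratio_centers
    )
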