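"""Three-component t-mixture model fitted by ECME.

Per SNP, the standardized statistics Z are modelled as

    f(z) = pi0 t(z; 0, 1, nu0) + pi1 t(z; mu1, tau1^2, nu1) + pi2 t(z; mu2, tau2^2, nu2)

where t(.; mu, tau^2, nu) is the location-scale t density.  Component 0
(no association) is pinned to the permutation null: mu0 = 0, tau0^2 = 1,
nu0 fixed at the value estimated from balanced permutations.  Components
1 and 2 carry positive and negative associations (mu1 > 0, mu2 < 0).

Fitting alternates an E-step (responsibilities xi and the gamma-scale
weights u of the normal-gamma representation of the t) with two
conditional maximizations: CM-step 1 updates the mixing proportions,
locations and scales in closed form with the degrees of freedom held
fixed; CM-step 2, after refreshing the E-step at the new parameters,
updates each free degree-of-freedom parameter by solving its univariate
estimating equation.  This is the ECME scheme of Liu and Rubin: every
step increases the observed-data likelihood, and the df update converges
much faster than plain EM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special
from scipy.special import logsumexp

__all__ = [
    "TMixtureParams",
    "EStepState",
    "t_pdf",
    "t_logpdf",
    "e_step",
    "cm_step1",
    "cm_step2",
    "ecme_fit",
    "pi0_upper_bound",
    "apply_pi0_cap",
]

NU_RANGE = (1.0, 200.0)
TAU2_FLOOR = 1e-6
SIGN_EPS = 1e-3
PRUNE_THRESHOLD = 1e-3  # fraction of n below which a component is dropped


@dataclass
class TMixtureParams:
    """Mixture parameters; index 0 is the pinned null component.

    A pruned component is encoded by ``pi[k] == 0`` and is never
    resurrected by later updates.
    """

    pi: np.ndarray
    mu: np.ndarray
    tau2: np.ndarray
    nu: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.tau2 = np.asarray(self.tau2, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        if not (self.pi.shape == self.mu.shape == self.tau2.shape == self.nu.shape == (3,)):
            raise ValueError("all parameter vectors must have length 3")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("mixing proportions must be nonnegative and sum to 1")
        if np.any(self.tau2 <= 0) or np.any(self.nu <= 0):
            raise ValueError("scales and degrees of freedom must be positive")
        if self.mu[0] != 0.0 or self.tau2[0] != 1.0:
            raise ValueError("null component must have mu=0, tau2=1")

    @property
    def active(self) -> np.ndarray:
        return self.pi > 0


@dataclass
class EStepState:
    """Responsibilities, gamma-scale weights and the log-likelihood."""

    xi: np.ndarray      # n x 3, rows sum to 1
    u: np.ndarray       # n x 3, positive
    loglik: float


def t_logpdf(z: np.ndarray, mu: float, tau2: float, nu: float) -> np.ndarray:
    """Log density of the location-scale t: Z ~ t(mu, tau2, nu).

    Equivalently Z | U=u ~ N(mu, tau2/u) with U ~ Gamma(nu/2, nu/2).
    """
    if tau2 <= 0 or nu <= 0:
        raise ValueError("tau2 and nu must be positive")
    z = np.asarray(z, dtype=float)
    return (
        special.gammaln((nu + 1) / 2)
        - special.gammaln(nu / 2)
        - 0.5 * np.log(nu * np.pi * tau2)
        - (nu + 1) / 2 * np.log1p((z - mu) ** 2 / (nu * tau2))
    )


def t_pdf(z: np.ndarray, mu: float, tau2: float, nu: float) -> np.ndarray:
    return np.exp(t_logpdf(z, mu, tau2, nu))


def _component_logdens(z: np.ndarray, params: TMixtureParams) -> np.ndarray:
    """n x 3 matrix of log pi_k + log f_k(z), -inf for pruned components."""
    n = z.size
    out = np.full((n, 3), -np.inf)
    for k in range(3):
        if params.pi[k] > 0:
            out[:, k] = np.log(params.pi[k]) + t_logpdf(
                z, params.mu[k], params.tau2[k], params.nu[k]
            )
    return out


def mixture_logpdf(z: np.ndarray, params: TMixtureParams) -> np.ndarray:
    return logsumexp(_component_logdens(np.asarray(z, dtype=float), params), axis=1)


def mixture_pdf(z: np.ndarray, params: TMixtureParams) -> np.ndarray:
    return np.exp(mixture_logpdf(z, params))


def e_step(z: np.ndarray, params: TMixtureParams) -> EStepState:
    """Responsibilities xi, weights u and log-likelihood at ``params``.

    Computed in log space so that points deep in one component's tail do
    not underflow the whole row.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z contains non-finite values")
    logd = _component_logdens(z, params)
    logmix = logsumexp(logd, axis=1)
    xi = np.exp(logd - logmix[:, None])
    u = np.empty((z.size, 3))
    for k in range(3):
        u[:, k] = (params.nu[k] + 1.0) / (
            params.nu[k] + (z - params.mu[k]) ** 2 / params.tau2[k]
        )
    return EStepState(xi=xi, u=u, loglik=float(logmix.sum()))


def cm_step1(
    z: np.ndarray,
    state: EStepState,
    params: TMixtureParams,
    prune_threshold: float = PRUNE_THRESHOLD,
) -> TMixtureParams:
    """Closed-form updates of (pi, mu, tau2) with degrees of freedom fixed.

    The null component's location and scale stay pinned.  Sign
    identification is enforced by projecting mu1 (mu2) onto the positive
    (negative) half line; a component whose total responsibility drops
    below ``prune_threshold * n`` is pruned and its mass reassigned by
    renormalization.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    pi = state.xi.sum(axis=0) / n
    mu = params.mu.copy()
    tau2 = params.tau2.copy()
    for k in (1, 2):
        if params.pi[k] <= 0:
            pi[k] = 0.0
            continue
        wk = state.xi[:, k]
        if wk.sum() < prune_threshold * n:
            pi[k] = 0.0
            continue
        xu = wk * state.u[:, k]
        mu_k = float((xu * z).sum() / xu.sum())
        if k == 1:
            mu_k = max(mu_k, SIGN_EPS)
        else:
            mu_k = min(mu_k, -SIGN_EPS)
        tau2_k = float((xu * (z - mu_k) ** 2).sum() / wk.sum())
        mu[k] = mu_k
        tau2[k] = max(tau2_k, TAU2_FLOOR)
    total = pi.sum()
    if total <= 0:
        raise RuntimeError("all components lost their mass")
    pi = pi / total
    return TMixtureParams(pi=pi, mu=mu, tau2=tau2, nu=params.nu.copy())


def _df_equation(nu: float, c: float) -> float:
    """LHS of the ECME df estimating equation at weight statistic ``c``.

    c = (1/n_k) sum_s xi_ks (log u_ks - u_ks); c <= -1 always, with
    equality exactly in the Gaussian limit (all u = 1).
    """
    return float(
        -special.digamma(nu / 2)
        + np.log(nu / 2)
        + 1.0
        + c
        + special.digamma((nu + 1) / 2)
        - np.log((nu + 1) / 2)
    )


def cm_step2(
    z: np.ndarray,
    params: TMixtureParams,
    nu_range: tuple[float, float] = NU_RANGE,
) -> tuple[TMixtureParams, EStepState]:
    """Degree-of-freedom updates for the alternative components.

    The E-step is refreshed at the CM-step-1 parameters first (the ECME
    speed-up), then each free nu solves its estimating equation by
    bracketed root-finding; when the equation has no root on the range
    the nearer endpoint is taken (the upper endpoint is the Gaussian
    limit).  nu0 is never touched.  Returns the updated parameters and
    the refreshed E-step state.
    """
    z = np.asarray(z, dtype=float)
    state = e_step(z, params)
    lo, hi = nu_range
    nu = params.nu.copy()
    for k in (1, 2):
        if params.pi[k] <= 0:
            continue
        wk = state.xi[:, k]
        nk = wk.sum()
        if nk <= 0:
            continue
        uk = state.u[:, k]
        c = float((wk * (np.log(uk) - uk)).sum() / nk)
        g_lo, g_hi = _df_equation(lo, c), _df_equation(hi, c)
        if g_lo <= 0:
            nu[k] = lo
        elif g_hi >= 0:
            nu[k] = hi
        else:
            nu[k] = float(optimize.brentq(_df_equation, lo, hi, args=(c,), xtol=1e-6))
    return replace(params, nu=nu), state


def _auto_init(z: np.ndarray, nu0: float) -> TMixtureParams:
    """Deterministic initialization by slicing z at +/-2.

    |z| <= 2 seeds the null, z > 2 the positive component, z < -2 the
    negative one; slice moments seed (mu, tau2), slice proportions seed
    pi, and both free dfs start at 10.  Respects sign identification by
    construction.
    """
    pi = np.zeros(3)
    mu = np.zeros(3)
    tau2 = np.ones(3)
    nu = np.array([nu0, 10.0, 10.0])
    n = z.size
    slices = {0: np.abs(z) <= 2, 1: z > 2, 2: z < -2}
    for k, mask in slices.items():
        cnt = int(mask.sum())
        pi[k] = cnt / n
        if k == 0:
            continue
        if cnt < 2:
            pi[k] = 0.0
            continue
        m = float(z[mask].mean())
        mu[k] = max(m, SIGN_EPS) if k == 1 else min(m, -SIGN_EPS)
        tau2[k] = max(float(z[mask].var()), TAU2_FLOOR)
    if pi.sum() <= 0:
        raise ValueError("cannot initialize: no data")
    pi = pi / pi.sum()
    if pi[0] == 0:  # pathological but possible: no central mass
        pi = np.array([0.5, 0.0, 0.0]) + 0.5 * pi
        pi = pi / pi.sum()
    return TMixtureParams(pi=pi, mu=mu, tau2=tau2, nu=nu)


def ecme_fit(
    z: np.ndarray,
    nu0: float,
    init: TMixtureParams | str = "auto",
    tol: float = 1e-6,
    max_iter: int = 1000,
    nu_range: tuple[float, float] = NU_RANGE,
    prune_threshold: float = PRUNE_THRESHOLD,
) -> tuple[TMixtureParams, np.ndarray]:
    """Fit the three-component t-mixture by ECME.

    Parameters
    ----------
    z : standardized statistics for one SNP (length >= 30).
    nu0 : null degrees of freedom from the permutation fit; pinned.
    init : starting parameters, or "auto" for the deterministic
        quantile-slice initialization.
    tol : relative log-likelihood change declaring convergence.
    max_iter : iteration cap.

    Returns
    -------
    (params, trace) where ``trace`` is the observed-data log-likelihood
    at each iteration; it is non-decreasing up to floating-point slack.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 30:
        raise ValueError("need at least 30 observations to fit the mixture")
    if nu0 <= 0:
        raise ValueError("nu0 must be positive")
    params = _auto_init(z, nu0) if isinstance(init, str) else init
    if float(params.nu[0]) != float(nu0):
        params = replace(params, nu=np.array([nu0, params.nu[1], params.nu[2]]))
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        state = e_step(z, params)
        if not np.isfinite(state.loglik):
            raise RuntimeError(f"non-finite log-likelihood at iteration {len(trace)}")
        trace.append(state.loglik)
        params = cm_step1(z, state, params, prune_threshold=prune_threshold)
        params, _ = cm_step2(z, params, nu_range=nu_range)
        if np.isfinite(prev) and abs(state.loglik - prev) <= tol * (abs(prev) + 1.0):
            break
        prev = state.loglik
    final = e_step(z, params)
    trace.append(final.loglik)
    return params, np.asarray(trace)


def pi0_upper_bound(
    z: np.ndarray, nu0: float, density_estimate: np.ndarray, central: float = 0.99
) -> float:
    """Upper bound on the null proportion: min_z fhat(z) / f0(z).

    Since fhat(z)/f0(z) = pi0 + sum_k pi_k f_k(z)/f0(z) >= pi0 at every
    z, the minimum of the ratio bounds pi0 from above.  The minimum is
    taken over the central ``central`` mass of |z| (the ratio is least
    reliable in the far tails where the density estimate starves), and
    clipped to [0, 1].
    """
    z = np.asarray(z, dtype=float)
    density_estimate = np.asarray(density_estimate, dtype=float)
    if z.size == 0:
        raise ValueError("empty grid")
    if np.any(density_estimate <= 0):
        raise ValueError("density estimate must be positive everywhere")
    mask = np.abs(z) <= np.quantile(np.abs(z), central)
    if not mask.any():
        mask = np.ones_like(z, dtype=bool)
    ratio = density_estimate[mask] / t_pdf(z[mask], 0.0, 1.0, nu0)
    return float(np.clip(ratio.min(), 0.0, 1.0))


def apply_pi0_cap(z: np.ndarray, params: TMixtureParams) -> TMixtureParams:
    """Cap the fitted pi0 by the min-density-ratio bound, renormalizing
    the alternative proportions to keep the mixture proper."""
    fhat = mixture_pdf(z, params)
    bound = pi0_upper_bound(z, float(params.nu[0]), fhat)
    if params.pi[0] <= bound:
        return params
    alt = params.pi[1] + params.pi[2]
    pi = params.pi.copy()
    if alt <= 0:
        # nothing to reassign mass to; keep the degenerate pure-null fit
        return params
    pi[0] = bound
    pi[1:] = params.pi[1:] * (1.0 - bound) / alt
    return replace(params, pi=pi)
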