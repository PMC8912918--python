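"""Bayesian piecewise-exponential proportional-hazards model of poration times.

The first-poration rate of system i is

    lambda_i(t) = lambda_0(t) * exp(beta_i),

with the baseline lambda_0(t) piecewise constant on intervals
[s_j, s_{j+1}) (default width 1.5 ns) and one regression coefficient per
system category (membrane composition x field polarity). The likelihood is
the standard piecewise-exponential one: each uncensored event contributes
log lambda(t_event) minus its cumulative hazard, a censored replica only the
cumulative hazard. Priors: independent Gamma(shape 0.2, rate 0.04) on each
lambda_j — essentially vague with mean 5 ns^-1 (a gamma prior acts like
``shape`` phantom events over ``rate`` nanoseconds of phantom exposure, and
even one phantom event per interval measurably biases the regression
coefficients at desk-scale event counts) — and Normal(0, 100) on the betas. An
optional time-varying variant gives each system a Gaussian-random-walk
beta_i(t) on the same interval grid.

The posterior is sampled with an affine-invariant ensemble MCMC sampler over
(log lambda_j, beta); by default the first system is the reference with
beta = 0 folded into lambda_0, removing the exact likelihood ridge
lambda_0 -> lambda_0 * c, beta -> beta - log c. Convergence is monitored
with the potential scale reduction factor over walker groups.

Interpretation helpers map the coefficients onto the Arrhenius-like pore
nucleation rate law lambda = A exp(-(delta - B dPsi^2)/kT): when prefactors
are comparable, beta_i - beta_j is the negative steady-state free-energy
barrier difference in kT units. A least-squares helper fits the E^2
proportionality of field-induced thinning and area expansion (Maxwell
stress) and correlates it with the betas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import stats

from .util import rng_for

DEFAULT_SYSTEMS = ["APM-dep", "APM-hyp", "BPM-dep", "BPM-hyp"]


def make_intervals(horizon: float, width: float = 1.5) -> np.ndarray:
    """Endpoints 0, width, 2*width, ... covering ``horizon`` (last interval
    may be shorter)."""
    if width <= 0:
        raise ValueError("interval width must be positive")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    n_full = int(math.floor(horizon / width + 1e-12))
    pts = [i * width for i in range(n_full + 1)]
    if pts[-1] < horizon - 1e-12:
        pts.append(horizon)
    if len(pts) == 1:
        pts.append(horizon)
    return np.asarray(pts, dtype=float)


@dataclass
class HazardModelSpec:
    """Model structure and priors.

    ``endpoints`` may be None, in which case intervals of ``width`` are built
    to cover the largest observed time at fit time. The default gamma prior
    on each baseline rate is vague (shape 0.2, rate 0.04 ns: mean 5 ns^-1);
    a strongly informative literature-style prior is obtained with
    ``gamma_shape=50, gamma_rate=10`` — note it contributes 50 phantom
    events per interval and biases rates toward its mean of 5 ns^-1 whenever
    real per-interval event counts are smaller. The gamma prior reads its
    second parameter as a *rate* by default; ``gamma_scale_is_scale``
    switches to the scale reading. ``reference_constraint`` fixes the first
    system's beta to 0; switching it off reproduces the unconstrained
    all-systems parameterization.
    """

    endpoints: np.ndarray | None = None
    width: float = 1.5
    systems: list[str] = field(default_factory=lambda: list(DEFAULT_SYSTEMS))
    gamma_shape: float = 0.2
    gamma_rate: float = 0.04
    gamma_scale_is_scale: bool = False
    beta_sd: float = 100.0
    rw_sd: float = 1.0
    reference_constraint: bool = True

    @property
    def gamma_rate_effective(self) -> float:
        return 1.0 / self.gamma_rate if self.gamma_scale_is_scale else self.gamma_rate


def _sufficient_stats(events: pd.DataFrame, endpoints: np.ndarray,
                      systems: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Event counts D[s, j] and exposures E[s, j] per system and interval."""
    s = np.asarray(endpoints)
    widths = np.diff(s)
    J = len(widths)
    D = np.zeros((len(systems), J))
    E = np.zeros((len(systems), J))
    sys_index = {name: k for k, name in enumerate(systems)}
    for _, row in events.iterrows():
        if row["system"] not in sys_index:
            raise ValueError(f"unknown system {row['system']!r}")
        k = sys_index[row["system"]]
        t = float(row["t_ns"])
        if t > s[-1] + 1e-9:
            raise ValueError(f"event time {t} ns beyond covered horizon {s[-1]} ns")
        E[k] += np.clip(t - s[:-1], 0.0, widths)
        if not bool(row.get("censored", False)):
            j = min(np.searchsorted(s, t, side="right") - 1, J - 1)
            D[k, j] += 1.0
    return D, E


def loglik(events: pd.DataFrame, endpoints: np.ndarray, rates: np.ndarray,
           betas: dict[str, float] | np.ndarray) -> float:
    """Piecewise-exponential log-likelihood of an event table.

    ``rates`` are the baseline lambda_j; ``betas`` one coefficient per
    system. Censored rows contribute only through the cumulative hazard.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("negative baseline rate")
    if isinstance(betas, dict):
        systems = list(betas)
        beta = np.array([betas[s] for s in systems], dtype=float)
    else:
        systems = sorted(events["system"].unique())
        beta = np.asarray(betas, dtype=float)
    D, E = _sufficient_stats(events, endpoints, systems)
    with np.errstate(divide="ignore"):
        log_rates = np.log(rates)
    ll_events = float((D * (log_rates[None, :] + beta[:, None])).sum())
    cum = float((np.exp(beta) * (E @ rates)).sum())
    if not np.isfinite(ll_events) and D.sum(axis=0)[rates == 0].sum() > 0:
        return -math.inf  # an event fell in a zero-rate interval
    return ll_events - cum


@dataclass
class HazardPosterior:
    """Posterior draws and diagnostics of the piecewise hazard model."""

    systems: list[str]
    endpoints: np.ndarray
    lambda_draws: np.ndarray            # (n_draws, J)
    beta_draws: np.ndarray              # (n_draws, S); reference column is 0
    beta_time_draws: np.ndarray | None  # (n_draws, S, J) for the time-varying variant
    rhat: dict[str, float]
    converged: bool
    variant: str

    @property
    def n_draws(self) -> int:
        return len(self.lambda_draws)

    def system_index(self, system: str) -> int:
        try:
            return self.systems.index(system)
        except ValueError:
            raise KeyError(f"unknown system {system!r}")


def _log_posterior_factory(spec: HazardModelSpec, D: np.ndarray, E: np.ndarray,
                           variant: str):
    S, J = D.shape
    a = spec.gamma_shape
    b = spec.gamma_rate_effective
    free = slice(1, S) if spec.reference_constraint else slice(0, S)
    n_beta = S - 1 if spec.reference_constraint else S
    Dj = D.sum(axis=0)
    d_s = D.sum(axis=1)

    if variant == "constant":
        ndim = J + n_beta

        def log_prob(theta: np.ndarray) -> np.ndarray:
            theta = np.atleast_2d(theta)
            bad = np.abs(theta).max(axis=1) > 50.0  # reject before exp overflows
            theta = np.where(bad[:, None], 0.0, theta)
            u = theta[:, :J]                      # log lambda_j
            beta = np.zeros((len(theta), S))
            beta[:, free] = theta[:, J:]
            lam = np.exp(u)
            lp = (a * u - b * lam).sum(axis=1)    # gamma prior + log Jacobian
            lp += -0.5 * (beta[:, free] ** 2).sum(axis=1) / spec.beta_sd ** 2
            ll = u @ Dj + beta @ d_s
            ll -= (np.exp(beta) * (lam @ E.T)).sum(axis=1)
            out = lp + ll
            out[bad | ~np.isfinite(out)] = -np.inf
            return out

        return log_prob, ndim

    if variant == "time-varying":
        ndim = J + n_beta * J

        def log_prob(theta: np.ndarray) -> np.ndarray:
            theta = np.atleast_2d(theta)
            bad = np.abs(theta).max(axis=1) > 50.0
            theta = np.where(bad[:, None], 0.0, theta)
            W = len(theta)
            u = theta[:, :J]
            beta = np.zeros((W, S, J))
            beta[:, free, :] = theta[:, J:].reshape(W, n_beta, J)
            lam = np.exp(u)
            lp = (a * u - b * lam).sum(axis=1)
            steps = np.diff(beta[:, free, :], axis=2)
            lp += -0.5 * (beta[:, free, 0] ** 2).sum(axis=1) / spec.rw_sd ** 2
            lp += -0.5 * (steps ** 2).sum(axis=(1, 2)) / spec.rw_sd ** 2
            ll = (D[None] * (u[:, None, :] + beta)).sum(axis=(1, 2))
            ll -= (E[None] * lam[:, None, :] * np.exp(beta)).sum(axis=(1, 2))
            out = lp + ll
            out[bad | ~np.isfinite(out)] = -np.inf
            return out

        return log_prob, ndim

    raise ValueError(f"unknown variant {variant!r}")


def fit_hazard(events: pd.DataFrame, spec: HazardModelSpec | None = None,
               variant: str = "constant", n_steps: int = 6000,
               n_burn: int = 3000, n_walkers: int | None = None,
               seed: int = 0, rhat_threshold: float = 1.01) -> HazardPosterior:
    """Sample the posterior of the piecewise hazard model.

    ``variant`` is ``constant`` (time-independent betas) or ``time-varying``
    (random-walk beta_i(t)). Walkers start from a crude occurrence/exposure
    rate estimate; four walker groups feed the potential-scale-reduction
    diagnostic, and a fit whose worst R-hat exceeds the threshold is flagged
    (``converged = False``), never silently accepted.
    """
    spec = spec or HazardModelSpec()
    if not (events["censored"] == False).any():  # noqa: E712
        raise ValueError("need at least one uncensored event")
    systems = [s for s in spec.systems if s in set(events["system"])]
    if not systems:
        systems = sorted(events["system"].unique())
    endpoints = spec.endpoints
    if endpoints is None:
        horizon = float(events["t_ns"].max()) * (1 + 1e-9)
        endpoints = make_intervals(horizon, spec.width)
    endpoints = np.asarray(endpoints, dtype=float)
    D, E = _sufficient_stats(events, endpoints, systems)
    J = len(endpoints) - 1
    S = len(systems)
    variant_key = "constant" if variant.startswith("constant") else "time-varying"
    log_prob, ndim = _log_posterior_factory(spec, D, E, variant_key)

    rng = rng_for(seed, "hazard-mcmc")
    crude = (D.sum(axis=0) + 0.5) / (E.sum(axis=0) + 0.5)
    u0 = np.log(np.clip(crude, 1e-3, None))
    center = np.concatenate([u0, np.zeros(ndim - J)])
    nw = n_walkers or max(2 * ndim + 2, 32)
    nw += (-nw) % 4  # equal walker groups for the convergence diagnostic
    p0 = center[None, :] + 0.1 * rng.standard_normal((nw, ndim))

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nw, ndim, log_prob, vectorize=True, moves=moves)
    sampler.random_state = np.random.RandomState(seed & 0x7FFFFFFF).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn)          # (steps, walkers, dim)

    # R-hat over four walker groups
    groups = np.array_split(np.arange(nw), 4)
    grouped = np.stack([chain[:, g, :].reshape(-1, ndim) for g in groups])  # (4, n, dim)
    ds = az.convert_to_dataset(grouped.transpose(0, 1, 2))
    rh = az.rhat(ds)["x"].values
    rhat = {"max": float(np.nanmax(rh))}
    converged = rhat["max"] < rhat_threshold

    flat = chain.reshape(-1, ndim)
    lam = np.exp(flat[:, :J])
    free0 = 1 if spec.reference_constraint else 0
    if variant_key == "constant":
        beta = np.zeros((len(flat), S))
        beta[:, free0:] = flat[:, J:]
        beta_time = None
    else:
        beta_time = np.zeros((len(flat), S, J))
        beta_time[:, free0:, :] = flat[:, J:].reshape(len(flat), S - free0, J)
        beta = beta_time.mean(axis=2)
    return HazardPosterior(systems=systems, endpoints=endpoints,
                           lambda_draws=lam, beta_draws=beta,
                           beta_time_draws=beta_time, rhat=rhat,
                           converged=converged, variant=variant_key)


def credible_interval(draws: np.ndarray, mass: float = 0.94) -> tuple[float, float]:
    """Central credible interval containing ``mass`` of the posterior draws.

    Equal-tailed by construction, so it always contains the posterior median.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    draws = np.asarray(draws, dtype=float)
    if draws.size < 100:
        raise ValueError("need at least 100 draws")
    alpha = (1.0 - mass) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def rate_ratio(posterior: HazardPosterior, system_i: str, system_j: str,
               mass: float = 0.94) -> dict:
    """Posterior of the poration-rate ratio exp(beta_i - beta_j)."""
    i = posterior.system_index(system_i)
    j = posterior.system_index(system_j)
    draws = np.exp(posterior.beta_draws[:, i] - posterior.beta_draws[:, j])
    lo, hi = credible_interval(draws, mass)
    return {"draws": draws, "median": float(np.median(draws)),
            "interval": (lo, hi), "mass": mass}


def barrier_difference(posterior: HazardPosterior, system_i: str,
                       system_j: str, mass: float = 0.94) -> dict:
    """Posterior of the effective pore-formation barrier difference
    delta_i - delta_j in kT units, assuming comparable prefactors: the
    negative coefficient difference -(beta_i - beta_j)."""
    i = posterior.system_index(system_i)
    j = posterior.system_index(system_j)
    draws = -(posterior.beta_draws[:, i] - posterior.beta_draws[:, j])
    lo, hi = credible_interval(draws, mass)
    return {"draws": draws, "median": float(np.median(draws)),
            "interval": (lo, hi), "mass": mass}


@dataclass
class RateLaw:
    """Arrhenius-like whole-cell pore nucleation rate
    lambda = A exp(-(delta - B dPsi^2) / kT)."""

    prefactor: float          # A, rate per ns
    barrier: float            # delta, in kT units when kT = 1
    b_coefficient: float      # B, kT per volt^2
    voltage: float            # dPsi, volt
    kT: float = 1.0

    def __post_init__(self) -> None:
        if self.kT <= 0:
            raise ValueError("kT must be positive")


def eval_rate_law(law: RateLaw) -> float:
    """lambda = A exp(-(delta - B dPsi^2)/kT)."""
    return law.prefactor * math.exp(
        -(law.barrier - law.b_coefficient * law.voltage ** 2) / law.kT)


def simulate_piecewise_times(endpoints: np.ndarray, rates: np.ndarray,
                             n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws from a piecewise-constant hazard (last rate extended)."""
    s = np.asarray(endpoints, dtype=float)
    widths = np.diff(s)
    rates = np.asarray(rates, dtype=float)
    targets = rng.exponential(1.0, n)
    cum = np.concatenate([[0.0], np.cumsum(rates * widths)])
    out = np.empty(n)
    for i, tgt in enumerate(targets):
        j = np.searchsorted(cum, tgt, side="right") - 1
        if j >= len(rates):
            out[i] = s[-1] + (tgt - cum[-1]) / rates[-1] if rates[-1] > 0 else np.inf
        else:
            out[i] = s[j] + (tgt - cum[j]) / rates[j] if rates[j] > 0 else np.inf
    return out


def posterior_predictive(posterior: HazardPosterior, events: pd.DataFrame,
                         n_replicas: int | None = None, seed: int = 0,
                         max_draws: int = 200) -> dict:
    """Simulate first-poration times from posterior draws and compare with
    the observed times by the two-sample Kolmogorov-Smirnov statistic."""
    rng = rng_for(seed, "posterior-predictive")
    obs = events.loc[~events["censored"], "t_ns"].to_numpy(dtype=float)
    counts = events.loc[~events["censored"]].groupby("system").size()
    pick = rng.choice(posterior.n_draws, size=min(max_draws, posterior.n_draws),
                      replace=False)
    sims = []
    for d in pick:
        lam = posterior.lambda_draws[d]
        for system, n_sys in counts.items():
            k = posterior.system_index(system)
            n_sim = n_sys if n_replicas is None else n_replicas
            t = simulate_piecewise_times(posterior.endpoints,
                                         lam * math.exp(posterior.beta_draws[d, k]),
                                         n_sim, rng)
            sims.append(t[np.isfinite(t)])
    pooled = np.concatenate(sims)
    ks = stats.ks_2samp(pooled, obs)
    return {"times": pooled, "ks_statistic": float(ks.statistic),
            "p_value": float(ks.pvalue)}


def fit_e2_response(field_strengths: np.ndarray, responses: np.ndarray) -> dict:
    """Least-squares fit of response = c * E^2 through the origin.

    Returns the slope, its standard error, and residuals. Field-induced
    membrane thinning and area expansion follow this Maxwell-stress scaling.
    """
    E = np.asarray(field_strengths, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(E) != len(r) or len(E) < 3:
        raise ValueError("need at least 3 paired (E, response) values")
    if not np.any(E == 0):
        raise ValueError("include the zero-field reference")
    x = E ** 2
    sxx = (x ** 2).sum()
    if sxx == 0:
        raise ValueError("degenerate design: all fields zero")
    c = (x * r).sum() / sxx
    resid = r - c * x
    dof = max(len(E) - 1, 1)
    se = math.sqrt((resid ** 2).sum() / dof / sxx)
    return {"slope": float(c), "stderr": float(se), "residuals": resid}


def beta_response_correlation(betas: np.ndarray, response_slopes: np.ndarray) -> dict:
    """Pearson correlation between system coefficients and their E^2-response
    slopes (mechanical-response analogue of the rate differences)."""
    r, p = stats.pearsonr(np.asarray(betas, float), np.asarray(response_slopes, float))
    return {"pearson_r": float(r), "p_value": float(p)}
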