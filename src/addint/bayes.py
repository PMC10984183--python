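"""Bayesian estimation of the interaction measures by random-walk Metropolis.

The model is Bernoulli logistic regression in the dummy (indicator) coding,
with independent diffuse normal priors on every coefficient — by default
N(0, 10^2) on the intercept, the three category effects and any confounder
effects.  The posterior is sampled with a Gaussian random-walk Metropolis
algorithm whose proposal covariance is the standard optimal scaling
(2.38^2/d) times the MLE covariance (identity fallback when no MLE is
available).  Chain 1 starts at the MLE; further chains start at the MLE
plus overdispersed jitter so that the Gelman-Rubin potential scale
reduction factor (PSRF) is a meaningful convergence check.

Because RERI, AP and S are deterministic functions of the coefficients, a
posterior sample of the measures is obtained by mapping every retained draw
through the measure formulas (optionally re-referencing each draw at its
own lowest-risk category when preventive factors are possible).  Summaries
are the posterior median and the equal-tailed credible interval — the
(alpha/2, 1-alpha/2) posterior quantiles; a highest-posterior-density
variant is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .bootstrap import empirical_quantile
from .measures import measures_from_draws
from .model_fit import (
    FitError,
    InteractionEstimate,
    Measure,
    SubjectData,
    fit_logistic_mle,
)

__all__ = [
    "PriorSpec",
    "PosteriorSample",
    "log_posterior",
    "random_walk_metropolis",
    "sample_posterior",
    "psrf",
    "posterior_measures",
]


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal priors, N(mean, sd^2), per coefficient.

    Scalars broadcast over all coefficients; the defaults (mean 0, sd 10)
    are proper but diffuse.
    """

    mean: float | Sequence[float] = 0.0
    sd: float | Sequence[float] = 10.0

    def moments(self, d: int) -> tuple[np.ndarray, np.ndarray]:
        mean = np.broadcast_to(np.asarray(self.mean, dtype=float), (d,))
        sd = np.broadcast_to(np.asarray(self.sd, dtype=float), (d,))
        if (sd <= 0).any():
            raise ValueError("prior sd must be strictly positive (proper prior)")
        return mean.copy(), sd.copy()

    def logpdf(self, theta: np.ndarray) -> float:
        mean, sd = self.moments(len(theta))
        z = (theta - mean) / sd
        return float(-0.5 * np.sum(z * z) - np.sum(np.log(sd))
                     - 0.5 * len(theta) * math.log(2 * math.pi))


@dataclass
class PosteriorSample:
    """Retained MCMC draws: one (n_retained, d) matrix per chain."""

    chains: list[np.ndarray]
    param_names: tuple[str, ...]
    n_iter: int
    n_burnin: int
    seed: int
    acceptance_rates: list[float]
    psrf: np.ndarray | None = None

    def pooled(self) -> np.ndarray:
        return np.vstack(self.chains)


def _loglik_factory(data: SubjectData) -> Callable[[np.ndarray], float]:
    """Stable Bernoulli log-likelihood, aggregated to the 8 exposure cells
    when there are no confounders (identical likelihood, far fewer terms)."""
    if data.confounders is None:
        t = data.to_table()
        ca = [float(c) for c in t.cases]
        co = [float(c) for c in t.controls]

        def loglik(theta: np.ndarray) -> float:
            b0 = theta[0]
            ll = 0.0
            for j in range(4):
                eta = b0 + (theta[j] if j else 0.0)
                if eta >= 0:
                    lse = math.log1p(math.exp(-eta))
                    ll += -ca[j] * lse + co[j] * (-eta - lse)
                else:
                    lse = math.log1p(math.exp(eta))
                    ll += ca[j] * (eta - lse) - co[j] * lse
            return ll

        return loglik

    x = data.design_matrix()
    y = np.asarray(data.outcome, dtype=float)
    xty = x.T @ y

    def loglik(theta: np.ndarray) -> float:
        eta = x @ theta
        return float(theta @ xty - np.logaddexp(0.0, eta).sum())

    return loglik


def log_posterior(
    theta: np.ndarray, data: SubjectData, prior: PriorSpec | None = None
) -> float:
    """Log posterior density (up to the evidence constant) at ``theta``.

    ``theta`` is the coefficient vector (beta0, beta1, beta2, beta3,
    gamma...) in dummy coding.
    """
    prior = prior or PriorSpec()
    theta = np.asarray(theta, dtype=float)
    if not np.isfinite(theta).all():
        return -math.inf
    return prior.logpdf(theta) + _loglik_factory(data)(theta)


def random_walk_metropolis(
    log_density: Callable[[np.ndarray], float],
    x0: np.ndarray,
    proposal_cov: np.ndarray,
    n_iter: int,
    n_burnin: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Generic Gaussian random-walk Metropolis sampler.

    Runs ``n_iter`` iterations, discards the first ``n_burnin``, and returns
    (retained draws, overall acceptance rate).  Proposals are x + N(0, C);
    acceptance probability min(1, exp(delta log density)).
    """
    x0 = np.asarray(x0, dtype=float)
    d = len(x0)
    if n_burnin >= n_iter:
        raise ValueError("n_burnin must be smaller than n_iter")
    chol = np.linalg.cholesky(np.atleast_2d(proposal_cov))
    steps = rng.standard_normal((n_iter, d)) @ chol.T
    log_u = np.log(rng.random(n_iter))
    out = np.empty((n_iter - n_burnin, d))
    x = x0.copy()
    lp = log_density(x)
    accepted = 0
    for i in range(n_iter):
        cand = x + steps[i]
        lp_cand = log_density(cand)
        if log_u[i] < lp_cand - lp:
            x, lp = cand, lp_cand
            accepted += 1
        if i >= n_burnin:
            out[i - n_burnin] = x
    return out, accepted / n_iter


def sample_posterior(
    data: SubjectData,
    prior: PriorSpec | None = None,
    n_iter: int = 20_000,
    n_burnin: int = 10_000,
    n_chains: int = 2,
    seed: int | None = None,
    tune: float | None = None,
) -> PosteriorSample:
    """Posterior sample of the logistic coefficients via random-walk Metropolis.

    Proposal covariance is ``tune * Sigma_MLE`` with ``tune = 2.38^2/d`` by
    default (the classical optimal random-walk scaling); when the MLE fit
    fails or does not converge the proposal falls back to ``tune * I`` with
    a warning.  Chain c > 1 starts at the MLE plus N(0, (2 * proposal sd)^2)
    jitter.  PSRF per parameter is recorded whenever at least two chains run.
    """
    if seed is None:
        raise ValueError("an MCMC seed is required for reproducibility")
    prior = prior or PriorSpec()
    d = 4 + data.n_confounders
    tune = tune if tune is not None else 2.38**2 / d
    try:
        fit = fit_logistic_mle(data)
        if not fit.converged or not np.isfinite(fit.covariance).all():
            raise FitError("MLE unavailable for proposal scaling")
        center = fit.params()
        prop_cov = tune * fit.covariance
    except FitError:
        warnings.warn(
            "MLE unavailable; using identity proposal covariance and zero start",
            RuntimeWarning,
            stacklevel=2,
        )
        center = np.zeros(d)
        prop_cov = tune * np.eye(d)
    loglik = _loglik_factory(data)
    mean, sd = prior.moments(d)
    prior_const = -np.sum(np.log(sd)) - 0.5 * d * math.log(2 * math.pi)

    def log_density(theta: np.ndarray) -> float:
        z = (theta - mean) / sd
        return prior_const - 0.5 * float(z @ z) + loglik(theta)

    names = ("beta0", "beta1", "beta2", "beta3") + tuple(
        f"gamma{i + 1}" for i in range(data.n_confounders)
    )
    ss = np.random.SeedSequence(seed)
    chains, rates = [], []
    jitter_sd = 2.0 * np.sqrt(np.diag(prop_cov))
    for c, child in enumerate(ss.spawn(n_chains)):
        rng = np.random.default_rng(child)
        x0 = center if c == 0 else center + jitter_sd * rng.standard_normal(d)
        draws, rate = random_walk_metropolis(
            log_density, x0, prop_cov, n_iter, n_burnin, rng
        )
        chains.append(draws)
        rates.append(rate)
    sample = PosteriorSample(
        chains=chains,
        param_names=names,
        n_iter=n_iter,
        n_burnin=n_burnin,
        seed=seed,
        acceptance_rates=rates,
        psrf=psrf(chains) if n_chains >= 2 else None,
    )
    if sample.psrf is not None and (sample.psrf > 1.1).any():
        worst = names[int(np.argmax(sample.psrf))]
        warnings.warn(
            f"PSRF above 1.1 for {worst} (max {sample.psrf.max():.3f}); "
            "chains may not have converged",
            RuntimeWarning,
            stacklevel=2,
        )
    return sample


def psrf(chains: Sequence[np.ndarray]) -> np.ndarray:
    """Gelman-Rubin potential scale reduction factor per parameter.

    sqrt([(n-1)/n * W + B/n] / W) from the within-chain variance W and the
    between-chain variance B = n * var(chain means).  Requires >= 2 chains
    of equal length.
    """
    if len(chains) < 2:
        raise ValueError(
            "PSRF needs at least two chains; split a single chain in half "
            "to use a split-chain variant"
        )
    arr = np.stack([np.atleast_2d(c.T).T for c in chains])  # (m, n, d)
    m, n, _ = arr.shape
    if n < 2:
        raise ValueError("chains too short for PSRF")
    means = arr.mean(axis=1)  # (m, d)
    w = arr.var(axis=1, ddof=1).mean(axis=0)
    b = n * means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(((n - 1) / n * w + b / n) / w)
    return np.where(w == 0, 1.0, r)


def _hpd(draws: np.ndarray, level: float) -> tuple[float, float]:
    x = np.sort(draws[np.isfinite(draws)])
    n = len(x)
    k = max(int(math.ceil(level * n)), 2)
    if k > n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def posterior_measures(
    sample: PosteriorSample,
    recode: bool = False,
    level: float = 0.95,
    hpd: bool = False,
    include_nonrisk_draws: bool = False,
) -> dict[str, InteractionEstimate]:
    """Posterior median and credible interval of each interaction measure.

    Every retained draw (pooled over chains) is mapped through the measure
    formulas.  The measures presuppose risk-factor coding — every joint
    exposure category at or above the reference risk — so by default draws
    violating it (some category coefficient below 0) are excluded from the
    summaries, with the excluded fraction reported; this extends to the
    whole triple the same domain logic that makes S undefined off-domain.
    ``include_nonrisk_draws=True`` keeps every draw instead (the full
    posterior), and ``recode=True`` re-references each draw at its own
    lowest-risk category before the measures are evaluated (the
    preventive-factor workflow; every recoded draw is risk-coded by
    construction).  Intervals are equal-tailed posterior quantiles (or HPD
    with ``hpd=True``).  If more than half the draws are excluded or
    undefined a summary is flagged unreliable in its diagnostics.
    """
    pooled = sample.pooled()
    if len(pooled) == 0:
        raise ValueError("empty posterior sample")
    beta = pooled[:, 1:4]
    mapped = measures_from_draws(beta, recode=recode)
    if not recode and not include_nonrisk_draws:
        bad = (beta < 0).any(axis=1)
        for v in mapped.values():
            v[bad] = np.nan
    alpha = 1.0 - level
    out: dict[str, InteractionEstimate] = {}
    for measure in Measure:
        draws = mapped[measure.value]
        defined = draws[~np.isnan(draws)]
        frac_undef = 1.0 - len(defined) / len(draws)
        diagnostics = {
            "n_draws": len(draws),
            "fraction_undefined": frac_undef,
            "posterior_mean": float(np.mean(defined[np.isfinite(defined)]))
            if len(defined)
            else math.nan,
            "recode": recode,
            "interval": "hpd" if hpd else "equal_tailed",
        }
        if frac_undef > 0.5:
            diagnostics["unreliable"] = (
                f"{frac_undef:.0%} of posterior draws undefined"
            )
        if len(defined) == 0:
            point = lo = hi = math.nan
        else:
            point = empirical_quantile(defined, 0.5)
            if hpd:
                lo, hi = _hpd(defined, level)
            else:
                lo = empirical_quantile(defined, alpha / 2)
                hi = empirical_quantile(defined, 1 - alpha / 2)
        out[measure.value] = InteractionEstimate(
            measure=measure,
            point=point,
            lower=lo,
            upper=hi,
            level=level,
            method="bayes_hpd" if hpd else "bayes_equal_tail",
            diagnostics=diagnostics,
        )
    return out
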