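"""Stratified bootstrap for the additive-interaction measures.

Resampling is done with replacement separately within cases and within
controls, so every resample keeps the case-control design fixed (the
resampled case and control totals equal the originals).  Each resample is
refit — by the saturated closed form when there are no confounders, by IRLS
otherwise — and three interval constructions are offered on the resulting
draw vectors:

* percentile: the (alpha/2, 1-alpha/2) order statistics of the draws;
* basic: the percentile interval reflected about the original estimate,
  (2*Zhat - upper, 2*Zhat - lower);
* normal: Zhat +/- z * sd(draws).

Sparse tables make the bootstrap pathological: a resample can empty the
reference cell, sending all three odds ratios to infinity.  Such draws are
kept in the order statistics at their limiting values (RERI -> +/-inf with
the sign of K11 - K10 - K01, where K_j = cases_j*controls_0/controls_j; AP
and S tend to finite limits), which is what produces the astronomically
large upper limits seen on sparse data.  Draws where a measure has no
limit, and S draws outside S's domain, are excluded from that measure's
order statistics with the exclusion counted in the diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .measures import measures_from_draws
from .model_fit import (
    FitError,
    InteractionEstimate,
    Measure,
    SubjectData,
    fit_logistic_mle,
    fit_saturated_from_table,
)

__all__ = [
    "BootstrapResult",
    "stratified_resample",
    "bootstrap_distribution",
    "bootstrap_intervals",
    "empirical_quantile",
]

METHODS = ("percentile", "basic", "normal")


@dataclass(frozen=True)
class BootstrapResult:
    """Draw vectors of the three measures over B stratified resamples.

    ``draws[m]`` has length B; NaN entries mark draws where measure ``m``
    is undefined (counted in ``n_undefined``).  ``n_failed`` counts
    resamples whose refit failed outright (all three measures NaN there).
    """

    draws: dict[str, np.ndarray]
    B: int
    seed: int
    n_failed: int = 0
    n_undefined: dict[str, int] = field(default_factory=dict)

    def defined(self, measure: Measure | str) -> np.ndarray:
        d = self.draws[Measure(measure).value]
        return d[~np.isnan(d)]


def stratified_resample(data: SubjectData, rng: np.random.Generator) -> SubjectData:
    """One bootstrap resample drawn within cases and within controls."""
    y = np.asarray(data.outcome, dtype=bool)
    case_idx = np.flatnonzero(y)
    control_idx = np.flatnonzero(~y)
    if len(case_idx) == 0 or len(control_idx) == 0:
        raise ValueError("need at least one case and one control to resample")
    pick = np.concatenate(
        [rng.choice(case_idx, size=len(case_idx), replace=True),
         rng.choice(control_idx, size=len(control_idx), replace=True)]
    )
    return SubjectData(
        outcome=data.outcome[pick],
        factor_a=data.factor_a[pick],
        factor_b=data.factor_b[pick],
        confounders=None if data.confounders is None else data.confounders[pick],
    )


def empirical_quantile(draws: np.ndarray, q: float) -> float:
    """Type-1 empirical quantile: the order statistic at index ceil(n*q).

    ``draws`` must be free of NaN; infinities participate as ordinary
    order-statistic values.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n == 0:
        return math.nan
    k = min(max(int(math.ceil(n * q)), 1), n)
    return float(x[k - 1])


def _table_draw_measures(
    cases: np.ndarray, controls: np.ndarray
) -> dict[str, np.ndarray]:
    """Measures for resampled tables (B, 4), with empty-reference-cell limits."""
    ca = cases.astype(float)
    co = controls.astype(float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ors = ca[:, 1:] * co[:, [0]] / (ca[:, [0]] * co[:, 1:])
        or10, or01, or11 = ors.T
        reri = or11 - or10 - or01 + 1.0
        ap = reri / or11
        num, den = or11 - 1.0, or10 + or01 - 2.0
        s = np.where((num > 0) & (den > 0), num / den, np.nan)
        # empty reference cases: every OR is +inf; substitute the exact
        # cases_0 -> 0 limits driven by K_j = cases_j * controls_0 / controls_j
        ref_empty = (ca[:, 0] == 0) & (co[:, 0] > 0) & (co[:, 1:] > 0).all(axis=1)
        if ref_empty.any():
            k = ca[ref_empty][:, 1:] * co[ref_empty][:, :1] / co[ref_empty][:, 1:]
            k10, k01, k11 = k.T
            gap = k11 - k10 - k01
            reri[ref_empty] = np.where(gap > 0, np.inf,
                                       np.where(gap < 0, -np.inf, np.nan))
            with np.errstate(divide="ignore", invalid="ignore"):
                ap[ref_empty] = np.where(k11 > 0, 1.0 - (k10 + k01) / k11, np.nan)
                s_lim = np.where((k11 > 0) & (k10 + k01 > 0),
                                 k11 / (k10 + k01), np.nan)
            s[ref_empty] = s_lim
    return {"RERI": reri, "AP": ap, "S": s}


def bootstrap_distribution(
    data: SubjectData, B: int = 1000, seed: int | None = None
) -> BootstrapResult:
    """Fit the measures on B stratified resamples of ``data``.

    Without confounders the stratified subject resample is equivalent in
    distribution to multinomial resampling of the case and control cell
    counts, so the saturated closed form is evaluated vectorised over all B
    tables; with confounders each resample is refit by IRLS.
    """
    if B < 1:
        raise ValueError("B must be positive")
    if seed is None:
        raise ValueError("a bootstrap seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    n_failed = 0
    if data.confounders is None:
        table = data.to_table()
        p_cases = np.asarray(table.cases) / table.n_cases
        p_controls = np.asarray(table.controls) / table.n_controls
        ca = rng.multinomial(table.n_cases, p_cases, size=B)
        co = rng.multinomial(table.n_controls, p_controls, size=B)
        draws = _table_draw_measures(ca, co)
    else:
        rows = {m.value: np.full(B, np.nan) for m in Measure}
        beta = np.full((B, 3), np.nan)
        for b in range(B):
            res = stratified_resample(data, rng)
            try:
                fit = fit_logistic_mle(res)
            except FitError:
                n_failed += 1
                continue
            if not fit.converged:
                n_failed += 1
                continue
            c = fit.coefficients
            beta[b] = (c.beta1, c.beta2, c.beta3)
        ok = ~np.isnan(beta[:, 0])
        mapped = measures_from_draws(beta[ok])
        for m in Measure:
            rows[m.value][ok] = mapped[m.value]
        draws = rows
    n_undefined = {
        m: int(np.isnan(v).sum()) - n_failed for m, v in draws.items()
    }
    return BootstrapResult(
        draws=draws, B=B, seed=seed, n_failed=n_failed, n_undefined=n_undefined
    )


def _interval(
    method: str, draws: np.ndarray, point: float, level: float
) -> tuple[float, float]:
    alpha = 1.0 - level
    if method == "percentile":
        return (empirical_quantile(draws, alpha / 2),
                empirical_quantile(draws, 1 - alpha / 2))
    if method == "basic":
        lo = empirical_quantile(draws, alpha / 2)
        hi = empirical_quantile(draws, 1 - alpha / 2)
        return (2 * point - hi, 2 * point - lo)
    if method == "normal":
        z = stats.norm.ppf(0.5 + level / 2)
        finite = draws[np.isfinite(draws)]
        se = float(np.std(finite, ddof=1)) if len(finite) > 1 else math.nan
        return (point - z * se, point + z * se)
    raise ValueError(f"unknown bootstrap method {method!r}")


def bootstrap_intervals(
    data: SubjectData,
    B: int = 1000,
    methods: tuple[str, ...] = ("percentile",),
    level: float = 0.95,
    seed: int | None = None,
) -> dict[tuple[str, str], InteractionEstimate]:
    """Bootstrap intervals for every (measure, method) pair.

    The point estimate is always the original-sample estimate; only the
    interval comes from the B resamples.  S draws outside S's domain are
    excluded from the order statistics, with the exclusion count reported
    in the diagnostics.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown bootstrap method {m!r}")
    if data.confounders is None:
        fit = fit_saturated_from_table(data.to_table())
    else:
        fit = fit_logistic_mle(data)
    from .measures import measures_from_coefficients

    point = measures_from_coefficients(fit.coefficients)
    points = {"RERI": point.reri, "AP": point.ap,
              "S": math.nan if point.s is None else point.s}
    boot = bootstrap_distribution(data, B=B, seed=seed)
    out: dict[tuple[str, str], InteractionEstimate] = {}
    for measure in Measure:
        d = boot.defined(measure)
        for method in methods:
            lo, hi = _interval(method, d, points[measure.value], level)
            out[(measure.value, method)] = InteractionEstimate(
                measure=measure,
                point=points[measure.value],
                lower=lo,
                upper=hi,
                level=level,
                method=f"boot_{method}",
                diagnostics={
                    "B": B,
                    "seed": seed,
                    "n_failed": boot.n_failed,
                    "n_undefined": boot.n_undefined[measure.value],
                },
            )
    return out
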