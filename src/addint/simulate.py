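"""Case-control simulation scenarios and the interval coverage study.

Twenty built-in scenarios cross two values of OR01 (4, 2), two of OR10
(5, 2.5) and five interaction strengths of OR11 chosen so that AP runs
through 0.60, 0.33, 0, -0.33 and -1 (strong synergy to strong antagonism).
In every scenario the control population's joint exposure distribution is
fixed at (A0B0, A1B0, A0B1, A1B1) = (0.6, 0.1, 0.2, 0.1) and a sample of
fixed case and control totals (default 300/300; the unbalanced design uses
200/400) is drawn:

* without a confounder, controls are multinomial on the exposure
  proportions q and cases are multinomial on p_j proportional to q_j * OR_j
  (OR_0 = 1), which makes the scenario ORs the exact population exposure
  odds ratios between cases and controls;
* with a confounder, a source cohort is generated — exposure ~ q, X ~
  standard normal independent of exposure, disease from the logistic model
  with the scenario's log-OR effects and coefficient gamma on X, intercept
  solved so the cohort's expected case fraction matches the design — and
  the required numbers of cases and controls are sampled from it.

The coverage study replays each scenario many times, builds the delta,
percentile-bootstrap and/or Bayesian 95% intervals for RERI, AP and S per
replicate, and reports per (scenario, method, measure) the median point
estimate, coverage of the true value, directional (left/right) miscoverage,
whether coverage falls inside the binomial target band around 95%, and the
rank of the absolute deviation of coverage from 95% across methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import bayes as _bayes
from .bootstrap import bootstrap_intervals
from .measures import InteractionMeasures, RelativeRiskTriple, interaction_measures
from .model_fit import (
    ContingencyTable2x4,
    FitError,
    Measure,
    SubjectData,
    delta_interval,
    fit_logistic_mle,
    fit_saturated_from_table,
)

__all__ = [
    "Scenario",
    "CoverageReport",
    "builtin_scenarios",
    "draw_sample",
    "run_coverage_study",
    "coverage_target_range",
]

EXPOSURE_PROPS = (0.6, 0.1, 0.2, 0.1)

# (id, OR01, OR10, OR11) grid; within each letter block AP steps through
# 0.60, 0.33, 0.00, -0.33, -1.00.
_SCENARIO_GRID = [
    ("A1", 4.0, 5.0, 20.0), ("A2", 4.0, 5.0, 12.0), ("A3", 4.0, 5.0, 8.0),
    ("A4", 4.0, 5.0, 6.0), ("A5", 4.0, 5.0, 4.0),
    ("B1", 2.0, 5.0, 15.0), ("B2", 2.0, 5.0, 9.0), ("B3", 2.0, 5.0, 6.0),
    ("B4", 2.0, 5.0, 4.5), ("B5", 2.0, 5.0, 3.0),
    ("C1", 4.0, 2.5, 13.75), ("C2", 4.0, 2.5, 8.25), ("C3", 4.0, 2.5, 5.5),
    ("C4", 4.0, 2.5, 4.125), ("C5", 4.0, 2.5, 2.75),
    ("D1", 2.0, 2.5, 8.75), ("D2", 2.0, 2.5, 5.25), ("D3", 2.0, 2.5, 3.5),
    ("D4", 2.0, 2.5, 2.625), ("D5", 2.0, 2.5, 1.75),
]


@dataclass(frozen=True)
class Scenario:
    """One simulation condition: OR settings, design sizes, confounder flag."""

    id: str
    or01: float
    or10: float
    or11: float
    exposure_props: tuple[float, float, float, float] = EXPOSURE_PROPS
    n_cases: int = 300
    n_controls: int = 300
    confounder: bool = False
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if abs(sum(self.exposure_props) - 1.0) > 1e-9:
            raise ValueError("exposure_props must sum to 1")
        if min(self.or01, self.or10, self.or11) <= 0:
            raise ValueError("odds ratios must be positive")

    @property
    def true_measures(self) -> InteractionMeasures:
        return interaction_measures(
            RelativeRiskTriple(rr10=self.or10, rr01=self.or01, rr11=self.or11)
        )

    def true_value(self, measure: Measure | str) -> float:
        t = self.true_measures
        m = Measure(measure)
        if m is Measure.RERI:
            return t.reri
        if m is Measure.AP:
            return t.ap
        return math.nan if t.s is None else t.s


def builtin_scenarios(
    n_cases: int = 300, n_controls: int = 300, confounder: bool = False
) -> list[Scenario]:
    """The 20 built-in scenarios A1..D5 (balanced design by default)."""
    return [
        Scenario(id=sid, or01=or01, or10=or10, or11=or11,
                 n_cases=n_cases, n_controls=n_controls, confounder=confounder)
        for sid, or01, or10, or11 in _SCENARIO_GRID
    ]


def _counts_to_subject_data(
    case_counts: np.ndarray, control_counts: np.ndarray
) -> SubjectData:
    return ContingencyTable2x4(
        tuple(int(c) for c in case_counts), tuple(int(c) for c in control_counts)
    ).to_subject_data()


def draw_sample(
    scenario: Scenario, seed: int | np.random.SeedSequence | np.random.Generator
) -> SubjectData:
    """Draw one case-control sample under ``scenario`` (deterministic in seed)."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    q = np.asarray(scenario.exposure_props)
    ors = np.array([1.0, scenario.or10, scenario.or01, scenario.or11])
    if not scenario.confounder:
        p_cases = q * ors
        p_cases = p_cases / p_cases.sum()
        cases = rng.multinomial(scenario.n_cases, p_cases)
        controls = rng.multinomial(scenario.n_controls, q)
        return _counts_to_subject_data(cases, controls)
    return _draw_confounded(scenario, rng, q, ors)


def _draw_confounded(
    scenario: Scenario, rng: np.random.Generator, q: np.ndarray, ors: np.ndarray
) -> SubjectData:
    """Cohort mechanism for the confounded design (X ~ N(0,1), gamma on X)."""
    beta = np.log(ors)  # beta[0] == 0 for the reference
    target = scenario.n_cases / (scenario.n_cases + scenario.n_controls)
    # intercept such that the cohort's expected case fraction hits the design
    grid = stats.norm.ppf((np.arange(200) + 0.5) / 200)  # X quadrature points

    def case_fraction(b0: float) -> float:
        eta = b0 + beta[:, None] + scenario.gamma * grid[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        return float(q @ p.mean(axis=1))

    try:
        b0 = optimize.brentq(lambda b: case_fraction(b) - target, -30.0, 30.0)
    except ValueError as exc:  # pragma: no cover - target in (0,1) is solvable
        raise FitError(f"cannot solve intercept for case fraction {target}") from exc

    need_cases, need_controls = scenario.n_cases, scenario.n_controls
    got: dict[int, list[np.ndarray]] = {0: [], 1: []}
    counts = [0, 0]
    batch = 4 * (need_cases + need_controls)
    while counts[0] < need_controls or counts[1] < need_cases:
        cat = rng.choice(4, size=batch, p=q)
        x = rng.standard_normal(batch)
        eta = b0 + np.take(beta, cat) + scenario.gamma * x
        y = (rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        for outcome in (0, 1):
            sel = np.flatnonzero(y == outcome)
            got[outcome].append(np.column_stack([cat[sel], x[sel]]))
            counts[outcome] += len(sel)
    controls = np.vstack(got[0])[:need_controls]
    cases = np.vstack(got[1])[:need_cases]
    both = np.vstack([cases, controls])
    cat = both[:, 0].astype(int)
    return SubjectData(
        outcome=np.r_[np.ones(need_cases, int), np.zeros(need_controls, int)],
        factor_a=(cat == 1) | (cat == 3),
        factor_b=(cat == 2) | (cat == 3),
        confounders=both[:, 1:2],
    )


def coverage_target_range(reps: int, level: float = 0.95) -> tuple[float, float]:
    """Binomial band (in %) a well-calibrated interval's coverage should hit.

    95 +/- 1.96 * sqrt(0.95 * 0.05 / reps) * 100; e.g. 93.6-96.4 at 1,000
    replicates.
    """
    half = 1.96 * math.sqrt(level * (1 - level) / reps) * 100
    return (level * 100 - half, level * 100 + half)


@dataclass(frozen=True)
class CoverageReport:
    """Tidy per-(scenario, method, measure) coverage results.

    ``table`` columns: scenario, method, measure, true, median_estimate,
    left (%), coverage (%), right (%), in_target, rank, n_failed.
    Coverage + left + right = 100 exactly in every row (failed replicates
    excluded from the denominator and counted in n_failed).
    """

    table: pd.DataFrame
    reps: int
    seed: int
    level: float = 0.95

    def mean_ranks(self, measure: Measure | str) -> pd.Series:
        m = Measure(measure).value
        sub = self.table[self.table["measure"] == m]
        return sub.groupby("method")["rank"].mean()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _replicate_intervals(
    data: SubjectData,
    methods: tuple[str, ...],
    level: float,
    boot_config: dict,
    bayes_config: dict,
    rep_seed: np.random.SeedSequence,
) -> dict[tuple[str, str], tuple[float, float, float]]:
    """(method, measure) -> (point, lower, upper) for one replicate."""
    out: dict[tuple[str, str], tuple[float, float, float]] = {}
    child = {m: s for m, s in zip(("boot", "bayes"), rep_seed.spawn(2))}
    if data.confounders is None:
        fit = fit_saturated_from_table(data.to_table())
    else:
        fit = fit_logistic_mle(data)
        if not fit.converged:
            raise FitError("replicate IRLS fit did not converge")
    if "delta" in methods:
        for measure in Measure:
            try:
                est = delta_interval(fit, measure, level)
                out[("delta", measure.value)] = (est.point, est.lower, est.upper)
            except FitError:
                out[("delta", measure.value)] = (math.nan, math.nan, math.nan)
    if "boot" in methods:
        cfg = {"B": 1000, **boot_config}
        seed = int(child["boot"].generate_state(1)[0] % (2**31))
        ests = bootstrap_intervals(
            data, B=cfg["B"], methods=("percentile",), level=level, seed=seed
        )
        for measure in Measure:
            est = ests[(measure.value, "percentile")]
            out[("boot", measure.value)] = (est.point, est.lower, est.upper)
    if "bayes" in methods:
        cfg = {"n_iter": 20_000, "n_burnin": 10_000, "n_chains": 1, **bayes_config}
        seed = int(child["bayes"].generate_state(1)[0] % (2**31))
        sample = _bayes.sample_posterior(
            data,
            n_iter=cfg["n_iter"],
            n_burnin=cfg["n_burnin"],
            n_chains=cfg["n_chains"],
            seed=seed,
        )
        ests = _bayes.posterior_measures(sample, level=level)
        for measure in Measure:
            est = ests[measure.value]
            out[("bayes", measure.value)] = (est.point, est.lower, est.upper)
    return out


def run_coverage_study(
    scenarios: list[Scenario],
    methods: tuple[str, ...] = ("delta", "boot", "bayes"),
    reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    boot_config: dict | None = None,
    bayes_config: dict | None = None,
) -> CoverageReport:
    """Coverage, directional miscoverage and deviation ranks per scenario.

    Replicate r of scenario s uses the seed stream ``SeedSequence(seed,
    spawn_key=(s_index, r))`` so any replicate is reproducible in isolation.
    Replicates whose fit fails are excluded and counted.  Ranks (1 = closest
    to nominal, ties averaged) compare |coverage - 95| across methods within
    each (scenario, measure).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    boot_config = boot_config or {}
    bayes_config = bayes_config or {}
    lo_t, hi_t = coverage_target_range(reps, level)
    rows = []
    for s_idx, scenario in enumerate(scenarios):
        truths = {m.value: scenario.true_value(m) for m in Measure}
        results = {
            (method, m.value): {"points": [], "left": 0, "right": 0, "n": 0}
            for method in methods
            for m in Measure
        }
        n_failed = 0
        for r in range(reps):
            rep_seed = np.random.SeedSequence(seed, spawn_key=(s_idx, r))
            data = draw_sample(scenario, np.random.default_rng(rep_seed))
            try:
                ests = _replicate_intervals(
                    data, methods, level, boot_config, bayes_config, rep_seed
                )
            except FitError:
                n_failed += 1
                continue
            for (method, m), (point, lo, hi) in ests.items():
                cell = results[(method, m)]
                true = truths[m]
                if math.isnan(lo) or math.isnan(hi) or math.isnan(true):
                    continue
                cell["points"].append(point)
                cell["n"] += 1
                if lo > true:
                    cell["left"] += 1
                elif hi < true:
                    cell["right"] += 1
        for m in Measure:
            covs = {}
            for method in methods:
                cell = results[(method, m.value)]
                n = cell["n"]
                if n == 0:
                    continue
                left = 100.0 * cell["left"] / n
                right = 100.0 * cell["right"] / n
                covs[method] = {
                    "scenario": scenario.id,
                    "method": method,
                    "measure": m.value,
                    "true": truths[m.value],
                    "median_estimate": float(np.nanmedian(cell["points"])),
                    "left": left,
                    "coverage": 100.0 - left - right,
                    "right": right,
                    "n_failed": n_failed + (reps - n_failed - n),
                }
            if not covs:
                continue
            devs = [abs(v["coverage"] - level * 100) for v in covs.values()]
            ranks = stats.rankdata(devs)
            for rank, v in zip(ranks, covs.values()):
                v["rank"] = float(rank)
                v["in_target"] = lo_t <= v["coverage"] <= hi_t
                rows.append(v)
    table = pd.DataFrame(rows)
    return CoverageReport(table=table, reps=reps, seed=seed, level=level)
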