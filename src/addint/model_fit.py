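"""Maximum-likelihood logistic regression and delta-method intervals.

Two fitting routes are provided for the two-factor interaction model:

* :func:`fit_logistic_mle` — general Newton/IRLS fit on subject-level data
  (binary outcome, the two factors in indicator coding, optional continuous
  confounders), covariance from the inverse observed information;
* :func:`fit_saturated_from_table` — the closed form for a 2x4 case-control
  table: with all cells positive the saturated-model MLEs are the log
  cross-product ratios beta_j = ln[(cases_j * controls_0)/(cases_0 *
  controls_j)] with Var(beta_j) = sum of reciprocal counts of the four cells
  involved and Cov(beta_j, beta_k) = 1/cases_0 + 1/controls_0.  Because the
  exposure-cell model is saturated the two routes agree exactly.

:func:`delta_interval` propagates the coefficient covariance to RERI, AP or
lnS by a first-order Taylor expansion (the delta method), yielding Wald-type
intervals symmetric about the point estimate; the S interval is built on the
log scale and exponentiated.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .measures import (
    CATEGORY_LABELS,
    CoefficientVector,
    interaction_measures,
    s_undefined_reason,
)

__all__ = [
    "Measure",
    "ContingencyTable2x4",
    "SubjectData",
    "LogisticFit",
    "InteractionEstimate",
    "FitError",
    "fit_logistic_mle",
    "fit_saturated_from_table",
    "delta_interval",
    "delta_gradient",
]


class FitError(RuntimeError):
    """A model fit could not be carried out on the given data."""


class Measure(str, enum.Enum):
    RERI = "RERI"
    AP = "AP"
    S = "S"


@dataclass(frozen=True)
class ContingencyTable2x4:
    """Case/control counts by joint exposure category (A0B0, A1B0, A0B1, A1B1)."""

    cases: tuple[int, int, int, int]
    controls: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        for name in ("cases", "controls"):
            row = getattr(self, name)
            if len(row) != 4:
                raise ValueError(f"{name} must have 4 entries, got {len(row)}")
            for label, c in zip(CATEGORY_LABELS, row):
                if c < 0 or c != int(c):
                    raise ValueError(
                        f"{name}[{label}] must be a non-negative integer, got {c!r}"
                    )
        if self.n_cases + self.n_controls == 0:
            raise ValueError("table is empty")

    @property
    def n_cases(self) -> int:
        return int(sum(self.cases))

    @property
    def n_controls(self) -> int:
        return int(sum(self.controls))

    def to_subject_data(self) -> "SubjectData":
        """Expand to one record per subject (no confounders)."""
        a = np.array([0, 1, 0, 1])
        b = np.array([0, 0, 1, 1])
        outcome, fa, fb = [], [], []
        for y, row in ((1, self.cases), (0, self.controls)):
            for j, n in enumerate(row):
                outcome.append(np.full(int(n), y))
                fa.append(np.full(int(n), a[j]))
                fb.append(np.full(int(n), b[j]))
        return SubjectData(
            outcome=np.concatenate(outcome),
            factor_a=np.concatenate(fa),
            factor_b=np.concatenate(fb),
        )


@dataclass(frozen=True)
class SubjectData:
    """Subject-level records: binary outcome/factors, optional confounders."""

    outcome: np.ndarray
    factor_a: np.ndarray
    factor_b: np.ndarray
    confounders: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("outcome", "factor_a", "factor_b"):
            v = np.asarray(getattr(self, name))
            if not np.isin(v, (0, 1)).all():
                raise ValueError(f"{name} must be binary (0/1)")
            object.__setattr__(self, name, v.astype(np.int8))
        n = len(self.outcome)
        if len(self.factor_a) != n or len(self.factor_b) != n:
            raise ValueError("outcome and factors must have equal length")
        if self.confounders is not None:
            x = np.atleast_2d(np.asarray(self.confounders, dtype=float))
            if x.shape[0] != n:
                x = x.T
            if x.shape[0] != n:
                raise ValueError("confounders must have one row per subject")
            object.__setattr__(self, "confounders", x)

    @property
    def n(self) -> int:
        return len(self.outcome)

    @property
    def n_confounders(self) -> int:
        return 0 if self.confounders is None else self.confounders.shape[1]

    def category_index(self) -> np.ndarray:
        """Joint-exposure category index per subject (0..3)."""
        return (self.factor_a + 2 * self.factor_b).astype(np.intp)

    def design_matrix(self) -> np.ndarray:
        """Dummy-coded design: intercept, I(A1B0), I(A0B1), I(A1B1), confounders."""
        cat = self.category_index()
        cols = [np.ones(self.n), cat == 1, cat == 2, cat == 3]
        x = np.column_stack(cols).astype(float)
        if self.confounders is not None:
            x = np.hstack([x, self.confounders])
        return x

    def to_table(self) -> ContingencyTable2x4:
        """Aggregate to a 2x4 table (confounders, if any, are dropped)."""
        cat = self.category_index()
        y = self.outcome.astype(bool)
        cases = np.bincount(cat[y], minlength=4)
        controls = np.bincount(cat[~y], minlength=4)
        return ContingencyTable2x4(tuple(int(c) for c in cases),
                                   tuple(int(c) for c in controls))


@dataclass(frozen=True)
class LogisticFit:
    """A fitted logistic model: coefficients, covariance, diagnostics.

    ``covariance`` is the full inverse observed information over
    (beta0, beta1, beta2, beta3, gamma...); the 3x3 block for the category
    effects used by the delta method is :meth:`interaction_covariance`.
    """

    coefficients: CoefficientVector
    covariance: np.ndarray
    log_likelihood: float
    converged: bool
    n_iterations: int
    diagnostics: dict = field(default_factory=dict)

    def interaction_covariance(self) -> np.ndarray:
        return np.asarray(self.covariance)[1:4, 1:4]

    def params(self) -> np.ndarray:
        c = self.coefficients
        return np.array([c.beta0, c.beta1, c.beta2, c.beta3, *c.gamma])


@dataclass(frozen=True)
class InteractionEstimate:
    """Point estimate and interval for one interaction measure."""

    measure: Measure
    point: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = "delta"
    diagnostics: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "measure": self.measure.value,
            "point": self.point,
            "lower": self.lower,
            "upper": self.upper,
            "level": self.level,
            "method": self.method,
            "diagnostics": self.diagnostics,
        }


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), stable for large |eta|
    return float(np.dot(y, eta) - np.logaddexp(0.0, eta).sum())


def fit_logistic_mle(
    data: SubjectData,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Newton/IRLS maximum-likelihood fit of the dummy-coded logistic model.

    Convergence is declared when the score (gradient) norm falls below
    ``tol``; steps that decrease the log-likelihood are halved (up to 30
    times).  Non-convergence (e.g. data separation) is reported through
    ``converged=False`` with the gradient norm in ``diagnostics`` — the
    caller decides whether that is fatal.
    """
    y = np.asarray(data.outcome, dtype=float)
    if y.min() == y.max():
        raise FitError("outcome has a single class; logistic MLE undefined")
    x = data.design_matrix()
    n, p = x.shape
    if n < p:
        raise FitError(f"need at least {p} subjects for {p} parameters, got {n}")

    beta = np.zeros(p)
    eta = x @ beta
    ll = _bernoulli_loglik(eta, y)
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = x.T @ (y - mu)
        grad_norm = float(np.linalg.norm(grad))
        if grad_norm < tol:
            break
        w = mu * (1.0 - mu)
        info = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break  # singular information: report non-convergence below
        # step-halving on likelihood decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            cand_ll = _bernoulli_loglik(x @ cand, y)
            if cand_ll >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        eta = x @ beta
        ll = _bernoulli_loglik(eta, y)

    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (x * w[:, None]).T @ x
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    converged = grad_norm < tol
    coef = CoefficientVector(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        beta3=float(beta[3]),
        gamma=tuple(float(g) for g in beta[4:]),
        tag="dummy",
    )
    return LogisticFit(
        coefficients=coef,
        covariance=cov,
        log_likelihood=ll,
        converged=converged,
        n_iterations=it,
        diagnostics={"grad_norm": grad_norm},
    )


def fit_saturated_from_table(
    table: ContingencyTable2x4, continuity_correction: bool = False
) -> LogisticFit:
    """Closed-form saturated fit of a 2x4 case-control table.

    Coefficients are log cross-product ratios against the A0B0 cell and the
    covariance is the analytic inverse information of the saturated model.
    All eight cells must be positive; ``continuity_correction=True`` adds
    0.5 to every cell instead of raising (noted in diagnostics).
    """
    ca = np.asarray(table.cases, dtype=float)
    co = np.asarray(table.controls, dtype=float)
    diagnostics: dict = {}
    if (ca == 0).any() or (co == 0).any():
        if not continuity_correction:
            zeros = [
                f"{row}[{CATEGORY_LABELS[j]}]"
                for row, counts in (("cases", ca), ("controls", co))
                for j in range(4)
                if counts[j] == 0
            ]
            raise FitError(
                "zero cell(s) in table: " + ", ".join(zeros)
                + "; re-run with continuity_correction=True to add 0.5 to every cell"
            )
        ca = ca + 0.5
        co = co + 0.5
        diagnostics["continuity_correction"] = 0.5
    beta = np.log(ca[1:] * co[0] / (ca[0] * co[1:]))
    beta0 = math.log(ca[0] / co[0])
    # Inverse information via the cell log-odds lambda_j (independent, with
    # Var = 1/ca_j + 1/co_j): beta0 = lambda_0 and beta_j = lambda_j - lambda_0.
    base = 1.0 / ca[0] + 1.0 / co[0]
    cov = np.full((4, 4), base)
    cov[0, 1:] = cov[1:, 0] = -base
    for j in range(1, 4):
        cov[j, j] = base + 1.0 / ca[j] + 1.0 / co[j]
    ll = float(
        np.sum(ca * np.log(ca / (ca + co))) + np.sum(co * np.log(co / (ca + co)))
    )
    coef = CoefficientVector(
        beta0=beta0,
        beta1=float(beta[0]),
        beta2=float(beta[1]),
        beta3=float(beta[2]),
        tag="dummy",
    )
    return LogisticFit(
        coefficients=coef,
        covariance=cov,
        log_likelihood=ll,
        converged=True,
        n_iterations=0,
        diagnostics=diagnostics,
    )


def delta_gradient(measure: Measure, beta: np.ndarray) -> np.ndarray:
    """Gradient of the measure (RERI, AP, or lnS for S) wrt (beta1, beta2, beta3)."""
    b1, b2, b3 = beta
    measure = Measure(measure)
    if measure is Measure.RERI:
        return np.array([-math.exp(b1), -math.exp(b2), math.exp(b3)])
    if measure is Measure.AP:
        return np.array(
            [
                -math.exp(b1 - b3),
                -math.exp(b2 - b3),
                (math.exp(b1) + math.exp(b2) - 1.0) * math.exp(-b3),
            ]
        )
    d = math.exp(b1) + math.exp(b2) - 2.0
    return np.array(
        [-math.exp(b1) / d, -math.exp(b2) / d, math.exp(b3) / (math.exp(b3) - 1.0)]
    )


def delta_interval(
    fit: LogisticFit, measure: Measure | str, level: float = 0.95
) -> InteractionEstimate:
    """Delta-method Wald interval for one interaction measure.

    RERI and AP intervals are symmetric about the point estimate; the S
    interval is symmetric about lnS and exponentiated back.  Confounder
    coefficients are accounted for through the full-model covariance (the
    (beta1, beta2, beta3) block of the inverse information marginalises over
    them).
    """
    measure = Measure(measure)
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if not fit.converged:
        raise FitError("cannot build a delta interval from a non-converged fit")
    c = fit.coefficients.to_dummy()
    beta = np.array([c.beta1, c.beta2, c.beta3])
    m = interaction_measures(fit.coefficients.odds_ratios())
    if measure is Measure.S and m.s is None:
        raise FitError(f"S undefined at the point estimate: {m.s_undefined_reason}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    sigma = fit.interaction_covariance()
    g = delta_gradient(measure, beta)
    var = float(g @ sigma @ g)
    if var < 0 and var > -1e-12:
        var = 0.0
    se = math.sqrt(var)
    if measure is Measure.RERI:
        point, lo, hi = m.reri, m.reri - z * se, m.reri + z * se
    elif measure is Measure.AP:
        point, lo, hi = m.ap, m.ap - z * se, m.ap + z * se
    else:
        point = m.s
        lo, hi = math.exp(m.ln_s - z * se), math.exp(m.ln_s + z * se)
    return InteractionEstimate(
        measure=measure,
        point=float(point),
        lower=float(lo),
        upper=float(hi),
        level=level,
        method="delta",
        diagnostics={"se": se},
    )
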