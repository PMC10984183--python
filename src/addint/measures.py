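"""Additive-scale interaction measures for two binary factors.

Given relative risks (or, in a case-control design, odds ratios) of the
three non-reference joint exposure categories — RR10 (factor A alone),
RR01 (factor B alone) and RR11 (both factors) relative to the doubly
unexposed group — the three classical measures of interaction on the
additive scale are

    RERI = RR11 - RR10 - RR01 + 1
    AP   = RERI / RR11
    S    = (RR11 - 1) / (RR10 + RR01 - 2)

RERI and AP are zero and S is one under exact additivity of excess risks;
larger values indicate synergy, smaller values antagonism.  S is only
meaningful when both its numerator and denominator are positive, i.e. when
every factor combination carries excess risk relative to the reference;
outside that domain this module reports a tagged undefined value rather
than raising, so that resampled or posterior draws falling outside the
domain can be counted instead of aborting a run.

When a factor is preventive (relative risk below 1) the measures are made
meaningful by recoding so that the lowest-risk joint category becomes the
reference; :func:`recode_lowest_reference` performs this purely on the
coefficient scale (subtracting the minimal category coefficient), which is
algebraically identical to refitting the model with recoded factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "RelativeRiskTriple",
    "InteractionMeasures",
    "CoefficientVector",
    "RecodeMap",
    "compute_reri",
    "compute_ap",
    "compute_s",
    "interaction_measures",
    "measures_from_coefficients",
    "recode_lowest_reference",
    "measures_from_draws",
    "CATEGORY_LABELS",
]

#: Fixed order of the joint exposure categories used throughout the package.
CATEGORY_LABELS = ("A0B0", "A1B0", "A0B1", "A1B1")

#: Exposure pattern (a, b) of each category index.
_CATEGORY_PATTERNS = ((0, 0), (1, 0), (0, 1), (1, 1))

# For each possible new reference category r, the original category indices
# whose recoded labels are A1B0*, A0B1*, A1B1* (derived from a* = a XOR a_r,
# b* = b XOR b_r).
_RECODE_TRIPLE_INDEX = {0: (1, 2, 3), 1: (0, 3, 2), 2: (3, 0, 1), 3: (2, 1, 0)}


@dataclass(frozen=True)
class RelativeRiskTriple:
    """Relative risks (or odds-ratio surrogates) of the non-reference categories."""

    rr10: float
    rr01: float
    rr11: float

    def __post_init__(self) -> None:
        for name in ("rr10", "rr01", "rr11"):
            v = getattr(self, name)
            if math.isnan(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class InteractionMeasures:
    """RERI, AP and S (with lnS) for one relative-risk triple.

    ``s`` and ``ln_s`` are ``None`` when S is undefined (RR11 <= 1 or
    RR10 + RR01 <= 2); ``s_undefined_reason`` then explains why.
    """

    reri: float
    ap: float
    s: float | None
    ln_s: float | None = None
    s_undefined_reason: str | None = None


def compute_reri(rr: RelativeRiskTriple) -> float:
    """Relative excess risk due to interaction: RR11 - RR10 - RR01 + 1."""
    return rr.rr11 - rr.rr10 - rr.rr01 + 1.0


def compute_ap(rr: RelativeRiskTriple) -> float:
    """Attributable proportion due to interaction: RERI / RR11."""
    return compute_reri(rr) / rr.rr11


def compute_s(rr: RelativeRiskTriple) -> float | None:
    """Synergy index (RR11 - 1)/(RR10 + RR01 - 2), or ``None`` off-domain.

    S is defined only when both the excess risk of the doubly exposed group
    (RR11 - 1) and the summed single-factor excess risks (RR10 + RR01 - 2)
    are strictly positive.  Use :func:`s_undefined_reason` for a diagnostic.
    """
    if s_undefined_reason(rr) is not None:
        return None
    return (rr.rr11 - 1.0) / (rr.rr10 + rr.rr01 - 2.0)


def s_undefined_reason(rr: RelativeRiskTriple) -> str | None:
    """Explain why S is undefined for ``rr``, or ``None`` if it is defined."""
    reasons = []
    if rr.rr11 <= 1.0:
        reasons.append(f"RR11 = {rr.rr11:g} <= 1 (numerator non-positive)")
    if rr.rr10 + rr.rr01 - 2.0 <= 0.0:
        reasons.append(
            f"RR10 + RR01 - 2 = {rr.rr10 + rr.rr01 - 2.0:g} <= 0 "
            "(denominator non-positive)"
        )
    return "; ".join(reasons) or None


def interaction_measures(rr: RelativeRiskTriple) -> InteractionMeasures:
    """All three measures for one triple, with S's domain handled."""
    s = compute_s(rr)
    return InteractionMeasures(
        reri=compute_reri(rr),
        ap=compute_ap(rr),
        s=s,
        ln_s=None if s is None else math.log(s),
        s_undefined_reason=s_undefined_reason(rr),
    )


@dataclass(frozen=True)
class CoefficientVector:
    """Logistic-regression coefficients for the two-factor interaction model.

    Under ``tag='dummy'`` the linear predictor is
    ``beta0 + beta1*I(A1B0) + beta2*I(A0B1) + beta3*I(A1B1) + X @ gamma``,
    so OR10 = exp(beta1), OR01 = exp(beta2), OR11 = exp(beta3).

    Under ``tag='product'`` the slots hold the product-term coding
    ``eta0 + eta1*A + eta2*B + eta3*A*B + X @ gamma`` (OR11 =
    exp(eta1+eta2+eta3)); the two codings are a bijection because the model
    is saturated in the four exposure cells.
    """

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    gamma: tuple[float, ...] = field(default_factory=tuple)
    tag: Literal["dummy", "product"] = "dummy"

    def to_dummy(self) -> "CoefficientVector":
        """Convert to dummy (indicator) coding; identity if already dummy."""
        if self.tag == "dummy":
            return self
        return CoefficientVector(
            beta0=self.beta0,
            beta1=self.beta1,
            beta2=self.beta2,
            beta3=self.beta1 + self.beta2 + self.beta3,
            gamma=self.gamma,
            tag="dummy",
        )

    def category_coefficients(self) -> tuple[float, float, float, float]:
        """Coefficients of (A0B0, A1B0, A0B1, A1B1) relative to A0B0 (dummy)."""
        d = self.to_dummy()
        return (0.0, d.beta1, d.beta2, d.beta3)

    def odds_ratios(self) -> RelativeRiskTriple:
        d = self.to_dummy()
        return RelativeRiskTriple(
            rr10=math.exp(d.beta1), rr01=math.exp(d.beta2), rr11=math.exp(d.beta3)
        )


def measures_from_coefficients(theta: CoefficientVector) -> InteractionMeasures:
    """Exponentiate coefficients to odds ratios and apply the three measures."""
    return interaction_measures(theta.odds_ratios())


@dataclass(frozen=True)
class RecodeMap:
    """Record of a lowest-risk-reference recoding.

    ``flip_a``/``flip_b`` say whether the recoded factors are A* = 1 - A /
    B* = 1 - B; ``relabel`` maps each original category label to its label
    under the recoded factors.
    """

    reference: str
    flip_a: bool
    flip_b: bool
    relabel: dict[str, str]

    @property
    def identity(self) -> bool:
        return self.reference == "A0B0"


def recode_lowest_reference(
    theta: CoefficientVector,
) -> tuple[CoefficientVector, RecodeMap]:
    """Re-reference the model at the lowest-risk joint exposure category.

    Subtracts the smallest of the four category coefficients (the reference
    itself counting as 0) from all of them, which is equivalent to refitting
    the saturated model with the factors recoded so that the lowest-risk
    category is doubly unexposed.  The intercept absorbs the shift so fitted
    probabilities are unchanged.  Ties for the minimum prefer the original
    reference, then category order A1B0, A0B1, A1B1.
    """
    d = theta.to_dummy()
    coefs = d.category_coefficients()
    r = int(np.argmin(coefs))  # first minimum == the required tie-break order
    a_r, b_r = _CATEGORY_PATTERNS[r]
    relabel = {
        CATEGORY_LABELS[i]: f"A{a ^ a_r}B{b ^ b_r}"
        for i, (a, b) in enumerate(_CATEGORY_PATTERNS)
    }
    rmap = RecodeMap(
        reference=CATEGORY_LABELS[r], flip_a=bool(a_r), flip_b=bool(b_r),
        relabel=relabel,
    )
    if r == 0:
        return d, rmap
    i10, i01, i11 = _RECODE_TRIPLE_INDEX[r]
    shift = coefs[r]
    recoded = CoefficientVector(
        beta0=d.beta0 + shift,
        beta1=coefs[i10] - shift,
        beta2=coefs[i01] - shift,
        beta3=coefs[i11] - shift,
        gamma=d.gamma,
        tag="dummy",
    )
    return recoded, rmap


def measures_from_draws(
    beta: np.ndarray, recode: bool = False
) -> dict[str, np.ndarray]:
    """Vectorised measures for a matrix of coefficient draws.

    Parameters
    ----------
    beta
        Array of shape (n, 3) holding (beta1, beta2, beta3) per draw, dummy
        coding.
    recode
        If true, each draw is independently re-referenced at its own
        lowest-risk category before the measures are evaluated.

    Returns
    -------
    dict with float arrays ``"RERI"``, ``"AP"``, ``"S"`` of length n; S is
    NaN where undefined (its domain excludes that draw).
    """
    beta = np.asarray(beta, dtype=float)
    if beta.ndim != 2 or beta.shape[1] != 3:
        raise ValueError("beta must have shape (n, 3)")
    cat = np.column_stack([np.zeros(len(beta)), beta])  # (n, 4) category coefs
    if recode:
        r = np.argmin(cat, axis=1)
        shift = np.take_along_axis(cat, r[:, None], axis=1)
        cat = cat - shift
        idx = np.array([_RECODE_TRIPLE_INDEX[k] for k in range(4)])  # (4, 3)
        triple = np.take_along_axis(cat, idx[r], axis=1)
    else:
        triple = cat[:, 1:]
    with np.errstate(over="ignore"):
        or10, or01, or11 = np.exp(triple).T
    reri = or11 - or10 - or01 + 1.0
    ap = reri / or11
    num = or11 - 1.0
    den = or10 + or01 - 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where((num > 0) & (den > 0), num / den, np.nan)
    return {"RERI": reri, "AP": ap, "S": s}
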