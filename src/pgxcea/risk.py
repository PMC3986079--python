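"""Genotype-conditional incidence algebra and screening-test predictive values.

The model observes three population-level quantities: the marginal incidence
``Ia`` of allopurinol-induced SJS/TEN among treated patients, the prevalence
``P`` of the HLA-B*5801 risk allele, and an association measure between
carriage and disease.  What the decision tree needs are the conditional
incidences ``i1`` (carriers) and ``i0`` (non-carriers).  Two decompositions
are provided:

``split_incidence_by_genotype``
    Treats the association strictly as an odds ratio and solves the exact
    two-constraint system

        Ia = P * i1 + (1 - P) * i0
        OR = [i1 / (1 - i1)] / [i0 / (1 - i0)]

    by bracketed root-finding on ``i0``.

``split_incidence_risk_ratio``
    Treats the association as a risk ratio, giving the closed form
    ``i0 = Ia / ((1 - P) + P * R)`` and ``i1 = R * i0``.  This is the
    pipeline default (``association_form="risk_ratio"``): it is the algebra
    the reference cost accounting is consistent with, and for rare events
    the two forms agree closely.

Predictive values of the genotyping assay follow from Bayes' rule on the
2x2 confusion table; degenerate 0/0 cases return ``None`` rather than a
number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy.optimize import brentq

__all__ = [
    "IncidenceSplit",
    "PredictiveValues",
    "split_incidence_by_genotype",
    "split_incidence_risk_ratio",
    "incidence_split",
    "predictive_values",
]


@dataclass(frozen=True)
class IncidenceSplit:
    """Conditional SJS/TEN incidences: ``i1`` carriers, ``i0`` non-carriers."""

    i1: float
    i0: float


@dataclass(frozen=True)
class PredictiveValues:
    """Bayesian test characteristics at a given prevalence.

    ``ppv``/``npv`` are ``None`` when the corresponding denominator is zero
    (no positive or no negative tests occur).
    """

    ppv: Optional[float]
    npv: Optional[float]
    p_test_positive: float
    p_test_negative: float


def split_incidence_by_genotype(ia: float, p: float, odds_ratio: float) -> IncidenceSplit:
    """Solve the exact odds-ratio constraint system for (i1, i0).

    Solved by bracketed root-finding on ``i0`` in ``(0, min(1, Ia/(1-P)))``;
    both defining equations hold at the root to ~1e-12 absolute.

    Raises ``ValueError`` on invalid inputs or when no root exists in the
    bracket (inconsistent Ia/P/OR combination).
    """
    if not 0.0 < ia < 1.0:
        raise ValueError(f"marginal incidence must lie in (0, 1), got {ia!r}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"prevalence must lie in (0, 1), got {p!r}")
    if odds_ratio <= 0.0:
        raise ValueError(f"odds ratio must be > 0, got {odds_ratio!r}")

    def i1_of(i0: float) -> float:
        # odds_1 = OR * odds_0, mapped back to a risk
        return odds_ratio * i0 / (1.0 + (odds_ratio - 1.0) * i0)

    def marginal_gap(i0: float) -> float:
        return p * i1_of(i0) + (1.0 - p) * i0 - ia

    hi = min(1.0 - 1e-15, ia / (1.0 - p))
    lo = 1e-300
    if marginal_gap(hi) < 0.0:
        raise ValueError(
            f"no genotype split satisfies Ia={ia!r}, P={p!r}, OR={odds_ratio!r}"
        )
    i0 = brentq(marginal_gap, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    return IncidenceSplit(i1=i1_of(i0), i0=i0)


def split_incidence_risk_ratio(ia: float, p: float, risk_ratio: float) -> IncidenceSplit:
    """Closed-form split treating the association as a risk ratio."""
    if not 0.0 < ia < 1.0:
        raise ValueError(f"marginal incidence must lie in (0, 1), got {ia!r}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"prevalence must lie in (0, 1), got {p!r}")
    if risk_ratio <= 0.0:
        raise ValueError(f"risk ratio must be > 0, got {risk_ratio!r}")
    i0 = ia / ((1.0 - p) + p * risk_ratio)
    i1 = risk_ratio * i0
    if i1 > 1.0:
        raise ValueError(
            f"risk-ratio split yields carrier incidence {i1!r} > 1 "
            f"(Ia={ia!r}, P={p!r}, R={risk_ratio!r})"
        )
    return IncidenceSplit(i1=i1, i0=i0)


def incidence_split(ia: float, p: float, association: float, form: str = "risk_ratio") -> IncidenceSplit:
    """Dispatch on the association interpretation (``risk_ratio``/``odds_ratio``).

    Degenerate edges the decision tree still needs: no events at all
    (``ia = 0``) gives a zero split, and an allele-free population
    (``p = 0``) carries the whole marginal incidence in non-carriers (the
    carrier incidence is then a counterfactual, capped at 1).
    """
    if ia == 0.0:
        return IncidenceSplit(i1=0.0, i0=0.0)
    if p == 0.0:
        if form == "odds_ratio":
            odds1 = association * ia / (1.0 - ia)
            return IncidenceSplit(i1=odds1 / (1.0 + odds1), i0=ia)
        return IncidenceSplit(i1=min(1.0, association * ia), i0=ia)
    if form == "risk_ratio":
        return split_incidence_risk_ratio(ia, p, association)
    if form == "odds_ratio":
        return split_incidence_by_genotype(ia, p, association)
    raise ValueError(f"unknown association form {form!r}")


def predictive_values(p: float, s: float, sp: float) -> PredictiveValues:
    """PPV, NPV and marginal test-result probabilities.

    ``ppv = S*P / (S*P + (1-Sp)(1-P))`` and
    ``npv = Sp(1-P) / (Sp(1-P) + (1-S)P)``; a zero denominator yields
    ``None`` for that predictive value.
    """
    for name, v in (("prevalence", p), ("sensitivity", s), ("specificity", sp)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
    true_pos = s * p
    false_pos = (1.0 - sp) * (1.0 - p)
    true_neg = sp * (1.0 - p)
    false_neg = (1.0 - s) * p
    p_pos = true_pos + false_pos
    p_neg = 1.0 - p_pos
    ppv = true_pos / p_pos if p_pos > 0.0 else None
    npv = true_neg / (true_neg + false_neg) if (true_neg + false_neg) > 0.0 else None
    return PredictiveValues(ppv=ppv, npv=npv, p_test_positive=p_pos, p_test_negative=p_neg)
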