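"""Partial credit (polytomous Rasch) model engine.

The model gives person ``n`` with location ``beta`` (logits) probability

    P(X_i = x) ∝ exp( -τ_1i - τ_2i - ... - τ_xi + x (beta - δ_i) )

of scoring ``x`` on item ``i`` with location ``δ_i`` and centered
thresholds ``τ_ki`` (the ``x = 0`` weight is 1).  A dichotomous item is the
special case of one threshold fixed at 0, recovering the basic Rasch model
``P = exp(beta - δ) / (1 + exp(beta - δ))``.

The raw total score is a sufficient statistic for ``beta``, so person
estimation reduces to solving ``E[total | beta] = raw score`` on the
strictly increasing expected-score curve; the standard error is
``1/sqrt(I(beta))`` with ``I`` the Fisher information (the total score
variance).  Persons scoring 0 or the maximum have infinite maximum
likelihood locations; they are handled by re-estimating at a pseudo-score a
small ``epsilon`` inside the range, and flagged as extreme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .transform import ScoreLogitRow, ScoreLogitTable

__all__ = [
    "ItemCalibration",
    "Instrument",
    "PersonLocation",
    "category_probabilities",
    "expected_score_and_information",
    "estimate_person",
    "extreme_adjustment",
    "score_to_logit_table",
]

_CENTER_TOL = 1e-9


@dataclass(frozen=True)
class ItemCalibration:
    """One polytomous item: location ``delta`` and centered thresholds.

    ``thresholds`` are the ``m_i`` points dividing the latent continuum into
    ``m_i + 1`` ordered categories, expressed as deviations from ``delta``
    (they must sum to 0).  Users whose calibrations express thresholds as
    absolute locations ``delta + tau`` should subtract the item location
    first.
    """

    delta: float
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.thresholds) < 1:
            raise ValueError("an item needs at least one threshold")
        total = sum(self.thresholds)
        if abs(total) > _CENTER_TOL:
            raise ValueError(
                f"thresholds must be centered (sum 0), got sum {total!r}"
            )

    @property
    def max_score(self) -> int:
        return len(self.thresholds)

    def category_exponents(self, beta: float) -> np.ndarray:
        """Unnormalized log-weights for categories 0..m_i."""
        tau = np.concatenate(([0.0], np.asarray(self.thresholds)))
        x = np.arange(self.max_score + 1)
        return -np.cumsum(tau) + x * (beta - self.delta)


@dataclass(frozen=True)
class Instrument:
    """A fixed set of calibrated items defining a scale with max score L."""

    items: tuple[ItemCalibration, ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("an instrument needs at least one item")

    @property
    def L(self) -> int:
        return sum(item.max_score for item in self.items)


@dataclass(frozen=True)
class PersonLocation:
    """Estimated person location with its standard error.

    ``is_extreme`` marks raw scores 0 and L, whose locations are
    extrapolated from a pseudo-score rather than directly measured.
    """

    beta: float
    se: float
    raw_score: int
    is_extreme: bool


def category_probabilities(beta: float, item: ItemCalibration) -> np.ndarray:
    """Probabilities of scoring 0..m_i on one item at person location beta."""
    expo = item.category_exponents(beta)
    w = np.exp(expo - expo.max())  # max-shift keeps exp() in range
    return w / w.sum()


def _item_moments(beta: float, item: ItemCalibration) -> tuple[float, float]:
    p = category_probabilities(beta, item)
    x = np.arange(item.max_score + 1)
    mean = float(p @ x)
    var = float(p @ (x - mean) ** 2)
    return mean, var


def expected_score_and_information(
    beta: float, instrument: Instrument
) -> tuple[float, float]:
    """Expected raw total score and Fisher information at ``beta``.

    The information equals the total score variance (sum of per-item
    category variances), which is also the derivative of the expected score
    in ``beta`` — hence the expected score is strictly increasing.
    """
    means, variances = zip(*(_item_moments(beta, item) for item in instrument.items))
    return float(sum(means)), float(sum(variances))


def _solve_score(
    target: float,
    instrument: Instrument,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[float, float]:
    """Solve E[total|beta] = target by safeguarded Newton-Raphson.

    Falls back to Brent bracketing if Newton leaves the bracket or stalls.
    Returns (beta, information at beta).
    """
    L = instrument.L
    if not (0.0 < target < L):
        raise ValueError(f"target score must lie strictly inside (0, {L}), got {target}")

    def f(b: float) -> float:
        return expected_score_and_information(b, instrument)[0] - target

    # bracket the root; the expected score is monotone in beta
    lo, hi = -10.0, 10.0
    while f(lo) > 0 and lo > -700:
        lo *= 2
    while f(hi) < 0 and hi < 700:
        hi *= 2
    if f(lo) > 0 or f(hi) < 0:
        raise RuntimeError(
            f"could not bracket the ML solution for target {target} in [{lo}, {hi}]"
        )

    beta = math.log(target / (L - target))  # logistic start on the right scale
    beta = min(max(beta, lo), hi)
    for _ in range(max_iter):
        exp_score, info = expected_score_and_information(beta, instrument)
        resid = exp_score - target
        if abs(resid) < tol:
            return beta, info
        step = resid / info
        nxt = beta - step
        if not (lo < nxt < hi):
            break
        beta = nxt
    beta = brentq(f, lo, hi, xtol=tol)
    return beta, expected_score_and_information(beta, instrument)[1]


def estimate_person(
    raw_score: int,
    instrument: Instrument,
    *,
    adjust_extremes: bool = True,
    epsilon: float = 0.3,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> PersonLocation:
    """Maximum likelihood person location for a raw total score.

    Non-extreme scores solve the sufficient-statistic equation
    ``E[total|beta] = raw_score``; the SE is ``1/sqrt(information)``.
    Raw scores 0 and L have infinite ML locations: with
    ``adjust_extremes=True`` (default) they are re-estimated at a
    pseudo-score ``epsilon`` inside the range, otherwise returned as
    non-finite and flagged.
    """
    L = instrument.L
    if not 0 <= raw_score <= L:
        raise ValueError(f"raw score must be in 0..{L}, got {raw_score}")
    if raw_score in (0, L):
        if not adjust_extremes:
            sign = -1.0 if raw_score == 0 else 1.0
            return PersonLocation(
                beta=sign * math.inf, se=math.inf, raw_score=raw_score, is_extreme=True
            )
        return extreme_adjustment(
            raw_score, instrument, epsilon=epsilon, tol=tol, max_iter=max_iter
        )
    beta, info = _solve_score(float(raw_score), instrument, tol=tol, max_iter=max_iter)
    return PersonLocation(
        beta=beta, se=1.0 / math.sqrt(info), raw_score=raw_score, is_extreme=False
    )


def extreme_adjustment(
    raw_score: int,
    instrument: Instrument,
    epsilon: float = 0.3,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> PersonLocation:
    """Finite location for an extreme raw score via a pseudo-score.

    A raw score of 0 is estimated at ``epsilon`` and a raw score of L at
    ``L - epsilon`` (0 < epsilon < 1), giving finite extrapolated locations
    and SEs so persons at the floor or ceiling can be carried through
    further analysis.  Different estimation packages use different
    conventions for the pseudo-score; ``epsilon`` makes the choice explicit.
    """
    L = instrument.L
    if raw_score not in (0, L):
        raise ValueError(f"extreme adjustment applies to raw scores 0 and {L} only")
    if not 0 < epsilon < 1:
        raise ValueError(f"epsilon must lie in (0, 1), got {epsilon}")
    target = epsilon if raw_score == 0 else L - epsilon
    beta, info = _solve_score(target, instrument, tol=tol, max_iter=max_iter)
    return PersonLocation(
        beta=beta, se=1.0 / math.sqrt(info), raw_score=raw_score, is_extreme=True
    )


def score_to_logit_table(
    instrument: Instrument,
    *,
    epsilon: float = 0.3,
    tol: float = 1e-8,
) -> ScoreLogitTable:
    """Raw-score -> logit conversion table for every score 0..L.

    Extreme scores are extrapolated with the ``epsilon`` pseudo-score so the
    table is complete; SEs grow toward the ends of the score range on
    well-targeted instruments.
    """
    rows = []
    for raw in range(instrument.L + 1):
        loc = estimate_person(
            raw, instrument, adjust_extremes=True, epsilon=epsilon, tol=tol
        )
        rows.append(
            ScoreLogitRow(
                raw_score=raw, logit=loc.beta, se=loc.se, is_extreme=loc.is_extreme
            )
        )
    return ScoreLogitTable(tuple(rows))
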