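"""Closed-form stable-model probabilities.

Conditioning on the binary indicator ``D`` (D = 1 iff clinical onset falls
inside the program window ``(t0, T)``), the proportion of clinical cases
with zero lead time — the *interval cases*, diagnosed symptomatically
between exams — is

    P(L = 0 | D = 1) = P(L = 0, D = 1) / P(D = 1),

where the joint probability decomposes over the inter-exam interval in
which the woman turns clinical:

    P(L = 0, D = 1) = sum_{j=1}^{K} I_{K,j}.

``I_{K,j}`` is the probability of becoming an interval case in
``(t_{j-1}, t_j)``.  With onset hazard constant at ``w`` per year
(realized as onset-age density ``w`` on ``(0, T)``) and Exp(``lam``)
sojourn, each ``I_{K,j}`` is a sum of three onset cases:

* onset before the first exam ``t0`` — the woman is preclinical at all
  ``j`` exams preceding her clinical onset, so a factor ``(1-beta)^j``;
* onset in an earlier interval ``(t_{i-1}, t_i)``, ``i < j`` — she misses
  the ``j - i`` exams ``t_i .. t_{j-1}``;
* onset in ``(t_{j-1}, t_j)`` itself — no exam intervenes before onset of
  symptoms.

Each case integrates the onset density against the exponential sojourn in
closed form; see ``docs/methods.md`` for the derivation.  The conditional
proportion is independent of ``w`` (every term is proportional to it) and
depends only on ``beta``, ``lam`` and ``delta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ScreeningSchedule, StableDiseaseParams, ValidationError

__all__ = [
    "IntervalCaseProbs",
    "interval_case_prob",
    "interval_case_probs",
    "prob_zero_lead_joint",
    "prob_clinical_before_T",
    "prob_no_benefit",
    "prob_benefit",
]


@dataclass(frozen=True)
class IntervalCaseProbs:
    """Interval-case probabilities ``I_{K,j}`` for j = 1..K and their sum."""

    probs: np.ndarray
    total: float


def interval_case_prob(
    params: StableDiseaseParams, sched: ScreeningSchedule, j: int
) -> float:
    """Probability ``I_{K,j}`` of becoming an interval case in interval j.

    Interval j is ``(t_{j-1}, t_j)`` with ``t_j = t0 + j*delta`` and
    ``t_K = T``; indices run 1..K.
    """
    if not 1 <= j <= sched.K:
        raise IndexError(f"interval index j={j} out of range 1..{sched.K}")
    w, beta, lam = params.w, params.beta, params.lam
    d = sched.delta
    t_jm1 = sched.t0 + (j - 1) * d
    t_j = sched.t0 + j * d

    # Onset before t0: preclinical at (and missed by) all j exams t_0..t_{j-1}.
    term1 = (
        w
        * lam
        * (1.0 - beta) ** j
        * (
            np.exp(-(j - 1) * d / lam)
            - np.exp(-t_jm1 / lam)
            - np.exp(-j * d / lam)
            + np.exp(-t_j / lam)
        )
    )
    # Onset in an earlier interval (t_{i-1}, t_i): misses the j-i exams t_i..t_{j-1}.
    k = np.arange(1, j)  # k = j - i
    term2 = w * lam * np.sum(
        (1.0 - beta) ** k
        * (
            np.exp(-(k - 1) * d / lam)
            - 2.0 * np.exp(-k * d / lam)
            + np.exp(-(k + 1) * d / lam)
        )
    )
    # Onset inside (t_{j-1}, t_j): no exam before clinical onset.
    term3 = w * d + w * lam * np.expm1(-d / lam)
    return float(term1 + term2 + term3)


def interval_case_probs(
    params: StableDiseaseParams, sched: ScreeningSchedule
) -> IntervalCaseProbs:
    """All ``I_{K,j}`` for j = 1..K, with their sum ``P(L=0, D=1)``."""
    probs = np.array(
        [interval_case_prob(params, sched, j) for j in range(1, sched.K + 1)]
    )
    return IntervalCaseProbs(probs=probs, total=float(probs.sum()))


def prob_zero_lead_joint(
    params: StableDiseaseParams, sched: ScreeningSchedule
) -> float:
    """Joint probability ``P(L = 0, D = 1)`` of being an interval case."""
    return interval_case_probs(params, sched).total


def prob_clinical_before_T(
    params: StableDiseaseParams, sched: ScreeningSchedule
) -> float:
    """``P(D = 1)``: probability clinical onset falls in ``(t0, T)``.

    Equals ``w(T - t0) + w*lam*(e^{-T/lam} - e^{-t0/lam})`` — the constant
    onset density ``w`` on ``(0, T)`` convolved with the exponential
    sojourn.
    """
    w, lam = params.w, params.lam
    t0, T = sched.t0, sched.T
    return float(w * (T - t0) + w * lam * (np.exp(-T / lam) - np.exp(-t0 / lam)))


def prob_no_benefit(params: StableDiseaseParams, sched: ScreeningSchedule) -> float:
    """``P = P(L = 0 | D = 1)``: clinical cases screening cannot advance.

    Independent of the transition rate ``w``; a function of ``beta``,
    ``lam`` and ``delta`` only.
    """
    denom = prob_clinical_before_T(params, sched)
    if denom <= 0.0:
        raise ValidationError(
            "P(D=1) is zero for this program; the conditional proportion "
            "P(L=0 | D=1) is undefined"
        )
    return prob_zero_lead_joint(params, sched) / denom


def prob_benefit(params: StableDiseaseParams, sched: ScreeningSchedule) -> float:
    """``Q = 1 - P``: proportion of clinical cases with positive lead time."""
    return 1.0 - prob_no_benefit(params, sched)
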