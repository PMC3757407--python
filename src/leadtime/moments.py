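"""Analytic moments of the zero-inflated lead-time distribution.

The positive part of the lead-time law is built from *detection weights*:
``weight_i`` is the joint density-mass of being screen-detected for the
first time at exam age ``t_i`` while still preclinical.  Conditional on
first detection at ``t_i``, the residual sojourn ``T2 - t_i`` is again
Exp(lam) by memorylessness, and restricting to clinical onset before the
horizon truncates it to ``(0, T - t_i)``.  The lead time of such a case is
exactly that truncated residual, so all moments over the D=1 group follow
from the weights and truncated-exponential moments — a deterministic twin
of the Monte-Carlo simulator.
"""

from __future__ import annotations

import numpy as np

from .closed_form import prob_clinical_before_T, prob_zero_lead_joint
from .params import ScreeningSchedule, StableDiseaseParams
from .summary import LeadTimeSummary

__all__ = [
    "detection_weight_at_exam",
    "detection_weights",
    "analytic_mean_sd",
]


def detection_weight_at_exam(
    params: StableDiseaseParams, sched: ScreeningSchedule, i: int
) -> float:
    """Joint mass of {first screen detection at exam ``t_i``, preclinical at ``t_i``}.

    Integrates the constant onset density ``w`` over onset ages in
    ``(0, t_i]`` with a miss factor ``(1 - beta)`` per intervening exam and
    sojourn survival ``e^{-(t_i - u)/lam}``, times the hit probability
    ``beta`` at exam i.  Exam indices run 0..K-1.
    """
    if not 0 <= i <= sched.K - 1:
        raise IndexError(f"exam index i={i} out of range 0..{sched.K - 1}")
    w, beta, lam = params.w, params.beta, params.lam
    d = sched.delta
    t_i = sched.t0 + i * d

    # Onset before the first exam: misses exams 0..i-1 (i of them).
    acc = (1.0 - beta) ** i * (np.exp(-i * d / lam) - np.exp(-t_i / lam))
    # Onset in (t_{m-1}, t_m) for m = 1..i: misses the i-m exams t_m..t_{i-1}.
    m = np.arange(1, i + 1)
    acc += np.sum(
        (1.0 - beta) ** (i - m)
        * (np.exp(-(i - m) * d / lam) - np.exp(-(i - m + 1) * d / lam))
    )
    return float(beta * w * lam * acc)


def detection_weights(
    params: StableDiseaseParams, sched: ScreeningSchedule
) -> np.ndarray:
    """Vector of detection weights for exams 0..K-1."""
    return np.array(
        [detection_weight_at_exam(params, sched, i) for i in range(sched.K)]
    )


def analytic_mean_sd(
    params: StableDiseaseParams, sched: ScreeningSchedule
) -> LeadTimeSummary:
    """Exact P, Q, mean, SD and mean/lam of the lead time over D=1 cases.

    Zeros (interval cases) are included in the mean and SD, matching the
    convention that the lead-time distribution describes the whole
    clinical group.
    """
    lam = params.lam
    p_d1 = prob_clinical_before_T(params, sched)
    p_zero = prob_zero_lead_joint(params, sched)

    weights = detection_weights(params, sched)
    tau = sched.T - sched.exam_ages  # truncation horizons T - t_i
    e = np.exp(-tau / lam)

    # Truncated-exponential partial moments: E[R 1{R < tau}], E[R^2 1{R < tau}].
    m1_part = lam * (1.0 - e) - tau * e
    m2_part = 2.0 * lam**2 - e * (tau**2 + 2.0 * lam * tau + 2.0 * lam**2)

    p_positive = float(np.sum(weights * (1.0 - e)))
    # Conservation: screen-detected-within-horizon mass + interval-case mass
    # must exhaust P(D=1).  Guards the weight algebra against regression.
    if not np.isclose(p_positive + p_zero, p_d1, rtol=1e-10, atol=1e-14):
        raise AssertionError(
            f"detection weights violate conservation: {p_positive + p_zero} != {p_d1}"
        )

    mean = float(np.sum(weights * m1_part)) / p_d1
    second = float(np.sum(weights * m2_part)) / p_d1
    var = max(second - mean**2, 0.0)
    P = min(max(p_zero / p_d1, 0.0), 1.0)  # clamp away 1-ulp overshoot
    return LeadTimeSummary(
        P=P, Q=1.0 - P, mean=mean, sd=float(np.sqrt(var)), ratio=mean / lam
    )
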