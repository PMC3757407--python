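"""Parameter containers for the stable disease model and screening schedule.

The natural-history model has three states: disease-free (S0), preclinical
(Sp, screen-detectable but asymptomatic) and clinical (Sc, symptomatic).
Under the *stable* model the S0 -> Sp transition rate ``w`` (per year), the
exam sensitivity ``beta`` and the sojourn-time distribution (exponential
with mean ``lam`` years) are all independent of age.

A screening program offers exams at ages ``t0, t0 + delta, ...`` every
``delta`` years until the program horizon ``T``; the program length must be
an integer number ``K`` of inter-exam intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = [
    "ValidationError",
    "ScheduleError",
    "StableDiseaseParams",
    "ScreeningSchedule",
]

#: Yearly S0 -> Sp transition probability: a lifetime risk bound of 0.20
#: spread over the 50 ages (30-80) at which onset is considered possible.
DEFAULT_TRANSITION_RATE = 0.004

# Relative slack when checking that (T - t0) / delta is an integer.
_K_ROUNDTRIP_RTOL = 1e-9


class ValidationError(ValueError):
    """Invalid disease or program parameters."""


class ScheduleError(ValidationError):
    """Invalid screening schedule (e.g. interval does not divide the span)."""


@dataclass(frozen=True)
class StableDiseaseParams:
    """Age-independent disease and exam parameters.

    Parameters
    ----------
    w : float
        Yearly probability of transition from the disease-free state into
        the preclinical state; must be positive.
    beta : float
        Exam sensitivity: probability that a single screening exam detects
        disease given the woman is in the preclinical state, in [0, 1].
    lam : float
        Mean preclinical sojourn time in years (exponential), positive.
    """

    w: float = DEFAULT_TRANSITION_RATE
    beta: float = 1.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        if not (self.w > 0 and np.isfinite(self.w)):
            raise ValidationError(f"transition rate w must be positive, got {self.w}")
        if not (0.0 <= self.beta <= 1.0):
            raise ValidationError(f"sensitivity beta must lie in [0, 1], got {self.beta}")
        if not (self.lam > 0 and np.isfinite(self.lam)):
            raise ValidationError(f"mean sojourn time lam must be positive, got {self.lam}")


@dataclass(frozen=True)
class ScreeningSchedule:
    """Equally-spaced screening exams from age ``t0`` to horizon ``T``.

    Exams are offered at ages ``t_i = t0 + i * delta`` for ``i = 0..K-1``
    with ``K = (T - t0) / delta`` intervals; the inter-exam intervals are
    ``(t_{j-1}, t_j)`` for ``j = 1..K`` with ``t_K = T``.  An additional
    exam at age ``T`` itself would be irrelevant to every quantity that
    conditions on clinical onset before ``T``: a detection at ``T`` implies
    clinical onset after the horizon.

    Parameters
    ----------
    t0 : float
        Age at the first exam, years.
    T : float
        End-of-program age, years; must exceed ``t0``.
    delta : float
        Inter-exam interval in years; must divide ``T - t0`` exactly.
    """

    t0: float
    T: float
    delta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t0) and self.t0 >= 0):
            raise ScheduleError(f"first-exam age t0 must be nonnegative, got {self.t0}")
        if not self.T > self.t0:
            raise ScheduleError(
                f"program horizon T={self.T} must exceed the first-exam age t0={self.t0}"
            )
        if not (self.delta > 0 and np.isfinite(self.delta)):
            raise ScheduleError(f"exam interval delta must be positive, got {self.delta}")
        span = self.T - self.t0
        k = round(span / self.delta)
        if k < 1 or abs(k * self.delta - span) > _K_ROUNDTRIP_RTOL * max(1.0, span):
            raise ScheduleError(
                f"interval delta={self.delta} must divide the program span "
                f"T - t0 = {span} into a whole number of intervals"
            )

    @cached_property
    def K(self) -> int:
        """Number of inter-exam intervals (= number of exams)."""
        return round((self.T - self.t0) / self.delta)

    @cached_property
    def exam_ages(self) -> np.ndarray:
        """Ages ``t_i = t0 + i*delta`` of the K exams, strictly increasing."""
        return self.t0 + np.arange(self.K) * self.delta

    @cached_property
    def interval_endpoints(self) -> np.ndarray:
        """Right endpoints ``t_j = t0 + j*delta`` for j = 1..K (t_K = T)."""
        return self.t0 + np.arange(1, self.K + 1) * self.delta
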