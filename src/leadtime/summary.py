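"""Shared summary container for one (parameter set, interval) cell."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class LeadTimeSummary:
    """Moments of the zero-inflated lead-time distribution for D=1 cases.

    The lead-time law is a mixture: a point mass ``P`` at zero (interval
    cases) and a continuous positive part (screen-detected cases).  Mean
    and SD are taken over the *whole* clinical group, zeros included.

    Attributes
    ----------
    P, Q : float
        Proportions of clinical (D=1) cases with zero / positive lead time.
    mean, sd : float
        Mean and standard deviation of the lead time in years.
    ratio : float
        ``mean / lam`` — mean lead time over mean sojourn time; a
        scale-free effectiveness indicator, always below 1 because a
        lead time can never exceed its sojourn time.
    se_p, se_mean, se_sd : float or None
        Monte-Carlo standard errors when the summary is empirical.
    n : int or None
        Number of cases behind an empirical summary.
    """

    P: float
    Q: float
    mean: float
    sd: float
    ratio: float
    se_p: float | None = field(default=None, compare=False)
    se_mean: float | None = field(default=None, compare=False)
    se_sd: float | None = field(default=None, compare=False)
    n: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.P <= 1.0 and 0.0 <= self.Q <= 1.0):
            raise ValueError(f"P={self.P} and Q={self.Q} must be probabilities")
        if abs(self.P + self.Q - 1.0) > 1e-9:
            raise ValueError(f"P + Q must equal 1, got {self.P + self.Q}")
        if self.mean < 0 or self.sd < 0:
            raise ValueError("mean and sd must be nonnegative")
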