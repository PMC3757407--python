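"""Monte-Carlo natural-history simulator for the stable disease model.

Each simulated woman gets a preclinical-onset age drawn uniformly on
``(0, T)`` (the constant-hazard onset realized as a flat density — only
the shape matters for D=1-conditional quantities, and the constant ``w``
rescales the acceptance rate), an Exp(lam) sojourn, and independent
Bernoulli(beta) detection attempts at every scheduled exam that falls
inside her preclinical window.  Cases whose clinical onset age lands in
``(t0, T)`` form the D=1 group over which lead-time summaries are taken;
rejection sampling on that event realizes the conditional law exactly,
with no importance weights.

The cohort path draws the first successful exam directly from a
geometric(beta) variable — distributionally identical to per-exam
Bernoulli draws, and vectorizable; `simulate_case` performs the literal
per-exam coin flips.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ScreeningSchedule, StableDiseaseParams, ValidationError
from .summary import LeadTimeSummary

__all__ = [
    "SimulatedCase",
    "CohortConfig",
    "CohortResult",
    "simulate_case",
    "simulate_cohort",
    "empirical_summary",
]

CASE_COLUMNS = (
    "onset_age",
    "sojourn",
    "clinical_age",
    "detection_age",
    "lead_time",
    "d_indicator",
)


@dataclass(frozen=True)
class SimulatedCase:
    """One woman's latent disease history and realized lead time.

    ``detection_age`` is ``None`` when no exam detected her; then the lead
    time is zero.  ``d_indicator`` is 1 iff clinical onset falls in
    ``(t0, T)``; screen-detected women whose clinical onset would occur
    after the horizon carry ``d_indicator = 0`` and are excluded from D=1
    summaries.
    """

    onset_age: float
    sojourn: float
    clinical_age: float
    detection_age: float | None
    lead_time: float
    d_indicator: int


@dataclass(frozen=True)
class CohortConfig:
    """Reproducible recipe for one simulated cohort of accepted D=1 cases."""

    params: StableDiseaseParams
    sched: ScreeningSchedule
    n_cases: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValidationError(f"n_cases must be >= 1, got {self.n_cases}")


@dataclass(frozen=True)
class CohortResult:
    """Accepted D=1 cases plus the raw-draw record behind them."""

    cases: pd.DataFrame
    n_raw: int
    config: CohortConfig

    @property
    def empirical_prob_clinical(self) -> float:
        """Empirical P(D=1): acceptance rate rescaled from the uniform
        onset density 1/T back to the model's density w."""
        p = self.config.params
        s = self.config.sched
        return len(self.cases) / self.n_raw * p.w * s.T

    def to_csv(self, path: str | Path) -> None:
        """One row per simulated woman, plain delimited text."""
        self.cases.to_csv(path, index=False)


def simulate_case(
    params: StableDiseaseParams,
    sched: ScreeningSchedule,
    rng: np.random.Generator,
) -> SimulatedCase:
    """Draw one unconditioned disease history (any D)."""
    onset = rng.uniform(0.0, sched.T)
    sojourn = rng.exponential(params.lam)
    clinical = onset + sojourn
    detection: float | None = None
    for t_i in sched.exam_ages:
        if t_i < onset or t_i >= clinical:
            continue  # not yet preclinical, or already symptomatic
        if rng.uniform() < params.beta:
            detection = float(t_i)
            break
    d = int(sched.t0 < clinical < sched.T)
    lead = clinical - detection if (detection is not None and d == 1) else 0.0
    if detection is not None and d == 0:
        # Screen-detected but clinical onset beyond the horizon: outside the
        # D=1 group; the detection age is kept, the lead time is not defined
        # within the program comparison and is recorded as 0.
        lead = 0.0
    return SimulatedCase(
        onset_age=float(onset),
        sojourn=float(sojourn),
        clinical_age=float(clinical),
        detection_age=detection,
        lead_time=float(lead),
        d_indicator=d,
    )


def _simulate_batch(
    params: StableDiseaseParams,
    sched: ScreeningSchedule,
    rng: np.random.Generator,
    m: int,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw m raw histories; return the accepted (D=1) ones and their raw positions."""
    t0, T, d, K = sched.t0, sched.T, sched.delta, sched.K
    onset = rng.uniform(0.0, T, m)
    sojourn = rng.exponential(params.lam, m)
    clinical = onset + sojourn
    acc = (clinical > t0) & (clinical < T)
    positions = np.nonzero(acc)[0]
    onset, sojourn, clinical = onset[acc], sojourn[acc], clinical[acc]
    n = onset.size

    # Exams eligible to detect: t_i >= onset (ceil) and t_i < clinical.
    i_start = np.maximum(0, np.ceil((onset - t0) / d)).astype(np.int64)
    i_end = np.minimum(np.ceil((clinical - t0) / d).astype(np.int64), K)
    n_elig = np.maximum(0, i_end - i_start)

    detection_age = np.full(n, np.nan)
    lead = np.zeros(n)
    if params.beta > 0.0 and n > 0:
        # First success among the eligible exams via a geometric draw.
        g = rng.geometric(params.beta, n)
        hit = g <= n_elig
        det = t0 + (i_start + g - 1) * d
        detection_age[hit] = det[hit]
        lead[hit] = clinical[hit] - det[hit]

    frame = pd.DataFrame(
        {
            "onset_age": onset,
            "sojourn": sojourn,
            "clinical_age": clinical,
            "detection_age": detection_age,
            "lead_time": lead,
            "d_indicator": np.ones(n, dtype=np.int64),
        }
    )
    return frame, positions


def simulate_cohort(config: CohortConfig, batch_size: int | None = None) -> CohortResult:
    """Rejection-sample exactly ``n_cases`` accepted D=1 histories.

    Identical configs produce bit-identical cohorts.  ``batch_size``
    controls only the raw-draw chunking (and hence the random stream), so
    it is part of the reproducibility contract; the default sizes batches
    from the known acceptance probability.
    """
    params, sched = config.params, config.sched
    # Acceptance probability under the uniform proposal is P(D=1)/(w*T).
    from .closed_form import prob_clinical_before_T

    p_acc = prob_clinical_before_T(params, sched) / (params.w * sched.T)
    if p_acc <= 0.0:
        raise ValidationError("no disease history can be accepted for this program")
    if batch_size is None:
        batch_size = int(1.05 * config.n_cases / p_acc) + 1000

    rng = np.random.default_rng(config.seed)
    chunks: list[pd.DataFrame] = []
    n_acc, n_raw = 0, 0
    while n_acc < config.n_cases:
        remaining = config.n_cases - n_acc
        m = min(batch_size, int(1.2 * remaining / p_acc) + 1000)
        chunk, positions = _simulate_batch(params, sched, rng, m)
        if len(chunk) >= remaining:
            # Stop at the raw draw that produced the last case we need, so
            # accepted/raw stays an unbiased acceptance-rate record.
            chunk = chunk.iloc[:remaining]
            n_raw += int(positions[remaining - 1]) + 1
        else:
            n_raw += m
        n_acc += len(chunk)
        chunks.append(chunk)
    cases = pd.concat(chunks, ignore_index=True)
    return CohortResult(cases=cases, n_raw=n_raw, config=config)


def empirical_summary(
    cases: pd.DataFrame | CohortResult, lam: float | None = None
) -> LeadTimeSummary:
    """Zero-inflated lead-time summary over a collection of D=1 cases.

    ``P`` is the fraction with zero lead time; mean and SD include the
    zeros.  Monte-Carlo standard errors accompany each statistic (the SD's
    via the fourth-central-moment delta method).
    """
    if isinstance(cases, CohortResult):
        if lam is None:
            lam = cases.config.params.lam
        cases = cases.cases
    if lam is None:
        raise ValueError("lam (mean sojourn time) is required for the ratio column")
    if len(cases) == 0:
        raise ValidationError("cannot summarize an empty case collection")
    if not (cases["d_indicator"] == 1).all():
        raise ValidationError("summaries are defined over D=1 cases only")

    lead = cases["lead_time"].to_numpy()
    n = lead.size
    P = float(np.mean(lead == 0.0))
    mean = float(lead.mean())
    var = float(lead.var())  # population variance; n is large in practice
    sd = float(np.sqrt(var))

    se_p = float(np.sqrt(P * (1.0 - P) / n))
    se_mean = sd / np.sqrt(n)
    if sd > 0:
        m4 = float(np.mean((lead - mean) ** 4))
        se_sd = float(np.sqrt(max(m4 - var**2, 0.0) / n) / (2.0 * sd))
    else:
        se_sd = 0.0
    return LeadTimeSummary(
        P=P,
        Q=1.0 - P,
        mean=mean,
        sd=sd,
        ratio=mean / lam,
        se_p=se_p,
        se_mean=se_mean,
        se_sd=se_sd,
        n=n,
    )
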