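"""Registry of trial parameter estimates shipped with the package."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .params import DEFAULT_TRANSITION_RATE, StableDiseaseParams

__all__ = ["TrialEstimates", "load_trials", "trial_params"]


@dataclass(frozen=True)
class TrialEstimates:
    """Point estimates (and standard errors, metadata only) for one trial."""

    name: str
    beta: float
    lam: float
    se_beta: float
    se_lam: float

    def to_params(self, w: float = DEFAULT_TRANSITION_RATE) -> StableDiseaseParams:
        return StableDiseaseParams(w=w, beta=self.beta, lam=self.lam)


def load_trials() -> dict[str, TrialEstimates]:
    """Load the four shipped trial parameter sets, keyed by trial name."""
    text = resources.files("leadtime").joinpath("data/trials.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: TrialEstimates(
            name=name,
            beta=entry["beta"],
            lam=entry["lam"],
            se_beta=entry["se_beta"],
            se_lam=entry["se_lam"],
        )
        for name, entry in raw.items()
    }


def trial_params(
    name: str, w: float = DEFAULT_TRANSITION_RATE
) -> StableDiseaseParams:
    """Disease parameters for a named trial (HIP, Edinburgh, CNBS1, CNBS2)."""
    trials = load_trials()
    try:
        return trials[name].to_params(w=w)
    except KeyError:
        raise KeyError(
            f"unknown trial {name!r}; available: {sorted(trials)}"
        ) from None
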