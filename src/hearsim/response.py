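"""Psychometric model of the simulated subject's hand-raise response.

The subject's probability of responding to a tone is a lapse/guess-adjusted
logistic in the presentation level relative to the ear's threshold:

    p(level) = g + (1 - g - l) * logistic((level - threshold) / s)

with guess rate ``g`` (false alarms), lapse rate ``l`` (missed audible
tones) and slope ``s`` in dB. With ``s = 0`` the model degenerates to a
deterministic step: respond exactly when the level is at or above
threshold (the threshold itself is by definition audible). Nonzero
parameters reproduce the response inconsistency real screeners encounter.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["ResponseParams", "response_probability", "simulate_response"]


class ResponseParams(BaseModel):
    """Psychometric parameters; the all-zero default is the step model."""

    model_config = ConfigDict(frozen=True)

    slope_s: float = Field(default=0.0, ge=0.0, description="logistic slope in dB; 0 = step")
    guess_rate_g: float = Field(default=0.0, ge=0.0, lt=1.0)
    lapse_rate_l: float = Field(default=0.0, ge=0.0, lt=1.0)

    @model_validator(mode="after")
    def _check(self) -> "ResponseParams":
        if self.guess_rate_g + self.lapse_rate_l >= 1.0:
            raise ValueError("guess_rate_g + lapse_rate_l must be < 1")
        return self


def response_probability(level: float, threshold: float, params: ResponseParams | None = None) -> float:
    """Probability that the subject raises a hand to a tone at ``level`` dB HL."""
    p = params or ResponseParams()
    if p.slope_s == 0.0:
        return 1.0 if level >= threshold else p.guess_rate_g
    z = (level - threshold) / p.slope_s
    # numerically safe logistic
    if z >= 0:
        core = 1.0 / (1.0 + math.exp(-z))
    else:
        e = math.exp(z)
        core = e / (1.0 + e)
    return p.guess_rate_g + (1.0 - p.guess_rate_g - p.lapse_rate_l) * core


def simulate_response(
    level: float,
    threshold: float,
    params: ResponseParams | None,
    rng: np.random.Generator,
) -> bool:
    """One Bernoulli hand-raise draw; deterministic given the rng state."""
    prob = response_probability(level, threshold, params)
    if prob >= 1.0:
        return True
    if prob <= 0.0:
        return False
    return bool(rng.random() < prob)
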