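"""Rescorla-Wagner reward learning over odor signatures.

Each species' signature odor carries two learned values: a positive
associative strength V+ (expected reward) and a negative strength V-
(expected punishment), both in [0, 1].  A single consumption updates the
relevant strength toward an asymptote set by the experienced reward:

    V <- V + alpha * (lambda - V)

with lambda = min(1, |reward| / r_norm) for rewarding or noxious
consumptions, and lambda = 0 (extinction) when a previously rewarding item is
consumed without reward.  Updates touch one signature at a time; there is no
compound-stimulus competition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .environment import SPECIES
from .errors import ConfigurationError
from .forager import ConsumptionEvent


@dataclass
class LearningParams:
    """Learning rates and the reward normalization for the asymptote.

    With ``alpha = 0.3``, fifteen maximally rewarded trials reach
    1 - 0.7^15 ~= 0.995, i.e. an associative strength of 1.00 at two-decimal
    reporting.  ``r_norm = 0.5`` makes both prey rewards (|r| = 0.5) and the
    drug reward (r = 4.0, capped) train toward the maximum of 1.
    """

    alpha: float = 0.3
    alpha_extinction: float = 0.3
    r_norm: float = 0.5

    def __post_init__(self) -> None:
        for name in ("alpha", "alpha_extinction"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ConfigurationError(
                    f"learning.{name} must be in (0, 1), got {a}"
                )
        if self.r_norm <= 0:
            raise ConfigurationError(f"learning.r_norm must be > 0, got {self.r_norm}")


def _zero_map() -> dict[str, float]:
    return {sp: 0.0 for sp in SPECIES}


@dataclass
class AssociativeStrengths:
    """Learned positive (V+) and negative (V-) values per odor signature."""

    pos: dict[str, float] = field(default_factory=_zero_map)
    neg: dict[str, float] = field(default_factory=_zero_map)

    @classmethod
    def naive(cls) -> "AssociativeStrengths":
        return cls()

    def copy(self) -> "AssociativeStrengths":
        return AssociativeStrengths(dict(self.pos), dict(self.neg))


def rw_update(V: float, lam: float, alpha: float) -> float:
    """One Rescorla-Wagner step toward asymptote ``lam``."""
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"learning rate must be in (0, 1), got {alpha}")
    return V + alpha * (lam - V)


def apply_learning_event(
    V: AssociativeStrengths,
    event: ConsumptionEvent,
    params: LearningParams,
    mode: str | None = None,
) -> AssociativeStrengths:
    """Update associative strengths for one consumption (in place).

    ``mode`` ('feeding' or 'avoidance') selects the learning channel; by
    default it is inferred from the reward sign.  Rewarding consumption trains
    V+, noxious consumption trains V-, and zero-reward consumption of a
    signature extinguishes V+ toward 0.
    """
    sp = event.species
    if sp not in V.pos:
        raise ConfigurationError(f"unknown species in consumption event: {sp!r}")
    r = event.reward_magnitude
    if mode is None:
        mode = "avoidance" if r < 0 else "feeding"
    if mode not in ("feeding", "avoidance"):
        raise ConfigurationError(f"unknown learning mode {mode!r}")
    if mode == "avoidance":
        lam = min(1.0, abs(r) / params.r_norm)
        V.neg[sp] = rw_update(V.neg[sp], lam, params.alpha)
    elif r > 0:
        lam = min(1.0, r / params.r_norm)
        V.pos[sp] = rw_update(V.pos[sp], lam, params.alpha)
    else:  # zero-reward consumption: extinction of the positive association
        V.pos[sp] = rw_update(V.pos[sp], 0.0, params.alpha_extinction)
    return V
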