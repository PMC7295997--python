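"""Homeostatic reward circuit (HRC) and pain center with reciprocal inhibition.

The HRC is a two-neuron rate circuit.  Neuron R receives reward pulses from
consumption on top of a tonic baseline ``r0``; neuron M's activity is the
product of R's activity and a plastic synaptic weight W.  W follows a
homeostatic setpoint rule that pulls M's activity toward ``M_set``:

    u   <- u * (1 - 1/tau_u)           (pulse trace decay)
    x_R  = max(0, r0 + u)
    x_M  = W * x_R
    W   <- clip(W + eta_W * (M_set - x_M) * dt, W_min, W_max)
    RE   = k_RE * (x_M - M_set)        (signed reward-experience readout)

Sustained reward drives W down (desensitization).  Because R carries a tonic
baseline, the depressed weight expresses as x_M < M_set once the input stops,
i.e. negative reward experience (withdrawal), which then relaxes back to zero
as W recovers toward M_set / r0 (resensitization).  These four phases — onset
peak, decline under input, negative undershoot at offset, decay of the
undershoot — reproduce the classic opponent-process timecourse.

The pain center is a leaky accumulator of applied nociceptive stimuli.  Pain
and positive reward experience are reciprocally inhibitory: each subtracts
from the other's effective output, negative reward experience amplifies pain,
and the survivor of the competition is what suppresses appetitive state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ComputationError, ConfigurationError


@dataclass
class HRCParams:
    """Constants of the homeostatic reward circuit.

    ``k_RE`` scales the readout so that reward-experience excursions under the
    default species rewards span roughly the [-20, 20] band used by the
    selectivity-map protocols.
    """

    r0: float = 1.0        # tonic presynaptic baseline rate
    M_set: float = 1.0     # homeostatic setpoint for neuron M's activity
    W_min: float = 0.05
    W_max: float = 2.0
    W_init: float = 1.0
    eta_W: float = 0.00025  # weight learning rate, per tick
    tau_u: float = 150.0    # reward-pulse decay time constant, ticks
    g_pulse: float = 1.0   # reward-to-pulse gain
    k_RE: float = 5.0      # reward-experience readout gain
    dt: float = 1.0


@dataclass
class HRCState:
    """Instantaneous state of the reward circuit."""

    u: float = 0.0
    x_R: float = 1.0
    x_M: float = 1.0
    W: float = 1.0
    RE: float = 0.0

    @classmethod
    def equilibrium(cls, params: HRCParams) -> "HRCState":
        """The no-input fixed point: x_M = M_set, RE = 0."""
        w = params.M_set / params.r0
        return cls(u=0.0, x_R=params.r0, x_M=params.M_set, W=w, RE=0.0)


@dataclass
class PainParams:
    """Pain-center decay and reciprocal-inhibition couplings."""

    tau_P: float = 30.0  # pain decay time constant, ticks
    k_rp: float = 1.0    # pain -> reward-experience inhibition
    k_pr: float = 1.0    # reward-experience -> pain inhibition
    c_p: float = 1.0     # pain amplification per unit negative reward experience


@dataclass
class PainState:
    """Pain-center output and body-relative bearing of the last stimulus."""

    P: float = 0.0
    site: float = 0.0  # degrees; positive = left of heading


def inject_reward(hrc: HRCState, r: float, params: HRCParams) -> HRCState:
    """Add one consumption's reward pulse to the circuit input trace."""
    if not np.isfinite(r):
        raise ComputationError(f"reward magnitude is not finite: {r}")
    return replace(hrc, u=hrc.u + params.g_pulse * r)


def hrc_step(hrc: HRCState, params: HRCParams) -> tuple[HRCState, float]:
    """Advance the reward circuit one tick; returns (state', RE)."""
    if not (np.isfinite(hrc.u) and np.isfinite(hrc.W)):
        raise ComputationError("HRC state is not finite")
    u = hrc.u * (1.0 - 1.0 / params.tau_u)
    x_R = max(0.0, params.r0 + u)
    x_M = hrc.W * x_R
    W = float(
        np.clip(
            hrc.W + params.eta_W * (params.M_set - x_M) * params.dt,
            params.W_min,
            params.W_max,
        )
    )
    RE = params.k_RE * (x_M - params.M_set)
    return HRCState(u=u, x_R=x_R, x_M=x_M, W=W, RE=RE), RE


def pain_step(
    pain: PainState,
    applied_strength: float = 0.0,
    params: PainParams = PainParams(),
    site: float | None = None,
) -> PainState:
    """Advance the pain center one tick, optionally applying a stimulus.

    Pain decays geometrically with time constant ``tau_P``; an applied
    stimulus adds its strength and records its body-relative bearing for
    somatic-map routing.
    """
    if applied_strength < 0:
        raise ConfigurationError(
            f"pain stimulus strength must be >= 0, got {applied_strength}"
        )
    P = pain.P * (1.0 - 1.0 / params.tau_P) + applied_strength
    new_site = pain.site if (site is None or applied_strength == 0) else site
    return PainState(P=P, site=new_site)


def mutual_inhibition(
    RE: float, P: float, params: PainParams
) -> tuple[float, float]:
    """Reciprocal inhibition between reward experience and pain.

    Returns ``(Q, P_eff)`` where Q is the net suppression applied to
    appetitive state and P_eff the effective (post-inhibition) pain.  Positive
    reward experience and pain inhibit each other one-for-one through
    ``k_pr`` / ``k_rp``; negative reward experience amplifies pain by
    ``1 + c_p * |RE|``.  With both drives high the suppressions cancel, which
    is how a strong pain stimulus can disinhibit appetitive state under high
    reward experience.
    """
    if P < 0:
        raise ConfigurationError(f"pain output must be >= 0, got {P}")
    re_pos = max(0.0, RE)
    re_neg = max(0.0, -RE)
    P_eff = max(0.0, P * (1.0 + params.c_p * re_neg) - params.k_pr * re_pos)
    RE_eff = max(0.0, re_pos - params.k_rp * P)
    return P_eff + RE_eff, P_eff
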