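"""The forager agent: sensing, appetitive state, turn decision, locomotion.

The forager carries two odor sensors placed symmetrically about its heading.
Sensed concentrations are log-compressed, summed per body side into a somatic
map that sets turn *amplitude*, while turn *direction* (toward or away from
the stimulus side) is set by the appetitive state AS — a logistic readout of
the forager's net drive:

    drive = I + h0*(1-S)*(1 + c_w*max(0,-RE))          (hunger, amplified in
                                                        withdrawal)
            - c_s*S*(1 + c_re*max(0,RE))               (satiation suppression,
                                                        amplified by reward)
            - Q(RE, P)                                 (net reward/pain
                                                        suppression)
            - theta
    AS = sigmoid(beta * drive)

where I is incentive (resource signal plus learned signature values), S
satiation, RE reward experience, and Q the surviving suppression from the
reciprocal inhibition of reward experience and pain.  AS >= approach_threshold
inverts the turn response from avoidance to approach; AS >= bite_threshold
permits consumption of items within reach.

Angles are degrees, counterclockwise positive, 0 along +x; a positive turn is
toward the left sensor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .affect import PainParams, mutual_inhibition
from .environment import SIGNATURES, OdorFields, PreyItem, SpeciesParams, sample_odor
from .errors import ComputationError

S_FLOOR = 0.01  # satiation is clamped to [S_FLOOR, 1.0]


@dataclass
class SensorParams:
    """Two-sensor geometry and the log compression of odor concentration."""

    sensor_angle: float = 40.0   # degrees off heading, each side
    sensor_reach: float = 3.0    # patches from body centre
    k_log: float = 7.0           # s = max(0, k_log + log10(c + c_floor))
    c_floor: float = 1e-7


@dataclass
class ForagerParams:
    """Drive integration, turning, locomotion, and satiation constants.

    The drive constants are calibrated jointly (with the default species and
    circuit constants) so that the selectivity-map, pain-map, and
    addiction-cycle protocols reproduce their expected qualitative patterns;
    see docs/methods.md for the calibration argument.
    """

    beta: float = 1.0              # logistic gain
    theta: float = 1.0             # decision threshold offset
    h0: float = 16.0               # hunger drive at empty gut
    c_s: float = 12.0              # satiation suppression gain
    c_w: float = 0.5               # hunger amplification per unit negative RE
    c_re: float = 0.01             # satiation amplification per unit positive RE
    w_betaine: float = 0.05        # innate resource-signal weight in incentive
    approach_threshold: float = 0.5
    bite_threshold: float = 0.6
    gain_turn: float = 5.0         # degrees per unit side difference
    max_turn: float = 20.0         # degrees per tick
    capture_radius: float = 1.5    # patches
    speed: float = 0.4             # patches per tick when mobile
    k_N: float = 0.002             # nutrition decay per tick (metabolism)
    K_half: float = 0.3            # nutrition at half-maximal satiation


@dataclass
class SensorReading:
    """Per-signature log-scaled sensed values for the left and right sensors."""

    left: dict[str, float]
    right: dict[str, float]

    def side_sum(self, signature: str) -> float:
        return self.left[signature] + self.right[signature]

    def totals(self) -> tuple[float, float]:
        return (sum(self.left.values()), sum(self.right.values()))


@dataclass
class SomaticMap:
    """Body-referenced stimulus side and the turn-amplitude template."""

    stimulus_side: str  # 'left' | 'right' | 'center'
    amplitude: float    # degrees per tick, >= 0


@dataclass
class ConsumptionEvent:
    """Emitted when the forager consumes an item."""

    species: str
    reward_magnitude: float
    nutrition_value: float


@dataclass
class ForagerState:
    """Pose and internal state of the forager."""

    x: float = 0.0
    y: float = 0.0
    heading: float = 0.0   # degrees CCW from +x
    nutrition: float = 0.0
    satiation: float = S_FLOOR
    appetitive_state: float = 0.5
    incentive: float = 0.0

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


def _sensor_positions(
    forager: ForagerState, sp: SensorParams
) -> tuple[tuple[float, float], tuple[float, float]]:
    h = math.radians(forager.heading)
    a = math.radians(sp.sensor_angle)
    left = (
        forager.x + sp.sensor_reach * math.cos(h + a),
        forager.y + sp.sensor_reach * math.sin(h + a),
    )
    right = (
        forager.x + sp.sensor_reach * math.cos(h - a),
        forager.y + sp.sensor_reach * math.sin(h - a),
    )
    return left, right


def _log_scale(c: float, sp: SensorParams) -> float:
    return max(0.0, sp.k_log + math.log10(c + sp.c_floor))


def sense(
    fields: OdorFields, forager: ForagerState, sp: SensorParams
) -> SensorReading:
    """Sample every signature field at both sensors, log-compressed."""
    left_pos, right_pos = _sensor_positions(forager, sp)
    left = {
        sig: _log_scale(sample_odor(fields[sig], left_pos), sp) for sig in SIGNATURES
    }
    right = {
        sig: _log_scale(sample_odor(fields[sig], right_pos), sp) for sig in SIGNATURES
    }
    return SensorReading(left=left, right=right)


def somatic_map(
    reading: SensorReading,
    params: ForagerParams,
    extra_left: float = 0.0,
    extra_right: float = 0.0,
) -> SomaticMap:
    """Reduce a sensor reading to stimulus side and turn amplitude.

    ``extra_left`` / ``extra_right`` admit non-odor somatic inputs (the pain
    site's contribution at its bearing).
    """
    left_total, right_total = reading.totals()
    left_total += extra_left
    right_total += extra_right
    diff = left_total - right_total
    if diff > 0:
        side = "left"
    elif diff < 0:
        side = "right"
    else:
        side = "center"
    amplitude = min(params.max_turn, params.gain_turn * abs(diff))
    return SomaticMap(stimulus_side=side, amplitude=amplitude)


def compute_incentive(
    reading: SensorReading, V, w_betaine: float
) -> float:
    """Incentive: learned signature values plus the innate resource signal.

    I = sum_k V+_k * s_k + w_betaine * s_betaine - sum_k V-_k * s_k, with s_k
    the side-summed sensed value of signature k.
    """
    I = w_betaine * reading.side_sum("betaine")
    for sp in V.pos:
        s = reading.side_sum(sp)
        I += V.pos[sp] * s - V.neg[sp] * s
    return I


def compute_appetitive_state(
    I: float,
    S: float,
    RE: float,
    P: float,
    params: ForagerParams,
    pain_params: PainParams,
) -> float:
    """Logistic appetitive state from incentive, satiation, reward, and pain."""
    if not all(np.isfinite(v) for v in (I, S, RE, P)):
        raise ComputationError("appetitive-state inputs must be finite")
    Q, _ = mutual_inhibition(RE, P, pain_params)
    hunger = params.h0 * (1.0 - S) * (1.0 + params.c_w * max(0.0, -RE))
    suppression = params.c_s * S * (1.0 + params.c_re * max(0.0, RE))
    drive = I + hunger - suppression - Q - params.theta
    return float(expit(params.beta * drive))


def decide_turn(AS: float, smap: SomaticMap, approach_threshold: float) -> float:
    """Signed turn angle: toward the stimulus side above threshold, away below."""
    if smap.stimulus_side == "center" or smap.amplitude == 0.0:
        return 0.0
    toward = 1.0 if smap.stimulus_side == "left" else -1.0
    if AS >= approach_threshold:
        return toward * smap.amplitude
    return -toward * smap.amplitude


def step_and_consume(
    forager: ForagerState,
    items: list[PreyItem],
    turn: float,
    mobility: bool,
    species_params: dict[str, SpeciesParams],
    params: ForagerParams,
    arena_size: float,
    reward_overrides: dict[str, float] | None = None,
) -> list[ConsumptionEvent]:
    """Turn, optionally advance, and consume items within capture radius.

    The forager is updated in place.  Consumption requires appetitive state at
    or above the bite threshold.  ``reward_overrides`` replaces a species'
    reward magnitude in the emitted events (drug-without-reward phase) without
    touching its odor emission.
    """
    forager.heading = (forager.heading + turn) % 360.0
    if mobility:
        h = math.radians(forager.heading)
        forager.x = (forager.x + params.speed * math.cos(h)) % arena_size
        forager.y = (forager.y + params.speed * math.sin(h)) % arena_size
    events: list[ConsumptionEvent] = []
    if forager.appetitive_state < params.bite_threshold:
        return events
    for item in items:
        if not item.alive:
            continue
        dx = _torus_delta(item.x - forager.x, arena_size)
        dy = _torus_delta(item.y - forager.y, arena_size)
        if dx * dx + dy * dy <= params.capture_radius**2:
            sp = species_params[item.species]
            reward = sp.reward_magnitude
            if reward_overrides and item.species in reward_overrides:
                reward = reward_overrides[item.species]
            item.alive = False
            events.append(
                ConsumptionEvent(item.species, reward, sp.nutrition_value)
            )
    return events


def _torus_delta(d: float, size: float) -> float:
    """Shortest signed displacement along one toroidal axis."""
    return (d + size / 2.0) % size - size / 2.0


def update_satiation(
    forager: ForagerState, events: list[ConsumptionEvent], params: ForagerParams
) -> ForagerState:
    """Metabolize and digest: decay nutrition, add meals, refresh satiation.

    Satiation is a saturating function of the nutrition store, clamped to
    [0.01, 1.0].  Non-nutritive consumptions (the drug) add nothing.
    """
    N = forager.nutrition * (1.0 - params.k_N)
    N += sum(ev.nutrition_value for ev in events)
    forager.nutrition = N
    forager.satiation = float(np.clip(N / (N + params.K_half), S_FLOOR, 1.0))
    return forager
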