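"""Per-tick orchestration of world, forager, reward circuit, and learning.

One tick proceeds:

1. live items deposit odor; fields diffuse and evaporate
2. pain center updated (stimulus applied or decaying)
3. reward circuit advanced; satiation / reward-experience clamps re-imposed
4. sensing -> somatic map -> incentive -> appetitive state -> turn decision
5. locomotion and consumption
6. per consumption: reward injected into the circuit, associative strengths
   updated, nutrition credited
7. dead items respawn (when enabled)

The order (deposition before transport, decision before consumption, clamps
before the decision step) is fixed and tested; any fixed order would do, this
one is the documented convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import affect, environment, forager as fg, learning
from .environment import OdorFields, PreyItem, SpeciesParams, WorldConfig
from .learning import AssociativeStrengths


def _wrap180(angle: float) -> float:
    """Wrap an angle to (-180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass
class PainStimulus:
    """A maintained nociceptive stimulus at a world-fixed bearing.

    ``bearing`` is measured from the forager's position at application, in
    world coordinates; the body-relative side is recomputed each tick as the
    forager turns.  ``hold`` clamps the pain-center output at the applied
    strength for the stimulus' duration (a maintained stimulus), instead of
    accumulating it tick over tick.
    """

    strength: float
    bearing: float  # degrees, world frame
    hold: bool = True


@dataclass
class Fixation:
    """Optional per-tick clamps on satiation and reward experience."""

    satiation: float | None = None
    reward_experience: float | None = None


@dataclass
class TickTrace:
    """Selected per-tick observables."""

    S: float
    AS: float
    I: float
    RE: float
    P: float
    turn: float
    events: list


class Simulation:
    """A world plus one forager, stepped tick by tick."""

    def __init__(
        self,
        world: WorldConfig,
        species: dict[str, SpeciesParams],
        forager_params: fg.ForagerParams,
        sensor_params: fg.SensorParams,
        hrc_params: affect.HRCParams,
        pain_params: affect.PainParams,
        learning_params: learning.LearningParams,
        rng: np.random.Generator,
    ):
        self.world = world
        self.species = species
        self.fp = forager_params
        self.sp = sensor_params
        self.hp = hrc_params
        self.pp = pain_params
        self.lp = learning_params
        self.rng = rng

        n = world.arena_size
        self.fields = OdorFields(n)
        self.items: list[PreyItem] = []
        self.forager = fg.ForagerState(x=n / 2.0, y=n / 2.0, heading=0.0)
        self.hrc = affect.HRCState.equilibrium(hrc_params)
        self.pain = affect.PainState()
        self.V = AssociativeStrengths.naive()
        self.respawn_enabled: dict[str, bool] = {s: True for s in environment.SPECIES}
        self.reward_overrides: dict[str, float] = {}
        self.tick_count = 0

    # -- world management -------------------------------------------------

    def add_items(self, species: str, count: int) -> None:
        self.items.extend(
            environment.spawn_items(species, count, self.world.arena_size, self.rng)
        )

    def remove_items(self, species: str) -> None:
        self.items = [it for it in self.items if it.species != species]

    def equilibrate_fields(self, ticks: int) -> None:
        """Run deposition + transport alone until fields approach steady state."""
        for _ in range(ticks):
            environment.deposit_odors(self.items, self.fields, self.species)
            environment.step_fields(self.fields, self.world)

    # -- stepping ----------------------------------------------------------

    def _pain_somatic_input(self, stimulus: PainStimulus | None) -> tuple[float, float]:
        """Route pain output to the somatic-map side of its bearing."""
        if self.pain.P <= 0.0:
            return 0.0, 0.0
        rel = _wrap180(self.pain.site)
        if rel > 0:
            return self.pain.P, 0.0
        if rel < 0:
            return 0.0, self.pain.P
        return self.pain.P / 2.0, self.pain.P / 2.0

    def step(
        self,
        mobility: bool = True,
        fixation: Fixation | None = None,
        pain_stimulus: PainStimulus | None = None,
        learning_enabled: bool = True,
        consume: bool = True,
    ) -> TickTrace:
        """Advance the whole simulation by one tick."""
        world = self.world
        # 1. odor deposition and transport
        environment.deposit_odors(self.items, self.fields, self.species)
        environment.step_fields(self.fields, world)

        # 2. pain center
        if pain_stimulus is not None:
            rel_site = _wrap180(pain_stimulus.bearing - self.forager.heading)
            if pain_stimulus.hold:
                self.pain = affect.PainState(P=pain_stimulus.strength, site=rel_site)
            else:
                self.pain = affect.pain_step(
                    self.pain, pain_stimulus.strength, self.pp, site=rel_site
                )
        else:
            self.pain = affect.pain_step(self.pain, 0.0, self.pp)

        # 3. reward circuit, then clamps (clamps win for the decision step)
        self.hrc, RE = affect.hrc_step(self.hrc, self.hp)
        if fixation is not None:
            if fixation.reward_experience is not None:
                RE = fixation.reward_experience
            if fixation.satiation is not None:
                self.forager.satiation = fixation.satiation

        # 4. decision chain
        reading = fg.sense(self.fields, self.forager, self.sp)
        extra_left, extra_right = self._pain_somatic_input(pain_stimulus)
        smap = fg.somatic_map(reading, self.fp, extra_left, extra_right)
        I = fg.compute_incentive(reading, self.V, self.fp.w_betaine)
        AS = fg.compute_appetitive_state(
            I, self.forager.satiation, RE, self.pain.P, self.fp, self.pp
        )
        self.forager.incentive = I
        self.forager.appetitive_state = AS
        turn = fg.decide_turn(AS, smap, self.fp.approach_threshold)

        # 5. locomotion and consumption
        events = fg.step_and_consume(
            self.forager,
            self.items if consume else [],
            turn,
            mobility,
            self.species,
            self.fp,
            world.arena_size,
            self.reward_overrides or None,
        )

        # 6. consequences of consumption
        for ev in events:
            self.hrc = affect.inject_reward(self.hrc, ev.reward_magnitude, self.hp)
            if learning_enabled:
                learning.apply_learning_event(self.V, ev, self.lp)
        fg.update_satiation(self.forager, events, self.fp)
        if fixation is not None and fixation.satiation is not None:
            self.forager.satiation = fixation.satiation

        # 7. respawn
        for item in self.items:
            if not item.alive and self.respawn_enabled.get(item.species, False):
                environment.respawn_prey(item, world.arena_size, self.rng)

        self.tick_count += 1
        return TickTrace(
            S=self.forager.satiation,
            AS=AS,
            I=I,
            RE=RE,
            P=self.pain.P,
            turn=turn,
            events=events,
        )
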