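"""Experiment protocols: presentations, selectivity maps, pain maps, cycles.

Three protocols probe the forager's aesthetic dynamics:

* **Presentation mode** — the forager is immobilized (free turning only), a
  single item (or a maintained pain stimulus) is placed at a fixed bearing,
  satiation and reward experience are clamped, and the net turn toward the
  stimulus is classified as approach / none / avoid.
* **Selectivity maps** — one presentation per cell of a satiation x
  reward-experience grid, per item, under a "drug_free" or "addicted"
  preparation of the associative strengths.
* **Addiction cycle mode** — a free-running simulation through four phases
  (prey only, drug introduced, drug removed, drug without reward) with
  learning and the reward circuit unconstrained, aggregated over trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .config import RE_BAND, S_BAND, RunConfig
from .environment import PreyItem, WorldConfig
from .errors import AggregationError, ConfigurationError
from .learning import AssociativeStrengths
from .simulation import Fixation, PainStimulus, Simulation

PHASES = ("prey_only", "drug_introduced", "drug_removed", "drug_without_reward")
CONSUMABLE = ("hermi", "flab", "drug")
OUTCOME_CODE = {"approach": 1, "none": 0, "avoid": -1}


@dataclass
class FixationSpec:
    """Per-tick clamps on satiation and/or reward experience (None = free)."""

    satiation: float | None = None
    reward_experience: float | None = None

    def __post_init__(self) -> None:
        if self.satiation is not None and not (
            S_BAND[0] <= self.satiation <= S_BAND[1]
        ):
            raise ConfigurationError(
                f"satiation fixation must be in [{S_BAND[0]}, {S_BAND[1]}], "
                f"got {self.satiation}"
            )
        if self.reward_experience is not None and not (
            RE_BAND[0] <= self.reward_experience <= RE_BAND[1]
        ):
            raise ConfigurationError(
                f"reward-experience fixation must be in [{RE_BAND[0]}, {RE_BAND[1]}], "
                f"got {self.reward_experience}"
            )


def fix_variables(forager, hrc, spec: FixationSpec):
    """Impose a fixation on forager satiation and the reward-experience readout.

    Returns ``(forager, effective_RE)``; the circuit's internal state is left
    free to evolve, only the readout used by the decision step is overridden.
    """
    if spec.satiation is not None:
        forager.satiation = spec.satiation
    RE = hrc.RE if spec.reward_experience is None else spec.reward_experience
    return forager, RE


@dataclass
class TrialOutcome:
    """Classified result of one presentation trial."""

    item: str
    outcome: str      # 'approach' | 'none' | 'avoid'
    net_turn: float   # degrees toward the stimulus (signed)


@dataclass
class SelectivityGrid:
    """Outcome matrices over a satiation x reward-experience grid."""

    satiation_axis: list[float]
    re_axis: list[float]
    outcomes: dict[str, np.ndarray]  # item -> (len(S), len(RE)) int8 matrix
    state_label: str

    def __post_init__(self) -> None:
        shape = (len(self.satiation_axis), len(self.re_axis))
        for item, grid in self.outcomes.items():
            if grid.shape != shape:
                raise ConfigurationError(
                    f"selectivity grid for {item!r} has shape {grid.shape}, "
                    f"expected {shape}"
                )

    def approach_cells(self, item: str) -> set[tuple[int, int]]:
        ii, jj = np.nonzero(self.outcomes[item] == OUTCOME_CODE["approach"])
        return set(zip(ii.tolist(), jj.tolist()))


def classify_turn(net_turn: float, dead_zone: float) -> str:
    """Approach / none / avoid from a signed net turn toward the stimulus."""
    if dead_zone <= 0:
        raise ConfigurationError(f"dead_zone must be > 0, got {dead_zone}")
    if net_turn >= dead_zone:
        return "approach"
    if net_turn <= -dead_zone:
        return "avoid"
    return "none"


def _state_strengths(state_label: str) -> AssociativeStrengths:
    """Associative-strength preparation for a selectivity-map state."""
    V = AssociativeStrengths.naive()
    V.pos["hermi"] = 1.0
    V.neg["flab"] = 1.0
    if state_label == "addicted":
        V.pos["drug"] = 1.0
    elif state_label != "drug_free":
        raise ConfigurationError(f"unknown state label {state_label!r}")
    return V


def _presentation_sim(config: RunConfig, seed) -> Simulation:
    """A small immobile-forager world for presentation trials."""
    exp = config.experiment
    world = replace(
        config.world, arena_size=exp.presentation_arena, rng_seed=config.world.rng_seed
    )
    rng = np.random.default_rng(seed)
    sim = Simulation(
        world,
        config.species,
        config.forager,
        config.sensors,
        config.hrc,
        config.pain,
        config.learning,
        rng,
    )
    return sim


def _place_item_ahead(sim: Simulation, species: str, bearing: float, distance: float):
    b = math.radians(sim.forager.heading + bearing)
    sim.items = [
        PreyItem(
            species,
            sim.forager.x + distance * math.cos(b),
            sim.forager.y + distance * math.sin(b),
        )
    ]
    sim.respawn_enabled = {s: False for s in sim.respawn_enabled}


def run_presentation(
    item: str,
    spec: FixationSpec,
    seed,
    config: RunConfig | None = None,
    V: AssociativeStrengths | None = None,
    equilibrated_fields=None,
) -> TrialOutcome:
    """Present one item to an immobilized forager and classify its net turn.

    The item sits at ``experiment.item_bearing`` degrees (left-positive) and
    ``experiment.item_distance`` patches from the forager.  Odor fields are
    pre-equilibrated for ``experiment.t_equilibrate`` ticks (or supplied via
    ``equilibrated_fields``), then the trial runs ``experiment.t_present``
    ticks with satiation / reward experience clamped per ``spec``.
    """
    config = config or RunConfig()
    exp = config.experiment
    sim = _presentation_sim(config, seed)
    _place_item_ahead(sim, item, exp.item_bearing, exp.item_distance)
    if V is not None:
        sim.V = V.copy()
    if equilibrated_fields is not None:
        sim.fields = equilibrated_fields.copy()
    else:
        sim.equilibrate_fields(exp.t_equilibrate)
    fixation = Fixation(spec.satiation, spec.reward_experience)
    total_turn = 0.0
    for _ in range(exp.t_present):
        trace = sim.step(
            mobility=False, fixation=fixation, learning_enabled=False, consume=False
        )
        total_turn += trace.turn
    toward = 1.0 if exp.item_bearing >= 0 else -1.0
    net = toward * total_turn
    return TrialOutcome(item, classify_turn(net, exp.dead_zone), net)


def build_selectivity_map(
    state_label: str,
    axes: tuple[list[float], list[float]] | None = None,
    seed: int = 0,
    config: RunConfig | None = None,
    items: tuple[str, ...] = CONSUMABLE,
) -> SelectivityGrid:
    """One presentation per (satiation, reward experience, item) grid cell."""
    config = config or RunConfig()
    exp = config.experiment
    s_axis, re_axis = axes if axes is not None else (exp.satiation_axis, exp.re_axis)
    V = _state_strengths(state_label)
    outcomes: dict[str, np.ndarray] = {}
    for item in items:
        # Field equilibration is deterministic and identical across grid
        # cells, so it is done once per item and reused.
        sim = _presentation_sim(config, seed)
        _place_item_ahead(sim, item, exp.item_bearing, exp.item_distance)
        sim.equilibrate_fields(exp.t_equilibrate)
        fields0 = sim.fields
        grid = np.zeros((len(s_axis), len(re_axis)), dtype=np.int8)
        for i, s in enumerate(s_axis):
            for j, re in enumerate(re_axis):
                outcome = run_presentation(
                    item,
                    FixationSpec(satiation=s, reward_experience=re),
                    seed,
                    config,
                    V=V,
                    equilibrated_fields=fields0,
                )
                grid[i, j] = OUTCOME_CODE[outcome.outcome]
        outcomes[item] = grid
    return SelectivityGrid(list(s_axis), list(re_axis), outcomes, state_label)


def run_pain_map(
    axes: tuple[list[float], list[float]] | None = None,
    seed: int = 0,
    config: RunConfig | None = None,
) -> SelectivityGrid:
    """Approach/avoid map for a maintained pain stimulus at the right anterior.

    No items are present; a pain stimulus of ``experiment.pain_strength`` is
    maintained at ``experiment.pain_bearing`` (negative = right of heading)
    for the whole trial, and the net turn toward the stimulus is classified.
    """
    config = config or RunConfig()
    exp = config.experiment
    s_axis, re_axis = (
        axes if axes is not None else (exp.satiation_axis, exp.pain_re_axis)
    )
    grid = np.zeros((len(s_axis), len(re_axis)), dtype=np.int8)
    for i, s in enumerate(s_axis):
        for j, re in enumerate(re_axis):
            sim = _presentation_sim(config, seed)
            bearing_world = sim.forager.heading + exp.pain_bearing
            stim = PainStimulus(exp.pain_strength, bearing_world, hold=True)
            fixation = Fixation(s, re)
            total_turn = 0.0
            for _ in range(exp.t_present):
                trace = sim.step(
                    mobility=False,
                    fixation=fixation,
                    pain_stimulus=stim,
                    learning_enabled=False,
                    consume=False,
                )
                total_turn += trace.turn
            toward = 1.0 if exp.pain_bearing >= 0 else -1.0
            grid[i, j] = OUTCOME_CODE[classify_turn(toward * total_turn, exp.dead_zone)]
    return SelectivityGrid(list(s_axis), list(re_axis), {"pain": grid}, "pain")


@dataclass
class CycleResult:
    """Phase-stamped timecourses of one (or aggregated) addiction cycle(s)."""

    ticks: np.ndarray
    phase: np.ndarray                    # integer codes into PHASES
    re: np.ndarray
    cum_consumed: dict[str, np.ndarray]  # species -> cumulative count
    v_pos_drug: np.ndarray
    seed: int | None = None
    n_trials: int = 1
    re_sem: np.ndarray | None = None
    cum_sem: dict[str, np.ndarray] | None = None

    def phase_slice(self, phase: str) -> slice:
        code = PHASES.index(phase)
        idx = np.nonzero(self.phase == code)[0]
        if idx.size == 0:
            raise KeyError(f"phase {phase!r} absent from this cycle")
        return slice(int(idx[0]), int(idx[-1]) + 1)


def run_addiction_cycle(
    seed, schedule: dict[str, int] | None = None, config: RunConfig | None = None
) -> CycleResult:
    """Run the four-phase free-running protocol for one seed.

    Phases: prey only (3 hermi + 3 flab, respawning) -> 6 drug items
    introduced -> drug removed -> drug reintroduced with unchanged odor but
    zero reward (extinction).  Learning and the reward circuit run free
    throughout; mobility is on.
    """
    config = config or RunConfig()
    exp = config.experiment
    schedule = dict(schedule or exp.phase_ticks)
    unknown = set(schedule) - set(PHASES)
    if unknown:
        raise ConfigurationError(f"unknown phases in schedule: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    sim = Simulation(
        config.world,
        config.species,
        config.forager,
        config.sensors,
        config.hrc,
        config.pain,
        config.learning,
        rng,
    )
    total = sum(schedule.get(p, 0) for p in PHASES)
    re = np.empty(total)
    phase_codes = np.empty(total, dtype=np.int8)
    v_pos_drug = np.empty(total)
    cum = {sp: np.zeros(total, dtype=np.int64) for sp in CONSUMABLE}
    counts = {sp: 0 for sp in CONSUMABLE}

    t = 0
    for code, phase in enumerate(PHASES):
        ticks = schedule.get(phase, 0)
        if ticks == 0:
            continue
        if phase == "prey_only":
            sim.add_items("hermi", exp.n_hermi)
            sim.add_items("flab", exp.n_flab)
        elif phase == "drug_introduced":
            sim.add_items("drug", exp.n_drug)
            sim.respawn_enabled["drug"] = True
        elif phase == "drug_removed":
            sim.remove_items("drug")
            sim.respawn_enabled["drug"] = False
        elif phase == "drug_without_reward":
            sim.add_items("drug", exp.n_drug)
            sim.respawn_enabled["drug"] = True
            sim.reward_overrides = {"drug": 0.0}
        for _ in range(ticks):
            trace = sim.step(mobility=True)
            for ev in trace.events:
                counts[ev.species] += 1
            re[t] = trace.RE
            phase_codes[t] = code
            v_pos_drug[t] = sim.V.pos["drug"]
            for sp in CONSUMABLE:
                cum[sp][t] = counts[sp]
            t += 1
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return CycleResult(
        ticks=np.arange(total),
        phase=phase_codes,
        re=re,
        cum_consumed=cum,
        v_pos_drug=v_pos_drug,
        seed=seed_int,
    )


def aggregate_trials(results: list[CycleResult]) -> CycleResult:
    """Across-trial mean and SEM (sample std / sqrt(n)) of cycle timecourses.

    With a single trial the mean is the trial itself and the SEM is reported
    as NaN (undefined at n = 1), not zero.
    """
    if not results:
        raise AggregationError("no trials to aggregate")
    n = len(results)
    length = results[0].re.size
    for r in results[1:]:
        if r.re.size != length:
            raise AggregationError("trials have mismatched lengths")
        if not np.array_equal(r.phase, results[0].phase):
            raise AggregationError("trials are not phase-aligned")
    re_stack = np.stack([r.re for r in results])
    v_stack = np.stack([r.v_pos_drug for r in results])
    cum_stacks = {
        sp: np.stack([r.cum_consumed[sp] for r in results]) for sp in CONSUMABLE
    }
    if n > 1:
        re_sem = re_stack.std(axis=0, ddof=1) / math.sqrt(n)
        cum_sem = {
            sp: s.std(axis=0, ddof=1) / math.sqrt(n) for sp, s in cum_stacks.items()
        }
    else:
        re_sem = np.full(length, np.nan)
        cum_sem = {sp: np.full(length, np.nan) for sp in CONSUMABLE}
    return CycleResult(
        ticks=results[0].ticks.copy(),
        phase=results[0].phase.copy(),
        re=re_stack.mean(axis=0),
        cum_consumed={sp: s.mean(axis=0) for sp, s in cum_stacks.items()},
        v_pos_drug=v_stack.mean(axis=0),
        seed=None,
        n_trials=n,
        re_sem=re_sem,
        cum_sem=cum_sem,
    )


# -- cycle metrics ---------------------------------------------------------


def consumption_rate(
    result: CycleResult,
    phase: str,
    species: tuple[str, ...],
    window: tuple[float, float] = (0.0, 1.0),
) -> float:
    """Consumptions per tick of the given species over a fraction of a phase."""
    sl = result.phase_slice(phase)
    start, stop = sl.start, sl.stop
    length = stop - start
    a = start + int(window[0] * length)
    b = start + int(window[1] * length)
    b = max(b, a + 1)
    total = 0.0
    for sp in species:
        c = result.cum_consumed[sp]
        before = c[a - 1] if a > 0 else 0.0
        total += c[b - 1] - before
    return float(total) / (b - a)


def ticks_to_first_consumption(
    result: CycleResult, phase: str, species: str
) -> float:
    """Ticks from phase start to the first consumption (phase length if none)."""
    sl = result.phase_slice(phase)
    c = result.cum_consumed[species]
    base = c[sl.start - 1] if sl.start > 0 else 0
    seg = c[sl] - base
    hits = np.nonzero(seg > 0)[0]
    return float(hits[0] + 1) if hits.size else float(sl.stop - sl.start)


def count_zero_crossings(x: np.ndarray) -> int:
    """Number of strict sign changes in a sequence (zeros carried forward)."""
    signs = np.sign(x)
    nz = signs[signs != 0]
    if nz.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(nz) != 0))
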