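"""Toroidal 2D odor world: diffusing/decaying odor fields and respawning items.

The arena is a square grid of unit patches with periodic (toroidal) boundary
conditions.  Agents and prey live at continuous coordinates; odors live on the
patch grid, one field per odor signature.  Three item species exist:

* ``hermi`` — benign prey: nutritive, small positive reward.
* ``flab``  — noxious prey: nutritive, small negative reward.
* ``drug``  — high-reward item with no nutritive value and, by default, no
  resource-signal (betaine) emission, so a naive forager is not innately
  attracted to it.

Every live item deposits odor into its patch each tick: its own signature
odor, plus betaine (the innately attractive resource signal) for nutritive
prey.  Fields then diffuse to their 8 toroidal neighbours and evaporate.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError

#: Item species tags, in canonical order.
SPECIES = ("hermi", "flab", "drug")

#: Odor signatures carried by the field stack (betaine = resource signal).
SIGNATURES = ("betaine", "hermi", "flab", "drug")


@dataclass
class WorldConfig:
    """Geometry and odor-transport constants of the arena.

    Parameters
    ----------
    arena_size:
        Patches per side of the square toroidal arena (>= 20).
    dt:
        Tick duration.  All rate constants in the package are per tick, so
        this stays at 1.
    diffusion_fraction:
        Fraction of each cell's content shared equally with its 8 toroidal
        neighbours per tick, in [0, 1].
    evaporation_fraction:
        Fraction of each cell's content lost per tick after diffusion,
        in [0, 1).
    rng_seed:
        Seed for the world's random stream (item placement and respawn).
    """

    arena_size: int = 60
    dt: float = 1.0
    diffusion_fraction: float = 0.5
    evaporation_fraction: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.arena_size < 20:
            raise ConfigurationError(
                f"world.arena_size must be >= 20, got {self.arena_size}"
            )
        if not 0.0 <= self.diffusion_fraction <= 1.0:
            raise ConfigurationError(
                f"world.diffusion_fraction must be in [0, 1], got {self.diffusion_fraction}"
            )
        if not 0.0 <= self.evaporation_fraction < 1.0:
            raise ConfigurationError(
                f"world.evaporation_fraction must be in [0, 1), got {self.evaporation_fraction}"
            )


@dataclass
class SpeciesParams:
    """Per-species odor emission, nutrition, and reward constants."""

    species: str
    signature_deposit: float = 0.5  # odor units deposited per tick
    betaine_deposit: float = 0.5    # resource-signal units per tick
    nutrition_value: float = 0.3    # satiation-driving units per consumption
    reward_magnitude: float = 0.5   # signed reward units per consumption

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ConfigurationError(
                f"unknown species tag {self.species!r}; expected one of {SPECIES}"
            )
        if self.signature_deposit < 0 or self.betaine_deposit < 0:
            raise ConfigurationError(
                f"species.{self.species}: odor deposits must be non-negative"
            )


def default_species_params() -> dict[str, SpeciesParams]:
    """The shipped species set.

    The drug's signature odor is deposited 10x more strongly than prey odor so
    that, once its association is learned, its incentive exceeds that of benign
    prey even though prey additionally emit the resource signal.  The drug
    emits no betaine and carries no nutrition; its reward is 8x the benign
    prey's.
    """
    return {
        "hermi": SpeciesParams("hermi", 0.5, 0.5, 0.3, +0.5),
        "flab": SpeciesParams("flab", 0.5, 0.5, 0.3, -0.5),
        "drug": SpeciesParams("drug", 5.0, 0.0, 0.0, +4.0),
    }


def validate_species_set(
    params: dict[str, SpeciesParams], allow_nonstandard: bool = False
) -> None:
    """Check the cross-species constraints of the three-item ecology.

    The drug must be non-nutritive, hermi rewarding, flab punishing, and the
    drug's reward must exceed hermi's.  ``allow_nonstandard`` disables these
    checks for exploratory configurations.
    """
    if allow_nonstandard:
        return
    drug, hermi, flab = params["drug"], params["hermi"], params["flab"]
    if drug.nutrition_value != 0.0:
        raise ConfigurationError(
            "species.drug.nutrition_value must be 0 (the drug is non-nutritive); "
            "set allow_nonstandard_species to override"
        )
    if hermi.reward_magnitude <= 0:
        raise ConfigurationError("species.hermi.reward_magnitude must be > 0")
    if flab.reward_magnitude >= 0:
        raise ConfigurationError("species.flab.reward_magnitude must be < 0")
    if drug.reward_magnitude <= hermi.reward_magnitude:
        raise ConfigurationError(
            "species.drug.reward_magnitude must exceed hermi's"
        )


@dataclass
class PreyItem:
    """A prey or drug item at continuous arena coordinates."""

    species: str
    x: float
    y: float
    alive: bool = True

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


class OdorFields:
    """Stack of non-negative 2D concentration grids, one per signature."""

    def __init__(self, arena_size: int):
        self.arena_size = int(arena_size)
        self.arrays: dict[str, np.ndarray] = {
            sig: np.zeros((self.arena_size, self.arena_size)) for sig in SIGNATURES
        }

    def __getitem__(self, signature: str) -> np.ndarray:
        return self.arrays[signature]

    def total_mass(self, signature: str) -> float:
        return float(self.arrays[signature].sum())

    def copy(self) -> "OdorFields":
        out = OdorFields(self.arena_size)
        for sig in SIGNATURES:
            out.arrays[sig] = self.arrays[sig].copy()
        return out


def _cell_index(position: tuple[float, float], arena_size: int) -> tuple[int, int]:
    x, y = position
    return (int(np.floor(x)) % arena_size, int(np.floor(y)) % arena_size)


def deposit_odors(
    items: list[PreyItem],
    fields: OdorFields,
    params_by_species: dict[str, SpeciesParams],
) -> OdorFields:
    """Deposit one tick's odor from every live item into its patch (in place)."""
    n = fields.arena_size
    for item in items:
        if not item.alive:
            continue
        try:
            params = params_by_species[item.species]
        except KeyError:
            raise ConfigurationError(
                f"no species parameters for item species {item.species!r}"
            ) from None
        i, j = _cell_index(item.position, n)
        fields[item.species][i, j] += params.signature_deposit
        if params.betaine_deposit:
            fields["betaine"][i, j] += params.betaine_deposit
    return fields


# 8-neighbour diffusion kernel template: centre keeps (1 - f), each neighbour
# receives f/8; assembled per call because f is configurable.
def _diffusion_kernel(diffusion_fraction: float) -> np.ndarray:
    k = np.full((3, 3), diffusion_fraction / 8.0)
    k[1, 1] = 1.0 - diffusion_fraction
    return k


def diffuse_decay(
    field: np.ndarray, diffusion_fraction: float, evaporation_fraction: float
) -> np.ndarray:
    """One transport tick: share with 8 toroidal neighbours, then evaporate.

    Diffusion is mass-conserving; evaporation multiplies the whole field by
    ``1 - evaporation_fraction``.  Returns a new array.
    """
    if not 0.0 <= diffusion_fraction <= 1.0:
        raise ConfigurationError(
            f"diffusion_fraction must be in [0, 1], got {diffusion_fraction}"
        )
    if not 0.0 <= evaporation_fraction < 1.0:
        raise ConfigurationError(
            f"evaporation_fraction must be in [0, 1), got {evaporation_fraction}"
        )
    if not field.any():
        return field.copy()
    out = ndimage.convolve(field, _diffusion_kernel(diffusion_fraction), mode="wrap")
    if evaporation_fraction:
        out *= 1.0 - evaporation_fraction
    return out


def step_fields(fields: OdorFields, world: WorldConfig) -> None:
    """Apply diffuse_decay to every signature field in place."""
    for sig in SIGNATURES:
        fields.arrays[sig] = diffuse_decay(
            fields.arrays[sig], world.diffusion_fraction, world.evaporation_fraction
        )


def respawn_prey(item: PreyItem, arena_size: int, rng: np.random.Generator) -> PreyItem:
    """Respawn a dead item at a uniform-random arena position (in place).

    Draws exactly one position (two uniforms) from ``rng``, so the stream
    advances identically regardless of where the item died.
    """
    if item.alive:
        raise ValueError("respawn_prey called on a live item")
    pos = rng.uniform(0.0, arena_size, size=2)
    item.x, item.y = float(pos[0]), float(pos[1])
    item.alive = True
    return item


def spawn_items(
    species: str, count: int, arena_size: int, rng: np.random.Generator
) -> list[PreyItem]:
    """Place ``count`` live items of one species uniformly at random."""
    items = []
    for _ in range(count):
        pos = rng.uniform(0.0, arena_size, size=2)
        items.append(PreyItem(species, float(pos[0]), float(pos[1])))
    return items


def sample_odor(field: np.ndarray, position: tuple[float, float]) -> float:
    """Concentration of the patch containing ``position`` (toroidal wrap)."""
    n = field.shape[0]
    i, j = _cell_index(position, n)
    return float(field[i, j])
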