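"""Parametric synthetic town: grid zones, households, schools, workplaces.

The town is a rectangular grid of cells, each zoned residential,
commercial/industrial, community, or empty. Households (with sizes drawn
from a configurable distribution) are placed on residential cells and
grouped into contiguous "small areas" of roughly 50-200 dwellings; schools
sit on community cells and workplaces on commercial cells. The society
populates the households with agents carrying an age class and economic
status; students attend the school of their level nearest their home.

The layout is entirely seeded and parametric: it emulates the structure of
a small Irish town (default population 9547) without any geographic input
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TownConfig", "Town", "Society", "build_town", "build_society"]


@dataclass(frozen=True)
class TownConfig:
    """Structural parameters of the synthetic town and its population."""

    n_agents: int = 9547
    grid_shape: tuple[int, int] = (64, 64)
    frac_residential: float = 0.45
    frac_commercial: float = 0.15
    frac_community: float = 0.15
    n_workplaces: int = 40
    n_primary_schools: int = 4
    n_secondary_schools: int = 2
    #: probabilities of household sizes 1..len (mean ~2.7, Irish-like)
    household_size_probs: tuple[float, ...] = (0.23, 0.29, 0.17, 0.15, 0.10, 0.06)
    #: target mean dwellings per small area (areas hold 50-200 at full scale)
    dwellings_per_small_area: int = 125
    #: among children: probability of primary (vs secondary) school age
    child_primary_prob: float = 0.55
    #: among adults: probabilities of working / retired / unemployed
    adult_status_probs: tuple[float, float, float] = (0.60, 0.20, 0.20)
    #: contact-space granularity inside schools and workplaces: agents mix
    #: within classrooms/offices, not across a whole building
    classroom_size: int = 25
    office_size: int = 15

    def __post_init__(self):
        if self.n_agents <= 0:
            raise ValueError("n_agents must be positive")
        fr = (self.frac_residential, self.frac_commercial, self.frac_community)
        if any(not (0.0 <= f <= 1.0) for f in fr) or sum(fr) > 1.0 + 1e-12:
            raise ValueError("zone fractions must lie in [0,1] and sum to <= 1")
        n_cells = self.grid_shape[0] * self.grid_shape[1]
        if int(self.frac_residential * n_cells) < 1:
            raise ValueError("configuration yields zero residential cells")
        if int(self.frac_community * n_cells) < 1:
            raise ValueError("configuration yields zero community cells")
        if abs(sum(self.household_size_probs) - 1.0) > 1e-9:
            raise ValueError("household size probabilities must sum to 1")
        if abs(sum(self.adult_status_probs) - 1.0) > 1e-9:
            raise ValueError("adult status probabilities must sum to 1")

    def scaled(self, factor: float) -> "TownConfig":
        """A proportionally smaller (or larger) town for desk-scale runs."""
        side = max(8, int(round(self.grid_shape[0] * factor**0.5)))
        return TownConfig(
            n_agents=max(50, int(round(self.n_agents * factor))),
            grid_shape=(side, side),
            frac_residential=self.frac_residential,
            frac_commercial=self.frac_commercial,
            frac_community=self.frac_community,
            n_workplaces=max(2, int(round(self.n_workplaces * factor))),
            n_primary_schools=max(1, int(round(self.n_primary_schools * factor))),
            n_secondary_schools=max(1, int(round(self.n_secondary_schools * factor))),
            household_size_probs=self.household_size_probs,
            dwellings_per_small_area=self.dwellings_per_small_area,
            child_primary_prob=self.child_primary_prob,
            adult_status_probs=self.adult_status_probs,
        )


# zone codes
ZONE_EMPTY, ZONE_RESIDENTIAL, ZONE_COMMERCIAL, ZONE_COMMUNITY = 0, 1, 2, 3


@dataclass(frozen=True)
class Town:
    """A built town: zoned grid plus placed households, schools, workplaces."""

    config: TownConfig
    zones: np.ndarray  # flat array of zone codes, length nx*ny
    grid_shape: tuple[int, int]
    household_cell: np.ndarray  # cell index per household
    household_size: np.ndarray
    household_small_area: np.ndarray
    primary_school_cells: np.ndarray
    secondary_school_cells: np.ndarray
    workplace_cells: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    @property
    def n_households(self) -> int:
        return len(self.household_cell)

    def cell_xy(self, cells: np.ndarray) -> np.ndarray:
        """(x, y) coordinates of flat cell indices, shape (len, 2)."""
        nx = self.grid_shape[1]
        cells = np.asarray(cells)
        return np.stack([cells // nx, cells % nx], axis=-1).astype(float)

    def cells_of_zone(self, zone: int) -> np.ndarray:
        return np.flatnonzero(self.zones == zone)


def build_town(config: TownConfig, seed: int) -> Town:
    """Deterministically build the town layout from a seed.

    Zones are drawn by shuffling the cell index set and cutting it by the
    configured fractions; schools and workplaces are placed uniformly on
    cells of their zone; household sizes are drawn until the population is
    exactly ``n_agents`` (the last household is shrunk to fit).
    """
    rng = np.random.default_rng(seed)
    n_cells = config.grid_shape[0] * config.grid_shape[1]
    zones = np.full(n_cells, ZONE_EMPTY, dtype=np.int8)
    order = rng.permutation(n_cells)
    n_res = max(1, int(config.frac_residential * n_cells))
    n_com = int(config.frac_commercial * n_cells)
    n_cty = max(1, int(config.frac_community * n_cells))
    zones[order[:n_res]] = ZONE_RESIDENTIAL
    zones[order[n_res : n_res + n_com]] = ZONE_COMMERCIAL
    zones[order[n_res + n_com : n_res + n_com + n_cty]] = ZONE_COMMUNITY

    res_cells = np.flatnonzero(zones == ZONE_RESIDENTIAL)
    com_cells = np.flatnonzero(zones == ZONE_COMMERCIAL)
    cty_cells = np.flatnonzero(zones == ZONE_COMMUNITY)
    if config.n_workplaces > 0 and len(com_cells) == 0:
        raise ValueError("workplaces configured but no commercial cells")

    def _place(cells, n):
        if n == 0:
            return np.empty(0, dtype=np.int64)
        return rng.choice(cells, size=n, replace=n > len(cells))

    primary = _place(cty_cells, config.n_primary_schools)
    secondary = _place(cty_cells, config.n_secondary_schools)
    workplaces = _place(com_cells, config.n_workplaces)

    # household sizes until the population is exactly n_agents
    sizes = []
    total = 0
    probs = np.asarray(config.household_size_probs)
    while total < config.n_agents:
        s = int(rng.choice(len(probs), p=probs)) + 1
        s = min(s, config.n_agents - total)
        sizes.append(s)
        total += s
    sizes = np.asarray(sizes, dtype=np.int64)
    hh_cells = rng.choice(res_cells, size=len(sizes), replace=True)

    # contiguous-ish small areas: sort households by cell index, chunk
    n_areas = max(1, int(round(len(sizes) / config.dwellings_per_small_area)))
    order_hh = np.argsort(hh_cells, kind="stable")
    small_area = np.empty(len(sizes), dtype=np.int64)
    small_area[order_hh] = np.arange(len(sizes)) * n_areas // len(sizes)

    return Town(
        config=config,
        zones=zones,
        grid_shape=config.grid_shape,
        household_cell=hh_cells,
        household_size=sizes,
        household_small_area=small_area,
        primary_school_cells=primary,
        secondary_school_cells=secondary,
        workplace_cells=workplaces,
    )


# economic status codes
ECON_WORKING, ECON_STUDENT, ECON_RETIRED, ECON_UNEMPLOYED = 0, 1, 2, 3
# age classes
AGE_CHILD_PRIMARY, AGE_CHILD_SECONDARY, AGE_ADULT = 0, 1, 2


@dataclass
class Society:
    """Agent attribute arrays (one entry per agent).

    ``home_cell`` is the geographic grid cell of the household (used for
    distances); ``home_space`` is the household's own contact space — a
    dwelling is private, so agents at home share space only with household
    members, while agents visiting a residential area occupy the public
    street cell."""

    household_id: np.ndarray
    home_cell: np.ndarray
    home_space: np.ndarray  # n_cells + household_id: private dwelling space
    age_class: np.ndarray
    econ: np.ndarray
    dest_cell: np.ndarray  # school or workplace cell; -1 if none
    dest_space: np.ndarray  # classroom/office contact space; -1 if none
    vaccinated: np.ndarray  # bool
    n_spaces: int = 0  # total distinct contact spaces (cells + private)

    @property
    def n_agents(self) -> int:
        return len(self.home_cell)

    @property
    def has_schedule(self) -> np.ndarray:
        """Agents with scheduled weekday movements (students and workers)."""
        return self.dest_cell >= 0


def _nearest(town: Town, homes: np.ndarray, school_cells: np.ndarray) -> np.ndarray:
    """For each home cell, the school cell minimizing Euclidean distance
    (lowest index on ties)."""
    hxy = town.cell_xy(homes)
    sxy = town.cell_xy(school_cells)
    d2 = ((hxy[:, None, :] - sxy[None, :, :]) ** 2).sum(axis=2)
    return school_cells[np.argmin(d2, axis=1)]


def build_society(
    town: Town, vaccination_rate: float, seed: int
) -> Society:
    """Populate the town's households with agents.

    Each household gets one adult (size 1) or two adults, remaining members
    are children; children are students of the primary or secondary level
    and attend the nearest school of that level; working adults pick a
    uniform random workplace. Exactly ``round(vaccination_rate * n_agents)``
    agents are flagged vaccinated, uniformly at random regardless of age.
    """
    if not 0.0 <= vaccination_rate <= 1.0:
        raise ValueError("vaccination_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cfg = town.config
    n = int(town.household_size.sum())

    household_id = np.repeat(np.arange(town.n_households), town.household_size)
    home_cell = np.repeat(town.household_cell, town.household_size)

    # first min(2, size) members of each household are adults
    member_idx = np.concatenate([np.arange(s) for s in town.household_size])
    n_adults_hh = np.minimum(town.household_size, 2)
    is_adult = member_idx < np.repeat(n_adults_hh, town.household_size)

    age_class = np.full(n, AGE_ADULT, dtype=np.int8)
    child_mask = ~is_adult
    n_child = int(child_mask.sum())
    primary_child = rng.random(n_child) < cfg.child_primary_prob
    age_class[child_mask] = np.where(
        primary_child, AGE_CHILD_PRIMARY, AGE_CHILD_SECONDARY
    )

    econ = np.full(n, ECON_STUDENT, dtype=np.int8)
    n_adult = int(is_adult.sum())
    econ[is_adult] = rng.choice(
        [ECON_WORKING, ECON_RETIRED, ECON_UNEMPLOYED],
        size=n_adult,
        p=cfg.adult_status_probs,
    )

    dest = np.full(n, -1, dtype=np.int64)
    prim = (age_class == AGE_CHILD_PRIMARY)
    seco = (age_class == AGE_CHILD_SECONDARY)
    if prim.any() and len(town.primary_school_cells):
        dest[prim] = _nearest(town, home_cell[prim], town.primary_school_cells)
    if seco.any() and len(town.secondary_school_cells):
        dest[seco] = _nearest(town, home_cell[seco], town.secondary_school_cells)
    workers = econ == ECON_WORKING
    if workers.any() and len(town.workplace_cells):
        dest[workers] = rng.choice(town.workplace_cells, size=int(workers.sum()))

    vaccinated = np.zeros(n, dtype=bool)
    n_vax = int(round(vaccination_rate * n))
    if n_vax > 0:
        vaccinated[rng.choice(n, size=n_vax, replace=False)] = True

    # classroom/office contact spaces: chunk each destination's occupants
    # into room-sized groups so a school is many classrooms, not one space
    dest_space = np.full(n, -1, dtype=np.int64)
    next_space = town.n_cells + town.n_households
    for mask, room in (
        (prim, cfg.classroom_size),
        (seco, cfg.classroom_size),
        (workers, cfg.office_size),
    ):
        idx = np.flatnonzero(mask & (dest >= 0))
        for cell in np.unique(dest[idx]):
            members = idx[dest[idx] == cell]
            n_rooms = max(1, int(np.ceil(len(members) / room)))
            rooms = next_space + (np.arange(len(members)) * n_rooms // len(members))
            dest_space[members] = rooms
            next_space += n_rooms

    return Society(
        household_id=household_id,
        home_cell=home_cell,
        home_space=town.n_cells + household_id,
        age_class=age_class,
        econ=econ,
        dest_cell=dest,
        dest_space=dest_space,
        vaccinated=vaccinated,
        n_spaces=next_space,
    )
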