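"""Stochastic agent-based measles outbreak simulator.

Time advances in 2-hour ticks (12 per day). On weekdays students and
workers travel to their school or workplace between the configured leave
and return ticks; everyone else — and everyone at the weekend — picks a
random community or residential cell during daytime ticks and is home at
night. Two agents in the same grid cell in the same tick are "in contact";
each co-located susceptible-infectious pair triggers an independent
Bernoulli infection trial with the per-contact probability

    p = R0 / (c * d)

where ``c`` is the measured mean pair-contact rate and ``d`` the infectious
period in ticks. Vaccinated agents escape an otherwise-successful exposure
with probability ``ve`` (vaccine effectiveness). Newly exposed agents draw
a latent period ~ Normal(10 d, 0.5 d) and, on becoming infectious, an
infectious period ~ Normal(8 d, 0.5 d), both rounded to whole ticks.
Infectious agents may self-isolate at home: at isolation rate 1 they never
leave; at intermediate rates they stay home by an independent per-tick coin
flip. Daily incidence counts entries into the infectious state, matching
the deterministic model's cumulative-case counter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .town import Society, Town, TownConfig, build_society, build_town
from .town import ZONE_COMMUNITY, ZONE_RESIDENTIAL

# disease state codes
ST_S, ST_E, ST_I, ST_R = 0, 1, 2, 3

__all__ = [
    "DiseaseConfig",
    "ContactModelParams",
    "EpidemicTrace",
    "Scenario",
    "SCENARIOS",
    "infection_probability",
    "measure_contact_rate",
    "SimulationState",
    "init_simulation",
    "step",
    "run_outbreak",
    "simulate_outbreak",
    "truncate_first_peak",
    "first_peak_cut_index",
    "generate_scenario_dataset",
]


@dataclass(frozen=True)
class DiseaseConfig:
    """Measles natural history and intervention parameters for the ABM."""

    r0: float = 12.0
    exposed_mean_days: float = 10.0
    exposed_sd_days: float = 0.5
    infectious_mean_days: float = 8.0
    infectious_sd_days: float = 0.5
    ve: float = 0.97  # vaccine effectiveness (two-dose MMR)
    isolation_rate: float = 0.0
    vaccination_rate: float = 0.0
    steps_per_day: int = 12  # 2-hour ticks
    leave_tick: int = 4  # 08:00 departure for school/work
    return_tick: int = 8  # 16:00 return home
    max_days: int = 730  # safety cap on outbreak length

    def __post_init__(self):
        for name in ("ve", "isolation_rate", "vaccination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.steps_per_day < 1 or not 0 <= self.leave_tick < self.return_tick <= self.steps_per_day:
            raise ValueError("invalid daily schedule")

    @property
    def d_ticks(self) -> float:
        """Mean time per infection in ticks (96 at defaults)."""
        return self.infectious_mean_days * self.steps_per_day


@dataclass(frozen=True)
class ContactModelParams:
    """Inputs of the per-contact infection probability p = R0/(c*d)."""

    r0: float
    c: float  # mean pair-contact events per agent per tick, measured
    d: float  # mean time per infection in ticks


def infection_probability(params: ContactModelParams) -> float:
    """Per-contact infection probability p = R0/(c*d), clamped to [0, 1]."""
    if params.c <= 0:
        raise ValueError("contact rate c must be positive")
    if params.d <= 0:
        raise ValueError("time per infection d must be positive")
    return float(min(1.0, params.r0 / (params.c * params.d)))


@dataclass(frozen=True)
class Scenario:
    """One cell of the isolation x vaccination study grid."""

    name: str
    isolation_rate: float
    vaccination_rate: float


#: The nine study scenarios: isolation {0, 50, 100}% x vaccination {0, 50, 80}%.
SCENARIOS: dict[str, Scenario] = {
    s.name: s
    for s in [
        Scenario("S1_I0_V0", 0.0, 0.0),
        Scenario("S2_I50_V0", 0.5, 0.0),
        Scenario("S3_I100_V0", 1.0, 0.0),
        Scenario("S4_I0_V50", 0.0, 0.5),
        Scenario("S5_I50_V50", 0.5, 0.5),
        Scenario("S6_I100_V50", 1.0, 0.5),
        Scenario("S7_I0_V80", 0.0, 0.8),
        Scenario("S8_I50_V80", 0.5, 0.8),
        Scenario("S9_I100_V80", 1.0, 0.8),
    ]
}


@dataclass
class EpidemicTrace:
    """Per-day compartment counts and incidence from one ABM run."""

    scenario: str
    run: int
    S: np.ndarray  # all susceptibles, vaccinated included
    E: np.ndarray
    I: np.ndarray
    R: np.ndarray  # recovered from infection
    incidence: np.ndarray  # new infectious cases per day (E -> I entries)
    n_agents: int
    truncated: bool = False  # safety cap reached
    meta: dict = field(default_factory=dict)

    @property
    def n_days(self) -> int:
        return len(self.incidence)

    @property
    def final_size(self) -> int:
        """Total cases beyond the index case."""
        return int(self.incidence.sum())

    def prefix(self, n_days: int) -> "EpidemicTrace":
        return replace(
            self,
            S=self.S[:n_days],
            E=self.E[:n_days],
            I=self.I[:n_days],
            R=self.R[:n_days],
            incidence=self.incidence[:n_days],
        )


@dataclass
class SimulationState:
    """Mutable per-agent state of a running simulation."""

    town: Town
    society: Society
    disease: DiseaseConfig
    p: float  # per-contact infection probability
    rng: np.random.Generator
    state: np.ndarray  # disease state per agent
    counter: np.ndarray  # remaining E/I ticks
    current_cell: np.ndarray
    tick: int = 0
    new_infectious: int = 0  # E->I entries since last harvest
    movement_cells: np.ndarray = None  # random-movement destinations

    def __post_init__(self):
        if self.movement_cells is None:
            z = self.town.zones
            self.movement_cells = np.flatnonzero(
                (z == ZONE_COMMUNITY) | (z == ZONE_RESIDENTIAL)
            )


def init_simulation(
    town: Town,
    society: Society,
    disease: DiseaseConfig,
    p: float,
    seed: int,
) -> SimulationState:
    """Seed the outbreak: one infectious index case (unvaccinated when
    possible), everyone else susceptible."""
    rng = np.random.default_rng(seed)
    n = society.n_agents
    state = np.full(n, ST_S, dtype=np.int8)
    counter = np.zeros(n, dtype=np.int64)
    candidates = np.flatnonzero(~society.vaccinated)
    if len(candidates) == 0:
        candidates = np.arange(n)
    index_case = int(rng.choice(candidates))
    state[index_case] = ST_I
    counter[index_case] = _draw_period_ticks(
        rng, 1, disease.infectious_mean_days, disease.infectious_sd_days,
        disease.steps_per_day,
    )[0]
    return SimulationState(
        town=town,
        society=society,
        disease=disease,
        p=p,
        rng=rng,
        state=state,
        counter=counter,
        current_cell=society.home_space.copy(),
    )


def _draw_period_ticks(rng, n, mean_days, sd_days, steps_per_day):
    ticks = np.rint(rng.normal(mean_days, sd_days, size=n) * steps_per_day)
    return np.maximum(ticks, 1).astype(np.int64)


def _move(sim: SimulationState, infect: bool = True) -> None:
    """Place every agent for the current tick (whole trip in one tick)."""
    dz = sim.disease
    soc = sim.society
    tod = sim.tick % dz.steps_per_day
    day = sim.tick // dz.steps_per_day
    weekday = (day % 7) < 5
    daytime = dz.leave_tick <= tod < dz.return_tick

    cells = soc.home_space.copy()
    if daytime:
        scheduled = soc.has_schedule & weekday
        cells[scheduled] = soc.dest_space[scheduled]
        movers = ~scheduled
        n_m = int(movers.sum())
        if n_m:
            cells[movers] = sim.rng.choice(sim.movement_cells, size=n_m)

    if infect and dz.isolation_rate > 0.0:
        infectious = sim.state == ST_I
        if dz.isolation_rate >= 1.0:
            stay = infectious
        else:
            stay = infectious & (sim.rng.random(len(cells)) < dz.isolation_rate)
        cells[stay] = soc.home_space[stay]
    sim.current_cell = cells


def step(sim: SimulationState) -> None:
    """Advance one 2-hour tick: movement, infection trials, progression."""
    dz = sim.disease
    was_e = sim.state == ST_E
    was_i = sim.state == ST_I

    _move(sim)

    # infection trials: per co-located S-I pair, escape prob (1-p_eff)^nI
    if was_i.any():
        n_spaces = max(sim.society.n_spaces,
                       sim.town.n_cells + sim.town.n_households)
        n_inf = np.bincount(sim.current_cell[was_i], minlength=n_spaces)
        sus = sim.state == ST_S
        exposed_to = n_inf[sim.current_cell[sus]]
        at_risk = exposed_to > 0
        if at_risk.any():
            idx = np.flatnonzero(sus)[at_risk]
            p_eff = np.where(
                sim.society.vaccinated[idx], sim.p * (1.0 - dz.ve), sim.p
            )
            p_inf = 1.0 - (1.0 - p_eff) ** exposed_to[at_risk]
            hit = idx[sim.rng.random(len(idx)) < p_inf]
            if len(hit):
                sim.state[hit] = ST_E
                sim.counter[hit] = _draw_period_ticks(
                    sim.rng, len(hit), dz.exposed_mean_days, dz.exposed_sd_days,
                    dz.steps_per_day,
                )

    # countdowns for agents that entered the tick as E or I
    sim.counter[was_e | was_i] -= 1
    to_i = was_e & (sim.counter <= 0)
    to_r = was_i & (sim.counter <= 0)
    if to_i.any():
        n_new = int(to_i.sum())
        sim.state[to_i] = ST_I
        sim.counter[to_i] = _draw_period_ticks(
            sim.rng, n_new, dz.infectious_mean_days, dz.infectious_sd_days,
            dz.steps_per_day,
        )
        sim.new_infectious += n_new
    if to_r.any():
        sim.state[to_r] = ST_R
        sim.counter[to_r] = 0
    sim.tick += 1


def run_outbreak(
    town: Town,
    society: Society,
    disease: DiseaseConfig,
    p: float,
    seed: int,
    scenario: str = "",
    run_id: int = 0,
) -> EpidemicTrace:
    """Run one outbreak to extinction (or the safety cap), recording daily
    compartment counts and incidence."""
    sim = init_simulation(town, society, disease, p, seed)
    spd = disease.steps_per_day
    S, E, I, R, inc = [], [], [], [], []
    truncated = False
    for day in range(disease.max_days):
        for _ in range(spd):
            step(sim)
        S.append(int(np.sum(sim.state == ST_S)))
        E.append(int(np.sum(sim.state == ST_E)))
        I.append(int(np.sum(sim.state == ST_I)))
        R.append(int(np.sum(sim.state == ST_R)))
        inc.append(sim.new_infectious)
        sim.new_infectious = 0
        if E[-1] + I[-1] == 0:
            break
    else:
        truncated = True
    return EpidemicTrace(
        scenario=scenario,
        run=run_id,
        S=np.asarray(S),
        E=np.asarray(E),
        I=np.asarray(I),
        R=np.asarray(R),
        incidence=np.asarray(inc),
        n_agents=society.n_agents,
        truncated=truncated,
        meta={"p": p, "seed": seed},
    )


def measure_contact_rate(
    town: Town,
    society: Society,
    disease: DiseaseConfig,
    n_days: int = 14,
    seed: int = 0,
    movement: bool = True,
) -> float:
    """Mean pair-contact events per agent per tick from a disease-free
    rehearsal run (isolation never triggers because nobody is infectious).

    A contact event is an unordered pair of agents occupying the same cell
    in the same tick; ``c = total events / (n_agents * n_ticks)``.
    """
    if n_days < 1:
        raise ValueError("need at least one simulated day")
    n_ticks = n_days * disease.steps_per_day
    sim = init_simulation(town, society, disease, p=0.0, seed=seed)
    sim.state[:] = ST_S  # disease-free
    total_pairs = 0
    for _ in range(n_ticks):
        if movement:
            _move(sim, infect=False)
        occ = np.bincount(
            sim.current_cell,
            minlength=max(society.n_spaces, town.n_cells + town.n_households),
        )
        total_pairs += int(np.sum(occ * (occ - 1) // 2))
        sim.tick += 1
    return total_pairs / (society.n_agents * n_ticks)


def _centered_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def first_peak_cut_index(
    incidence: np.ndarray,
    window: int = 7,
    depth_frac: float = 0.2,
    rise_days: int = 3,
) -> int | None:
    """Day index (0-based, inclusive) at which to cut a multi-wave series.

    The daily incidence is smoothed with a centered moving average; after
    the global maximum, the first local minimum below ``depth_frac`` of the
    peak that is followed (past any flat plateau) by ``rise_days``
    consecutive strict rises marks the end of the first wave. Returns None
    for a single-wave series.
    """
    x = np.asarray(incidence, dtype=float)
    n = len(x)
    if n == 0 or not np.any(x > 0):
        return None
    s = _centered_moving_average(x, window)
    m = int(np.argmax(s))
    thresh = depth_frac * s[m]
    for j in range(m + 1, n - 1):
        if s[j] <= s[j - 1] and s[j] <= s[j + 1] and s[j] < thresh:
            k = j
            while k + 1 < n and s[k + 1] == s[j]:
                k += 1
            if k + rise_days < n and all(
                s[k + r + 1] > s[k + r] for r in range(rise_days)
            ):
                return j
    return None


def truncate_first_peak(trace: EpidemicTrace, **kwargs) -> EpidemicTrace:
    """Restrict a trace to its first epidemic wave; idempotent."""
    cut = first_peak_cut_index(trace.incidence, **kwargs)
    if cut is None:
        return trace
    return trace.prefix(cut + 1)


def simulate_outbreak(
    town_config: TownConfig,
    disease: DiseaseConfig,
    seed: int,
    scenario: str = "",
    run_id: int = 0,
    p: float | None = None,
) -> EpidemicTrace:
    """Convenience wrapper: build town and society, measure the contact
    rate, derive p and run a single outbreak."""
    ss = np.random.SeedSequence(entropy=int(seed))
    s_town, s_soc, s_c, s_run = (int(c.generate_state(1)[0] >> 33) for c in ss.spawn(4))
    town = build_town(town_config, s_town)
    society = build_society(town, disease.vaccination_rate, s_soc)
    if p is None:
        baseline = replace(disease, isolation_rate=0.0)
        c = measure_contact_rate(town, society, baseline, seed=s_c)
        p = infection_probability(ContactModelParams(disease.r0, c, disease.d_ticks))
    return run_outbreak(town, society, disease, p, s_run, scenario, run_id)


def generate_scenario_dataset(
    scenario: Scenario | str,
    n_runs: int = 50,
    base_seed: int = 0,
    town_config: TownConfig | None = None,
    disease: DiseaseConfig | None = None,
    truncate: bool = True,
) -> list[EpidemicTrace]:
    """Replicate ground-truth traces for one scenario.

    The town layout is built once from the base seed and the contact rate
    measured on a disease-free rehearsal with isolation disabled; each run
    then rebuilds the society (re-randomizing vaccination and the index
    case) and simulates an outbreak, first-peak truncated by default.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    town_config = town_config or TownConfig()
    disease = disease or DiseaseConfig()
    disease = replace(
        disease,
        isolation_rate=scenario.isolation_rate,
        vaccination_rate=scenario.vaccination_rate,
    )
    town = build_town(town_config, base_seed)
    baseline = replace(disease, isolation_rate=0.0)
    ref_society = build_society(town, disease.vaccination_rate, base_seed)
    c = measure_contact_rate(town, ref_society, baseline, seed=base_seed)
    p = infection_probability(ContactModelParams(disease.r0, c, disease.d_ticks))
    traces = []
    for k in range(n_runs):
        seed_k = base_seed + k
        society = build_society(town, disease.vaccination_rate, seed_k)
        tr = run_outbreak(town, society, disease, p, seed_k, scenario.name, k)
        tr.meta["c"] = c
        if truncate:
            tr = truncate_first_peak(tr)
        traces.append(tr)
    return traces
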