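"""Agent-based outbreak simulator: contact process, infection arithmetic,
bookkeeping invariants and scenario contrasts."""

from dataclasses import replace

import numpy as np
import pytest

from epicalib import (
    SCENARIOS,
    ContactModelParams,
    DiseaseConfig,
    build_society,
    build_town,
    generate_scenario_dataset,
    infection_probability,
    measure_contact_rate,
    run_outbreak,
    truncate_first_peak,
)
from epicalib.abm import (
    ST_E,
    ST_I,
    ST_S,
    EpidemicTrace,
    first_peak_cut_index,
    init_simulation,
    step,
)
from epicalib.town import TownConfig


@pytest.mark.parametrize(
    "r0,c,d,expected",
    [
        (12.0, 0.125, 96.0, 1.0),  # R0 = c*d boundary, clamps at 1
        (12.0, 0.25, 96.0, 0.5),
        (12.0, 10.0, 96.0, 0.0125),
    ],
)
def test_infection_probability_arithmetic(r0, c, d, expected):
    assert infection_probability(ContactModelParams(r0, c, d)) == pytest.approx(expected)


def test_infection_probability_rejects_zero_contacts():
    with pytest.raises(ValueError):
        infection_probability(ContactModelParams(12.0, 0.0, 96.0))


def test_disease_config_d_ticks_default():
    assert DiseaseConfig().d_ticks == 96.0


def _pinned_sim(n_agents, cells):
    """A degenerate simulation whose agents sit at fixed cells."""
    cfg = TownConfig(n_agents=n_agents, grid_shape=(8, 8), n_workplaces=2,
                     n_primary_schools=1, n_secondary_schools=1)
    town = build_town(cfg, seed=0)
    soc = build_society(town, 0.0, seed=0)
    sim = init_simulation(town, soc, DiseaseConfig(), p=0.0, seed=0)
    sim.current_cell = np.asarray(cells[: soc.n_agents])
    return town, soc, sim


def test_contact_rate_hand_count():
    """2 agents sharing one cell for 10 ticks: c = 10 pair events /
    (2 agents * 10 ticks) = 0.5; agents on distinct cells give c = 0."""
    cfg = TownConfig(n_agents=2, grid_shape=(8, 8), n_workplaces=1,
                     n_primary_schools=1, n_secondary_schools=1)
    town = build_town(cfg, seed=0)
    soc = build_society(town, 0.0, seed=0)
    soc.home_space[:] = 5  # both pinned to one shared space
    dz = replace(DiseaseConfig(), steps_per_day=10)
    c = measure_contact_rate(town, soc, dz, n_days=1, seed=0, movement=False)
    assert c == pytest.approx(0.5)
    soc.home_space[:] = [1, 2]
    c0 = measure_contact_rate(town, soc, dz, n_days=1, seed=0, movement=False)
    assert c0 == 0.0


def test_contact_rate_reproducible_across_seeds(small_town_config):
    town = build_town(small_town_config, seed=1)
    soc = build_society(town, 0.0, seed=1)
    dz = DiseaseConfig()
    c1 = measure_contact_rate(town, soc, dz, n_days=7, seed=1)
    c2 = measure_contact_rate(town, soc, dz, n_days=7, seed=2)
    assert c1 > 0 and c2 > 0
    assert abs(c1 - c2) / c1 < 0.10


def test_zero_transmission_keeps_disease_static(small_town_config):
    town = build_town(small_town_config, seed=4)
    soc = build_society(town, 0.0, seed=4)
    sim = init_simulation(town, soc, DiseaseConfig(), p=0.0, seed=4)
    before_i = int((sim.state == ST_I).sum())
    for _ in range(24):
        step(sim)
    assert int((sim.state == ST_E).sum()) == 0
    assert int((sim.state == ST_I).sum()) <= before_i  # index may recover


def test_disease_free_state_absorbing(small_town_config):
    town = build_town(small_town_config, seed=4)
    soc = build_society(town, 0.0, seed=4)
    sim = init_simulation(town, soc, DiseaseConfig(), p=0.5, seed=4)
    sim.state[:] = ST_S  # remove the index case
    sim.counter[:] = 0
    for _ in range(24):
        step(sim)
    assert np.all(sim.state == ST_S)


def test_full_isolation_single_person_households_extinguishes():
    """Index case isolating at home alone can never transmit."""
    cfg = TownConfig(
        n_agents=40, grid_shape=(12, 12),
        household_size_probs=(1.0,),  # singles only
        n_workplaces=2, n_primary_schools=1, n_secondary_schools=1,
    )
    town = build_town(cfg, seed=9)
    soc = build_society(town, 0.0, seed=9)
    dz = DiseaseConfig(isolation_rate=1.0)
    tr = run_outbreak(town, soc, dz, p=1.0, seed=9)
    assert tr.final_size == 0


def test_outbreak_conservation_and_determinism(small_town_config):
    town = build_town(small_town_config, seed=6)
    soc = build_society(town, 0.5, seed=6)
    dz = DiseaseConfig(vaccination_rate=0.5)
    tr1 = run_outbreak(town, soc, dz, p=0.05, seed=6)
    tr2 = run_outbreak(town, soc, dz, p=0.05, seed=6)
    for f in ("S", "E", "I", "R", "incidence"):
        assert np.array_equal(getattr(tr1, f), getattr(tr2, f))
    assert np.all(tr1.S + tr1.E + tr1.I + tr1.R == tr1.n_agents)
    assert np.all(np.diff(np.cumsum(tr1.incidence)) >= 0)
    assert tr1.E[-1] + tr1.I[-1] == 0  # ran to extinction


def test_fully_immune_population_stops_at_index_case(small_town_config):
    town = build_town(small_town_config, seed=8)
    soc = build_society(town, 1.0, seed=8)
    dz = DiseaseConfig(vaccination_rate=1.0, ve=1.0)
    tr = run_outbreak(town, soc, dz, p=1.0, seed=8)
    assert tr.final_size == 0


def test_final_size_monotone_in_vaccination(small_town_config):
    """Matched seeds, 10 replicates: mean final size shrinks as coverage
    rises (stochastic monotonicity check)."""
    means = []
    for vax in (0.0, 0.8):
        sizes = []
        for seed in range(10):
            town = build_town(small_town_config, seed=seed)
            soc = build_society(town, vax, seed=seed)
            dz = DiseaseConfig(vaccination_rate=vax)
            sizes.append(run_outbreak(town, soc, dz, p=0.05, seed=seed).final_size)
        means.append(np.mean(sizes))
    assert means[1] < means[0]


def _trace_from_incidence(inc):
    inc = np.asarray(inc)
    n = len(inc)
    return EpidemicTrace(
        scenario="T", run=0, S=np.zeros(n, int), E=np.zeros(n, int),
        I=np.zeros(n, int), R=np.zeros(n, int), incidence=inc, n_agents=100,
    )


def test_truncate_unimodal_unchanged():
    inc = np.concatenate([np.arange(20), np.arange(20)[::-1]])
    tr = truncate_first_peak(_trace_from_incidence(inc))
    assert tr.n_days == 40


def test_truncate_two_bumps_cuts_at_interwave_zero():
    """Two triangular waves separated by 12 zero days: the rule applied by
    hand cuts at the first smoothed local minimum below 20% of the peak."""
    bump1 = np.concatenate([np.linspace(0, 40, 8), np.linspace(40, 0, 8)])
    gap = np.zeros(12)
    bump2 = np.concatenate([np.linspace(0, 25, 10), np.linspace(25, 0, 10)])
    inc = np.concatenate([bump1, gap, bump2])
    cut = first_peak_cut_index(inc)
    assert cut is not None
    # the cut lands inside the inter-wave gap (days 16..27, 0-based)
    assert 15 <= cut <= 27
    tr = truncate_first_peak(_trace_from_incidence(inc))
    assert tr.n_days == cut + 1
    # idempotence
    tr2 = truncate_first_peak(tr)
    assert tr2.n_days == tr.n_days


def test_truncate_all_zero_unchanged():
    tr = truncate_first_peak(_trace_from_incidence(np.zeros(15)))
    assert tr.n_days == 15


def test_generate_scenario_dataset(small_town_config):
    traces = generate_scenario_dataset(
        "S1_I0_V0", n_runs=3, base_seed=5, town_config=small_town_config
    )
    assert len(traces) == 3
    assert sorted(t.run for t in traces) == [0, 1, 2]
    again = generate_scenario_dataset(
        "S1_I0_V0", n_runs=3, base_seed=5, town_config=small_town_config
    )
    for a, b in zip(traces, again):
        assert np.array_equal(a.incidence, b.incidence)


def test_scenario_grid_matches_study_design():
    assert len(SCENARIOS) == 9
    assert SCENARIOS["S9_I100_V80"].isolation_rate == 1.0
    assert SCENARIOS["S9_I100_V80"].vaccination_rate == 0.8
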