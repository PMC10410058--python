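"""Spatial stochastic simulator: rates, Gillespie loop, delays, juxtacrine."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from senspread import minimal as mm
from senspread import spatial as sp
from senspread.params import KineticParams, derive_compound_params
from oracles import bernoulli_chain_first_event_cdf


def small_cfg(params, **kw):
    base = dict(
        kinetic=params, domain=40.0, lesion_radius=3.0, delay=0.0,
        t_max=48.0, seed=5, placement="random",
    )
    base.update(kw)
    return sp.SimConfig(**base)


class TestInitialization:
    def test_cell_count_within_two_percent(self, params):
        cfg = sp.SimConfig(kinetic=params, domain=100.0, seed=1)
        pop = sp.initialize_population(cfg)
        expected = 0.35 * (100 * params.rcell) ** 2 / (math.pi * params.rcell**2)
        assert abs(pop.n_cells - expected) / expected < 0.02

    def test_empty_lesion_rejected(self, params):
        cfg = sp.SimConfig(kinetic=params, domain=40.0, lesion_radius=0.0, seed=1)
        with pytest.raises(ValueError, match="no cells"):
            sp.initialize_population(cfg)

    def test_single_cell_lattice_lesion_at_center(self, params):
        cfg = sp.SimConfig(
            kinetic=params, domain=60.0, lesion_radius=0.5,
            placement="lattice", seed=0,
        )
        pop = sp.initialize_population(cfg)
        primaries = np.flatnonzero(pop.mechanism == sp.MECH_PRIMARY)
        assert len(primaries) == 1
        center = 60.0 * params.rcell / 2
        assert np.allclose(pop.positions[primaries[0]], [center, center])

    def test_seeded_cells_emit_and_others_do_not(self, params):
        pop = sp.initialize_population(small_cfg(params))
        primary = pop.mechanism == sp.MECH_PRIMARY
        assert (pop.sasp_scale[primary] == 1.0).all()
        assert (pop.sasp_scale[~primary] == 0.0).all()
        assert (pop.state[primary] == sp.STATE_SENESCENT).all()


class TestInductionRate:
    def test_no_emitters_means_zero_rate(self, params):
        pop = sp.initialize_population(small_cfg(params))
        pop.sasp_scale[:] = 0.0  # silence the lesion
        j = int(np.flatnonzero(pop.state == sp.STATE_NORMAL)[0])
        assert sp.per_cell_induction_rate(j, pop, params) == 0.0

    def test_single_emitter_reduces_to_poisson_tail(self, params, derived):
        cfg = small_cfg(params, lesion_radius=0.5, placement="lattice")
        pop = sp.initialize_population(cfg)
        e = int(np.flatnonzero(pop.mechanism == sp.MECH_PRIMARY)[0])
        j = int(np.flatnonzero(pop.state == sp.STATE_NORMAL)[0])
        r = float(np.hypot(*(pop.positions[j] - pop.positions[e])))
        lam = params.NE * mm.per_cell_binding_probability(r, derived, params.rcell)
        expected = stats.poisson.sf(int(params.ND) - 1, lam)
        assert sp.per_cell_induction_rate(j, pop, params) == pytest.approx(expected)

    def test_two_emitter_rate_against_monte_carlo(self, params, derived, rng):
        """Summed Poisson streams: the tail of Poisson(lam1+lam2) must match
        paired Poisson draws from the two sources."""
        p = params.replace(ND=12.0)
        r1, r2 = 3 * p.rcell, 5 * p.rcell
        lam1 = p.NE * mm.per_cell_binding_probability(r1, derived, p.rcell)
        lam2 = p.NE * mm.per_cell_binding_probability(r2, derived, p.rcell)
        analytic = sp.poisson_induction_rate(lam1 + lam2, p.ND)
        n = 1_000_000
        draws = rng.poisson(lam1, n) + rng.poisson(lam2, n)
        emp = float((draws >= 12).mean())
        se = math.sqrt(analytic * (1 - analytic) / n)
        assert abs(emp - analytic) <= 3 * se

    def test_nd_zero_rate_is_one(self):
        assert sp.poisson_induction_rate(0.5, 0.0) == 1.0

    def test_neglog_conversion_exceeds_direct(self):
        lam = 8.0
        assert sp.poisson_induction_rate(lam, 5.0, "neglog") > (
            sp.poisson_induction_rate(lam, 5.0, "direct")
        )


class TestGillespieStep:
    def test_degenerate_selection(self, rng):
        t, cell = sp.gillespie_step(np.array([0.7, 0.0]), 0.0, rng)
        assert cell == 0 and t > 0

    def test_zero_total_rate_is_absorbing(self, rng):
        t, cell = sp.gillespie_step(np.zeros(3), 1.0, rng)
        assert math.isinf(t) and cell == -1

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ValueError, match="negative"):
            sp.gillespie_step(np.array([-0.1, 0.2]), 0.0, rng)

    def test_interevent_times_exponential_ks(self, rng):
        """Constant single-cell rate: inter-event times follow Exp(lam)."""
        lam = 0.37
        times = np.array([
            sp.gillespie_step(np.array([lam]), 0.0, rng)[0] for _ in range(10_000)
        ])
        ks = stats.kstest(times, "expon", args=(0.0, 1.0 / lam))
        assert ks.pvalue > 0.01


class TestDelayedAdvance:
    def test_zero_delay_matures_with_induction(self, params):
        cfg = small_cfg(params, kinetic=params.replace(ND=10.0), t_max=24.0)
        pop, log = sp.run_simulation(cfg)
        ind = log[log.event == "induced_paracrine"].set_index("cell_id").t
        mat = log[(log.event == "matured") & (log.mechanism == "paracrine")]
        mat = mat.set_index("cell_id").t
        assert len(ind) > 0
        common = ind.index.intersection(mat.index)
        assert np.allclose(ind.loc[common], mat.loc[common])

    def test_maturation_follows_induction_by_delay(self, params):
        cfg = small_cfg(
            params, kinetic=params.replace(ND=30.0), lesion_radius=5.0,
            delay=30.0, t_max=90.0,
        )
        pop, log = sp.run_simulation(cfg)
        ind = log[log.event == "induced_paracrine"].set_index("cell_id").t
        mat = log[(log.event == "matured") & (log.mechanism == "paracrine")]
        mat = mat.set_index("cell_id").t
        common = ind.index.intersection(mat.index)
        assert len(common) > 0
        assert np.allclose(mat.loc[common] - ind.loc[common], 30.0)

    def test_no_secondary_sourced_events_before_delay(self, params):
        """With a 144 h maturation delay no secondary cell emits (and so none
        can source an induction) before t = 144 h."""
        cfg = sp.SimConfig(
            kinetic=params.replace(ND=30.0), domain=60.0, lesion_radius=0.5,
            delay=144.0, t_max=200.0, seed=9,
        )
        pop, log = sp.run_simulation(cfg)
        mat = log[(log.event == "matured") & (log.mechanism == "paracrine")]
        assert (mat.t >= 144.0 - 1e-9).all()

    def test_event_log_invariants(self, params):
        cfg = small_cfg(params, kinetic=params.replace(ND=15.0))
        pop, log = sp.run_simulation(cfg)
        assert (np.diff(log.t) >= -1e-12).all()
        induced = log[log.event.str.startswith("induced")]
        assert induced.cell_id.is_unique
        # state machine end states
        assert set(np.unique(pop.state)) <= {0, 1, 2}

    def test_first_event_distribution_matches_fine_timestep_oracle(self, params):
        """5-cell fixture: the Gillespie first-induction time distribution
        agrees with a dt = 0.01 h Bernoulli-chain oracle within 3 SE."""
        from senspread.fixtures import tiny_population_frame

        frame = tiny_population_frame()
        p = params.replace(ND=6.0)
        positions = frame[["x", "y"]].to_numpy()
        n_reps = 2000
        t_grid = np.array([6.0, 24.0, 48.0])
        oracle = bernoulli_chain_first_event_cdf(
            positions[1:], positions[0], p, t_grid, dt=0.01,
            n_reps=n_reps, seed=3,
        )

        firsts = []
        rng = np.random.default_rng(77)
        base_pop = None
        for rep in range(n_reps):
            pop = sp.CellPopulation(
                positions=positions.copy(),
                state=np.array([2, 0, 0, 0, 0], dtype=np.int8),
                mechanism=np.array([1, 0, 0, 0, 0], dtype=np.int8),
                t_induced=np.array([0.0, *[np.nan] * 4]),
                t_mature=np.array([0.0, *[np.nan] * 4]),
                sasp_scale=np.array([1.0, 0, 0, 0, 0.0]),
            )
            cfg = sp.SimConfig(
                kinetic=p, delay=144.0, t_max=48.0,
                stop_on_first_induction=True, seed=rep,
            )
            log = sp.advance_with_delays(pop, cfg, rng)
            ind = log[log.event == "induced_paracrine"]
            firsts.append(float(ind.t.iloc[0]) if len(ind) else np.inf)
        firsts = np.array(firsts)
        for t, p_oracle in zip(t_grid, oracle):
            emp = float((firsts <= t).mean())
            se = math.sqrt(max(p_oracle * (1 - p_oracle), 1e-12) / n_reps)
            assert abs(emp - p_oracle) <= 3 * se + 1e-3, (t, emp, p_oracle)


class TestJuxtacrine:
    def test_isolated_inducer_converts_nobody(self, params):
        positions = np.array([[0.0, 0.0], [10 * params.rcell, 0.0]])
        pop = sp.CellPopulation(
            positions=positions,
            state=np.array([2, 0], dtype=np.int8),
            mechanism=np.array([1, 0], dtype=np.int8),
            t_induced=np.array([0.0, np.nan]),
            t_mature=np.array([0.0, np.nan]),
            sasp_scale=np.array([1.0, 0.0]),
        )
        cfg = sp.SimConfig(kinetic=params, juxtacrine_enabled=True)
        assert sp.apply_juxtacrine(0, pop, cfg, 0.0) == []

    def test_fire_break_cells_never_propagate(self, params):
        positions = np.array([[0.0, 0.0], [2.1 * params.rcell, 0.0]])
        pop = sp.CellPopulation(
            positions=positions,
            state=np.array([2, 0], dtype=np.int8),
            mechanism=np.array([3, 0], dtype=np.int8),  # juxtacrine inducer
            t_induced=np.array([0.0, np.nan]),
            t_mature=np.array([0.0, np.nan]),
            sasp_scale=np.array([0.0, 0.0]),
        )
        cfg = sp.SimConfig(kinetic=params, juxtacrine_enabled=True)
        assert sp.apply_juxtacrine(0, pop, cfg, 0.0) == []

    def test_paracrine_inducers_gated_by_flag(self, params):
        positions = np.array([[0.0, 0.0], [2.1 * params.rcell, 0.0]])

        def fresh():
            return sp.CellPopulation(
                positions=positions.copy(),
                state=np.array([2, 0], dtype=np.int8),
                mechanism=np.array([2, 0], dtype=np.int8),  # paracrine inducer
                t_induced=np.array([0.0, np.nan]),
                t_mature=np.array([0.0, np.nan]),
                sasp_scale=np.array([1.0, 0.0]),
            )

        off = sp.SimConfig(kinetic=params, juxtacrine_enabled=True,
                           paracrine_secondary_juxtacrine=False)
        on = off.replace(paracrine_secondary_juxtacrine=True)
        assert sp.apply_juxtacrine(0, fresh(), off, 0.0) == []
        assert sp.apply_juxtacrine(0, fresh(), on, 0.0) == [1]

    def test_converted_cells_are_silent(self, params):
        positions = np.array([[0.0, 0.0], [2.1 * params.rcell, 0.0]])
        pop = sp.CellPopulation(
            positions=positions,
            state=np.array([2, 0], dtype=np.int8),
            mechanism=np.array([1, 0], dtype=np.int8),
            t_induced=np.array([0.0, np.nan]),
            t_mature=np.array([0.0, np.nan]),
            sasp_scale=np.array([1.0, 0.0]),
        )
        cfg = sp.SimConfig(kinetic=params, juxtacrine_enabled=True)
        converted = sp.apply_juxtacrine(0, pop, cfg, 3.0)
        assert converted == [1]
        assert pop.sasp_scale[1] == 0.0
        assert pop.mechanism[1] == sp.MECH_JUXTACRINE
        assert pop.t_mature[1] == 3.0

    def test_lattice_coordination_count(self, params):
        """On the sigma=0.35 lattice (spacing ~3 rcell) no neighbour sits
        within the 2.2 rcell contact radius — the geometric oracle count."""
        cfg = sp.SimConfig(
            kinetic=params, domain=30.0, lesion_radius=0.5,
            placement="lattice", juxtacrine_enabled=True, seed=0,
        )
        pop = sp.initialize_population(cfg)
        e = int(np.flatnonzero(pop.mechanism == sp.MECH_PRIMARY)[0])
        spacing = math.sqrt(math.pi * params.rcell**2 / params.sigma)
        r = np.hypot(*(pop.positions - pop.positions[e]).T)
        oracle = int(((r > 0) & (r <= 2.2 * params.rcell)).sum())
        assert oracle == (0 if spacing > 2.2 * params.rcell else oracle)
        assert sp.apply_juxtacrine(e, pop, cfg, 0.0) == []


class TestSummaries:
    def test_counts_partition_and_monotone(self, params):
        cfg = small_cfg(
            params, kinetic=params.replace(ND=20.0),
            juxtacrine_enabled=True, paracrine_secondary_juxtacrine=True,
        )
        pop, log = sp.run_simulation(cfg)
        summ = sp.summarize(log, pop, np.linspace(0, 48, 9))
        assert (summ.total == summ.primary + summ.paracrine + summ.juxtacrine).all()
        assert (summ.paracrine.diff().dropna() >= 0).all()
        assert (summ.juxtacrine.diff().dropna() >= 0).all()

    def test_radial_profile_covers_population(self, params):
        cfg = small_cfg(params, kinetic=params.replace(ND=20.0))
        pop, log = sp.run_simulation(cfg)
        prof = sp.radial_profile(pop, n_bins=10)
        assert prof.n_cells.sum() == pop.n_cells
        assert prof.n_senescent.sum() >= (pop.mechanism == sp.MECH_PRIMARY).sum()


class TestPairedScenarios:
    def test_fire_break_reduces_paracrine_counts(self, params):
        """Juxtacrine conversion consumes inducible neighbours, so paracrine
        counts at matched times do not increase when it is enabled
        (paired seeds, majority over replicates)."""
        p = params.replace(ND=62.0)
        times = [2.0, 6.0, 12.0, 24.0]
        wins = 0
        n_reps = 6
        for rep in range(n_reps):
            base = sp.SimConfig(
                kinetic=p, domain=60.0, lesion_radius=6.0, delay=0.0,
                t_max=24.0, seed=100 + rep,
                juxtacrine_enabled=False,
            )
            pop0, log0 = sp.run_simulation(base)
            pop1, log1 = sp.run_simulation(
                base.replace(juxtacrine_enabled=True,
                             paracrine_secondary_juxtacrine=True)
            )
            c0 = sp.summarize(log0, pop0, times).paracrine
            c1 = sp.summarize(log1, pop1, times).paracrine
            if (c1 <= c0).all():
                wins += 1
        assert wins > n_reps / 2

    def test_containment_with_silent_secondaries(self, params):
        """secondary_sasp_scale = 0: only the lesion ever emits, so the
        spread stays local over a lifespan horizon and creeps by at most a
        couple of cells when the horizon is extended tenfold."""
        p = params.replace(ND=62.0)
        base = sp.SimConfig(
            kinetic=p, domain=60.0, lesion_radius=5.0, delay=0.0,
            secondary_sasp_scale=0.0, t_max=5e5, seed=42,
        )
        pop1, log1 = sp.run_simulation(base)
        pop2, log2 = sp.run_simulation(base.replace(t_max=5e6))
        n1 = (pop1.state != sp.STATE_NORMAL).sum()
        n2 = (pop2.state != sp.STATE_NORMAL).sum()
        assert n2 - n1 <= 2
        assert n2 < 0.05 * pop2.n_cells  # spread stayed local


class TestCrossValidation:
    def test_impossible_points_never_spread(self, params):
        tab = sp.compare_to_minimal(
            params, nd_values=[60], rtot_values=[1e5], n_reps=20, seed=3,
        )
        assert tab.p_model.iloc[0] < 1e-12
        assert tab.p_empirical.iloc[0] == 0.0

    def test_lattice_agreement_over_nd_sweep(self, params):
        tab = sp.compare_to_minimal(
            params, nd_values=list(range(8, 20)), rtot_values=[1e5],
            n_reps=60, placement="lattice", seed=17,
        )
        ok = (tab.dev_se <= 3.0) | (
            (tab.p_model < 1e-9) & (tab.p_empirical == 0.0)
        )
        assert ok.mean() >= 0.9, tab.to_string()

    def test_random_placement_widens_transition(self, params):
        """Random geometry makes spread depend on the realised neighbours, so
        the ND range with empirical probability strictly inside (0,1) is at
        least as wide as on the lattice."""
        nds = list(range(8, 22))
        lat = sp.compare_to_minimal(
            params, nd_values=nds, rtot_values=[1e5], n_reps=40,
            placement="lattice", seed=23,
        )
        rnd = sp.compare_to_minimal(
            params, nd_values=nds, rtot_values=[1e5], n_reps=40,
            placement="random", seed=23,
        )

        def width(tab):
            mid = tab[(tab.p_empirical > 0) & (tab.p_empirical < 1)]
            return len(mid)

        assert width(rnd) >= width(lat)
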