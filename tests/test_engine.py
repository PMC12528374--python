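import math

import numpy as np
import pytest
from scipy import stats

from viscoclutch.engine import (
    ClutchEnsembleState,
    ClutchParams,
    Genotype,
    MotorParams,
    SimConfig,
    auto_dt,
    koff_of_force,
    replicate_seed,
    retrograde_velocity,
    run_simulation,
    step_ensemble,
)
from viscoclutch.substrate import SLSParams

from oracles import gillespie_occupancy_samples

CONTROL = Genotype.control()
KD = Genotype.piezo1_kd()


class TestKoffOfForce:
    @pytest.mark.parametrize(
        "force, genotype, expected_over_koff0",
        [
            (0.0, CONTROL, 1.0),
            (0.0, KD, 1.15),
            (2.0, CONTROL, math.e),  # f = f_bond
            (4.0, CONTROL, math.e**2),
        ],
    )
    def test_slip_law(self, slip_clutch, force, genotype, expected_over_koff0):
        assert koff_of_force(force, slip_clutch, genotype) == pytest.approx(
            expected_over_koff0 * slip_clutch.k_off0
        )

    def test_monotone_in_force(self, slip_clutch):
        fs = np.linspace(0, 30, 100)
        ks = [koff_of_force(f, slip_clutch, CONTROL) for f in fs]
        assert np.all(np.diff(ks) >= 0)

    def test_negative_force_rejected(self, slip_clutch):
        with pytest.raises(ValueError):
            koff_of_force(-0.1, slip_clutch, CONTROL)

    def test_catch_slip_zero_force_rate_and_valley(self):
        p = ClutchParams()  # default catch-slip
        assert koff_of_force(0.0, p, CONTROL) == pytest.approx(p.k_off0)
        # catch pathway: the rate dips below the force-free value at
        # intermediate force before the slip arm takes over
        fs = np.linspace(0.0, 15.0, 300)
        ks = np.array([koff_of_force(f, p, CONTROL) for f in fs])
        assert ks.min() < 0.5 * p.k_off0
        assert 1.0 < fs[ks.argmin()] < 10.0
        assert ks[-1] > p.k_off0


class TestRetrogradeVelocity:
    def test_force_velocity_law(self, motors):
        assert retrograde_velocity(0.0, motors) == motors.v_unloaded
        assert retrograde_velocity(motors.stall_force, motors) == 0.0
        assert retrograde_velocity(motors.stall_force / 2, motors) == pytest.approx(
            motors.v_unloaded / 2
        )
        assert retrograde_velocity(2 * motors.stall_force, motors) == 0.0

    def test_negative_load_rejected(self, motors):
        with pytest.raises(ValueError):
            retrograde_velocity(-1.0, motors)


class TestStepEnsemble:
    def test_no_binding_leaves_state_invariant(self, motors, sls_unit, rng):
        clutch = ClutchParams(k_on=0.0, bond_law="slip", k_off0=1.0)
        state = ClutchEnsembleState.initial(clutch, motors)
        out = step_ensemble(state, clutch, motors, sls_unit, CONTROL, 0.01, rng)
        assert out.t == pytest.approx(0.01)
        assert not out.bound.any()
        assert out.n_recruited == clutch.n_clutch_init
        assert out.x_sub == pytest.approx(0.0)

    def test_unreachable_unfolding_disables_recruitment(self, motors, rng):
        clutch = ClutchParams(bond_law="slip", f_unfold=1e18)
        sls = SLSParams(1.0, 5.0, 1.0)
        state = ClutchEnsembleState.initial(clutch, motors)
        for _ in range(300):
            state = step_ensemble(state, clutch, motors, sls, CONTROL, 0.005, rng)
        assert state.n_recruited == clutch.n_clutch_init
        assert not state.vinculin.any()

    def test_force_balance_every_step(self, motors, sls_unit, rng):
        clutch = ClutchParams(bond_law="slip", n_clutch_init=50, n_clutch_max=100)
        state = ClutchEnsembleState.initial(clutch, motors)
        for _ in range(200):
            state = step_ensemble(state, clutch, motors, sls_unit, CONTROL, 0.002, rng)
            clutch_load = clutch.k_clutch * (
                state.x_clutch[state.bound] - state.x_sub
            ).sum()
            assert state.substrate_force(sls_unit) == pytest.approx(
                clutch_load, abs=1e-6
            )

    def test_state_hierarchy_invariant(self, motors, rng):
        # vinculin-bound implies talin-unfolded implies bound
        clutch = ClutchParams(bond_law="slip", f_unfold=3.0, k_vin=5.0)
        sls = SLSParams(1.0, 10.0, 1.0)
        state = ClutchEnsembleState.initial(clutch, motors)
        for _ in range(400):
            state = step_ensemble(state, clutch, motors, sls, CONTROL, 0.002, rng)
            assert np.all(~state.vinculin | state.unfolded)
            assert np.all(~state.unfolded | state.bound)
            assert clutch.n_clutch_init <= state.n_recruited <= clutch.n_clutch_max

    def test_rate_contract_violation_raises(self, motors, sls_unit, rng):
        clutch = ClutchParams(bond_law="slip", k_on=100.0)
        state = ClutchEnsembleState.initial(clutch, motors)
        with pytest.raises(ValueError, match="tau-leaping"):
            step_ensemble(state, clutch, motors, sls_unit, CONTROL, 0.01, rng)


class TestRunSimulation:
    def test_same_seed_bit_identical(self, slip_clutch, motors, sls_unit, quick_sim):
        a = run_simulation(slip_clutch, motors, sls_unit, CONTROL, quick_sim)
        b = run_simulation(slip_clutch, motors, sls_unit, CONTROL, quick_sim)
        assert np.array_equal(a.substrate_force, b.substrate_force)
        assert np.array_equal(a.flow, b.flow)
        assert a.summary == b.summary

    def test_different_seeds_differ(self, slip_clutch, motors, sls_unit):
        a = run_simulation(slip_clutch, motors, sls_unit, CONTROL, SimConfig(duration=10, seed=1))
        b = run_simulation(slip_clutch, motors, sls_unit, CONTROL, SimConfig(duration=10, seed=2))
        assert not np.array_equal(a.substrate_force, b.substrate_force)

    def test_force_free_occupancy_matches_two_state_kinetics(self, sls_unit):
        # v = 0: no forces ever build, binding is a two-state process
        # with steady-state bound fraction k_on/(k_on + k_off0)
        clutch = ClutchParams(bond_law="slip", k_on=1.0, k_off0=1.0, f_unfold=1e18)
        motors = MotorParams(v_unloaded=0.0)
        res = run_simulation(
            clutch, motors, sls_unit, CONTROL,
            SimConfig(duration=120.0, dt=0.01, record_dt=0.5, seed=42),
        )
        window = res.t > 20.0
        samples = res.bound_fraction[window]
        expected = clutch.k_on / (clutch.k_on + clutch.k_off0)
        n = clutch.n_clutch_init
        # conservative SE: treat recorded samples as independent
        # binomial draws and inflate for autocorrelation
        se = math.sqrt(expected * (1 - expected) / n) * 3
        assert abs(samples.mean() - expected) < 3 * se

    def test_monotonicity_in_koff_factor(self, sls_unit):
        clutch = ClutchParams(
            bond_law="slip", k_on=1.0, k_off0=1.0, f_unfold=1e18
        )
        motors = MotorParams(v_unloaded=0.0)
        means = []
        for factor in (1.0, 1.5, 2.5):
            geno = Genotype("siPiezo1", factor) if factor != 1.0 else CONTROL
            vals = [
                run_simulation(
                    clutch, motors, sls_unit, geno,
                    SimConfig(duration=60.0, dt=0.01, seed=s),
                ).summary["bound_fraction"]
                for s in range(4)
            ]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_recruitment_is_non_decreasing(self, motors):
        clutch = ClutchParams(bond_law="slip", f_unfold=4.0, f_bond=4.0, k_vin=2.0)
        sls = SLSParams(2.0, 5.0, 2.0)
        res = run_simulation(clutch, motors, sls, CONTROL, SimConfig(duration=30, seed=3))
        assert np.all(np.diff(res.integrin_density) >= 0)

    def test_fixed_step_matches_event_driven_oracle(self, sls_unit):
        # 3-clutch toy at zero motor speed: occupancy distribution of
        # the tau-leaping engine vs an exact Gillespie simulation
        k_on, k_off = 1.0, 2.0
        clutch = ClutchParams(
            n_clutch_init=3, n_clutch_max=3, k_on=k_on, k_off0=k_off,
            bond_law="slip", f_unfold=1e18, d_recruit=0,
        )
        motors = MotorParams(v_unloaded=0.0)
        res = run_simulation(
            clutch, motors, sls_unit, CONTROL,
            SimConfig(duration=5000.0, dt=0.02, record_dt=1.0, seed=11),
        )
        fixed = np.rint(res.bound_fraction[res.t > 20.0] * 3).astype(int)
        oracle = gillespie_occupancy_samples(
            3, k_on, k_off, n_events=10_000, sample_dt=1.0,
            rng=np.random.default_rng(13),
        )
        counts_fixed = np.bincount(fixed, minlength=4)
        counts_oracle = np.bincount(oracle, minlength=4)
        table = np.vstack([counts_fixed, counts_oracle])
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_elastic_limit_recovers_classic_clutch_regimes(self, motors):
        # k1 -> 0 reduces to the classic elastic clutch: load-and-fail
        # engagement on soft springs (high bound fraction, slowed flow)
        # gives way to rapid frictional turnover on stiff springs
        # (sparse engagement, flow near the unloaded speed)
        clutch = ClutchParams(
            bond_law="slip", k_on=1.0, k_off0=1.0, f_bond=2.0, f_unfold=1e18
        )
        flows, bfs = [], []
        for k2 in (0.05, 0.2, 5.0):
            sls = SLSParams(k1=0.0, k2=k2, eta=1.0)
            vals = [
                run_simulation(
                    clutch, motors, sls, CONTROL, SimConfig(duration=40, seed=s)
                ).summary
                for s in range(3)
            ]
            flows.append(np.mean([v["retrograde_flow_nm_s"] for v in vals]))
            bfs.append(np.mean([v["bound_fraction"] for v in vals]))
        assert flows[2] > flows[0] and flows[2] > flows[1]
        assert bfs[0] > bfs[2] and bfs[1] > bfs[2]

    def test_auto_dt_honours_contracts(self, motors, sls_unit):
        clutch = ClutchParams()
        dt = auto_dt(clutch, motors, sls_unit, KD)
        assert dt * max(clutch.k_on, clutch.k_off0 * 1.15, clutch.k_vin) <= 0.1
        assert dt <= clutch.f_bond / (5 * clutch.k_clutch * motors.v_unloaded) + 1e-15
        assert dt <= sls_unit.tau_relax / 10


class TestReplicateSeed:
    def test_deterministic_and_distinct(self):
        s1 = replicate_seed(0, "soft|V+|scRNA", 3)
        assert s1 == replicate_seed(0, "soft|V+|scRNA", 3)
        assert s1 != replicate_seed(0, "soft|V+|scRNA", 4)
        assert s1 != replicate_seed(0, "soft|V-|scRNA", 3)
        assert s1 != replicate_seed(1, "soft|V+|scRNA", 3)
        assert 0 <= s1 < 2**31
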