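"""Euler integration of accumulating pools and the two-pool asymptote."""

import numpy as np
import pytest

from leakyflux.fluxes import FluxState
from leakyflux.hybrid_dynamics import (
    HybridSimulator,
    SimulationConfig,
    StepInstabilityError,
    pmol_per_cell,
    simulate_timecourse,
    two_pool_mixing_fraction,
)
from leakyflux.label_simulation import LabelInput
from leakyflux.network_model import parse_model
from leakyflux.synthetic_data import (
    central_label_input,
    central_true_fluxes,
    draw_random_fluxes,
)

# exchange toy: source -> A, A partly drained, A <-> pool P reversibly;
# with net exchange zero the pool concentration is constant and its MID
# approaches A's with a closed-form exponential.
EXCHANGE_TOY = """
@source S
@pool P
mk\tS (a) -> A (a)
drain\tA (a) ->
x\tA (a) <-> P (a)
"""


def toy_setup(net_x=0.0, e=0.5, mk=1.0):
    m = parse_model(EXCHANGE_TOY)
    fs = FluxState({"mk": mk, "drain": mk - net_x, "x": net_x}, {"x": e})
    li = LabelInput.from_patterns(m, {"S": [(1.0, "U")]})
    return m, fs, li


class TestTwoPoolMixing:
    @pytest.mark.parametrize("ratio, expected", [
        (0.0, 0.0), (0.1, 0.1 / 1.1), (1.0, 0.5), (2.0, 2 / 3),
        (10.0, 10 / 11), (100.0, 100 / 101),
    ])
    def test_asymptote(self, ratio, expected):
        assert two_pool_mixing_fraction(ratio) == pytest.approx(expected)

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            two_pool_mixing_fraction(-0.1)


class TestUnits:
    def test_extracellular_pool_per_cell(self):
        assert pmol_per_cell(10.0, 2.0, 1e6) == pytest.approx(20.0)
        assert pmol_per_cell(2.0, 2.0, 1e6) == pytest.approx(4.0)


class TestEulerStepping:
    def test_zero_net_zero_exchange_is_flat(self):
        m, fs, li = toy_setup(net_x=0.0, e=0.0)
        cfg = SimulationConfig(horizon_min=60, step_min=1.0)
        traj = simulate_timecourse(m, fs, {"P": 2.0}, li, cfg)
        np.testing.assert_allclose(traj.pool_conc["P"], 2.0)
        np.testing.assert_allclose(traj.pool_mid["P"][:, 0], 1.0)

    def test_pure_efflux_adds_fully_labelled(self):
        """One step of pure efflux from a fully labelled cell puts v*dt
        entirely into the top mass fraction of an unlabelled pool."""
        m = parse_model("@source S\n@pool P\nmk\tS (ab) -> A (ab)\nex\tA (ab) -> P (ab)")
        fs = FluxState({"mk": 0.5, "ex": 0.5})
        li = LabelInput.from_patterns(m, {"S": [(1.0, "U")]})
        cfg = SimulationConfig(horizon_min=1.0, step_min=1.0)
        traj = simulate_timecourse(m, fs, {"P": 1.0}, li, cfg)
        assert traj.pool_conc["P"][-1] == pytest.approx(1.5)
        np.testing.assert_allclose(
            traj.pool_mid["P"][-1] * 1.5, [1.0, 0.0, 0.5], atol=1e-12
        )

    def test_mass_conservation_per_step(self):
        m, fs, li = toy_setup(net_x=0.2, e=1.0)
        cfg = SimulationConfig(horizon_min=30, step_min=1.0)
        traj = simulate_timecourse(m, fs, {"P": 1.0}, li, cfg)
        # pool grows by exactly dt * net flux each step
        np.testing.assert_allclose(np.diff(traj.pool_conc["P"]), 0.2, atol=1e-12)

    def test_euler_first_order_convergence(self):
        """Halving dt roughly halves the terminal MID error vs the analytic
        exponential solution of the exchange-only two-pool system."""
        mk, e, C = 1.0, 0.5, 10.0
        horizon = 60.0
        k = e * mk / ((mk + e) * C)  # per min: effective mixing rate
        exact = 1.0 - np.exp(-k * horizon)  # labelled fraction of P
        errors = []
        for dt in (4.0, 2.0, 1.0):
            m, fs, li = toy_setup(net_x=0.0, e=e, mk=mk)
            cfg = SimulationConfig(horizon_min=horizon, step_min=dt)
            traj = simulate_timecourse(m, fs, {"P": C}, li, cfg)
            errors.append(abs(traj.pool_mid["P"][-1, 1] - exact))
        assert errors[0] > errors[1] > errors[2]
        assert errors[0] / errors[1] == pytest.approx(2.0, rel=0.25)
        assert errors[1] / errors[2] == pytest.approx(2.0, rel=0.25)

    def test_instability_error_when_step_too_large(self):
        m = parse_model("@source S\n@pool P\nmk\tS (a) -> A (a)\nup\tP (a) -> A (a)\ndrain\tA (a) ->")
        fs = FluxState({"mk": 1.0, "up": 1.0, "drain": 2.0})
        li = LabelInput.from_patterns(m, {"S": [(1.0, "U")]})
        cfg = SimulationConfig(horizon_min=10, step_min=5.0)
        with pytest.raises(StepInstabilityError):
            simulate_timecourse(m, fs, {"P": 2.0}, li, cfg)

    def test_measurement_times_must_lie_on_grid(self):
        with pytest.raises(ValueError, match="grid"):
            SimulationConfig(horizon_min=63, step_min=7.0, record_times=(0.0, 30.0))
        with pytest.raises(ValueError, match="multiple"):
            SimulationConfig(horizon_min=61, step_min=2.0)


@pytest.fixture(scope="module")
def simulator(suite):
    return HybridSimulator(
        suite["central_carbon"].model, record_intracellular=("PYR_c",)
    )


class TestCentralTimecourse:
    def test_mid_normalisation_along_trajectory(self, simulator):
        fs = central_true_fluxes()
        li = central_label_input(0.469)
        cfg = SimulationConfig.for_culture(180, step_min=2.0)
        traj = simulator.run(fs, {"LAC_x": 1.0, "PYR_x": 0.1, "GLC_x": 11.1}, li, cfg)
        for mids in traj.pool_mid.values():
            np.testing.assert_allclose(mids.sum(axis=1), 1.0, atol=1e-9)
            assert mids.min() >= -1e-12

    def test_carbon_bookkeeping_closes(self, suite, rng, simulator):
        """Glucose+glutamine carbon consumed equals carbon accumulated in
        pools + CO2 + biosynthetic sinks, within 1e-6 relative."""
        for _ in range(3):
            fs = draw_random_fluxes(suite["central_carbon"].model, rng,
                                    lo=0.1, hi=1.0)
            li = central_label_input(0.469)
            cfg = SimulationConfig.for_culture(180, step_min=5.0)
            traj = simulator.run(
                fs, {"LAC_x": 5.0, "PYR_x": 1.0, "GLC_x": 11.1}, li, cfg
            )
            assert traj.carbon_closure() < 1e-6

    def test_glucose_depletes_at_uptake_flux(self, simulator):
        fs = central_true_fluxes(hk=0.65)
        li = central_label_input(0.469)
        cfg = SimulationConfig.for_culture(180, step_min=1.0, protein_ug=150.0)
        traj = simulator.run(fs, {"LAC_x": 1.0, "PYR_x": 0.1, "GLC_x": 11.1}, li, cfg)
        expected_drop = 0.65 * 150.0 / 60000.0 * 180.0  # mM over 3 h
        drop = traj.source_conc["GLC_x"][0] - traj.source_conc["GLC_x"][-1]
        assert drop == pytest.approx(expected_drop, rel=1e-9)

    def test_lactate_pool_buffers_pyruvate_enrichment(self, simulator):
        """The paper's central qualitative claim: with fast lactate exchange,
        a 10x larger extracellular lactate pool slows pyruvate M3 enrichment
        (extracellular AND intracellular); with zero lactate exchange the
        pyruvate trajectories are independent of the lactate pool size."""
        li = central_label_input(0.469)
        cfg = SimulationConfig.for_culture(
            180, step_min=2.0, record_times=tuple(float(t) for t in range(0, 181, 30))
        )

        def run(lac0, exch_ratio):
            fs = central_true_fluxes(lactate_exchange_ratio=exch_ratio)
            return simulator.run(
                fs, {"LAC_x": lac0, "PYR_x": 0.1, "GLC_x": 11.1}, li, cfg
            )

        lo, hi = run(1.0, 20.0), run(10.0, 20.0)
        assert np.all(
            hi.pool_mid["PYR_x"][1:, 3] < lo.pool_mid["PYR_x"][1:, 3]
        )
        assert np.all(
            hi.intra_mid["PYR_c"][1:, 3] < lo.intra_mid["PYR_c"][1:, 3]
        )
        lo0, hi0 = run(1.0, 0.0), run(10.0, 0.0)
        np.testing.assert_allclose(
            lo0.pool_mid["PYR_x"][:, 3], hi0.pool_mid["PYR_x"][:, 3], atol=1e-12
        )
        np.testing.assert_allclose(
            lo0.intra_mid["PYR_c"], hi0.intra_mid["PYR_c"], atol=1e-12
        )

    def test_trajectory_export_tidy(self, simulator):
        fs = central_true_fluxes()
        li = central_label_input(0.469)
        cfg = SimulationConfig.for_culture(60, step_min=10.0)
        traj = simulator.run(fs, {"LAC_x": 1.0, "PYR_x": 0.1, "GLC_x": 11.1}, li, cfg)
        df = traj.to_frame()
        assert {"time_min", "pool", "conc_mM", "M0", "M3"} <= set(df.columns)
        assert set(df["pool"]) == {"LAC_x", "PYR_x", "GLC_x"}
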