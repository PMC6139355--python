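"""Closed-loop network: conservation, relaxation dynamics, steady state."""

import numpy as np
import pytest

import shuntsim as ss
from shuntsim import units as u
from shuntsim.model import assemble_rhs, run_to_steady_state
from shuntsim.parameters import (
    IX_V,
    NX,
    ShuntSpec,
    default_parameter_set,
    initial_state,
)


def random_states(rng, params, n):
    """Physiologically plausible random states around the cold-start point."""
    x0 = initial_state(params)
    for _ in range(n):
        x = x0.copy()
        x[:9] *= rng.uniform(0.5, 1.8, size=9)
        x[9:] = rng.uniform(-1e-4, 3e-4, size=NX - 9)  # flows, m^3/s
        yield x


@pytest.mark.parametrize("shunt", [ShuntSpec("NONE", 0.0),
                                   ShuntSpec("ASD", 8.0),
                                   ShuntSpec("POTTS", 8.0)])
def test_closed_loop_conserves_blood_volume(rng, shunt):
    """Sum of compartment dV/dt vanishes for any state and any shunt."""
    params = default_parameter_set().with_shunt(shunt)
    for x in random_states(rng, params, 10):
        for t in (0.0, 0.12, 0.3):
            dx = assemble_rhs(x, params, t=t)
            total = dx[:9].sum()
            scale = np.abs(dx[:9]).max() + 1e-12
            assert abs(total) < 1e-9 * scale + 1e-18


def test_quiescent_network_is_stationary():
    """No flows and no activation -> no volume changes."""
    params = default_parameter_set()
    for w in params.walls.values():
        w.sigma_act = 0.0
        w.sigma_pas = 0.0
    x = initial_state(params)
    x[:9] = np.array([20, 30, 20, 30, 25, 31, 215, 18, 50], dtype=float) * u.ML
    for name in ("AoP", "AoD", "SV", "PA", "PV"):
        x[IX_V[name]] = params.nodes[name].V_0 * u.ML  # all pressures zero
    x[9:] = 0.0
    dx = assemble_rhs(x, params, t=0.45)  # outside every activation window
    assert np.abs(dx[:9]).max() < 1e-15


def test_single_node_rc_relaxation():
    """A compliance node charged through a resistance relaxes exponentially
    with time constant R*C (checked against the analytic solution)."""
    from shuntsim.model import compliance_pressure
    from shuntsim.parameters import ComplianceNode

    node = ComplianceNode(V_0=60.0, C=1.2)   # mL/mmHg
    r = 30.0                                  # mmHg min/l
    p_src = 50.0
    # dV/dt = (p_src - p(V))/R  (clinical units: mL/s)
    r_si = r * u.R_CLIN
    c_si = node.C * u.C_CLIN
    tau = r_si * c_si
    dt = 1e-3
    v = node.V_0 * u.ML
    t_end = 3 * tau
    n = int(t_end / dt)
    for _ in range(n):
        p = compliance_pressure(node, v / u.ML) * u.MMHG
        # RK4 for dv/dt = (p_src - p(v))/R
        def f(vol):
            return (p_src * u.MMHG - compliance_pressure(node, vol / u.ML) * u.MMHG) / r_si
        k1 = f(v)
        k2 = f(v + 0.5 * dt * k1)
        k3 = f(v + 0.5 * dt * k2)
        k4 = f(v + dt * k3)
        v += dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    p_final = compliance_pressure(node, v / u.ML)
    expected = p_src * (1 - np.exp(-t_end / tau))
    assert p_final == pytest.approx(expected, rel=1e-4)


class TestSteadyState:
    def test_controllers_recover_set_points(self, quick_patient):
        assert quick_patient.co == pytest.approx(2.1, rel=2e-3)
        assert quick_patient.map == pytest.approx(61.0, rel=2e-3)

    def test_periodicity_of_converged_cycle(self, frozen_patient):
        """State at cycle start vs cycle end differs < 1e-4 relative.

        The recorded samples are step starts, so the cycle end is the state
        the solver carries after the recorded beat."""
        start = frozen_patient.cycle.volumes[0]
        end = frozen_patient.state[:9] / 1e-6  # SI m^3 -> mL
        rel = np.abs(end - start) / start
        assert rel.max() < 1e-4

    def test_volume_conservation_over_cycle(self, frozen_patient):
        """With controllers frozen total blood volume is conserved to 1e-6."""
        tot = frozen_patient.cycle.volumes.sum(axis=1)
        assert np.abs(tot - tot[0]).max() / tot[0] < 1e-6

    def test_restart_from_converged_state_is_fast_and_stable(self, frozen_patient):
        again = ss.run_to_steady_state(frozen_patient.params,
                                       init=frozen_patient.state,
                                       controllers=False)
        assert again.beats <= 4
        assert again.co == pytest.approx(frozen_patient.co, rel=1e-5)
        assert again.map == pytest.approx(frozen_patient.map, rel=1e-5)

    def test_node_flow_balance_at_periodicity(self, frozen_patient):
        """Cycle-mean inflow equals outflow for every node within 0.5%."""
        c = frozen_patient.cycle
        means = {name: np.mean(c.flow(name)) for name in c.FLOWS}
        co = means["ao"]
        balances = {
            "AoP": means["ao"] - means["seg"] - means["upper"],
            "AoD": means["seg"] - means["lower"],
            "SV": means["upper"] + means["lower"] - means["ven"],
            "PA": means["pulv"] - means["pulm"],
            "PV": means["pulm"] - means["pven"],
        }
        for name, residual in balances.items():
            assert abs(residual) / co < 5e-3, name

    def test_steady_orifice_matches_closed_form(self):
        """Integrating a single two-way orifice between fixed pressures
        converges to the closed-form Bernoulli flow within 0.1%."""
        from shuntsim.model import orifice_flow_rhs, steady_orifice_flow
        from shuntsim.parameters import Orifice

        orif = Orifice(A_open=0.385, one_way=False)
        dp = 20.0
        q = 0.0
        dt = 5e-4
        for _ in range(4000):
            k1 = orifice_flow_rhs(orif, dp, q)
            k2 = orifice_flow_rhs(orif, dp, q + 0.5 * dt * k1)
            k3 = orifice_flow_rhs(orif, dp, q + 0.5 * dt * k2)
            k4 = orifice_flow_rhs(orif, dp, q + dt * k3)
            q += dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        assert q == pytest.approx(steady_orifice_flow(orif.A_open, dp), rel=1e-3)

    def test_septal_coupling_squeezes_left_ventricle(self, frozen_patient):
        """Under suprasystemic right ventricular pressure the septal coupling
        shifts the LV loop left (lower end-diastolic volume) relative to the
        uncoupled model."""
        params = frozen_patient.params.copy()
        params.pulmonary.dp_ref *= 10.0  # acute suprasystemic afterload
        params.walls["RV"].sigma_act *= 4.0
        params.septum.S_c = 1.0
        high = ss.run_to_steady_state(params, init=frozen_patient.state,
                                      controllers=False)
        assert high.cycle.pressure("RV").max() > high.cycle.pressure("LV").max()
        uncoupled = params.copy()
        uncoupled.septum.S_c = 0.0
        high_unc = ss.run_to_steady_state(uncoupled, init=frozen_patient.state,
                                          controllers=False)
        edv = high.cycle.volume("LV").max()
        edv_unc = high_unc.cycle.volume("LV").max()
        assert edv < edv_unc
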