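"""Component laws: fiber stress, one-fiber pressure, orifices, storage, beds.

Expected values are closed-form evaluations of each law, computed by hand.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shuntsim.model import (
    compliance_pressure,
    one_fiber_pressure,
    orifice_flow_rhs,
    pulmonary_bed_flow,
    sarcomere_stress,
    septal_shift,
    steady_orifice_flow,
)
from shuntsim.parameters import (
    ComplianceNode,
    Orifice,
    PulmonaryBed,
    SeptalCoupling,
    Wall,
)


def make_wall(**kw):
    base = dict(V_w=35.0, V_ref=28.0, sigma_act=60.0, sigma_pas=0.5,
                k_pas=10.0, lambda_slack=0.8, t_on_frac=0.0, tau_act_frac=0.5)
    base.update(kw)
    return Wall(**base)


class TestSarcomereStress:
    def test_rest_length_outside_activation_is_stress_free(self):
        wall = make_wall(t_on_frac=0.2, tau_act_frac=0.3)
        assert sarcomere_stress(wall, 1.0, t=0.55, t_cycle=1.0) == 0.0

    def test_below_slack_no_active_stress(self):
        # at peak activation but below slack length only passive (zero at λ<1)
        wall = make_wall(sigma_pas=0.0)
        assert sarcomere_stress(wall, 0.75, t=0.25, t_cycle=1.0) == 0.0

    def test_total_stress_at_peak_activation(self):
        # active: 60*(1.2-0.8)/0.8 = 30; passive: 0.5*(e^2 - 1) = 3.1945
        wall = make_wall()
        sigma = sarcomere_stress(wall, 1.2, t=0.25, t_cycle=1.0)
        assert sigma == pytest.approx(30.0 + 0.5 * (np.exp(2.0) - 1.0), rel=1e-9)

    def test_activation_pulse_shape(self):
        wall = make_wall(sigma_pas=0.0, t_on_frac=0.0, tau_act_frac=0.4)
        s_mid = sarcomere_stress(wall, 1.1, t=0.2, t_cycle=1.0)   # sin^2(pi/2)=1
        s_half = sarcomere_stress(wall, 1.1, t=0.1, t_cycle=1.0)  # sin^2(pi/4)=0.5
        assert s_half == pytest.approx(0.5 * s_mid, rel=1e-9)

    def test_nonfinite_stretch_rejected(self):
        with pytest.raises(ValueError):
            sarcomere_stress(make_wall(), np.nan, 0.0)


class TestOneFiberPressure:
    def test_zero_stress_gives_zero_pressure(self):
        assert one_fiber_pressure(40.0, 60.0, 0.0) == 0.0

    def test_thin_wall_limit(self):
        assert one_fiber_pressure(40.0, 1e-9, 30.0) == pytest.approx(0.0, abs=1e-6)

    def test_reference_value(self):
        # p = 30/3 * ln(1 + 60/40) kPa = 9.1629 kPa = 68.73 mmHg
        p = one_fiber_pressure(40.0, 60.0, 30.0)
        assert p == pytest.approx(10.0 * np.log(2.5) * 7.50062, rel=1e-5)

    def test_collapsed_cavity_rejected(self):
        from shuntsim.model import CollapseError
        with pytest.raises(CollapseError):
            one_fiber_pressure(-1.0, 60.0, 30.0)


class TestSeptalShift:
    def test_equal_pressures_no_shift(self):
        assert septal_shift(25.0, 25.0, SeptalCoupling(0.2)) == 0.0

    def test_suprasystemic_rv_bows_left(self):
        assert septal_shift(20.0, 80.0, SeptalCoupling(0.2)) == pytest.approx(12.0)

    def test_zero_coupling_decouples(self):
        assert septal_shift(10.0, 90.0, SeptalCoupling(0.0)) == 0.0


class TestOrificeFlow:
    def test_equilibrium(self):
        orif = Orifice(A_open=1.0, one_way=False)
        assert orifice_flow_rhs(orif, 0.0, 0.0) == 0.0

    def test_two_way_sign_symmetry(self):
        orif = Orifice(A_open=1.0, one_way=False)
        assert orifice_flow_rhs(orif, -5.0, 0.0) == pytest.approx(
            -orifice_flow_rhs(orif, 5.0, 0.0), rel=1e-12)

    def test_steady_bernoulli_7mm_20mmHg(self):
        # q = A*sqrt(2*dp/rho): 0.3848 cm^2, 20 mmHg -> 86.7 mL/s
        area = np.pi * 0.35**2
        q = steady_orifice_flow(area, 20.0)
        assert q == pytest.approx(86.7, rel=2e-3)

    def test_steady_state_flow_has_zero_acceleration(self):
        orif = Orifice(A_open=np.pi * 0.35**2, one_way=False)
        q_ss = steady_orifice_flow(orif.A_open, 20.0)
        assert orifice_flow_rhs(orif, 20.0, q_ss) == pytest.approx(0.0, abs=1e-6)

    def test_closed_valve_relaxes_toward_leak_flow(self):
        orif = Orifice(A_open=2.0, one_way=True)
        q_leak = steady_orifice_flow(orif.A_leak, -40.0)
        dq = orifice_flow_rhs(orif, -40.0, q_leak)
        assert dq == pytest.approx(0.0, abs=1e-6)
        # above the leak equilibrium the flow is pushed down toward it
        assert orifice_flow_rhs(orif, -40.0, 0.0) < 0

    @given(dp=st.floats(-80, 80), q=st.floats(-200, 200))
    @settings(max_examples=50, deadline=None)
    def test_two_way_acceleration_sign_at_equilibrium_distance(self, dp, q):
        """Flow always accelerates toward the steady Bernoulli value."""
        orif = Orifice(A_open=1.5, one_way=False)
        q_ss = steady_orifice_flow(orif.A_open, dp)
        dq = orifice_flow_rhs(orif, dp, q)
        assert dq * np.sign(q_ss - q) >= 0 or abs(q - q_ss) < 1e-9


class TestStorageAndBeds:
    def test_unstressed_volume_gives_offset_pressure(self):
        node = ComplianceNode(V_0=60.0, C=1.2, p_0=2.0)
        assert compliance_pressure(node, 60.0) == pytest.approx(2.0)

    def test_linear_storage_value(self):
        node = ComplianceNode(V_0=60.0, C=1.2, p_0=0.0)
        assert compliance_pressure(node, 133.2) == pytest.approx(61.0)

    def test_large_compliance_limit(self):
        node = ComplianceNode(V_0=60.0, C=1e9, p_0=5.0)
        assert compliance_pressure(node, 100.0) == pytest.approx(5.0, abs=1e-6)

    @pytest.mark.parametrize("dp,expected", [
        (44.3, 2.1), (0.0, 0.0), (22.15, 1.05), (-44.3, -2.1)])
    def test_pulmonary_bed_linearity(self, dp, expected):
        bed = PulmonaryBed(q_ref=2.1, dp_ref=44.3)
        assert pulmonary_bed_flow(dp, bed) == pytest.approx(expected)
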