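"""Oxygen transport: Fick extraction, lung boundary, upwind mixing."""

import numpy as np
import pytest

from shuntsim import units as u
from shuntsim.model import Cycle
from shuntsim.oxygen import (
    COMPARTMENTS,
    bed_extraction,
    converge_saturations,
    lung_uptake,
    upwind_mixing_rhs,
)
from shuntsim.parameters import OxygenParams


class TestBedExtraction:
    def test_no_consumption_no_drop(self):
        s, limited = bed_extraction(0.98, 2.1, 0.0)
        assert s == 0.98 and not limited

    def test_fick_arithmetic(self):
        # 0.98 - 102/(2.1*174) = 0.7008
        s, limited = bed_extraction(0.98, 2.1, 102.0, c_cap=174.0)
        assert s == pytest.approx(0.7008, abs=2e-4)
        assert not limited

    def test_halving_flow_doubles_the_drop(self):
        s1, _ = bed_extraction(0.98, 2.1, 102.0)
        s2, _ = bed_extraction(0.98, 1.05, 102.0)
        assert (0.98 - s2) == pytest.approx(2 * (0.98 - s1), rel=1e-9)

    def test_supply_limited_is_flagged_and_clamped(self):
        s, limited = bed_extraction(0.5, 0.2, 102.0)
        assert s == 0.0 and limited

    def test_no_flow_with_consumption_is_shock(self):
        s, limited = bed_extraction(0.98, 0.0, 50.0)
        assert s == 0.0 and limited


class TestLungUptake:
    @pytest.mark.parametrize("s_in", [0.40, 0.98, 0.10])
    def test_pulmonary_venous_boundary(self, s_in):
        assert lung_uptake(s_in) == 0.98

    def test_configurable_boundary(self):
        assert lung_uptake(0.5, OxygenParams(S_pv=0.95)) == 0.95


def _flows(**kw):
    q = np.zeros(11)
    for name, val in kw.items():
        q[Cycle.FLOWS.index(name)] = val
    return q


class TestUpwindMixing:
    VOLS = np.array([20., 35., 20., 35., 40., 50., 230., 30., 60.])

    def test_uniform_field_is_stationary(self):
        sat = np.full(9, 0.8)
        q = _flows(ven=30.0, pven=30.0, pulm=30.0, upper=15.0, lower=15.0,
                   tri=30.0, pulv=30.0, mit=30.0, ao=30.0, seg=15.0)
        ds = upwind_mixing_rhs(sat, self.VOLS, q, lung=False, consumption=False)
        assert np.abs(ds).max() < 1e-9

    def test_mixing_alone_conserves_oxygen_content(self, rng):
        """d/dt sum(S_i V_i) = 0 without lung or tissue exchange."""
        sat = rng.uniform(0.3, 1.0, 9)
        q = _flows(ven=25.0, pven=28.0, pulm=30.0, upper=12.0, lower=14.0,
                   tri=31.0, pulv=29.0, mit=27.0, ao=26.0, seg=13.0,
                   shunt=7.0)
        ds = upwind_mixing_rhs(sat, self.VOLS, q, shunt_kind="ASD",
                               lung=False, consumption=False)
        # compartment volumes change too: d(SV)/dt = S dV/dt + V dS/dt
        dv = np.zeros(9)
        FL = Cycle.FLOWS
        def qv(n):
            return q[FL.index(n)]
        dv[0] = qv("ven") - qv("tri") - qv("shunt")
        dv[1] = qv("tri") - qv("pulv")
        dv[2] = qv("pven") - qv("mit") + qv("shunt")
        dv[3] = qv("mit") - qv("ao")
        dv[4] = qv("ao") - qv("seg") - qv("upper")
        dv[5] = qv("seg") - qv("lower")
        dv[6] = qv("upper") + qv("lower") - qv("ven")
        dv[7] = qv("pulv") - qv("pulm")
        dv[8] = qv("pulm") - qv("pven")
        total_rate = np.sum(ds * self.VOLS + sat * dv)
        assert abs(total_rate) < 1e-6 * np.sum(np.abs(q))

    def test_reverse_shunt_flow_carries_upwind_saturation(self):
        """An atrial defect with right-to-left flow pulls the left atrium
        toward the right atrial (venous) saturation."""
        sat = np.full(9, 0.98)
        sat[COMPARTMENTS.index("RA")] = 0.60
        q = _flows(shunt=20.0)
        ds = upwind_mixing_rhs(sat, self.VOLS, q, shunt_kind="ASD",
                               lung=False, consumption=False)
        assert ds[COMPARTMENTS.index("LA")] < 0
        assert ds[COMPARTMENTS.index("RA")] == 0.0

    def test_low_volume_rejected(self):
        from shuntsim.oxygen import TransportError
        vols = self.VOLS.copy()
        vols[3] = 0.05
        with pytest.raises(TransportError):
            upwind_mixing_rhs(np.full(9, 0.9), vols, _flows(ao=10.0))


class TestConvergedSaturations:
    def test_series_circulation_reaches_lung_saturation_arteries(self, frozen_patient):
        sats = converge_saturations(frozen_patient)
        assert sats.S_up == pytest.approx(0.98, abs=1e-3)
        assert sats.S_low == pytest.approx(0.98, abs=1e-3)

    def test_global_oxygen_balance(self, frozen_patient):
        """Steady state: lung uptake equals tissue consumption within 1%."""
        sats = converge_saturations(frozen_patient)
        ox = frozen_patient.params.oxygen
        qp = frozen_patient.qp  # l/min
        uptake = qp * (ox.S_pv - sats["PA"]) * ox.c_cap  # mL O2/min
        assert uptake == pytest.approx(ox.VO2_total, rel=0.01)

    def test_mixed_venous_saturation_physiologic(self, frozen_patient):
        """VO2 102 mL/min at CO 2.1 l/min with c_cap 174 gives S_mv ~ 0.70."""
        sats = converge_saturations(frozen_patient)
        assert sats.S_mv == pytest.approx(0.98 - 102.0 / (2.1 * 174.0), abs=0.02)

    def test_all_saturations_bounded(self, frozen_patient):
        sats = converge_saturations(frozen_patient)
        assert all(0.0 <= v <= 1.0 for v in sats.values.values())
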