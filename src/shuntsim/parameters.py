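"""Physiological parameter containers for one simulated patient.

A :class:`ParameterSet` fully describes the closed-loop circulation: the four
cardiac chambers (one-fiber walls), septal ventricular coupling, five arterial
and venous compliance nodes, the resistive systemic beds, the linear pulmonary
bed, the valve/shunt orifices, heart rate, homeostatic control targets and
oxygen-transport parameters.

Defaults describe a resting child with body surface area around 0.75 m^2
(cardiac output 2.1 l/min, mean arterial pressure 61 mmHg, heart rate
100 /min).  These defaults are only a starting point: the study protocol tunes
the pulmonary pressure drop to a target mean pulmonary artery pressure and
adapts wall volumes and vessel cross-sections to exercise load before any
shunt simulation is run.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from . import units as u

CHAMBERS = ("RA", "RV", "LA", "LV")
NODES = ("AoP", "AoD", "SV", "PA", "PV")
ORIFICES = ("TRI", "PULV", "MIT", "AO", "SEG", "SHUNT")


@dataclass
class Wall:
    """Myofiber wall of one chamber.

    Activation timing is stored as fractions of the cycle length so that heart
    rate changes rescale systole.  ``lambda_slack`` is the fiber stretch below
    which active stress vanishes.
    """

    V_w: float                 # wall volume, mL
    V_ref: float               # cavity volume at unit fiber stretch, mL
    sigma_act: float           # active stress scale, kPa
    sigma_pas: float           # passive stress scale, kPa
    k_pas: float = 10.0        # passive stiffness exponent
    lambda_slack: float = 0.85  # slack fiber stretch
    t_on_frac: float = 0.15    # activation onset, fraction of cycle
    tau_act_frac: float = 0.40  # activation duration, fraction of cycle

    def validate(self) -> None:
        if not (self.V_w > 0 and self.tau_act_frac > 0):
            raise ValueError("wall volume and activation duration must be positive")
        if self.sigma_act < 0 or self.sigma_pas < 0:
            raise ValueError("stress scales must be non-negative")


@dataclass
class SeptalCoupling:
    """Lumped interventricular septum: volume shift per pressure difference."""

    S_c: float = 0.2  # mL/mmHg

    def validate(self) -> None:
        if self.S_c < 0:
            raise ValueError("septal coupling compliance must be >= 0")


@dataclass
class ComplianceNode:
    """Linear storage element for a major artery or vein."""

    V_0: float        # unstressed volume, mL
    C: float          # compliance, mL/mmHg
    p_0: float = 0.0  # offset pressure, mmHg
    length: float = 0.1  # representative segment length, m (for adaptation)

    def validate(self) -> None:
        if self.C <= 0 or self.V_0 < 0:
            raise ValueError("node compliance must be > 0 and V_0 >= 0")

    @property
    def area(self) -> float:
        """Cross-sectional area implied by V_0 and segment length, m^2."""
        return self.V_0 * u.ML / self.length


@dataclass
class Orifice:
    """Valve or shunt orifice with Bernoulli pressure loss and inertia."""

    A_open: float            # cm^2
    l_eff: float = 0.016     # m
    one_way: bool = True
    leak_frac: float = 1e-4  # A_leak = leak_frac * A_open

    @property
    def A_leak(self) -> float:
        return self.leak_frac * self.A_open


@dataclass
class PulmonaryBed:
    """Linear pulmonary bed: q = q_ref * dp / dp_ref."""

    q_ref: float = 2.1    # l/min
    dp_ref: float = 9.0   # mmHg

    def validate(self) -> None:
        if self.q_ref <= 0 or self.dp_ref <= 0:
            raise ValueError("pulmonary reference flow and drop must be > 0")

    @property
    def resistance(self) -> float:
        """Equivalent resistance, mmHg·min/l."""
        return self.dp_ref / self.q_ref


@dataclass
class ControlTargets:
    """Homeostatic set-points for cardiac output and mean arterial pressure."""

    CO_target: float = 2.1   # l/min
    MAP_target: float = 61.0  # mmHg
    enabled: bool = True

    def validate(self) -> None:
        if self.CO_target <= 0 or self.MAP_target <= 0:
            raise ValueError("control targets must be positive")


@dataclass
class ExerciseSpec:
    """Multiplicative exercise load used during structural adaptation."""

    co_factor: float = 3.0
    hr_factor: float = 2.0

    def validate(self) -> None:
        if self.co_factor < 1 or self.hr_factor < 1:
            raise ValueError("exercise factors must be >= 1")


@dataclass
class AdaptationTargets:
    """Mechano-sensed targets for structural adaptation at exercise."""

    sigma_target: float = 55.0  # kPa, target peak fiber stress
    v_target: float = 0.17      # m/s, target mean blood velocity
    tol: float = 1e-3           # relative geometry convergence


@dataclass
class OxygenParams:
    """Oxygen transport parameters.

    c_cap = 174 mL O2 / L blood corresponds to Hb 13 g/dL x 1.34 mL/g;
    VO2 102 mL/min at CO 2.1 l/min puts mixed-venous saturation near 70%.
    """

    S_pv: float = 0.98          # pulmonary venous saturation
    VO2_total: float = 102.0    # mL O2/min
    f_up: float = 0.5           # upper-body consumption fraction
    c_cap: float = 174.0        # mL O2 per L blood at S=1

    def validate(self) -> None:
        if not (0 < self.S_pv <= 1 and self.VO2_total > 0 and 0 <= self.f_up <= 1
                and self.c_cap > 0):
            raise ValueError("invalid oxygen parameters")


SHUNT_KINDS = ("NONE", "ASD", "POTTS")


@dataclass
class ShuntSpec:
    """Shunt type and diameter.  diameter 0 behaves identically to NONE."""

    kind: str = "NONE"
    diameter_mm: float = 0.0

    def validate(self) -> None:
        if self.kind not in SHUNT_KINDS:
            raise ValueError(f"unknown shunt kind {self.kind!r}")
        if self.diameter_mm < 0:
            raise ValueError("shunt diameter must be >= 0")

    @property
    def area_cm2(self) -> float:
        """Orifice area pi*(d/2)^2 in cm^2."""
        r_cm = 0.05 * self.diameter_mm
        return float(np.pi * r_cm * r_cm)


@dataclass
class ParameterSet:
    """Complete physiological description of one simulated patient."""

    walls: dict[str, Wall]
    septum: SeptalCoupling
    nodes: dict[str, ComplianceNode]
    orifices: dict[str, Orifice]
    pulmonary: PulmonaryBed
    r_upper: float = 55.0      # mmHg·min/l
    r_lower: float = 55.0
    r_sys_vein: float = 0.3
    r_pulm_vein: float = 0.3
    hr: float = 100.0          # beats/min
    shunt: ShuntSpec = field(default_factory=ShuntSpec)
    control: ControlTargets = field(default_factory=ControlTargets)
    oxygen: OxygenParams = field(default_factory=OxygenParams)
    dt: float = 5e-4           # integrator step, s

    @property
    def t_cycle(self) -> float:
        return 60.0 / self.hr

    def validate(self) -> None:
        for w in self.walls.values():
            w.validate()
        self.septum.validate()
        for n in self.nodes.values():
            n.validate()
        self.pulmonary.validate()
        self.control.validate()
        self.oxygen.validate()
        self.shunt.validate()
        if min(self.r_upper, self.r_lower, self.r_sys_vein, self.r_pulm_vein) <= 0:
            raise ValueError("resistances must be positive")
        if self.hr <= 0 or self.dt <= 0 or self.dt > 1e-3:
            raise ValueError("need hr > 0 and 0 < dt <= 1 ms")

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def with_shunt(self, shunt: ShuntSpec) -> "ParameterSet":
        ps = self.copy()
        ps.shunt = copy.deepcopy(shunt)
        return ps


def default_parameter_set() -> ParameterSet:
    """Synthetic resting reference child (pre-tuning, pre-adaptation fixture)."""
    walls = {
        "RA": Wall(V_w=4.0, V_ref=18.0, sigma_act=100.0, sigma_pas=5.0,
                   t_on_frac=0.0, tau_act_frac=0.15),
        "LA": Wall(V_w=4.0, V_ref=16.0, sigma_act=100.0, sigma_pas=5.0,
                   t_on_frac=0.0, tau_act_frac=0.15),
        # the RV diastolic curve is nearly linear (k_pas 1) and engages just
        # above its reference volume: right-heart filling pressure then rises
        # gradually as the decompensating RV dilates, as seen clinically
        "RV": Wall(V_w=12.0, V_ref=28.0, sigma_act=250.0, sigma_pas=30.0,
                   k_pas=1.0),
        "LV": Wall(V_w=35.0, V_ref=26.0, sigma_act=250.0, sigma_pas=5.0),
    }
    nodes = {
        "AoP": ComplianceNode(V_0=25.0, C=0.30, length=0.04),
        "AoD": ComplianceNode(V_0=31.0, C=0.35, length=0.10),
        "SV": ComplianceNode(V_0=215.0, C=8.0, length=0.35),
        "PA": ComplianceNode(V_0=18.0, C=1.2, length=0.03),
        "PV": ComplianceNode(V_0=50.0, C=2.0, length=0.08),
    }
    orifices = {
        "TRI": Orifice(A_open=2.4),
        "PULV": Orifice(A_open=1.5),
        "MIT": Orifice(A_open=2.2),
        "AO": Orifice(A_open=1.3),
        "SEG": Orifice(A_open=1.3, one_way=False),
        "SHUNT": Orifice(A_open=0.0, one_way=False),
    }
    return ParameterSet(
        walls=walls,
        septum=SeptalCoupling(),
        nodes=nodes,
        orifices=orifices,
        pulmonary=PulmonaryBed(),
    )


# ---------------------------------------------------------------------------
# Packing into the flat SI vector consumed by the compiled kernels.
# ---------------------------------------------------------------------------

# state vector layout (SI): 9 volumes then 6 orifice flows
IX_V = {name: i for i, name in enumerate(CHAMBERS + NODES)}
IX_Q = {name: 9 + i for i, name in enumerate(ORIFICES)}
NX = 15

# parameter vector layout
_PW = 0          # 4 walls x 8: V_w, V_ref, s_act, s_pas, k_pas, lam_slack, t_on, tau
P_SC = 32
_PN = 33         # 5 nodes x 3: V_0, C, p_0
P_BED = 48       # R_up, R_low, R_sv, R_pv, q_pulm_ref, dp_pulm_ref
_PO = 54         # 6 orifices x 4: A_open, A_leak, l_eff, one_way
P_KIND = 78      # 0 none, 1 ASD, 2 POTTS
P_TC = 79
P_DT = 80
P_RHO = 81
NP = 82


def wall_slot(i: int) -> int:
    return _PW + 8 * i


def node_slot(i: int) -> int:
    return _PN + 3 * i


def orifice_slot(i: int) -> int:
    return _PO + 4 * i


def pack(ps: ParameterSet) -> np.ndarray:
    """Flatten a ParameterSet into the SI parameter vector for the kernels."""
    ps.validate()
    pv = np.zeros(NP)
    tc = ps.t_cycle
    for i, name in enumerate(CHAMBERS):
        w = ps.walls[name]
        b = wall_slot(i)
        pv[b + 0] = w.V_w * u.ML
        pv[b + 1] = w.V_ref * u.ML
        pv[b + 2] = w.sigma_act * u.KPA
        pv[b + 3] = w.sigma_pas * u.KPA
        pv[b + 4] = w.k_pas
        pv[b + 5] = w.lambda_slack
        pv[b + 6] = w.t_on_frac * tc
        pv[b + 7] = w.tau_act_frac * tc
    pv[P_SC] = ps.septum.S_c * u.C_CLIN
    for i, name in enumerate(NODES):
        n = ps.nodes[name]
        b = node_slot(i)
        pv[b + 0] = n.V_0 * u.ML
        pv[b + 1] = n.C * u.C_CLIN
        pv[b + 2] = n.p_0 * u.MMHG
    pv[P_BED + 0] = ps.r_upper * u.R_CLIN
    pv[P_BED + 1] = ps.r_lower * u.R_CLIN
    pv[P_BED + 2] = ps.r_sys_vein * u.R_CLIN
    pv[P_BED + 3] = ps.r_pulm_vein * u.R_CLIN
    pv[P_BED + 4] = ps.pulmonary.q_ref * u.LMIN
    pv[P_BED + 5] = ps.pulmonary.dp_ref * u.MMHG
    orifices = dict(ps.orifices)
    shunt_area = ps.shunt.area_cm2 if ps.shunt.kind != "NONE" else 0.0
    orifices["SHUNT"] = replace(orifices["SHUNT"], A_open=shunt_area, one_way=False)
    for i, name in enumerate(ORIFICES):
        o = orifices[name]
        b = orifice_slot(i)
        pv[b + 0] = o.A_open * u.CM2
        pv[b + 1] = o.A_leak * u.CM2
        pv[b + 2] = o.l_eff
        pv[b + 3] = 1.0 if o.one_way else 0.0
    pv[P_KIND] = float(SHUNT_KINDS.index(ps.shunt.kind)) if shunt_area > 0 else 0.0
    pv[P_TC] = tc
    nsteps = int(np.ceil(tc / ps.dt))
    pv[P_DT] = tc / nsteps
    pv[P_RHO] = u.RHO_BLOOD
    return pv


def n_steps(ps: ParameterSet) -> int:
    return int(np.ceil(ps.t_cycle / ps.dt))


def initial_state(ps: ParameterSet) -> np.ndarray:
    """Plausible resting initial state (SI) for cold starts."""
    x = np.zeros(NX)
    guesses_ml = {"RA": 25.0, "RV": 45.0, "LA": 25.0, "LV": 40.0}
    p_guess = {"AoP": 61.0, "AoD": 61.0, "SV": 4.0, "PA": 15.0, "PV": 6.0}
    for name, v in guesses_ml.items():
        x[IX_V[name]] = v * u.ML
    for name, p in p_guess.items():
        n = ps.nodes[name]
        x[IX_V[name]] = (n.V_0 + n.C * (p - n.p_0)) * u.ML
    return x
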