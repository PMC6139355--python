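"""Closed-loop circulation model: component laws and the beat-to-beat solver.

The public entry point is :func:`run_to_steady_state`, which integrates the
circulation beat by beat (fixed-step RK4, dt <= 1 ms) until every
compartment's cycle-mean volume is stationary, optionally applying the
between-beat homeostatic controller updates, and returns the last converged
cycle together with cycle diagnostics.

The per-component functions (``sarcomere_stress``, ``one_fiber_pressure``,
``septal_shift``, ``orifice_flow_rhs``, ``pulmonary_bed_flow``,
``compliance_pressure``, ``assemble_rhs``) expose the same compiled scalar
laws the integrator uses, in clinical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine as eng
from . import units as u
from .parameters import (
    CHAMBERS,
    NODES,
    NX,
    ComplianceNode,
    Orifice,
    ParameterSet,
    PulmonaryBed,
    SeptalCoupling,
    Wall,
    initial_state,
    n_steps,
    pack,
    P_BED,
)


class CollapseError(RuntimeError):
    """A cavity or vessel compartment emptied below 0.1 mL."""


class SolverError(RuntimeError):
    """Septal fixed point or beat-to-beat iteration failed to converge."""


class ConvergenceError(SolverError):
    """No periodic steady state within the beat budget."""

    def __init__(self, msg, residuals=None):
        super().__init__(msg)
        self.residuals = residuals or []


# ---------------------------------------------------------------------------
# Component laws (clinical units) — thin wrappers over the compiled kernels.
# ---------------------------------------------------------------------------

def _wall_pv(wall: Wall, t_cycle: float = 0.6) -> np.ndarray:
    ps_pv = np.zeros(eng.PW + 8)
    ps_pv[0] = wall.V_w * u.ML
    ps_pv[1] = wall.V_ref * u.ML
    ps_pv[2] = wall.sigma_act * u.KPA
    ps_pv[3] = wall.sigma_pas * u.KPA
    ps_pv[4] = wall.k_pas
    ps_pv[5] = wall.lambda_slack
    ps_pv[6] = wall.t_on_frac * t_cycle
    ps_pv[7] = wall.tau_act_frac * t_cycle
    return ps_pv


def sarcomere_stress(wall: Wall, stretch: float, t: float,
                     t_cycle: float = 0.6) -> float:
    """Total myofiber stress (kPa) at fiber stretch ``stretch`` and time ``t``.

    Active part: sigma_act * sin^2 pulse * (lam - lam_slack)/lam_slack (>=0);
    passive part: sigma_pas * (exp(k_pas (lam-1)) - 1) for lam > 1.
    """
    if not np.isfinite(stretch) or stretch <= 0:
        raise ValueError("fiber stretch must be finite and positive")
    pv = _wall_pv(wall, t_cycle)
    return eng.fiber_stress(pv, 0, float(stretch), float(t)) / u.KPA


def one_fiber_pressure(V_cav: float, V_w: float, sigma_f: float) -> float:
    """One-fiber transmural pressure (mmHg): p = sigma_f/3 * ln(1 + V_w/V_cav).

    ``V_cav``, ``V_w`` in mL, ``sigma_f`` in kPa.
    """
    if V_cav <= 0:
        raise CollapseError("cavity volume must be positive")
    if V_w <= 0:
        raise ValueError("wall volume must be positive")
    return eng.one_fiber_p(sigma_f * u.KPA, V_w * u.ML, V_cav * u.ML) / u.MMHG


def septal_shift(p_LV: float, p_RV: float, coupling: SeptalCoupling) -> float:
    """Septal volume shift (mL), positive when the septum bows leftward."""
    if not (np.isfinite(p_LV) and np.isfinite(p_RV)):
        raise ValueError("non-finite ventricular pressure")
    return coupling.S_c * (p_RV - p_LV)


def orifice_flow_rhs(orifice: Orifice, dp: float, q: float = 0.0) -> float:
    """dq/dt (mL/s^2) of an orifice at pressure drop ``dp`` (mmHg), flow ``q``
    (mL/s): Bernoulli convective loss plus blood column inertia.  A closed
    one-way valve relaxes quasi-steadily to its Bernoulli leak flow."""
    if orifice.A_open <= 0:
        raise ValueError("orifice area must be positive")
    pv = np.zeros(eng.P_RHO + 1)
    pv[eng.PO + 0] = orifice.A_open * u.CM2
    pv[eng.PO + 1] = orifice.A_leak * u.CM2
    pv[eng.PO + 2] = orifice.l_eff
    pv[eng.PO + 3] = 1.0 if orifice.one_way else 0.0
    pv[eng.P_RHO] = u.RHO_BLOOD
    return eng.orifice_dqdt(pv, 0, dp * u.MMHG, q * u.ML) / u.ML


def steady_orifice_flow(area_cm2: float, dp: float) -> float:
    """Closed-form steady Bernoulli flow (mL/s): q = sign(dp) A sqrt(2|dp|/rho)."""
    a = area_cm2 * u.CM2
    return np.sign(dp) * a * np.sqrt(2 * abs(dp) * u.MMHG / u.RHO_BLOOD) / u.ML


def pulmonary_bed_flow(dp_pulm: float, bed: PulmonaryBed) -> float:
    """Pulmonary bed flow (l/min): q = q_ref * dp / dp_ref."""
    bed.validate()
    return bed.q_ref * dp_pulm / bed.dp_ref


def compliance_pressure(node: ComplianceNode, V: float) -> float:
    """Storage pressure (mmHg): p = p_0 + (V - V_0)/C above the unstressed
    volume; below it the vessel collapses to a soft floor (see engine)."""
    node.validate()
    pv = np.zeros(eng.PN + 3)
    pv[eng.PN + 0] = node.V_0 * u.ML
    pv[eng.PN + 1] = node.C * u.C_CLIN
    pv[eng.PN + 2] = node.p_0 * u.MMHG
    return eng.compliance_p(pv, 0, V * u.ML) / u.MMHG


def assemble_rhs(state: np.ndarray, params: ParameterSet, t: float = 0.0
                 ) -> np.ndarray:
    """Network time derivative d(state)/dt for an SI state vector."""
    pv = pack(params)
    dx = np.empty(NX)
    pch = np.empty(4)
    pn = np.empty(5)
    sig = np.empty(4)
    qb = np.empty(5)
    sep = np.zeros(1)
    err = eng.rhs(float(t), state, pv, dx, pch, pn, sig, qb, sep)
    if err == eng.ERR_SEPTUM:
        raise SolverError("septal fixed point did not converge")
    return dx


# ---------------------------------------------------------------------------
# Recorded cycle and steady-state result containers.
# ---------------------------------------------------------------------------

@dataclass
class Cycle:
    """One converged cardiac cycle sampled at the integrator step.

    Pressures in mmHg, volumes in mL, flows in mL/s, fiber stresses in kPa.
    Column order for pressures/volumes: RA, RV, LA, LV, AoP, AoD, SV, PA, PV;
    for flows: ven(SV->RA), pven(PV->LA), pulm, upper, lower, tricuspid,
    pulmonary valve, mitral, aortic, aortic segment, shunt (positive
    right-to-left).
    """

    t: np.ndarray
    pressures: np.ndarray
    volumes: np.ndarray
    flows: np.ndarray
    stresses: np.ndarray
    dt: float

    COMPARTMENTS = CHAMBERS + NODES
    FLOWS = ("ven", "pven", "pulm", "upper", "lower",
             "tri", "pulv", "mit", "ao", "seg", "shunt")

    def pressure(self, name: str) -> np.ndarray:
        return self.pressures[:, self.COMPARTMENTS.index(name)]

    def volume(self, name: str) -> np.ndarray:
        return self.volumes[:, self.COMPARTMENTS.index(name)]

    def flow(self, name: str) -> np.ndarray:
        return self.flows[:, self.FLOWS.index(name)]


@dataclass
class SteadyState:
    """Periodic solution of one simulation.

    ``params`` carries any controller updates (systemic resistance); the total
    blood volume lives in ``state``.
    """

    params: ParameterSet
    state: np.ndarray          # SI state at cycle start
    cycle: Cycle
    diagnostics: np.ndarray    # engine diag vector of the last beat (SI)
    beats: int
    converged: bool
    residual_history: list = field(default_factory=list)

    @property
    def co(self) -> float:
        """Cycle-mean aortic valve flow, l/min."""
        return self.diagnostics[eng.D_QOR + eng.Q_AO] / u.LMIN

    @property
    def map(self) -> float:
        """Cycle-mean proximal aortic pressure, mmHg."""
        return self.diagnostics[eng.D_PN + 0] / u.MMHG

    @property
    def mpap(self) -> float:
        """Cycle-mean pulmonary artery pressure, mmHg."""
        return self.diagnostics[eng.D_PN + 3] / u.MMHG

    @property
    def qp(self) -> float:
        """Cycle-mean pulmonary bed flow, l/min."""
        return self.diagnostics[eng.D_QPULM] / u.LMIN

    @property
    def qs(self) -> float:
        """Cycle-mean systemic bed flow (upper + lower), l/min."""
        return (self.diagnostics[eng.D_QUP] + self.diagnostics[eng.D_QLOW]) / u.LMIN

    @property
    def shunt_flow(self) -> float:
        """Cycle-mean shunt flow, l/min, positive right-to-left."""
        return self.diagnostics[eng.D_QOR + eng.Q_SH] / u.LMIN

    @property
    def peak_stress(self) -> dict[str, float]:
        """Peak fiber stress per wall over the cycle, kPa."""
        return {name: self.diagnostics[eng.D_SIGPK + i] / u.KPA
                for i, name in enumerate(CHAMBERS)}

    @property
    def total_volume(self) -> float:
        """Total blood volume, mL."""
        return float(np.sum(self.state[:9])) / u.ML

    def summary(self) -> str:
        lines = [
            "steady-state cycle summary",
            f"  beats to converge : {self.beats}",
            f"  CO   {self.co:7.3f} l/min",
            f"  MAP  {self.map:7.2f} mmHg",
            f"  mPAP {self.mpap:7.2f} mmHg",
            f"  Qp   {self.qp:7.3f} l/min   Qs {self.qs:7.3f} l/min",
        ]
        if self.params.shunt.kind != "NONE":
            lines.append(f"  shunt flow {self.shunt_flow:+.3f} l/min (+ = right-to-left)")
        return "\n".join(lines)


def _decode_error(err: int, params: ParameterSet) -> None:
    if err == eng.OK:
        return
    if err == eng.ERR_SEPTUM:
        raise SolverError("septal fixed-point iteration did not converge")
    comp = (CHAMBERS + NODES)[err - 100]
    raise CollapseError(f"compartment {comp} collapsed below 0.1 mL")


def _record_cycle(x: np.ndarray, pv: np.ndarray, nsteps: int,
                  params: ParameterSet) -> tuple[Cycle, np.ndarray]:
    rec_p = np.empty((nsteps, 9))
    rec_v = np.empty((nsteps, 9))
    rec_q = np.empty((nsteps, eng.NRQ))
    rec_s = np.empty((nsteps, 4))
    diag = np.empty(eng.ND)
    err = eng.run_beat(x, pv, nsteps, diag, True, rec_p, rec_v, rec_q, rec_s)
    _decode_error(err, params)
    dt = pv[eng.P_DT]
    cyc = Cycle(
        t=np.arange(nsteps) * dt,
        pressures=rec_p / u.MMHG,
        volumes=rec_v / u.ML,
        flows=rec_q / u.ML,       # m^3/s -> mL/s
        stresses=rec_s / u.KPA,
        dt=dt,
    )
    return cyc, diag


def run_to_steady_state(
    params: ParameterSet,
    init: np.ndarray | None = None,
    controllers: bool | None = None,
    max_beats: int = 1000,
    vol_tol: float = 1e-4,
    set_point_tol: float = 1e-3,
    require_targets: bool = True,
) -> SteadyState:
    """Integrate consecutive beats to a periodic steady state.

    Convergence requires the maximum relative change of every compartment's
    cycle-mean volume between successive beats to fall below ``vol_tol``;
    with controllers enabled, the cycle-mean CO and MAP must additionally be
    within ``set_point_tol`` of their targets.  Controller updates (systemic
    resistance from CO error, total blood volume from MAP error) are applied
    between beats only.  The returned ``params`` carry the updated systemic
    resistance; the updated blood volume is in the returned state.

    With ``require_targets=False`` a stationary solution whose controllers
    have stalled (pump-limited: resistance pinned at its physiologic floor,
    volume stationary) is accepted even if the set-points are not met — the
    structural-adaptation loop needs such solutions to size the heart.
    """
    from .control import update_blood_volume, update_systemic_resistance

    params = params.copy()
    if controllers is not None:
        params.control.enabled = controllers
    pv = pack(params)
    nsteps = n_steps(params)
    x = initial_state(params) if init is None else np.array(init, dtype=float)
    diag = np.empty(eng.ND)
    dummy = np.empty((1, 1))
    prev_means = None
    residuals = []
    converged = False
    beats = 0
    quiet = 0
    ctl = params.control
    # controller gains are annealed whenever the residual stops improving:
    # a gain-induced limit cycle around the set-points damps out while the
    # fixed point itself is untouched
    gain_r, gain_v = 0.15, 0.05
    window_best = np.inf
    window_prev_best = np.inf
    x_prev = x.copy()
    kick_cooldown = 0
    for beat in range(max_beats):
        beats = beat + 1
        err = eng.run_beat(x, pv, nsteps, diag, False, dummy, dummy, dummy, dummy)
        _decode_error(err, params)
        means = diag[eng.D_MV:eng.D_MV + 9].copy()
        co = diag[eng.D_QOR + eng.Q_AO] / u.LMIN
        map_ = diag[eng.D_PN + 0] / u.MMHG
        resid = np.inf
        if prev_means is not None:
            resid = float(np.max(np.abs(means - prev_means) / np.maximum(means, 1e-12)))
        residuals.append(resid)
        prev_means = means
        window_best = min(window_best, resid)
        if beat % 40 == 39:
            if window_best > 0.5 * window_prev_best:
                gain_r *= 0.5
                gain_v *= 0.5
            window_prev_best = window_best
            window_best = np.inf
        # beat-to-beat alternans breaker: a residual that stops shrinking
        # while above tolerance indicates a period-2 (or longer) orbit; the
        # midpoint of consecutive cycle-start states lies near the coexisting
        # period-1 solution, so jump there
        kick_cooldown -= 1
        plateaued = (len(residuals) >= 30 and vol_tol < resid < 1e-2
                     and resid > 0.7 * min(residuals[-30:]))
        if kick_cooldown <= 0 and beat >= 40 and plateaued:
            x[:] = 0.5 * (x + x_prev)
            kick_cooldown = 25
        x_prev[:] = x
        on_target = True
        stalled = True
        if ctl.enabled and co > 0:
            on_target = (abs(co - ctl.CO_target) <= set_point_tol * ctl.CO_target
                         and abs(map_ - ctl.MAP_target) <= set_point_tol * ctl.MAP_target)
            # deadband: once both set-points sit within half tolerance the
            # controllers go quiet, letting the autonomous dynamics become
            # strictly periodic instead of micro-cycling around the target
            if (abs(co - ctl.CO_target) <= 0.5 * set_point_tol * ctl.CO_target
                    and abs(map_ - ctl.MAP_target) <= 0.5 * set_point_tol * ctl.MAP_target):
                if beat >= 2 and resid < vol_tol:
                    converged = True
                    break
                continue
            # between-beat homeostatic updates
            r_tot = (params.r_upper + params.r_lower)
            r_new = update_systemic_resistance(r_tot, co, ctl, gain=gain_r,
                                               rate_limit=True)
            # physiologic bounds on total systemic resistance keep the
            # transient after a sudden set-point change (exercise onset)
            # from draining the arterial nodes before volume control reacts
            r_new = min(1000.0, max(6.0, r_new))
            scale = r_new / r_tot
            params.r_upper *= scale
            params.r_lower *= scale
            pv[P_BED + 0] *= scale
            pv[P_BED + 1] *= scale
            v_tot = float(np.sum(x[:9]))
            v_new = update_blood_volume(v_tot / u.ML, map_, ctl, gain=gain_v) * u.ML
            dv = v_new - v_tot
            c = np.array([params.nodes[n].C for n in NODES]) * u.C_CLIN
            x[4:9] += dv * c / c.sum()
            stalled = abs(scale - 1.0) < 5e-4 and abs(dv) < 5e-5 * v_tot
        if beat >= 2 and resid < vol_tol and (on_target or
                                              (not require_targets and stalled)):
            quiet += 1
            # a pump-limited run must be stationary for several consecutive
            # beats before the stalled controllers are trusted
            if on_target or quiet >= 5:
                converged = True
                break
        else:
            quiet = 0
    if not converged:
        raise ConvergenceError(
            f"no periodic steady state in {max_beats} beats "
            f"(last residual {residuals[-1]:.3g})", residuals)
    # refine to pointwise periodicity: the cycle-mean criterion can be met
    # while the state at cycle start vs end still differs slightly, so keep
    # integrating quiet beats until the orbit itself is periodic
    cycle, diag = _record_cycle(x, pv, nsteps, params)
    for _ in range(200):
        start = cycle.volumes[0] * u.ML
        mismatch = float(np.max(np.abs(x[:9] - start) / start))
        if mismatch < vol_tol:
            break
        beats += 1
        cycle, diag = _record_cycle(x, pv, nsteps, params)
    return SteadyState(params=params, state=x, cycle=cycle, diagnostics=diag,
                       beats=beats, converged=True, residual_history=residuals)
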