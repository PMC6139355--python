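"""Homeostatic control and structural adaptation.

Between-beat control: systemic peripheral resistance is scaled by the ratio
of measured to target cardiac output, and total blood volume is nudged toward
the mean-arterial-pressure target (gain 0.3).  Both act only between beats;
within a cycle the dynamics are autonomous.

Structural adaptation sizes the cardiac walls and vessel cross-sections to
the mechanical load at exercise: wall volume is scaled by peak-fiber-stress
excess over the stress target, and vessel areas by mean-velocity excess over
the velocity target; the loop (exercise -> adapt -> rest) repeats until the
geometry is stationary.
"""

from __future__ import annotations

import numpy as np

from . import units as u
from .model import SteadyState, compliance_pressure, run_to_steady_state
from .parameters import (
    NODES,
    AdaptationTargets,
    ComplianceNode,
    ControlTargets,
    ExerciseSpec,
    ParameterSet,
    Wall,
)


class ControlError(RuntimeError):
    pass


class AdaptationError(RuntimeError):
    pass


def update_systemic_resistance(R: float, CO_meas: float,
                               targets: ControlTargets,
                               gain: float = 1.0,
                               rate_limit: bool = False) -> float:
    """R' = R * (CO_meas / CO_target)^gain (flow too high -> resistance rises).

    ``gain`` < 1 damps the update; the fixed point CO_meas = CO_target is the
    same for any positive gain.  The beat-to-beat solver applies this with
    gain 0.15 because the venous filling lag makes the undamped update ring.
    ``rate_limit`` clamps the per-application factor to [2/3, 3/2], which also
    leaves the fixed point untouched.
    """
    if CO_meas <= 0:
        raise ControlError("measured cardiac output must be positive")
    factor = (CO_meas / targets.CO_target) ** gain
    if rate_limit:
        factor = min(1.5, max(2.0 / 3.0, factor))
    return R * factor


def update_blood_volume(V_tot: float, MAP_meas: float,
                        targets: ControlTargets, gain: float = 0.3) -> float:
    """V' = V * (1 + gain * (MAP_target - MAP_meas)/MAP_target).

    The beat-to-beat solver uses gain 0.05 (see update_systemic_resistance).
    """
    if MAP_meas <= 0:
        raise ControlError("measured MAP must be positive")
    return V_tot * (1.0 + gain * (targets.MAP_target - MAP_meas) / targets.MAP_target)


def adapt_wall(wall: Wall, sigma_peak: float,
               targets: AdaptationTargets) -> Wall:
    """Scale wall volume by peak-stress excess: V_w' = V_w * sigma_peak/sigma_target."""
    new = Wall(**{**wall.__dict__})
    new.V_w = wall.V_w * sigma_peak / targets.sigma_target
    return new


def adapt_vessel(node: ComplianceNode, v_mean: float,
                 targets: AdaptationTargets) -> ComplianceNode:
    """Scale vessel cross-section (hence V_0 and C) by v_mean/v_target."""
    s = v_mean / targets.v_target
    return ComplianceNode(V_0=node.V_0 * s, C=node.C * s, p_0=node.p_0,
                          length=node.length)


# mean flow through each node, by recorded-flow column name
_NODE_FLOW = {"AoP": "ao", "AoD": "seg", "SV": "ven", "PA": "pulv", "PV": "pulm"}


def node_mean_velocity(sol: SteadyState, name: str) -> float:
    """Cycle-mean blood velocity (m/s) through a vessel node: |mean q| / area."""
    node = sol.params.nodes[name]
    q = float(np.mean(sol.cycle.flow(_NODE_FLOW[name]))) * u.ML  # m^3/s
    return abs(q) / node.area


def _exercise_params(params: ParameterSet, ex: ExerciseSpec) -> ParameterSet:
    """Exercise condition: raised flow target and heart rate.

    The pulmonary reference flow scales with the demanded output while the
    reference pressure drop is kept — exercise recruits and dilates the
    pulmonary bed, so the mean pulmonary pressure drop is preserved rather
    than multiplying with flow.
    """
    p = params.copy()
    p.control.CO_target *= ex.co_factor
    p.hr *= ex.hr_factor
    p.pulmonary.q_ref *= ex.co_factor
    return p


def run_adaptation_protocol(
    params: ParameterSet,
    ex: ExerciseSpec,
    targets: AdaptationTargets | None = None,
    init: np.ndarray | None = None,
    max_iter: int = 150,
) -> tuple[ParameterSet, SteadyState]:
    """Adapt walls and vessels to exercise load until the geometry is stable.

    Each iteration converges the exercising circulation (CO target and heart
    rate multiplied by the exercise factors, controllers active), rescales
    wall volumes and vessel areas from the measured peak stresses and mean
    velocities, then re-converges the resting circulation.  Returns the
    adapted parameters and the converged resting solution.
    """
    ex.validate()
    targets = targets or AdaptationTargets()
    params = params.copy()
    rest = run_to_steady_state(params, init=init)
    params = rest.params
    if ex.co_factor == 1.0 and ex.hr_factor == 1.0:
        return params, rest
    residual = np.inf
    # per-iteration growth/shrink factors are rate-limited and under-relaxed:
    # the fixed point (stress and velocity on target) is unchanged, but a
    # grossly undersized chamber grows over a few iterations instead of
    # overshooting in one.  When progress stalls (the loop ping-pongs around
    # the fixed point) the relaxation exponent is annealed further.
    lim = (0.6, 5.0 / 3.0)
    relax = 0.5
    best = np.inf
    stall = 0
    for _ in range(max_iter):
        ex_sol = run_to_steady_state(_exercise_params(params, ex),
                                     init=rest.state, require_targets=False)
        stresses = ex_sol.peak_stress
        changes = []
        for name, wall in params.walls.items():
            f = np.clip(stresses[name] / targets.sigma_target, *lim) ** relax
            new = adapt_wall(wall, f * targets.sigma_target, targets)
            changes.append(abs(new.V_w - wall.V_w) / wall.V_w)
            params.walls[name] = new
        init = rest.state.copy()
        for i, name in enumerate(NODES):
            old = params.nodes[name]
            v = node_mean_velocity(ex_sol, name)
            f = np.clip(v / targets.v_target, *lim) ** relax
            new = adapt_vessel(old, f * targets.v_target, targets)
            changes.append(abs(new.V_0 - old.V_0) / old.V_0)
            params.nodes[name] = new
            # remodeling is slow in vivo: remap the node volume so its
            # pressure carries over, instead of shocking the pressures
            p_old = compliance_pressure(old, init[4 + i] / u.ML)
            init[4 + i] = (new.V_0 + new.C * (p_old - new.p_0)) * u.ML
        # resting resistance restarts from the previous resting value; the
        # exercising controller state stays in the exercise copy
        rest = run_to_steady_state(params, init=init)
        params = rest.params
        residual = max(changes)
        if residual < targets.tol:
            return params, rest
        if residual < 0.7 * best:
            best = residual
            stall = 0
        else:
            stall += 1
            if stall >= 8:
                relax *= 0.5
                stall = 0
    raise AdaptationError(
        f"geometry not stable after {max_iter} iterations (residual {residual:.3g})")
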