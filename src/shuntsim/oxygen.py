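"""Oxygen saturation transport over the compartment network.

Saturations are advected with the blood, upwinded on the instantaneous flow
direction (so bidirectional shunt flow carries the saturation of whichever
side the blood actually comes from).  The lung fixes the saturation of
forward pulmonary-bed flow entering the pulmonary veins at S_pv (98%), and
whole-body oxygen consumption is withdrawn from the systemic venous
compartment.  Transport is one-way coupled: it runs on a frozen periodic
hemodynamic solution and has no feedback on hemodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import engine as eng
from . import units as u
from .model import Cycle, SteadyState
from .parameters import CHAMBERS, NODES, OxygenParams, SHUNT_KINDS

COMPARTMENTS = CHAMBERS + NODES


class TransportError(RuntimeError):
    pass


@dataclass
class SaturationState:
    """Cycle-averaged saturations per compartment (fractions)."""

    values: dict[str, float]
    cycles: int = 0
    supply_limited: bool = False

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @property
    def S_up(self) -> float:
        """Upper-body arterial saturation = proximal aorta."""
        return self.values["AoP"]

    @property
    def S_low(self) -> float:
        """Lower-body arterial saturation = descending aorta."""
        return self.values["AoD"]

    @property
    def S_mv(self) -> float:
        """Mixed-venous saturation = systemic veins."""
        return self.values["SV"]


def lung_uptake(S_in_PA: float, params: OxygenParams | None = None) -> float:
    """Pulmonary venous saturation after lung uptake: S_pv regardless of input."""
    params = params or OxygenParams()
    return params.S_pv


def bed_extraction(S_in: float, q_bed: float, VO2_bed: float,
                   c_cap: float = 174.0) -> tuple[float, bool]:
    """Fick extraction across a tissue bed.

    ``q_bed`` in l/min, ``VO2_bed`` in mL O2/min, ``c_cap`` in mL O2/L.
    Returns (outlet saturation, supply_limited flag); a non-positive bed flow
    with positive consumption is a flagged shock condition with S_out = 0.
    """
    if q_bed <= 0:
        return (S_in, False) if VO2_bed == 0 else (0.0, True)
    s_out = S_in - VO2_bed / (q_bed * c_cap)
    if s_out < 0:
        return 0.0, True
    return s_out, False


def upwind_mixing_rhs(sat: np.ndarray, volumes: np.ndarray, flows: np.ndarray,
                      shunt_kind: str = "NONE",
                      params: OxygenParams | None = None,
                      lung: bool = True, consumption: bool = True
                      ) -> np.ndarray:
    """dS/dt per compartment for one instant of a hemodynamic solution.

    ``sat``: 9 saturations; ``volumes``: 9 compartment volumes (mL);
    ``flows``: 11 connection flows (mL/s) in :class:`~shuntsim.model.Cycle`
    column order.  Lung uptake and tissue consumption can be switched off to
    check that mixing alone conserves total oxygen content.
    """
    params = params or OxygenParams()
    if np.any(volumes < 0.1):
        raise TransportError("compartment volume below 0.1 mL")
    rec_v = (volumes * u.ML)[None, :]
    rec_q = (flows * u.ML)[None, :].copy()
    s_pv = params.S_pv
    if not lung:
        # neutralise the lung by advecting the PV's own upstream saturation
        s_pv = sat[COMPARTMENTS.index("PA")]
    vo2 = params.VO2_total * 1e-6 / 60.0 if consumption else 0.0
    c_cap = params.c_cap * 1e-3
    kind = SHUNT_KINDS.index(shunt_kind)
    s0 = np.asarray(sat, dtype=float)
    # one explicit-Euler step of the kernel gives dS = (S1 - S0)/dt
    dt = 1e-6
    _, s1, _, _, _ = eng.o2_transport(rec_v, rec_q, dt, kind, s_pv, c_cap,
                                      vo2, s0, 1, np.inf)
    return (s1 - s0) / dt


def converge_saturations(sol: SteadyState | Cycle,
                         params: OxygenParams | None = None,
                         shunt_kind: str | None = None,
                         max_cycles: int = 200, tol: float = 1e-5
                         ) -> SaturationState:
    """Integrate saturation transport on a frozen periodic solution.

    Repeats the recorded cycle until every compartment's cycle-mean
    saturation changes by less than ``tol`` between cycles; returns the cycle
    means.
    """
    if isinstance(sol, SteadyState):
        cycle = sol.cycle
        params = params or sol.params.oxygen
        shunt_kind = sol.params.shunt.kind if shunt_kind is None else shunt_kind
    else:
        cycle = sol
        params = params or OxygenParams()
        shunt_kind = shunt_kind or "NONE"
    rec_v = cycle.volumes * u.ML
    rec_q = cycle.flows * u.ML
    s0 = np.full(9, params.S_pv)
    means, _, cycles, ok, limited = eng.o2_transport(
        rec_v, rec_q, cycle.dt, SHUNT_KINDS.index(shunt_kind), params.S_pv,
        params.c_cap * 1e-3, params.VO2_total * 1e-6 / 60.0, s0,
        max_cycles, tol)
    if not ok:
        raise TransportError(
            f"saturation transport not periodic after {max_cycles} cycles")
    return SaturationState(values={n: float(means[i])
                                   for i, n in enumerate(COMPARTMENTS)},
                           cycles=int(cycles), supply_limited=bool(limited))
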