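"""The study pipeline: reference patient, disease staging, shunt matrices.

Stages
------
1. Reference child: controllers tuned to CO 2.1 l/min and MAP 61 mmHg, the
   pulmonary pressure drop tuned so resting mPAP is 15 mmHg, then walls and
   vessels adapted to exercise (threefold CO, twofold heart rate).
2. Compensated moderate PAH: pulmonary drop re-tuned to mPAP 50 mmHg and the
   heart/vessels re-adapted to milder exercise (twofold CO, 1.8-fold HR).
3. Decompensation sweep: pulmonary resistance raised stepwise (no structural
   adaptation, controllers active) to mPAP 50..80 in 5 mmHg steps.
4. Acute shunts: for each base, an ASD or Potts shunt of 0..16 mm diameter is
   inserted with controllers and geometry frozen, run to a new periodic state
   and scored; two 7 x 17 matrices of beat metrics result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import units as u
from .control import run_adaptation_protocol
from .model import SteadyState, run_to_steady_state
from .oxygen import SaturationState, converge_saturations
from .parameters import (
    AdaptationTargets,
    CHAMBERS,
    ExerciseSpec,
    ParameterSet,
    ShuntSpec,
    default_parameter_set,
)

MPAP_LEVELS = (50.0, 55.0, 60.0, 65.0, 70.0, 75.0, 80.0)
DIAMETERS_MM = tuple(float(d) for d in range(17))


class ProtocolError(RuntimeError):
    pass


@dataclass
class BeatMetrics:
    """Cycle-averaged outputs of one converged simulation."""

    mPAP: float          # mmHg
    MAP: float           # mmHg
    CO: float            # l/min, cycle-mean aortic valve flow
    Qp: float            # l/min
    Qs: float            # l/min
    QpQs: float
    shunt_flow: float    # l/min, positive = right-to-left
    W_RA: float          # J/beat
    W_RV: float
    W_LA: float
    W_LV: float
    W_total: float
    S_up: float
    S_low: float
    S_mv: float

    FIELDS = ("mPAP", "MAP", "CO", "Qp", "Qs", "QpQs", "shunt_flow",
              "W_RA", "W_RV", "W_LA", "W_LV", "W_total",
              "S_up", "S_low", "S_mv")

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in self.FIELDS}


def pv_loop_work(p: np.ndarray, v: np.ndarray) -> float:
    """Pump work (J/beat) as the signed pV-loop area, shoelace over the cycle.

    ``p`` in mmHg, ``v`` in mL.  Positive for a chamber doing net work on the
    blood (ejection at higher pressure than filling).
    """
    dv = np.roll(v, -1) - v
    p_mid = 0.5 * (p + np.roll(p, -1))
    return float(-np.sum(p_mid * dv)) * u.J_PER_MMHG_ML


def compute_metrics(sol: SteadyState,
                    sats: SaturationState | None = None) -> BeatMetrics:
    """Score one periodic solution (and optional converged saturations)."""
    works = {name: pv_loop_work(sol.cycle.pressure(name), sol.cycle.volume(name))
             for name in CHAMBERS}
    qs = sol.qs
    return BeatMetrics(
        mPAP=sol.mpap, MAP=sol.map, CO=sol.co, Qp=sol.qp, Qs=qs,
        QpQs=sol.qp / qs, shunt_flow=sol.shunt_flow,
        W_RA=works["RA"], W_RV=works["RV"], W_LA=works["LA"], W_LV=works["LV"],
        W_total=sum(works.values()),
        S_up=sats.S_up if sats else np.nan,
        S_low=sats.S_low if sats else np.nan,
        S_mv=sats.S_mv if sats else np.nan,
    )


def tune_pulmonary_drop(params: ParameterSet, mpap_target: float,
                        init: np.ndarray | None = None,
                        tol: float = 0.05,
                        bracket: tuple[float, float] = (1.0, 150.0),
                        ) -> tuple[ParameterSet, SteadyState]:
    """Root-solve the reference pulmonary pressure drop for a target mPAP.

    Controllers stay active; returns the tuned parameters (with converged
    controller state) and the converged solution.  mPAP is nearly an affine
    function of dp_ref with unit slope, so the scalar root solve converges in
    a handful of converge-runs.
    """
    params = params.copy()
    warm = {"x": init, "params": params}
    lo, hi = bracket

    def evaluate(dp_ref: float) -> tuple[float, SteadyState]:
        p = warm["params"].copy()
        p.pulmonary.dp_ref = dp_ref
        sol = run_to_steady_state(p, init=warm["x"])
        warm["x"] = sol.state
        warm["params"] = sol.params
        return sol.mpap - mpap_target, sol

    # mPAP ~ p_PV + dp_ref * CO/q_ref, so the secant slope is close to one;
    # start from the current operating point rather than the bracket edges
    dp = float(np.clip(params.pulmonary.dp_ref, lo, hi))
    f, sol = evaluate(dp)
    dp_prev, f_prev = dp, f
    for _ in range(25):
        if abs(f) <= tol:
            return sol.params.copy(), sol
        if f_prev != f and dp_prev != dp:
            slope = (f - f_prev) / (dp - dp_prev)
            step = -f / slope if slope > 0.1 else -f
        else:
            step = -f
        step = float(np.clip(step, -25.0, 25.0))
        dp_prev, f_prev = dp, f
        dp = float(np.clip(dp + step, lo, hi))
        f, sol = evaluate(dp)
    raise ProtocolError(
        f"pulmonary tuning did not reach mPAP {mpap_target} "
        f"(best residual {f:+.3f} mmHg at dp_ref {dp:.2f})")


@dataclass
class PatientBuild:
    """A protocol stage output: parameters plus the converged resting state."""

    params: ParameterSet
    solution: SteadyState
    label: str = ""
    mpap_level: float | None = None  # pre-shunt set-point label, mmHg

    @property
    def state(self) -> np.ndarray:
        return self.solution.state


def build_reference_patient(
    config: ParameterSet | None = None,
    exercise: ExerciseSpec | None = None,
    adaptation: AdaptationTargets | None = None,
    mpap_target: float = 15.0,
) -> PatientBuild:
    """Build the resting reference child.

    Controllers recover CO 2.1 l/min and MAP 61 mmHg, the pulmonary drop is
    tuned to resting mPAP 15 mmHg, and walls/vessels are adapted to exercise
    with a threefold cardiac output and twofold heart rate.  Deterministic.
    """
    params = (config or default_parameter_set()).copy()
    exercise = exercise or ExerciseSpec(3.0, 2.0)
    adaptation = adaptation or AdaptationTargets()
    params, sol = _tune_and_adapt(params, mpap_target, exercise, adaptation)
    return PatientBuild(params=params, solution=sol, label="reference")


def _tune_and_adapt(params: ParameterSet, mpap_target: float,
                    exercise: ExerciseSpec, adaptation: AdaptationTargets,
                    init: np.ndarray | None = None,
                    max_outer: int = 15) -> tuple[ParameterSet, SteadyState]:
    """Alternate structural adaptation and pulmonary tuning until both hold.

    Adaptation runs first: an unadapted heart may be too weak to reach a low
    mPAP target at all (venous congestion floors the pulmonary artery
    pressure), whereas the adapted heart tunes in a few converge-runs.
    """
    state = init
    for _ in range(max_outer):
        geom_before = _geometry_vector(params)
        params, sol = run_adaptation_protocol(params, exercise, adaptation,
                                              init=state)
        params, sol = tune_pulmonary_drop(params, mpap_target, init=sol.state)
        state = sol.state
        geom_change = np.max(np.abs(_geometry_vector(params) / geom_before - 1.0))
        if geom_change < adaptation.tol and abs(sol.mpap - mpap_target) < 0.05:
            return params, sol
    raise ProtocolError(
        f"reference build did not stabilise (geometry change {geom_change:.3g})")


def _geometry_vector(params: ParameterSet) -> np.ndarray:
    return np.array([w.V_w for w in params.walls.values()]
                    + [n.V_0 for n in params.nodes.values()])


def build_compensated_pah(reference: PatientBuild) -> PatientBuild:
    """Moderate compensated PAH: resting mPAP 50 mmHg with the heart and
    vessels re-adapted to a twofold-CO, 1.8-fold-HR exercise load."""
    params, sol = _tune_and_adapt(reference.params.copy(), 50.0,
                                  ExerciseSpec(2.0, 1.8), AdaptationTargets(),
                                  init=reference.state)
    return PatientBuild(params=params, solution=sol, label="compensated")


def decompensation_sweep(compensated: PatientBuild,
                         levels: tuple[float, ...] = MPAP_LEVELS
                         ) -> list[PatientBuild]:
    """Stepwise pulmonary-resistance increases without structural adaptation.

    Controllers stay active (CO held at its target); geometry is frozen.
    Returns one base build per mPAP level.
    """
    bases = []
    params = compensated.params.copy()
    state = compensated.state
    for mpap in levels:
        params, sol = tune_pulmonary_drop(params, mpap, init=state)
        state = sol.state
        bases.append(PatientBuild(params=params.copy(), solution=sol,
                                  label=f"mPAP{mpap:g}", mpap_level=mpap))
    return bases


def insert_shunt(base: ParameterSet, spec: ShuntSpec) -> ParameterSet:
    """Add a bidirectional constant-diameter orifice (acute semantics).

    Controllers are frozen: the acute post-shunt state keeps the base's
    systemic resistance and blood volume.
    """
    spec.validate()
    params = base.with_shunt(spec)
    params.control.enabled = False
    return params


def run_shunt_cell(base: PatientBuild, spec: ShuntSpec,
                   with_oxygen: bool = True) -> tuple[BeatMetrics, SteadyState]:
    """One matrix cell: insert shunt, converge, score."""
    params = insert_shunt(base.params, spec)
    sol = run_to_steady_state(params, init=base.state)
    sats = converge_saturations(sol) if with_oxygen else None
    return compute_metrics(sol, sats), sol


@dataclass
class StudyMatrix:
    """7 mPAP levels x 17 diameters of beat metrics for one shunt kind."""

    shunt_kind: str
    mpap_levels: tuple[float, ...]
    diameters: tuple[float, ...]
    table: pd.DataFrame
    failures: list[tuple[float, float, str]] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.table)

    def cell(self, mpap_level: float, diameter: float) -> pd.Series:
        t = self.table
        row = t[(t.mpap_level_mmHg == mpap_level) & (t.diameter_mm == diameter)]
        return row.iloc[0]

    def pivot(self, metric: str) -> pd.DataFrame:
        """metric as a (level x diameter) grid for heatmaps."""
        return self.table.pivot(index="mpap_level_mmHg", columns="diameter_mm",
                                values=metric)


CSV_COLUMNS = ["shunt_kind", "mpap_level_mmHg", "diameter_mm", "mPAP", "MAP",
               "CO_lmin", "Qp_lmin", "Qs_lmin", "QpQs", "shuntflow_lmin",
               "W_RA_J", "W_RV_J", "W_LA_J", "W_LV_J", "W_total_J",
               "S_up", "S_low", "S_mv"]

_CSV_MAP = {"CO": "CO_lmin", "Qp": "Qp_lmin", "Qs": "Qs_lmin",
            "shunt_flow": "shuntflow_lmin", "W_RA": "W_RA_J", "W_RV": "W_RV_J",
            "W_LA": "W_LA_J", "W_LV": "W_LV_J", "W_total": "W_total_J"}


def run_study_matrix(bases: list[PatientBuild], shunt_kind: str,
                     diameters: tuple[float, ...] = DIAMETERS_MM,
                     with_oxygen: bool = True,
                     progress=None) -> StudyMatrix:
    """All cells of one shunt kind; failed cells are recorded, not fatal."""
    rows = []
    failures = []
    levels = tuple(b.mpap_level if b.mpap_level is not None
                   else round(b.solution.mpap, 1) for b in bases)
    for base, level in zip(bases, levels):
        for d in diameters:
            try:
                metrics, _ = run_shunt_cell(base, ShuntSpec(shunt_kind, d),
                                            with_oxygen=with_oxygen)
                row = {"shunt_kind": shunt_kind, "mpap_level_mmHg": level,
                       "diameter_mm": d}
                for f, val in metrics.as_dict().items():
                    row[_CSV_MAP.get(f, f)] = val
                rows.append(row)
            except Exception as exc:  # noqa: BLE001 - cell failures are data
                failures.append((level, d, str(exc)))
                rows.append({"shunt_kind": shunt_kind, "mpap_level_mmHg": level,
                             "diameter_mm": d})
            if progress is not None:
                progress(shunt_kind, level, d)
    table = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return StudyMatrix(shunt_kind=shunt_kind, mpap_levels=levels,
                       diameters=diameters, table=table, failures=failures)


def run_study_matrices(bases: list[PatientBuild],
                       diameters: tuple[float, ...] = DIAMETERS_MM,
                       with_oxygen: bool = True,
                       progress=None) -> dict[str, StudyMatrix]:
    """Both 7 x 17 matrices (Potts and ASD), deterministic ordering."""
    return {kind: run_study_matrix(bases, kind, diameters, with_oxygen, progress)
            for kind in ("POTTS", "ASD")}
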