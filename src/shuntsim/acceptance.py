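"""Acceptance evaluation: recompute the study's headline numbers and check
the model's structural invariants on pipeline outputs.

`acceptance_report` consumes the stage fixtures and matrix tables produced by
the protocol and returns a machine-readable report: measured values for the
printed set-points and pump-work deltas, plus one boolean per invariant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .protocol import PatientBuild


def pump_work_delta(table: pd.DataFrame, d_from: float, d_to: float) -> float:
    """Mean percent change of total pump work between two diameters,
    averaged over the mPAP levels (%)."""
    if not {d_from, d_to} <= set(table.diameter_mm):
        raise ValueError(f"diameters {d_from} and {d_to} not in the matrix")
    changes = []
    for level, rows in table.groupby("mpap_level_mmHg"):
        w_from = float(rows.loc[rows.diameter_mm == d_from, "W_total_J"].iloc[0])
        w_to = float(rows.loc[rows.diameter_mm == d_to, "W_total_J"].iloc[0])
        changes.append(100.0 * (w_to - w_from) / w_from)
    return float(np.mean(changes))


def _per_level(table: pd.DataFrame, column: str) -> dict[float, pd.Series]:
    out = {}
    for level, rows in table.groupby("mpap_level_mmHg"):
        out[level] = rows.sort_values("diameter_mm").set_index("diameter_mm")[column]
    return out


def invariants(tables: dict[str, pd.DataFrame]) -> dict[str, bool]:
    """One boolean per structural property of the two study matrices."""
    potts = tables["POTTS"]
    asd = tables["ASD"]
    checks: dict[str, bool] = {}

    checks["matrix_shape_119_per_kind"] = len(potts) == 119 and len(asd) == 119
    for t in (potts, asd):
        expect = t.mpap_level_mmHg.nunique() * t.diameter_mm.nunique()
        checks["matrix_grid_complete"] = checks.get("matrix_grid_complete", True) \
            and len(t) == expect

    base = potts[potts.diameter_mm == 0]
    checks["qp_qs_unity_without_shunt"] = bool(
        np.all(np.abs(base.QpQs - 1.0) < 0.005))

    sats = pd.concat([potts, asd])[["S_up", "S_low", "S_mv"]]
    checks["saturations_bounded"] = bool(
        ((sats >= 0) & (sats <= 1)).all().all())

    checks["potts_upper_body_saturation_98"] = bool(
        np.all(np.abs(potts.S_up - 0.98) < 1e-3))

    # septostomy desaturation is global: upper equals lower saturation
    checks["asd_desaturation_global"] = bool(
        np.all(np.abs(asd.S_up - asd.S_low) < 1e-3))

    # net Potts flow right-to-left iff the level is suprasystemic; the rule
    # compares pre-shunt pressures and is indeterminate within the pulse
    # pressure of the crossing, so the near-equal level is only required to
    # carry a small flow
    ok = True
    for level, rows in potts.groupby("mpap_level_mmHg"):
        base_map = float(rows.loc[rows.diameter_mm == 0, "MAP"].iloc[0])
        flows = rows.loc[rows.diameter_mm > 0, "shuntflow_lmin"]
        if abs(level - base_map) > 2.0:
            ok &= bool(np.all(np.sign(flows) == np.sign(level - base_map)))
        else:
            ok &= bool(np.all(np.abs(flows) < 0.15))
    checks["potts_direction_rule"] = ok

    # mPAP falls monotonically toward MAP as the Potts shunt grows
    ok = True
    for level, series in _per_level(potts, "mPAP").items():
        if level > 61.0:
            ok &= bool(np.all(np.diff(series.values) < 0.3))
    checks["potts_mpap_toward_map_monotone"] = ok

    # Qp/Qs plateau for Potts diameters >= 8 mm
    ok = True
    for level, series in _per_level(potts, "QpQs").items():
        plateau = series[series.index >= 8.0]
        ok &= bool(plateau.max() - plateau.min() < 0.05)
    checks["potts_qpqs_plateau_d8plus"] = ok

    # septostomy barely influences right heart pressures
    shifts = np.abs(asd.mPAP - asd.mpap_level_mmHg) / asd.mpap_level_mmHg
    checks["asd_mpap_within_10pct"] = bool(np.all(shifts < 0.10))

    # right ventricular unloading: W_RV non-increasing in defect size
    ok = True
    for level, series in _per_level(asd, "W_RV_J").items():
        ok &= bool(np.all(np.diff(series.values) <= 1e-9))
    checks["asd_w_rv_monotone_decrease"] = ok

    # Potts leaves W_RV nearly unchanged compared to the septostomy change
    ok = True
    for level in potts.mpap_level_mmHg.unique():
        p = _per_level(potts, "W_RV_J")[level]
        a = _per_level(asd, "W_RV_J")[level]
        ps_span = p.max() - p.min()
        as_span = abs(a.iloc[0] - a.iloc[-1])
        ok &= bool(ps_span < max(2.0 * as_span, 0.15 * p.iloc[0]))
    checks["potts_w_rv_insensitive"] = ok

    # flow bookkeeping: Qs = Qp + net shunt flow for the Potts
    resid = (potts.Qs_lmin - potts.Qp_lmin - potts.shuntflow_lmin).abs() \
        / potts.Qs_lmin
    checks["potts_flow_bookkeeping_1pct"] = bool(np.all(resid < 0.01))

    return checks


def acceptance_report(fixtures: dict[str, object],
                      tables: dict[str, pd.DataFrame]) -> dict:
    """Measured headline values plus the invariant suite."""
    ref: PatientBuild = fixtures["reference"]
    report: dict = {
        "reference_CO_lmin": ref.solution.co,
        "reference_MAP_mmHg": ref.solution.map,
        "reference_mPAP_mmHg": ref.solution.mpap,
        "compensated_mPAP_mmHg": fixtures["compensated"].solution.mpap,
        "dp_pulm_ref_at_mPAP50_mmHg":
            fixtures["bases"][0].params.pulmonary.dp_ref,
        "dp_pulm_ref_at_mPAP80_mmHg":
            fixtures["bases"][-1].params.pulmonary.dp_ref,
    }
    if {"POTTS", "ASD"} <= tables.keys():
        if {5.0, 16.0} <= set(tables["POTTS"].diameter_mm):
            report["potts_total_work_change_5_to_16mm_pct"] = \
                pump_work_delta(tables["POTTS"], 5.0, 16.0)
        if {0.0, 16.0} <= set(tables["ASD"].diameter_mm):
            report["asd_total_work_change_0_to_16mm_pct"] = \
                pump_work_delta(tables["ASD"], 0.0, 16.0)
        report["invariants"] = invariants(tables)
    return report
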