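"""CSV export, figures and the summary report.

Figures are qualitative reproductions: per-metric heatmaps over the
(mPAP level x shunt diameter) grid for both shunt kinds, and pressure-volume
loop / time-trace panels for the protocol stages.  All numeric acceptance
goes through the CSV tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .model import SteadyState
from .parameters import CHAMBERS
from .protocol import CSV_COLUMNS, PatientBuild, StudyMatrix


@dataclass
class RunManifest:
    """Record of one pipeline run: config hash, diagnostics, output files."""

    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def add_stage(self, label: str, sol: SteadyState) -> None:
        self.stages[label] = {
            "beats": sol.beats,
            "final_residual": sol.residual_history[-1] if sol.residual_history else None,
            "CO_lmin": sol.co,
            "MAP_mmHg": sol.map,
            "mPAP_mmHg": sol.mpap,
        }

    def add_output(self, path: str | Path) -> None:
        path = Path(path)
        if not path.exists() or path.stat().st_size == 0:
            raise IOError(f"output file missing or empty: {path}")
        self.outputs.append(str(path))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config_hash": self.config_hash, "version": self.version,
             "stages": self.stages, "outputs": self.outputs}, indent=2))


def config_hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_matrix_csv(matrix: StudyMatrix, path: str | Path) -> Path:
    """One row per cell, 6 significant digits, '.' decimal, fixed column set."""
    path = Path(path)
    matrix.table.to_csv(path, index=False, float_format="%.6g",
                        columns=CSV_COLUMNS)
    return path


HEATMAP_METRICS = ("QpQs", "W_RV_J", "W_LV_J", "W_total_J", "S_low")


def render_heatmaps(matrices: dict[str, StudyMatrix], outdir: str | Path,
                    fmt: str = "png") -> list[Path]:
    """Five heatmap pairs (Potts left, septostomy right) over the study grid."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for metric in HEATMAP_METRICS:
        fig, axes = plt.subplots(1, 2, figsize=(11, 3.6), sharey=True)
        for ax, kind in zip(axes, ("POTTS", "ASD")):
            grid = matrices[kind].pivot(metric)
            im = ax.imshow(grid.values, aspect="auto", origin="lower",
                           cmap="viridis",
                           extent=(grid.columns.min() - 0.5, grid.columns.max() + 0.5,
                                   grid.index.min() - 2.5, grid.index.max() + 2.5))
            ax.set_title(f"{metric} — {'Potts shunt' if kind == 'POTTS' else 'atrial septostomy'}")
            ax.set_xlabel("shunt diameter (mm)")
            fig.colorbar(im, ax=ax)
        axes[0].set_ylabel("pre-shunt mPAP (mmHg)")
        fig.tight_layout()
        p = outdir / f"heatmap_{metric}.{fmt}"
        fig.savefig(p, dpi=130)
        plt.close(fig)
        paths.append(p)
    return paths


def render_pv_panel(solutions: dict[str, SteadyState], outdir: str | Path,
                    fmt: str = "png") -> list[Path]:
    """pV loops of all four chambers plus pressure/flow traces per stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, sol in solutions.items():
        cyc = sol.cycle
        fig, (ax_pv, ax_p, ax_q) = plt.subplots(1, 3, figsize=(13, 3.6))
        for name in CHAMBERS:
            ax_pv.plot(cyc.volume(name), cyc.pressure(name), label=name)
        ax_pv.set_xlabel("volume (mL)")
        ax_pv.set_ylabel("pressure (mmHg)")
        ax_pv.set_title(f"pV loops — {label}")
        ax_pv.legend(fontsize=7)
        for name in ("LV", "RV", "AoP", "PA"):
            ax_p.plot(cyc.t, cyc.pressure(name), label=name)
        ax_p.axhline(sol.mpap, color="k", lw=0.8)
        ax_p.axhline(sol.map, color="k", lw=0.8, ls="--")
        ax_p.set_xlabel("time (s)")
        ax_p.set_title("pressures (solid line: mPAP, dashed: MAP)")
        ax_p.legend(fontsize=7)
        for name in ("ao", "pulv", "mit", "tri", "shunt"):
            ax_q.plot(cyc.t, cyc.flow(name), label=name)
        ax_q.set_xlabel("time (s)")
        ax_q.set_ylabel("flow (mL/s)")
        ax_q.set_title("valve and shunt flows")
        ax_q.legend(fontsize=7)
        fig.tight_layout()
        p = outdir / f"pv_{label}.{fmt}"
        fig.savefig(p, dpi=130)
        plt.close(fig)
        paths.append(p)
    return paths


def stage_summary(builds: list[PatientBuild]) -> str:
    """Aligned text table of the protocol stages' converged set-points."""
    lines = ["stage            CO(l/min)  MAP(mmHg)  mPAP(mmHg)  dp_pulm_ref(mmHg)"]
    for b in builds:
        s = b.solution
        lines.append(f"{b.label:<16s} {s.co:9.3f}  {s.map:9.2f}  {s.mpap:10.2f}"
                     f"  {b.params.pulmonary.dp_ref:17.2f}")
    return "\n".join(lines)
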