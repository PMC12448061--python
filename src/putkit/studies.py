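"""End-to-end study runners.

Three reproducible pipelines mirror the study design:

* ``run_mechanism_study`` — the three reference bubble trajectories, the
  threshold curve over fluence, and the grow/dissolve regime map.
* ``run_phantom_study`` — synthetic B-mode stacks over a pressure × fluence
  grid with a programmed event-probability surface, detected into a CP map.
* ``run_treatment_analysis`` — synthetic treated/untreated OCT series per
  (side, timepoint), quantified into densities, reductions and paired tests.

Each runner writes a config snapshot, a log file and CSV/JSON outputs into
its run directory; deterministic stages are bit-reproducible and stochastic
stages are seed-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bubble import MediumProperties, SolverOptions, classify_fate, simulate
from .cavitation_detect import FrameStack, cp_map, fit_baseline
from .config import snapshot
from .octa import quantify_series
from .synthetic_data import BmodeGenConfig, OctGenConfig, gen_bmode_stack, gen_oct_series
from .threshold import DriveProtocol, regime_map, threshold_curve

__all__ = [
    "MechanismConfig",
    "PhantomConfig",
    "TreatmentConfig",
    "run_mechanism_study",
    "run_phantom_study",
    "run_treatment_analysis",
    "validate_treatment_report",
]

_PRINTED_CASES = ((0.6, 100.0), (0.8, 120.0), (1.0, 120.0))


def _logger(out_dir: Path, name: str) -> logging.Logger:
    logger = logging.getLogger(f"putkit.{name}.{out_dir}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.propagate = False
    return logger


@dataclass(frozen=True)
class MechanismConfig:
    """Mechanism-study grids; 21 × 21 map over 0–1 MPa × 0–200 mJ/cm².

    The regime map uses a 32-cycle burst (fate labels at the reference
    parameter combinations are unchanged versus 100 and 500 cycles; the
    shorter burst keeps the 441-cell map desk-scale), while the threshold
    curve and reference trajectories use the 100-cycle default.
    """

    R0_m: float = 100e-9
    pressure_min_MPa: float = 0.0
    pressure_max_MPa: float = 1.0
    n_pressures: int = 21
    fluence_min: float = 0.0
    fluence_max: float = 200.0
    n_fluences: int = 21
    threshold_fluences: tuple = (0.0, 50.0, 100.0, 150.0, 200.0)
    threshold_radii_m: tuple = (100e-9,)
    map_cycles: int = 32
    trajectory_cycles: int = 100
    bisection_tolerance_MPa: float = 0.01

    def pressures(self) -> np.ndarray:
        return np.linspace(self.pressure_min_MPa, self.pressure_max_MPa, self.n_pressures)

    def fluences(self) -> np.ndarray:
        return np.linspace(self.fluence_min, self.fluence_max, self.n_fluences)


def run_mechanism_study(
    cfg: MechanismConfig | None = None,
    out_dir: str | Path = "mechanism_run",
    medium: MediumProperties | None = None,
) -> dict:
    """Reference trajectories + threshold curve + regime map; returns paths."""
    cfg = cfg or MechanismConfig()
    medium = medium or MediumProperties()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snapshot({"study": "mechanism", "config": cfg, "medium": medium}, out)
    log = _logger(out, "mechanism")
    t_start = time.perf_counter()

    traj_protocol = DriveProtocol(cycles=cfg.trajectory_cycles)
    fates = {}
    for pnp, fluence in _PRINTED_CASES:
        t0 = time.perf_counter()
        drive = traj_protocol.build(pnp, fluence)
        traj = simulate(drive, cfg.R0_m, medium)
        fate = classify_fate(traj, medium)
        fates[f"{pnp:.1f}MPa_{fluence:.0f}mJcm2"] = fate.value
        pd.DataFrame(
            {"time_us": traj.time_s * 1e6, "R_m": traj.radius_m, "R_over_R0": traj.ratio}
        ).to_csv(out / f"trajectory_{pnp:.1f}MPa_{fluence:.0f}mJcm2.csv", index=False)
        log.info("trajectory (%.1f MPa, %.0f mJ/cm2): %s [%.2f s]", pnp, fluence, fate.value,
                 time.perf_counter() - t0)

    t0 = time.perf_counter()
    curve = threshold_curve(
        cfg.threshold_radii_m,
        cfg.threshold_fluences,
        medium,
        tolerance_MPa=cfg.bisection_tolerance_MPa,
        protocol=traj_protocol,
    )
    curve.to_frame().to_csv(out / "threshold_curve.csv", index=False)
    log.info("threshold curve [%.1f s]", time.perf_counter() - t0)

    t0 = time.perf_counter()
    rmap = regime_map(
        cfg.pressures(),
        cfg.fluences(),
        cfg.R0_m,
        medium,
        protocol=DriveProtocol(cycles=cfg.map_cycles),
    )
    rmap.to_frame().to_csv(out / "regime_map.csv", index=False)
    log.info("regime map %dx%d [%.1f s]", cfg.n_pressures, cfg.n_fluences,
             time.perf_counter() - t0)

    summary = {
        "fates": fates,
        "threshold_MPa": {
            f"{f:.0f}": (None if np.isnan(v) else float(v))
            for f, v in zip(curve.fluences_mJ_cm2, curve.pressures_MPa[0])
        },
        "elapsed_s": time.perf_counter() - t_start,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return {"out_dir": out, "summary": summary, "curve": curve, "regime_map": rmap}


@dataclass(frozen=True)
class PhantomConfig:
    """Synthetic phantom CP study: programmed event-probability surface.

    The programmed per-frame event probability rises linearly with both
    pressure and fluence (an idealized stand-in for the measured stochastic
    CP surface), capped to [0, 1].
    """

    pressures_MPa: tuple = (0.6, 0.8, 1.0, 1.2, 1.4)
    fluences_mJ_cm2: tuple = (0.0, 50.0, 100.0, 150.0, 200.0)
    n_frames: int = 100
    gen: BmodeGenConfig = field(default_factory=BmodeGenConfig)
    seed: int = 0

    def programmed_p_event(self, pressure: float, fluence: float) -> float:
        p_term = (pressure - self.pressures_MPa[0]) / (
            self.pressures_MPa[-1] - self.pressures_MPa[0]
        )
        f_term = fluence / self.fluences_mJ_cm2[-1] if self.fluences_mJ_cm2[-1] else 0.0
        return float(np.clip(0.5 * p_term + 0.5 * f_term, 0.0, 1.0))


def run_phantom_study(
    cfg: PhantomConfig | None = None, out_dir: str | Path = "phantom_run"
) -> dict:
    """Generate stacks per grid cell, fit the zero-fluence baseline per
    pressure series, detect, and export the CP map plus a truth report."""
    cfg = cfg or PhantomConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snapshot({"study": "phantom", "config": cfg}, out)
    log = _logger(out, "phantom")
    rng = np.random.default_rng(cfg.seed)

    stacks: list[FrameStack] = []
    truth_rows = []
    baselines = {}
    # one physical phantom for the whole study: every stack shares the same
    # frozen speckle pattern, only temporal noise and events differ
    pattern_seed = int(rng.integers(2**31))
    for pressure in cfg.pressures_MPa:
        base_cfg = dataclasses.replace(
            cfg.gen,
            p_event=0.0,
            n_frames=cfg.n_frames,
            seed=int(rng.integers(2**31)),
            pattern_seed=pattern_seed,
        )
        base_stack, _ = gen_bmode_stack(base_cfg)
        base_stack = dataclasses.replace(
            base_stack, pressure_MPa=pressure, fluence_mJ_cm2=0.0, role="baseline"
        )
        baselines[pressure] = fit_baseline(base_stack, auto_mask=True)
        for fluence in cfg.fluences_mJ_cm2:
            p_ev = cfg.programmed_p_event(pressure, fluence)
            gen_cfg = dataclasses.replace(
                cfg.gen,
                p_event=p_ev,
                n_frames=cfg.n_frames,
                seed=int(rng.integers(2**31)),
                pattern_seed=pattern_seed,
            )
            stack, truth = gen_bmode_stack(gen_cfg)
            stack = dataclasses.replace(
                stack, pressure_MPa=pressure, fluence_mJ_cm2=fluence, role="test"
            )
            stacks.append(stack)
            truth_rows.append(
                {
                    "pressure_MPa": pressure,
                    "fluence_mJcm2": fluence,
                    "programmed_p_event": p_ev,
                    "true_cp": float(np.mean(truth["event_frames"])),
                }
            )
    cpm = cp_map(stacks, baselines)
    table = cpm.table.merge(pd.DataFrame(truth_rows), on=["pressure_MPa", "fluence_mJcm2"])
    table.to_csv(out / "cp_map.csv", index=False)
    log.info("CP map with %d cells", len(table))
    return {"out_dir": out, "cp_table": table}


@dataclass(frozen=True)
class TreatmentConfig:
    """Synthetic treatment-assessment study.

    Programmed Day-7 reductions default to the headline top/bottom values
    (45.20 % and 36.06 %); Day-1 values are set slightly lower.  Four regions
    per (side, timepoint) provide the paired samples.
    """

    reductions_pct: tuple = (
        ("top", "day1", 40.0),
        ("bottom", "day1", 30.0),
        ("top", "day7", 45.20),
        ("bottom", "day7", 36.06),
    )
    n_regions: int = 4
    depth_gate_um: tuple = (150.0, 300.0)
    gen: OctGenConfig = field(default_factory=OctGenConfig)
    seed: int = 0


def run_treatment_analysis(
    cfg: TreatmentConfig | None = None, out_dir: str | Path = "treatment_run"
) -> dict:
    """Generate series pairs, quantify densities/reductions, run paired tests."""
    cfg = cfg or TreatmentConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snapshot({"study": "treatment", "config": cfg}, out)
    log = _logger(out, "treatment")
    rng = np.random.default_rng(cfg.seed)

    series = []
    for side, timepoint, reduction in cfg.reductions_pct:
        for r in range(cfg.n_regions):
            gen_cfg = dataclasses.replace(
                cfg.gen,
                treated_fraction_retained=1.0 - reduction / 100.0,
                seed=int(rng.integers(2**31)),
            )
            untreated, treated, _ = gen_oct_series(
                gen_cfg, region_id=f"R{r + 1}", side=side, timepoint=timepoint
            )
            series.extend([untreated, treated])
    result = quantify_series(series, cfg.depth_gate_um)
    result.table.to_csv(out / "densities.csv", index=False)
    result.reductions.to_csv(out / "reductions.csv", index=False)

    report = {
        "depth_gate_um": list(cfg.depth_gate_um),
        "groups": [
            {
                "side": side,
                "timepoint": tp,
                "programmed_reduction_pct": red,
                "estimated_reduction_pct": float(
                    result.reductions.query("side == @side and timepoint == @tp")
                    .percent_reduction.iloc[0]
                ),
            }
            for side, tp, red in cfg.reductions_pct
        ],
        "paired_tests": {
            f"{side}_{tp}": {
                "t": res.t_statistic,
                "p": res.p_value,
                "n": res.n,
                "degenerate": res.degenerate,
            }
            for (side, tp), res in result.tests.items()
        },
    }
    validate_treatment_report(report)
    (out / "treatment_report.json").write_text(json.dumps(report, indent=2))
    log.info("treatment analysis: %d groups", len(report["groups"]))
    return {"out_dir": out, "report": report, "result": result}


_REPORT_SCHEMA_PATH = Path(__file__).parent / "schemas" / "treatment_report.schema.json"


def validate_treatment_report(report: dict) -> None:
    """Structural validation against the shipped report schema.

    Checks required keys and primitive types; raises ValueError on mismatch.
    """
    schema = json.loads(_REPORT_SCHEMA_PATH.read_text())
    for key in schema["required"]:
        if key not in report:
            raise ValueError(f"treatment report missing required key '{key}'")
    if not isinstance(report["groups"], list) or not report["groups"]:
        raise ValueError("treatment report 'groups' must be a non-empty list")
    group_req = schema["properties"]["groups"]["items"]["required"]
    for g in report["groups"]:
        for key in group_req:
            if key not in g:
                raise ValueError(f"treatment report group missing '{key}'")
        if not isinstance(g["estimated_reduction_pct"], (int, float)):
            raise ValueError("estimated_reduction_pct must be numeric")
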