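"""End-to-end glue: synthetic cohort (or stored data) to edge selection.

Convenience orchestration used by the examples, the calibration experiments
and the command-line front end; every step delegates to the corresponding
module.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .behavior import compute_bis
from .connectivity import FCMatrix, average_fc, compute_fc, condition_fc
from .edge_selection import (
    BehaviorVector,
    EdgeSelectionResult,
    build_difference_panel,
    loo_stability_selection,
)
from .io_config import PipelineConfig
from .synthetic import SimulationConfig, generate_cohort, simulate_timeseries

log = logging.getLogger("fcx")


def dual_task_fc(cfg: SimulationConfig, pipe_cfg: PipelineConfig,
                 regress: bool = False) -> dict[str, tuple[FCMatrix, FCMatrix]]:
    """Per-subject (incompatible, compatible) dual-task FC matrices from a
    simulation config.

    ``regress=False`` skips nuisance/task regression — appropriate when the
    generator plants no confound leakage or evoked signal, and the fast path
    for calibration experiments.
    """
    pairs: dict[str, tuple] = {}
    for s in range(cfg.n_subjects):
        mats = {}
        for cond in ("dual-incompatible", "dual-compatible"):
            run_mats = []
            for r in range(cfg.runs_per_condition.get(cond, 0)):
                run = simulate_timeseries(cfg, s, cond, r)
                if regress:
                    fcm = condition_fc([run], pipe_cfg)
                    if fcm is not None:
                        run_mats.append(fcm)
                else:
                    run_mats.append(compute_fc(run, pipe_cfg))
            mats[cond] = average_fc(run_mats) if run_mats else None
        sid = f"sub-{s + 1:03d}"
        pairs[sid] = (mats["dual-incompatible"], mats["dual-compatible"])
    return pairs


def dual_bis_difference(trials: pd.DataFrame) -> pd.Series:
    """Per-subject dual-task BIS difference (incompatible - compatible),
    the behavioral difference score the edge selection correlates against."""
    bis = compute_bis(trials)
    dual = bis.cells[bis.cells["task_type"] == "dual"]
    wide = dual.pivot(index="subject_id", columns="pairing", values="bis")
    return wide["incompatible"] - wide["compatible"]


def run_dual_task_selection(
    cfg: SimulationConfig,
    pipe_cfg: PipelineConfig | None = None,
    regress: bool = False,
) -> EdgeSelectionResult:
    """Full synthetic pipeline: simulate dual-task runs and trials, score
    behavior, and run the edge-level stability selection."""
    pipe_cfg = pipe_cfg or PipelineConfig()
    cohort = generate_cohort(cfg, pipe_cfg)
    pairs = dual_task_fc(cfg, pipe_cfg, regress=regress)
    panel = build_difference_panel(pairs)
    scores = dual_bis_difference(cohort.trials).reindex(list(panel.subjects))
    cov = cohort.covariates.for_subjects(panel.subjects)[
        ["age", "gender", "mean_fd"]
    ].to_numpy(dtype=float)
    behavior = BehaviorVector(panel.subjects, scores.to_numpy(), cov)
    return loo_stability_selection(panel, behavior, cfg.parcels, pipe_cfg)
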