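"""From per-run parcellated time series to per-subject Fisher-z FC matrices.

Pipeline per run: motion screening (mean FD, spike fraction, hard spikes),
nuisance regression against the confound set (global signal, CSF, white
matter, 6 motion parameters, framewise displacement — each expanded with its
temporal derivative and the squares of both), removal of mean task-evoked
activity with a finite-impulse-response basis, then Fisher-z Pearson
correlation between all regions.  Condition matrices are element-wise
averages over runs in Fisher-z space.

Missing edges (from zero-variance regions) are stored as NaN and propagate
pairwise-completely through all downstream statistics; they are never
imputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_config import PipelineConfig

log = logging.getLogger("fcx")

#: Confound columns consumed from the (fMRIPrep-style) confounds table.
CONFOUND_COLUMNS = (
    "global_signal",
    "csf",
    "white_matter",
    "trans_x",
    "trans_y",
    "trans_z",
    "rot_x",
    "rot_y",
    "rot_z",
    "framewise_displacement",
)


@dataclass
class RunTimeSeries:
    """One run: regions x timepoints data, confounds, and task events.

    ``events`` is a list of ``(condition_label, onset_frame, duration_frames)``.
    The FD column is nonnegative with the first frame conventionally 0.
    """

    data: np.ndarray
    confounds: pd.DataFrame
    events: list[tuple[str, int, int]] = field(default_factory=list)
    subject_id: str = ""
    condition: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (regions x timepoints)")
        if len(self.confounds) != self.data.shape[1]:
            raise ValueError("confound rows must equal timepoint count")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class MotionSummary:
    mean_fd: float
    spike_fraction: float
    max_fd: float
    passed: bool


@dataclass
class FCMatrix:
    """Symmetric R x R matrix of Fisher-z correlations for one subject and
    condition.  The diagonal is stored as 0 and is excluded from every
    statistic; missing edges are NaN."""

    values: np.ndarray
    subject_id: str = ""
    condition: str = ""
    n_runs_averaged: int = 1
    flagged_regions: tuple[int, ...] = ()
    clipped_edges: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        asym = np.nanmax(np.abs(v - v.T)) if v.size else 0.0
        if asym > 1e-12:
            raise ValueError(f"FC matrix asymmetric (max |v - v.T| = {asym:g})")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Motion screening
# ---------------------------------------------------------------------------


def screen_run_motion(run: RunTimeSeries, cfg: PipelineConfig) -> MotionSummary:
    """Evaluate the three motion inclusion criteria for a run.

    Passes iff mean FD is *below* the mean threshold, the spike fraction is
    *below* its maximum, and no frame exceeds the hard spike ceiling.
    """
    if "framewise_displacement" not in run.confounds.columns:
        raise ValueError("confounds table has no framewise_displacement column")
    fd = run.confounds["framewise_displacement"].to_numpy(dtype=float)
    mean_fd = float(fd.mean())
    spike_fraction = float(np.mean(fd > cfg.spike_fd_threshold))
    max_fd = float(fd.max())
    passed = (
        mean_fd < cfg.fd_mean_threshold
        and spike_fraction < cfg.spike_fraction_max
        and max_fd <= cfg.spike_hard_max
    )
    log.info(
        "motion screen %s/%s/%s: mean_fd=%.3f spike_frac=%.3f max_fd=%.3f pass=%s",
        run.subject_id, run.condition, run.run_id, mean_fd, spike_fraction, max_fd, passed,
    )
    return MotionSummary(mean_fd, spike_fraction, max_fd, passed)


# ---------------------------------------------------------------------------
# Regression helpers
# ---------------------------------------------------------------------------


def _residualize(data: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of each region's series against the design columns.

    Rank-deficient designs are handled through the pseudo-inverse (equivalent
    to dropping collinear columns); a warning is emitted when that happens.
    Residuals are orthogonal to the design column space.
    """
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            f"rank-deficient regression design ({rank}/{design.shape[1]} independent "
            "columns); collinear columns effectively dropped"
        )
    beta, *_ = np.linalg.lstsq(design, data.T, rcond=None)
    return data - (design @ beta).T


def _expand(col: np.ndarray) -> np.ndarray:
    """Satterthwaite-style 4-term expansion of a confound: the raw series,
    its backward-difference temporal derivative (first frame 0), its square,
    and the squared derivative."""
    d = np.zeros_like(col)
    d[1:] = np.diff(col)
    return np.column_stack([col, d, col**2, d**2])


def nuisance_regress(run: RunTimeSeries, expand_fd: bool = True) -> RunTimeSeries:
    """Regress the confound set out of every region's series.

    Each confound contributes its raw values plus three derived columns
    (derivative, square, squared derivative); set ``expand_fd=False`` to
    enter framewise displacement raw only.  Returns a new run whose data are
    the OLS residuals (demeaned via the intercept).
    """
    missing = [c for c in CONFOUND_COLUMNS if c not in run.confounds.columns]
    if missing:
        raise ValueError(f"confounds table missing columns: {missing}")
    T = run.n_timepoints
    blocks = [np.ones((T, 1))]
    for name in CONFOUND_COLUMNS:
        col = run.confounds[name].to_numpy(dtype=float)
        if name == "framewise_displacement" and not expand_fd:
            blocks.append(col[:, None])
        else:
            blocks.append(_expand(col))
    design = np.hstack(blocks)
    resid = _residualize(run.data, design)
    log.info("nuisance regression %s/%s/%s: %d design columns",
             run.subject_id, run.condition, run.run_id, design.shape[1])
    return replace(run, data=resid)


def fir_design(events: list[tuple[str, int, int]], n_timepoints: int,
               n_lags: int = 8) -> np.ndarray:
    """Finite-impulse-response task design: one indicator regressor per
    post-onset lag 0..n_lags-1 per condition label (all-zero lags dropped)."""
    labels = sorted({e[0] for e in events})
    cols = []
    for label in labels:
        onsets = [onset for lab, onset, _dur in events if lab == label]
        for lag in range(n_lags):
            col = np.zeros(n_timepoints)
            for onset in onsets:
                t = onset + lag
                if 0 <= t < n_timepoints:
                    col[t] = 1.0
            if col.any():
                cols.append(col)
    if not cols:
        return np.zeros((n_timepoints, 0))
    return np.column_stack(cols)


def task_regress(run: RunTimeSeries, n_lags: int = 8) -> RunTimeSeries:
    """Remove mean task-evoked activity with an FIR basis so that evoked
    transients do not inflate inter-region correlations.

    With no events the run is returned unchanged with a warning.
    """
    if not run.events:
        warnings.warn("task_regress called on a run with no events; returning unchanged")
        return run
    if n_lags > run.n_timepoints / 5:
        raise ValueError("FIR basis order exceeds timepoints/5")
    fir = fir_design(run.events, run.n_timepoints, n_lags)
    design = np.hstack([np.ones((run.n_timepoints, 1)), fir])
    resid = _residualize(run.data, design)
    return replace(run, data=resid)


# ---------------------------------------------------------------------------
# FC computation
# ---------------------------------------------------------------------------


def compute_fc(run: RunTimeSeries, cfg: PipelineConfig | None = None) -> FCMatrix:
    """Fisher-z Pearson correlation matrix of a run's regional series.

    Correlations of exactly +/-1 are clipped at ``cfg.fisher_clip`` before
    arctanh and the affected edges recorded.  Zero-variance regions get NaN
    (missing) edges and are flagged, never silently zeroed.
    """
    cfg = cfg or PipelineConfig()
    if run.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    data = run.data
    var = data.var(axis=1)
    flagged = tuple(int(i) for i in np.flatnonzero(var == 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    clip_mask = np.abs(r) >= 1.0
    np.fill_diagonal(clip_mask, False)
    clipped = tuple(
        (int(i), int(j)) for i, j in zip(*np.nonzero(np.triu(clip_mask, 1)))
    )
    if clipped:
        warnings.warn(f"{len(clipped)} edge(s) at |r|=1 clipped before Fisher transform")
    z = np.arctanh(np.clip(r, -cfg.fisher_clip, cfg.fisher_clip))
    for i in flagged:
        z[i, :] = np.nan
        z[:, i] = np.nan
    np.fill_diagonal(z, 0.0)
    if flagged:
        warnings.warn(f"zero-variance regions {flagged}: edges set missing")
    return FCMatrix(z, run.subject_id, run.condition, 1, flagged, clipped)


def average_fc(matrices: list[FCMatrix]) -> FCMatrix:
    """Element-wise mean of FC matrices in Fisher-z space.

    Edges missing in some runs average over the runs where they are present;
    edges missing everywhere stay missing.  ``n_runs_averaged`` accumulates.
    """
    if not matrices:
        raise ValueError("need at least one FC matrix")
    shapes = {m.values.shape for m in matrices}
    if len(shapes) > 1:
        raise ValueError(f"mixed FC dimensions: {shapes}")
    subjects = {m.subject_id for m in matrices}
    if len(subjects) > 1:
        raise ValueError("average_fc mixes subjects")
    stack = np.stack([m.values for m in matrices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices stay NaN
        mean = np.nanmean(stack, axis=0)
    np.fill_diagonal(mean, 0.0)
    flagged = tuple(sorted({i for m in matrices for i in m.flagged_regions}))
    return FCMatrix(
        mean,
        matrices[0].subject_id,
        matrices[0].condition,
        sum(m.n_runs_averaged for m in matrices),
        flagged,
    )


def condition_fc(runs: list[RunTimeSeries], cfg: PipelineConfig | None = None,
                 regress: bool = True, n_lags: int = 8) -> FCMatrix | None:
    """Convenience pipeline for one subject x condition: screen each run,
    regress nuisance and task structure, correlate, and average over the
    surviving runs.  Returns None when no run passes screening."""
    cfg = cfg or PipelineConfig()
    mats = []
    for run in runs:
        if not screen_run_motion(run, cfg).passed:
            continue
        if regress:
            run = nuisance_regress(run)
            if run.events:
                run = task_regress(run, n_lags=n_lags)
        mats.append(compute_fc(run, cfg))
    if not mats:
        return None
    return average_fc(mats)
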