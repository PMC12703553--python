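"""Synthetic cohort generator with planted effects.

Generates everything the analysis consumes — parcellation metadata,
per-run regional time series with confounds and motion traces, trial-level
behavior, and covariates — from a single seeded configuration, so every
downstream stage can be scored against known ground truth.

Time series are draws from a zero-mean Gaussian process whose correlation
matrix has 7-community block structure (one block per functional network):
white noise multiplied by the Cholesky factor of the target matrix.  No
hemodynamic model is used; the analysis consumes only second-order
structure.  Condition-specific offsets (``effect_edges``) shift designated
edges' correlations in designated conditions.  Brain-behavior coupling is
induced by a shared per-subject latent Gaussian: it adds a subject-specific
offset to each ``coupling_edge`` in the incompatible dual task and shifts
that subject's incompatible dual-task speed and accuracy, so the subject's
FC difference (incompatible - compatible) correlates with the behavioral
difference score at a controlled level.

Default rates and sizes mirror the dual-task modality-compatibility design
this package analyzes: 47 subjects, 200 regions, 139 frames per run, one
dual-task run per pairing plus eight runs per single task, 128 dual trials
per run, single-task error rates near 2.5% against dual-task error rates of
17% (compatible) and 34% (incompatible), with dual RT means near 752 and
869 ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import RunTimeSeries
from .io_config import (
    CONDITIONS,
    NETWORKS,
    CLUSTER_LABELS,
    CovariateTable,
    ParcelTable,
    PipelineConfig,
    SINGLE_TASKS,
    child_seed,
    read_matrix,
    write_covariates,
    write_matrix,
    write_parcel_table,
    write_trials,
)

log = logging.getLogger("fcx")


@dataclass(frozen=True)
class BehaviorParams:
    """Per-condition trial generation parameters: RT in ms (truncated normal,
    floor 150 ms), error rate as a proportion, trials per run."""

    rt_mean: float
    rt_sd: float
    error_rate: float
    n_trials: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error rate must be in [0, 1]")


#: Observed-scale defaults per condition (dual runs: 128 trials; single
#: blocks: 16 trials).
BEHAVIOR_DEFAULTS: dict[str, BehaviorParams] = {
    "VM": BehaviorParams(508.07, 241.14, 0.0275, 16),
    "AV": BehaviorParams(508.07, 241.14, 0.0275, 16),
    "VV": BehaviorParams(470.59, 170.65, 0.0247, 16),
    "AM": BehaviorParams(470.59, 170.65, 0.0247, 16),
    "dual-compatible": BehaviorParams(751.92, 193.98, 0.1723, 128),
    "dual-incompatible": BehaviorParams(868.59, 229.92, 0.3431, 128),
}

#: Added to the difficult single-task blocks (RT ms, error rate).
DIFFICULT_RT_SHIFT = 80.0
DIFFICULT_ERR_SHIFT = 0.03

RT_FLOOR = 150.0
OMISSION_SHARE = 0.2  # share of error trials that are omissions


@dataclass(frozen=True)
class MotionParams:
    """Framewise displacement model: per-subject median drawn log-normally
    around ``median_fd`` (mm), frames i.i.d. log-normal around the subject
    median.  Spikes are injected explicitly by callers testing screening."""

    median_fd: float = 0.08
    subject_log_sd: float = 0.25
    frame_log_sd: float = 0.4


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 47
    n_regions: int = 200
    n_timepoints: int = 139
    runs_per_condition: dict[str, int] = field(
        default_factory=lambda: {**{t: 8 for t in SINGLE_TASKS},
                                 "dual-compatible": 1, "dual-incompatible": 1}
    )
    base_within_network_r: float = 0.30
    base_between_network_r: float = 0.10
    #: (region_i, region_j, condition, delta_r): mean correlation offset.
    effect_edges: tuple[tuple[int, int, str, float], ...] = ()
    #: (region_i, region_j, coupling_r): subject-level FC-behavior coupling.
    coupling_edges: tuple[tuple[int, int, float], ...] = ()
    #: subject SD of the coupling edges' incompatible-dual offset (corr units)
    coupling_fc_sd: float = 0.15
    #: behavioral side of the latent: RT (ms) and error-rate shift per latent SD
    coupling_rt_sd: float = 60.0
    coupling_err_sd: float = 0.04
    behavior_params: dict[str, BehaviorParams] = field(
        default_factory=lambda: dict(BEHAVIOR_DEFAULTS)
    )
    motion_params: MotionParams = field(default_factory=MotionParams)
    #: weight with which the global-signal confound leaks into every region
    confound_leak: float = 0.0
    #: boxcar amplitude added to all regions during task events
    evoked_amplitude: float = 0.0
    network_assignment: ParcelTable | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.base_within_network_r, self.base_between_network_r):
            if not abs(r) < 1.0:
                raise ValueError("base correlations must satisfy |r| < 1")
        for i, j, cond, dr in self.effect_edges:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r} in effect_edges")
            base = (self.base_within_network_r
                    if _same_network(self.parcels, i, j) else self.base_between_network_r)
            if not abs(base + dr) < 1.0:
                raise ValueError(f"edge ({i},{j}): |base + delta_r| must be < 1")
        for _i, _j, r in self.coupling_edges:
            if not -1.0 < r < 1.0:
                raise ValueError("coupling_r must be in (-1, 1)")
        for cond in self.runs_per_condition:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r} in runs_per_condition")

    @property
    def parcels(self) -> ParcelTable:
        if self.network_assignment is not None:
            return self.network_assignment
        pt = make_parcel_table(self.n_regions)
        object.__setattr__(self, "network_assignment", pt)
        return pt


@dataclass
class SyntheticCohort:
    """All generated artifacts plus the ground truth needed to score
    recovery: the config, per-subject latents/behavioral shifts and the
    per-subject planted edge offsets."""

    config: SimulationConfig
    parcels: ParcelTable
    runs: dict[tuple[str, str, int], RunTimeSeries]
    trials: pd.DataFrame
    covariates: CovariateTable
    truth: dict

    def subject_ids(self) -> list[str]:
        return [_subject_id(i) for i in range(self.config.n_subjects)]


def make_parcel_table(n_regions: int, cluster_fraction: float = 0.25) -> ParcelTable:
    """Deterministic parcellation metadata: regions split as evenly as
    possible over the 7 networks (round-robin), hemispheres alternating, and
    the first ``cluster_fraction`` of each network's regions tagged with a
    task-activity cluster label (cycled over the 5 labels).

    The default coverage reflects strictly thresholded localizer activity
    restricted to the maximum-intensity cluster per contrast and hemisphere,
    which tags a minority of cortical regions; it is also the coverage at
    which the edge-selection procedure's planted-null calibration holds (see
    the package methods note).
    """
    if n_regions < 14:
        raise ValueError("need at least 14 regions (2 per network)")
    nets = [NETWORKS[i % len(NETWORKS)] for i in range(n_regions)]
    overlap: list[frozenset] = []
    per_net_count: dict[str, int] = {}
    per_net_total = {n: nets.count(n) for n in NETWORKS}
    k = 0
    for net in nets:
        seen = per_net_count.get(net, 0)
        per_net_count[net] = seen + 1
        if seen < round(cluster_fraction * per_net_total[net]):
            overlap.append(frozenset({CLUSTER_LABELS[k % len(CLUSTER_LABELS)]}))
            k += 1
        else:
            overlap.append(frozenset())
    frame = pd.DataFrame(
        {
            "region_id": np.arange(1, n_regions + 1),
            "region_label": [f"region_{i:03d}" for i in range(1, n_regions + 1)],
            "hemisphere": ["left" if i % 2 == 0 else "right" for i in range(n_regions)],
            "network": nets,
            "cluster_overlap": overlap,
        }
    )
    return ParcelTable(frame)


def _subject_id(i: int) -> str:
    return f"sub-{i + 1:03d}"


def _same_network(parcels: ParcelTable, i: int, j: int) -> bool:
    nets = parcels.networks
    return bool(nets[i] == nets[j])


def subject_latents(cfg: SimulationConfig, subject_index: int) -> tuple[float, float]:
    """The shared latent u (drives both FC and behavior) and the independent
    residual used to de-correlate the FC side down to coupling_r."""
    rng = np.random.default_rng(child_seed(cfg.seed, f"latent:{subject_index}"))
    u, e = rng.standard_normal(2)
    return float(u), float(e)


def planted_edge_offsets(cfg: SimulationConfig, subject_index: int) -> dict[tuple[int, int], float]:
    """Per-subject zero-mean offsets (correlation units) applied to the
    coupling edges in the incompatible dual task."""
    out = {}
    u, e = subject_latents(cfg, subject_index)
    for i, j, r in cfg.coupling_edges:
        a = r * u + np.sqrt(1.0 - r * r) * e
        out[(i, j)] = cfg.coupling_fc_sd * a
    return out


def nearest_pd_corr(c: np.ndarray, min_eig: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Eigenvalue clipping at ``min_eig`` followed by diagonal
    re-normalization; returns the repaired matrix and whether repair ran."""
    w, v = np.linalg.eigh(c)
    if w.min() >= min_eig:
        return c, False
    w = np.clip(w, min_eig, None)
    c2 = (v * w) @ v.T
    d = np.sqrt(np.diag(c2))
    c2 = c2 / np.outer(d, d)
    np.fill_diagonal(c2, 1.0)
    return c2, True


def target_correlation(cfg: SimulationConfig, subject_index: int, condition: str) -> np.ndarray:
    """Block-structured target correlation for one subject x condition."""
    parcels = cfg.parcels
    nets = parcels.networks
    same = nets[:, None] == nets[None, :]
    c = np.where(same, cfg.base_within_network_r, cfg.base_between_network_r).astype(float)
    np.fill_diagonal(c, 1.0)
    for i, j, cond, dr in cfg.effect_edges:
        if cond == condition:
            c[i, j] += dr
            c[j, i] += dr
    if condition == "dual-incompatible":
        for (i, j), offset in planted_edge_offsets(cfg, subject_index).items():
            c[i, j] += offset
            c[j, i] += offset
    np.clip(c, -0.999, 0.999, out=c)
    np.fill_diagonal(c, 1.0)
    c, repaired = nearest_pd_corr(c)
    if repaired:
        log.info("nearest-PD repair applied (subject %d, %s)", subject_index, condition)
    return c


def _default_events(condition: str, n_timepoints: int) -> list[tuple[str, int, int]]:
    # regular task blocks: 12-frame boxcars every 24 frames
    return [(condition, onset, 12) for onset in range(4, n_timepoints - 12, 24)]


def simulate_timeseries(
    cfg: SimulationConfig, subject_index: int, condition: str, run_index: int
) -> RunTimeSeries:
    """One run's regions x timepoints draw plus confounds and motion trace.

    Deterministic given (config seed, subject, condition, run): per-run
    randomness is derived by stage-name hashing so any run can be
    regenerated independently.
    """
    rng = np.random.default_rng(
        child_seed(cfg.seed, f"ts:{subject_index}:{condition}:{run_index}")
    )
    R, T = cfg.n_regions, cfg.n_timepoints
    c = target_correlation(cfg, subject_index, condition)
    try:
        L = np.linalg.cholesky(c)
    except np.linalg.LinAlgError as e:
        raise ValueError("target correlation not positive definite after repair") from e
    data = L @ rng.standard_normal((R, T))

    # confounds
    mrng = np.random.default_rng(child_seed(cfg.seed, f"motion:{subject_index}"))
    subj_median = cfg.motion_params.median_fd * np.exp(
        cfg.motion_params.subject_log_sd * mrng.standard_normal()
    )
    fd = np.exp(np.log(subj_median) + cfg.motion_params.frame_log_sd * rng.standard_normal(T))
    fd[0] = 0.0
    motion = np.cumsum(rng.normal(0.0, 0.01, size=(T, 6)), axis=0)
    confounds = pd.DataFrame(
        {
            "global_signal": rng.standard_normal(T),
            "csf": rng.standard_normal(T),
            "white_matter": rng.standard_normal(T),
            "trans_x": motion[:, 0],
            "trans_y": motion[:, 1],
            "trans_z": motion[:, 2],
            "rot_x": motion[:, 3],
            "rot_y": motion[:, 4],
            "rot_z": motion[:, 5],
            "framewise_displacement": fd,
        }
    )
    if cfg.confound_leak != 0.0:
        data = data + cfg.confound_leak * confounds["global_signal"].to_numpy()[None, :]
    events = _default_events(condition, T)
    if cfg.evoked_amplitude != 0.0:
        box = np.zeros(T)
        for _lab, onset, dur in events:
            box[onset:onset + dur] = cfg.evoked_amplitude
        data = data + box[None, :]
    return RunTimeSeries(
        data=data,
        confounds=confounds,
        events=events,
        subject_id=_subject_id(subject_index),
        condition=condition,
        run_id=f"run-{run_index + 1:02d}",
    )


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------


def _draw_trials(rng, params: BehaviorParams, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RTs (NaN on omission), correctness, omission flags for n trials."""
    a = (RT_FLOOR - params.rt_mean) / params.rt_sd
    rt = stats.truncnorm.rvs(a, np.inf, loc=params.rt_mean, scale=params.rt_sd,
                             size=n, random_state=rng)
    correct = rng.random(n) >= params.error_rate
    omitted = (~correct) & (rng.random(n) < OMISSION_SHARE)
    rt = np.where(omitted, np.nan, rt)
    return rt, correct, omitted


def _subject_behavior_params(cfg: SimulationConfig, subject_index: int,
                             condition: str) -> BehaviorParams:
    """Condition parameters with the latent-coupled shift applied to the
    incompatible dual task (higher latent -> faster and more accurate)."""
    params = cfg.behavior_params[condition]
    if condition == "dual-incompatible" and cfg.coupling_edges:
        u, _ = subject_latents(cfg, subject_index)
        return BehaviorParams(
            rt_mean=max(params.rt_mean - cfg.coupling_rt_sd * u, RT_FLOOR + 50.0),
            rt_sd=params.rt_sd,
            error_rate=float(np.clip(params.error_rate - cfg.coupling_err_sd * u,
                                     0.005, 0.995)),
            n_trials=params.n_trials,
        )
    return params


def simulate_behavior(cfg: SimulationConfig) -> pd.DataFrame:
    """Trial table for the whole cohort.

    Single-task runs contain an easy and a difficult block per run (the
    difficult block is slower and more error-prone and is excluded from BIS
    scoring downstream); dual-task runs contain 16-trial blocks with random
    congruency.  All error trials have a 20% chance of being omissions
    (missing RT, no response modality).
    """
    for task in SINGLE_TASKS + ("dual-compatible", "dual-incompatible"):
        if task not in cfg.behavior_params:
            raise ValueError(f"behavior_params missing condition {task!r}")
    rng = np.random.default_rng(child_seed(cfg.seed, "behavior"))
    from .behavior import EXPECTED_MODALITY

    rows = []
    for s in range(cfg.n_subjects):
        sid = _subject_id(s)
        for task in SINGLE_TASKS:
            pairing = "compatible" if task in ("VM", "AV") else "incompatible"
            for run_idx in range(cfg.runs_per_condition.get(task, 0)):
                for b, difficulty in enumerate(("easy", "difficult")):
                    params = cfg.behavior_params[task]
                    if difficulty == "difficult":
                        params = BehaviorParams(
                            params.rt_mean + DIFFICULT_RT_SHIFT, params.rt_sd,
                            min(params.error_rate + DIFFICULT_ERR_SHIFT, 1.0),
                            params.n_trials,
                        )
                    rt, correct, omitted = _draw_trials(rng, params, params.n_trials)
                    for k in range(params.n_trials):
                        rows.append((
                            sid, f"single-{task}-{run_idx + 1:02d}", b, "single",
                            pairing, task, "",
                            "none" if omitted[k] else EXPECTED_MODALITY[task],
                            rt[k], bool(correct[k]), difficulty,
                        ))
        for cond, pairing in (("dual-compatible", "compatible"),
                              ("dual-incompatible", "incompatible")):
            for run_idx in range(cfg.runs_per_condition.get(cond, 0)):
                params = _subject_behavior_params(cfg, s, cond)
                rt, correct, omitted = _draw_trials(rng, params, params.n_trials)
                congruency = rng.choice(["congruent", "incongruent"], size=params.n_trials)
                for k in range(params.n_trials):
                    rows.append((
                        sid, f"dual-{pairing}-{run_idx + 1:02d}", k // 16, "dual",
                        pairing, "+".join(
                            ("VM", "AV") if pairing == "compatible" else ("VV", "AM")),
                        congruency[k], "none" if omitted[k] else "both",
                        rt[k], bool(correct[k]), "",
                    ))
    trials = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "run_id", "block_id", "task_type", "pairing",
            "component_task", "congruency", "response_modality_used", "rt",
            "correct", "difficulty",
        ],
    )
    return trials


# ---------------------------------------------------------------------------
# Cohort assembly and I/O
# ---------------------------------------------------------------------------


def generate_cohort(cfg: SimulationConfig,
                    screening_cfg: PipelineConfig | None = None) -> SyntheticCohort:
    """Generate runs, trials, covariates and the ground-truth record."""
    screening_cfg = screening_cfg or PipelineConfig()
    from .connectivity import screen_run_motion

    parcels = cfg.parcels
    runs: dict[tuple[str, str, int], RunTimeSeries] = {}
    mean_fds: dict[str, list[float]] = {}
    valid_single: dict[str, int] = {}
    for s in range(cfg.n_subjects):
        sid = _subject_id(s)
        mean_fds[sid] = []
        valid_single[sid] = 0
        for cond, n_runs in cfg.runs_per_condition.items():
            for r in range(n_runs):
                run = simulate_timeseries(cfg, s, cond, r)
                runs[(sid, cond, r)] = run
                summary = screen_run_motion(run, screening_cfg)
                if cond in ("dual-compatible", "dual-incompatible"):
                    mean_fds[sid].append(summary.mean_fd)
                elif summary.passed:
                    valid_single[sid] += 1

    trials = simulate_behavior(cfg)

    crng = np.random.default_rng(child_seed(cfg.seed, "covariates"))
    subjects = [_subject_id(s) for s in range(cfg.n_subjects)]
    covariates = CovariateTable(pd.DataFrame({
        "subject_id": subjects,
        "age": np.round(crng.normal(22.4, 2.8, cfg.n_subjects), 1),
        "gender": crng.integers(0, 2, cfg.n_subjects),
        "mean_fd": [float(np.mean(mean_fds[sid])) if mean_fds[sid] else np.nan
                    for sid in subjects],
        "n_valid_single_runs": [valid_single[sid] for sid in subjects],
    }))

    truth_subjects = pd.DataFrame({
        "subject_id": subjects,
        "latent": [subject_latents(cfg, s)[0] for s in range(cfg.n_subjects)],
    })
    truth_edges = []
    for i, j, cond, dr in cfg.effect_edges:
        truth_edges.append({"region_i": i, "region_j": j, "kind": "effect",
                            "condition": cond, "value": dr})
    for i, j, r in cfg.coupling_edges:
        truth_edges.append({"region_i": i, "region_j": j, "kind": "coupling",
                            "condition": "dual-incompatible", "value": r})
    planted = {
        sid: planted_edge_offsets(cfg, s) for s, sid in enumerate(subjects)
    }
    truth = {
        "config": cfg,
        "subjects": truth_subjects,
        "edges": pd.DataFrame(truth_edges,
                              columns=["region_i", "region_j", "kind", "condition", "value"]),
        "planted_offsets": planted,
    }
    return SyntheticCohort(cfg, parcels, runs, trials, covariates, truth)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> pd.DataFrame:
    """Write the cohort in the directory layout the I/O module reads back;
    the ground truth goes to a separate ``truth/`` subdirectory.  Returns a
    manifest of the files written."""
    out = Path(out_dir)
    (out / "runs").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    files = []
    write_parcel_table(cohort.parcels, out / "parcels.tsv")
    files.append("parcels.tsv")
    write_covariates(cohort.covariates, out / "covariates.tsv")
    files.append("covariates.tsv")
    write_trials(cohort.trials, out / "trials.tsv")
    files.append("trials.tsv")
    for (sid, cond, r), run in sorted(cohort.runs.items()):
        stem = f"{sid}_{cond}_run-{r + 1:02d}"
        write_matrix(run.data, out / "runs" / f"{stem}_ts.tsv")
        run.confounds.to_csv(out / "runs" / f"{stem}_confounds.tsv", sep="\t",
                             index=False, float_format="%.17g")
        pd.DataFrame(run.events, columns=["label", "onset_frame", "duration_frames"]
                     ).to_csv(out / "runs" / f"{stem}_events.tsv", sep="\t", index=False)
        files += [f"runs/{stem}_ts.tsv", f"runs/{stem}_confounds.tsv",
                  f"runs/{stem}_events.tsv"]
    cohort.truth["subjects"].to_csv(out / "truth" / "truth_subjects.tsv", sep="\t",
                                    index=False, float_format="%.17g")
    cohort.truth["edges"].to_csv(out / "truth" / "truth_edges.tsv", sep="\t", index=False)
    files += ["truth/truth_subjects.tsv", "truth/truth_edges.tsv"]
    manifest = pd.DataFrame({"file": files})
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


def read_cohort_runs(data_dir: str | Path) -> dict[tuple[str, str, int], RunTimeSeries]:
    """Read back the runs written by :func:`write_cohort`."""
    out = {}
    runs_dir = Path(data_dir) / "runs"
    for ts_path in sorted(runs_dir.glob("*_ts.tsv")):
        stem = ts_path.name[: -len("_ts.tsv")]
        sid, cond, run_id = stem.split("_")
        data = read_matrix(ts_path)
        confounds = pd.read_csv(runs_dir / f"{stem}_confounds.tsv", sep="\t")
        ev = pd.read_csv(runs_dir / f"{stem}_events.tsv", sep="\t")
        events = [(str(a), int(b), int(c)) for a, b, c in ev.itertuples(index=False)]
        run_index = int(run_id.split("-")[1]) - 1
        out[(sid, cond, run_index)] = RunTimeSeries(
            data=data, confounds=confounds, events=events,
            subject_id=sid, condition=cond, run_id=run_id,
        )
    return out
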