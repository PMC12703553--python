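"""Trial/run exclusion rules, balanced integration scoring, and the
behavioral modality-compatibility contrast.

The balanced integration score (BIS) combines speed and accuracy into one
performance measure: z-standardized accuracy minus z-standardized mean RT,
where the standardization pool is the full set of subject x task-type x
pairing cells.  Higher BIS = better performance.  The dual-task cost of a
pairing is BIS(single) - BIS(dual), so larger values mean a larger cost;
the modality-compatibility effect is the cost difference between the
incompatible (visual-vocal + auditory-manual) and compatible (visual-manual
+ auditory-vocal) pairings.

Exclusion rules operate per run: wrong response modality in a block for more
than five trials; more than 30% errors (omissions included) in single-task
or localizer runs; for dual-task runs the 30% rule is applied to congruent
trials only (both stimuli mapped to the same response side), by default
averaged across the subject's two dual runs.  A participant is excluded when
one dual-task run, more than one localizer run, or more than three
single-task runs are invalid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import DEFAULT_BF_SCALE, TestResult, paired_ttest
from .io_config import PAIRING_COMPONENTS, PipelineConfig, TRIAL_COLUMNS

log = logging.getLogger("fcx")

#: Expected response modality per single component task.
EXPECTED_MODALITY = {"VM": "manual", "AV": "vocal", "VV": "vocal", "AM": "manual"}


@dataclass
class BISResult:
    """``cells``: one row per subject x task_type x pairing with mean RT (ms),
    accuracy and BIS; ``costs``: one row per subject x pairing with the
    dual-task cost (NaN when either cell did not survive exclusion)."""

    cells: pd.DataFrame
    costs: pd.DataFrame


def _run_category(sub: pd.DataFrame) -> str:
    """A run with both single and dual trials is a localizer run."""
    if "run_type" in sub.columns and sub["run_type"].notna().all():
        return str(sub["run_type"].iloc[0])
    kinds = set(sub["task_type"])
    if kinds == {"single", "dual"}:
        return "localizer"
    return "dual" if kinds == {"dual"} else "single"


def apply_exclusion_criteria(
    trials: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    congruent_scope: str = "across-runs",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag invalid runs and excluded participants; return the retained
    trials and a report with one row per run and rule hit.

    ``congruent_scope`` controls the dual-task 30% criterion: whether the
    congruent-trial error rate is averaged across the subject's dual runs
    (``"across-runs"``, the default) or evaluated within each run
    (``"within-run"``).
    """
    cfg = cfg or PipelineConfig()
    if congruent_scope not in ("across-runs", "within-run"):
        raise ValueError("congruent_scope must be 'across-runs' or 'within-run'")
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")

    records = []
    run_info: dict[tuple, dict] = {}
    for (sid, rid), sub in trials.groupby(["subject_id", "run_id"], sort=True):
        category = _run_category(sub)
        rules: list[str] = []
        # wrong response modality, per single-task block
        single = sub[sub["task_type"] == "single"]
        for bid, block in single.groupby("block_id"):
            task = block["component_task"].iloc[0]
            expected = EXPECTED_MODALITY.get(task)
            wrong = (~block["response_modality_used"].isin([expected, "none"])).sum()
            if wrong > 5:
                rules.append(f"wrong_modality_block_{bid}")
        # 30% errors incl. omissions (single and localizer runs; all trials)
        if category in ("single", "localizer"):
            err = (~sub["correct"]).mean()
            if err > 0.30:
                rules.append("error_rate")
        if category == "dual" and congruent_scope == "within-run":
            cong = sub[sub["congruency"] == "congruent"]
            if len(cong) and (~cong["correct"]).mean() > 0.30:
                rules.append("dual_congruent_errors")
        run_info[(sid, rid)] = {"category": category, "rules": rules}

    if congruent_scope == "across-runs":
        dual = trials[trials["task_type"] == "dual"]
        for sid, sub in dual.groupby("subject_id"):
            dual_runs = [
                rid for (s, rid), info in run_info.items()
                if s == sid and info["category"] == "dual"
            ]
            rates = []
            for rid in dual_runs:
                cong = sub[(sub["run_id"] == rid) & (sub["congruency"] == "congruent")]
                if len(cong):
                    rates.append((~cong["correct"]).mean())
            if rates and float(np.mean(rates)) > 0.30:
                for rid in dual_runs:
                    run_info[(sid, rid)]["rules"].append("dual_congruent_errors")

    # participant-level exclusion
    excluded_subjects = set()
    for sid in pd.unique(trials["subject_id"]):
        counts = {"single": 0, "dual": 0, "localizer": 0}
        for (s, _rid), info in run_info.items():
            if s == sid and info["rules"]:
                counts[info["category"]] += 1
        if counts["dual"] >= 1 or counts["localizer"] > 1 or counts["single"] > 3:
            excluded_subjects.add(sid)

    for (sid, rid), info in run_info.items():
        records.append(
            {
                "subject_id": sid,
                "run_id": rid,
                "category": info["category"],
                "valid": not info["rules"],
                "rules": ";".join(info["rules"]),
                "subject_excluded": sid in excluded_subjects,
            }
        )
    report = pd.DataFrame.from_records(records)

    valid_runs = {
        (sid, rid) for (sid, rid), info in run_info.items()
        if not info["rules"] and sid not in excluded_subjects
    }
    keep = trials.apply(
        lambda row: (row["subject_id"], row["run_id"]) in valid_runs, axis=1
    ) if len(trials) else pd.Series(dtype=bool)
    retained = trials[keep].reset_index(drop=True)
    log.info(
        "exclusion: %d/%d runs valid, %d subject(s) excluded",
        len(valid_runs), len(run_info), len(excluded_subjects),
    )
    return retained, report


def _z(values: np.ndarray) -> np.ndarray:
    """Sample z-scores over the pooled cells; a zero-variance pool maps to
    all-zero scores rather than dividing by zero."""
    v = np.asarray(values, dtype=float)
    sd = np.nanstd(v, ddof=1)
    if not np.isfinite(sd) or sd == 0.0:
        log.info("zero-variance standardization pool; z-scores set to 0")
        return np.zeros_like(v)
    return (v - np.nanmean(v)) / sd


def compute_bis(trials: pd.DataFrame) -> BISResult:
    """Balanced integration scores per subject x task_type x pairing, and
    dual-task costs per subject x pairing.

    Only correct trials with an observed RT contribute to mean RT; accuracy
    counts omissions as errors.  Single-task input is restricted to easy
    blocks, and each pairing's single-task cell averages its two component
    tasks.  z-standardization pools all cells jointly (separately for RT and
    accuracy).
    """
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        for pairing in ("compatible", "incompatible"):
            # dual cell
            dual = sub[(sub["task_type"] == "dual") & (sub["pairing"] == pairing)]
            rows.append(_cell_row(sid, "dual", pairing, [dual]))
            # single cell: average of the two component tasks, easy blocks only
            comps = []
            for task in PAIRING_COMPONENTS[pairing]:
                comp = sub[
                    (sub["task_type"] == "single")
                    & (sub["component_task"] == task)
                    & (sub["difficulty"] == "easy")
                ]
                comps.append(comp)
            rows.append(_cell_row(sid, "single", pairing, comps))
    cells = pd.DataFrame.from_records(rows)
    cells["z_rt"] = _z(cells["mean_rt"])
    cells["z_acc"] = _z(cells["accuracy"])
    cells["bis"] = cells["z_acc"] - cells["z_rt"]
    cells.loc[~np.isfinite(cells["mean_rt"]), "bis"] = np.nan

    cost_rows = []
    for (sid, pairing), sub in cells.groupby(["subject_id", "pairing"], sort=True):
        pivot = sub.set_index("task_type")["bis"]
        cost = np.nan
        if {"single", "dual"} <= set(pivot.index):
            cost = pivot["single"] - pivot["dual"]
        if not np.isfinite(cost):
            log.info("cost undefined for subject %s pairing %s", sid, pairing)
        cost_rows.append({"subject_id": sid, "pairing": pairing, "cost": cost})
    return BISResult(cells, pd.DataFrame.from_records(cost_rows))


def _cell_row(sid, task_type: str, pairing: str, parts: list[pd.DataFrame]) -> dict:
    """Aggregate one or two trial subsets into a cell (components averaged)."""
    rts, accs = [], []
    for part in parts:
        if len(part) == 0:
            continue
        correct_rt = part.loc[part["correct"] & part["rt"].notna(), "rt"]
        rts.append(correct_rt.mean() if len(correct_rt) else np.nan)
        accs.append(part["correct"].mean())
    mean_rt = float(np.mean(rts)) if rts else np.nan
    acc = float(np.mean(accs)) if accs else np.nan
    return {
        "subject_id": sid,
        "task_type": task_type,
        "pairing": pairing,
        "mean_rt": mean_rt,
        "accuracy": acc,
    }


def behavioral_contrast(bis: BISResult, bf_scale: float = DEFAULT_BF_SCALE) -> TestResult:
    """Paired contrast of dual-task costs between modality pairings
    (incompatible minus compatible), with the matching JZS Bayes factor.

    A positive estimate means larger costs for the incompatible pairing.
    """
    wide = bis.costs.pivot(index="subject_id", columns="pairing", values="cost").dropna()
    if len(wide) < 3:
        raise ValueError("need >= 3 subjects with both pairing costs defined")
    return paired_ttest(wide["incompatible"], wide["compatible"], bf_scale)
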