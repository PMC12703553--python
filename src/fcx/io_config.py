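"""Typed I/O for the tabular artifacts shared across the pipeline.

Every other module consumes only the objects defined here: the parcellation
metadata (:class:`ParcelTable`), the run-wide thresholds and seeds
(:class:`PipelineConfig`), and the per-subject covariates
(:class:`CovariateTable`).  All tables are tab-separated text with a header
row; numeric matrices are headerless delimited text written at 17 significant
digits so that a write/read cycle is bit-identical for float64.

Region ids are 1-based in files and converted to 0-based indices at this
boundary only; no other module ever sees a 1-based index.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

log = logging.getLogger("fcx")

#: The seven canonical resting-state networks regions are assigned to.
NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal-attention",
    "ventral-attention",
    "limbic",
    "control",
    "default",
)

#: Task-activity cluster labels a region may overlap with (localizer-derived).
CLUSTER_LABELS = ("visual", "auditory", "manual", "vocal", "dual-frontal")

#: Task conditions: four single tasks (stimulus-response modality pairs) and
#: the two dual-task modality pairings.
CONDITIONS = ("VM", "AV", "VV", "AM", "dual-compatible", "dual-incompatible")
SINGLE_TASKS = ("VM", "AV", "VV", "AM")
#: Component single tasks of each modality pairing.
PAIRING_COMPONENTS = {"compatible": ("VM", "AV"), "incompatible": ("VV", "AM")}


class FormatError(ValueError):
    """A file violated the expected schema."""


# ---------------------------------------------------------------------------
# ParcelTable
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParcelTable:
    """Region metadata: label, hemisphere, network membership and the set of
    localizer task-activity clusters the region overlaps with.

    ``frame`` has one row per region in region-id order with columns
    ``region_id`` (1-based, contiguous), ``region_label``, ``hemisphere``,
    ``network`` and ``cluster_overlap`` (a frozenset, possibly empty).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"region_id", "region_label", "hemisphere", "network", "cluster_overlap"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"parcel table missing columns: {sorted(missing)}")
        rid = self.frame["region_id"].to_numpy()
        if len(rid) != len(set(rid)):
            raise FormatError("duplicate region_id in parcel table")
        if not np.array_equal(np.sort(rid), np.arange(1, len(rid) + 1)):
            raise FormatError("region_ids must be contiguous 1..R")
        bad = set(self.frame["network"]) - set(NETWORKS)
        if bad:
            raise FormatError(f"unknown network labels: {sorted(bad)}")
        bad_hemi = set(self.frame["hemisphere"]) - {"left", "right"}
        if bad_hemi:
            raise FormatError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        for s in self.frame["cluster_overlap"]:
            bad = set(s) - set(CLUSTER_LABELS)
            if bad:
                raise FormatError(f"unknown cluster labels: {sorted(bad)}")
        # canonical region-id order
        object.__setattr__(
            self, "frame", self.frame.sort_values("region_id").reset_index(drop=True)
        )

    @property
    def n_regions(self) -> int:
        return len(self.frame)

    @property
    def networks(self) -> np.ndarray:
        """Network label per region, 0-based region order."""
        return self.frame["network"].to_numpy()

    @property
    def has_cluster_overlap(self) -> np.ndarray:
        """Boolean per region: does it overlap any task-activity cluster?"""
        return np.array([len(s) > 0 for s in self.frame["cluster_overlap"]])

    @property
    def labels(self) -> np.ndarray:
        return self.frame["region_label"].to_numpy()


def read_parcel_table(path: str | Path) -> ParcelTable:
    """Read a tab-separated parcellation table.

    The ``cluster_overlap`` column holds comma-separated cluster labels or is
    empty.  Unknown network labels and duplicate region ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "region_id" not in df.columns:
        raise FormatError(f"{path}: no region_id column")
    try:
        df["region_id"] = df["region_id"].astype(int)
    except ValueError as e:
        raise FormatError(f"{path}: non-integer region_id") from e
    df["cluster_overlap"] = [
        frozenset(x.split(",")) if x else frozenset() for x in df["cluster_overlap"]
    ]
    pt = ParcelTable(df)
    log.info("read parcel table %s: R=%d", path, pt.n_regions)
    return pt


def write_parcel_table(parcels: ParcelTable, path: str | Path) -> None:
    df = parcels.frame.copy()
    df["cluster_overlap"] = [",".join(sorted(s)) for s in df["cluster_overlap"]]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PipelineConfig
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Run-wide thresholds, counts and seeds.

    Motion screening: a run enters the analysis only if mean framewise
    displacement (FD) is below ``fd_mean_threshold`` (mm), the fraction of
    frames with FD above ``spike_fd_threshold`` is below
    ``spike_fraction_max``, and no frame exceeds ``spike_hard_max``.

    Edge selection keeps edges whose one-sample Bayes factor exceeds
    ``bf_edge_threshold`` (strictly); the permutation null uses
    ``n_permutations`` draws and the ``percentile_bounds`` band.
    """

    fd_mean_threshold: float = 0.2
    spike_fd_threshold: float = 0.25
    spike_fraction_max: float = 0.20
    spike_hard_max: float = 5.0
    bf_edge_threshold: float = 3.0
    n_permutations: int = 10_000
    percentile_bounds: tuple[float, float] = (0.05, 0.95)
    alpha_behavior: float = 0.05
    rng_seed: int = 0
    fisher_clip: float = 1.0 - 1e-7

    def __post_init__(self) -> None:
        for name in (
            "fd_mean_threshold",
            "spike_fd_threshold",
            "spike_fraction_max",
            "spike_hard_max",
            "bf_edge_threshold",
            "alpha_behavior",
            "fisher_clip",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_permutations <= 0:
            raise ValueError("n_permutations must be strictly positive")
        lo, hi = self.percentile_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("percentile_bounds must be ordered and within (0,1)")


_TUPLE_KEYS = {"percentile_bounds"}
_INT_KEYS = {"n_permutations", "rng_seed"}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a ``key=value`` config file; missing keys take the defaults.

    Blank lines and ``#`` comments are ignored.  Values are validated by the
    :class:`PipelineConfig` constructor; the resulting config is echoed to the
    log.
    """
    known = {f.name for f in fields(PipelineConfig)}
    kwargs: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in known:
            raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
        try:
            if key in _TUPLE_KEYS:
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif key in _INT_KEYS:
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: unparseable value {value!r}") from e
    cfg = PipelineConfig(**kwargs)
    log.info("config: %s", cfg)
    return cfg


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    lines = []
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, tuple):
            v = ",".join(repr(x) for x in v)
        lines.append(f"{f.name}={v}")
    Path(path).write_text("\n".join(lines) + "\n")


def child_seed(seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed from the global seed.

    Hashes ``"{seed}:{stage}"`` so stages can be re-run independently with
    identical randomness; the result is always below 2**31.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# CovariateTable
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateTable:
    """One row per subject: age (years), gender (pre-coded 0/1), mean FD (mm)
    and the number of valid single-task runs."""

    frame: pd.DataFrame

    REQUIRED = ("subject_id", "age", "gender", "mean_fd", "n_valid_single_runs")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.frame.columns)
        if missing:
            raise FormatError(f"covariate table missing columns: {sorted(missing)}")
        sid = self.frame["subject_id"]
        if sid.duplicated().any():
            raise FormatError("duplicate subject_id in covariate table")
        object.__setattr__(self, "frame", self.frame.reset_index(drop=True))

    def for_subjects(self, subjects: Iterable) -> pd.DataFrame:
        """Rows for the given subjects, in the given order; missing values
        among requested subjects are an error."""
        df = self.frame.set_index("subject_id").loc[list(subjects)].reset_index()
        if df[list(self.REQUIRED)].isna().any().any():
            raise ValueError("missing covariate values for requested subjects")
        return df


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t")
    return CovariateTable(df)


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    cov.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a headerless delimited numeric matrix (whitespace/tab separated).

    Ragged rows and non-numeric cells raise :class:`FormatError`.
    """
    try:
        m = np.loadtxt(path, ndmin=2)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e
    log.info("read matrix %s: shape=%s", path, m.shape)
    return m


def write_matrix(m: np.ndarray, path: str | Path) -> None:
    """Write a matrix at 17 significant digits (lossless for float64)."""
    np.savetxt(path, np.asarray(m, dtype=float), fmt="%.17g", delimiter="\t")


# ---------------------------------------------------------------------------
# Trial tables (schema shared with the behavior module)
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = (
    "subject_id",
    "run_id",
    "block_id",
    "task_type",
    "pairing",
    "component_task",
    "congruency",
    "response_modality_used",
    "rt",
    "correct",
    "difficulty",
)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"trial table missing columns: {sorted(missing)}")
    df["correct"] = df["correct"].astype(bool)
    return df


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, sep="\t", index=False)
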