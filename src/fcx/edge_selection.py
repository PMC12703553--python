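"""Edge-level brain-behavior selection with leave-one-out stability.

The procedure relates the per-subject dual-task FC difference (incompatible
minus compatible, Fisher-z) to the behavioral modality-compatibility effect
(the dual-task BIS difference), edge by edge:

1.  Build the subjects x edges difference panel.
2.  Keep edges whose difference is credibly nonzero: one-sample JZS Bayes
    factor strictly above 3 ("moderate evidence").
3.  Keep edges whose BOTH endpoint regions overlap a localizer task-activity
    cluster.
4.  Partial Spearman correlation (controlling age, gender, mean FD) between
    each surviving edge and the behavioral difference; screen at uncorrected
    p < alpha (deliberately lenient, as brain-behavior correlations are
    small).
5.  Leave-one-out stability: re-apply the filters and recompute the partial
    correlation N times, leaving out one subject each time; build a per-edge
    permutation null (drop one random subject, permute behavior, correlate)
    and select only edges for which every fold's rho falls below the null
    5th percentile or above the 95th.

The permutation null recomputes rho only (not the filters), and its
candidate universe is the full-sample surviving set, matching the order of
operations of the screening pipeline.  Null percentiles use the linear
(type-7) empirical quantile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import FCMatrix
from .inference import DEFAULT_BF_SCALE, jzs_bf_vec
from .io_config import ParcelTable, PipelineConfig, child_seed

log = logging.getLogger("fcx")


@dataclass
class EdgeDifferencePanel:
    """Subjects x edges matrix of Fisher-z FC differences
    (incompatible - compatible), columns in fixed lexicographic (i, j)
    order over the upper triangle."""

    data: np.ndarray
    subjects: tuple[str, ...]
    edge_index: np.ndarray  # (n_edges, 2) int array of (i, j), i < j

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_edges(self) -> int:
        return self.data.shape[1]


@dataclass
class BehaviorVector:
    """Per-subject behavioral difference score with covariates, row-aligned
    to an :class:`EdgeDifferencePanel`."""

    subjects: tuple[str, ...]
    scores: np.ndarray
    covariates: np.ndarray  # (n, k)
    covariate_names: tuple[str, ...] = ("age", "gender", "mean_fd")

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.scores.size:
            raise ValueError("covariate rows must match score length")


@dataclass
class EdgeSelectionResult:
    """Candidate edges (post BF + cluster filters + p screen) with their
    full-sample statistics, fold-wise rho traces, null bands and the final
    stability-selection verdict."""

    edge_index: np.ndarray          # (m, 2) candidate edges
    bf10: np.ndarray                # full-sample BF per candidate
    partial_rho: np.ndarray
    p_uncorrected: np.ndarray
    loo_rhos: np.ndarray            # (n_folds, m)
    fold_bf_pass: np.ndarray        # (n_folds, m) bool
    null_percentiles: np.ndarray    # (m, 2): lower, upper
    selected: np.ndarray            # (m,) bool
    n_subjects: int
    n_permutations: int
    n_candidates_prescreen: int = 0


def build_difference_panel(
    fc_pairs: dict[str, tuple[FCMatrix, FCMatrix]]
) -> EdgeDifferencePanel:
    """Subjects x edges panel of (incompatible - compatible) differences.

    ``fc_pairs`` maps subject id to its (incompatible, compatible) dual-task
    FC matrices; subjects missing a condition matrix (None) are dropped with
    a log entry.  Missing edges propagate as NaN.
    """
    subjects, rows = [], []
    edge_index = None
    for sid in sorted(fc_pairs):
        incompat, compat = fc_pairs[sid]
        if incompat is None or compat is None:
            log.info("subject %s missing a dual condition; dropped from panel", sid)
            continue
        if incompat.n_regions != compat.n_regions:
            raise ValueError(f"subject {sid}: condition FCs differ in size")
        r = incompat.n_regions
        if edge_index is None:
            ii, jj = np.triu_indices(r, k=1)
            edge_index = np.column_stack([ii, jj])
        diff = incompat.values - compat.values
        rows.append(diff[edge_index[:, 0], edge_index[:, 1]])
        subjects.append(sid)
    if not rows:
        raise ValueError("no subject has both dual-task conditions")
    return EdgeDifferencePanel(np.vstack(rows), tuple(subjects), edge_index)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def _column_t(data: np.ndarray) -> np.ndarray:
    """One-sample t statistic per column (vs zero); zero-variance columns
    get t=0 when their mean is 0 and +/-inf otherwise."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    return t


def edge_bayes_factors(data: np.ndarray, bf_scale: float = DEFAULT_BF_SCALE) -> np.ndarray:
    """One-sample JZS BF10 per edge column of a difference panel."""
    t = _column_t(data)
    bf = np.empty_like(t)
    finite = np.isfinite(t)
    bf[finite] = jzs_bf_vec(t[finite], data.shape[0], bf_scale)
    bf[~finite] = np.inf
    return bf


def bf_filter(panel: EdgeDifferencePanel, cfg: PipelineConfig | None = None,
              bf10: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask of edges with BF10 strictly above the threshold."""
    cfg = cfg or PipelineConfig()
    if panel.n_subjects < 3:
        raise ValueError("need >= 3 subjects for the Bayes factor filter")
    if bf10 is None:
        bf10 = edge_bayes_factors(panel.data)
    return bf10 > cfg.bf_edge_threshold


def cluster_overlap_filter(edge_index: np.ndarray, parcels: ParcelTable) -> np.ndarray:
    """Boolean mask of edges whose both endpoints overlap a task-activity
    cluster."""
    has = parcels.has_cluster_overlap
    return has[edge_index[:, 0]] & has[edge_index[:, 1]]


# ---------------------------------------------------------------------------
# Partial Spearman correlation
# ---------------------------------------------------------------------------


def _rank(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return stats.rankdata(a, axis=axis)


def _residual_projector(covariates_ranked: np.ndarray) -> np.ndarray:
    """Orthonormal basis Q of [1 | ranked covariates]; residualization is
    x - Q (Q^T x)."""
    n = covariates_ranked.shape[0]
    z = np.column_stack([np.ones(n), covariates_ranked])
    q, r = np.linalg.qr(z)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def partial_spearman(x, y, covariates) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given covariates.

    Ranks all inputs (average ranks on ties), residualizes the ranked x and
    y on the ranked covariates plus an intercept by least squares, and
    returns the Pearson correlation of the residuals with a t-approximation
    p value at df = n - 2 - n_covariates.  Constant covariates reduce this
    to the plain Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != x.size:
        cov = cov.T
    n = x.size
    k = cov.shape[1]
    if n < k + 3:
        raise ValueError("need n >= n_covariates + 3")
    rho, p = _partial_spearman_block(x[:, None], y, cov)
    return float(rho[0]), float(p[0])


def _partial_spearman_block(X: np.ndarray, y: np.ndarray,
                            cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized partial Spearman of each column of X against y."""
    n, k = cov.shape
    q = _residual_projector(_rank(cov))
    rx = _rank(X)
    ry = _rank(y)
    ex = rx - q @ (q.T @ rx)
    ey = ry - q @ (q.T @ ry)
    ex_sd = np.sqrt((ex * ex).sum(axis=0))
    ey_sd = np.sqrt((ey * ey).sum())
    if ey_sd == 0 or np.any(ex_sd == 0):
        raise ValueError("constant vector after ranking/residualization")
    rho = (ex * ey[:, None]).sum(axis=0) / (ex_sd * ey_sd)
    rho = np.clip(rho, -1.0, 1.0)
    df = n - 2 - k
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(df / (1.0 - rho * rho))
    p = np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    return rho, p


# ---------------------------------------------------------------------------
# Leave-one-out stability selection
# ---------------------------------------------------------------------------


def loo_stability_selection(
    panel: EdgeDifferencePanel,
    behavior: BehaviorVector,
    parcels: ParcelTable,
    cfg: PipelineConfig | None = None,
) -> EdgeSelectionResult:
    """Full screening pipeline with leave-one-out stability selection.

    Candidates are determined on the full sample (BF > threshold, cluster
    overlap, uncorrected p < alpha on the partial Spearman).  Each candidate
    then faces (a) N leave-one-subject-out folds, in which the Bayes-factor
    filter is re-applied on n-1 subjects and rho recomputed, and (b) a
    permutation null of ``cfg.n_permutations`` draws (drop one random
    subject, permute the behavioral vector, recompute rho).  An edge is
    selected iff it survives the filters on every fold and every fold rho
    lies outside the null percentile band.
    """
    cfg = cfg or PipelineConfig()
    if panel.n_subjects < 10:
        raise ValueError("need >= 10 subjects for leave-one-out selection")
    if tuple(behavior.subjects) != tuple(panel.subjects):
        raise ValueError("behavior vector not aligned to panel subjects")
    n = panel.n_subjects

    bf_full = edge_bayes_factors(panel.data)
    mask = (bf_full > cfg.bf_edge_threshold) & cluster_overlap_filter(panel.edge_index, parcels)
    cand = np.flatnonzero(mask)
    n_prescreen = cand.size
    log.info("full-sample filters: %d candidate edge(s)", cand.size)

    if cand.size:
        rho_full, p_full = _partial_spearman_block(
            panel.data[:, cand], behavior.scores, behavior.covariates
        )
        keep = p_full < cfg.alpha_behavior
        cand, rho_full, p_full = cand[keep], rho_full[keep], p_full[keep]
    else:
        rho_full = p_full = np.empty(0)
    log.info("p<%.3g screen: %d candidate edge(s)", cfg.alpha_behavior, cand.size)

    m = cand.size
    loo_rhos = np.zeros((n, m))
    fold_bf_pass = np.zeros((n, m), dtype=bool)
    null_percentiles = np.zeros((m, 2))
    selected = np.zeros(m, dtype=bool)

    if m:
        X = panel.data[:, cand]
        for f in range(n):
            rows = np.delete(np.arange(n), f)
            fold_bf = edge_bayes_factors(X[rows])
            fold_bf_pass[f] = fold_bf > cfg.bf_edge_threshold
            rho_f, _ = _partial_spearman_block(
                X[rows], behavior.scores[rows], behavior.covariates[rows]
            )
            loo_rhos[f] = rho_f

        rng = np.random.default_rng(child_seed(cfg.rng_seed, "edge-null"))
        null_rhos = np.zeros((cfg.n_permutations, m))
        for rep in range(cfg.n_permutations):
            drop = rng.integers(n)
            rows = np.delete(np.arange(n), drop)
            perm = rng.permutation(rows.size)
            rho_p, _ = _partial_spearman_block(
                X[rows], behavior.scores[rows][perm], behavior.covariates[rows]
            )
            null_rhos[rep] = rho_p
        lo, hi = cfg.percentile_bounds
        null_percentiles[:, 0] = np.percentile(null_rhos, 100 * lo, axis=0)
        null_percentiles[:, 1] = np.percentile(null_rhos, 100 * hi, axis=0)

        outside = (loo_rhos < null_percentiles[:, 0]) | (loo_rhos > null_percentiles[:, 1])
        selected = outside.all(axis=0) & fold_bf_pass.all(axis=0)

    log.info("stability selection: %d edge(s) selected", int(selected.sum()))
    return EdgeSelectionResult(
        edge_index=panel.edge_index[cand],
        bf10=bf_full[cand],
        partial_rho=np.asarray(rho_full),
        p_uncorrected=np.asarray(p_full),
        loo_rhos=loo_rhos,
        fold_bf_pass=fold_bf_pass,
        null_percentiles=null_percentiles,
        selected=selected,
        n_subjects=n,
        n_permutations=cfg.n_permutations,
        n_candidates_prescreen=n_prescreen,
    )


def report_selection(result: EdgeSelectionResult, parcels: ParcelTable) -> pd.DataFrame:
    """Per-candidate report: endpoint labels and cluster overlap, the
    direction of the FC difference implied by rho's sign, fold-wise rho
    range, null band and the selection verdict.  Empty selections yield a
    header-only table."""
    rows = []
    labels = parcels.labels
    overlap = parcels.frame["cluster_overlap"]
    for k in range(result.edge_index.shape[0]):
        i, j = (int(v) for v in result.edge_index[k])
        rows.append({
            "region_i": i + 1,
            "region_j": j + 1,
            "label_i": labels[i],
            "label_j": labels[j],
            "clusters_i": ",".join(sorted(overlap[i])),
            "clusters_j": ",".join(sorted(overlap[j])),
            "bf10": result.bf10[k],
            "partial_rho": result.partial_rho[k],
            "p_uncorrected": result.p_uncorrected[k],
            "rho_sign": "positive" if result.partial_rho[k] >= 0 else "negative",
            "loo_rho_min": result.loo_rhos[:, k].min() if result.loo_rhos.size else np.nan,
            "loo_rho_max": result.loo_rhos[:, k].max() if result.loo_rhos.size else np.nan,
            "null_lower": result.null_percentiles[k, 0],
            "null_upper": result.null_percentiles[k, 1],
            "selected": bool(result.selected[k]),
        })
    columns = ["region_i", "region_j", "label_i", "label_j", "clusters_i",
               "clusters_j", "bf10", "partial_rho", "p_uncorrected", "rho_sign",
               "loo_rho_min", "loo_rho_max", "null_lower", "null_upper", "selected"]
    return pd.DataFrame(rows, columns=columns)
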