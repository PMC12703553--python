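import numpy as np
import pytest

from fcx.connectivity import FCMatrix
from fcx.edge_selection import (
    BehaviorVector,
    build_difference_panel,
    bf_filter,
    cluster_overlap_filter,
    edge_bayes_factors,
    loo_stability_selection,
    partial_spearman,
    report_selection,
)
from fcx.io_config import PipelineConfig
from fcx.synthetic import make_parcel_table


def sym(v):
    v = np.asarray(v, dtype=float)
    out = (v + v.T) / 2
    np.fill_diagonal(out, 0.0)
    return out


def random_panel(rng, n_subjects=20, n_regions=8, shift=None):
    pairs = {}
    for s in range(n_subjects):
        a = sym(rng.standard_normal((n_regions, n_regions)) * 0.1)
        b = sym(rng.standard_normal((n_regions, n_regions)) * 0.1)
        if shift is not None:
            (i, j), delta = shift
            a[i, j] += delta
            a[j, i] += delta
        pairs[f"s{s:03d}"] = (FCMatrix(a), FCMatrix(b))
    return build_difference_panel(pairs)


class TestDifferencePanel:
    def test_identical_conditions_zero_rows(self, rng):
        m = sym(rng.standard_normal((5, 5)))
        panel = build_difference_panel({"s1": (FCMatrix(m), FCMatrix(m.copy()))})
        assert np.allclose(panel.data, 0.0)
        assert panel.n_edges == 10

    def test_swapped_conditions_negate_panel(self, rng):
        a, b = sym(rng.standard_normal((5, 5))), sym(rng.standard_normal((5, 5)))
        p1 = build_difference_panel({"s1": (FCMatrix(a), FCMatrix(b))})
        p2 = build_difference_panel({"s1": (FCMatrix(b), FCMatrix(a))})
        assert np.allclose(p1.data, -p2.data)

    def test_200_regions_gives_19900_columns(self):
        z = np.zeros((200, 200))
        panel = build_difference_panel({"s1": (FCMatrix(z), FCMatrix(z.copy()))})
        assert panel.n_edges == 19_900

    def test_missing_condition_dropped(self, rng):
        m = sym(rng.standard_normal((4, 4)))
        panel = build_difference_panel({
            "s1": (FCMatrix(m), FCMatrix(m.copy())),
            "s2": (None, FCMatrix(m.copy())),
        })
        assert panel.subjects == ("s1",)


class TestBFFilter:
    def test_null_edges_mostly_excluded(self, rng):
        panel = random_panel(rng, n_subjects=30)
        mask = bf_filter(panel)
        assert mask.mean() < 0.05

    def test_planted_shift_retained(self, rng):
        """Mean shift 0.3 with SD 0.2 at n=47: BF10 >> 3 essentially always."""
        retained = 0
        reps = 40
        for _ in range(reps):
            data = 0.3 + 0.2 * rng.standard_normal((47, 1))
            bf = edge_bayes_factors(data)
            retained += bf[0] > 3.0
        assert retained / reps >= 0.95

    def test_threshold_is_strict(self, rng):
        panel = random_panel(rng, n_subjects=25)
        bf = edge_bayes_factors(panel.data)
        cfg = PipelineConfig(bf_edge_threshold=float(bf[0]))
        mask = bf_filter(panel, cfg, bf10=bf)
        assert not mask[0]  # "above threshold" excludes exact equality


class TestClusterOverlapFilter:
    def test_endpoint_rules(self, toy_parcels):
        # regions 0 and 2 are labeled; 1 and 3 are not
        edges = np.array([[0, 2], [0, 1], [1, 3]])
        mask = cluster_overlap_filter(edges, toy_parcels)
        assert list(mask) == [True, False, False]

    def test_all_labeled_identity(self):
        parcels = make_parcel_table(14, cluster_fraction=1.0)
        edges = np.array([[0, 1], [5, 13]])
        assert cluster_overlap_filter(edges, parcels).all()

    def test_none_labeled_empty(self, rng):
        parcels = make_parcel_table(14, cluster_fraction=0.0)
        panel = random_panel(rng, n_regions=14, n_subjects=15)
        assert not cluster_overlap_filter(panel.edge_index, parcels).any()
        behavior = BehaviorVector(panel.subjects, rng.standard_normal(15),
                                  rng.standard_normal((15, 3)))
        res = loo_stability_selection(panel, behavior, parcels,
                                      PipelineConfig(n_permutations=50))
        assert res.selected.size == 0
        assert len(report_selection(res, parcels)) == 0


class TestPartialSpearman:
    def test_constant_covariates_reduce_to_plain_spearman(self, rng):
        from scipy.stats import spearmanr

        x, y = rng.standard_normal((2, 25))
        rho, _ = partial_spearman(x, y, np.ones((25, 2)))
        assert rho == pytest.approx(spearmanr(x, y).statistic, abs=1e-10)

    def test_monotone_relation_approaches_one(self, rng):
        x = rng.standard_normal(300)
        y = np.exp(x)  # strictly increasing
        cov = rng.standard_normal((300, 3))
        rho, p = partial_spearman(x, y, cov)
        assert rho > 0.97
        assert p < 1e-10

    def test_matches_brute_force_residualization_oracle(self, rng):
        """n=8 worked case against explicit rank + projection algebra."""
        from scipy.stats import rankdata

        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        cov = rng.standard_normal((8, 2))
        rx, ry = rankdata(x), rankdata(y)
        z = np.column_stack([np.ones(8), rankdata(cov, axis=0)])
        h = z @ np.linalg.inv(z.T @ z) @ z.T
        ex, ey = rx - h @ rx, ry - h @ ry
        expected = (ex @ ey) / np.sqrt((ex @ ex) * (ey @ ey))
        rho, _ = partial_spearman(x, y, cov)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        n = 40
        df = pd.DataFrame({
            "x": rng.standard_normal(n), "y": rng.standard_normal(n),
            "c1": rng.standard_normal(n), "c2": rng.standard_normal(n),
        })
        rho, p = partial_spearman(df["x"], df["y"], df[["c1", "c2"]].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"], method="spearman")
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-6)

    def test_tied_values_use_average_ranks(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 2.0, 3.0, 5.0, 4.0, 5.0, 7.0])
        rho, _ = partial_spearman(x, y, np.ones((8, 1)))
        from scipy.stats import spearmanr
        assert rho == pytest.approx(spearmanr(x, y).statistic, abs=1e-10)


class TestStabilitySelection:
    def _behavior(self, rng, panel, coupled_col=None, strength=1.0):
        scores = rng.standard_normal(panel.n_subjects)
        if coupled_col is not None:
            scores = strength * panel.data[:, coupled_col] + 0.1 * scores
        cov = rng.standard_normal((panel.n_subjects, 3))
        return BehaviorVector(panel.subjects, scores, cov)

    def test_deterministic_under_fixed_seed(self, rng):
        parcels = make_parcel_table(14, cluster_fraction=1.0)
        panel = random_panel(rng, n_subjects=16, n_regions=14,
                             shift=((0, 7), 0.4))
        col = int(np.flatnonzero((panel.edge_index == (0, 7)).all(axis=1))[0])
        behavior = self._behavior(np.random.default_rng(3), panel, coupled_col=col)
        cfg = PipelineConfig(n_permutations=500, rng_seed=99)
        r1 = loo_stability_selection(panel, behavior, parcels, cfg)
        r2 = loo_stability_selection(panel, behavior, parcels, cfg)
        assert np.array_equal(r1.selected, r2.selected)
        assert np.array_equal(r1.null_percentiles, r2.null_percentiles)
        assert np.array_equal(r1.loo_rhos, r2.loo_rhos)

    def test_subject_order_invariance(self, rng):
        """Permuting subjects (rows with behavior co-permuted) leaves the
        selection and per-edge statistics identical."""
        parcels = make_parcel_table(14, cluster_fraction=1.0)
        panel = random_panel(rng, n_subjects=14, n_regions=14, shift=((0, 7), 0.4))
        col = int(np.flatnonzero((panel.edge_index == (0, 7)).all(axis=1))[0])
        behavior = self._behavior(np.random.default_rng(5), panel, coupled_col=col)
        cfg = PipelineConfig(n_permutations=300, rng_seed=11)
        res = loo_stability_selection(panel, behavior, parcels, cfg)

        perm = np.random.default_rng(1).permutation(panel.n_subjects)
        from fcx.edge_selection import EdgeDifferencePanel
        panel_p = EdgeDifferencePanel(panel.data[perm],
                                      tuple(panel.subjects[i] for i in perm),
                                      panel.edge_index)
        behavior_p = BehaviorVector(panel_p.subjects, behavior.scores[perm],
                                    behavior.covariates[perm])
        res_p = loo_stability_selection(panel_p, behavior_p, parcels, cfg)
        assert np.array_equal(res.edge_index, res_p.edge_index)
        np.testing.assert_allclose(res.partial_rho, res_p.partial_rho, atol=1e-12)
        assert np.array_equal(res.selected, res_p.selected)

    def test_antisymmetry_of_rho(self, rng):
        """Negating the difference panel negates every candidate rho."""
        from fcx.edge_selection import EdgeDifferencePanel, _partial_spearman_block

        panel = random_panel(rng, n_subjects=18, n_regions=8)
        behavior = self._behavior(np.random.default_rng(2), panel)
        rho, _ = _partial_spearman_block(panel.data, behavior.scores,
                                         behavior.covariates)
        rho_neg, _ = _partial_spearman_block(-panel.data, behavior.scores,
                                             behavior.covariates)
        np.testing.assert_allclose(rho_neg, -rho, atol=1e-12)

    def test_fold_band_exit_probability_bounded(self, rng):
        """Under exchangeable behavior a single fold rho exits the 5%/95%
        band about 10% of the time; requiring all folds is more stringent."""
        from fcx.edge_selection import _partial_spearman_block

        n = 24
        exits = 0
        reps = 300
        nulls = np.empty(500)
        x = rng.standard_normal((n, 1))
        cov = rng.standard_normal((n, 3))
        for k in range(500):
            nulls[k] = _partial_spearman_block(
                x[:-1], rng.permutation(rng.standard_normal(n - 1)), cov[:-1]
            )[0][0]
        lo, hi = np.percentile(nulls, [5, 95])
        for _ in range(reps):
            y = rng.standard_normal(n)
            rho = _partial_spearman_block(x[:-1], y[:-1], cov[:-1])[0][0]
            exits += (rho < lo) or (rho > hi)
        assert exits / reps < 0.16  # ~10% plus Monte-Carlo slack

    def test_planted_edge_selected_noise_rejected(self, rng):
        parcels = make_parcel_table(14, cluster_fraction=1.0)
        panel = random_panel(rng, n_subjects=30, n_regions=14, shift=((0, 7), 0.4))
        col = int(np.flatnonzero((panel.edge_index == (0, 7)).all(axis=1))[0])
        behavior = self._behavior(np.random.default_rng(7), panel,
                                  coupled_col=col, strength=2.0)
        res = loo_stability_selection(panel, behavior, parcels,
                                      PipelineConfig(n_permutations=500, rng_seed=4))
        sel = {tuple(e) for e in res.edge_index[res.selected]}
        assert (0, 7) in sel
        assert len(sel) <= 2

    def test_report_round_trip(self, tmp_path, rng):
        import pandas as pd

        parcels = make_parcel_table(14, cluster_fraction=1.0)
        panel = random_panel(rng, n_subjects=16, n_regions=14, shift=((0, 7), 0.4))
        col = int(np.flatnonzero((panel.edge_index == (0, 7)).all(axis=1))[0])
        behavior = self._behavior(np.random.default_rng(9), panel, coupled_col=col)
        res = loo_stability_selection(panel, behavior, parcels,
                                      PipelineConfig(n_permutations=200, rng_seed=1))
        report = report_selection(res, parcels)
        report.to_csv(tmp_path / "sel.tsv", sep="\t", index=False)
        back = pd.read_csv(tmp_path / "sel.tsv", sep="\t")
        assert len(back) == len(report)
        if len(back):
            np.testing.assert_allclose(back["partial_rho"], res.partial_rho)
            assert list(back["selected"]) == list(res.selected)
        # planted endpoints carried through with 1-based region ids
        planted = back[(back["region_i"] == 1) & (back["region_j"] == 8)]
        assert len(planted) == 1
        assert planted["partial_rho"].iloc[0] > 0
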