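"""Series preparation, GP marginal likelihood, and DP-GP Gibbs clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from metaregulon.cluster import (ClusterConfig, gibbs_cluster,
                                 gp_marginal_loglik, member_trajectories,
                                 prepare_series, se_kernel, summarize_clusters)

TIMES = [3.0, 7.0, 13.0, 27.0]


def make_raw(values_by_gene, times=TIMES, n_reps=1, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, vals in values_by_gene.items():
        for _ in range(n_reps):
            for t, v in zip(times, vals):
                rows.append({"gene_id": g, "time": t, "value": v + rng.normal(0, noise)})
    return pd.DataFrame(rows)


class TestPrepareSeries:
    def test_constant_gene_dropped(self, caplog):
        raw = make_raw({"flat": [5, 5, 5, 5], "ramp": [1, 2, 3, 4]}, n_reps=6)
        with caplog.at_level("WARNING"):
            series = prepare_series(raw)
        assert series.gene_ids == ["ramp"]

    def test_standardization(self):
        series = prepare_series(make_raw({"g": [1, 2, 3, 4]}))
        row = series.matrix[0]
        assert row.mean() == pytest.approx(0.0, abs=1e-9)
        assert row.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(row) > 0)  # order preserved

    def test_replicate_averaging_matches_two_step_oracle(self):
        rng = np.random.default_rng(5)
        rows = []
        vals = {}
        for g in ("a", "b"):
            vals[g] = {}
            for t in TIMES:
                reps = rng.normal(size=6)
                vals[g][t] = reps.mean()
                for v in reps:
                    rows.append({"gene_id": g, "time": t, "value": v})
        series = prepare_series(pd.DataFrame(rows))
        for gi, g in enumerate(series.gene_ids):
            mean_vec = np.array([vals[g][t] for t in TIMES])
            expected = (mean_vec - mean_vec.mean()) / mean_vec.std(ddof=0)
            assert np.allclose(series.matrix[gi], expected, atol=1e-12)

    def test_gene_missing_a_time_point_dropped(self):
        raw = make_raw({"full": [1, 2, 3, 4]})
        partial = raw[~((raw.gene_id == "full") & (raw.time == 13.0))]
        partial = pd.concat([partial, make_raw({"other": [4, 3, 2, 1]})])
        series = prepare_series(partial, times=TIMES)
        assert series.gene_ids == ["other"]

    def test_fewer_than_two_time_points_rejected(self):
        with pytest.raises(ValueError, match="2 time"):
            prepare_series(make_raw({"g": [1]}, times=[3.0]), times=[3.0])


class TestGpMarginalLoglik:
    def test_matches_multivariate_normal_oracle(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(2, 3))
        ts = np.array([0.0, 1.0, 2.0])
        cfg = ClusterConfig(sigma_f2=1.3, length_scale=1.5, sigma_n2=0.2)
        K = se_kernel(ts, 1.3, 1.5)
        cov = np.kron(np.ones((2, 2)), K) + 0.2 * np.eye(6)
        oracle = multivariate_normal(mean=np.zeros(6), cov=cov).logpdf(Y.reshape(-1))
        assert gp_marginal_loglik(Y, ts, cfg) == pytest.approx(oracle, abs=1e-6)

    def test_member_order_invariance(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(4, 4))
        cfg = ClusterConfig()
        a = gp_marginal_loglik(Y, TIMES, cfg)
        b = gp_marginal_loglik(Y[::-1], TIMES, cfg)
        assert a == pytest.approx(b, abs=1e-9)

    def test_zero_signal_reduces_to_iid_gaussian(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(1, 4))
        cfg = ClusterConfig(sigma_f2=1e-14, length_scale=5.0, sigma_n2=0.3)
        iid = multivariate_normal(mean=np.zeros(4), cov=0.3 * np.eye(4)).logpdf(y[0])
        assert gp_marginal_loglik(y, TIMES, cfg) == pytest.approx(iid, abs=1e-5)


class TestGibbsCluster:
    def _two_shape_series(self, n_per=6, noise=0.15, seed=0):
        rng = np.random.default_rng(seed)
        t = np.array(TIMES)
        u = (t - t.min()) / np.ptp(t)
        shapes = {0: 2 * u - 1, 1: 1 - 2 * u}
        rows, truth = [], {}
        for i in range(2 * n_per):
            g = f"g{i:02d}"
            truth[g] = i % 2
            for rep in range(6):
                for tp, m in zip(TIMES, shapes[i % 2]):
                    rows.append({"gene_id": g, "time": tp,
                                 "value": m + rng.normal(0, noise)})
        return prepare_series(pd.DataFrame(rows)), truth

    def test_two_clean_shapes_perfectly_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        series, truth = self._two_shape_series()
        result = gibbs_cluster(series, ClusterConfig(seed=1))
        ari = adjusted_rand_score([truth[g] for g in result.gene_ids],
                                  [result.assignment[g] for g in result.gene_ids])
        assert result.n_clusters == 2 and ari == 1.0

    def test_identical_genes_form_one_cluster(self):
        raw = make_raw({f"h{i}": [1, 3, 2, 4] for i in range(6)})
        result = gibbs_cluster(prepare_series(raw),
                               ClusterConfig(seed=0, n_iterations=200, burn_in=100))
        assert result.n_clusters == 1

    def test_seed_determinism(self):
        series, _ = self._two_shape_series(seed=7)
        cfg = ClusterConfig(seed=5, n_iterations=150, burn_in=50)
        r1 = gibbs_cluster(series, cfg)
        r2 = gibbs_cluster(series, cfg)
        assert r1.assignment == r2.assignment
        assert np.array_equal(r1.similarity, r2.similarity)

    def test_input_order_invariance(self):
        series, _ = self._two_shape_series(seed=9)
        cfg = ClusterConfig(seed=3, n_iterations=150, burn_in=50)
        base = gibbs_cluster(series, cfg)
        perm = np.random.default_rng(0).permutation(len(series.gene_ids))
        shuffled = type(series)(gene_ids=[series.gene_ids[i] for i in perm],
                                times=series.times, matrix=series.matrix[perm])
        other = gibbs_cluster(shuffled, cfg)
        # same partition up to label renaming
        pairs = {(g, h) for g in base.assignment for h in base.assignment
                 if g < h and base.assignment[g] == base.assignment[h]}
        pairs2 = {(g, h) for g in other.assignment for h in other.assignment
                  if g < h and other.assignment[g] == other.assignment[h]}
        assert pairs == pairs2

    def test_similarity_matrix_properties(self):
        series, truth = self._two_shape_series(seed=11)
        result = gibbs_cluster(series, ClusterConfig(seed=2, n_iterations=150, burn_in=50))
        S = result.similarity
        assert np.all(S >= 0) and np.all(S <= 1)
        assert np.allclose(S, S.T)
        assert np.allclose(np.diag(S), 1.0)
        idx = {g: i for i, g in enumerate(result.gene_ids)}
        same, diff = [], []
        for g in truth:
            for h in truth:
                if g < h:
                    (same if truth[g] == truth[h] else diff).append(S[idx[g], idx[h]])
        assert np.mean(same) > np.mean(diff)

    def test_labels_contiguous_from_one(self):
        series, _ = self._two_shape_series(seed=13)
        result = gibbs_cluster(series, ClusterConfig(seed=4, n_iterations=100, burn_in=50))
        labels = sorted(set(result.assignment.values()))
        assert labels == list(range(1, len(labels) + 1))

    def test_single_gene_rejected(self):
        series = prepare_series(make_raw({"g": [1, 2, 3, 4]}))
        with pytest.raises(ValueError, match="2 genes"):
            gibbs_cluster(series, ClusterConfig())


class TestSummaries:
    def test_singleton_cluster_has_zero_band(self):
        raw = make_raw({"a": [1, 2, 3, 4], "b": [4, 1, 3, 2]})
        series = prepare_series(raw)
        result = gibbs_cluster(series, ClusterConfig(seed=0, n_iterations=100, burn_in=50))
        summary = summarize_clusters(result, series)
        if result.n_clusters == 2:  # singletons
            assert np.allclose(summary["sd"], 0.0)
            assert np.allclose(summary["lower"], summary["mean"])

    def test_plus_minus_one_members_give_band_two(self):
        """Two members at +1 and -1 at a time point: mean 0, band +/-2."""
        import metaregulon.cluster as mc
        series = mc.ExpressionSeries(gene_ids=["a", "b"], times=np.array([0.0, 1.0]),
                                     matrix=np.array([[1.0, -1.0], [-1.0, 1.0]]))
        result = mc.ClusterResult(gene_ids=["a", "b"],
                                  assignment={"a": 1, "b": 1},
                                  similarity=np.eye(2), n_clusters=1, n_samples=1)
        summary = mc.summarize_clusters(result, series)
        assert np.allclose(summary["mean"], 0.0)
        assert np.allclose(summary["upper"], 2.0)
        assert np.allclose(summary["lower"], -2.0)

    def test_matches_mean_sd_oracle(self):
        rng = np.random.default_rng(21)
        raw = make_raw({f"g{i}": rng.normal(size=4) for i in range(5)})
        series = prepare_series(raw)
        result = gibbs_cluster(series, ClusterConfig(seed=1, n_iterations=100, burn_in=50))
        summary = summarize_clusters(result, series)
        idx = {g: i for i, g in enumerate(series.gene_ids)}
        for cluster in sorted(set(result.assignment.values())):
            block = series.matrix[[idx[g] for g, c in result.assignment.items()
                                   if c == cluster]]
            sub = summary[summary.cluster == cluster]
            assert np.allclose(sub["mean"], block.mean(axis=0), atol=1e-12)
            assert np.allclose(sub["sd"], block.std(axis=0, ddof=0), atol=1e-12)
        traj = member_trajectories(result, series)
        assert set(traj["gene_id"]) == set(series.gene_ids)
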