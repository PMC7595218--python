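import numpy as np
import pytest
from scipy import stats

from cnvstrat import cluster_engine as ce
from cnvstrat import phenotype_io as pio
from cnvstrat import synthetic_cohort as sc
from cnvstrat.errors import (
    DegeneratePartitionError,
    DomainError,
    InsufficientDataError,
    LabelingError,
)


def fm(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{i}" for i in range(values.shape[1])]
    return ce.FeatureMatrix(values, names)


class TestStandardize:
    def test_symmetric_column_maps_to_unit_steps(self):
        out = ce.standardize(fm([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out.values[:, 0], [-1, 0, 1])

    def test_constant_column_zeroed_and_flagged(self):
        out = ce.standardize(fm([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        np.testing.assert_allclose(out.values[:, 0], 0.0)
        assert out.constant_columns.tolist() == [True, False]

    def test_idempotent(self, rng):
        x = rng.normal(size=(40, 6)) * 7 + 3
        once = ce.standardize(fm(x))
        twice = ce.standardize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_columns_have_zero_mean_unit_sample_sd(self, rng):
        out = ce.standardize(fm(rng.normal(size=(30, 4))))
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1.0, atol=1e-9)


class TestPCA:
    def test_collinear_data_has_rank_one(self):
        t = np.linspace(-1, 1, 10)
        model = ce.fit_pca(fm(np.column_stack([t, 2 * t])))
        assert model.rank == 1

    def test_reconstruction_identity_at_full_rank(self, rng):
        x = rng.normal(size=(25, 4))
        model = ce.fit_pca(fm(x))
        assert model.rank == 4
        recon = model.scores @ model.component_loadings.T + model.column_means
        np.testing.assert_allclose(recon, x, atol=1e-10)

    def test_loadings_orthonormal_and_variances_nonincreasing(self, rng):
        model = ce.fit_pca(fm(rng.normal(size=(30, 6))))
        gram = model.component_loadings.T @ model.component_loadings
        np.testing.assert_allclose(gram, np.eye(model.rank), atol=1e-8)
        assert np.all(np.diff(model.explained_variance) <= 1e-12)

    def test_explained_variance_matches_eigendecomposition_oracle(self, rng):
        x = rng.normal(size=(20, 5))
        model = ce.fit_pca(fm(x))
        cov = np.cov(x, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(model.explained_variance, eig[: model.rank], atol=1e-10)

    def test_matches_sklearn(self, rng):
        from sklearn.decomposition import PCA

        x = rng.normal(size=(40, 7))
        model = ce.fit_pca(fm(x))
        ref = PCA().fit(x)
        np.testing.assert_allclose(
            model.explained_variance, ref.explained_variance_, atol=1e-10
        )
        # loadings agree up to sign
        dots = np.abs(np.sum(model.component_loadings * ref.components_.T, axis=0))
        np.testing.assert_allclose(dots, 1.0, atol=1e-8)

    def test_single_row_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            ce.fit_pca(fm([[1.0, 2.0]]))


class TestWithinDispersion:
    def test_two_points_single_cluster(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])  # distance 5
        w = ce.within_dispersion(pts, np.zeros(2, dtype=int))
        assert w == pytest.approx(25.0 / 2)

    def test_identical_points_give_zero(self):
        pts = np.ones((6, 3))
        assert ce.within_dispersion(pts, np.zeros(6, dtype=int)) == 0.0

    def test_matches_pairwise_brute_force(self, rng):
        """W_k from centroids equals Tibshirani's pairwise definition."""
        for _ in range(5):
            pts = rng.normal(size=(12, 3))
            assign = rng.integers(0, 3, size=12)
            while len(set(assign.tolist())) < 3:
                assign = rng.integers(0, 3, size=12)
            brute = 0.0
            for c in range(3):
                member = pts[assign == c]
                d2 = ((member[:, None, :] - member[None, :, :]) ** 2).sum(-1)
                brute += d2.sum() / (2 * len(member))
            fast = ce.within_dispersion(pts, assign)
            assert fast == pytest.approx(brute, abs=1e-10)

    def test_plain_metric_uses_unsquared_distances(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        w = ce.within_dispersion(pts, np.zeros(3, dtype=int), metric="plain")
        # ordered pairs: 2*(1 + 2 + 1) = 8; / (2*3)
        assert w == pytest.approx(8.0 / 6)

    def test_empty_partition_rejected(self):
        with pytest.raises(DegeneratePartitionError):
            ce.within_dispersion(np.empty((0, 2)), np.empty(0, dtype=int))


class TestKMeans:
    def test_k_equals_n_gives_zero_inertia(self, rng):
        pts = rng.normal(size=(6, 2))
        res = ce.kmeans(pts, k=6, seed=0, n_restarts=5)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)

    def test_k1_inertia_equals_within_dispersion(self, rng):
        pts = rng.normal(size=(30, 3))
        res = ce.kmeans(pts, k=1, seed=0)
        assert res.inertia == pytest.approx(
            ce.within_dispersion(pts, np.zeros(30, dtype=int)), rel=1e-10
        )

    def test_recovers_well_separated_blobs(self, rng):
        truth = np.r_[np.zeros(50, dtype=int), np.ones(50, dtype=int)]
        pts = rng.normal(size=(100, 3))
        pts[truth == 1] += 10.0
        res = ce.kmeans(pts, k=2, seed=0)
        agree = max(
            (res.assignments == truth).mean(), (res.assignments != truth).mean()
        )
        assert agree == 1.0

    def test_matches_sklearn_inertia_on_blobs(self, rng):
        from sklearn.cluster import KMeans

        pts = rng.normal(size=(90, 4))
        pts[30:60] += 8.0
        pts[60:] -= 8.0
        ours = ce.kmeans(pts, k=3, seed=0, n_restarts=20)
        ref = KMeans(n_clusters=3, n_init=20, random_state=0).fit(pts)
        assert ours.inertia == pytest.approx(ref.inertia_, rel=1e-6)

    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(size=(50, 3))
        a = ce.kmeans(pts, k=3, seed=42)
        b = ce.kmeans(pts, k=3, seed=42)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        assert a.inertia == b.inertia

    def test_more_restarts_never_worse(self, rng):
        pts = rng.normal(size=(60, 2))
        one = ce.kmeans(pts, k=4, seed=3, n_restarts=1)
        many = ce.kmeans(pts, k=4, seed=3, n_restarts=20)
        assert many.inertia <= one.inertia + 1e-9

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(DomainError):
            ce.kmeans(np.zeros((3, 2)), k=4)


class TestGapStatistic:
    def test_definitional_identity_and_nonnegative_se(self, rng):
        pts = rng.normal(size=(60, 2))
        pts[:30] += 8.0
        gap = ce.gap_statistic(pts, k_max=4, B=20, seed=0)
        np.testing.assert_allclose(gap.gap + gap.log_wk, gap.e_log_wk, atol=1e-12)
        assert np.all(gap.s_k >= 0)
        assert gap.chosen_k in gap.k_values

    def test_two_separated_blobs_choose_two(self, rng):
        pts = rng.normal(size=(80, 3))
        pts[:40] += 8.0
        for rule in ("firstSEmax", "tibshirani2001"):
            gap = ce.gap_statistic(pts, k_max=5, B=30, seed=1, rule=rule)
            assert gap.chosen_k == 2, rule

    def test_single_blob_usually_chooses_one(self):
        hits = 0
        for s in range(20):
            pts = np.random.default_rng(100 + s).normal(size=(100, 2))
            gap = ce.gap_statistic(pts, k_max=5, B=30, seed=s)
            hits += gap.chosen_k == 1
        assert hits >= 16  # large majority of null datasets

    def test_k_max_bounds_enforced(self, rng):
        pts = rng.normal(size=(10, 2))
        with pytest.raises(DomainError):
            ce.gap_statistic(pts, k_max=1, B=5)
        with pytest.raises(DomainError):
            ce.gap_statistic(pts, k_max=10, B=5)


class TestClusterCohortPipeline:
    def test_identical_records_raise_degenerate_error(self, schema):
        feats = {n: 1.0 for n in schema.names}
        recs = [pio.PatientRecord(f"p{i}", dict(feats)) for i in range(20)]
        with pytest.raises(DegeneratePartitionError):
            ce.cluster_cohort(recs, schema, seed=0, B=5, k_max=3)

    def test_default_cohort_recovers_published_structure(
        self, schema, default_cohort, clustered_default
    ):
        """Two clusters; PNV-type has thicker fellow choroid and more CVH."""
        pca, gap, km, labeling = clustered_default
        assert gap.chosen_k == 2
        assert labeling is not None
        labels = np.array([labeling.labels[int(c)] for c in km.assignments])
        sfct = np.array([r.get("sfct_fellow") for r in default_cohort])
        cvh = np.array([r.get("cvh_either") for r in default_cohort])
        assert sfct[labels == ce.PNV].mean() > sfct[labels == ce.AMD].mean()
        assert cvh[labels == ce.PNV].mean() > cvh[labels == ce.AMD].mean()

    def test_row_order_invariance_of_partition(self, schema, small_config):
        records = sc.simulate_cohort(small_config, schema)
        perm = np.random.default_rng(0).permutation(len(records))
        shuffled = [records[i] for i in perm]

        def partition(recs):
            m = ce.standardize(ce.encode_records(recs, schema))
            km = ce.kmeans(ce.fit_pca(m).scores, 2, seed=5, n_restarts=10)
            groups = {}
            for rec, c in zip(recs, km.assignments):
                groups.setdefault(int(c), set()).add(rec.patient_id)
            return {frozenset(v) for v in groups.values()}

        assert partition(sorted(records, key=lambda r: r.patient_id)) == partition(
            sorted(shuffled, key=lambda r: r.patient_id)
        )

    def test_labeling_tie_raises(self):
        recs = [
            pio.PatientRecord("a", {"sfct_fellow": 200.0}),
            pio.PatientRecord("b", {"sfct_fellow": 200.0}),
        ]
        with pytest.raises(LabelingError):
            ce.label_clusters(recs, np.array([0, 1]))


class TestCompareClusters:
    @staticmethod
    def _binary_records(n1, k1, n2, k2):
        schema = pio.FeatureSchema((("flag", "binary", "flag"),))
        recs = [
            pio.PatientRecord(f"a{i}", {"flag": 1.0 if i < k1 else 0.0})
            for i in range(n1)
        ] + [
            pio.PatientRecord(f"b{i}", {"flag": 1.0 if i < k2 else 0.0})
            for i in range(n2)
        ]
        labels = ["g1"] * n1 + ["g2"] * n2
        return schema, recs, labels

    def test_published_cvh_contingency_is_highly_significant(self):
        schema, recs, labels = self._binary_records(289, 18, 248, 107)
        table = ce.compare_clusters(recs, labels, schema)
        assert table.loc[0, "p_value"] < 1e-4

    def test_identical_groups_give_p_one(self):
        schema, recs, labels = self._binary_records(10, 3, 10, 3)
        table = ce.compare_clusters(recs, labels, schema)
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher p = sum of hypergeometric probabilities <= observed."""
        n1, k1, n2, k2 = 10, 3, 10, 7
        schema, recs, labels = self._binary_records(n1, k1, n2, k2)
        table = ce.compare_clusters(recs, labels, schema)
        total, successes = n1 + n2, k1 + k2
        p_obs = stats.hypergeom.pmf(k1, total, successes, n1)
        brute = sum(
            stats.hypergeom.pmf(x, total, successes, n1)
            for x in range(max(0, successes - n2), min(n1, successes) + 1)
            if stats.hypergeom.pmf(x, total, successes, n1) <= p_obs * (1 + 1e-9)
        )
        assert table.loc[0, "p_value"] == pytest.approx(brute, rel=1e-9)

    def test_continuous_feature_uses_rank_sum(self, rng):
        schema = pio.FeatureSchema((("x", "continuous", "um"),))
        recs = [pio.PatientRecord(f"p{i}", {"x": float(v)}) for i, v in
                enumerate(np.r_[rng.normal(0, 1, 30), rng.normal(3, 1, 30)])]
        labels = ["g1"] * 30 + ["g2"] * 30
        table = ce.compare_clusters(recs, labels, schema)
        x1 = np.array([recs[i].get("x") for i in range(30)])
        x2 = np.array([recs[i].get("x") for i in range(30, 60)])
        ref = stats.mannwhitneyu(x1, x2, alternative="two-sided").pvalue
        assert table.loc[0, "p_value"] == pytest.approx(ref, rel=1e-12)

    def test_empty_group_rejected(self):
        schema, recs, _ = self._binary_records(5, 2, 5, 3)
        with pytest.raises(DegeneratePartitionError):
            ce.compare_clusters(recs, ["g1"] * 10, schema)
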