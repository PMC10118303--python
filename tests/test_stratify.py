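import numpy as np
import pandas as pd
import pytest

from phenostrat import simcage, stratify
from phenostrat.events_io import bin_events_hourly
from phenostrat.learning_metrics import cognitive_flexibility

# young reference summary of reversal entries-to-criterion
YOUNG = dict(mean=813.03, sem=105.92, n=40)


class TestReferenceCutoff:
    def test_young_summary_reproduces_1000_entry_cutoff(self):
        cut = stratify.compute_reference_cutoff(**YOUNG)
        # one-sided bound frozen from t-table arithmetic:
        # 813.03 + 1.6849 * 105.92 = 991.49
        assert cut.raw_upper_bound == pytest.approx(991.49, abs=0.05)
        assert cut.cutoff == 1000.0

    def test_raw_values_route(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(800, 600, size=40)
        cut = stratify.compute_reference_cutoff(vals)
        sem = vals.std(ddof=1) / np.sqrt(40)
        assert cut.sem_ref == pytest.approx(sem)
        assert cut.cutoff >= cut.raw_upper_bound

    def test_zero_sem_degenerates_to_rounded_mean(self):
        cut = stratify.compute_reference_cutoff(mean=813.03, sem=0.0, n=40)
        assert cut.raw_upper_bound == 813.03
        assert cut.cutoff == 900.0

    def test_percentile_method(self):
        vals = np.arange(100.0, 2100.0, 20.0)  # 100 values
        cut = stratify.compute_reference_cutoff(vals, method="percentile", rounding="none")
        assert cut.raw_upper_bound == pytest.approx(np.quantile(vals, 0.95))

    def test_insufficient_reference_rejected(self):
        with pytest.raises(ValueError):
            stratify.compute_reference_cutoff([800.0])
        with pytest.raises(ValueError):
            stratify.compute_reference_cutoff(mean=800.0, sem=10.0, n=1)


class TestClassification:
    @pytest.fixture
    def cutoff(self):
        return stratify.compute_reference_cutoff(**YOUNG)

    def _results(self, etcs, reached=None):
        reached = [True] * len(etcs) if reached is None else reached
        return pd.DataFrame(
            {
                "animal_id": [f"a{i}" for i in range(len(etcs))],
                "etc": etcs,
                "reached": reached,
            }
        )

    def test_printed_subgroup_means_classify_correctly(self, cutoff):
        labels, summary = stratify.classify_cohort(self._results([736.81, 2439.05]), cutoff)
        assert list(labels["label"]) == [stratify.INTACT, stratify.IMPAIRED]
        assert set(summary["label"]) == {stratify.INTACT, stratify.IMPAIRED}

    def test_boundary_and_censoring_rules(self, cutoff):
        labels, _ = stratify.classify_cohort(
            self._results([1000.0, 999.9, 3000.0], [True, True, False]), cutoff
        )
        # exactly at cutoff -> impaired; censored -> impaired regardless of etc
        assert list(labels["label"]) == ["impaired", "intact", "impaired"]

    def test_order_independence(self, cutoff):
        res = self._results([500.0, 1500.0, 900.0, 2500.0])
        labels_fwd, _ = stratify.classify_cohort(res, cutoff)
        labels_rev, _ = stratify.classify_cohort(res.iloc[::-1].reset_index(drop=True), cutoff)
        merged = labels_fwd.merge(labels_rev, on="animal_id", suffixes=("_f", "_r"))
        assert (merged["label_f"] == merged["label_r"]).all()

    def test_empty_cohort_rejected(self, cutoff):
        with pytest.raises(ValueError):
            stratify.classify_cohort(self._results([]), cutoff)

    def test_monte_carlo_fraction_matches_closed_form(self, cutoff):
        """Impaired fraction under the two printed subgroup distributions.

        Independent oracle: normal tail arithmetic. With intact ~
        N(736.81, 151.12) and impaired ~ N(2439.05, 791.24), the expected
        impaired count is 16*P(intact >= 1000) + 19*P(impaired >= 1000).
        """
        from scipy.stats import norm

        p_int = norm.sf(1000, 736.81, 37.78 * np.sqrt(16))
        p_imp = norm.sf(1000, 2439.05, 181.51 * np.sqrt(19))
        expect_pct = (16 * p_int + 19 * p_imp) / 35 * 100
        imp, intact = stratify.simulate_classification_fractions(
            [(16, 736.81, 37.78), (19, 2439.05, 181.51)], cutoff,
            n_replicates=4000, seed=5,
        )
        assert imp == pytest.approx(expect_pct, abs=0.5)
        assert imp + intact == pytest.approx(100.0)


class TestZScores:
    def test_closed_form_sample_sd(self):
        z = stratify.zscore_series(pd.Series([1.0, 2.0, 3.0]))
        assert list(z) == pytest.approx([-1.0, 0.0, 1.0])

    def test_normalization(self):
        rng = np.random.default_rng(3)
        z = stratify.zscore_series(pd.Series(rng.normal(50, 7, 25)))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            stratify.zscore_series(pd.Series([2.0, 2.0, 2.0]))

    def test_nan_propagates(self):
        z = stratify.zscore_series(pd.Series([1.0, np.nan, 3.0, 5.0]))
        assert np.isnan(z.iloc[1]) and np.isfinite(z.drop(index=1)).all()


class TestEmbedding:
    def test_recovers_orthogonal_group_shifts(self):
        rng = np.random.default_rng(11)
        n, p = 30, 12
        X = rng.standard_normal((n, p)) * 0.2
        X[:10, 0] += 8.0   # group A shifted along feature 0
        X[10:20, 1] += 8.0  # group B shifted along feature 1
        emb = stratify.augment_embedding(pd.DataFrame(X), np.zeros(n))
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        # principal plane ~ span(e0, e1): check subspace angle < 5 degrees
        basis = np.eye(p)[:, :2]
        sv = np.linalg.svd(Vt[:2] @ basis)[1]
        angle = np.degrees(np.arccos(np.clip(sv.min(), -1, 1)))
        assert angle < 5.0
        assert emb.explained_variance_ratio[0] > 0.4

    def test_constant_zero_behavior_degenerates_to_plane(self):
        rng = np.random.default_rng(1)
        emb = stratify.augment_embedding(pd.DataFrame(rng.standard_normal((8, 5))), np.zeros(8))
        assert (emb.coords["z3"] == 0.0).all()

    def test_duplicated_rows_get_identical_coordinates(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((6, 4))
        Xdup = np.vstack([X, X])
        z = np.tile(rng.standard_normal(6), 2)
        emb = stratify.augment_embedding(pd.DataFrame(Xdup), z)
        first = emb.coords.iloc[:6].to_numpy()
        second = emb.coords.iloc[6:].to_numpy()
        np.testing.assert_allclose(first, second, atol=1e-8)

    def test_rank_deficient_matrix_rejected(self):
        X = np.outer(np.arange(6.0), np.ones(4))  # rank 1 after centering
        with pytest.raises(ValueError, match="rank"):
            stratify.augment_embedding(pd.DataFrame(X), np.zeros(6))

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((10, 6)))
        a = stratify.augment_embedding(X, np.zeros(10))
        b = stratify.augment_embedding(X, np.zeros(10))
        pd.testing.assert_frame_equal(a.coords, b.coords)


class TestSeparationProperty:
    def test_3d_embedding_separates_simulated_groups(self, sim_cohort, sim_bins, schedule):
        """Centroids of the three phenotypes separate beyond within-group radius."""
        _, cohort, _ = sim_cohort
        X = simcage.generate_feature_matrix(cohort, n_features=30, effect_size=2.5, seed=8)
        flex = cognitive_flexibility(sim_bins, schedule)
        z = stratify.zscore_series(flex.reindex(X.index))
        emb = stratify.augment_embedding(X, z.to_numpy())
        coords = emb.coords.copy()
        coords["group"] = cohort.set_index("animal_id")["group"].reindex(coords.index)
        centroids = coords.groupby("group")[["pc1", "pc2", "z3"]].mean()
        radii = coords.groupby("group").apply(
            lambda g: np.linalg.norm(
                g[["pc1", "pc2", "z3"]].to_numpy() - g[["pc1", "pc2", "z3"]].mean().to_numpy(),
                axis=1,
            ).mean(),
            include_groups=False,
        )
        groups = list(centroids.index)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                d = np.linalg.norm(centroids.loc[groups[i]] - centroids.loc[groups[j]])
                assert d > radii.mean()
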