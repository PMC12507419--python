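import numpy as np
import pandas as pd
import pytest
from scipy import stats

from statesig import (
    FRatioSelector,
    ShadowFeatureSelector,
    SyntheticSpec,
    VarianceTopKSelector,
    elbow_select,
    f_values,
    preprocess_counts,
    select_genes,
    simulate_counts,
)
from statesig.selection import (
    NoGenesSelectedError,
    one_way_f,
    perpendicular_distances,
    rank_genes,
)


def brute_force_f(X, y):
    """Textbook one-way ANOVA sums of squares, by explicit loops."""
    out = []
    groups = sorted(set(y))
    for j in range(X.shape[1]):
        col = X[:, j]
        grand = col.mean()
        ssb = sum(
            (y == g).sum() * (col[y == g].mean() - grand) ** 2 for g in groups
        )
        ssw = sum(((col[y == g] - col[y == g].mean()) ** 2).sum() for g in groups)
        msb = ssb / (len(groups) - 1)
        msw = ssw / (len(col) - len(groups))
        out.append(msb / msw if msw > 0 else np.inf)
    return np.array(out)


def brute_force_elbow(curve):
    """Exhaustive perpendicular-distance search on the min-max scaled curve."""
    n = len(curve)
    x = np.linspace(0, 1, n)
    y = (curve - curve.min()) / (curve.max() - curve.min())
    p0, p1 = np.array([x[0], y[0]]), np.array([x[-1], y[-1]])
    best, best_d = 0, -1.0
    for i in range(n):
        ux, uy = p1 - p0
        vx, vy = np.array([x[i], y[i]]) - p0
        d = abs(ux * vy - uy * vx) / np.hypot(ux, uy)
        if d > best_d + 1e-15:
            best, best_d = i, d
    return best


class TestOneWayF:
    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            k = rng.integers(2, 5)
            sizes = rng.integers(2, 6, size=k)
            y = np.repeat([f"c{i}" for i in range(k)], sizes)
            X = rng.normal(size=(sizes.sum(), rng.integers(1, 8)))
            expected = brute_force_f(X, y)
            got = one_way_f(X, y)
            assert np.allclose(got, expected, rtol=1e-10)

    def test_agrees_with_scipy_f_oneway(self, rng):
        y = np.repeat(["a", "b", "c"], 5)
        X = rng.normal(size=(15, 20))
        expected = np.array([
            stats.f_oneway(*(X[y == g, j] for g in "abc")).statistic
            for j in range(20)
        ])
        assert np.allclose(one_way_f(X, y), expected, rtol=1e-10)

    def test_constant_gene_gets_zero_and_last_rank(self):
        X = np.column_stack([np.full(6, 4.0), np.arange(6.0)])
        y = np.repeat(["a", "b"], 3)
        f = one_way_f(X, y)
        assert f[0] == 0.0
        ranking = rank_genes(f, ["flat", "varying"])
        assert ranking.iloc[-1]["gene"] == "flat"

    def test_zero_within_variance_gets_infinity_and_first_rank(self):
        X = np.column_stack([
            np.array([0, 0, 0, 5, 5, 5.0]),
            np.random.default_rng(0).normal(size=6),
        ])
        y = np.repeat(["a", "b"], 3)
        f = one_way_f(X, y)
        assert np.isinf(f[0])
        assert rank_genes(f, ["sep", "noise"]).iloc[0]["gene"] == "sep"

    def test_two_groups_of_three_hand_computed(self):
        # groups {1, 2, 3} and {4, 6, 8}: means 2 and 6, grand 4
        # SSB = 3*(2-4)^2 + 3*(6-4)^2 = 24, MSB = 24
        # SSW = (1+0+1) + (4+0+4) = 10, MSW = 10/4 = 2.5 -> F = 9.6
        X = np.array([[1.0], [2], [3], [4], [6], [8]])
        y = np.repeat(["lo", "hi"], 3)
        assert one_way_f(X, y)[0] == pytest.approx(9.6)

    def test_affine_invariance(self, rng):
        X = rng.normal(size=(12, 10))
        y = np.repeat(["a", "b", "c"], 4)
        assert np.allclose(one_way_f(X, y), one_way_f(3.2 * X - 7.0, y),
                           rtol=1e-9)

    def test_fewer_than_two_categories_rejected(self, rng):
        with pytest.raises(ValueError, match="categories"):
            one_way_f(rng.normal(size=(4, 3)), np.repeat(["a"], 4))


class TestElbowSelect:
    @staticmethod
    def _ranking(values, genes=None):
        values = np.asarray(values, dtype=float)
        genes = genes or [f"g{i}" for i in range(len(values))]
        return rank_genes(values, genes)

    def test_sharp_corner_curve(self):
        # [100, 10, 9, 8, 7]: elbow at rank 2, only the rank-1 gene above it
        result = elbow_select(self._ranking([100, 10, 9, 8, 7]))
        assert result.elbow_index == 2
        assert len(result.selected_genes) == 1
        assert result.ranking.iloc[0]["gene"] in result.selected_genes

    def test_matches_exhaustive_search_on_random_curves(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(3, 60))
            curve = np.sort(rng.gamma(2.0, 5.0, size=n))[::-1]
            if curve.max() == curve.min():
                continue
            result = elbow_select(self._ranking(curve))
            assert result.elbow_index == brute_force_elbow(curve) + 1

    def test_linear_curve_tie_rule_and_warning(self, caplog):
        with caplog.at_level("WARNING"):
            result = elbow_select(self._ranking([5, 4, 3, 2, 1]))
        assert result.elbow_index == 1
        assert len(result.selected_genes) == 1
        assert any("degenerate" in r.message for r in caplog.records)

    def test_infinite_sentinels_sort_first_and_are_selected(self):
        ranking = self._ranking([np.inf, 50, 5, 4, 3, 2])
        result = elbow_select(ranking)
        assert ranking.iloc[0]["f_value"] == np.inf
        assert ranking.iloc[0]["gene"] in result.selected_genes

    def test_duplicating_last_gene_leaves_selection_unchanged(self):
        curve = [90, 80, 12, 5, 4, 3, 2]
        base = elbow_select(self._ranking(curve))
        extended = elbow_select(self._ranking(curve + [curve[-1]]))
        assert base.selected_genes == extended.selected_genes

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            elbow_select(self._ranking([2, 1]))

    def test_recovers_planted_genes_in_simulation(self):
        # ~50 strongly shifted genes among 5000: the elbow should land near
        # the planted count and capture nearly all of them
        spec = SyntheticSpec(
            n_categories=2, datasets_per_category=6, replicates_per_dataset=2,
            n_genes=5000, n_informative_per_category=25, effect_size=3.0,
            nb_dispersion=0.05, batch_effect_sd=0.0, n_batches=1, seed=99,
        )
        counts, meta, truth = simulate_counts(spec)
        expr = preprocess_counts(counts, meta, batch_correct=False)
        result = select_genes(expr, meta, method="f_elbow", level="dataset")
        planted = set(truth.informative_genes()) & set(expr.index)
        assert 40 <= result.elbow_index <= 200
        recall = len(set(result.selected_genes) & planted) / len(planted)
        assert recall >= 0.9


class TestFRatioSelectorEstimator:
    def test_sklearn_fit_transform_selects_columns(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 6)),
                         columns=[f"g{i}" for i in range(6)])
        X["g0"] += np.repeat([0, 4, 8], 4)  # strong category signal
        y = np.repeat(["a", "b", "c"], 4)
        sel = FRatioSelector().fit(X, y)
        assert "g0" in sel.selected_genes_
        reduced = sel.transform(X)
        assert reduced.shape == (12, len(sel.selected_genes_))
        assert sel.elbow_index_ >= 1

    def test_get_params_round_trip(self):
        sel = FRatioSelector()
        assert sel.get_params() == {}
        assert isinstance(sel.set_params(), FRatioSelector)


class TestVarianceTopK:
    def test_k_larger_than_gene_count_returns_all(self, rng):
        X = rng.normal(size=(8, 5))
        sel = VarianceTopKSelector(k=50).fit(X)
        assert sel.support_.all()

    def test_inflated_variance_genes_found_exactly(self, rng):
        X = rng.normal(size=(20, 200))
        planted = rng.choice(200, size=10, replace=False)
        X[:, planted] *= 100
        sel = VarianceTopKSelector(k=10).fit(X)
        assert set(np.flatnonzero(sel.support_)) == set(planted)

    def test_ties_resolved_by_gene_id(self):
        X = pd.DataFrame(
            np.tile([[0.0], [1.0]], (1, 4)), columns=list("dcba"),
        )
        sel = VarianceTopKSelector(k=2).fit(X)
        assert sel.selected_genes_ == ["a", "b"]


class TestShadowFeatureSelector:
    def test_perfect_separator_confirmed(self, rng):
        n = 30
        X = rng.normal(size=(n, 201))
        y = np.repeat(["a", "b"], n // 2)
        X[:, 0] = np.where(y == "a", 0.0, 10.0) + rng.normal(0, 0.1, n)
        sel = ShadowFeatureSelector(n_iter=15, n_estimators=40,
                                    random_state=3).fit(X, y)
        assert 0 in np.flatnonzero(sel.support_)

    def test_same_seed_same_output(self, rng):
        X = rng.normal(size=(20, 50))
        y = np.repeat(["a", "b"], 10)
        X[:, 3] += np.where(y == "a", 0, 5.0)
        r1 = ShadowFeatureSelector(n_iter=12, n_estimators=30,
                                   random_state=7).fit(X, y)
        r2 = ShadowFeatureSelector(n_iter=12, n_estimators=30,
                                   random_state=7).fit(X, y)
        assert r1.selected_genes_ == r2.selected_genes_
        assert np.array_equal(r1.hits_, r2.hits_)

    def test_pure_noise_raises_empty_selection(self, rng):
        X = rng.normal(size=(16, 40))
        y = np.repeat(["a", "b"], 8)
        with pytest.raises(NoGenesSelectedError):
            ShadowFeatureSelector(n_iter=12, n_estimators=30,
                                  random_state=0).fit(X, y)

    def test_n_iter_floor_enforced(self, rng):
        with pytest.raises(ValueError, match="n_iter"):
            ShadowFeatureSelector(n_iter=5).fit(
                rng.normal(size=(6, 4)), np.repeat(["a", "b"], 3)
            )


class TestDataFrameWrappers:
    def test_f_values_dataset_level_collapses_replicates(self, default_fixture):
        ranking = f_values(default_fixture["expr"], default_fixture["meta"],
                           level="dataset")
        assert len(ranking) == default_fixture["expr"].shape[0]
        assert (np.diff(ranking["f_value"].to_numpy()
                        [np.isfinite(ranking["f_value"])]) <= 1e-12).all()
        assert list(ranking["rank"]) == list(range(1, len(ranking) + 1))

    def test_unknown_method_rejected(self, default_fixture):
        with pytest.raises(ValueError, match="unknown"):
            select_genes(default_fixture["expr"], default_fixture["meta"],
                         method="pca")
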