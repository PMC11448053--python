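import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from microstab.compositional import (
    aitchison_distance,
    chord_transform,
    clr_transform,
    depth_robustness,
    normalize_metabolites,
    rarefy,
    stability_series,
    subject_stability_summary,
)
from microstab.io import FeatureTable, SampleMetadata


def _table(cols: dict, kind="counts"):
    df = pd.DataFrame(cols)
    df.index = [f"f{i}" for i in range(len(df))]
    return FeatureTable(df, kind=kind)


class TestCLR:
    def test_worked_example(self):
        # geometric mean of (1,2,4,8) is 2^1.5; clr = ln(x) - ln(gm)
        clr = clr_transform(_table({"s": [1, 2, 4, 8]}), pseudocount=0)
        np.testing.assert_allclose(
            clr["s"], [-1.0397, -0.3466, 0.3466, 1.0397], atol=1e-4
        )

    def test_uniform_composition_is_zero(self):
        clr = clr_transform(_table({"s": [2, 2, 2, 2]}), pseudocount=1)
        np.testing.assert_allclose(clr["s"], 0.0, atol=1e-12)

    def test_pseudocount_example(self):
        clr = clr_transform(_table({"s": [0, 1, 3]}), pseudocount=1)
        np.testing.assert_allclose(clr["s"], [-np.log(2), 0.0, np.log(2)], atol=1e-9)

    def test_zeros_require_pseudocount(self):
        with pytest.raises(ValueError, match="pseudocount"):
            clr_transform(_table({"s": [0, 1, 2]}), pseudocount=0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1000), min_size=2, max_size=30), st.integers(0, 10**6))
    def test_rows_sum_to_zero(self, counts, salt):
        rng = np.random.default_rng(salt)
        data = np.column_stack([counts, rng.integers(0, 1000, len(counts))])
        clr = clr_transform(
            FeatureTable(pd.DataFrame(data, index=[f"f{i}" for i in range(len(counts))],
                                      columns=["a", "b"])), 1.0)
        assert np.abs(clr.sum(axis=0).to_numpy()).max() < 1e-9


class TestChord:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ([3, 4], [0.6, 0.8]),
            ([1, 0, 0], [1, 0, 0]),
            ([2, 2, 2, 2], [0.5, 0.5, 0.5, 0.5]),
        ],
    )
    def test_examples(self, vec, expected):
        out = chord_transform(_table({"s": vec}))
        np.testing.assert_allclose(out["s"], expected, atol=1e-12)

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            chord_transform(_table({"s": [0, 0]}))


class TestAitchison:
    def test_worked_distance(self):
        d = aitchison_distance(_table({"x": [1, 2, 4, 8], "y": [8, 4, 2, 1]}), pseudocount=0)
        assert d["x", "y"] == pytest.approx(3.100, abs=5e-4)

    def test_scale_invariance(self, rng):
        x = rng.integers(1, 100, 12).astype(float)
        d = aitchison_distance(_table({"x": x, "y": 10 * x}, kind="abundance"), pseudocount=0)
        assert d["x", "y"] <= 1e-10

    def test_feature_permutation_invariance(self, rng):
        x = rng.integers(1, 50, 8)
        y = rng.integers(1, 50, 8)
        perm = rng.permutation(8)
        d1 = aitchison_distance(_table({"x": x, "y": y}), 0)["x", "y"]
        d2 = aitchison_distance(_table({"x": x[perm], "y": y[perm]}), 0)["x", "y"]
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_triangle_inequality(self, rng):
        t = FeatureTable(
            pd.DataFrame(rng.integers(0, 200, (15, 30)),
                         index=[f"f{i}" for i in range(15)],
                         columns=[f"s{j}" for j in range(30)]))
        d = aitchison_distance(t, 1.0)
        for _ in range(100):
            i, j, k = rng.choice(30, 3, replace=False)
            a, b, c = d.ids[i], d.ids[j], d.ids[k]
            assert d[a, c] <= d[a, b] + d[b, c] + 1e-9


class TestRarefy:
    def test_exhaustive_draw_unchanged(self):
        t = _table({"s": [3, 2, 5]})
        out = rarefy(t, 10, seed=0)
        np.testing.assert_array_equal(out.table.values[:, 0], [3, 2, 5])

    def test_under_depth_sample_dropped_and_reported(self):
        t = _table({"big": [50, 50], "small": [1, 1]})
        out = rarefy(t, 20, seed=0)
        assert out.dropped == ["small"]
        assert out.table.sample_ids == ["big"]

    def test_deterministic_and_total_preserved(self, rng):
        t = _table({"s": rng.integers(0, 100, 20)})
        a = rarefy(t, 200, seed=7).table.values
        b = rarefy(t, 200, seed=7).table.values
        np.testing.assert_array_equal(a, b)
        assert a.sum() == 200

    def test_expected_proportions_preserved(self):
        # mean over 1000 seeds within 3 SE of the input proportions
        t = _table({"s": [800, 150, 50]})
        draws = np.array([rarefy(t, 100, seed=s).table.values[:, 0] for s in range(1000)])
        mean = draws.mean(axis=0)
        p = np.array([0.8, 0.15, 0.05])
        # hypergeometric variance with finite-population correction
        var = 100 * p * (1 - p) * (1000 - 100) / (1000 - 1)
        se = np.sqrt(var / 1000)
        assert (np.abs(mean - 100 * p) <= 3 * se).all()


class TestStability:
    def _dist(self, toy_metadata):
        t = FeatureTable(
            pd.DataFrame(
                np.random.default_rng(3).integers(1, 500, (20, 8)),
                index=[f"f{i}" for i in range(20)],
                columns=toy_metadata.sample_ids,
            )
        )
        return aitchison_distance(t, 1.0)

    def test_record_count_and_intervals(self, toy_metadata):
        recs = stability_series(self._dist(toy_metadata), toy_metadata)
        per_a = [r for r in recs if r.subject_id == "A"]
        assert [(r.day_from, r.day_to) for r in per_a] == [(1, 7), (7, 14), (14, 78)]
        assert len(recs) == 6

    def test_stability_is_reciprocal(self, toy_metadata):
        recs = stability_series(self._dist(toy_metadata), toy_metadata)
        for r in recs:
            assert r.stability == pytest.approx(1.0 / r.distance)

    def test_single_sample_subject_warns(self, toy_metadata):
        d = self._dist(toy_metadata).filter(["A.d1", "A.d7", "B.d1"])
        with pytest.warns(UserWarning, match="B"):
            recs = stability_series(d, toy_metadata)
        assert {r.subject_id for r in recs} == {"A"}

    def test_subject_summary_means(self, toy_metadata):
        recs = stability_series(self._dist(toy_metadata), toy_metadata)
        summary = subject_stability_summary(recs)
        manual = np.mean([r.distance for r in recs if r.subject_id == "A"])
        assert summary.loc["A", "mean_distance"] == pytest.approx(manual)


class TestMetaboliteNormalization:
    def _meta(self, weights):
        samples = pd.DataFrame(
            {
                "subject_id": ["A", "B"],
                "group": ["placebo", "treatment"],
                "day": [1, 1],
                "fecal_weight": weights,
            },
            index=["s1", "s2"],
        )
        return SampleMetadata(samples)

    def test_per_gram_division(self):
        t = _table({"s1": [1000.0], "s2": [1000.0]}, kind="abundance")
        out = normalize_metabolites(t, self._meta([0.5, 1.0]))
        # ln(1+2000) vs ln(1+1000), centred
        expect = np.log1p([2000, 1000])
        expect = expect - expect.mean()
        np.testing.assert_allclose(out.loc["f0"], expect, atol=1e-12)

    def test_centering_property(self, rng):
        t = FeatureTable(
            pd.DataFrame(rng.uniform(0, 1e5, (10, 2)), columns=["s1", "s2"],
                         index=[f"f{i}" for i in range(10)]), kind="abundance")
        out = normalize_metabolites(t, self._meta([0.3, 0.6]))
        assert np.abs(out.mean(axis=1)).max() < 1e-9

    def test_missing_weight_errors(self):
        t = _table({"s1": [1.0], "s2": [1.0]}, kind="abundance")
        with pytest.raises(ValueError, match="fecal weight"):
            normalize_metabolites(t, self._meta([0.5, 0.0]))


class TestDepthRobustness:
    def test_perfect_monotonicity(self):
        # distances constructed as |delta depth| -> rho = 1
        depths = pd.Series([10.0, 20.0, 40.0, 80.0], index=list("abcd"))
        import skbio

        d = np.abs(depths.to_numpy()[:, None] - depths.to_numpy()[None, :])
        res = depth_robustness(skbio.DistanceMatrix(d, ids=list("abcd")), depths, 199, 0)
        assert res["rho"] == pytest.approx(1.0)
        assert res["p_value"] < 0.2  # only 4 samples; permutation floor

    def test_independent_depths_near_zero(self, rng):
        import skbio

        n = 25
        pts = rng.normal(0, 1, (n, 5))
        import scipy.spatial.distance as ssd

        d = skbio.DistanceMatrix(ssd.squareform(ssd.pdist(pts)), ids=[str(i) for i in range(n)])
        depths = pd.Series(rng.uniform(1e4, 5e4, n), index=d.ids)
        res = depth_robustness(d, depths, 199, 1)
        assert abs(res["rho"]) < 0.15
        assert res["p_value"] > 0.05

    def test_too_few_samples(self):
        import skbio

        d = skbio.DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"])
        with pytest.raises(ValueError, match="at least 3"):
            depth_robustness(d, pd.Series([1.0, 2.0], index=["a", "b"]))
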