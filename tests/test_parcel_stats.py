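"""Parcel extraction, the ranking statistic, summary t tests, median
splits, fear-group analysis plumbing and map comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import seednets.parcel_stats as ps
from seednets.dual_regression import GroupFCMap


class TestExtractParcelZ:
    def _atlas(self):
        atlas = np.zeros((4, 4, 2), dtype=np.int32)
        atlas[:2, :2, :] = 1
        atlas[2:, :2, :] = 2
        atlas[:2, 2:, :] = 3
        lookup = pd.DataFrame([
            {"label": 1, "name": "a", "hemisphere": "L"},
            {"label": 2, "name": "a", "hemisphere": "R"},
            {"label": 3, "name": "b", "hemisphere": "L"},
        ])
        coords = np.argwhere(np.ones((4, 4, 2), dtype=bool))
        return atlas, lookup, coords

    def test_constant_map_gives_constant_means(self):
        atlas, lookup, coords = self._atlas()
        out = ps.extract_parcel_z(np.full(32, 3.5), coords, atlas, lookup)
        assert (out["mean_z"] == 3.5).all()
        assert set(out["hemisphere"]) == {"L", "R"}

    def test_single_voxel_region(self):
        atlas = np.zeros((2, 2, 1), dtype=np.int32)
        atlas[0, 0, 0] = 1
        lookup = pd.DataFrame([{"label": 1, "name": "solo", "hemisphere": "L"}])
        coords = np.argwhere(np.ones((2, 2, 1), dtype=bool))
        z = np.arange(4, dtype=float)
        out = ps.extract_parcel_z(z, coords, atlas, lookup)
        assert out["mean_z"].iloc[0] == z[0]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        atlas, lookup, coords = self._atlas()
        z = rng.standard_normal(32)
        out = ps.extract_parcel_z(z, coords, atlas, lookup).set_index("label")
        flat = atlas[coords[:, 0], coords[:, 1], coords[:, 2]]
        for lab in (1, 2, 3):
            assert out.loc[lab, "mean_z"] == pytest.approx(
                z[flat == lab].mean(), abs=1e-12)

    def test_unknown_label_errors_and_empty_label_omitted(self):
        atlas, lookup, coords = self._atlas()
        with pytest.raises(ValueError, match="missing"):
            ps.extract_parcel_z(np.zeros(32), coords, atlas, lookup.iloc[:2])
        lookup2 = pd.concat([lookup, pd.DataFrame(
            [{"label": 9, "name": "ghost", "hemisphere": "L"}])],
            ignore_index=True)
        out = ps.extract_parcel_z(np.zeros(32), coords, atlas, lookup2)
        assert "ghost" not in set(out["region"])


class TestRankNuclei:
    def test_hand_example(self):
        Z = np.array([[0.0, 2.0, 3.0],
                      [-2.0, 0.0, 1.0],
                      [-3.0, -1.0, 0.0]])
        out = ps.rank_nuclei(Z, ["n1", "n2", "n3"])
        assert np.allclose(out.all_sums.to_numpy(), [5.0, -1.0, -4.0])
        assert list(out.table["subregion"]) == ["n1"]
        assert list(out.table["rank"]) == [1]

    def test_zero_matrix_empty_ranking(self):
        out = ps.rank_nuclei(np.zeros((4, 4)), list("abcd"))
        assert out.table.empty

    def test_random_antisymmetric_conserved_and_sorted(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((9, 9))
        Z = A - A.T
        names = [f"n{i}" for i in range(9)]
        out = ps.rank_nuclei(Z, names)
        assert abs(out.all_sums.sum()) < 1e-10
        sums = Z.sum(axis=1)
        expected = [names[i] for i in np.argsort(-sums) if sums[i] > 0]
        assert list(out.table["subregion"]) == expected
        assert list(out.table["rank"]) == list(range(1, len(expected) + 1))

    def test_non_antisymmetric_rejected(self):
        with pytest.raises(ValueError, match="antisymmetric"):
            ps.rank_nuclei(np.ones((3, 3)), list("abc"))


class TestTwoSampleT:
    def test_group_summary_t(self):
        t, df, p = ps.two_sample_t(86, 44.0, 4.9, 86, 55.2, 4.5)
        assert df == 170
        assert abs(t) == pytest.approx(15.47, abs=0.2)
        assert p < 1e-4

    def test_identical_groups(self):
        t, df, _ = ps.two_sample_t(10, 1.0, 1.0, 10, 1.0, 1.0)
        assert t == 0.0

    def test_matches_raw_data_oracle(self):
        rng = np.random.default_rng(2)

        def sample(n, mean, sd):
            x = rng.standard_normal(n)
            x = (x - x.mean()) / x.std(ddof=1)
            return mean + sd * x

        a, b = sample(40, 3.0, 1.2), sample(35, 2.2, 0.9)
        t, df, p = ps.two_sample_t(40, 3.0, 1.2, 35, 2.2, 0.9)
        ref = sps.ttest_ind(a, b)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ps.two_sample_t(1, 0, 1, 10, 0, 1)
        with pytest.raises(ValueError):
            ps.two_sample_t(5, 0, 0, 5, 0, -1)


class TestMedianSplit:
    def test_ties_at_median_go_low(self):
        s = pd.Series([1.0, 2.0, 2.0, 3.0, 4.0])
        g = ps.median_split(s)
        assert list(g) == ["low", "low", "low", "high", "high"]

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError, match="median"):
            ps.median_split(pd.Series([2.0, 2.0, 2.0]))


class TestFearAnalysisPlumbing:
    def _table(self, n_part=172, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_part):
            pid = f"p{i:03d}"
            for h in "LR":
                for r in ("n1", "n2", "n3"):
                    for m in ("m1", "m2"):
                        rows.append(dict(participant_id=pid, hemisphere=h,
                                         region=r, fc_map=m,
                                         mean_z=rng.normal()))
        return pd.DataFrame(rows)

    def test_median_split_yields_balanced_groups(self):
        from seednets.synthetic import make_fear_scores
        table = self._table()
        scores = dict(zip(table["participant_id"].unique(),
                          make_fear_scores(172, rng_seed=1)))
        groups = ps.median_split(pd.Series(scores))
        assert (groups == "low").sum() == 86
        assert (groups == "high").sum() == 86

    def test_missing_scores_rejected(self):
        table = self._table(n_part=6)
        with pytest.raises(ValueError, match="missing"):
            ps.fear_group_analysis(table, {}, {}, {})

    def test_null_table_rarely_passes_gate(self):
        table = self._table(n_part=24, seed=3)
        ids = table["participant_id"].unique()
        rng = np.random.default_rng(4)
        scores = dict(zip(ids, rng.normal(50, 5, len(ids))))
        age = {i: "26-30" for i in ids}
        gender = dict(zip(ids, rng.choice(["F", "M"], len(ids))))
        out = ps.fear_group_analysis(table, scores, age, gender)
        # age band constant -> dropped without refitting errors
        assert out.age_dropped
        assert out.anova["term"].str.contains("group:region").any()


class TestCompareTestValidation:
    def _gmap(self, z):
        V = z.shape[1]
        return GroupFCMap(z=z, n_subjects=5,
                          voxel_coords=np.argwhere(np.ones((V, 1, 1),
                                                           dtype=bool)),
                          grid_shape=(V, 1, 1))

    def test_identical_maps_r_one(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal((2, 50))
        mask = np.ones((50, 1, 1), dtype=np.uint8)
        t = np.zeros((50, 1, 1), dtype=np.uint8)
        t[:10] = 1
        rs, _, _ = ps.compare_test_validation(self._gmap(z), self._gmap(z),
                                              [t], mask)
        assert np.allclose(rs, 1.0)

    def test_negated_maps_r_minus_one(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal((1, 50))
        mask = np.ones((50, 1, 1), dtype=np.uint8)
        t = np.zeros((50, 1, 1), dtype=np.uint8)
        t[:10] = 1
        rs, _, _ = ps.compare_test_validation(self._gmap(z), self._gmap(-z),
                                              [t], mask)
        assert rs[0] == pytest.approx(-1.0)

    def test_grid_mismatch(self):
        rng = np.random.default_rng(7)
        a = self._gmap(rng.standard_normal((1, 50)))
        b = self._gmap(rng.standard_normal((1, 40)))
        with pytest.raises(ValueError, match="grid|component"):
            ps.compare_test_validation(a, b, [], np.ones((50, 1, 1)))
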