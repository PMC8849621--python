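import math
import random

import numpy as np
import pandas as pd
import pytest

from morphoclade import morphometrics as mo

from . import oracles


class TestToothRatios:
    def test_equal_width_gives_cbr_one(self):
        r = mo.ToothRecord("x", "g", CBL=5, CBW=5, CH=12)
        assert mo.derive_tooth_ratios(r)[0] == 1.0

    def test_direct_arithmetic(self):
        r = mo.ToothRecord("x", "g", CBL=10, CBW=6, CH=25)
        cbr, chr_ = mo.derive_tooth_ratios(r)
        assert cbr == pytest.approx(0.6)
        assert chr_ == pytest.approx(2.5)

    def test_scale_invariance(self):
        mm = mo.ToothRecord("x", "g", CBL=10, CBW=6, CH=25)
        cm = mo.ToothRecord("x", "g", CBL=1.0, CBW=0.6, CH=2.5)
        assert mo.derive_tooth_ratios(mm) == pytest.approx(
            mo.derive_tooth_ratios(cm)
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mo.ToothRecord("x", "g", CBL=0, CBW=6, CH=25)


class TestDropIncomplete:
    def _records(self):
        return [
            mo.ToothRecord("a", "g", 10, 6, 25, AL=27.0),
            mo.ToothRecord("b", "g", 11, 7, 26),
            mo.ToothRecord("c", "g", 12, 8, 27, AL=30.0),
            mo.ToothRecord("d", "g", 13, 9, 28),
            mo.ToothRecord("e", "g", 14, 10, 29, AL=33.0),
        ]

    def test_no_missing_identity(self):
        recs = self._records()
        assert mo.drop_incomplete(recs, ["CBL", "CBW"]) == recs

    def test_two_missing_al(self):
        kept = mo.drop_incomplete(self._records(), ["AL"])
        assert [r.specimen_id for r in kept] == ["a", "c", "e"]

    def test_idempotent(self):
        recs = self._records()
        once = mo.drop_incomplete(recs, ["AL"])
        assert mo.drop_incomplete(once, ["AL"]) == once

    def test_nan_counts_as_missing(self):
        df = pd.DataFrame({"AL": [1.0, float("nan")], "CBL": [1.0, 2.0]})
        kept = mo.drop_incomplete([r for _, r in df.iterrows()], ["AL"])
        assert len(kept) == 1


class TestRunPca:
    def test_collinear_pc1_is_everything(self):
        df = pd.DataFrame({"X": [1.0, 2, 3, 4], "Y": [2.0, 4, 6, 8]})
        res = mo.run_pca(df, ["X", "Y"])
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_closed_form_two_by_two(self):
        # cov = [[4, 2], [2, 3]]; eigenvalues (7 +/- sqrt(17)) / 2
        rng = np.random.default_rng(5)
        A = np.linalg.cholesky(np.array([[4.0, 2.0], [2.0, 3.0]]))
        X = rng.standard_normal((2000, 2)) @ A.T
        df = pd.DataFrame(X, columns=["u", "v"])
        res = mo.run_pca(df, ["u", "v"])
        cov = np.cov(X.T, ddof=1)
        tr, det = cov.trace(), np.linalg.det(cov)
        lam1 = (tr + math.sqrt(tr * tr - 4 * det)) / 2
        lam2 = (tr - math.sqrt(tr * tr - 4 * det)) / 2
        assert res.eigenvalues[0] == pytest.approx(lam1)
        assert res.eigenvalues[1] == pytest.approx(lam2)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            rng.random((30, 4)) + 1, columns=list("wxyz")
        )
        for scaling in mo.SCALINGS:
            res = mo.run_pca(df, list("wxyz"), scaling)
            assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
            assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_scores_uncorrelated(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.random((40, 3)) + 1, columns=list("abc"))
        res = mo.run_pca(df, list("abc"))
        sc = res.scores[["PC1", "PC2", "PC3"]].to_numpy()
        cov = np.cov(sc.T, ddof=1)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-9 * res.eigenvalues[0]

    def test_row_and_column_order_invariance(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.random((25, 3)) + 1, columns=list("abc"))
        base = mo.run_pca(df, ["a", "b", "c"])
        shuffled = mo.run_pca(df.sample(frac=1, random_state=1), ["a", "b", "c"])
        reordered = mo.run_pca(df, ["c", "a", "b"])
        assert np.allclose(base.eigenvalues, shuffled.eigenvalues)
        assert np.allclose(base.eigenvalues, reordered.eigenvalues)

    def test_global_rescale_leaves_fractions(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.random((20, 3)) + 1, columns=list("abc"))
        res1 = mo.run_pca(df, list("abc"))
        res2 = mo.run_pca(df * 10.0, list("abc"))
        assert np.allclose(res2.eigenvalues, 100.0 * res1.eigenvalues)
        assert np.allclose(res2.variance_fractions, res1.variance_fractions)

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"a": [1.0, None, 3.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="drop_incomplete"):
            mo.run_pca(df, ["a", "b"])

    def test_too_few_records(self):
        df = pd.DataFrame({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError):
            mo.run_pca(df, ["a", "b"])

    def test_zero_variance_under_correlation(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            mo.run_pca(df, ["a", "b"], "correlation")


class TestLoadingSignReport:
    def test_rank_one_all_same_sign(self):
        df = pd.DataFrame({"X": [1.0, 2, 3, 4], "Y": [3.0, 6, 9, 12]})
        res = mo.run_pca(df, ["X", "Y"])
        report = mo.loading_sign_report(res, 1)
        assert {v[0] for v in report.values()} == {"positive"}

    def test_anticorrelated_variable_flips_sign(self):
        t = np.linspace(1, 5, 30)
        df = pd.DataFrame({"X": t, "Y": 2 * t, "Z": 10 - t})
        res = mo.run_pca(df, ["X", "Y", "Z"])
        report = mo.loading_sign_report(res, 1)
        assert report["X"][0] == "positive"
        assert report["Y"][0] == "positive"
        assert report["Z"][0] == "negative"

    def test_component_out_of_range(self):
        df = pd.DataFrame({"X": [1.0, 2], "Y": [2.0, 1]})
        res = mo.run_pca(df, ["X", "Y"])
        with pytest.raises(ValueError):
            mo.loading_sign_report(res, 3)


class TestHullMembership:
    def _scores(self, pts, ids, group="g"):
        df = pd.DataFrame(pts, columns=["PC1", "PC2"], index=ids)
        df["group"] = group
        return df

    def test_member_point_inside(self):
        df = self._scores([(0, 0), (2, 0), (0, 2)], list("abc"))
        assert mo.hull_membership(df, "g", "a") == "inside"

    def test_far_point_outside(self):
        df = self._scores([(0, 0), (1, 0), (0, 1), (2, 2)], list("abcq"))
        df.loc["q", "group"] = "other"
        assert mo.hull_membership(df, "g", "q") == "outside"

    def test_half_plane_check_by_hand(self):
        df = self._scores([(0, 0), (2, 0), (0, 2), (0.5, 0.5)], list("abcq"))
        df.loc["q", "group"] = "other"
        assert mo.hull_membership(df, "g", "q") == "inside"

    def test_degenerate_falls_back_to_interval(self):
        df = self._scores([(0, 0), (1, 0), (2, 0), (1.5, 0)], list("abcq"))
        df.loc["q", "group"] = "other"
        res = mo.hull_membership(df, "g", "q")
        assert res.method == "pc1-interval"
        assert res == "inside"

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_half_plane_oracle(self, seed):
        rng = np.random.default_rng(900 + seed)
        pts = rng.random((rng.integers(4, 9), 2)) * 4
        q = rng.random(2) * 4
        ids = [f"p{i}" for i in range(len(pts))] + ["q"]
        df = pd.DataFrame(
            np.vstack([pts, q]), columns=["PC1", "PC2"], index=ids
        )
        df["group"] = ["g"] * len(pts) + ["query"]
        expected = oracles.convex_hull_membership(pts, q)
        got = mo.hull_membership(df, "g", "q")
        assert (got.status == "inside") == expected


class TestAlveolusProfiles:
    def _rec(self, pos, md, ll, hlab, hlin, spec="s1"):
        return mo.AlveolusRecord(spec, pos, md, ll, hlab, hlin)

    def test_equal_diameters_ratio_one(self):
        prof = mo.alveolus_profiles([self._rec(1, 5, 5, 10, 14)], "s1")
        assert prof.loc[1, "compression_ratio"] == pytest.approx(1.0)
        assert prof.loc[1, "mean_height"] == pytest.approx(12.0)

    def test_positions_sorted(self):
        recs = [self._rec(3, 5, 4, 10, 10), self._rec(1, 5, 5, 9, 9)]
        prof = mo.alveolus_profiles(recs, "s1")
        assert list(prof.index) == [1, 3]

    def test_duplicate_positions_rejected(self):
        recs = [self._rec(2, 5, 4, 10, 10), self._rec(2, 5, 5, 9, 9)]
        with pytest.raises(ValueError, match="duplicate"):
            mo.alveolus_profiles(recs, "s1")

    def test_other_specimens_ignored(self):
        recs = [self._rec(1, 5, 4, 10, 10), self._rec(1, 6, 6, 9, 9, spec="s2")]
        prof = mo.alveolus_profiles(recs, "s1")
        assert len(prof) == 1

    def test_extreme_compression_position(self):
        # narrowest (most compressed) socket has the lowest ratio
        recs = [
            self._rec(1, 10, 9, 30, 32),
            self._rec(2, 10, 8, 31, 33),
            self._rec(3, 10, 5, 32, 34),
            self._rec(4, 10, 9, 33, 35),
        ]
        prof = mo.alveolus_profiles(recs, "s1")
        assert prof["compression_ratio"].idxmin() == 3


class TestNearestSpecimen:
    def test_exact_match(self):
        data = [("s1", 30.0, 100.0), ("s2", 60.0, 50.0)]
        assert mo.nearest_specimen(data, (60.0, 50.0)) == "s2"

    def test_hand_computed(self):
        # after z-scoring, q is closest to s2
        data = [("s1", 10.0, 10.0), ("s2", 20.0, 20.0), ("s3", 30.0, 40.0)]
        pts = np.array([[10, 10], [20, 20], [30, 40]], dtype=float)
        q = np.array([22.0, 24.0])
        mean, sd = pts.mean(0), pts.std(0)
        z = (pts - mean) / sd
        zq = (q - mean) / sd
        expected = ["s1", "s2", "s3"][int(np.argmin(((z - zq) ** 2).sum(1)))]
        assert mo.nearest_specimen(data, (22.0, 24.0)) == expected

    def test_tie_breaks_to_earlier_row(self):
        data = [("s1", 10.0, 20.0), ("s2", 30.0, 20.0)]
        assert mo.nearest_specimen(data, (20.0, 20.0)) == "s1"

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            mo.nearest_specimen([], (1.0, 1.0))

    def test_standardization_matters(self):
        # raw distance favours s1; standardized favours s2
        data = [("s1", 30.0, 100.0), ("s2", 31.0, 500.0)]
        q = (31.0, 120.0)
        assert mo.nearest_specimen(data, q, standardize=False) == "s1"
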