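"""Absolute-position geometry recovery: means, regression, RSA, group MDS."""

import numpy as np
import pandas as pd
import pytest

from gazegeom import conceptspace as cs
from gazegeom import geomrec
from gazegeom.errors import (AlignmentError, DataError, DegenerateDataError,
                             UndefinedCorrelationError)


def _positions(rows):
    return pd.DataFrame(rows, columns=["word", "mean_x_px", "mean_y_px",
                                       "n_trials"])


class TestConceptMeanPositions:
    def test_single_trial_per_concept(self, make_trials):
        t = make_trials([(0, "1", 5, 6, 1), (0, "2", 7, 8, 1)])
        mp = geomrec.concept_mean_positions(t)
        assert mp.set_index("word").loc["1", "mean_x_px"] == 5

    def test_two_trials_average(self, make_trials):
        t = make_trials([(0, "1", 0, 0, 1), (0, "1", 10, 0, 1)])
        mp = geomrec.concept_mean_positions(t)
        assert mp.loc[0, "mean_x_px"] == 5.0

    def test_invalid_trials_excluded(self, make_trials):
        t = make_trials([(0, "1", 0, 0, 1), (0, "1", 100, 0, 0)])
        mp = geomrec.concept_mean_positions(t)
        assert mp.loc[0, "mean_x_px"] == 0.0

    def test_matches_groupby_oracle(self, make_trials):
        rng = np.random.default_rng(0)
        rows = [(0, str(rng.integers(1, 5)), rng.normal(), rng.normal(), 1)
                for _ in range(50)]
        t = make_trials(rows)
        mp = geomrec.concept_mean_positions(t).set_index("word")
        for w in set(r[1] for r in rows):
            xs = [r[2] for r in rows if r[1] == w]
            assert mp.loc[w, "mean_x_px"] == pytest.approx(np.mean(xs))
            assert mp.loc[w, "n_trials"] == len(xs)


class TestPositionRegression:
    values = {str(i): float(i) for i in range(1, 13)}

    def test_exact_fit_reproduces_coefficients(self):
        # construct positions exactly on a line with the reported mental
        # number line slope/intercept; OLS must recover them exactly
        rows = [(str(i), 873.94 + 6.46 * i, 0.0, 5) for i in range(1, 13)]
        slope, intercept = geomrec.position_regression(_positions(rows),
                                                       self.values, axis="x")
        assert slope == pytest.approx(6.46, abs=1e-10)
        assert intercept == pytest.approx(873.94, abs=1e-8)

    def test_flat_positions_zero_slope(self):
        rows = [(str(i), 400.0, 0.0, 5) for i in range(1, 13)]
        slope, _ = geomrec.position_regression(_positions(rows), self.values)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_two_points(self):
        rows = [("1", 0.0, 0.0, 1), ("2", 10.0, 0.0, 1)]
        slope, intercept = geomrec.position_regression(_positions(rows),
                                                       {"1": 1.0, "2": 2.0})
        assert (slope, intercept) == (pytest.approx(10.0), pytest.approx(-10.0))

    def test_single_concept_rejected(self):
        with pytest.raises(DegenerateDataError):
            geomrec.position_regression(_positions([("1", 0, 0, 1)]),
                                        {"1": 1.0})

    def test_group_regression_averages_subjects(self):
        tables = [_positions([(str(i), 10 * i, 0.0, 1) for i in range(1, 13)]),
                  _positions([(str(i), 20 * i, 0.0, 1) for i in range(1, 13)])]
        reg = geomrec.group_position_regression(tables, self.values)
        assert reg.slope == pytest.approx(15.0)
        assert np.allclose(reg.per_subject_slopes, [10.0, 20.0])


class TestDistanceMatrix:
    def test_three_four_five(self):
        t = _positions([("a", 0, 0, 1), ("b", 3, 0, 1), ("c", 0, 4, 1)])
        dm = geomrec.distance_matrix_from_points(t)
        assert dm.matrix[0, 1] == 3
        assert dm.matrix[0, 2] == 4
        assert dm.matrix[1, 2] == 5

    def test_identical_points_zero(self):
        t = _positions([("a", 1, 1, 1), ("b", 1, 1, 1)])
        assert np.allclose(geomrec.distance_matrix_from_points(t).matrix, 0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 2))
        t = _positions([(str(i), pts[i, 0], pts[i, 1], 1) for i in range(6)])
        dm = geomrec.distance_matrix_from_points(t)
        for i in range(6):
            for j in range(6):
                assert dm.matrix[i, j] == pytest.approx(
                    np.sqrt(((pts[i] - pts[j]) ** 2).sum()))


class TestRSA:
    def _random_dm(self, seed, n=6):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        return cs.DissimilarityMatrix(tuple(str(i) for i in range(n)), d)

    def test_identity_gives_unit_rho(self):
        dm = self._random_dm(0)
        rho, _ = geomrec.rsa_lower_triangle(dm, dm)
        assert rho == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        dm = self._random_dm(1)
        sq = cs.DissimilarityMatrix(dm.labels, dm.matrix ** 2)
        rho, _ = geomrec.rsa_lower_triangle(dm, sq)
        assert rho == pytest.approx(1.0)

    def test_matches_flat_lower_triangle_oracle(self):
        from scipy import stats
        a, b = self._random_dm(2), self._random_dm(3)
        rho, _ = geomrec.rsa_lower_triangle(a, b)
        i, j = np.tril_indices(6, k=-1)
        oracle = stats.spearmanr(a.matrix[i, j], b.matrix[i, j]).statistic
        assert rho == pytest.approx(float(oracle), abs=1e-12)

    def test_symmetric_in_arguments(self):
        a, b = self._random_dm(4), self._random_dm(5)
        assert geomrec.rsa_lower_triangle(a, b)[0] == pytest.approx(
            geomrec.rsa_lower_triangle(b, a)[0])

    def test_label_mismatch_rejected(self):
        a = self._random_dm(6)
        b = cs.DissimilarityMatrix(tuple("abcdef"), a.matrix)
        with pytest.raises(AlignmentError):
            geomrec.rsa_lower_triangle(a, b)

    def test_constant_triangle_rejected(self):
        ones = np.ones((5, 5)) - np.eye(5)
        other = self._random_dm(7, n=5)
        dm = cs.DissimilarityMatrix(other.labels, ones)
        with pytest.raises(UndefinedCorrelationError):
            geomrec.rsa_lower_triangle(dm, other)


class TestGroupGazeMDS:
    def _ring_dm(self, noise=0.0, seed=0, scale=1.0):
        rng = np.random.default_rng(seed)
        ang = 2 * np.pi * np.arange(12) / 12
        pts = scale * np.c_[np.cos(ang), np.sin(ang)]
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        if noise:
            e = rng.normal(0, noise * d.mean(), size=d.shape)
            d = np.abs(d + (e + e.T) / 2)
            np.fill_diagonal(d, 0)
        return cs.DissimilarityMatrix(tuple(str(i) for i in range(12)), d)

    def test_single_subject_equals_classical_mds(self):
        dm = self._ring_dm()
        norm = cs.DissimilarityMatrix(
            dm.labels, dm.matrix / dm.lower_triangle().mean())
        a = geomrec.group_gaze_mds([dm])
        b = cs.classical_mds(norm)
        assert np.allclose(a.coords, b.coords)

    def test_identical_subjects_match_single(self):
        # a ring's eigenvalues come in degenerate pairs, so the embedding
        # basis may rotate; compare shapes, not raw coordinates
        dm = self._ring_dm()
        a = geomrec.group_gaze_mds([dm, dm, dm])
        b = geomrec.group_gaze_mds([dm])
        assert geomrec.procrustes_disparity(a, b) < 1e-12

    def test_scale_normalization_makes_subject_scale_irrelevant(self):
        a = geomrec.group_gaze_mds([self._ring_dm(scale=1.0),
                                    self._ring_dm(scale=250.0)])
        b = geomrec.group_gaze_mds([self._ring_dm(scale=1.0)])
        assert geomrec.procrustes_disparity(a, b) < 1e-12

    def test_noisy_ring_cohort_recovers_ring(self):
        mats = [self._ring_dm(noise=0.05, seed=s) for s in range(20)]
        emb = geomrec.group_gaze_mds(mats)
        ang = 2 * np.pi * np.arange(12) / 12
        pts = np.c_[np.cos(ang), np.sin(ang)]
        truth = cs.Embedding2D(emb.labels, pts - pts.mean(axis=0))
        assert geomrec.procrustes_disparity(truth, emb) < 0.02

    def test_zero_matrix_skipped_with_warning(self):
        zero = cs.DissimilarityMatrix(self._ring_dm().labels,
                                      np.zeros((12, 12)))
        with pytest.warns(UserWarning):
            emb = geomrec.group_gaze_mds([self._ring_dm(), zero])
        assert np.allclose(emb.coords,
                           geomrec.group_gaze_mds([self._ring_dm()]).coords)

    def test_all_zero_rejected(self):
        zero = cs.DissimilarityMatrix(tuple(str(i) for i in range(12)),
                                      np.zeros((12, 12)))
        with pytest.warns(UserWarning):
            with pytest.raises(DataError):
                geomrec.group_gaze_mds([zero])


class TestProcrustes:
    def _emb(self, pts, labels=None):
        labels = labels or tuple(str(i) for i in range(len(pts)))
        return cs.Embedding2D(labels, np.asarray(pts, float))

    def test_self_disparity_zero(self):
        rng = np.random.default_rng(0)
        a = self._emb(rng.normal(size=(5, 2)))
        assert geomrec.procrustes_disparity(a, a) == pytest.approx(0.0)

    def test_isometry_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(7, 2))
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        refl = np.array([[1.0, 0.0], [0.0, -1.0]])
        moved = 3.1 * pts @ (rot @ refl).T + np.array([5.0, -2.0])
        assert geomrec.procrustes_disparity(self._emb(pts),
                                            self._emb(moved)) < 1e-12

    def test_matches_rotation_grid_oracle(self):
        """Exhaustive search over rotations/reflections and scales agrees
        with the closed-form solution on a small case."""
        a = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        b = np.array([[0.1, 0.0], [1.2, 0.3], [-0.2, 1.8]])
        an = (a - a.mean(0)) / np.linalg.norm(a - a.mean(0))
        bn = (b - b.mean(0)) / np.linalg.norm(b - b.mean(0))
        best = np.inf
        for th in np.linspace(0, 2 * np.pi, 100_000, endpoint=False):
            rot = np.array([[np.cos(th), -np.sin(th)],
                            [np.sin(th), np.cos(th)]])
            for flip in (1.0, -1.0):
                r = rot @ np.diag([1.0, flip])
                c = bn @ r.T
                s = np.sum(an * c)  # optimal scale for normalized configs
                best = min(best, np.sum((an - s * c) ** 2))
        ours = geomrec.procrustes_disparity(self._emb(a), self._emb(b))
        assert ours == pytest.approx(best, abs=1e-6)

    def test_degenerate_target_rejected(self):
        a = self._emb([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        b = self._emb([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(DegenerateDataError):
            geomrec.procrustes_disparity(a, b)
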