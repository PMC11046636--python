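"""Conceptual distance models and classical MDS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazegeom import conceptspace as cs
from gazegeom import geomrec
from gazegeom.errors import DataError, DegenerateDataError


def _judgments(rows):
    return pd.DataFrame(rows, columns=["subject", "day", "word_a", "word_b",
                                       "rating"])


class TestSignedNumberChange:
    def test_four_to_ten_is_plus_six(self):
        assert cs.signed_number_change(["4", "10"]).values.tolist() == [6.0]

    def test_constant_sequence_zero(self):
        assert cs.signed_number_change(["7", "7", "7"]).values.tolist() == [0, 0]

    def test_twelve_to_one(self):
        assert cs.signed_number_change(["12", "1"]).values.tolist() == [-11.0]

    def test_unparseable_word_named_in_error(self):
        with pytest.raises(DataError, match="banana"):
            cs.signed_number_change(["3", "banana"])


class TestDissimilarityFromJudgments:
    def test_constant_rating_two(self):
        rows = [("s", 0, "a", "b", 2), ("s", 1, "b", "a", 2)]
        dm = cs.dissimilarity_from_judgments(_judgments(rows))
        assert dm.matrix[0, 1] == 8.0

    def test_all_nines_give_one(self):
        rows = [("s", 0, a, b, 9) for a, b in [("a", "b"), ("a", "c"), ("b", "c")]]
        dm = cs.dissimilarity_from_judgments(_judgments(rows))
        off = dm.matrix[~np.eye(3, dtype=bool)]
        assert np.all(off == 1.0)

    def test_orderings_and_reps_averaged(self):
        rows = [("s", 0, "a", "b", 3), ("s", 1, "b", "a", 5)]
        dm = cs.dissimilarity_from_judgments(_judgments(rows))
        assert dm.matrix[0, 1] == 6.0

    def test_missing_pair_listed(self):
        rows = [("s", 0, "a", "b", 4)]
        with pytest.raises(DataError, match=r"\(a, c\)"):
            cs.dissimilarity_from_judgments(_judgments(rows),
                                            labels=["a", "b", "c"])

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(0)
        labels = list("abcde")
        rows = [("s", r, a, b, int(rng.integers(1, 10)))
                for r in range(2) for i, a in enumerate(labels)
                for b in labels[i + 1:]]
        dm = cs.dissimilarity_from_judgments(_judgments(rows))
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.allclose(np.diag(dm.matrix), 0)


class TestClassicalMDS:
    def test_zero_matrix_collapses_to_origin(self):
        dm = cs.DissimilarityMatrix(("a", "b", "c"), np.zeros((3, 3)))
        with pytest.warns(UserWarning):
            emb = cs.classical_mds(dm)
        assert np.allclose(emb.coords, 0)

    def test_ring_chords_recover_circle(self):
        ang = 2 * np.pi * np.arange(12) / 12
        pts = np.c_[np.cos(ang), np.sin(ang)]
        chord = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = tuple(str(i) for i in range(12))
        emb = cs.classical_mds(cs.DissimilarityMatrix(labels, chord))
        truth = cs.Embedding2D(labels, pts - pts.mean(axis=0))
        assert geomrec.procrustes_disparity(truth, emb) < 1e-6

    def test_additive_line_is_collinear_with_unit_spacing(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        with pytest.warns(UserWarning):  # a line has one positive eigenvalue
            emb = cs.classical_mds(cs.DissimilarityMatrix(("a", "b", "c"), d))
        assert np.allclose(emb.coords[:, 1], 0, atol=1e-6)
        x = np.sort(emb.coords[:, 0])
        assert np.allclose(np.diff(x), 1.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_recovers_random_planar_configs_up_to_isometry(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        pts = rng.normal(size=(n, 2)) * rng.uniform(0.5, 20)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = tuple(str(i) for i in range(n))
        emb = cs.classical_mds(cs.DissimilarityMatrix(labels, d))
        truth = cs.Embedding2D(labels, pts - pts.mean(axis=0))
        assert geomrec.procrustes_disparity(truth, emb) < 1e-8

    def test_agrees_with_pcoa_oracle(self):
        """Independent cross-check against scikit-bio's principal
        coordinate analysis on a random Euclidean matrix."""
        from skbio.stats.ordination import pcoa
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = tuple(str(i) for i in range(8))
        ours = cs.classical_mds(cs.DissimilarityMatrix(labels, d))
        ref = pcoa(d, number_of_dimensions=2).samples.to_numpy()
        assert geomrec.procrustes_disparity(
            ours, cs.Embedding2D(labels, ref - ref.mean(axis=0))) < 1e-10


class TestMdsDistanceSeries:
    emb = cs.Embedding2D(("red", "cyan", "lime"),
                         np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0]]))

    def test_same_word_zero(self):
        s = cs.mds_distance_series(["red", "red"], self.emb)
        assert s.values.tolist() == [0.0]

    def test_antipodal_pair(self):
        s = cs.mds_distance_series(["red", "cyan"], self.emb)
        assert s.values.tolist() == [2.0]

    def test_matches_pairwise_lookup_oracle(self):
        rng = np.random.default_rng(1)
        words = [self.emb.labels[i] for i in rng.integers(0, 3, size=10)]
        s = cs.mds_distance_series(words, self.emb)
        for k, (a, b) in enumerate(zip(words, words[1:])):
            d = np.linalg.norm(self.emb.coord_of(a) - self.emb.coord_of(b))
            assert s.values[k] == pytest.approx(d)

    def test_unknown_word_rejected(self):
        with pytest.raises(DataError, match="blue"):
            cs.mds_distance_series(["red", "blue"], self.emb)


class TestAnimalDistances:
    def test_cluster_jump_binary(self):
        res = {"clusters": {"dog": {"pets"}, "cat": {"pets"},
                            "eagle": {"birds"}}}
        s = cs.animal_distance_series(["dog", "cat", "eagle"], "cluster", res)
        assert s.values.tolist() == [0.0, 1.0]

    def test_graded_cluster_counts_shared_labels(self):
        res = {"clusters": {"dog": {"pets", "canines"}, "wolf": {"canines"},
                            "eagle": {"birds"}}}
        s = cs.animal_distance_series(["dog", "wolf", "eagle"], "cluster",
                                      res, graded_cluster=True)
        assert s.values.tolist() == [-1.0, 0.0]

    def test_frequency_unsigned_difference(self):
        res = {"frequency": {"a": 100, "b": 80, "c": 1}}
        s = cs.animal_distance_series(["a", "b", "c"], "frequency", res)
        assert s.values.tolist() == [20.0, 79.0]

    def test_cosine_identical_and_orthogonal(self):
        res = {"vectors": {"a": [1, 0], "b": [2, 0], "c": [0, 5]}}
        s = cs.animal_distance_series(["a", "b", "c"], "cosine", res)
        assert s.values == pytest.approx([0.0, 1.0])

    def test_cosine_zero_norm_rejected(self):
        res = {"vectors": {"a": [1, 0], "b": [0, 0]}}
        with pytest.raises(DataError):
            cs.animal_distance_series(["a", "b"], "cosine", res)

    def test_external_similarity_ten_minus(self):
        sim = pd.DataFrame([[9.0, 3.0], [3.0, 9.0]],
                           index=["a", "b"], columns=["a", "b"])
        s = cs.animal_distance_series(["a", "b"], "external_similarity",
                                      {"similarity": sim})
        assert s.values.tolist() == [7.0]

    def test_missing_words_listed(self):
        with pytest.raises(DataError, match="fox"):
            cs.animal_distance_series(["dog", "fox"], "frequency",
                                      {"frequency": {"dog": 1.0}})

    def test_resource_order_irrelevant(self):
        """Distance models are invariant to permuting the resource tables."""
        rng = np.random.default_rng(2)
        words = list("abcdef")
        vecs = {w: rng.normal(size=4) for w in words}
        seq = [words[i] for i in rng.integers(0, 6, size=12)]
        fwd = cs.animal_distance_series(seq, "pc1", {"vectors": vecs})
        rev = cs.animal_distance_series(
            seq, "pc1", {"vectors": dict(reversed(list(vecs.items())))})
        assert np.allclose(fwd.values, rev.values)


class TestPC1:
    def test_axis_aligned_points(self):
        vec = {"a": [0.0, 0.0], "b": [3.0, 0.0], "c": [7.0, 0.0]}
        p = cs.pc1_projection(vec)
        assert abs(p["b"] - p["a"]) == pytest.approx(3.0)
        assert abs(p["c"] - p["a"]) == pytest.approx(7.0)

    def test_two_points_pc1_equals_euclidean(self):
        vec = {"a": [0.0, 0.0, 0.0], "b": [3.0, 4.0, 0.0]}
        p = cs.pc1_projection(vec)
        assert abs(p["b"] - p["a"]) == pytest.approx(5.0)

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        labels = [f"w{i}" for i in range(20)]
        x = rng.normal(size=(20, 5)) @ np.diag([5, 3, 1, 1, 0.5])
        vec = {w: x[i] for i, w in enumerate(labels)}
        p = cs.pc1_projection(vec)
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(xc.T, bias=False))
        axis = evecs[:, np.argmax(evals)]
        oracle = xc @ axis
        ours = np.array([p[w] for w in labels])
        # sign of the axis is arbitrary; distances must agree exactly
        dist = lambda v: np.abs(v[:, None] - v[None, :])
        assert np.allclose(dist(ours), dist(oracle), atol=1e-10)

    def test_constant_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            cs.pc1_projection({"a": [1.0, 2.0], "b": [1.0, 2.0]})


class TestTransitionCounts:
    def test_exhaustive_count(self):
        (s,) = cs.transition_count_series([["1", "2", "1", "2"]])
        assert s.values.tolist() == [2.0, 1.0, 2.0]

    def test_unique_transitions_all_one(self):
        (s,) = cs.transition_count_series([["1", "2", "3", "4"]])
        assert s.values.tolist() == [1.0, 1.0, 1.0]

    def test_counts_pool_across_blocks(self):
        a, b = cs.transition_count_series([["1", "2"], ["1", "2"]])
        assert a.values.tolist() == [2.0] and b.values.tolist() == [2.0]
        assert b.index.tolist() == [2]

    def test_conservation(self):
        """Summing each distinct pair's count once recovers the number of
        transitions, and the annotations match a Counter oracle."""
        from collections import Counter
        rng = np.random.default_rng(4)
        seq = [str(i) for i in rng.integers(1, 5, size=30)]
        (s,) = cs.transition_count_series([seq])
        pairs = list(zip(seq, seq[1:]))
        counts = Counter(pairs)
        assert sum(counts.values()) == len(seq) - 1
        assert s.values.tolist() == [float(counts[p]) for p in pairs]


class TestWord2VecReader:
    def test_roundtrip(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("2 3\ndog 1.0 2.0 3.0\ncat -1.0 0.5 0.0\n")
        vec = cs.load_word2vec_text(path)
        assert np.allclose(vec["cat"], [-1.0, 0.5, 0.0])

    def test_header_mismatch_rejected(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("3 2\ndog 1 2\n")
        with pytest.raises(DataError):
            cs.load_word2vec_text(path)
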