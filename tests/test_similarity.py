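"""Similarity computations against independent oracles and hand values."""

import numpy as np
import pytest
from Bio import Align

from mdassoc import graph_data as gd
from mdassoc import similarity as sim

R = gd.SequenceRecord


# -- independent alignment oracles ------------------------------------------


def _global_score(u: str, v: str) -> int:
    """Needleman-Wunsch global score (match +1, mismatch -1, linear gap -2)."""
    prev = [-2 * j for j in range(len(v) + 1)]
    for i in range(1, len(u) + 1):
        cur = [-2 * i] + [0] * len(v)
        for j in range(1, len(v) + 1):
            s = 1 if u[i - 1] == v[j - 1] else -1
            cur[j] = max(prev[j - 1] + s, prev[j] - 2, cur[j - 1] - 2)
        prev = cur
    return prev[-1]


def exhaustive_local_score(a: str, b: str) -> int:
    """Best local score by exhaustively aligning every substring pair globally."""
    best = 0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, _global_score(a[i1:i2], b[j1:j2]))
    return best


def _biopython_local(a: str, b: str) -> int:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return int(aligner.score(a, b))


class TestLocalAlignment:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACGT", 4),  # identity: 4 matches
            ("AAAA", "TTTT", 0),  # all mismatches floor at zero
            ("ACGT", "ACGG", 3),  # best local block ACG
        ],
    )
    def test_hand_cases(self, a, b, expected):
        assert sim.local_align_score(R("a", a), R("b", b)) == expected

    def test_matches_exhaustive_oracle_on_short_pairs(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        for _ in range(40):
            a = "".join(rng.choice(bases, size=rng.integers(1, 9)))
            b = "".join(rng.choice(bases, size=rng.integers(1, 9)))
            assert sim.local_align_score(R("a", a), R("b", b)) == exhaustive_local_score(a, b)

    def test_matches_biopython_on_longer_pairs(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        for _ in range(20):
            a = "".join(rng.choice(bases, size=60))
            b = "".join(rng.choice(bases, size=70))
            assert sim.local_align_score(R("a", a), R("b", b)) == _biopython_local(a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            gd.SequenceRecord("x", "")


class TestSequenceSimilarity:
    def test_identity_is_one(self):
        assert sim.sequence_similarity(R("a", "ACGTAC"), R("b", "ACGTAC")) == 1.0

    def test_disjoint_is_zero(self):
        assert sim.sequence_similarity(R("a", "AAAA"), R("b", "TTTT")) == 0.0

    def test_hand_normalization(self):
        # sw=3, self scores 4 and 4 -> 3/sqrt(16)
        assert sim.sequence_similarity(R("a", "ACGT"), R("b", "ACGG")) == pytest.approx(0.75)

    def test_matrix_symmetric_unit_diagonal(self, small_mss):
        v = small_mss.values
        assert np.abs(v - v.T).max() < 1e-12
        np.testing.assert_allclose(np.diag(v), 1.0)

    def test_matrix_separates_blocks(self, small_dataset, small_mss):
        mb = small_dataset.microbe_blocks
        same = mb[:, None] == mb[None, :]
        np.fill_diagonal(same, False)
        off = ~same & ~np.eye(len(mb), dtype=bool)
        assert small_mss.values[same].mean() > 2 * small_mss.values[off].mean()


class TestGip:
    def test_bandwidth_closed_form(self):
        params = sim.gip_bandwidth(np.array([[1.0, 0.0], [0.0, 1.0]]), gamma_prime=1.0)
        assert params.gamma == pytest.approx(1.0)

    def test_bandwidth_identical_profiles(self):
        profiles = np.tile([1, 1, 1, 0], (5, 1)).astype(float)
        assert sim.gip_bandwidth(profiles).gamma == pytest.approx(1 / 3)

    def test_zero_profiles_error(self):
        with pytest.raises(ValueError, match="bandwidth undefined"):
            sim.gip_bandwidth(np.zeros((3, 4)))

    def test_orthogonal_profiles_value(self):
        profiles = np.array([[1.0, 0.0], [0.0, 1.0]])
        m = sim.gip_similarity(profiles, sim.GipParams(1.0, 1.0))
        assert m.values[0, 1] == pytest.approx(np.exp(-2), abs=1e-9)

    def test_identical_profiles_offdiagonal_one(self):
        profiles = np.tile([1, 0, 1], (4, 1)).astype(float)
        m = sim.gip_similarity(profiles, sim.gip_bandwidth(profiles))
        np.testing.assert_allclose(m.values, 1.0)

    def test_positive_semidefinite(self, rng):
        for _ in range(5):
            profiles = (rng.random((8, 6)) < 0.4).astype(float)
            profiles[0] = 1  # keep at least one nonzero profile
            m = sim.gip_similarity(profiles, sim.gip_bandwidth(profiles))
            eig = np.linalg.eigvalsh(m.values)
            assert eig.min() >= -1e-8

    def test_permutation_invariance(self, rng):
        profiles = (rng.random((7, 5)) < 0.5).astype(float)
        profiles[0, 0] = 1
        perm = rng.permutation(7)
        base = sim.gip_similarity(profiles, sim.gip_bandwidth(profiles)).values
        permuted = sim.gip_similarity(profiles[perm], sim.gip_bandwidth(profiles[perm])).values
        np.testing.assert_allclose(permuted, base[np.ix_(perm, perm)], atol=1e-12)


class TestFuseSmoothBinarize:
    def _m(self, values, kind="gip"):
        ids = [f"n{i}" for i in range(len(values))]
        return sim.SimilarityMatrix(np.asarray(values, float), ids, kind=kind)

    def test_fuse_branches(self):
        primary = self._m([[1.0, 0.4, 0.0], [0.4, 1.0, 0.0], [0.0, 0.0, 1.0]])
        gip = self._m([[1.0, 0.2, 0.2], [0.2, 1.0, 0.2], [0.2, 0.2, 1.0]])
        fused = sim.fuse(primary, gip)
        assert fused.values[0, 1] == pytest.approx(0.3)  # average branch
        assert fused.values[0, 2] == pytest.approx(0.2)  # gip fallback branch

    def test_fuse_fixed_point(self):
        gip = self._m([[1.0, 0.5], [0.5, 1.0]])
        np.testing.assert_allclose(sim.fuse(gip, gip).values, gip.values)

    def test_fuse_id_mismatch(self):
        a = self._m([[1.0]])
        b = sim.SimilarityMatrix(np.array([[1.0]]), ["other"], kind="gip")
        with pytest.raises(ValueError, match="id orders"):
            sim.fuse(a, b)

    def test_smooth_window_one_is_identity(self):
        m = self._m([[1.0, 0.3], [0.3, 1.0]])
        np.testing.assert_allclose(sim.smooth_rows(m, 1).values, m.values)

    def test_smooth_truncated_window_hand_case(self):
        m = sim.SimilarityMatrix(
            np.array([[0.0, 1.0, 0.0]] * 3), [f"n{i}" for i in range(3)], kind="smoothed"
        )
        out = sim.smooth_rows(m, 3)
        np.testing.assert_allclose(out.values[0], [0.5, 1 / 3, 0.5])

    def test_smooth_constant_rows_unchanged(self):
        m = sim.SimilarityMatrix(np.full((5, 5), 0.6), [f"n{i}" for i in range(5)],
                                 kind="smoothed")
        np.testing.assert_allclose(sim.smooth_rows(m, 5).values, 0.6)

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_smooth_rejects_even_or_nonpositive(self, window):
        m = self._m([[1.0, 0.3], [0.3, 1.0]])
        with pytest.raises(ValueError):
            sim.smooth_rows(m, window)

    def test_binarize_basic_and_threshold_edge(self):
        m = self._m([[0.9, 0.3], [0.3, 0.9]])
        assert sim.binarize(m, 0.8).values.tolist() == [[1.0, 0.0], [0.0, 1.0]]
        assert sim.binarize(m, 0.95).values.sum() == 0

    @pytest.mark.parametrize("threshold", [0.0, 1.5, -0.1])
    def test_binarize_threshold_domain(self, threshold):
        with pytest.raises(ValueError):
            sim.binarize(self._m([[1.0]]), threshold)

    def test_binarize_after_identity_smooth_commutes(self, rng):
        vals = rng.random((6, 6))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        m = self._m(vals, kind="fused")
        lhs = sim.binarize(sim.smooth_rows(m, 1), 0.5).values
        rhs = sim.binarize(m, 0.5).values
        np.testing.assert_array_equal(lhs, rhs)

    def test_binarize_monotone_in_threshold(self, rng):
        vals = rng.random((8, 8))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        m = self._m(vals, kind="fused")
        previous = None
        for th in (0.2, 0.4, 0.6, 0.8, 1.0):
            edges = sim.binarize(m, th).values
            if previous is not None:
                assert (edges <= previous).all()  # raising threshold never adds edges
            previous = edges


class TestFeatureGraph:
    def test_feature_width_is_sum_of_sides(self, small_dataset, block_graph):
        mg, dg, _, _ = block_graph
        n_m, n_d = small_dataset.associations.values.shape
        assert mg.features.shape == (n_m, n_m + n_d)
        assert dg.features.shape == (n_d, n_d + n_m)

    def test_zero_associations_leave_profile_zero(self, small_mss):
        n_m = small_mss.n
        assoc = gd.AssociationMatrix(
            np.zeros((n_m, 4), dtype=np.int8), list(small_mss.ids), list("wxyz")
        )
        binar = sim.binarize(small_mss, 0.99)
        graph = sim.build_feature_graph(binar, small_mss, assoc, "microbe")
        assert (graph.features[:, n_m:] == 0).all()

    def test_block_adjacency_dominance(self, small_dataset, block_graph):
        mg, _, _, _ = block_graph
        mb = small_dataset.microbe_blocks
        same = mb[:, None] == mb[None, :]
        np.fill_diagonal(same, False)
        off = ~same & ~np.eye(len(mb), dtype=bool)
        assert mg.adjacency[same].mean() > mg.adjacency[off].mean()

    def test_self_edges_always_kept(self, block_graph):
        mg, dg, _, _ = block_graph
        assert np.diag(mg.adjacency).min() == 1.0
        assert np.diag(dg.adjacency).min() == 1.0
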