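"""Unit-vector aligner: URMS, similarity matrix, DP, superposition, MaxSub."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rna3dcons.sara import (AlignmentPath, align_pair, build_similarity_matrix,
                            global_align, global_align_score, maxsub_refine,
                            random_window_urms, superpose, unit_vector_profile,
                            urms_distance)
from rna3dcons.scoring import score_alignment
from rna3dcons.synthetic import (HomologParams, derive_homolog,
                                 generate_decoy_set)


def random_profile(n_res, seed):
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_res - 1, 3)) * 2.0 + np.array([5.0, 0.0, 0.0])
    coords = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
    return unit_vector_profile(coords)


def random_window(length, seed):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(length, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestUnitVectorProfile:
    def test_single_step(self):
        prof = unit_vector_profile(np.array([[0.0, 0, 0], [0, 0, 2]]))
        np.testing.assert_allclose(prof.vectors, [[0, 0, 1]])
        assert prof.n_res == 2

    def test_collinear_points(self):
        prof = unit_vector_profile(np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]))
        np.testing.assert_allclose(prof.vectors, [[1, 0, 0], [1, 0, 0]])

    def test_all_norms_unit(self):
        prof = random_profile(50, seed=2)
        np.testing.assert_allclose(np.linalg.norm(prof.vectors, axis=1), 1.0,
                                   atol=1e-9)

    def test_zero_step_raises(self):
        with pytest.raises(ValueError, match="zero-length"):
            unit_vector_profile(np.array([[0.0, 0, 0], [0, 0, 0], [1, 0, 0]]))


def brute_force_urms(wA, wB):
    """Rotation search on an Euler-angle grid refined to 0.5 degrees."""
    def cost(matrices):
        rot = np.einsum("rij,kj->rki", matrices, wB)
        return np.sqrt(np.mean(np.sum((wA[None] - rot) ** 2, axis=2), axis=1))

    coarse = np.array(list(itertools.product(
        np.arange(0, 360, 6.0), np.arange(0, 180.001, 6.0),
        np.arange(0, 360, 6.0))))
    c = cost(Rotation.from_euler("zyz", coarse, degrees=True).as_matrix())
    best = coarse[np.argmin(c)]
    fine_axes = [best[i] + np.arange(-6, 6.001, 0.5) for i in range(3)]
    fine = np.array(list(itertools.product(*fine_axes)))
    return float(cost(Rotation.from_euler("zyz", fine, degrees=True).as_matrix()).min())


class TestUrms:
    def test_identical_windows_zero(self):
        # sqrt amplification of float error bounds the achievable zero at ~1e-7
        w = random_window(6, seed=1)
        assert urms_distance(w, w) == pytest.approx(0.0, abs=1e-6)

    def test_rotated_copy_zero(self):
        w = random_window(6, seed=2)
        R = Rotation.from_euler("zyx", [31, -54, 100], degrees=True).as_matrix()
        assert urms_distance(w, w @ R.T) == pytest.approx(0.0, abs=1e-7)

    def test_symmetric(self):
        wA, wB = random_window(6, seed=3), random_window(6, seed=4)
        assert urms_distance(wA, wB) == pytest.approx(urms_distance(wB, wA),
                                                      abs=1e-9)

    def test_matches_rotation_grid_oracle(self):
        wA, wB = random_window(6, seed=7), random_window(6, seed=8)
        assert urms_distance(wA, wB) == pytest.approx(brute_force_urms(wA, wB),
                                                      abs=1e-3)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="equal"):
            urms_distance(random_window(5, 0), random_window(6, 0))


class TestSimilarityMatrix:
    def test_identical_profiles_diagonal_row_maximal(self):
        prof = random_profile(30, seed=5)
        S = build_similarity_matrix(prof, prof)
        interior = range(2, S.shape[0] - 3)
        for i in interior:
            assert S[i, i] == S[i].max()

    def test_matches_naive_reimplementation(self):
        # independent oracle: per-cell window extraction + LAPACK URMS
        pA, pB = random_profile(9, seed=70), random_profile(9, seed=71)
        S = build_similarity_matrix(pA, pB)
        A, B = pA.vectors, pB.vectors
        na, nb = len(A), len(B)
        for i in range(na):
            for j in range(nb):
                a = max(-2, -i, -j)
                b = min(3, na - 1 - i, nb - 1 - j)
                L = b - a + 1
                if L < 3:
                    expected = 0.0
                else:
                    u = urms_distance(A[i + a:i + b + 1], B[j + a:j + b + 1])
                    expected = max(0.0, 10.0 * (1.0 - u / random_window_urms(L)))
                assert S[i, j] == pytest.approx(expected, abs=1e-9)

    def test_scores_clamped_at_zero(self):
        pA, pB = random_profile(25, seed=9), random_profile(25, seed=10)
        S = build_similarity_matrix(pA, pB)
        assert S.min() >= 0.0

    def test_short_profile_raises(self):
        with pytest.raises(ValueError, match="4 unit vectors"):
            build_similarity_matrix(random_profile(4, 0), random_profile(20, 0))


def enumerate_alignment_optimum(S, gap_open, gap_extend):
    """Exhaustive search over all monotone paths with affine internal gaps."""
    n, m = S.shape
    best = 0.0  # empty alignment
    rows = range(n)
    cols = range(m)
    for k in range(1, min(n, m) + 1):
        for rsel in itertools.combinations(rows, k):
            for csel in itertools.combinations(cols, k):
                score = sum(S[r, c] for r, c in zip(rsel, csel))
                for (r1, c1), (r2, c2) in zip(zip(rsel, csel),
                                              zip(rsel[1:], csel[1:])):
                    dr = r2 - r1 - 1
                    dc = c2 - c1 - 1
                    if dr > 0:
                        score -= gap_open + (dr - 1) * gap_extend
                    if dc > 0:
                        score -= gap_open + (dc - 1) * gap_extend
                best = max(best, score)
    return best


def path_score(S, path, gap_open, gap_extend):
    score = sum(S[i, j] for i, j in path.pairs)
    for (i1, j1), (i2, j2) in zip(path.pairs, path.pairs[1:]):
        if i2 - i1 - 1 > 0:
            score -= gap_open + (i2 - i1 - 2) * gap_extend
        if j2 - j1 - 1 > 0:
            score -= gap_open + (j2 - j1 - 2) * gap_extend
    return score


class TestGlobalAlign:
    def test_matches_enumeration_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            n, m = rng.integers(2, 6, size=2)
            S = rng.integers(0, 10, size=(n, m)).astype(float)
            go, ge = 4.0, 0.2
            expected = enumerate_alignment_optimum(S, go, ge)
            assert global_align_score(S, go, ge) == pytest.approx(expected)
            path = global_align(S, go, ge)
            assert path_score(S, path, go, ge) == pytest.approx(expected)

    def test_identity_matrix_gives_diagonal(self):
        S = np.eye(6) * 10.0
        path = global_align(S)
        assert path.pairs == [(i, i) for i in range(6)]

    def test_all_zero_matrix_tie_breaks_to_diagonal(self):
        path = global_align(np.zeros((5, 5)))
        assert path.pairs == [(i, i) for i in range(5)]

    def test_empty_matrix(self):
        assert global_align(np.zeros((0, 0))).pairs == []

    def test_dominates_random_paths(self):
        rng = np.random.default_rng(7)
        S = rng.uniform(0, 10, size=(12, 12))
        opt = global_align_score(S, 4.0, 0.2)
        for _ in range(50):
            k = int(rng.integers(1, 12))
            ri = np.sort(rng.choice(12, k, replace=False))
            ci = np.sort(rng.choice(12, k, replace=False))
            path = AlignmentPath(pairs=list(zip(ri.tolist(), ci.tolist())))
            assert opt >= path_score(S, path, 4.0, 0.2) - 1e-9


class TestSuperpose:
    def test_identical_sets(self):
        x = np.random.default_rng(0).normal(size=(10, 3)) * 5
        sup, rmsd = superpose(x, x)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-8)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_known_rotation_recovered(self):
        rng = np.random.default_rng(1)
        xB = rng.normal(size=(20, 3)) * 8
        R = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        xA = xB @ R.T + np.array([1.0, 2.0, 3.0])
        sup, rmsd = superpose(xA, xB)
        np.testing.assert_allclose(sup.rotation, R, atol=1e-6)
        assert rmsd < 1e-6

    def test_mirror_yields_proper_rotation(self):
        rng = np.random.default_rng(2)
        xB = rng.normal(size=(15, 3)) * 5
        xA = xB * np.array([1.0, 1.0, -1.0])  # reflection
        sup, rmsd = superpose(xA, xB)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)
        assert rmsd > 0.1

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="3 points"):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestMaxsub:
    def test_exact_copy_keeps_full_path(self):
        rng = np.random.default_rng(3)
        A = np.cumsum(rng.normal(size=(40, 3)) * 2 + [4, 0, 0], axis=0)
        path = AlignmentPath(pairs=[(i, i) for i in range(40)])
        core, _ = maxsub_refine(path, A, A.copy())
        assert core == path.pairs

    def test_two_block_fixture_keeps_undisplaced_half(self):
        rng = np.random.default_rng(0)
        A = np.cumsum(rng.normal(size=(100, 3)) * 1.5 + [4, 1, 0], axis=0)
        B = A.copy()
        B[50:] += np.array([15.0, 0.0, 0.0])
        path = AlignmentPath(pairs=[(i, i) for i in range(100)])
        core, sup = maxsub_refine(path, A, B)
        assert [p[0] for p in core] == list(range(50))
        d = np.linalg.norm(A[:50] - sup.apply(B[:50]), axis=1)
        assert d.max() < 1e-6

    def test_short_path_single_seed(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(3, 3)) * 5
        path = AlignmentPath(pairs=[(i, i) for i in range(3)])
        core, _ = maxsub_refine(path, A, A.copy())
        assert core == path.pairs


class TestAlignPair:
    def test_self_alignment_perfect(self, folds20):
        chain, bps = folds20[0]
        aln = align_pair(chain, chain, bps, bps)
        s = score_alignment(aln, chain, chain, bps, bps)
        assert (s.psi, s.pid, s.pss) == (100.0, 100.0, 100.0)
        assert s.core_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_in_argument_order(self, folds20):
        (A, bA), (B, bB) = folds20[0], folds20[1]
        s1 = score_alignment(align_pair(A, B, bA, bB), A, B, bA, bB)
        s2 = score_alignment(align_pair(B, A, bB, bA), B, A, bB, bA)
        assert (s1.psi, s1.pss, s1.pid, s1.n_al) == (s2.psi, s2.pss, s2.pid, s2.n_al)
        assert s1.core_rmsd == pytest.approx(s2.core_rmsd)

    def test_insufficient_paired_core(self, folds20):
        from rna3dcons.pairing import BasePairSet
        from rna3dcons.sara import AlignmentError
        chain, bps = folds20[0]
        tiny = BasePairSet(pairs=frozenset(list(sorted(bps.pairs))[:2]),
                           source="constructed")
        with pytest.raises(AlignmentError, match="insufficient paired core"):
            align_pair(chain, chain, tiny, tiny)

    def test_monotone_degradation_with_noise(self):
        chain, bps = generate_decoy_set(2, (90, 120), seed=17)[0]
        psis, rmsds = [], []
        for sigma in (0.5, 1.0, 2.0, 4.0, 8.0):
            hom, hbps = derive_homolog(
                chain, bps, HomologParams(target_pid=100.0, coord_noise=sigma,
                                          seed=23))
            s = score_alignment(align_pair(chain, hom, bps, hbps),
                                chain, hom, bps, hbps)
            psis.append(s.psi)
            rmsds.append(s.core_rmsd)
        for a, b in zip(psis, psis[1:]):
            assert b <= a + 2.0
        # core RMSD grows while the 4 A core still covers the structure;
        # beyond that the surviving core is a selection of lucky atoms
        meaningful = [r for r, p in zip(rmsds, psis) if p >= 50.0]
        for a, b in zip(meaningful, meaningful[1:]):
            assert b >= a - 1e-9

    def test_homolog_core_rmsd_matches_noise_expectation(self):
        chain, bps = generate_decoy_set(2, (150, 200), seed=29)[0]
        hom, hbps = derive_homolog(
            chain, bps, HomologParams(target_pid=100.0, coord_noise=0.5, seed=5))
        s = score_alignment(align_pair(chain, hom, bps, hbps),
                            chain, hom, bps, hbps)
        assert s.psi == 100.0
        expected = 0.5 * np.sqrt(3.0)
        assert s.core_rmsd == pytest.approx(expected, rel=0.15)
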