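"""Pairwise RNA 3D structure alignment by the unit-vector method.

The aligner represents each chain by the unit vectors between
consecutive base-paired C3' atoms, scores local windows of that
representation by unit-vector RMSD (URMS), aligns the two window-score
profiles by an affine-gap dynamic program with free end gaps, refines
the alignment with a MaxSub-style seed-and-extend core search at 3.5 A,
and reports the 4.0 A structurally superposable core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .chains import RnaChain
from .pairing import BasePairSet

__all__ = [
    "AlignConfig",
    "UnitVectorProfile",
    "AlignmentPath",
    "Superposition",
    "StructureAlignment",
    "AlignmentError",
    "unit_vector_profile",
    "urms_distance",
    "random_window_urms",
    "build_similarity_matrix",
    "global_align",
    "superpose",
    "maxsub_refine",
    "align_pair",
    "canonical_order",
]


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignConfig:
    """Tunable aligner parameters.

    window
        Unit vectors per comparison window (6 vectors = 7 residues),
        truncated near the termini to at least ``min_window``.
    gap_open, gap_extend
        Affine internal gap penalties in similarity-score units; end
        gaps are free.
    refine_dist, core_dist
        MaxSub admission threshold (3.5 A) and the distance defining the
        reported aligned core (4.0 A).
    """

    window: int = 6
    min_window: int = 3
    gap_open: float = 4.0
    gap_extend: float = 0.2
    refine_dist: float = 3.5
    core_dist: float = 4.0
    seed_len: int = 4
    max_refine_iter: int = 20
    urms_random_pairs: int = 10_000
    urms_seed: int = 20100615


DEFAULT_CONFIG = AlignConfig()


@dataclass
class UnitVectorProfile:
    """Consecutive inter-residue directions normalised onto the unit sphere."""

    vectors: np.ndarray  # (n_res - 1, 3), unit norm
    n_res: int


@dataclass
class AlignmentPath:
    """Matched index pairs, strictly increasing in both coordinates."""

    pairs: list

    def __post_init__(self):
        prev = (-1, -1)
        for i, j in self.pairs:
            if not (i > prev[0] and j > prev[1]):
                raise ValueError("alignment path must be strictly monotone")
            prev = (i, j)

    def __len__(self):
        return len(self.pairs)


@dataclass
class Superposition:
    """Proper rigid transform x -> R x + t mapping chain B coordinates onto A."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class StructureAlignment:
    """Result of aligning chain B onto chain A (canonical order).

    ``path`` holds full-chain residue index pairs; ``core_4A`` is the
    subset within 4.0 A after superposition (its size is n_al);
    ``refine_core_35`` is the 3.5 A MaxSub core the superposition was
    fitted on.
    """

    key_a: str
    key_b: str
    path: AlignmentPath
    superposition: Superposition
    core_4A: list
    core_rmsd: float
    refine_core_35: list
    dp_score: float = 0.0


# ---------------------------------------------------------------------------
# unit vectors and URMS

def unit_vector_profile(coords: np.ndarray) -> UnitVectorProfile:
    """Unit vectors between consecutive points of a C3' trace."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least 2 coordinates")
    steps = np.diff(coords, axis=0)
    norms = np.linalg.norm(steps, axis=1)
    if np.any(norms < 1e-9):
        raise ValueError("zero-length step between consecutive points")
    return UnitVectorProfile(vectors=steps / norms[:, None], n_res=coords.shape[0])


def urms_distance(wA: np.ndarray, wB: np.ndarray) -> float:
    """RMSD between two unit-vector windows after the optimal rotation.

    Rotation-only Kabsch: URMS^2 = 2 (n - s) / n where s is the signed
    singular-value sum of the correlation matrix.
    """
    wA = np.asarray(wA, dtype=float)
    wB = np.asarray(wB, dtype=float)
    if wA.shape != wB.shape:
        raise ValueError("windows must have equal lengths")
    n = wA.shape[0]
    if n < 3:
        raise ValueError("windows need at least 3 vectors")
    H = wA.T @ wB
    U, sv, Vt = np.linalg.svd(H)
    sign = 1.0 if np.linalg.det(H) >= 0 else -1.0
    s = sv[0] + sv[1] + sign * sv[2]
    return float(np.sqrt(max(0.0, 2.0 * (n - s) / n)))


_URMS_R_CACHE: dict[tuple[int, int, int], float] = {}


def random_window_urms(length: int, n_pairs: int = DEFAULT_CONFIG.urms_random_pairs,
                       seed: int = DEFAULT_CONFIG.urms_seed) -> float:
    """Monte-Carlo mean URMS between random unit-vector windows of ``length``.

    Used as the normalisation URMS_R of the similarity transform; the
    seed is fixed and the estimate cached per window length.
    """
    key = (length, n_pairs, seed)
    if key in _URMS_R_CACHE:
        return _URMS_R_CACHE[key]
    rng = np.random.default_rng([seed, length])
    def draw():
        v = rng.normal(size=(n_pairs, length, 3))
        return v / np.linalg.norm(v, axis=2, keepdims=True)
    A, B = draw(), draw()
    H = np.einsum("nkp,nkq->npq", A, B)
    s = _kernels.signed_singular_sums(np.ascontiguousarray(H))
    urms = np.sqrt(np.maximum(0.0, 2.0 * (length - s) / length))
    value = float(urms.mean())
    _URMS_R_CACHE[key] = value
    return value


# ---------------------------------------------------------------------------
# similarity matrix

def _window_offsets(w: int) -> tuple[int, int]:
    # window of w vectors centred at a cell: offsets [-(w//2 - 1), w - w//2]
    lo = -(w // 2 - 1)
    hi = w - w // 2
    return lo, hi


def build_similarity_matrix(pA: UnitVectorProfile, pB: UnitVectorProfile,
                            config: AlignConfig = DEFAULT_CONFIG) -> np.ndarray:
    """All-against-all window similarity S = max(0, 10 (1 - URMS/URMS_R)).

    Windows of ``config.window`` unit vectors centred at each cell,
    truncated identically on both profiles near the termini; cells whose
    common window would fall below ``config.min_window`` vectors score 0.
    URMS_R is the random-window expectation for the effective length.
    """
    A = pA.vectors
    B = pB.vectors
    na, nb = A.shape[0], B.shape[0]
    if na < 4 or nb < 4:
        raise AlignmentError("profiles need at least 4 unit vectors")
    w = config.window
    klo, khi = _window_offsets(w)

    S = np.zeros((na, nb))
    urms_r = {L: random_window_urms(L, config.urms_random_pairs, config.urms_seed)
              for L in range(config.min_window, w + 1)}

    # interior cells: full windows via shifted outer-product sums
    out_a, out_b = na - w + 1, nb - w + 1
    if out_a > 0 and out_b > 0:
        P = np.einsum("ip,jq->ijpq", A, B)
        H = np.zeros((out_a, out_b, 3, 3))
        for k in range(w):
            H += P[k:k + out_a, k:k + out_b]
        s = _kernels.signed_singular_sums(
            np.ascontiguousarray(H.reshape(-1, 3, 3)))
        urms = np.sqrt(np.maximum(0.0, 2.0 * (w - s) / w)).reshape(out_a, out_b)
        sim = 10.0 * (1.0 - urms / urms_r[w])
        S[-klo:-klo + out_a, -klo:-klo + out_b] = np.maximum(0.0, sim)

    # border cells: truncated windows, batched per effective length
    ilo, ihi = -klo, na - khi  # interior centre range [ilo, ihi)
    jlo, jhi = -klo, nb - khi
    groups: dict[int, list[tuple[int, int, int]]] = {}
    for i in range(na):
        inner_i = ilo <= i < ihi
        for j in range(nb):
            if inner_i and jlo <= j < jhi:
                continue
            a = max(klo, -i, -j)
            b = min(khi, na - 1 - i, nb - 1 - j)
            L = b - a + 1
            if L < config.min_window:
                continue  # S stays 0
            groups.setdefault(L, []).append((i, j, a))
    for L, cells in groups.items():
        arr = np.array(cells, dtype=np.int64)
        offs = np.arange(L)
        wa = A[(arr[:, 0] + arr[:, 2])[:, None] + offs]   # (m, L, 3)
        wb = B[(arr[:, 1] + arr[:, 2])[:, None] + offs]
        H = np.einsum("mkp,mkq->mpq", wa, wb)
        s = _kernels.signed_singular_sums(np.ascontiguousarray(H))
        u = np.sqrt(np.maximum(0.0, 2.0 * (L - s) / L))
        S[arr[:, 0], arr[:, 1]] = np.maximum(0.0, 10.0 * (1.0 - u / urms_r[L]))
    return S


# ---------------------------------------------------------------------------
# dynamic programming, superposition, refinement

def global_align(S: np.ndarray, gap_open: float = DEFAULT_CONFIG.gap_open,
                 gap_extend: float = DEFAULT_CONFIG.gap_extend) -> AlignmentPath:
    """Optimal monotone path through S under affine internal gaps, free end gaps."""
    S = np.ascontiguousarray(S, dtype=float)
    if S.size == 0:
        return AlignmentPath(pairs=[])
    if not np.all(np.isfinite(S)):
        raise ValueError("similarity matrix must be finite")
    path, _ = _kernels.semiglobal_affine(S, float(gap_open), float(gap_extend))
    return AlignmentPath(pairs=[(int(i), int(j)) for i, j in path])


def global_align_score(S: np.ndarray, gap_open: float = DEFAULT_CONFIG.gap_open,
                       gap_extend: float = DEFAULT_CONFIG.gap_extend) -> float:
    """Optimal alignment score (used by oracle tests)."""
    S = np.ascontiguousarray(S, dtype=float)
    if S.size == 0:
        return 0.0
    _, score = _kernels.semiglobal_affine(S, float(gap_open), float(gap_extend))
    return float(score)


def superpose(xA: np.ndarray, xB: np.ndarray) -> tuple[Superposition, float]:
    """Least-squares rigid superposition of xB onto xA (proper rotation only)."""
    xA = np.ascontiguousarray(xA, dtype=float)
    xB = np.ascontiguousarray(xB, dtype=float)
    if xA.shape != xB.shape or xA.ndim != 2 or xA.shape[1] != 3:
        raise ValueError("coordinate sets must be equal-shaped (n, 3)")
    if xA.shape[0] < 3:
        raise ValueError("need at least 3 points")
    R, t = _kernels.kabsch(xA, xB)
    sup = Superposition(rotation=R, translation=t)
    rmsd = float(np.sqrt(np.mean(np.sum((xA - sup.apply(xB)) ** 2, axis=1))))
    return sup, rmsd


def _coords_of(obj) -> np.ndarray:
    return obj.coords if isinstance(obj, RnaChain) else np.asarray(obj, dtype=float)


def maxsub_refine(path: AlignmentPath, A, B,
                  config: AlignConfig = DEFAULT_CONFIG) -> tuple[list, Superposition]:
    """Largest subset of the path superposable within ``config.refine_dist``.

    Seeds every run of ``config.seed_len`` consecutive path pairs and
    extends each by iterative superposition until stable.  ``A`` and
    ``B`` may be chains or (n, 3) coordinate arrays indexed by the path.
    Returns the winning core (as path pairs) and the superposition
    fitted on it.
    """
    if len(path) == 0:
        raise AlignmentError("empty alignment path")
    cA = _coords_of(A)
    cB = _coords_of(B)
    pa = np.array([p[0] for p in path.pairs])
    pb = np.array([p[1] for p in path.pairs])
    PA = np.ascontiguousarray(cA[pa])
    PB = np.ascontiguousarray(cB[pb])
    mask = _kernels.maxsub(PA, PB, config.refine_dist, config.seed_len,
                           config.max_refine_iter)
    if not mask.any():
        idx = np.arange(len(path.pairs))
    else:
        idx = np.nonzero(mask)[0]
    core = [path.pairs[k] for k in idx]
    sup, _ = superpose(PA[idx], PB[idx])
    return core, sup


def canonical_order(A: RnaChain, B: RnaChain, bpA: BasePairSet, bpB: BasePairSet):
    """Order the two chains canonically: shorter paired core first, ties by key.

    Returns (A, B, bpA, bpB, swapped).
    """
    ra = (len(bpA.paired_indices()), len(A), A.key)
    rb = (len(bpB.paired_indices()), len(B), B.key)
    if rb < ra:
        return B, A, bpB, bpA, True
    return A, B, bpA, bpB, False


def align_pair(A: RnaChain, B: RnaChain, bpA: BasePairSet, bpB: BasePairSet,
               config: AlignConfig = DEFAULT_CONFIG) -> StructureAlignment:
    """Full unit-vector alignment of two chains restricted to paired residues.

    Chains are restricted to base-paired residues, profiled, scored,
    aligned by the semiglobal dynamic program, refined by MaxSub at
    3.5 A; the final superposition is fitted on the refined core and the
    4.0 A core and its RMSD are reported.  The argument order is
    canonicalised (shorter paired core first; ties by key) so the result
    does not depend on the caller's order; ``path`` holds full-chain
    residue indices of the canonical-first chain versus the second.
    """
    A, B, bpA, bpB, _ = canonical_order(A, B, bpA, bpB)
    idxA = bpA.paired_indices()
    idxB = bpB.paired_indices()
    if len(idxA) < 5 or len(idxB) < 5:
        raise AlignmentError("insufficient paired core")
    if idxA[-1] >= len(A) or idxB[-1] >= len(B):
        raise AlignmentError("base-pair indices outside chain")

    cA = A.coords[idxA]
    cB = B.coords[idxB]
    profA = unit_vector_profile(cA)
    profB = unit_vector_profile(cB)
    S = build_similarity_matrix(profA, profB, config)
    cells, dp_score = _kernels.semiglobal_affine(
        np.ascontiguousarray(S), config.gap_open, config.gap_extend)

    # a window cell (i, j) aligns restricted residues (i + 1, j + 1);
    # the head cell also contributes its own (i, j) pair so a perfect
    # diagonal covers every residue.
    res_pairs = [(int(i) + 1, int(j) + 1) for i, j in cells]
    if len(cells) > 0:
        res_pairs.insert(0, (int(cells[0, 0]), int(cells[0, 1])))
    path = AlignmentPath(pairs=res_pairs)

    core35, sup = maxsub_refine(path, cA, cB, config)

    pa = np.array([p[0] for p in path.pairs])
    pb = np.array([p[1] for p in path.pairs])
    d = np.linalg.norm(cA[pa] - sup.apply(cB[pb]), axis=1)
    in_core = d < config.core_dist
    core4 = [path.pairs[k] for k in np.nonzero(in_core)[0]]
    core_rmsd = float(np.sqrt(np.mean(d[in_core] ** 2))) if in_core.any() else float("nan")

    # report in full-chain residue indices
    to_full = lambda pairs: [(int(idxA[i]), int(idxB[j])) for i, j in pairs]
    return StructureAlignment(
        key_a=A.key,
        key_b=B.key,
        path=AlignmentPath(pairs=to_full(path.pairs)),
        superposition=sup,
        core_4A=to_full(core4),
        core_rmsd=core_rmsd,
        refine_core_35=to_full(core35),
        dp_score=float(dp_score),
    )
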