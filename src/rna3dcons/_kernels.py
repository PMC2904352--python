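"""Compiled inner loops: batched 3x3 signed singular sums, the affine
semiglobal dynamic program, and the MaxSub seed-and-extend refinement."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _det3(A):
    return (
        A[0, 0] * (A[1, 1] * A[2, 2] - A[1, 2] * A[2, 1])
        - A[0, 1] * (A[1, 0] * A[2, 2] - A[1, 2] * A[2, 0])
        + A[0, 2] * (A[1, 0] * A[2, 1] - A[1, 1] * A[2, 0])
    )


@njit(cache=True)
def signed_singular_sums(H):
    """For each 3x3 correlation matrix, sigma1 + sigma2 + sign(det) * sigma3.

    This is max_R tr(R @ H) over proper rotations, the quantity behind
    rotation-only RMSD minimisation.  Singular values come from the
    closed-form (trigonometric) eigenvalues of H^T H; accuracy is
    ~1e-13 for generic matrices and ~1e-8 absolute in the degenerate
    smallest-singular-value limit, both far inside the score scale.
    """
    n = H.shape[0]
    out = np.empty(n)
    twopi3 = 2.0 * np.pi / 3.0
    for k in range(n):
        A = H[k]
        d = _det3(A)
        # Gram matrix M = A^T A (symmetric PSD)
        m00 = A[0, 0] * A[0, 0] + A[1, 0] * A[1, 0] + A[2, 0] * A[2, 0]
        m11 = A[0, 1] * A[0, 1] + A[1, 1] * A[1, 1] + A[2, 1] * A[2, 1]
        m22 = A[0, 2] * A[0, 2] + A[1, 2] * A[1, 2] + A[2, 2] * A[2, 2]
        m01 = A[0, 0] * A[0, 1] + A[1, 0] * A[1, 1] + A[2, 0] * A[2, 1]
        m02 = A[0, 0] * A[0, 2] + A[1, 0] * A[1, 2] + A[2, 0] * A[2, 2]
        m12 = A[0, 1] * A[0, 2] + A[1, 1] * A[1, 2] + A[2, 1] * A[2, 2]
        q = (m00 + m11 + m22) / 3.0
        p1 = m01 * m01 + m02 * m02 + m12 * m12
        p2 = (m00 - q) ** 2 + (m11 - q) ** 2 + (m22 - q) ** 2 + 2.0 * p1
        if p2 <= 0.0:
            e1 = q
            e3 = q
            e2 = q
        else:
            p = np.sqrt(p2 / 6.0)
            b00 = (m00 - q) / p
            b11 = (m11 - q) / p
            b22 = (m22 - q) / p
            b01 = m01 / p
            b02 = m02 / p
            b12 = m12 / p
            detb = (b00 * (b11 * b22 - b12 * b12)
                    - b01 * (b01 * b22 - b12 * b02)
                    + b02 * (b01 * b12 - b11 * b02))
            r = detb / 2.0
            if r > 1.0:
                r = 1.0
            elif r < -1.0:
                r = -1.0
            phi = np.arccos(r) / 3.0
            e1 = q + 2.0 * p * np.cos(phi)
            e3 = q + 2.0 * p * np.cos(phi + twopi3)
            e2 = 3.0 * q - e1 - e3
        s1 = np.sqrt(e1) if e1 > 0.0 else 0.0
        s2 = np.sqrt(e2) if e2 > 0.0 else 0.0
        s3 = np.sqrt(e3) if e3 > 0.0 else 0.0
        if d >= 0.0:
            out[k] = s1 + s2 + s3
        else:
            out[k] = s1 + s2 - s3
    return out


@njit(cache=True)
def kabsch(A, B):
    """Least-squares proper rotation R and translation t mapping B onto A.

    Minimises sum |a_i - (R b_i + t)|^2; reflections are rejected by the
    determinant correction.
    """
    n = A.shape[0]
    ca = np.zeros(3)
    cb = np.zeros(3)
    for i in range(n):
        for p in range(3):
            ca[p] += A[i, p]
            cb[p] += B[i, p]
    ca /= n
    cb /= n
    K = np.zeros((3, 3))
    for i in range(n):
        for p in range(3):
            for q in range(3):
                K[p, q] += (B[i, p] - cb[p]) * (A[i, q] - ca[q])
    U, s, Vt = np.linalg.svd(K)
    V = Vt.T
    R = V @ U.T
    if _det3(R) < 0.0:
        D = np.eye(3)
        D[2, 2] = -1.0
        R = V @ D @ U.T
    t = ca - R @ cb
    return R, t


@njit(cache=True)
def semiglobal_affine(S, gap_open, gap_extend):
    """Affine-gap dynamic program with free end gaps over score matrix S.

    Maximises the sum of matched cell scores minus affine internal gap
    costs (open + (len-1) * extend per maximal per-sequence gap run);
    leading and trailing gaps are free.  Tie-break: diagonal > up > left,
    continuation preferred over restart, and the traceback starts from
    the best-scoring cell with the largest (i + j, i).

    Returns (path, score) where path is an (L, 2) int32 array of matched
    cells, strictly increasing in both coordinates.
    """
    n, m = S.shape
    NEG = -1e30
    M = np.full((n, m), NEG)
    Ix = np.full((n, m), NEG)
    Iy = np.full((n, m), NEG)
    pM = np.zeros((n, m), np.int8)
    pIx = np.zeros((n, m), np.int8)
    pIy = np.zeros((n, m), np.int8)

    for i in range(n):
        for j in range(m):
            best = 0.0
            ptr = 0
            if i > 0 and j > 0:
                if M[i - 1, j - 1] >= best:
                    best = M[i - 1, j - 1]
                    ptr = 1
                if Ix[i - 1, j - 1] > best:
                    best = Ix[i - 1, j - 1]
                    ptr = 2
                if Iy[i - 1, j - 1] > best:
                    best = Iy[i - 1, j - 1]
                    ptr = 3
            M[i, j] = S[i, j] + best
            pM[i, j] = ptr
            if i > 0:
                v = M[i - 1, j] - gap_open
                p = 1
                if Ix[i - 1, j] - gap_extend > v:
                    v = Ix[i - 1, j] - gap_extend
                    p = 2
                if Iy[i - 1, j] - gap_open > v:
                    v = Iy[i - 1, j] - gap_open
                    p = 3
                Ix[i, j] = v
                pIx[i, j] = p
            if j > 0:
                v = M[i, j - 1] - gap_open
                p = 1
                if Ix[i, j - 1] - gap_open > v:
                    v = Ix[i, j - 1] - gap_open
                    p = 2
                if Iy[i, j - 1] - gap_extend > v:
                    v = Iy[i, j - 1] - gap_extend
                    p = 3
                Iy[i, j] = v
                pIy[i, j] = p

    bi = 0
    bj = 0
    bv = M[0, 0]
    for i in range(n):
        for j in range(m):
            v = M[i, j]
            if v > bv or (v == bv and (i + j > bi + bj or (i + j == bi + bj and i > bi))):
                bv = v
                bi = i
                bj = j

    path_i = np.empty(n + m, np.int32)
    path_j = np.empty(n + m, np.int32)
    L = 0
    i = bi
    j = bj
    state = 0  # 0 = M, 1 = Ix, 2 = Iy
    while True:
        if state == 0:
            path_i[L] = i
            path_j[L] = j
            L += 1
            ptr = pM[i, j]
            if ptr == 0:
                break
            state = ptr - 1
            i -= 1
            j -= 1
        elif state == 1:
            ptr = pIx[i, j]
            state = ptr - 1
            i -= 1
        else:
            ptr = pIy[i, j]
            state = ptr - 1
            j -= 1

    out = np.empty((L, 2), np.int32)
    for k in range(L):
        out[k, 0] = path_i[L - 1 - k]
        out[k, 1] = path_j[L - 1 - k]
    return out, bv


@njit(cache=True)
def maxsub(A, B, dist, seed_len, max_iter):
    """MaxSub-style core search over an aligned coordinate path.

    A and B are (L, 3) arrays of the paired C3' coordinates.  From every
    seed of ``seed_len`` consecutive path pairs, iteratively superpose on
    the current core and re-admit all pairs within ``dist`` angstroms,
    until the core is stable or ``max_iter`` iterations.  Returns the
    boolean mask of the largest core found (ties: lower core RMSD).
    """
    L = A.shape[0]
    d2max = dist * dist
    sl = seed_len if seed_len <= L else L
    n_seeds = L - sl + 1
    best_mask = np.zeros(L, np.bool_)
    best_size = 0
    best_rmsd = 1e30

    for s in range(n_seeds):
        mask = np.zeros(L, np.bool_)
        for q in range(s, s + sl):
            mask[q] = True
        size = sl
        for _ in range(max_iter):
            if size < 3:
                break
            Ac = np.empty((size, 3))
            Bc = np.empty((size, 3))
            c = 0
            for q in range(L):
                if mask[q]:
                    Ac[c] = A[q]
                    Bc[c] = B[q]
                    c += 1
            R, t = kabsch(Ac, Bc)
            newmask = np.zeros(L, np.bool_)
            nsize = 0
            sumsq = 0.0
            for q in range(L):
                d2 = 0.0
                for p in range(3):
                    x = R[p, 0] * B[q, 0] + R[p, 1] * B[q, 1] + R[p, 2] * B[q, 2] + t[p]
                    diff = A[q, p] - x
                    d2 += diff * diff
                if d2 < d2max:
                    newmask[q] = True
                    nsize += 1
                    sumsq += d2
            if nsize < 3:
                break
            rmsd = np.sqrt(sumsq / nsize)
            if nsize > best_size or (nsize == best_size and rmsd < best_rmsd):
                best_size = nsize
                best_rmsd = rmsd
                best_mask = newmask.copy()
            same = True
            for q in range(L):
                if newmask[q] != mask[q]:
                    same = False
                    break
            mask = newmask
            size = nsize
            if same:
                break
    return best_mask
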