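"""Alignment identity scores and their extreme-value significance.

Three percentages summarise a structure alignment:

* PSI = 100 * n_al / N  -- aligned C3' atoms within 4.0 A over the
  length N of the shorter (paired-residue) structure;
* PSS = 100 * p_al / NP -- aligned base pairs over the smaller pair
  count NP; a pair is aligned when both of its C3' atoms superpose
  within 4.0 A of its partner pair's atoms;
* PID = 100 * n_id / N  -- identical aligned nucleotides (N bases never
  match).

Scores of alignments between unrelated structures follow a Gumbel
(extreme-value) distribution; the exceedance probability
p = 1 - exp(-exp(-z)), z = (x - mu)/sigma, gives the p-value, with
(mu, sigma) fitted on a background of unrelated-pair alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chains import RnaChain
from .pairing import BasePairSet
from .sara import StructureAlignment, canonical_order

__all__ = [
    "GAMMA",
    "AlignmentScores",
    "EvdParams",
    "SignificanceResult",
    "identity_percentages",
    "score_alignment",
    "fit_evd_background",
    "alignment_significance",
    "gumbel_exceedance",
]


def identity_percentages(n_al: int, N: int, p_al: int | None, NP: int,
                         n_id: int) -> tuple[float, float | None, float]:
    """The three identity percentages from their raw counts.

    PSI = 100 n_al / N, PSS = 100 p_al / NP (None when NP = 0),
    PID = 100 n_id / N.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    psi = 100.0 * n_al / N
    pid = 100.0 * n_id / N
    pss = 100.0 * p_al / NP if NP > 0 and p_al is not None else None
    return psi, pss, pid

#: Euler-Mascheroni constant as used by the method-of-moments estimator
GAMMA = 0.5772

#: p-values are clamped here so -ln(p) stays finite
P_FLOOR = 1e-300


@dataclass
class AlignmentScores:
    n_al: int
    N: int
    p_al: int | None
    NP: int
    n_id: int
    psi: float
    pss: float | None
    pid: float
    core_rmsd: float


@dataclass
class EvdParams:
    """Gumbel location/scale for one score type, fitted on a background."""

    mu: float
    sigma: float
    score_type: str
    n_background: int

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass
class SignificanceResult:
    p_psi: float | None
    p_pss: float | None
    p_pid: float | None
    nlp_psi: float | None
    nlp_pss: float | None
    nlp_pid: float | None


def score_alignment(aln: StructureAlignment, A: RnaChain, B: RnaChain,
                    bpA: BasePairSet, bpB: BasePairSet) -> AlignmentScores:
    """Compute PSI, PSS, PID and core RMSD for an alignment of A and B.

    Arguments are canonicalised the same way as in ``align_pair`` so the
    caller's order does not matter.  N is the number of base-paired
    residues of the shorter structure; NP the smaller base-pair count.
    """
    A, B, bpA, bpB, _ = canonical_order(A, B, bpA, bpB)
    if {aln.key_a, aln.key_b} - {A.key, B.key}:
        raise ValueError("alignment does not belong to these chains")

    N = min(len(bpA.paired_indices()), len(bpB.paired_indices()))
    NP = min(len(bpA), len(bpB))
    n_al = len(aln.core_4A)

    n_id = 0
    mapping: dict[int, int] = {}
    for i, j in aln.path.pairs:
        mapping[i] = j
        if A.sequence[i] == B.sequence[j] and A.sequence[i] != "N":
            n_id += 1

    core = set(aln.core_4A)
    p_al = 0
    for i, j in bpA.pairs:
        if i not in mapping or j not in mapping:
            continue
        k, l = mapping[i], mapping[j]
        if (min(k, l), max(k, l)) not in bpB.pairs:
            continue
        if (i, k) in core and (j, l) in core:
            p_al += 1

    psi, pss, pid = identity_percentages(n_al, N, p_al, NP, n_id)
    return AlignmentScores(
        n_al=n_al, N=N,
        p_al=p_al if NP > 0 else None, NP=NP,
        n_id=n_id, psi=psi, pss=pss, pid=pid,
        core_rmsd=aln.core_rmsd,
    )


def fit_evd_background(scores, method: str = "moments",
                       score_type: str = "PSI") -> EvdParams:
    """Fit Gumbel location and scale to background scores.

    ``moments``: sigma = sd * sqrt(6)/pi, mu = mean - gamma * sigma
    (gamma = 0.5772).  ``mle``: numerical maximum likelihood.  Requires
    at least 100 finite scores with positive variance.
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise ValueError("need at least 100 finite background scores")
    if np.var(x) <= 0:
        raise ValueError("background scores have zero variance")
    if method == "moments":
        sigma = np.std(x, ddof=1) * math.sqrt(6.0) / math.pi
        mu = float(np.mean(x) - GAMMA * sigma)
    elif method == "mle":
        mu, sigma = stats.gumbel_r.fit(x)
    else:
        raise ValueError(f"unknown method {method!r}")
    return EvdParams(mu=float(mu), sigma=float(sigma),
                     score_type=score_type, n_background=int(x.size))


def gumbel_exceedance(x: float, params: EvdParams) -> float:
    """P(score > x) under the fitted Gumbel null, clamped to [1e-300, 1]."""
    z = (x - params.mu) / params.sigma
    # 1 - exp(-exp(-z)), computed stably in the right tail
    p = -math.expm1(-math.exp(-min(z, 700.0)))
    return min(1.0, max(P_FLOOR, p))


def alignment_significance(scores: AlignmentScores,
                           params: dict[str, EvdParams]) -> SignificanceResult:
    """Per-score Gumbel p-values and their negative logarithms.

    ``params`` maps score types ("PSI", "PSS", "PID") to fitted
    EvdParams; a missing score type (or an undefined PSS) yields None
    for that p-value.
    """
    def one(value, key):
        if value is None or key not in params:
            return None, None
        p = gumbel_exceedance(value, params[key])
        return p, -math.log(p)

    p_psi, nlp_psi = one(scores.psi, "PSI")
    p_pss, nlp_pss = one(scores.pss, "PSS")
    p_pid, nlp_pid = one(scores.pid, "PID")
    return SignificanceResult(
        p_psi=p_psi, p_pss=p_pss, p_pid=p_pid,
        nlp_psi=nlp_psi, nlp_pss=nlp_pss, nlp_pid=nlp_pid,
    )
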