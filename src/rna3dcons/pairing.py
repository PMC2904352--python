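"""Base-pair annotation: external pair lists or a built-in geometric detector.

The detector works on the C3' trace alone: two complementary bases whose
C3'-C3' distance falls in the antiparallel-helix window pair up.  When
glycosidic-edge nitrogen coordinates are available (full-atom files),
a donor-acceptor N1/N3 distance criterion takes precedence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .chains import RnaChain

logger = logging.getLogger(__name__)

__all__ = ["BasePairSet", "detect_base_pairs", "read_pair_annotation"]

#: canonical complementarity (Watson-Crick + GU wobble); N never pairs
_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

#: C3'-C3' distance window (angstroms) for paired bases in an
#: antiparallel helix when only backbone atoms exist
C3_PAIR_WINDOW = (16.0, 20.0)
#: donor-acceptor N1/N3 distance window for a hydrogen-bonded pair
HBOND_WINDOW = (2.6, 3.3)
#: minimum sequence separation of a pair
MIN_PAIR_SEPARATION = 3


@dataclass(frozen=True)
class BasePairSet:
    """Unordered canonical base pairs as 0-based residue index pairs (i < j).

    Each residue appears in at most one pair and |i - j| >= 3.
    """

    pairs: frozenset = field(default_factory=frozenset)
    source: str = "constructed"

    def __post_init__(self):
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j):
                raise ValueError(f"pair indices must satisfy 0 <= i < j: {(i, j)}")
            if j - i < MIN_PAIR_SEPARATION:
                raise ValueError(f"pair {(i, j)} violates |i-j| >= {MIN_PAIR_SEPARATION}")
            if i in seen or j in seen:
                raise ValueError(f"residue in more than one pair: {(i, j)}")
            seen.add(i)
            seen.add(j)

    def __len__(self) -> int:
        return len(self.pairs)

    def validate_for(self, chain: RnaChain) -> None:
        n = len(chain)
        for i, j in self.pairs:
            if j >= n:
                raise ValueError(f"pair {(i, j)} outside chain of length {n}")

    def paired_indices(self) -> np.ndarray:
        """Sorted array of all residue indices involved in a pair."""
        idx = sorted({k for p in self.pairs for k in p})
        return np.array(idx, dtype=np.int64)


def detect_base_pairs(
    chain: RnaChain,
    n1n3: dict[int, np.ndarray] | None = None,
    window: tuple[float, float] = C3_PAIR_WINDOW,
    kind: str = "canonical",
) -> BasePairSet:
    """Detect base pairs geometrically from the C3' trace.

    Complementary bases (A-U, G-C, G-U for ``kind="canonical"``; any
    base combination for ``kind="all"``) whose C3'-C3' distance lies in
    ``window`` are candidates; each residue keeps at most one partner,
    chosen greedily by smallest deviation from the window centre.  If
    ``n1n3`` coordinates are supplied, candidates whose N1/N3 distance
    lies in the hydrogen-bond window take precedence.  Deterministic.
    """
    n = len(chain)
    if n < 4:
        raise ValueError("chain needs at least 4 residues")
    lo, hi = window
    centre = 0.5 * (lo + hi)
    dist = cdist(chain.coords, chain.coords)

    # local backbone direction (central difference); at the minimum
    # separation of 3 a straight strand reaches pairing distance while
    # running parallel, which a genuine pair never does, so sep-3
    # candidates must additionally be antiparallel
    tangent = np.empty_like(chain.coords)
    tangent[1:-1] = chain.coords[2:] - chain.coords[:-2]
    tangent[0] = chain.coords[1] - chain.coords[0]
    tangent[-1] = chain.coords[-1] - chain.coords[-2]
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)

    candidates = []
    for i in range(n):
        bi = chain.sequence[i]
        for j in range(i + MIN_PAIR_SEPARATION, n):
            bj = chain.sequence[j]
            if kind == "canonical":
                if (bi, bj) not in _CANONICAL:
                    continue
            elif bi == "N" or bj == "N":
                continue
            d = dist[i, j]
            if not (lo <= d <= hi):
                continue
            if j - i == MIN_PAIR_SEPARATION and tangent[i] @ tangent[j] >= 0.0:
                continue
            dev = abs(d - centre)
            hbond = False
            if n1n3 and i in n1n3 and j in n1n3:
                dh = float(np.linalg.norm(n1n3[i] - n1n3[j]))
                hbond = HBOND_WINDOW[0] <= dh <= HBOND_WINDOW[1]
            candidates.append((0 if hbond else 1, dev, i, j))

    candidates.sort()
    used: set[int] = set()
    pairs: set[tuple[int, int]] = set()
    for _, _, i, j in candidates:
        if i in used or j in used:
            continue
        used.add(i)
        used.add(j)
        pairs.add((i, j))
    return BasePairSet(pairs=frozenset(pairs), source="geometric")


def _parse_dssr_json(text: str) -> list[tuple[int, int]]:
    obj = json.loads(text)
    out = []
    for rec in obj.get("pairs", []):
        out.append((_trailing_int(rec["nt1"]), _trailing_int(rec["nt2"])))
    return out


def _trailing_int(nt_id: str) -> int:
    """Author residue number from a DSSR nucleotide id such as 'B.G25' or '1.A.U.6'."""
    tail = nt_id.split(".")[-1]
    digits = "".join(ch for ch in tail if ch.isdigit() or ch == "-")
    if not digits:
        raise ValueError(f"cannot extract residue number from {nt_id!r}")
    return int(digits)


def read_pair_annotation(file_content: str, chain: RnaChain) -> BasePairSet:
    """Read a base-pair annotation for ``chain``.

    Accepts two-column whitespace-separated author residue-number pairs
    (one pair per line, ``#`` comments allowed) or a DSSR ``--json``
    document with a ``pairs`` list (``nt1``/``nt2`` fields).  Author
    numbers are mapped to 0-based indices; lines naming unknown residues
    or violating the pair invariants are skipped with a warning.
    """
    text = file_content.strip()
    if text.startswith("{"):
        raw = _parse_dssr_json(text)
    else:
        raw = []
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                logger.warning("malformed pair line skipped: %r", line)
                continue
            try:
                raw.append((int(parts[0]), int(parts[1])))
            except ValueError:
                logger.warning("malformed pair line skipped: %r", line)

    num_to_idx: dict[int, int] = {}
    for idx, num in enumerate(chain.auth_numbers):
        num_to_idx.setdefault(int(num), idx)

    used: set[int] = set()
    pairs: set[tuple[int, int]] = set()
    for a, b in raw:
        if a not in num_to_idx or b not in num_to_idx:
            logger.warning("pair (%d, %d): residue number not in chain; skipped", a, b)
            continue
        i, j = sorted((num_to_idx[a], num_to_idx[b]))
        if i == j or j - i < MIN_PAIR_SEPARATION:
            logger.warning("pair (%d, %d) violates separation; skipped", a, b)
            continue
        if i in used or j in used:
            logger.warning("pair (%d, %d): residue already paired; keeping first", a, b)
            continue
        used.add(i)
        used.add(j)
        pairs.add((i, j))
    return BasePairSet(pairs=frozenset(pairs), source="file")
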