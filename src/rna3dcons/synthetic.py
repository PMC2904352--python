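"""Synthetic RNA folds, homolog pairs, decoy sets and twilight point clouds.

The generator emits C3'-only helical folds with known Watson-Crick
pairing, so every stage of the analysis runs without downloads.  Stems
follow a fixed helix template (two antiparallel strands on a cylinder);
hairpin loops and internal-loop connectors are equal-step circular arcs;
linkers are seeded random walks.  The template guarantees consecutive
C3'-C3' spacing inside [5, 7] A and a paired C3'-C3' distance of 18 A
(the centre of the detector's window).  Template constants are package
conventions for a recognisable helix, not claims about real A-form
geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .chains import RnaChain
from .pairing import BasePairSet
from .twilight import TwilightCurve, TwilightPoint

__all__ = [
    "Segment",
    "FoldSpec",
    "DomainShift",
    "HomologParams",
    "generate_fold",
    "derive_homolog",
    "generate_decoy_set",
    "generate_twilight_points",
    "ladder_pairs",
    "chain_to_pdb",
    "pairs_to_text",
    "RISE",
    "TWIST",
    "RADIUS",
    "STEP",
]

RISE = 2.81           # axial rise per base-pair step (A)
TWIST = math.radians(32.7)
RADIUS = 9.0          # cylinder radius; paired C3'-C3' distance = 2 * RADIUS
STEP = 5.9            # target consecutive C3'-C3' spacing (A)

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WC_PAIRS = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]


class GeometryError(RuntimeError):
    pass


@dataclass(frozen=True)
class Segment:
    kind: str            # stem, loop or linker
    length: int
    partner: int | None = None   # stem id shared by the two halves


@dataclass
class FoldSpec:
    """Declarative stem/loop layout of one fold.

    Stems appear twice with the same ``partner`` id (5' and 3' halves).
    Supported topologies are pseudoknot-free: hairpins (terminal loop of
    at least 2 nt), stems nested inside stems with symmetric internal-
    loop linkers, and top-level linkers between units.
    """

    segments: list = field(default_factory=list)
    seed: int = 0

    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    def validate(self) -> list[str]:
        errors = []
        counts: dict[int, list[Segment]] = {}
        for s in self.segments:
            if s.kind not in ("stem", "loop", "linker"):
                errors.append(f"unknown segment kind {s.kind!r}")
            if s.length < 0 or (s.kind != "linker" and s.length < 2):
                errors.append(f"{s.kind} of length {s.length} too short")
            if s.kind == "stem":
                if s.partner is None:
                    errors.append("stem without partner id")
                else:
                    counts.setdefault(s.partner, []).append(s)
        for sid, halves in counts.items():
            if len(halves) != 2:
                errors.append(f"stem id {sid} appears {len(halves)} times (need 2)")
            elif halves[0].length != halves[1].length:
                errors.append(f"stem id {sid} halves have different lengths")
        if self.total_length() < 20:
            errors.append(f"total length {self.total_length()} < 20")
        if not errors:
            try:
                _parse_tree(self.segments)
            except ValueError as exc:
                errors.append(str(exc))
        return errors


@dataclass(frozen=True)
class DomainShift:
    """Rigid displacement of a residue range (inclusive), for partial-core cases."""

    start: int
    end: int
    rotation_deg: float = 0.0
    translation: float = 0.0


@dataclass(frozen=True)
class HomologParams:
    """Controlled divergence from a parent fold.

    ``target_pid`` is the aimed sequence identity (percent);
    ``coord_noise`` the isotropic Gaussian sd per coordinate (A);
    ``compensatory`` mutates stem partners jointly so pairing survives.
    """

    target_pid: float = 100.0
    coord_noise: float = 0.0
    domain_shift: DomainShift | None = None
    compensatory: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.target_pid <= 100.0:
            raise ValueError("target_pid must be in [0, 100]")
        if self.coord_noise < 0:
            raise ValueError("coord_noise must be >= 0")


# ---------------------------------------------------------------------------
# topology parsing

@dataclass
class _Node:
    kind: str                    # "stem", "loop" or "linker"
    length: int = 0
    start5: int = 0              # first index of the 5' half / leaf
    start3: int = 0              # first index of the 3' half (stems)
    inner: list = field(default_factory=list)


def _parse_tree(segments) -> list:
    """Nest the flat segment list; raises ValueError on unsupported topology."""
    starts = np.concatenate([[0], np.cumsum([s.length for s in segments])])

    def parse_region(lo: int, hi: int, inside_stem: bool) -> list:
        nodes = []
        i = lo
        while i < hi:
            seg = segments[i]
            if seg.kind == "stem":
                close = None
                for j in range(i + 1, hi):
                    if segments[j].kind == "stem" and segments[j].partner == seg.partner:
                        close = j
                        break
                if close is None:
                    raise ValueError(
                        f"stem id {seg.partner} is not properly nested (pseudoknot?)")
                node = _Node(kind="stem", length=seg.length,
                             start5=int(starts[i]), start3=int(starts[close]))
                node.inner = parse_region(i + 1, close, True)
                _check_stem_content(node)
                nodes.append(node)
                i = close + 1
            elif seg.kind == "loop":
                if not inside_stem:
                    raise ValueError("loop segment outside any stem")
                nodes.append(_Node(kind="loop", length=seg.length,
                                   start5=int(starts[i])))
                i += 1
            else:
                nodes.append(_Node(kind="linker", length=seg.length,
                                   start5=int(starts[i])))
                i += 1
        return nodes

    def _check_stem_content(node: _Node) -> None:
        kinds = tuple(n.kind for n in node.inner)
        if kinds == ("loop",):
            if node.inner[0].length < 2:
                raise ValueError("terminal loop must have at least 2 nt")
            return
        if kinds == ("stem",):
            return
        if (kinds == ("linker", "stem", "linker")
                and node.inner[0].length == node.inner[2].length):
            return
        raise ValueError(
            "a stem must enclose a terminal loop or one nested stem with "
            "symmetric linkers (multiloops unsupported)")

    return parse_region(0, len(segments), False)


# ---------------------------------------------------------------------------
# geometry

def _frame_from_axis(axis: np.ndarray, azimuth: float) -> np.ndarray:
    """Orthonormal frame whose third column is ``axis``, spun by ``azimuth``."""
    z = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(z @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    x = ref - (ref @ z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    F = np.column_stack([x, y, z])
    return F @ _rz(azimuth)


def _rz(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _helix_point(F, origin, k, phase):
    local = np.array([RADIUS * math.cos(k * TWIST + phase),
                      RADIUS * math.sin(k * TWIST + phase),
                      k * RISE])
    return origin + F @ local


def _connector(p1, p2, n_interior, bulge_dir):
    """``n_interior`` points between p1 and p2 with equal consecutive spacing.

    Straight line when the per-segment spacing lands in [5, 7] A;
    otherwise a circular arc with exactly STEP-length segments, bulging
    towards ``bulge_dir``.
    """
    n_seg = n_interior + 1
    delta = p2 - p1
    c = float(np.linalg.norm(delta))
    if c / n_seg > 7.0:
        raise GeometryError(f"connector span {c:.1f} A unreachable with {n_seg} steps")
    if 5.0 <= c / n_seg <= 7.0:
        return [p1 + delta * (m / n_seg) for m in range(1, n_seg)]

    s = STEP
    u = delta / c

    def ratio(theta):
        return math.sin(theta / 2.0) / math.sin(theta / (2.0 * n_seg))

    theta = brentq(lambda t: ratio(t) - c / s, 1e-6, 2.0 * math.pi - 1e-6)
    rho = c / (2.0 * math.sin(theta / 2.0))
    v = bulge_dir - (bulge_dir @ u) * u
    nv = np.linalg.norm(v)
    if nv < 1e-8:
        v = np.array([1.0, 0.0, 0.0]) - u[0] * u
        nv = np.linalg.norm(v)
        if nv < 1e-8:
            v = np.array([0.0, 1.0, 0.0]) - u[1] * u
            nv = np.linalg.norm(v)
    v /= nv
    h = rho * math.cos(theta / 2.0)
    centre = (p1 + p2) / 2.0 - v * h
    phi1 = math.atan2(h, -c / 2.0)
    pts = []
    for m in range(1, n_seg):
        phi = phi1 - theta * m / n_seg
        pts.append(centre + rho * (math.cos(phi) * u + math.sin(phi) * v))
    return pts


def _radial_out(F, origin, point):
    """Unit vector from the helix axis through ``point`` (bulge direction)."""
    z = F[:, 2]
    rel = point - origin
    radial = rel - (rel @ z) * z
    n = np.linalg.norm(radial)
    return radial / n if n > 1e-8 else F[:, 0]


def _place_stem(node: _Node, F, origin, coords, pairs):
    """Place one stem and its enclosed content in the frame (F, origin)."""
    L = node.length
    for k in range(L):
        coords[node.start5 + k] = _helix_point(F, origin, k, 0.0)
        # 3' strand runs antiparallel: residue m of the 3' half sits at k = L-1-m
        coords[node.start3 + (L - 1 - k)] = _helix_point(F, origin, k, math.pi)
        pairs.append((node.start5 + k, node.start3 + (L - 1 - k)))

    p_top5 = coords[node.start5 + L - 1]
    p_top3 = coords[node.start3]
    inner = node.inner
    if len(inner) == 1 and inner[0].kind == "loop":
        loop = inner[0]
        pts = _connector(p_top5, p_top3, loop.length, F[:, 2])
        for m, p in enumerate(pts):
            coords[loop.start5 + m] = p
        return

    # one nested stem with symmetric linkers of length l each side
    l = inner[0].length if inner[0].kind == "linker" else 0
    stem = next(n for n in inner if n.kind == "stem")
    delta = (l + 1) * TWIST
    h = (l + 1) * RISE
    F_in = F @ _rz((L - 1) * TWIST + delta)
    origin_in = origin + F @ np.array([0.0, 0.0, (L - 1) * RISE + h])
    _place_stem(stem, F_in, origin_in, coords, pairs)

    if l > 0:
        lk5 = inner[0]
        q1 = coords[stem.start5]
        mid = (p_top5 + q1) / 2.0
        pts = _connector(p_top5, q1, l, _radial_out(F, origin, mid))
        for m, p in enumerate(pts):
            coords[lk5.start5 + m] = p
        lk3 = inner[-1]
        q2 = coords[stem.start3 + stem.length - 1]
        mid = (q2 + p_top3) / 2.0
        pts = _connector(q2, p_top3, l, _radial_out(F, origin, mid))
        for m, p in enumerate(pts):
            coords[lk3.start5 + m] = p


def generate_fold(spec: FoldSpec, entry_id: str | None = None):
    """Build the C3' trace and pairing of a fold specification.

    Deterministic per spec seed.  Returns (RnaChain, BasePairSet); the
    pair set is the constructed stem pairing.  Raises ValueError listing
    all specification violations.
    """
    errors = spec.validate()
    if errors:
        raise ValueError("invalid fold spec: " + "; ".join(errors))
    rng = np.random.default_rng(spec.seed)
    n = spec.total_length()
    coords = np.full((n, 3), np.nan)
    pairs: list[tuple[int, int]] = []
    tree = _parse_tree(spec.segments)

    cursor = None      # position of the previously placed residue
    direction = np.array([0.0, 0.0, 1.0])
    for node in tree:
        if node.kind == "linker":
            pos = cursor
            for m in range(node.length):
                direction = direction + 0.6 * rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                pos = np.zeros(3) if pos is None else pos + STEP * direction
                coords[node.start5 + m] = pos
            cursor = pos
        else:  # top-level stem unit
            if cursor is None:
                entry = np.zeros(3)
                axis = np.array([0.0, 0.0, 1.0])
            else:
                step_dir = direction + 0.3 * rng.normal(size=3)
                step_dir /= np.linalg.norm(step_dir)
                entry = cursor + STEP * step_dir
                axis = step_dir + 0.5 * rng.normal(size=3)
                axis /= np.linalg.norm(axis)
            F = _frame_from_axis(axis, float(rng.uniform(0.0, 2.0 * math.pi)))
            origin = entry - F @ np.array([RADIUS, 0.0, 0.0])
            _place_stem(node, F, origin, coords, pairs)
            exit_idx = node.start3 + node.length - 1     # 3' strand base (k = 0)
            cursor = coords[exit_idx]
            if node.length >= 2:
                prev = coords[node.start3 + node.length - 2]  # k = 1
                direction = cursor - prev
            else:
                direction = cursor - entry
            direction /= np.linalg.norm(direction)

    if np.isnan(coords).any():
        raise GeometryError("internal error: unplaced residues")

    seq = list(rng.choice(list("ACGU"), size=n))
    for i, j in pairs:
        seq[j] = _WC[seq[i]]

    chain = RnaChain(
        entry_id=entry_id or f"sim{spec.seed % 10**8:08d}",
        chain_id="A",
        sequence="".join(seq),
        auth_numbers=np.arange(1, n + 1),
        coords=coords,
        resolution=float(np.round(rng.uniform(1.5, 3.5), 2)),
        method="SYNTHETIC",
    )
    bps = BasePairSet(pairs=frozenset((min(i, j), max(i, j)) for i, j in pairs),
                      source="constructed")
    return chain, bps


# ---------------------------------------------------------------------------
# homologs, decoys, twilight clouds

def derive_homolog(chain: RnaChain, bp: BasePairSet, params: HomologParams):
    """Mutate and perturb a parent fold into a controlled homolog.

    Positions are mutated in seeded random order until the realised
    identity reaches ``target_pid``; with ``compensatory`` stem partners
    mutate jointly to another Watson-Crick pair so the pairing (and its
    index set) is preserved.  Coordinates get iid Gaussian noise and,
    optionally, a rigid domain shift.
    """
    rng = np.random.default_rng(params.seed)
    n = len(chain)
    seq = list(chain.sequence)
    partner = {}
    for i, j in bp.pairs:
        partner[i] = j
        partner[j] = i

    m_target = round(n * (100.0 - params.target_pid) / 100.0)
    processed: set[int] = set()
    order = rng.permutation(n)

    def n_diff():
        return sum(1 for i in range(n) if seq[i] != chain.sequence[i])

    for pos in order:
        if n_diff() >= m_target:
            break
        pos = int(pos)
        if pos in processed:
            continue
        if pos in partner and params.compensatory:
            j = partner[pos]
            i, j = (pos, j) if pos < j else (j, pos)
            options = [p for p in _WC_PAIRS if p != (seq[i], seq[j])]
            choice = options[int(rng.integers(len(options)))]
            seq[i], seq[j] = choice
            processed.update((i, j))
        else:
            others = [b for b in "ACGU" if b != seq[pos]]
            seq[pos] = others[int(rng.integers(3))]
            processed.add(pos)

    coords = chain.coords.copy()
    if params.coord_noise > 0:
        coords = coords + rng.normal(0.0, params.coord_noise, size=coords.shape)
    if params.domain_shift is not None:
        ds = params.domain_shift
        sl = slice(ds.start, ds.end + 1)
        block = coords[sl]
        centroid = block.mean(axis=0)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = Rotation.from_rotvec(math.radians(ds.rotation_deg) * axis).as_matrix()
        tdir = rng.normal(size=3)
        tdir /= np.linalg.norm(tdir)
        coords[sl] = (block - centroid) @ R.T + centroid + ds.translation * tdir

    hom = RnaChain(
        entry_id=f"{chain.entry_id}h{params.seed % 10**6}",
        chain_id=chain.chain_id,
        sequence="".join(seq),
        auth_numbers=chain.auth_numbers.copy(),
        coords=coords,
        resolution=chain.resolution,
        method=chain.method,
    )
    return hom, BasePairSet(pairs=bp.pairs, source="constructed")


def _random_spec(rng, target: int, seed: int) -> FoldSpec:
    segs: list[Segment] = []
    total = 0
    sid = 0
    first = True
    while total < target:
        if not first:
            l = int(rng.integers(2, 7))
            segs.append(Segment("linker", l))
            total += l
        stem = int(rng.integers(4, 13))
        loop = int(rng.integers(3, 9))
        if rng.random() < 0.4 and target - total > 60:
            inner = int(rng.integers(3, 9))
            il = int(rng.integers(0, 4))
            segs.append(Segment("stem", stem, sid))
            if il:
                segs.append(Segment("linker", il))
            segs.append(Segment("stem", inner, sid + 1))
            segs.append(Segment("loop", loop))
            segs.append(Segment("stem", inner, sid + 1))
            if il:
                segs.append(Segment("linker", il))
            segs.append(Segment("stem", stem, sid))
            total += 2 * stem + 2 * il + 2 * inner + loop
            sid += 2
        else:
            segs.append(Segment("stem", stem, sid))
            segs.append(Segment("loop", loop))
            segs.append(Segment("stem", stem, sid))
            total += 2 * stem + loop
            sid += 1
        first = False
    return FoldSpec(segments=segs, seed=seed)


def generate_decoy_set(n: int, length_range=(30, 300), seed: int = 0,
                       prefix: str = "dec"):
    """``n`` independent random folds with unrelated layouts and sequences.

    Deterministic per seed; every decoy passes the dataset filters (at
    least 20 nt and 4 base pairs).  Returns a list of (chain, pairs).
    """
    if n < 2:
        raise ValueError("need at least 2 decoys")
    lo, hi = length_range
    rng = np.random.default_rng(seed)
    out = []
    for d in range(n):
        target = int(rng.integers(lo, hi + 1))
        child = int(rng.integers(2**31))
        spec = _random_spec(np.random.default_rng(child), max(target, 20), child)
        out.append(generate_fold(spec, entry_id=f"{prefix}{d:04d}"))
    return out


def generate_twilight_points(curve: TwilightCurve, n_pos: int, n_neg: int,
                             margin: float = 0.5, label_noise: float = 0.0,
                             seed: int = 0, spread: float = 3.0):
    """Labeled (length, e-value) cloud around a known separating curve.

    Positives sit a clearance of at least ``margin`` (-log10 units)
    above the curve, negatives below, with an extra uniform offset up to
    ``spread``; labels flip with probability ``label_noise``.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    rng = np.random.default_rng(seed)
    points = []
    for label, count, sign in (("TP", n_pos, 1.0), ("TN", n_neg, -1.0)):
        for _ in range(count):
            N = int(rng.integers(30, 501))
            u = 1.0 - rng.random()   # in (0, 1]
            y = curve(N) + sign * (margin + spread * u)
            lab = label
            if label_noise > 0 and rng.random() < label_noise:
                lab = "TN" if label == "TP" else "TP"
            points.append(TwilightPoint(N=N, evalue=float(10.0 ** (-y)), label=lab))
    return points


def ladder_pairs(pids=(30, 40, 50, 60, 70, 80, 90, 100), n_folds: int = 6,
                 length_range=(60, 150), coupling: float = 0.05, seed: int = 0):
    """Homolog ladder: parent folds crossed with a grid of target identities.

    Structural divergence is coupled to sequence divergence as
    coord_noise = coupling * (100 - target_pid) A per coordinate, the
    package's default monotone sequence-structure relationship.  Returns
    tuples (parent, parent_pairs, homolog, homolog_pairs, target_pid).
    """
    rng = np.random.default_rng(seed)
    parents = generate_decoy_set(n_folds, length_range,
                                 seed=int(rng.integers(2**31)), prefix="fam")
    out = []
    for f, (chain, bps) in enumerate(parents):
        for pid in pids:
            params = HomologParams(
                target_pid=float(pid),
                coord_noise=coupling * (100.0 - float(pid)),
                compensatory=True,
                seed=int(rng.integers(2**31)),
            )
            hom, hbps = derive_homolog(chain, bps, params)
            out.append((chain, bps, hom, hbps, float(pid)))
    return out


# ---------------------------------------------------------------------------
# writers (minimal PDB + pair list, readable by the parsing module)

def chain_to_pdb(chain: RnaChain) -> str:
    lines = ["HEADER    RNA"]
    if chain.method:
        lines.append(f"EXPDTA    {chain.method}")
    if chain.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {chain.resolution:7.2f} ANGSTROMS.")
    for i in range(len(chain)):
        x, y, z = chain.coords[i]
        base = chain.sequence[i]
        lines.append(
            f"ATOM  {i + 1:5d}  C3' {base:>3s} {chain.chain_id[:1]}"
            f"{int(chain.auth_numbers[i]):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def pairs_to_text(chain: RnaChain, bps: BasePairSet) -> str:
    """Two-column author-number pair list (the annotation reader's format)."""
    rows = []
    for i, j in sorted(bps.pairs):
        rows.append(f"{int(chain.auth_numbers[i])} {int(chain.auth_numbers[j])}")
    return "\n".join(rows) + "\n"
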