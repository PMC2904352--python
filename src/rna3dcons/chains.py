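"""RNA chain model, structure-file parsing and dataset-construction filters.

The package represents an RNA chain by the C3' trace of its nucleotides:
the whole downstream analysis (unit-vector alignment, identity scores,
core RMSD) operates on C3' atoms only.  Modified nucleotides are mapped
to their parent base where the parent is known, otherwise to ``N``;
``N`` never counts as identical in sequence-identity scores.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RnaChain",
    "DatasetFilterReport",
    "parse_rna_chain",
    "extract_n1n3",
    "filter_dataset",
    "is_substructure",
    "chain_to_tsv",
    "chain_from_tsv",
    "MODIFIED_BASE_MAP",
]

#: Parent-base lookup for common modified ribonucleotides.  Unknown
#: nucleotide-like residues fall back to "N".
MODIFIED_BASE_MAP: dict[str, str] = {
    # uridine family
    "PSU": "U", "H2U": "U", "5MU": "U", "4SU": "U", "OMU": "U", "UR3": "U",
    "70U": "U", "5BU": "U", "DHU": "U", "S4U": "U", "T": "U", "RT": "U",
    # adenosine family
    "1MA": "A", "2MA": "A", "MA6": "A", "MIA": "A", "T6A": "A", "RIA": "A",
    "A23": "A", "6MZ": "A",
    # guanosine family
    "2MG": "G", "M2G": "G", "7MG": "G", "OMG": "G", "1MG": "G", "G7M": "G",
    "YG": "G", "YYG": "G", "QUO": "G", "I": "G", "IG": "G",
    # cytidine family
    "5MC": "C", "OMC": "C", "4OC": "C", "M5C": "C", "IC": "C",
}

_DNA_NAMES = {"DA", "DC", "DG", "DT", "DI", "DU"}
_C3_NAMES = ("C3'", "C3*")


@dataclass
class RnaChain:
    """An ordered RNA chain reduced to its C3' trace.

    ``sequence`` is over {A, C, G, U, N}; ``coords`` holds one C3'
    coordinate per residue (angstroms, model order 5'->3').  Author
    residue numbers are retained for reporting only; all internal
    indexing is 0-based.
    """

    entry_id: str
    chain_id: str
    sequence: str
    auth_numbers: np.ndarray
    coords: np.ndarray
    resolution: float | None = None
    method: str = ""

    def __post_init__(self) -> None:
        self.auth_numbers = np.asarray(self.auth_numbers, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        n = len(self.sequence)
        if n < 1:
            raise ValueError("empty chain")
        if self.coords.shape != (n, 3) or self.auth_numbers.shape != (n,):
            raise ValueError("sequence, coords and auth_numbers lengths disagree")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def key(self) -> str:
        """Chain key: lowercase entry id, case-preserved chain id."""
        return f"{self.entry_id.lower()}_{self.chain_id}"

    @property
    def residues(self) -> list[tuple[int, str, np.ndarray]]:
        return [
            (int(self.auth_numbers[i]), self.sequence[i], self.coords[i])
            for i in range(len(self))
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RnaChain):
            return NotImplemented
        return (
            self.entry_id == other.entry_id
            and self.chain_id == other.chain_id
            and self.sequence == other.sequence
            and np.array_equal(self.auth_numbers, other.auth_numbers)
            and np.array_equal(self.coords, other.coords)
            and self.resolution == other.resolution
            and self.method == other.method
        )


@dataclass
class DatasetFilterReport:
    """Bookkeeping of the dataset-inclusion filters (first-failing wins)."""

    n_input: int = 0
    n_too_short: int = 0
    n_too_few_pairs: int = 0
    n_duplicate: int = 0
    kept: list[str] = field(default_factory=list)

    def check(self) -> None:
        total = self.n_too_short + self.n_too_few_pairs + self.n_duplicate
        if self.n_input != len(self.kept) + total:
            raise AssertionError("filter report counts do not sum to input count")


def _base_code(resname: str) -> str | None:
    """Map a residue name to {A,C,G,U,N} or None for non-RNA residues."""
    rn = resname.strip().upper()
    if rn in {"A", "C", "G", "U"}:
        return rn
    if rn in MODIFIED_BASE_MAP:
        return MODIFIED_BASE_MAP[rn]
    if rn in _DNA_NAMES or rn == "HOH":
        return None
    info = gemmi.find_tabulated_residue(rn)
    if info is not None and info.found():
        if info.is_amino_acid() or info.is_water():
            return None
        if info.is_nucleic_acid():
            return "N"
    return None


def _read_structure(file_content: str) -> gemmi.Structure:
    text = file_content.lstrip()
    if text.startswith("data_") or "_atom_site." in text:
        doc = gemmi.cif.read_string(file_content)
        return gemmi.make_structure_from_block(doc.sole_block())
    return gemmi.read_pdb_string(file_content)


def _pick_atom(residue: gemmi.Residue, names: tuple[str, ...]) -> gemmi.Atom | None:
    """Highest-occupancy atom among ``names``; occupancy ties go to altloc A."""
    candidates = [a for a in residue if a.name in names]
    if not candidates:
        return None
    def rank(a: gemmi.Atom) -> tuple[float, int, str]:
        alt = a.altloc if a.altloc != "\0" else ""
        return (-a.occ, 0 if alt in ("", "A") else 1, alt)
    return sorted(candidates, key=rank)[0]


def _extract(file_content: str, chain_id: str, entry_id: str | None,
             atom_names: tuple[str, ...]) -> tuple[RnaChain, dict[int, np.ndarray]]:
    st = _read_structure(file_content)
    if len(st) == 0:
        raise ValueError("structure contains no models")
    model = st[0]  # model 1 only
    chain = None
    for ch in model:
        if ch.name == chain_id:
            chain = ch
            break
    if chain is None:
        raise KeyError(f"chain not found: {chain_id!r}")

    seq: list[str] = []
    nums: list[int] = []
    xyz: list[list[float]] = []
    extra: dict[int, np.ndarray] = {}
    for res in chain:
        code = _base_code(res.name)
        if code is None:
            continue
        atom = _pick_atom(res, _C3_NAMES)
        if atom is None:
            logger.warning(
                "residue %s %s in chain %s lacks a C3' atom; dropped",
                res.name, res.seqid.num, chain_id,
            )
            continue
        idx = len(seq)
        seq.append(code)
        nums.append(res.seqid.num)
        xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        other = _pick_atom(res, atom_names) if atom_names else None
        if other is not None:
            extra[idx] = np.array([other.pos.x, other.pos.y, other.pos.z])
    if not seq:
        raise ValueError(f"no RNA residues in chain {chain_id!r}")

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    info = dict(st.info)
    method = info.get("_exptl.method", "")
    eid = (entry_id or info.get("_entry.id") or st.name or "xxxx").lower()
    chain_obj = RnaChain(
        entry_id=eid,
        chain_id=chain_id,
        sequence="".join(seq),
        auth_numbers=np.array(nums, dtype=np.int64),
        coords=np.array(xyz, dtype=np.float64),
        resolution=resolution,
        method=method,
    )
    return chain_obj, extra


def parse_rna_chain(file_content: str, chain_id: str,
                    entry_id: str | None = None) -> RnaChain:
    """Parse one RNA chain (C3' trace) from PDB or mmCIF text.

    Residues lacking a C3' atom are dropped with a logged warning;
    non-RNA residues (amino acids, waters, ions, DNA) are excluded.
    Multi-model files use model 1 only; alternate locations resolve to
    the highest-occupancy atom (ties to altloc A).

    Raises
    ------
    KeyError
        If the chain is absent ("chain not found").
    ValueError
        If the chain has no usable nucleotides ("no RNA residues").
    """
    chain, _ = _extract(file_content, chain_id, entry_id, ())
    return chain


def extract_n1n3(file_content: str, chain_id: str) -> dict[int, np.ndarray]:
    """Per-residue glycosidic-edge nitrogen coordinates (N1 purine / N3 pyrimidine).

    Returns a mapping from the 0-based index of each residue kept by
    :func:`parse_rna_chain` to the coordinate of its N1 or N3 atom, for
    use by the hydrogen-bond criterion of the base-pair detector.  Only
    available for full-atom files; C3'-only traces yield an empty dict.
    """
    chain, extra = _extract(file_content, chain_id, None, ("N1", "N3"))
    picked: dict[int, np.ndarray] = {}
    st = _read_structure(file_content)
    model = st[0]
    for ch in model:
        if ch.name != chain_id:
            continue
        idx = 0
        for res in ch:
            code = _base_code(res.name)
            if code is None:
                continue
            if _pick_atom(res, _C3_NAMES) is None:
                continue
            name = "N1" if code in ("A", "G") else "N3"
            atom = _pick_atom(res, (name,))
            if atom is not None:
                picked[idx] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            idx += 1
    return picked


def filter_dataset(chains, pair_sets):
    """Apply the dataset-inclusion filters.

    Removes chains shorter than 20 nt or with fewer than 4 base pairs
    (first-failing filter wins, length checked first), then removes
    chains whose sequence is 100% identical to an already-kept chain.
    Deduplication keeps the first chain by (resolution ascending,
    entry id, chain id); entries without resolution sort last.

    Returns ``(kept_chains, kept_pair_sets, report)``.
    """
    report = DatasetFilterReport(n_input=len(chains))
    if len(chains) != len(pair_sets):
        raise ValueError("chains and pair_sets must align by index")

    survivors: list[int] = []
    for i, (chain, bps) in enumerate(zip(chains, pair_sets)):
        if len(chain) < 20:
            report.n_too_short += 1
        elif len(bps.pairs) < 4:
            report.n_too_few_pairs += 1
        else:
            survivors.append(i)

    def dedup_rank(i: int):
        c = chains[i]
        res = c.resolution if c.resolution is not None else float("inf")
        return (res, c.entry_id, c.chain_id)

    seen: dict[str, int] = {}
    for i in sorted(survivors, key=dedup_rank):
        seq = chains[i].sequence
        if seq in seen:
            report.n_duplicate += 1
        else:
            seen[seq] = i
    kept_idx = sorted(seen.values())
    kept = [chains[i] for i in kept_idx]
    kept_pairs = [pair_sets[i] for i in kept_idx]
    report.kept = [c.key for c in kept]
    report.check()
    return kept, kept_pairs, report


def is_substructure(a: RnaChain, b: RnaChain) -> bool:
    """True iff the shorter chain's sequence is a contiguous substring of the longer's."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    return short.sequence in long_.sequence


# ---------------------------------------------------------------------------
# internal TSV dump (exact round trip)

def chain_to_tsv(chain: RnaChain) -> str:
    buf = io.StringIO()
    res = "" if chain.resolution is None else repr(chain.resolution)
    buf.write(f"# entry_id={chain.entry_id}\n")
    buf.write(f"# chain_id={chain.chain_id}\n")
    buf.write(f"# resolution={res}\n")
    buf.write(f"# method={chain.method}\n")
    buf.write("key\tindex\tauthor_number\tbase\tx\ty\tz\n")
    for i in range(len(chain)):
        x, y, z = (float(v) for v in chain.coords[i])
        buf.write(
            f"{chain.key}\t{i}\t{chain.auth_numbers[i]}\t{chain.sequence[i]}"
            f"\t{x!r}\t{y!r}\t{z!r}\n"
        )
    return buf.getvalue()


def chain_from_tsv(text: str) -> RnaChain:
    meta: dict[str, str] = {}
    seq, nums, xyz = [], [], []
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v
            continue
        if line.startswith("key\t"):
            continue
        parts = line.split("\t")
        seq.append(parts[3])
        nums.append(int(parts[2]))
        xyz.append([float(parts[4]), float(parts[5]), float(parts[6])])
    resolution = float(meta["resolution"]) if meta.get("resolution") else None
    return RnaChain(
        entry_id=meta["entry_id"],
        chain_id=meta["chain_id"],
        sequence="".join(seq),
        auth_numbers=np.array(nums, dtype=np.int64),
        coords=np.array(xyz, dtype=np.float64),
        resolution=resolution,
        method=meta.get("method", ""),
    )
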