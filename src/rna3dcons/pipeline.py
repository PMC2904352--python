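"""All-against-all comparison and dataset construction.

Reproduces the dataset logic of the conservation analysis: an
all-against-all structure comparison yields one record per unordered
chain pair; the non-related subset (NR, sequence identity below 25%)
calibrates the Gumbel background; the high-accuracy subset (HA, all
three -ln(p) >= 4.5, resolution <= 5 A, no substructure pairs) feeds
the sequence-structure conservation analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, asdict

import pandas as pd

from .chains import RnaChain, is_substructure
from .pairing import BasePairSet
from .sara import AlignConfig, DEFAULT_CONFIG, align_pair
from .scoring import (AlignmentScores, EvdParams, SignificanceResult,
                      alignment_significance, fit_evd_background, score_alignment)

logger = logging.getLogger(__name__)

__all__ = [
    "PairRecord",
    "all_against_all",
    "build_nr_set",
    "build_ha_set",
    "attach_significance",
    "calibrate_from_records",
    "decoy_background",
    "records_to_dataframe",
    "write_records_tsv",
    "read_evd_params_tsv",
    "write_evd_params_tsv",
]

NR_MAX_PID = 25.0
HA_MIN_NLP = 4.5
HA_MAX_RESOLUTION = 5.0


@dataclass
class PairRecord:
    """One unordered chain pair: keys in canonical order, scores, significance."""

    key_a: str
    key_b: str
    scores: AlignmentScores | None = None
    significance: SignificanceResult | None = None
    resolution_worst: float | None = None
    error: str | None = None


def _params_hash(config: AlignConfig) -> str:
    return hashlib.sha1(repr(config).encode()).hexdigest()[:12]


def _record_to_cache(rec: PairRecord) -> dict:
    d = {"key_a": rec.key_a, "key_b": rec.key_b, "error": rec.error,
         "resolution_worst": rec.resolution_worst}
    d["scores"] = asdict(rec.scores) if rec.scores else None
    return d


def _record_from_cache(d: dict) -> PairRecord:
    scores = AlignmentScores(**d["scores"]) if d.get("scores") else None
    return PairRecord(key_a=d["key_a"], key_b=d["key_b"], scores=scores,
                      resolution_worst=d.get("resolution_worst"),
                      error=d.get("error"))


def all_against_all(chains, pair_sets, config: AlignConfig = DEFAULT_CONFIG,
                    cache_path: str | None = None) -> list[PairRecord]:
    """Align and score every unordered pair of chains.

    Produces exactly n(n-1)/2 records in deterministic order.  Failures
    of individual pairs are recorded (``error`` field), never dropped.
    With ``cache_path``, finished pairs are stored as JSON lines keyed
    by (pair key, parameter hash) and re-used on resumption.
    """
    phash = _params_hash(config)
    cache: dict[tuple[str, str], PairRecord] = {}
    if cache_path and os.path.exists(cache_path):
        with open(cache_path) as fh:
            for line in fh:
                d = json.loads(line)
                if d.get("phash") == phash:
                    cache[(d["key_a"], d["key_b"])] = _record_from_cache(d)

    out_fh = open(cache_path, "a") if cache_path else None
    records: list[PairRecord] = []
    try:
        n = len(chains)
        for i in range(n):
            for j in range(i + 1, n):
                A, B = chains[i], chains[j]
                bpA, bpB = pair_sets[i], pair_sets[j]
                key = tuple(sorted((A.key, B.key)))
                if key in cache:
                    records.append(cache[key])
                    continue
                resolutions = [c.resolution for c in (A, B)]
                worst = (max(resolutions) if all(r is not None for r in resolutions)
                         else None)
                try:
                    aln = align_pair(A, B, bpA, bpB, config)
                    scores = score_alignment(aln, A, B, bpA, bpB)
                    rec = PairRecord(key_a=aln.key_a, key_b=aln.key_b,
                                     scores=scores, resolution_worst=worst)
                except Exception as exc:  # recorded, not dropped
                    logger.warning("pair %s failed: %s", key, exc)
                    rec = PairRecord(key_a=key[0], key_b=key[1],
                                     resolution_worst=worst, error=str(exc))
                records.append(rec)
                if out_fh is not None:
                    d = _record_to_cache(rec)
                    d["phash"] = phash
                    out_fh.write(json.dumps(d, sort_keys=True) + "\n")
    finally:
        if out_fh is not None:
            out_fh.close()
    return records


def build_nr_set(records) -> list[PairRecord]:
    """Non-related subset: sequence identity strictly below 25%."""
    return [r for r in records
            if r.scores is not None and r.scores.pid < NR_MAX_PID]


def build_ha_set(records, chains: dict[str, RnaChain],
                 report: dict | None = None) -> list[PairRecord]:
    """High-accuracy subset: all three -ln(p) >= 4.5, both resolutions
    <= 5 A, and not a structure/substructure pair.

    ``chains`` maps chain keys to RnaChain (for the substructure test).
    Records lacking significance or resolution are excluded and counted
    in ``report`` when given.
    """
    counts = {"no_scores": 0, "no_significance": 0, "below_cutoff": 0,
              "missing_resolution": 0, "poor_resolution": 0, "substructure": 0}
    kept = []
    for r in records:
        if r.scores is None:
            counts["no_scores"] += 1
            continue
        sig = r.significance
        if sig is None or None in (sig.nlp_psi, sig.nlp_pss, sig.nlp_pid):
            counts["no_significance"] += 1
            continue
        if not (sig.nlp_psi >= HA_MIN_NLP and sig.nlp_pss >= HA_MIN_NLP
                and sig.nlp_pid >= HA_MIN_NLP):
            counts["below_cutoff"] += 1
            continue
        if r.resolution_worst is None:
            counts["missing_resolution"] += 1
            continue
        if r.resolution_worst > HA_MAX_RESOLUTION:
            counts["poor_resolution"] += 1
            continue
        if is_substructure(chains[r.key_a], chains[r.key_b]):
            counts["substructure"] += 1
            continue
        kept.append(r)
    if report is not None:
        report.update(counts)
    return kept


def calibrate_from_records(records, method: str = "moments") -> dict[str, EvdParams]:
    """Fit the Gumbel background from the NR subset of scored records."""
    nr = build_nr_set(records)
    params = {}
    for key, attr in (("PSI", "psi"), ("PSS", "pss"), ("PID", "pid")):
        vals = [getattr(r.scores, attr) for r in nr
                if getattr(r.scores, attr) is not None]
        params[key] = fit_evd_background(vals, method=method, score_type=key)
    return params


def decoy_background(n_decoys: int = 120, length_range=(30, 300),
                     seed: int = 20100615, config: AlignConfig = DEFAULT_CONFIG,
                     method: str = "moments"):
    """Gumbel background from all-against-all alignments of generated decoys.

    The desk-scale default: 120 independent random folds of 30-300 nt,
    aligned all against all; PSI/PSS/PID backgrounds fitted on the
    resulting unrelated-pair scores.  Returns (params, records).
    """
    from .synthetic import generate_decoy_set

    decoys = generate_decoy_set(n_decoys, length_range, seed=seed)
    chains = [c for c, _ in decoys]
    pair_sets = [b for _, b in decoys]
    records = all_against_all(chains, pair_sets, config)
    scored = [r for r in records if r.scores is not None]
    params = {}
    for key, attr in (("PSI", "psi"), ("PSS", "pss"), ("PID", "pid")):
        vals = [getattr(r.scores, attr) for r in scored
                if getattr(r.scores, attr) is not None]
        params[key] = fit_evd_background(vals, method=method, score_type=key)
    return params, records


def attach_significance(records, params: dict[str, EvdParams]) -> None:
    """Fill the significance field of every scored record in place."""
    for r in records:
        if r.scores is not None:
            r.significance = alignment_significance(r.scores, params)


# ---------------------------------------------------------------------------
# tabular output

_COLUMNS = ["key_a", "key_b", "N", "NP", "n_al", "p_al", "n_id",
            "psi", "pss", "pid", "core_rmsd",
            "p_psi", "p_pss", "p_pid", "nlp_psi", "nlp_pss", "nlp_pid",
            "resolution_worst", "error"]


def records_to_dataframe(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"key_a": r.key_a, "key_b": r.key_b,
               "resolution_worst": r.resolution_worst, "error": r.error}
        if r.scores is not None:
            s = r.scores
            row.update(N=s.N, NP=s.NP, n_al=s.n_al, p_al=s.p_al, n_id=s.n_id,
                       psi=s.psi, pss=s.pss, pid=s.pid, core_rmsd=s.core_rmsd)
        if r.significance is not None:
            g = r.significance
            row.update(p_psi=g.p_psi, p_pss=g.p_pss, p_pid=g.p_pid,
                       nlp_psi=g.nlp_psi, nlp_pss=g.nlp_pss, nlp_pid=g.nlp_pid)
        rows.append(row)
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_records_tsv(records, path: str) -> None:
    df = records_to_dataframe(records)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g",
              lineterminator="\n")


def write_evd_params_tsv(params: dict[str, EvdParams], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("score_type\tmu\tsigma\tn\n")
        for key in sorted(params):
            p = params[key]
            fh.write(f"{p.score_type}\t{p.mu!r}\t{p.sigma!r}\t{p.n_background}\n")


def read_evd_params_tsv(path_or_text: str) -> dict[str, EvdParams]:
    if os.path.exists(path_or_text):
        with open(path_or_text) as fh:
            text = fh.read()
    else:
        text = path_or_text
    params = {}
    for line in text.strip().splitlines()[1:]:
        st, mu, sigma, n = line.split("\t")
        params[st] = EvdParams(mu=float(mu), sigma=float(sigma),
                               score_type=st, n_background=int(n))
    return params
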