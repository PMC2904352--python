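"""The twilight zone of RNA homology detection.

Structure-verified pair labels (true positive / true negative by the
triple -ln(p) cutoff at 4.5) are combined with sequence-search e-values
to fit, in (alignment length N, -log10 e-value) space, the exponential
curve  -log10(e-value) = A + B * exp(-k * N)  that best separates true
positives from true negatives by Matthews correlation coefficient.
Pairs above the curve are predicted homologous.
"""

from __future__ import annotations

import io
import logging
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "TwilightPoint",
    "TwilightCurve",
    "ConfusionCounts",
    "label_pairs",
    "evaluate_curve",
    "classify_points",
    "fit_twilight_curve",
    "read_points_tsv",
    "read_cmsearch_tblout",
    "NLP_CUTOFF",
]

NLP_CUTOFF = 4.5


@dataclass(frozen=True)
class TwilightPoint:
    """One aligned pair: shorter sequence length, e-value and label."""

    N: int
    evalue: float
    label: str  # TP, TN or MEDIUM

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not (self.evalue > 0 and math.isfinite(self.evalue)):
            raise ValueError("evalue must be finite and positive")
        if self.label not in ("TP", "TN", "MEDIUM"):
            raise ValueError(f"bad label {self.label!r}")


@dataclass(frozen=True)
class TwilightCurve:
    """-log10(e-value) threshold curve A + B * exp(-k N)."""

    A: float
    B: float
    k: float

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("decay rate k must be >= 0")

    def __call__(self, N):
        return evaluate_curve(self, N)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    mcc: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "ConfusionCounts":
        return cls(tp=tp, fp=fp, tn=tn, fn=fn, mcc=_mcc(tp, fp, tn, fn))


def _mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def label_pairs(records) -> list[tuple]:
    """Label pair records by the triple significance cutoff.

    TP: all three -ln(p) strictly above 4.5; TN: all three at or below
    4.5; otherwise MEDIUM.  Records without significance are skipped
    with a warning.  Returns (record, label) tuples.
    """
    out = []
    for r in records:
        sig = getattr(r, "significance", None)
        if sig is None or None in (sig.nlp_psi, sig.nlp_pss, sig.nlp_pid):
            logger.warning("record %s-%s lacks significance; skipped",
                           getattr(r, "key_a", "?"), getattr(r, "key_b", "?"))
            continue
        nlps = (sig.nlp_psi, sig.nlp_pss, sig.nlp_pid)
        if all(v > NLP_CUTOFF for v in nlps):
            label = "TP"
        elif all(v <= NLP_CUTOFF for v in nlps):
            label = "TN"
        else:
            label = "MEDIUM"
        out.append((r, label))
    return out


def evaluate_curve(curve: TwilightCurve, N) -> np.ndarray | float:
    """-log10 e-value threshold at length N: A + B * exp(-k N)."""
    N = np.asarray(N, dtype=float)
    val = curve.A + curve.B * np.exp(-curve.k * N)
    return float(val) if val.ndim == 0 else val


def _arrays(points):
    pts = [p for p in points if p.label != "MEDIUM"]
    if not pts:
        raise ValueError("no non-MEDIUM points")
    N = np.array([p.N for p in pts], dtype=float)
    y = -np.log10(np.array([p.evalue for p in pts], dtype=float))
    pos = np.array([p.label == "TP" for p in pts])
    return N, y, pos


def classify_points(points, curve: TwilightCurve) -> ConfusionCounts:
    """Confusion counts of the curve as a homology classifier.

    Predicted positive iff -log10(e-value) strictly exceeds the curve at
    N; MEDIUM points are ignored; MCC is 0 when any confusion marginal
    is empty.
    """
    N, y, pos = _arrays(points)
    pred = y > evaluate_curve(curve, N)
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    return ConfusionCounts.from_counts(tp, fp, tn, fn)


def _counts_for(N, y, pos, A, B, k):
    pred = y > A + B * np.exp(-k * N)
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    return tp, fp, tn, fn


def fit_twilight_curve(points) -> tuple[TwilightCurve, ConfusionCounts]:
    """Curve in the A + B exp(-k N) family maximising MCC over TP/TN points.

    Deterministic search: a coarse grid (A in [0, 10] step 0.25, B in
    [1, 1000] and k in [0.005, 0.3] log-spaced), followed by local grid
    refinement around the best cells and a Nelder-Mead polish.  Ties are
    broken by fewer false positives, then smaller B.  MEDIUM points are
    excluded.  Raises if either class is absent.
    """
    N, y, pos = _arrays(points)
    n_tp = int(pos.sum())
    n_tn = int((~pos).sum())
    if n_tp == 0 or n_tn == 0:
        raise ValueError("need both TP and TN points to fit the twilight curve")
    if n_tp < 10 or n_tn < 10:
        logger.warning("fewer than 10 points in a class (TP=%d, TN=%d)", n_tp, n_tn)

    def quality(A, B, k):
        tp, fp, tn, fn = _counts_for(N, y, pos, A, B, k)
        return (_mcc(tp, fp, tn, fn), -fp, -B), (tp, fp, tn, fn)

    A_grid = np.arange(0.0, 10.0 + 1e-9, 0.25)
    B_grid = np.geomspace(1.0, 1000.0, 25)
    k_grid = np.geomspace(0.005, 0.3, 25)

    best_q = None
    best = None
    top: list = []  # (quality, params), kept small
    for k in k_grid:
        E = np.exp(-k * N)
        for B in B_grid:
            t0 = B * E
            for A in A_grid:
                pred = y > t0 + A
                tp = int(np.sum(pred & pos))
                fp = int(np.sum(pred & ~pos))
                fn = n_tp - tp
                tn = n_tn - fp
                q = (_mcc(tp, fp, tn, fn), -fp, -B)
                top.append((q, (A, B, k)))
                if len(top) > 200:
                    top.sort(key=lambda z: z[0], reverse=True)
                    del top[5:]
                if best_q is None or q > best_q:
                    best_q = q
                    best = (A, B, k)
    top.sort(key=lambda z: z[0], reverse=True)
    seeds = [p for _, p in top[:5]]

    # local grid refinement (the MCC surface is piecewise constant)
    ratio_B = (B_grid[1] / B_grid[0])
    ratio_k = (k_grid[1] / k_grid[0])
    stepA = 0.25
    for seed in seeds:
        local = seed
        local_q, _c = quality(*seed)
        rB, rk, sA = ratio_B, ratio_k, stepA
        for _ in range(4):
            A0, B0, k0 = local
            A_loc = A0 + sA * np.linspace(-1, 1, 9)
            B_loc = B0 * rB ** np.linspace(-1, 1, 9)
            k_loc = k0 * rk ** np.linspace(-1, 1, 9)
            for k in k_loc:
                for B in B_loc:
                    for A in A_loc:
                        if A < 0 or B <= 0 or k < 0:
                            continue
                        q, _c = quality(A, B, k)
                        if q > local_q:
                            local_q = q
                            local = (float(A), float(B), float(k))
            rB = rB ** 0.35
            rk = rk ** 0.35
            sA *= 0.35
        if local_q > best_q:
            best_q = local_q
            best = local

    # Nelder-Mead polish (may not improve on a plateau; kept for smooth cases)
    def neg_mcc(theta):
        A, B, k = theta
        if A < 0 or B <= 0 or k < 0:
            return 2.0
        tp, fp, tn, fn = _counts_for(N, y, pos, A, B, k)
        return -_mcc(tp, fp, tn, fn)

    res = optimize.minimize(neg_mcc, np.array(best), method="Nelder-Mead",
                            options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-6})
    if res.x is not None and np.all(np.isfinite(res.x)):
        A, B, k = res.x
        if A >= 0 and B > 0 and k >= 0:
            q, _c = quality(A, B, k)
            if q > best_q:
                best_q = q
                best = (float(A), float(B), float(k))

    curve = TwilightCurve(A=float(best[0]), B=float(best[1]), k=float(best[2]))
    tp, fp, tn, fn = _counts_for(N, y, pos, *best)
    return curve, ConfusionCounts.from_counts(tp, fp, tn, fn)


# ---------------------------------------------------------------------------
# input adapters

def read_points_tsv(path_or_text: str) -> list[TwilightPoint]:
    """Read a (query, target, N, evalue[, label]) tab-separated table.

    Rows with missing or non-positive e-values are dropped with a
    warning; without a label column every point is MEDIUM (labels can be
    joined later from structure alignments).
    """
    if os.path.exists(path_or_text):
        df = pd.read_csv(path_or_text, sep="\t")
    else:
        df = pd.read_csv(io.StringIO(path_or_text), sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for needed in ("n", "evalue"):
        if needed not in cols:
            raise ValueError(f"missing column {needed!r}")
    points = []
    for _, row in df.iterrows():
        ev = row[cols["evalue"]]
        if not (pd.notna(ev) and float(ev) > 0):
            logger.warning("row with non-positive/missing e-value dropped: %s",
                           row.to_dict())
            continue
        label = str(row[cols["label"]]) if "label" in cols else "MEDIUM"
        points.append(TwilightPoint(N=int(row[cols["n"]]), evalue=float(ev),
                                    label=label))
    return points


def read_cmsearch_tblout(text: str) -> pd.DataFrame:
    """Extract (target, query, evalue) from Infernal cmsearch --tblout text."""
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 16:
            continue
        rows.append({"target": parts[0], "query": parts[2],
                     "evalue": float(parts[15])})
    return pd.DataFrame(rows, columns=["target", "query", "evalue"])
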