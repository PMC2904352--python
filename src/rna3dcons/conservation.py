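"""Sequence-structure conservation: exponential-decay fits and summaries.

The central empirical relationship is an exponential decay of structural
divergence with sequence identity: y = c + a * exp(-b * x), fitted by
least squares from a fixed multi-start grid.  The "correlation
coefficient" of a fit is the Pearson r between observed and fitted
responses, as conventional when a nonlinear curve is reported with a
single r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["DecayFit", "fit_exponential_decay", "summarize_relationship", "pearson"]


@dataclass
class DecayFit:
    a: float
    b: float
    c: float
    pearson_r: float
    n: int
    sse: float


def _model(x, a, b, c):
    return c + a * np.exp(-np.clip(b * x, -700.0, 700.0))


def fit_exponential_decay(x, y, fix_c_zero: bool = False) -> DecayFit:
    """Least-squares fit of y = c + a exp(-b x) (deterministic multi-start).

    Starts span a in {+range(y), -range(y)}, b in {0.001, 0.01, 0.1},
    c = min(y); the best converged fit by residual sum of squares wins.
    ``fix_c_zero`` switches to the two-parameter family c = 0.

    Raises on fewer than 10 points, degenerate x spread, constant y, or
    non-convergence from every start.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 10:
        raise ValueError("need at least 10 finite points")
    if np.ptp(x) <= 0:
        raise ValueError("x has no spread")
    if np.ptp(y) <= 0:
        raise ValueError("y is constant; decay model is degenerate")

    yr = float(np.ptp(y))
    c0 = float(np.min(y))
    failures = []
    best = None
    for a0 in (yr, -yr):
        for b0 in (0.001, 0.01, 0.1):
            p0 = [a0, b0] if fix_c_zero else [a0, b0, c0]
            fun = (lambda x, a, b: _model(x, a, b, 0.0)) if fix_c_zero else _model
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = optimize.curve_fit(fun, x, y, p0=p0, maxfev=20000)
            except (RuntimeError, optimize.OptimizeWarning) as exc:
                failures.append(str(exc))
                continue
            yhat = fun(x, *popt)
            sse = float(np.sum((y - yhat) ** 2))
            if np.isfinite(sse) and (best is None or sse < best[0]):
                best = (sse, popt, yhat)
    if best is None:
        raise RuntimeError(
            "exponential fit did not converge from any start: " + "; ".join(failures))
    sse, popt, yhat = best
    if np.ptp(yhat) > 0:
        r = float(stats.pearsonr(y, yhat)[0])
    else:
        r = float("nan")
    a, b = float(popt[0]), float(popt[1])
    c = 0.0 if fix_c_zero else float(popt[2])
    return DecayFit(a=a, b=b, c=c, pearson_r=r, n=int(x.size), sse=sse)


def pearson(x, y):
    """Pearson r with a two-sided p-value (t-distribution transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) <= 0 or np.ptp(y) <= 0:
        return None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def summarize_relationship(df) -> dict:
    """Medians, correlations and decay fits of a high-accuracy pair table.

    ``df`` is a DataFrame with columns pid, psi, pss, core_rmsd (the
    output of the dataset pipeline).  Returns a dict with score medians,
    Pearson correlations (r, two-sided p) for the pairings (PID, PSI),
    (PID, RMSD), (PSS, PSI) and (PID, PSS), the (PID, RMSD) correlation
    inside the 30-60% and 90-100% identity subgroups, a sensitivity
    correlation excluding alignments above 95% identity, and the
    exponential-decay fits for each pairing.  Cells that cannot be
    computed (fewer than 3 points, no spread) are None.
    """
    need = {"pid", "psi", "pss", "core_rmsd"}
    if not need <= set(df.columns):
        raise ValueError(f"missing columns: {need - set(df.columns)}")
    d = df.dropna(subset=["pid", "psi", "core_rmsd"])
    if len(d) < 10:
        raise ValueError("need at least 10 scored records")

    out: dict = {
        "n": int(len(d)),
        "median_pid": float(d["pid"].median()),
        "median_psi": float(d["psi"].median()),
        "median_pss": float(d["pss"].median()) if d["pss"].notna().any() else None,
    }
    pairings = {
        "pid_psi": ("pid", "psi"),
        "pid_rmsd": ("pid", "core_rmsd"),
        "pss_psi": ("pss", "psi"),
        "pid_pss": ("pid", "pss"),
    }
    out["correlations"] = {k: pearson(d[cx], d[cy]) for k, (cx, cy) in pairings.items()}

    low = d[(d["pid"] >= 30) & (d["pid"] < 60)]
    high = d[(d["pid"] >= 90) & (d["pid"] <= 100)]
    out["subgroup_pid_rmsd_30_60"] = (
        pearson(low["pid"], low["core_rmsd"]) if len(low) >= 3 else None)
    out["subgroup_pid_rmsd_90_100"] = (
        pearson(high["pid"], high["core_rmsd"]) if len(high) >= 3 else None)

    trimmed = d[d["pid"] <= 95]
    out["pid_rmsd_excl_gt95"] = (
        pearson(trimmed["pid"], trimmed["core_rmsd"]) if len(trimmed) >= 3 else None)

    fits = {}
    for k, (cx, cy) in pairings.items():
        sub = d.dropna(subset=[cx, cy])
        try:
            fits[k] = fit_exponential_decay(sub[cx], sub[cy])
        except (ValueError, RuntimeError):
            fits[k] = None
    out["decay_fits"] = fits
    return out
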