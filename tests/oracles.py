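"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths under test: the convex-programming
oracle is a general-purpose scipy optimizer, the substring counters use
plain Python loops, and the AUC oracle is the O(n^2) all-pairs count.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import NonlinearConstraint, minimize


def slsqp_weighted_l1(y, X, w, eps, maxiter=3000):
    """Solve min sum w_i |a_i| s.t. ||y - X a|| <= eps with a general-purpose
    convex optimizer on the non-negative split a = p - q (a smooth program).

    SLSQP at tight tolerance is tried first; instances where its line search
    stalls are re-solved with the interior trust-region method.
    """
    n = X.shape[1]
    w = np.asarray(w, dtype=float)

    def obj(v):
        return float(w @ (v[:n] + v[n:]))

    def con(v):
        r = y - X @ (v[:n] - v[n:])
        return eps**2 - float(r @ r)

    res = minimize(
        obj,
        np.zeros(2 * n),
        method="SLSQP",
        constraints=[{"type": "ineq", "fun": con}],
        bounds=[(0.0, None)] * (2 * n),
        options={"maxiter": maxiter, "ftol": 1e-12},
    )
    if not res.success or con(res.x) < -1e-10:
        res = minimize(
            obj,
            np.zeros(2 * n),
            method="trust-constr",
            constraints=[NonlinearConstraint(lambda v: con(v), 0.0, np.inf)],
            bounds=[(0.0, None)] * (2 * n),
            options={"maxiter": 5000, "gtol": 1e-12, "xtol": 1e-14},
        )
        if not res.success:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"oracle failed to converge: {res.message}")
    return res.x[:n] - res.x[n:]


def naive_segment_stats(bits: str):
    """Sliding-window substring counter, percent scale, pure Python."""
    m = len(bits)
    ones = bits.count("1")
    freq0 = 100.0 * (m - ones) / m
    freq1 = 100.0 * ones / m
    n11 = sum(1 for i in range(m - 1) if bits[i : i + 2] == "11")
    n111 = sum(1 for i in range(m - 2) if bits[i : i + 3] == "111")
    ntr = sum(1 for i in range(m - 1) if bits[i] != bits[i + 1])
    freq11 = 100.0 * n11 / (m - 1) if m > 1 else 0.0
    freq111 = 100.0 * n111 / (m - 2) if m > 2 else 0.0
    trans = 100.0 * ntr / (m - 1) if m > 1 else 0.0
    return freq0, freq1, freq11, freq111, trans


def naive_ct_vector(seq: str, residue_order: str, L: int = 4):
    """Recompute the CT descriptor with string operations only."""
    n = len(seq)
    out = []
    for res in residue_order:
        track = "".join("1" if c == res else "0" for c in seq)
        bounds = [(i * n) // L for i in range(L + 1)]
        for i in range(L):
            out.extend(naive_segment_stats(track[bounds[i] : bounds[i + 1]]))
    return np.array(out)


def pairwise_auc(scores, labels):
    """Mann-Whitney probability by explicit all-pairs comparison."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def eq14_metrics(tp, fp, tn, fn):
    """Direct transcription of the confusion-matrix formulas."""
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / (tp + fp + tn + fn)
    d = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(d) if d else 0.0
    return sn, sp, acc, mcc
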