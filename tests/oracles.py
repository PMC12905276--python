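"""Independent brute-force oracles used to pin down expected values.

Each oracle is a direct, unoptimized transcription of the definition it
checks, deliberately sharing no code with the implementation.
"""

from __future__ import annotations

import numpy as np


def brute_force_es(gene_set, ranked_list) -> float:
    """Unweighted KS enrichment by walking the full running sum."""
    members = set(gene_set)
    hits = [g in members for g in ranked_list]
    k = sum(hits)
    n = len(ranked_list)
    if k == 0:
        raise ValueError("empty overlap")
    if k == n:
        return 1.0
    value = 0.0
    best = 0.0
    for hit in hits:
        value += 1.0 / k if hit else -1.0 / (n - k)
        if abs(value) > abs(best):
            best = value
    return best


def step_up_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg by the textbook step-up recursion."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        q = min(prev, p[idx] * m / rank_from_top)
        adjusted[idx] = q
        prev = q
    return adjusted


def pooled_t(x, y) -> float:
    """Textbook two-sample pooled-variance t statistic (x mean - y mean)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


def brute_force_gba(kc_frame, kd_frame, indications):
    """Guilt-by-association scores by explicit triple loop."""
    scores = {}
    for c in kc_frame.index:
        for d in kd_frame.index:
            best = 0.0
            for b, a in indications:
                best = max(best, kc_frame.at[c, b] * kd_frame.at[d, a])
            scores[(c, d)] = best
    return scores


def brute_force_propagation(direct_frame, kc_frame, kd_frame, damping):
    """Damped evidence propagation by explicit quadruple loop."""
    out = {}
    for c in direct_frame.index:
        for d in direct_frame.columns:
            best = -np.inf
            for c2 in direct_frame.index:
                for d2 in direct_frame.columns:
                    s = direct_frame.at[c2, d2]
                    if s > 0:
                        best = max(best, kc_frame.at[c, c2] * kd_frame.at[d, d2] * s)
            inferred = direct_frame.at[c, d]
            if np.isfinite(best):
                inferred = max(inferred, damping * best)
            out[(c, d)] = inferred
    return out


def brute_force_msa(delta, window=3) -> float:
    """Most-synergistic-area by enumerating every window corner."""
    d = np.asarray(delta, dtype=float)
    best = -np.inf
    for i in range(d.shape[0] - window + 1):
        for j in range(d.shape[1] - window + 1):
            total = 0.0
            for a in range(window):
                for b in range(window):
                    total += d[i + a, j + b]
            best = max(best, total / window**2)
    return best
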