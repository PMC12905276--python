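"""Literature evidence, triage filters, and consensus ranking.

Literature support for a compound-disease pair is scored by pointwise
mutual information (PMI) over co-mention counts: how much more often the
pair is mentioned together than independence would predict.  Direct
evidence is propagated to similar pairs through the compound/disease
similarity kernels, damped by a configurable factor, so an unstudied
pair can inherit (attenuated) support from a well-studied neighbor.

The final recommendation table fuses the connectivity-matching and
pair-kernel rankings by a weighted mean of normalized ranks; literature
evidence acts as a confirmation multiplier on top rather than as a third
ranked source.  Declarative triage rules (approval status, profile
attribute thresholds) remove unsuitable compounds with recorded reasons.
"""

from __future__ import annotations

import operator
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .prism import SimilarityMatrix

__all__ = [
    "literature_score",
    "propagate_evidence",
    "triage",
    "consensus_rank",
]

_COMPARATORS = {
    ">=": operator.ge,
    "<=": operator.le,
    ">": operator.gt,
    "<": operator.lt,
    "==": operator.eq,
    "!=": operator.ne,
}


def literature_score(
    n_cd: float, n_c: float, n_d: float, N: float, pseudocount: float = 0.5
) -> float:
    """Pointwise mutual information of a compound-disease co-mention.

    ``log2[(n_cd + a) * N / ((n_c + a) * (n_d + a))]`` with pseudocount
    ``a``.  Positive scores mean the pair co-occurs more often than
    chance; 0 is independence; negative scores mean avoidance.
    """
    if N <= 0:
        raise ValueError("corpus size N must be positive")
    if min(n_cd, n_c, n_d) < 0:
        raise ValueError("counts must be nonnegative")
    if n_cd > min(n_c, n_d) or max(n_c, n_d) > N:
        raise ValueError("count invariants violated: n_cd <= min(n_c, n_d) <= N")
    a = pseudocount
    if a == 0 and n_cd == 0:
        return float("-inf")
    return float(np.log2((n_cd + a) * N / ((n_c + a) * (n_d + a))))


def propagate_evidence(
    direct: pd.DataFrame,
    kc: SimilarityMatrix,
    kd: SimilarityMatrix,
    damping: float = 0.5,
) -> pd.DataFrame:
    """Spread direct literature scores to similar compound-disease pairs.

    ``inferred(c,d) = max(direct(c,d), damping * max over (c',d') with
    direct > 0 of Kc(c,c') * Kd(d,d') * direct(c',d'))``.  ``direct`` is
    a compound x disease score table; entries <= 0 carry no evidence to
    propagate but are preserved as floors.
    """
    if not 0 <= damping <= 1:
        raise ValueError("damping must lie in [0, 1]")
    comp_order = [c for c in kc.ids if c in direct.index]
    dis_order = [d for d in kd.ids if d in direct.columns]
    if len(comp_order) != len(direct.index) or len(dis_order) != len(direct.columns):
        raise ValueError("direct score table ids must be covered by the kernels")
    D = direct.loc[comp_order, dis_order].to_numpy(dtype=float)
    inferred = D.copy()
    if damping > 0:
        ci = [kc.index_of(c) for c in comp_order]
        di = [kd.index_of(d) for d in dis_order]
        Kc = kc.values[np.ix_(ci, ci)]
        Kd = kd.values[np.ix_(di, di)]
        src_c, src_d = np.nonzero(D > 0)
        best = np.full_like(D, -np.inf)
        for i, j in zip(src_c, src_d):
            np.maximum(best, np.outer(Kc[:, i], Kd[:, j]) * D[i, j], out=best)
        if len(src_c):
            inferred = np.maximum(D, damping * best)
    return pd.DataFrame(inferred, index=comp_order, columns=dis_order)


def triage(
    candidates: pd.DataFrame,
    approved: Mapping[str, bool] | None = None,
    profile_rules: Sequence[tuple[str, str, float]] = (),
) -> tuple[pd.DataFrame, pd.Series]:
    """Filter candidate compounds by approval status and profile rules.

    ``candidates`` is indexed by compound id with attribute columns
    (e.g. ``bioavailability``).  ``profile_rules`` are declarative
    ``(attribute, comparator, threshold)`` triples; a candidate must pass
    every rule.  Returns ``(survivors, reasons)`` where ``reasons`` maps
    each removed compound to its first failing check ("not_approved" or
    "fail:<attribute><comparator><threshold>").  The filter is
    order-independent and idempotent.
    """
    for attr, cmp_name, _ in profile_rules:
        if cmp_name not in _COMPARATORS:
            raise ValueError(f"unknown comparator {cmp_name!r}")
        if attr not in candidates.columns:
            raise KeyError(f"profile rule references missing attribute {attr!r}")

    reasons: dict[str, str] = {}
    keep = []
    for compound in candidates.index:
        if approved is not None and not approved.get(compound, False):
            reasons[compound] = "not_approved"
            continue
        failed = None
        for attr, cmp_name, threshold in profile_rules:
            value = candidates.at[compound, attr]
            if pd.isna(value) or not _COMPARATORS[cmp_name](value, threshold):
                failed = f"fail:{attr}{cmp_name}{threshold}"
                break
        if failed:
            reasons[compound] = failed
        else:
            keep.append(compound)
    survivors = candidates.loc[keep]
    return survivors, pd.Series(reasons, dtype=object, name="reason")


def _normalized_ranks(ordered_best_first: Sequence[str]) -> dict[str, float]:
    """Map each id to a rank score in [0, 1], 1 = best, 0 = worst."""
    n = len(ordered_best_first)
    if n == 1:
        return {ordered_best_first[0]: 1.0}
    return {c: 1.0 - i / (n - 1) for i, c in enumerate(ordered_best_first)}


def consensus_rank(
    dgem_ranking: Sequence[str],
    prism_ranking: Sequence[str],
    literature: Mapping[str, float] | None = None,
    weights: tuple[float, float] = (0.5, 0.5),
    literature_bonus: float = 0.25,
) -> pd.DataFrame:
    """Fuse connectivity and pair-kernel rankings into recommendations.

    Both rankings are ordered best-candidate first.  Per-source ranks are
    normalized to [0, 1] (1 = best); a compound missing from a source
    receives that source's worst normalized rank (0).  The consensus is
    the weighted mean of the two normalized ranks, multiplied by
    ``1 + literature_bonus`` when the compound's literature score is
    positive, then renormalized back to [0, 1].  Output is sorted by
    descending consensus with lexicographic id tiebreak.
    """
    dgem_list = list(dgem_ranking)
    prism_list = list(prism_ranking)
    universe = sorted(set(dgem_list) | set(prism_list))
    if not (set(dgem_list) & set(prism_list)):
        raise ValueError("rankings share no compounds")
    w1, w2 = weights
    if w1 < 0 or w2 < 0 or w1 + w2 <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    literature = literature or {}

    nr_dgem = _normalized_ranks(dgem_list)
    nr_prism = _normalized_ranks(prism_list)
    rows = []
    for c in universe:
        a = nr_dgem.get(c, 0.0)
        b = nr_prism.get(c, 0.0)
        lit = float(literature.get(c, 0.0))
        base = (w1 * a + w2 * b) / (w1 + w2)
        boosted = base * (1.0 + (literature_bonus if lit > 0 else 0.0))
        rows.append({
            "compound": c,
            "dgem_rank_score": a,
            "prism_rank_score": b,
            "literature_score": lit,
            "consensus": boosted / (1.0 + literature_bonus),
        })
    out = pd.DataFrame(rows).sort_values(
        ["consensus", "compound"], ascending=[False, True], kind="mergesort"
    )
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out.set_index("compound")
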