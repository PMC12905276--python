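"""Disease-gene-expression matching (DGEM): connectivity scoring.

A disease signature (disjoint up/down gene lists) is matched against a
compendium of drug-perturbation gene rankings with the classic two-sided
KS connectivity score: the up set and the down set are each scored by
weighted-KS enrichment within a drug's ranking, and

    combined = (ES_up - ES_down) / 2   when the two scores have opposite
                                       signs, and 0 otherwise.

A drug whose perturbation profile *inverts* the disease signature (pushes
the disease's up-genes down and vice versa) scores -1; a mimic scores +1.
Therapeutic candidates are therefore the most negative scores, and the
result table is sorted ascending.

Significance comes from a signature-permutation null: random gene sets of
the same sizes as the signature's sides, scored the same way.  Because a
random set scored against a fixed permutation is distributionally
identical to a fixed set against a random permutation, one null sample is
shared across drugs of a compendium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .signatures import (
    DEFAULT_MIN_OVERLAP,
    GeneSignature,
    bh_adjust,
    build_signature,
    ks_enrichment,
    moderated_t_stats,
)

__all__ = [
    "connectivity_score",
    "match_compendium",
    "positive_control_enrichment",
    "optimize_parameters",
]


def _combined(es_up: float, es_down: float) -> float:
    if es_up * es_down > 0:
        return 0.0
    return (es_up - es_down) / 2.0


def connectivity_score(
    signature: GeneSignature,
    drug_ranking: Sequence[str],
    weight_exponent: float = 0.0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[float, float, float]:
    """Two-sided KS connectivity of a signature within one drug ranking.

    Returns ``(ES_up, ES_down, combined)`` with combined in [-1, 1];
    -1 is a perfect inversion (therapeutic ideal), +1 a perfect mimic.
    """
    es_up = ks_enrichment(signature.up, drug_ranking, weight_exponent=weight_exponent,
                          scores=signature.scores, min_overlap=min_overlap).es
    es_down = ks_enrichment(signature.down, drug_ranking, weight_exponent=weight_exponent,
                            scores=signature.scores, min_overlap=min_overlap).es
    return es_up, es_down, _combined(es_up, es_down)


def _es_unweighted_from_positions(positions: np.ndarray, n: int) -> np.ndarray:
    """Vectorized unweighted KS enrichment from 0-based hit positions.

    ``positions`` has shape (n_draws, k) and need not be sorted.  Returns
    the signed maximal running-sum deviation per draw.
    """
    pos = np.sort(positions, axis=1)
    n_draws, k = pos.shape
    if k >= n:
        return np.ones(n_draws)
    i = np.arange(1, k + 1)
    miss = 1.0 / (n - k)
    # running sum immediately after hit i sits at i/k - (pos_i + 1 - i) * miss;
    # immediately before hit i it is (i-1)/k - (pos_i - (i-1)) * miss
    after = i / k - (pos + 1 - i) * miss
    before = (i - 1) / k - (pos - (i - 1)) * miss
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), after[:, -1] if k < n else 0.0)
    # the running sum ends at 0; the minimum over the full walk is the
    # smallest pre-hit value or the tail descent floor (which is < 0 only
    # via pre-hit values, all covered by `before`); include 0-boundary
    lo = np.minimum(lo, 0.0)
    return np.where(hi >= -lo, hi, lo)


def _null_combined(
    n_genes: int, k_up: int, k_down: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null distribution of the combined score for random signatures."""
    up_pos = np.empty((n_perm, k_up), dtype=np.int64)
    down_pos = np.empty((n_perm, k_down), dtype=np.int64)
    for i in range(n_perm):
        draw = rng.choice(n_genes, size=k_up + k_down, replace=False)
        up_pos[i] = draw[:k_up]
        down_pos[i] = draw[k_up:]
    es_up = _es_unweighted_from_positions(up_pos, n_genes)
    es_down = _es_unweighted_from_positions(down_pos, n_genes)
    combined = np.where(es_up * es_down > 0, 0.0, (es_up - es_down) / 2.0)
    return combined


def match_compendium(
    signature: GeneSignature,
    compendium,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 0.0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Score a signature against every drug in a compendium.

    Returns a table indexed by drug with columns ``es_up``, ``es_down``,
    ``combined``, ``pval`` (two-sided permutation p with +1 smoothing),
    ``qval`` (BH across drugs), ``rank`` (1 = most negative combined =
    strongest inverse/therapeutic candidate) and ``note`` (reason string
    for drugs skipped due to insufficient overlap).  Sorting is stable
    ascending in combined with drug-id tiebreak, so the output is
    invariant to compendium insertion order.
    """
    drugs = compendium.drug_ids
    if not drugs:
        raise ValueError("compendium is empty")
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse permutation p-values",
                      UserWarning, stacklevel=2)

    rng = np.random.default_rng(seed)
    n_genes = len(compendium.gene_ids)
    rows = []
    for drug in drugs:
        ranking = compendium.rankings[drug]
        try:
            es_up, es_down, combined = connectivity_score(
                signature, ranking, weight_exponent=weight_exponent,
                min_overlap=min_overlap,
            )
            rows.append({"drug": drug, "es_up": es_up, "es_down": es_down,
                         "combined": combined, "note": ""})
        except ValueError as exc:
            rows.append({"drug": drug, "es_up": np.nan, "es_down": np.nan,
                         "combined": np.nan, "note": str(exc)})
    table = pd.DataFrame(rows).set_index("drug")

    k_up = len([g for g in signature.up if g in set(compendium.gene_ids)])
    k_down = len([g for g in signature.down if g in set(compendium.gene_ids)])
    null = _null_combined(n_genes, k_up, k_down, n_perm, rng) if k_up and k_down else None

    pvals = np.full(len(table), np.nan)
    valid = table["combined"].notna().to_numpy()
    if null is not None and valid.any():
        obs = table.loc[valid, "combined"].to_numpy()
        exceed = (np.abs(null)[None, :] >= np.abs(obs)[:, None]).sum(axis=1)
        pvals[valid] = (1.0 + exceed) / (n_perm + 1.0)
    table["pval"] = pvals
    qvals = np.full(len(table), np.nan)
    if valid.any():
        qvals[valid] = bh_adjust(table.loc[valid, "pval"].to_numpy())
    table["qval"] = qvals

    table = table.sort_values(["combined", "drug"], ascending=[True, True],
                              kind="mergesort", na_position="last")
    ranks = np.full(len(table), np.nan)
    ranks[: int(valid.sum())] = np.arange(1, int(valid.sum()) + 1)
    table["rank"] = ranks
    return table[["es_up", "es_down", "combined", "pval", "qval", "rank", "note"]]


def positive_control_enrichment(
    ranked_drug_list: Sequence[str],
    positive_set: Iterable[str],
    k: int = 10,
) -> tuple[float, float]:
    """Recovery of known therapeutics near the top of a drug ranking.

    ``ranked_drug_list`` is ordered best-candidate first.  Returns
    ``(auroc, fold_enrichment_at_k)`` where AUROC is the probability that
    a random positive outranks a random non-positive, and fold enrichment
    compares the positive rate in the top ``k`` with the base rate.
    """
    ranked = list(ranked_drug_list)
    n = len(ranked)
    positives = set(positive_set)
    if not positives:
        raise ValueError("positive_set is empty")
    if not positives <= set(ranked):
        missing = positives - set(ranked)
        raise ValueError(f"positives missing from the ranking: {sorted(missing)[:5]}")
    if k > n:
        raise ValueError("k cannot exceed the ranking length")
    n_pos = len(positives)
    if n_pos == n:
        raise ValueError("AUROC undefined when every drug is a positive control")

    is_pos = np.fromiter((d in positives for d in ranked), dtype=bool, count=n)
    pos_ranks = np.flatnonzero(is_pos) + 1  # 1 = best
    # count of (positive, negative) pairs where the positive ranks better
    n_neg = n - n_pos
    better = np.sum(n - pos_ranks) - (n_pos * (n_pos - 1)) / 2.0
    auroc = better / (n_pos * n_neg)
    top_hits = int(is_pos[:k].sum())
    fold = (top_hits / k) / (n_pos / n)
    return float(auroc), float(fold)


def optimize_parameters(
    dataset,
    compendium,
    positives: Iterable[str],
    grid: Mapping[str, Sequence],
    n_perm: int = 100,
    seed: int = 0,
    contrast: tuple[str, str] = ("case", "control"),
    prior_weight: float = 4.0,
    k: int = 10,
) -> tuple[dict, pd.DataFrame]:
    """Choose signature/matching parameters by positive-control recovery.

    ``grid`` maps any of ``top_n``, ``alpha``, ``weight_exponent`` to
    candidate values; every combination is evaluated by rebuilding the
    signature, re-matching the compendium, and measuring the AUROC with
    which the known positives concentrate at the top of the ranking.
    The AUROC-maximizing configuration wins; ties break toward smaller
    ``top_n`` then lexicographic parameter order.

    Returns ``(best_config, metrics_table)``.
    """
    if not grid:
        raise ValueError("parameter grid is empty")
    positives = set(positives)
    keys = sorted(grid)
    stats = moderated_t_stats(dataset, contrast=contrast, prior_weight=prior_weight)

    records = []
    for values in product(*(grid[key] for key in keys)):
        config = dict(zip(keys, values))
        sig = build_signature(
            stats,
            alpha=config.get("alpha", 0.05),
            top_n=config.get("top_n", 100),
        )
        if sig.is_empty():
            records.append({**config, "auroc": np.nan, "fold_enrichment": np.nan,
                            "n_signature": 0})
            continue
        result = match_compendium(
            sig, compendium, n_perm=n_perm, seed=seed,
            weight_exponent=config.get("weight_exponent", 0.0),
        )
        ranked = [d for d in result.index if result.at[d, "note"] == ""]
        if not set(ranked) & positives or set(ranked) <= positives:
            records.append({**config, "auroc": np.nan, "fold_enrichment": np.nan,
                            "n_signature": sig.n_genes})
            continue
        auroc, fold = positive_control_enrichment(ranked, positives & set(ranked),
                                                  k=min(k, len(ranked)))
        records.append({**config, "auroc": auroc, "fold_enrichment": fold,
                        "n_signature": sig.n_genes})
    metrics = pd.DataFrame(records)
    if metrics["auroc"].isna().all():
        raise ValueError("every grid configuration yielded an empty signature")

    sort_cols = ["auroc"] + (["top_n"] if "top_n" in keys else []) + \
        [key for key in keys if key != "top_n"]
    ordered = metrics.sort_values(
        sort_cols, ascending=[False] + [True] * (len(sort_cols) - 1),
        kind="mergesort", na_position="last",
    )
    best_row = ordered.iloc[0]
    best = {key: best_row[key] for key in keys}
    return best, metrics
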