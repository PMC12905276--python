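"""Disease gene-expression signatures from case/control matrices.

This module turns a two-group expression matrix into a quality-controlled,
ranked up/down gene signature, and provides the weighted Kolmogorov-Smirnov
(KS) enrichment score that both the GSEA-style signature QC and the
connectivity matching in :mod:`repurposekit.dgem` are built on.

The differential-expression model is a two-sample t-test with a simple
empirical-Bayes style variance shrinkage: each gene's pooled variance is
blended toward the cross-gene mean variance with a configurable prior
weight.  With prior weight 0 the statistic reduces to the ordinary
pooled-variance t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneStats",
    "GeneSignature",
    "EnrichmentScore",
    "qc_outliers",
    "moderated_t_stats",
    "bh_adjust",
    "build_signature",
    "ks_enrichment",
    "gsea_qc",
]

DEFAULT_MIN_OVERLAP = 3
DEFAULT_CONTROL_PREFIXES = ("AFFX",)


@dataclass(frozen=True)
class GeneStats:
    """Per-gene differential-expression statistics for one contrast.

    ``table`` holds one row per gene with columns ``log2fc`` (case minus
    control mean on the log2 scale), ``t`` (variance-shrunken t statistic),
    ``pval`` and ``qval`` (Benjamini-Hochberg adjusted).
    """

    table: pd.DataFrame
    contrast: tuple[str, str]
    prior_weight: float

    @property
    def genes(self) -> pd.Index:
        return self.table.index


@dataclass(frozen=True)
class GeneSignature:
    """Disjoint, ranked up- and down-regulated gene lists.

    Genes on each side are ordered by decreasing |t|; membership requires
    adjusted p <= alpha.  ``scores`` maps every member gene to its t
    statistic (used by score-weighted enrichment).
    """

    up: tuple[str, ...]
    down: tuple[str, ...]
    alpha: float
    top_n: int
    scores: Mapping[str, float] = field(default_factory=dict)
    empty_warning: bool = False

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down gene lists must be disjoint")

    @property
    def n_genes(self) -> int:
        return len(self.up) + len(self.down)

    def is_empty(self) -> bool:
        return self.n_genes == 0


@dataclass(frozen=True)
class EnrichmentScore:
    """Signed maximal running-sum deviation of a gene set in a ranking."""

    es: float
    n_hits: int
    pvalue: float | None = None

    def __float__(self) -> float:
        return self.es


def qc_outliers(dataset, k_mad: float = 3.0) -> set[str]:
    """Flag outlier samples by mean inter-sample Pearson correlation.

    A sample is flagged when its mean correlation with all other samples
    falls below ``median - k_mad * MAD`` of the per-sample mean
    correlations.  Constant-valued samples (zero variance, undefined
    correlation) are flagged with a warning rather than raising.

    Parameters
    ----------
    dataset : ExpressionDataset
        Expression matrix with >= 3 samples.
    k_mad : float
        Number of median-absolute-deviations below the median at which a
        sample is declared an outlier.  ``inf`` disables flagging.
    """
    matrix = np.asarray(dataset.matrix, dtype=float)
    sample_ids = list(dataset.sample_ids)
    n = len(sample_ids)
    if n < 3:
        raise ValueError("outlier QC requires at least 3 samples")

    sds = matrix.std(axis=0)
    constant = sds == 0
    flagged: set[str] = set()
    if constant.any():
        for idx in np.flatnonzero(constant):
            warnings.warn(
                f"sample {sample_ids[idx]!r} is constant-valued; flagged as outlier",
                UserWarning,
                stacklevel=2,
            )
            flagged.add(sample_ids[idx])

    ok = ~constant
    if ok.sum() < 3:
        return flagged
    sub = matrix[:, ok]
    corr = np.corrcoef(sub, rowvar=False)
    np.fill_diagonal(corr, np.nan)
    mean_corr = np.nanmean(corr, axis=0)
    med = np.median(mean_corr)
    mad = np.median(np.abs(mean_corr - med))
    if not np.isfinite(k_mad):
        return flagged
    threshold = med - k_mad * mad
    ok_ids = [s for s, keep in zip(sample_ids, ok) if keep]
    flagged.update(s for s, m in zip(ok_ids, mean_corr) if m < threshold)
    return flagged


def moderated_t_stats(dataset, contrast: tuple[str, str], prior_weight: float = 4.0) -> GeneStats:
    """Variance-shrunken two-sample t statistics for a case/control contrast.

    Each gene's pooled variance ``s2_g`` (df ``d_g``) is blended toward the
    cross-gene mean pooled variance ``s2_0``::

        s2_shrunk = (prior_weight * s2_0 + d_g * s2_g) / (prior_weight + d_g)

    and the t statistic uses ``s2_shrunk`` with ``prior_weight + d_g``
    degrees of freedom for the p-value.  ``prior_weight=0`` recovers the
    ordinary pooled-variance t exactly.  A group contributing a single
    sample contributes no degrees of freedom, so a gene observed with df 0
    falls back entirely on the cross-gene prior variance.

    Parameters
    ----------
    contrast : (case_label, control_label)
        Group labels; log2fc is mean(case) - mean(control).
    """
    case_label, control_label = contrast
    if case_label == control_label:
        raise ValueError("contrast must name two distinct groups")
    labels = np.asarray(dataset.groups)
    case = np.asarray(dataset.matrix, dtype=float)[:, labels == case_label]
    control = np.asarray(dataset.matrix, dtype=float)[:, labels == control_label]
    n1, n2 = case.shape[1], control.shape[1]
    if n1 == 0 or n2 == 0:
        raise ValueError(f"both contrast groups must be non-empty (got {n1} and {n2})")
    if prior_weight < 0:
        raise ValueError("prior_weight must be >= 0")

    diff = case.mean(axis=1) - control.mean(axis=1)
    ss1 = case.var(axis=1, ddof=1) * (n1 - 1) if n1 > 1 else np.zeros(case.shape[0])
    ss2 = control.var(axis=1, ddof=1) * (n2 - 1) if n2 > 1 else np.zeros(control.shape[0])
    df = (n1 - 1) + (n2 - 1)
    if df > 0:
        s2 = (ss1 + ss2) / df
        s2_prior = float(s2.mean())
    else:
        raise ValueError("contrast has zero residual degrees of freedom in every gene")

    denom_df = prior_weight + df
    if denom_df == 0:
        raise ValueError("prior_weight=0 with zero residual df leaves the variance undefined")
    s2_shrunk = (prior_weight * s2_prior + df * s2) / denom_df
    se = np.sqrt(s2_shrunk * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    pval = 2.0 * sps.t.sf(np.abs(t), df=denom_df)
    qval = bh_adjust(pval)
    table = pd.DataFrame(
        {"log2fc": diff, "t": t, "pval": pval, "qval": qval},
        index=pd.Index(dataset.gene_ids, name="gene"),
    )
    return GeneStats(table=table, contrast=contrast, prior_weight=prior_weight)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_signature(
    stats: GeneStats,
    alpha: float = 0.05,
    top_n: int = 100,
    control_prefixes: Sequence[str] = DEFAULT_CONTROL_PREFIXES,
) -> GeneSignature:
    """Select significant genes and split them into ranked up/down lists.

    Genes whose id starts with any of ``control_prefixes`` (array control
    probe sets) are removed first; the remainder is filtered to adjusted
    p <= alpha, split by the sign of log2fc, ordered by decreasing |t|
    (gene-id tiebreak), and truncated to ``top_n`` per side.

    An empty signature (no gene passes alpha) is returned with
    ``empty_warning=True`` rather than raising.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    table = stats.table
    if control_prefixes:
        keep = ~table.index.str.startswith(tuple(control_prefixes))
        table = table.loc[keep]
    sig = table.loc[(table["qval"] <= alpha) & (table["log2fc"] != 0)]

    def _side(frame: pd.DataFrame) -> tuple[str, ...]:
        order = pd.DataFrame({
            "gene": frame.index,
            "abs_t": frame["t"].abs().to_numpy(),
        }).sort_values(["abs_t", "gene"], ascending=[False, True], kind="mergesort")
        return tuple(order["gene"].iloc[:top_n])

    up = _side(sig.loc[sig["log2fc"] > 0])
    down = _side(sig.loc[sig["log2fc"] < 0])
    empty = len(up) + len(down) == 0
    if empty:
        warnings.warn("no genes pass the significance threshold; signature is empty",
                      UserWarning, stacklevel=2)
    scores = {g: float(table.at[g, "t"]) for g in (*up, *down)}
    return GeneSignature(up=up, down=down, alpha=alpha, top_n=top_n,
                         scores=scores, empty_warning=empty)


def ks_enrichment(
    gene_set: Iterable[str],
    ranked_list: Sequence[str],
    weight_exponent: float = 0.0,
    scores: Mapping[str, float] | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> EnrichmentScore:
    """Weighted KS enrichment score of ``gene_set`` within ``ranked_list``.

    Walking down the ranking, the running sum increases by ``1/|hits|``
    on set members (``weight_exponent=0``) or by ``|score|^w`` normalized
    over hits (``weight_exponent=w`` with per-gene ``scores``), and
    decreases by ``1/(N - |hits|)`` on non-members.  The enrichment score
    is the deviation of maximal magnitude, signed; it is +1 exactly when
    every member precedes every non-member and -1 in the mirrored case.

    Raises
    ------
    ValueError
        If the set/ranking overlap is below ``min_overlap``.
    """
    ranked = list(ranked_list)
    n = len(ranked)
    if n == 0:
        raise ValueError("ranked_list is empty")
    if len(set(ranked)) != n:
        raise ValueError("ranked_list contains duplicate gene ids")
    members = set(gene_set)
    hit_mask = np.fromiter((g in members for g in ranked), dtype=bool, count=n)
    k = int(hit_mask.sum())
    if k < min_overlap:
        raise ValueError(
            f"gene set overlaps the ranking in only {k} genes (min_overlap={min_overlap})"
        )
    if k == n:
        return EnrichmentScore(es=1.0, n_hits=k)

    if weight_exponent == 0:
        hit_weights = np.where(hit_mask, 1.0, 0.0)
    else:
        if scores is None:
            raise ValueError("weight_exponent != 0 requires per-gene scores")
        w = np.array([abs(scores.get(g, 0.0)) ** weight_exponent for g in ranked])
        hit_weights = np.where(hit_mask, w, 0.0)
        if hit_weights.sum() == 0:
            # degenerate all-zero weights: fall back to unweighted hits
            hit_weights = np.where(hit_mask, 1.0, 0.0)
    increments = np.where(
        hit_mask,
        hit_weights / hit_weights.sum(),
        -1.0 / (n - k),
    )
    running = np.cumsum(increments)
    idx = int(np.argmax(np.abs(running)))
    # cumsum round-off can overshoot the theoretical |ES| <= 1 bound
    return EnrichmentScore(es=float(np.clip(running[idx], -1.0, 1.0)), n_hits=k)


def gsea_qc(
    signature: GeneSignature,
    ranked_list: Sequence[str],
    collection: Mapping[str, Iterable[str]],
    n_perm: int = 999,
    seed: int = 0,
    weight_exponent: float = 0.0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Enrichment QC of a signature's ranking against a gene-set collection.

    For each set in ``collection`` the KS enrichment score within
    ``ranked_list`` is computed, and a gene-label permutation null (random
    same-size sets from the ranking universe) gives a two-sided
    permutation p-value ``(1 + #{|ES_perm| >= |ES|}) / (n_perm + 1)``,
    followed by BH adjustment across sets.
    """
    if not collection:
        raise ValueError("gene-set collection is empty")
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    rng = np.random.default_rng(seed)
    ranked = list(ranked_list)
    universe = np.array(ranked)
    rows = []
    for name, genes in collection.items():
        genes = set(genes)
        overlap = genes & set(ranked)
        if len(overlap) < min_overlap:
            rows.append({"set": name, "es": np.nan, "pval": np.nan, "n_hits": len(overlap)})
            continue
        obs = ks_enrichment(overlap, ranked, weight_exponent=weight_exponent,
                            scores=signature.scores, min_overlap=min_overlap)
        null = np.empty(n_perm)
        k = obs.n_hits
        for i in range(n_perm):
            perm_set = rng.choice(universe, size=k, replace=False)
            null[i] = ks_enrichment(perm_set, ranked, min_overlap=1).es
        p = (1.0 + np.sum(np.abs(null) >= abs(obs.es))) / (n_perm + 1.0)
        rows.append({"set": name, "es": obs.es, "pval": p, "n_hits": k})
    out = pd.DataFrame(rows).set_index("set")
    valid = out["pval"].notna()
    qvals = np.full(len(out), np.nan)
    if valid.any():
        qvals[valid.to_numpy()] = bh_adjust(out.loc[valid, "pval"].to_numpy())
    out["qval"] = qvals
    return out
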