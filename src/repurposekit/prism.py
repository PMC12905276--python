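"""Pairwise similarity-kernel prediction of novel drug-disease indications.

Known compound-disease treatment pairs rarely exhaust the useful ones: a
compound structurally close to a known treatment of a disease, applied to
a disease phenotypically close to the treated one, is itself a candidate
("guilt by association").  This module formalizes that intuition two
ways:

* a *baseline* that scores a candidate pair by its best similarity-
  weighted path through any known indication, and
* a support-vector classifier over the Kronecker product pair kernel
  ``K((c,d),(c',d')) = Kc(c,c') * Kd(d,d')``, trained on known indication
  pairs against sampled unlabeled negatives (PU-learning style).

Compound kernels come from Tanimoto fingerprint similarity and Jaccard
target-set overlap; disease kernels from ontology ancestor-set Jaccard
and cosine similarity of literature co-mention profiles.  Convex
combinations are repaired to positive semidefinite by eigenvalue
clipping so the product kernel stays a valid kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = [
    "SimilarityMatrix",
    "KroneckerKernel",
    "MaterializationError",
    "PairClassifier",
    "tanimoto_matrix",
    "jaccard_target_similarity",
    "ontology_similarity",
    "cooccurrence_similarity",
    "combine_similarities",
    "kronecker_kernel",
    "train_pair_classifier",
    "guilt_by_association_score",
    "predict_pairs",
]

_SYM_TOL = 1e-10
_PSD_TOL = -1e-8


class MaterializationError(RuntimeError):
    """Full pair-kernel materialization would exceed the configured cap."""


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric unit-diagonal similarity matrix over named entities."""

    ids: tuple[str, ...]
    values: np.ndarray
    source: str = "combined"

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("similarity matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=_SYM_TOL):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=_SYM_TOL):
            raise ValueError("similarity matrix diagonal must be 1")

    def __getitem__(self, key: tuple[str, str]) -> float:
        i = self.ids.index(key[0])
        j = self.ids.index(key[1])
        return float(self.values[i, j])

    def index_of(self, entity: str) -> int:
        return self.ids.index(entity)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


def _as_fp_matrix(fingerprints: Mapping[str, np.ndarray]) -> tuple[tuple[str, ...], np.ndarray]:
    ids = tuple(sorted(fingerprints))
    lengths = {len(fingerprints[c]) for c in ids}
    if len(lengths) > 1:
        raise ValueError(f"fingerprints have mismatched lengths: {sorted(lengths)}")
    X = np.array([np.asarray(fingerprints[c], dtype=np.int64) for c in ids])
    if not np.isin(X, (0, 1)).all():
        raise ValueError("fingerprints must be binary")
    return ids, X


def tanimoto_matrix(fingerprints: Mapping[str, np.ndarray]) -> SimilarityMatrix:
    """Tanimoto (bitwise Jaccard) similarity of binary fingerprints.

    ``T(a, b) = |a AND b| / |a OR b|``; pairs of all-zero fingerprints get
    off-diagonal 0, and the diagonal is forced to 1.
    """
    ids, X = _as_fp_matrix(fingerprints)
    inter = X @ X.T
    pop = X.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(ids=ids, values=sim, source="fingerprint")


def jaccard_target_similarity(target_sets: Mapping[str, Iterable[str]]) -> SimilarityMatrix:
    """Jaccard similarity of per-entity target sets (both-empty -> 0)."""
    ids = tuple(sorted(target_sets))
    sets = [frozenset(target_sets[c]) for c in ids]
    n = len(ids)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            union = sets[i] | sets[j]
            sim[i, j] = sim[j, i] = len(sets[i] & sets[j]) / len(union) if union else 0.0
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(ids=ids, values=sim, source="target")


def _ancestor_closures(edges: Iterable[tuple[str, str]]) -> dict[str, frozenset[str]]:
    """Self-inclusive ancestor sets of every term in a child->parent DAG."""
    parents: dict[str, set[str]] = {}
    nodes: set[str] = set()
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
        nodes.update((child, parent))

    closures: dict[str, frozenset[str]] = {}

    def close(term: str, trail: tuple[str, ...]) -> frozenset[str]:
        if term in closures:
            return closures[term]
        if term in trail:
            cycle = " -> ".join((*trail[trail.index(term):], term))
            raise ValueError(f"ontology contains a cycle: {cycle}")
        anc = {term}
        for p in parents.get(term, ()):
            anc |= close(p, (*trail, term))
        closures[term] = frozenset(anc)
        return closures[term]

    for node in nodes:
        close(node, ())
    return closures


def ontology_similarity(
    ontology_edges: Iterable[tuple[str, str]],
    annotations: Mapping[str, Iterable[str]],
) -> SimilarityMatrix:
    """Jaccard similarity of ancestor-closure sets of annotated terms.

    Each disease's feature set is the union of the self-inclusive
    ancestor closures of its annotated terms; similarity is the Jaccard
    index of those sets.  Cycles in the edge list and unannotated
    diseases raise.
    """
    closures = _ancestor_closures(ontology_edges)
    ids = tuple(sorted(annotations))
    feature_sets = {}
    for d in ids:
        terms = list(annotations[d])
        if not terms:
            raise ValueError(f"disease {d!r} has no ontology annotation")
        unknown = [t for t in terms if t not in closures]
        if unknown:
            raise ValueError(f"terms not in the ontology: {unknown[:5]}")
        feats: set[str] = set()
        for t in terms:
            feats |= closures[t]
        feature_sets[d] = feats
    sim = jaccard_target_similarity(feature_sets)
    return SimilarityMatrix(ids=sim.ids, values=sim.values, source="ontology")


def cooccurrence_similarity(comention_counts: pd.DataFrame) -> SimilarityMatrix:
    """Cosine similarity of disease literature co-mention count profiles.

    ``comention_counts`` is a square disease x disease count table; each
    disease's row is its co-mention profile.  All-zero profiles yield 0
    similarity to everything (with a warning); the diagonal is forced 1.
    """
    if comention_counts.shape[0] != comention_counts.shape[1]:
        raise ValueError("co-mention count table must be square")
    if (np.asarray(comention_counts) < 0).any():
        raise ValueError("co-mention counts must be nonnegative")
    order = sorted(comention_counts.index)
    counts = comention_counts.loc[order, order].to_numpy(dtype=float)
    norms = np.linalg.norm(counts, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} disease(s) have all-zero co-mention profiles",
            UserWarning, stacklevel=2,
        )
    safe = np.where(zero, 1.0, norms)
    sim = (counts / safe[:, None]) @ (counts / safe[:, None]).T
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(ids=tuple(order), values=np.clip(sim, -1.0, 1.0),
                            source="cooccurrence")


def _psd_repair(values: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to 0 and renormalize the diagonal to 1."""
    eigval, eigvec = np.linalg.eigh(values)
    if eigval[0] >= _PSD_TOL:
        out = values.copy()
        np.fill_diagonal(out, 1.0)
        return out
    repaired = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T
    diag = np.diag(repaired).copy()
    diag[diag <= 0] = 1.0
    scale = np.sqrt(diag)
    repaired = repaired / np.outer(scale, scale)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    return repaired


def combine_similarities(
    matrices: Sequence[SimilarityMatrix],
    weights: Sequence[float] | None = None,
    source: str = "combined",
) -> SimilarityMatrix:
    """Convex combination of similarity matrices with PSD repair.

    All inputs must share the same entity ids.  Negative eigenvalues of
    the weighted sum are clipped at zero and the diagonal renormalized to
    1, so the result is a valid kernel (min eigenvalue >= -1e-8).
    """
    if not matrices:
        raise ValueError("no similarity matrices given")
    ids = matrices[0].ids
    for m in matrices[1:]:
        if m.ids != ids:
            raise ValueError("similarity matrices cover different entity ids")
    if weights is None:
        weights = [1.0] * len(matrices)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    w = w / w.sum()
    combined = sum(wi * m.values for wi, m in zip(w, matrices))
    return SimilarityMatrix(ids=ids, values=_psd_repair(combined), source=source)


@dataclass(frozen=True)
class KroneckerKernel:
    """Lazy pair kernel ``K((c,d),(c',d')) = Kc(c,c') * Kd(d,d')``."""

    kc: SimilarityMatrix
    kd: SimilarityMatrix
    materialize_cap: int = 250_000

    def value(self, pair_a: tuple[str, str], pair_b: tuple[str, str]) -> float:
        return self.kc[pair_a[0], pair_b[0]] * self.kd[pair_a[1], pair_b[1]]

    def block(
        self,
        pairs_rows: Sequence[tuple[str, str]],
        pairs_cols: Sequence[tuple[str, str]],
    ) -> np.ndarray:
        """Gram block between two lists of (compound, disease) pairs."""
        ci = np.array([self.kc.index_of(c) for c, _ in pairs_rows])
        di = np.array([self.kd.index_of(d) for _, d in pairs_rows])
        cj = np.array([self.kc.index_of(c) for c, _ in pairs_cols])
        dj = np.array([self.kd.index_of(d) for _, d in pairs_cols])
        return self.kc.values[np.ix_(ci, cj)] * self.kd.values[np.ix_(di, dj)]

    def materialize(self) -> np.ndarray:
        """Full Kronecker product (compound index varies slowest)."""
        n = len(self.kc.ids) * len(self.kd.ids)
        if n * n > self.materialize_cap:
            raise MaterializationError(
                f"materializing a {n}x{n} pair kernel exceeds the cap "
                f"({self.materialize_cap} entries); use block() instead"
            )
        return np.kron(self.kc.values, self.kd.values)


def kronecker_kernel(
    kc: SimilarityMatrix, kd: SimilarityMatrix, materialize_cap: int = 250_000
) -> KroneckerKernel:
    """Build the lazy Kronecker pair kernel from PSD component kernels."""
    for name, m in (("compound", kc), ("disease", kd)):
        if m.min_eigenvalue() < _PSD_TOL:
            raise ValueError(f"{name} kernel is not PSD; run combine_similarities first")
    return KroneckerKernel(kc=kc, kd=kd, materialize_cap=materialize_cap)


@dataclass
class PairClassifier:
    """Trained max-margin pair scorer over the Kronecker kernel."""

    kernel: KroneckerKernel
    svc: SVC
    training_pairs: tuple[tuple[str, str], ...]

    def decision_function(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        """Raw (uncalibrated) margin scores for arbitrary pairs."""
        gram = self.kernel.block(list(pairs), list(self.training_pairs))
        return self.svc.decision_function(gram)


def train_pair_classifier(
    kc: SimilarityMatrix,
    kd: SimilarityMatrix,
    indications: Sequence[tuple[str, str]],
    negative_ratio: int = 5,
    C: float = 1.0,
    seed: int = 0,
) -> PairClassifier:
    """Train an SVM on known indication pairs vs. sampled unlabeled pairs.

    Positives are the known (compound, disease) indication pairs;
    negatives are drawn uniformly (seeded) from the unlabeled pairs at
    ``negative_ratio`` per positive (PU-learning style, since verified
    non-indications are unavailable).  Because the sampled negatives are
    contaminated with unobserved true pairs, classes are re-weighted
    inversely to their frequency so a contaminated negative cannot
    outvote a genuine positive at the same point in kernel space.  The
    SVM uses the precomputed Kronecker pair kernel; decision scores are
    raw margins.
    """
    positives = sorted(set(indications))
    if not positives:
        raise ValueError("at least one positive indication pair is required")
    if negative_ratio < 1:
        raise ValueError("negative_ratio must be >= 1")
    for c, d in positives:
        if c not in kc.ids or d not in kd.ids:
            raise ValueError(f"indication pair ({c!r}, {d!r}) outside the entity universes")

    rng = np.random.default_rng(seed)
    pos_set = set(positives)
    unlabeled = [(c, d) for c in kc.ids for d in kd.ids if (c, d) not in pos_set]
    if not unlabeled:
        raise ValueError("no unlabeled pairs available for negative sampling")
    n_neg = min(negative_ratio * len(positives), len(unlabeled))
    neg_idx = rng.choice(len(unlabeled), size=n_neg, replace=False)
    negatives = [unlabeled[i] for i in neg_idx]

    train_pairs = positives + negatives
    y = np.array([1] * len(positives) + [0] * len(negatives))
    if len(np.unique(y)) < 2:
        raise ValueError("training set is single-class")
    kernel = kronecker_kernel(kc, kd)
    gram = kernel.block(train_pairs, train_pairs)
    svc = SVC(kernel="precomputed", C=C, class_weight="balanced")
    svc.fit(gram, y)
    return PairClassifier(kernel=kernel, svc=svc, training_pairs=tuple(train_pairs))


def guilt_by_association_score(
    kc: SimilarityMatrix,
    kd: SimilarityMatrix,
    indications: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Best similarity-weighted path through a known indication.

    ``score(c, d) = max over known (b, a) of Kc(c, b) * Kd(d, a)`` — the
    nearest-neighbor rationale: compound c resembles a compound b known
    to treat a disease a resembling d.  Returns a compound x disease
    score table.
    """
    scores = np.zeros((len(kc.ids), len(kd.ids)))
    for b, a in indications:
        col_c = kc.values[:, kc.index_of(b)]
        col_d = kd.values[:, kd.index_of(a)]
        np.maximum(scores, np.outer(col_c, col_d), out=scores)
    return pd.DataFrame(scores, index=list(kc.ids), columns=list(kd.ids))


def predict_pairs(
    model: PairClassifier,
    candidates: Sequence[tuple[str, str]],
    known_pairs: Iterable[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Score candidate pairs and rank the novel (non-known) ones.

    Returns a table with columns ``compound``, ``disease``, ``score``,
    ``known`` and ``novel_rank`` (1 = best among pairs not already known;
    NaN for known pairs).  Sorting is stable descending in score with an
    id tiebreak.
    """
    known = set(known_pairs)
    kc_ids, kd_ids = set(model.kernel.kc.ids), set(model.kernel.kd.ids)
    for c, d in candidates:
        if c not in kc_ids or d not in kd_ids:
            raise ValueError(f"candidate pair ({c!r}, {d!r}) outside the entity universes")
    scores = model.decision_function(candidates)
    out = pd.DataFrame({
        "compound": [c for c, _ in candidates],
        "disease": [d for _, d in candidates],
        "score": scores,
        "known": [(c, d) in known for c, d in candidates],
    })
    out = out.sort_values(["score", "compound", "disease"],
                          ascending=[False, True, True], kind="mergesort")
    novel = ~out["known"].to_numpy()
    ranks = np.full(len(out), np.nan)
    ranks[novel] = np.arange(1, int(novel.sum()) + 1)
    out["novel_rank"] = ranks
    return out.reset_index(drop=True)
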