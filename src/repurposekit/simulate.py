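"""Synthetic-data generators with planted ground truth.

Every input the repurposing pipeline consumes can be generated here:

* two-group expression matrices with planted log2 fold-change effects and
  Gaussian noise (a surrogate for normalized microarray case/control
  contrasts, e.g. high-risk vs. favorable-outcome tumors);
* a drug-perturbation compendium in which a known subset of drugs carries
  a profile that exactly inverts (or mimics) a given disease signature,
  embedded among random decoys;
* a block-structured compound/disease similarity world — fingerprints,
  target sets, a rooted disease ontology, literature co-occurrence counts
  and known indications — in which similar compounds treat similar
  diseases;
* dose-response viability matrices built from four-parameter-logistic
  monotherapy curves combined under the zero-interaction-potency (ZIP)
  expectation plus an additive synergy bonus.

All generators take an integer seed, route every draw through one
``numpy.random.Generator``, and return the planted truth alongside the
data, so downstream estimators can be scored against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signatures import GeneSignature

__all__ = [
    "SimWorldTruth",
    "ExpressionDataset",
    "DrugProfileCompendium",
    "SimilarityWorld",
    "generate_expression_dataset",
    "generate_drug_compendium",
    "generate_similarity_world",
    "generate_dose_response",
    "generate_pipeline_world",
]


@dataclass(frozen=True)
class SimWorldTruth:
    """Planted ground truth attached to a generated dataset."""

    de_genes: Mapping[str, float] = field(default_factory=dict)
    inverse_drugs: frozenset[str] = frozenset()
    mimic_drugs: frozenset[str] = frozenset()
    true_pairs: frozenset[tuple[str, str]] = frozenset()
    holdout_pairs: frozenset[tuple[str, str]] = frozenset()
    synergy_bonus: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inverse_drugs & self.mimic_drugs:
            raise ValueError("inverse and mimic drug sets must be disjoint")


@dataclass(frozen=True)
class ExpressionDataset:
    """Genes x samples log2 expression matrix with case/control labels."""

    matrix: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(set(self.gene_ids)):
            raise ValueError("gene ids must be unique")
        if self.matrix.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match gene/sample ids")
        if np.isnan(self.matrix).any():
            raise ValueError("expression matrix contains missing values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.gene_ids),
                            columns=list(self.sample_ids))


@dataclass(frozen=True)
class DrugProfileCompendium:
    """Per-drug total orderings of a shared gene universe.

    ``rankings[drug]`` is an array of gene ids, rank 1 (index 0) being the
    gene most up-regulated by the drug.
    """

    gene_ids: tuple[str, ...]
    rankings: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        universe = set(self.gene_ids)
        for drug, ranking in self.rankings.items():
            if set(ranking) != universe:
                raise ValueError(f"ranking for {drug!r} is not a permutation of the gene universe")

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.rankings)


@dataclass(frozen=True)
class SimilarityWorld:
    """Block-structured compound/disease world for pair prediction."""

    compound_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    fingerprints: Mapping[str, np.ndarray]
    target_sets: Mapping[str, frozenset[str]]
    ontology_edges: tuple[tuple[str, str], ...]  # (child, parent)
    disease_terms: Mapping[str, frozenset[str]]
    disease_comention: pd.DataFrame  # disease x disease co-mention counts
    cooccurrence: pd.DataFrame  # columns compound, disease, n_cd
    compound_marginals: Mapping[str, int]
    disease_marginals: Mapping[str, int]
    corpus_size: int
    indications: tuple[tuple[str, str], ...]  # training positives
    compound_blocks: Mapping[str, int]
    disease_blocks: Mapping[str, int]
    truth: SimWorldTruth


def generate_expression_dataset(
    n_genes: int = 2000,
    n_per_group: int = 20,
    n_de: int = 100,
    effect_log2: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.0,
) -> tuple[ExpressionDataset, SimWorldTruth]:
    """Simulate a case/control expression matrix with planted DE genes.

    ``n_de`` genes carry a mean case-minus-control difference of exactly
    ``±effect_log2`` (half up, half down; an odd count puts the extra gene
    up).  Remaining genes differ only by N(0, noise_sd) noise around a
    gene-specific baseline.
    """
    if n_genes <= 0 or n_per_group <= 0:
        raise ValueError("n_genes and n_per_group must be positive")
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    gene_ids = tuple(f"G{i:0{width}d}" for i in range(1, n_genes + 1))
    sample_ids = tuple(
        [f"case_{i:02d}" for i in range(1, n_per_group + 1)]
        + [f"ctrl_{i:02d}" for i in range(1, n_per_group + 1)]
    )
    groups = tuple(["case"] * n_per_group + ["control"] * n_per_group)

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    matrix = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, 2 * n_per_group))

    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    n_up = (n_de + 1) // 2
    effects: dict[str, float] = {}
    for j, idx in enumerate(de_idx):
        signed = effect_log2 if j < n_up else -effect_log2
        # shift case samples so the *group-mean* difference is exactly signed
        matrix[idx, :n_per_group] += signed
        current = matrix[idx, :n_per_group].mean() - matrix[idx, n_per_group:].mean()
        matrix[idx, :n_per_group] += signed - current
        effects[gene_ids[idx]] = signed

    dataset = ExpressionDataset(matrix=matrix, gene_ids=gene_ids,
                                sample_ids=sample_ids, groups=groups)
    truth = SimWorldTruth(de_genes=effects, seed=seed)
    return dataset, truth


def generate_drug_compendium(
    signature: GeneSignature,
    gene_ids: Sequence[str],
    n_drugs: int = 200,
    n_inverse: int = 5,
    n_mimic: int = 0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[DrugProfileCompendium, SimWorldTruth]:
    """Simulate a drug-perturbation compendium around a disease signature.

    Inverse drugs down-regulate the signature's up-genes and up-regulate
    its down-genes: their latent scores place signature up-genes in a band
    below the background and down-genes above it, so at ``noise_sd=0`` an
    inverse drug ranks every up-gene in the bottom ``|up|`` positions and
    every down-gene in the top ``|down|``.  Mimic drugs are the mirror
    image; the remaining decoys are random orderings.  Gaussian noise with
    ``noise_sd`` perturbs the planted scores.
    """
    if signature.is_empty():
        raise ValueError("cannot build a compendium around an empty signature")
    if n_inverse + n_mimic > n_drugs:
        raise ValueError("n_inverse + n_mimic cannot exceed n_drugs")
    gene_ids = tuple(gene_ids)
    universe = set(gene_ids)
    missing = (set(signature.up) | set(signature.down)) - universe
    if missing:
        raise ValueError(f"signature genes missing from the gene universe: {sorted(missing)[:5]}")

    rng = np.random.default_rng(seed)
    n_genes = len(gene_ids)
    width = len(str(n_drugs))
    drug_ids = [f"D{i:0{width}d}" for i in range(1, n_drugs + 1)]
    inverse = frozenset(drug_ids[:n_inverse])
    mimic = frozenset(drug_ids[n_inverse:n_inverse + n_mimic])

    up_idx = np.array([gene_ids.index(g) for g in signature.up])
    down_idx = np.array([gene_ids.index(g) for g in signature.down])

    rankings: dict[str, np.ndarray] = {}
    order = np.arange(n_genes)
    for drug in drug_ids:
        if drug in inverse or drug in mimic:
            scores = rng.uniform(-1.0, 1.0, size=n_genes)
            hi = rng.uniform(2.0, 3.0, size=len(down_idx) if drug in inverse else len(up_idx))
            lo = rng.uniform(-3.0, -2.0, size=len(up_idx) if drug in inverse else len(down_idx))
            if drug in inverse:
                scores[down_idx] = hi
                scores[up_idx] = lo
            else:
                scores[up_idx] = hi
                scores[down_idx] = lo
            if noise_sd > 0:
                scores = scores + rng.normal(0.0, noise_sd, size=n_genes)
        else:
            scores = rng.normal(0.0, 1.0, size=n_genes)
        # descending score = most up-regulated first; index tiebreak for determinism
        ranking_idx = order[np.lexsort((order, -scores))]
        rankings[drug] = np.array([gene_ids[i] for i in ranking_idx])

    compendium = DrugProfileCompendium(gene_ids=gene_ids, rankings=rankings)
    truth = SimWorldTruth(inverse_drugs=inverse, mimic_drugs=mimic, seed=seed)
    return compendium, truth


def generate_similarity_world(
    n_compounds: int = 40,
    n_diseases: int = 16,
    n_blocks: int = 4,
    fp_len: int = 128,
    ontology_depth: int = 3,
    holdout_frac: float = 0.5,
    cooccur_rate_true: float = 20.0,
    cooccur_rate_null: float = 2.0,
    seed: int = 0,
    fp_flip_prob: float = 0.1,
    n_targets_per_block: int = 8,
    n_true_per_block: int | None = None,
    comention_rate_within: float = 30.0,
    comention_rate_between: float = 3.0,
) -> SimilarityWorld:
    """Simulate a block-structured compound/disease similarity world.

    Compounds and diseases are partitioned into ``n_blocks`` matched
    blocks.  Compounds within a block share a fingerprint prototype (bits
    flipped independently with ``fp_flip_prob``; 0 gives identical
    within-block fingerprints) and draw targets from a block-specific
    pool; diseases within a block are annotated to leaves of the same
    branch of a rooted ontology tree of depth ``ontology_depth`` and
    co-occur in the literature at ``comention_rate_within`` (vs.
    ``comention_rate_between`` across blocks).  True indication pairs
    connect compounds to diseases of the same block — all matched-block
    combinations by default (the world's premise is that similar
    compounds treat similar diseases), or ``n_true_per_block`` randomly
    chosen ones for a sparser truth.  A ``holdout_frac`` fraction of the
    true pairs is flagged for evaluation and withheld from the training
    indication list.  Compound-disease literature co-mention
    counts are Poisson with rate ``cooccur_rate_true`` on true pairs and
    ``cooccur_rate_null`` elsewhere.
    """
    if n_blocks > min(n_compounds, n_diseases):
        raise ValueError("n_blocks cannot exceed the number of compounds or diseases")
    if not 0 <= holdout_frac < 1:
        raise ValueError("holdout_frac must lie in [0, 1)")
    if ontology_depth < 1:
        raise ValueError("ontology_depth must be >= 1")

    rng = np.random.default_rng(seed)
    compound_ids = tuple(f"C{i:03d}" for i in range(1, n_compounds + 1))
    disease_ids = tuple(f"Dis{i:03d}" for i in range(1, n_diseases + 1))
    compound_blocks = {c: i % n_blocks for i, c in enumerate(compound_ids)}
    disease_blocks = {d: i % n_blocks for i, d in enumerate(disease_ids)}

    # fingerprints: block prototype + independent bit flips
    prototypes = rng.integers(0, 2, size=(n_blocks, fp_len))
    fingerprints = {}
    for c in compound_ids:
        fp = prototypes[compound_blocks[c]].copy()
        if fp_flip_prob > 0:
            flips = rng.random(fp_len) < fp_flip_prob
            fp[flips] = 1 - fp[flips]
        fingerprints[c] = fp.astype(np.int8)

    # targets: block-specific pools, each compound draws a majority subset
    target_pools = [
        [f"T{b:02d}_{j:02d}" for j in range(n_targets_per_block)] for b in range(n_blocks)
    ]
    target_sets = {}
    for c in compound_ids:
        pool = target_pools[compound_blocks[c]]
        n_draw = max(2, int(round(0.75 * len(pool))))
        target_sets[c] = frozenset(rng.choice(pool, size=n_draw, replace=False))

    # ontology: root -> per-block chains of the stated depth
    edges: list[tuple[str, str]] = []
    block_leaves: list[list[str]] = []
    for b in range(n_blocks):
        parent = "ROOT"
        for level in range(ontology_depth):
            node = f"B{b:02d}_L{level}"
            edges.append((node, parent))
            parent = node
        leaves = [f"B{b:02d}_leaf{j}" for j in range(2)]
        for leaf in leaves:
            edges.append((leaf, parent))
        block_leaves.append(leaves)
    disease_terms = {
        d: frozenset([block_leaves[disease_blocks[d]][i % 2]])
        for i, d in enumerate(disease_ids)
    }

    # disease-disease literature co-mention counts (symmetric)
    n_d = n_diseases
    comention = np.zeros((n_d, n_d), dtype=int)
    for i in range(n_d):
        for j in range(i + 1, n_d):
            same = disease_blocks[disease_ids[i]] == disease_blocks[disease_ids[j]]
            rate = comention_rate_within if same else comention_rate_between
            comention[i, j] = comention[j, i] = rng.poisson(rate)
    np.fill_diagonal(comention, comention.sum(axis=1))
    disease_comention = pd.DataFrame(comention, index=list(disease_ids),
                                     columns=list(disease_ids))

    # true pairs: within-block compound-disease links
    true_pairs: list[tuple[str, str]] = []
    for b in range(n_blocks):
        block_c = [c for c in compound_ids if compound_blocks[c] == b]
        block_d = [d for d in disease_ids if disease_blocks[d] == b]
        combos = [(c, d) for c in block_c for d in block_d]
        if n_true_per_block is None:
            true_pairs.extend(combos)
        else:
            n_pick = min(n_true_per_block, len(combos))
            picked = rng.choice(len(combos), size=n_pick, replace=False)
            true_pairs.extend(combos[i] for i in picked)
    true_pairs.sort()

    # holdout stratified by block so every block keeps >=1 training pair
    holdout_set: set[tuple[str, str]] = set()
    for b in range(n_blocks):
        block_pairs = [p for p in true_pairs if compound_blocks[p[0]] == b]
        n_hold = min(int(round(holdout_frac * len(block_pairs))),
                     max(len(block_pairs) - 1, 0))
        if n_hold:
            hold_idx = rng.choice(len(block_pairs), size=n_hold, replace=False)
            holdout_set.update(block_pairs[i] for i in hold_idx)
    holdout = frozenset(holdout_set)
    indications = tuple(p for p in true_pairs if p not in holdout)

    # compound-disease co-occurrence counts
    true_set = set(true_pairs)
    rows = []
    for c in compound_ids:
        for d in disease_ids:
            rate = cooccur_rate_true if (c, d) in true_set else cooccur_rate_null
            rows.append((c, d, int(rng.poisson(rate))))
    cooccurrence = pd.DataFrame(rows, columns=["compound", "disease", "n_cd"])
    compound_marginals = cooccurrence.groupby("compound")["n_cd"].sum().to_dict()
    disease_marginals = cooccurrence.groupby("disease")["n_cd"].sum().to_dict()
    corpus_size = int(cooccurrence["n_cd"].sum()) + 1

    truth = SimWorldTruth(true_pairs=frozenset(true_pairs),
                          holdout_pairs=holdout, seed=seed)
    return SimilarityWorld(
        compound_ids=compound_ids,
        disease_ids=disease_ids,
        fingerprints=fingerprints,
        target_sets=target_sets,
        ontology_edges=tuple(edges),
        disease_terms=disease_terms,
        disease_comention=disease_comention,
        cooccurrence=cooccurrence,
        compound_marginals=compound_marginals,
        disease_marginals=disease_marginals,
        corpus_size=corpus_size,
        indications=indications,
        compound_blocks=compound_blocks,
        disease_blocks=disease_blocks,
        truth=truth,
    )


def _four_pl_inhibition(dose: np.ndarray, ic50: float, hill: float) -> np.ndarray:
    """Fractional inhibition of a 0-to-1 logistic dose-response curve."""
    dose = np.asarray(dose, dtype=float)
    out = np.zeros_like(dose)
    pos = dose > 0
    out[pos] = 1.0 / (1.0 + (ic50 / dose[pos]) ** hill)
    return out


def generate_dose_response(
    dose_grid_1: Sequence[float],
    dose_grid_2: Sequence[float],
    ic50_1: float = 1.0,
    ic50_2: float = 1.0,
    hill_1: float = 2.0,
    hill_2: float = 2.0,
    synergy_bonus: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Simulate a two-drug combination viability matrix under the ZIP model.

    Monotherapy margins follow four-parameter-logistic inhibition curves
    (bottom 0, top 1).  Interior cells follow the zero-interaction
    expectation ``y1 + y2 - y1*y2`` plus ``synergy_bonus`` plus Gaussian
    noise, clipped to [0, 1].  Returned values are percent viability
    (100 x (1 - inhibition)); rows index drug-1 doses, columns drug-2.
    """
    from .synergy import DoseResponseMatrix  # local import avoids a cycle

    d1 = np.asarray(dose_grid_1, dtype=float)
    d2 = np.asarray(dose_grid_2, dtype=float)
    if (d1 < 0).any() or (d2 < 0).any():
        raise ValueError("doses must be nonnegative")
    if 0 not in d1 or 0 not in d2:
        raise ValueError("dose grids must include 0 (control margins)")
    if ic50_1 <= 0 or ic50_2 <= 0:
        raise ValueError("IC50 values must be positive")

    rng = np.random.default_rng(seed)
    y1 = _four_pl_inhibition(d1, ic50_1, hill_1)
    y2 = _four_pl_inhibition(d2, ic50_2, hill_2)
    expected = y1[:, None] + y2[None, :] - y1[:, None] * y2[None, :]
    inhibition = expected.copy()
    interior = (d1[:, None] > 0) & (d2[None, :] > 0)
    inhibition[interior] += synergy_bonus
    if noise_sd > 0:
        inhibition = inhibition + rng.normal(0.0, noise_sd, size=inhibition.shape)
    inhibition = np.clip(inhibition, 0.0, 1.0)
    viability = 100.0 * (1.0 - inhibition)

    matrix = DoseResponseMatrix(doses1=tuple(d1), doses2=tuple(d2), viability=viability)
    truth = SimWorldTruth(synergy_bonus=synergy_bonus, seed=seed)
    return matrix, truth


def generate_pipeline_world(
    seed: int = 0,
    n_genes: int = 2000,
    n_per_group: int = 20,
    n_de: int = 100,
    effect_log2: float = 2.0,
    expr_noise_sd: float = 1.0,
    n_drugs: int = 40,
    n_true: int = 5,
    compendium_noise_sd: float = 1.0,
    n_blocks: int = 8,
    n_diseases: int = 16,
):
    """Generate one coherent end-to-end world for the full pipeline.

    The drug compendium's drug ids coincide with the similarity world's
    compound ids.  The ``n_true`` planted therapeutic compounds (i) invert
    the planted disease signature in the compendium, (ii) sit in the
    compound block matched to the focal disease's block, with their pairs
    to the focal disease held out of the training indications, and (iii)
    carry elevated literature co-occurrence with the focal disease.

    Returns a dict with keys ``dataset``, ``expression_truth``,
    ``compendium``, ``world``, ``focal_disease``, ``true_compounds``.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=4)
    dataset, expr_truth = generate_expression_dataset(
        n_genes=n_genes, n_per_group=n_per_group, n_de=n_de,
        effect_log2=effect_log2, noise_sd=expr_noise_sd, seed=int(sub[0]),
    )
    # the planted signature (what a perfect DE analysis would recover)
    up = tuple(sorted(g for g, e in expr_truth.de_genes.items() if e > 0))
    down = tuple(sorted(g for g, e in expr_truth.de_genes.items() if e < 0))
    planted = GeneSignature(up=up, down=down, alpha=0.05, top_n=max(len(up), len(down)))

    world = generate_similarity_world(
        n_compounds=n_drugs, n_diseases=n_diseases, n_blocks=n_blocks,
        holdout_frac=0.0, seed=int(sub[1]),
    )
    focal_disease = world.disease_ids[0]
    focal_block = world.disease_blocks[focal_disease]
    block_compounds = sorted(
        c for c in world.compound_ids if world.compound_blocks[c] == focal_block
    )
    true_compounds = tuple(block_compounds[:n_true])

    # rebuild indications: pair every block compound with its block diseases,
    # then hold out the focal disease's pairs (they are the evaluation truth)
    pairs = set(world.truth.true_pairs)
    pairs.update((c, focal_disease) for c in true_compounds)
    holdout = frozenset((c, focal_disease) for c in true_compounds)
    indications = tuple(sorted(p for p in pairs if p not in holdout))

    # literature co-occurrence: boost the held-out true pairs
    cooc = world.cooccurrence.copy()
    mask = cooc.apply(lambda r: (r["compound"], r["disease"]) in holdout, axis=1)
    cooc.loc[mask, "n_cd"] = rng.poisson(20.0, size=int(mask.sum()))
    compound_marginals = cooc.groupby("compound")["n_cd"].sum().to_dict()
    disease_marginals = cooc.groupby("disease")["n_cd"].sum().to_dict()

    world = SimilarityWorld(
        compound_ids=world.compound_ids,
        disease_ids=world.disease_ids,
        fingerprints=world.fingerprints,
        target_sets=world.target_sets,
        ontology_edges=world.ontology_edges,
        disease_terms=world.disease_terms,
        disease_comention=world.disease_comention,
        cooccurrence=cooc,
        compound_marginals=compound_marginals,
        disease_marginals=disease_marginals,
        corpus_size=int(cooc["n_cd"].sum()) + 1,
        indications=indications,
        compound_blocks=world.compound_blocks,
        disease_blocks=world.disease_blocks,
        truth=SimWorldTruth(true_pairs=frozenset(pairs), holdout_pairs=holdout,
                            seed=int(sub[1])),
    )

    # compendium over the same compound ids: planted inverse drugs = true compounds
    compendium, comp_truth = generate_drug_compendium(
        planted, dataset.gene_ids, n_drugs=n_drugs, n_inverse=n_true,
        noise_sd=compendium_noise_sd, seed=int(sub[2]),
    )
    # remap generated drug ids onto compound ids so that the inverse drugs
    # are exactly the planted true compounds
    gen_ids = sorted(compendium.rankings)
    inverse_gen = sorted(comp_truth.inverse_drugs)
    decoy_gen = [d for d in gen_ids if d not in comp_truth.inverse_drugs]
    other_compounds = [c for c in world.compound_ids if c not in true_compounds]
    id_map = dict(zip(inverse_gen, true_compounds)) | dict(zip(decoy_gen, other_compounds))
    rankings = {id_map[d]: r for d, r in compendium.rankings.items()}
    compendium = DrugProfileCompendium(gene_ids=compendium.gene_ids, rankings=rankings)

    return {
        "dataset": dataset,
        "expression_truth": expr_truth,
        "planted_signature": planted,
        "compendium": compendium,
        "world": world,
        "focal_disease": focal_disease,
        "true_compounds": true_compounds,
    }
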