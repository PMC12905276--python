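"""Plain-text readers and writers for pipeline inputs and outputs.

All tabular formats are TSV/CSV via pandas; gene-set collections use the
GMT convention (set name, description, then member genes, tab-separated).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .prism import SimilarityMatrix
from .signatures import GeneSignature
from .simulate import DrugProfileCompendium, ExpressionDataset
from .synergy import DoseResponseMatrix

__all__ = [
    "read_expression", "write_expression",
    "read_groups", "write_groups",
    "read_signature", "write_signature",
    "read_compendium", "write_compendium",
    "read_fingerprints", "write_fingerprints",
    "read_target_sets", "write_target_sets",
    "read_edge_list", "write_edge_list",
    "read_pairs", "write_pairs",
    "read_gmt",
    "read_dose_response", "write_dose_response",
    "read_similarity", "write_similarity",
    "write_truth", "read_truth",
]


def read_expression(expr_path, groups_path) -> ExpressionDataset:
    """Read a genes x samples TSV plus a (sample, label) groups TSV."""
    frame = pd.read_csv(expr_path, sep="\t", index_col=0)
    groups = read_groups(groups_path)
    missing = [s for s in frame.columns if s not in groups]
    if missing:
        raise ValueError(f"samples without group labels: {missing[:5]}")
    return ExpressionDataset(
        matrix=frame.to_numpy(dtype=float),
        gene_ids=tuple(frame.index.astype(str)),
        sample_ids=tuple(frame.columns.astype(str)),
        groups=tuple(groups[s] for s in frame.columns),
    )


def write_expression(dataset: ExpressionDataset, expr_path, groups_path) -> None:
    dataset.to_frame().rename_axis("gene").to_csv(expr_path, sep="\t")
    write_groups(dict(zip(dataset.sample_ids, dataset.groups)), groups_path)


def read_groups(path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def write_groups(groups: Mapping[str, str], path) -> None:
    pd.DataFrame({"sample": list(groups), "label": list(groups.values())}).to_csv(
        path, sep="\t", index=False
    )


def write_signature(signature: GeneSignature, path) -> None:
    rows = [
        {"gene": g, "direction": direction, "statistic": signature.scores.get(g, np.nan)}
        for direction, genes in (("up", signature.up), ("down", signature.down))
        for g in genes
    ]
    pd.DataFrame(rows, columns=["gene", "direction", "statistic"]).to_csv(
        path, sep="\t", index=False
    )


def read_signature(path, alpha: float = 0.05, top_n: int = 10**6) -> GeneSignature:
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str})
    up = tuple(frame.loc[frame["direction"] == "up", "gene"])
    down = tuple(frame.loc[frame["direction"] == "down", "gene"])
    scores = dict(zip(frame["gene"], frame["statistic"]))
    return GeneSignature(up=up, down=down, alpha=alpha, top_n=top_n, scores=scores)


def write_compendium(compendium: DrugProfileCompendium, path) -> None:
    """Long-format TSV: drug, gene, rank (1 = most up-regulated)."""
    records = []
    for drug in compendium.drug_ids:
        for rank, gene in enumerate(compendium.rankings[drug], start=1):
            records.append((drug, gene, rank))
    pd.DataFrame(records, columns=["drug", "gene", "rank"]).to_csv(
        path, sep="\t", index=False
    )


def read_compendium(path) -> DrugProfileCompendium:
    frame = pd.read_csv(path, sep="\t", dtype={"drug": str, "gene": str})
    gene_ids = tuple(sorted(frame["gene"].unique()))
    rankings = {}
    for drug, sub in frame.groupby("drug"):
        rankings[drug] = sub.sort_values("rank")["gene"].to_numpy()
    return DrugProfileCompendium(gene_ids=gene_ids, rankings=rankings)


def write_fingerprints(fingerprints: Mapping[str, np.ndarray], path) -> None:
    rows = [(c, "".join(str(int(b)) for b in fingerprints[c])) for c in sorted(fingerprints)]
    pd.DataFrame(rows, columns=["compound", "fingerprint"]).to_csv(path, sep="\t", index=False)


def read_fingerprints(path) -> dict[str, np.ndarray]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return {
        row["compound"]: np.fromiter(row["fingerprint"], dtype=np.int8)
        for _, row in frame.iterrows()
    }


def write_target_sets(target_sets: Mapping[str, frozenset], path) -> None:
    rows = [(e, t) for e in sorted(target_sets) for t in sorted(target_sets[e])]
    pd.DataFrame(rows, columns=["entity", "target"]).to_csv(path, sep="\t", index=False)


def read_target_sets(path) -> dict[str, frozenset]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return {e: frozenset(sub["target"]) for e, sub in frame.groupby("entity")}


def write_edge_list(edges, path, columns=("child", "parent")) -> None:
    pd.DataFrame(list(edges), columns=list(columns)).to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> list[tuple[str, str]]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return [tuple(row) for row in frame.itertuples(index=False)]


def write_pairs(pairs, path, columns=("compound", "disease")) -> None:
    pd.DataFrame(list(pairs), columns=list(columns)).to_csv(path, sep="\t", index=False)


def read_pairs(path) -> list[tuple[str, str]]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return [(row[0], row[1]) for row in frame.itertuples(index=False)]


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set collection: name <tab> description <tab> genes..."""
    collection = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        collection[parts[0]] = set(parts[2:])
    return collection


def write_dose_response(matrix: DoseResponseMatrix, path) -> None:
    """CSV with the first row/column holding doses, cells percent viability."""
    matrix.to_frame().rename_axis("dose").to_csv(path)


def read_dose_response(path) -> DoseResponseMatrix:
    frame = pd.read_csv(path, index_col=0)
    return DoseResponseMatrix(
        doses1=tuple(float(d) for d in frame.index),
        doses2=tuple(float(d) for d in frame.columns),
        viability=frame.to_numpy(dtype=float),
    )


def write_similarity(matrix: SimilarityMatrix, path) -> None:
    matrix.to_frame().rename_axis("entity").to_csv(path, sep="\t")


def read_similarity(path, source: str = "combined") -> SimilarityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(ids=tuple(frame.index.astype(str)),
                            values=frame.to_numpy(dtype=float), source=source)


def write_truth(truth, path) -> None:
    payload = {
        "de_genes": dict(truth.de_genes),
        "inverse_drugs": sorted(truth.inverse_drugs),
        "mimic_drugs": sorted(truth.mimic_drugs),
        "true_pairs": sorted(list(p) for p in truth.true_pairs),
        "holdout_pairs": sorted(list(p) for p in truth.holdout_pairs),
        "synergy_bonus": truth.synergy_bonus,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())
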