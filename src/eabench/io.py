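"""Readers and writers for the plain-text formats the framework touches.

Formats
-------
* GMT gene sets (tab-separated: set-id, description, genes...; MSigDB dialect)
* weighted edge lists (TSV with header ``gene1  gene2  score``)
* expression matrices (TSV, first column gene-id) with a companion design
  file (``#key=value`` header lines, then ``sample  condition`` rows)
* externally computed p-value matrices (TSV, rows pathways, columns datasets)
* term DAGs (TSV: child, parent, relation) and annotations (TSV: gene, term)
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    EnrichmentResultMatrix,
    ExpressionDataset,
    FunctionalNetwork,
    GeneSetCollection,
    ParseError,
    TermGraph,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_PATHWAY_SIZE = 15
DEFAULT_TOP_LINK_FRACTION = 0.2


def read_gmt(path: str | Path, min_size: int = DEFAULT_MIN_PATHWAY_SIZE) -> GeneSetCollection:
    """Read a GMT file, dropping sets with fewer than ``min_size`` genes.

    Duplicate genes within a line are collapsed before the size filter is
    applied.  Lines with fewer than three fields raise :class:`ParseError`;
    duplicate pathway identifiers raise :class:`ValidationError`.
    """
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            pid, desc = fields[0], fields[1]
            if pid in sets:
                raise ValidationError(f"{path}: duplicate pathway id {pid!r} (line {lineno})")
            genes = frozenset(g for g in fields[2:] if g)
            if len(genes) < min_size:
                continue
            sets[pid] = genes
            names[pid] = desc or pid
    if n_lines == 0:
        logger.warning("%s: empty GMT file, returning empty collection", path)
    return GeneSetCollection(sets, names)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in collection.ids:
            genes = "\t".join(sorted(collection[pid]))
            fh.write(f"{pid}\t{collection.names[pid]}\t{genes}\n")


def read_edge_list(
    path: str | Path, top_fraction: float = DEFAULT_TOP_LINK_FRACTION
) -> FunctionalNetwork:
    """Read a weighted edge list, keeping only the top-scoring link fraction.

    The filter is a threshold on score, not a count: all edges tied with the
    score at the cutoff are retained.  Self-loop rows are dropped with a
    warning; duplicate unordered pairs keep their highest score.
    """
    if not (0 < top_fraction <= 1):
        raise ValidationError(f"top_fraction must be in (0, 1], got {top_fraction}")
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    required = {"gene1", "gene2", "score"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: edge list requires columns {sorted(required)}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        bad = int(scores.isna().idxmax()) + 2  # +2: header + 1-based
        raise ParseError(f"{path}: non-numeric score near line {bad}")
    loops = df["gene1"] == df["gene2"]
    if loops.any():
        logger.warning("%s: dropped %d self-loop rows", path, int(loops.sum()))
        df = df[~loops]
        scores = scores[~loops]

    best: dict[tuple[str, str], float] = {}
    for u, v, s in zip(df["gene1"], df["gene2"], scores):
        key = (u, v) if u <= v else (v, u)
        if key not in best or s > best[key]:
            best[key] = float(s)
    if not best:
        return FunctionalNetwork()
    vals = np.sort(np.array(list(best.values())))[::-1]
    n_keep = max(1, math.ceil(top_fraction * len(vals)))
    threshold = vals[n_keep - 1]
    return FunctionalNetwork(
        (u, v, s) for (u, v), s in best.items() if s >= threshold
    )


def write_edge_list(net: FunctionalNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\tscore\n")
        for u, v, w in sorted(net.edges()):
            fh.write(f"{u}\t{v}\t{w:.10g}\n")


def read_expression(matrix_path: str | Path, design_path: str | Path) -> ExpressionDataset:
    """Read an expression matrix and its case/control design file.

    Genes whose rows are entirely missing are dropped with a warning.  A
    design sample absent from the matrix, or an unknown condition label,
    raises :class:`ValidationError`.
    """
    meta: dict[str, str] = {}
    rows: list[tuple[str, str]] = []
    with open(design_path) as fh:
        header_seen = False
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.lower() for f in fields[:2]] != ["sample", "condition"]:
                    raise ParseError(f"{design_path}: expected header 'sample\\tcondition'")
                header_seen = True
                continue
            if len(fields) < 2:
                raise ParseError(f"{design_path}: malformed row {line!r}")
            rows.append((fields[0], fields[1]))
    condition = dict(rows)

    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    for sample in condition:
        if sample not in mat.columns:
            raise ValidationError(f"{design_path}: sample {sample!r} not in expression matrix")
    extra = [c for c in mat.columns if c not in condition]
    if extra:
        logger.warning("%s: %d samples not in design dropped", matrix_path, len(extra))
    mat = mat[[s for s, _ in rows]]
    all_missing = mat.isna().all(axis=1)
    if all_missing.any():
        logger.warning("%s: dropped %d all-missing gene rows", matrix_path, int(all_missing.sum()))
        mat = mat[~all_missing]

    return ExpressionDataset(
        dataset_id=meta.get("dataset_id", Path(matrix_path).stem),
        genes=list(mat.index),
        samples=list(mat.columns),
        values=mat.to_numpy(dtype=float),
        condition=condition,
        platform=meta.get("platform", "microarray"),
        target_pathway=meta.get("target") or None,
    )


def write_expression(
    dataset: ExpressionDataset, matrix_path: str | Path, design_path: str | Path
) -> None:
    frame = pd.DataFrame(dataset.values, index=dataset.genes, columns=dataset.samples)
    frame.index.name = "gene"
    frame.to_csv(matrix_path, sep="\t")
    with open(design_path, "w") as fh:
        fh.write(f"#dataset_id={dataset.dataset_id}\n")
        fh.write(f"#platform={dataset.platform}\n")
        if dataset.target_pathway:
            fh.write(f"#target={dataset.target_pathway}\n")
        fh.write("sample\tcondition\n")
        for s in dataset.samples:
            fh.write(f"{s}\t{dataset.condition[s]}\n")


def read_pvalue_matrix(
    path: str | Path, collection: GeneSetCollection, method: str | None = None
) -> EnrichmentResultMatrix:
    """Read an externally computed pathway x dataset p-value matrix.

    Missing entries, and collection pathways absent from the file, are
    filled with p = 1 and flagged untested.  Entries outside [0, 1] raise
    :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    vals = df.to_numpy(dtype=float)
    finite = vals[~np.isnan(vals)]
    if ((finite < 0) | (finite > 1)).any():
        raise ValidationError(f"{path}: p-value entries outside [0, 1]")
    unknown = [p for p in df.index if p not in collection]
    if unknown:
        logger.warning("%s: dropped %d pathways not in the collection", path, len(unknown))
        df = df.drop(index=unknown)
    tested = ~df.isna()
    df = df.fillna(1.0)
    missing = [p for p in collection.ids if p not in df.index]
    if missing:
        add = pd.DataFrame(1.0, index=missing, columns=df.columns)
        df = pd.concat([df, add])
        tested = pd.concat([tested, pd.DataFrame(False, index=missing, columns=df.columns)])
    df = df.loc[collection.ids]
    tested = tested.loc[collection.ids]
    return EnrichmentResultMatrix(method or Path(path).stem, df, tested)


def write_pvalue_matrix(matrix: EnrichmentResultMatrix, path: str | Path) -> None:
    out = matrix.pvalues.copy()
    out.index.name = "pathway"
    out.to_csv(path, sep="\t")


def read_term_graph(dag_path: str | Path, annotation_path: str | Path | None = None) -> TermGraph:
    """Read a term DAG (child, parent, relation) and optional annotations."""
    dag = pd.read_csv(dag_path, sep="\t", dtype=str)
    required = {"child", "parent", "relation"}
    if not required.issubset(dag.columns):
        raise ParseError(f"{dag_path}: term DAG requires columns {sorted(required)}")
    parents: dict[str, set[tuple[str, str]]] = {}
    for child, parent, rel in zip(dag["child"], dag["parent"], dag["relation"]):
        parents.setdefault(child, set()).add((parent, rel))
    annotations: dict[str, set[str]] = {}
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
        if not {"gene", "term"}.issubset(ann.columns):
            raise ParseError(f"{annotation_path}: annotations require columns ['gene', 'term']")
        for gene, term in zip(ann["gene"], ann["term"]):
            annotations.setdefault(gene, set()).add(term)
    return TermGraph(parents, annotations)


def write_term_graph(
    graph: TermGraph, dag_path: str | Path, annotation_path: str | Path | None = None
) -> None:
    with open(dag_path, "w") as fh:
        fh.write("child\tparent\trelation\n")
        for child in sorted(graph.parents):
            for parent, rel in sorted(graph.parents[child]):
                fh.write(f"{child}\t{parent}\t{rel}\n")
    if annotation_path is not None:
        with open(annotation_path, "w") as fh:
            fh.write("gene\tterm\n")
            for gene in sorted(graph.annotations):
                for term in sorted(graph.annotations[gene]):
                    fh.write(f"{gene}\t{term}\n")
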