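"""Feature-ID resolution and heterogeneous graph assembly.

The model operates on a three-node-type graph: proteins, genes and cells.
Protein-protein and gene-gene edges come from a knowledge base keyed by
external IDs with confidence scores in (0, 1] (STRING-style combined scores);
this module resolves those IDs onto the dataset's display names through an
alias map, builds the within-modality adjacencies, links genes to the proteins
they encode by symbol matching, and derives the cell-gene bipartite block from
log-normalized expression.  The blocks are assembled into the single N x N
adjacency

    A = [[Ap,    S^T,      0      ],
         [S,     Ag,       A_RNA^T],
         [0,     A_RNA,    0      ]]

with node order [proteins | genes | cells].  Node counts are always fixed by
the dataset: features missing from the knowledge base stay as isolated nodes
(the global attention block of the model is what lets them still communicate).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.preprocessing import normalize as sk_normalize

from .data import ExpressionMatrix
from .simdata import LOGNORM_SCALE

logger = logging.getLogger(__name__)


@dataclass
class IdAliasMap:
    """external_id -> ordered list of aliases."""

    entries: dict[str, list[str]]

    @classmethod
    def from_tsv(cls, path: str) -> "IdAliasMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls({row.external_id: row.aliases.split(",")
                    for row in df.itertuples()})


@dataclass
class WeightedEdgeList:
    """(node_a, node_b, weight) triples, weight in (0, 1]."""

    edges: list[tuple[str, str, float]]

    @classmethod
    def from_tsv(cls, path: str, min_score: float = 0.0) -> "WeightedEdgeList":
        df = pd.read_csv(path, sep="\t")
        edges = [(str(a), str(b), float(w))
                 for a, b, w in zip(df["node_a"], df["node_b"], df["score"])
                 if float(w) >= min_score]
        return cls(edges)


@dataclass
class HeteroGraph:
    """Typed node sets and the four sparse blocks of the heterogeneous graph.

    Optional blocks ``A_cell_cell`` and ``A_cell_protein`` exist only for the
    ablation variants; the default model never builds them (a static cell-cell
    graph is replaced by learned attention, and cell-protein edges would leak
    the prediction target).
    """

    protein_names: list[str]
    gene_names: list[str]
    cell_ids: list[str]
    Ap: sp.csr_matrix            # Np x Np, symmetric
    Ag: sp.csr_matrix            # Ng x Ng, symmetric
    S: sp.csr_matrix             # Ng x Np, gene encodes protein
    A_RNA: sp.csr_matrix         # Nc x Ng, log-normalized expression
    A_cell_cell: sp.csr_matrix | None = None
    A_cell_protein: sp.csr_matrix | None = None

    @property
    def Np(self) -> int:
        return len(self.protein_names)

    @property
    def Ng(self) -> int:
        return len(self.gene_names)

    @property
    def Nc(self) -> int:
        return len(self.cell_ids)

    @property
    def N(self) -> int:
        return self.Np + self.Ng + self.Nc

    def assembled(self) -> sp.csr_matrix:
        """The full block adjacency in node order [protein | gene | cell]."""
        Zpc = sp.csr_matrix((self.Np, self.Nc))
        Zcc = sp.csr_matrix((self.Nc, self.Nc))
        return sp.bmat(
            [[self.Ap, self.S.T, Zpc],
             [self.S, self.Ag, self.A_RNA.T],
             [Zpc.T, self.A_RNA, Zcc]], format="csr")

    def save(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        sp.save_npz(os.path.join(out_dir, "Ap.npz"), sp.csr_matrix(self.Ap))
        sp.save_npz(os.path.join(out_dir, "Ag.npz"), sp.csr_matrix(self.Ag))
        sp.save_npz(os.path.join(out_dir, "S.npz"), sp.csr_matrix(self.S))
        sp.save_npz(os.path.join(out_dir, "A_RNA.npz"), sp.csr_matrix(self.A_RNA))
        pd.DataFrame({"name": self.protein_names}).to_csv(
            os.path.join(out_dir, "proteins.tsv"), sep="\t", index=False)
        pd.DataFrame({"name": self.gene_names}).to_csv(
            os.path.join(out_dir, "genes.tsv"), sep="\t", index=False)
        pd.DataFrame({"name": self.cell_ids}).to_csv(
            os.path.join(out_dir, "cells.tsv"), sep="\t", index=False)

    @classmethod
    def load(cls, out_dir: str) -> "HeteroGraph":
        def names(f):
            return pd.read_csv(os.path.join(out_dir, f), sep="\t",
                               dtype=str)["name"].tolist()
        return cls(
            protein_names=names("proteins.tsv"), gene_names=names("genes.tsv"),
            cell_ids=names("cells.tsv"),
            Ap=sp.load_npz(os.path.join(out_dir, "Ap.npz")),
            Ag=sp.load_npz(os.path.join(out_dir, "Ag.npz")),
            S=sp.load_npz(os.path.join(out_dir, "S.npz")),
            A_RNA=sp.load_npz(os.path.join(out_dir, "A_RNA.npz")))


def map_feature_ids(
    edges: WeightedEdgeList,
    aliases: IdAliasMap,
    display_names: list[str],
) -> tuple[WeightedEdgeList, dict]:
    """Resolve external IDs to dataset display names through the alias map.

    Matching is case-insensitive.  An external ID that resolves to several
    display names is mapped to all of them (the edge is duplicated) to
    maximize prior coverage.  Edges with any unresolvable endpoint are dropped
    and reported.  Duplicate unordered pairs keep the maximum weight;
    self-loops are removed.  Already-resolved lists pass through unchanged
    (display names resolve to themselves), making the operation idempotent.
    """
    if len(set(display_names)) != len(display_names):
        raise ValueError("display names must be unique")
    by_lower = {}
    for name in display_names:
        by_lower.setdefault(name.lower(), []).append(name)

    resolution: dict[str, list[str]] = {}
    ambiguous: dict[str, int] = {}

    def resolve(node: str) -> list[str]:
        if node in resolution:
            return resolution[node]
        hits: list[str] = []
        if node.lower() in by_lower:          # already a display name
            hits = list(by_lower[node.lower()])
        else:
            for alias in aliases.entries.get(node, []):
                hits.extend(by_lower.get(alias.lower(), []))
        hits = list(dict.fromkeys(hits))
        if len(hits) > 1:
            ambiguous[node] = len(hits)
        resolution[node] = hits
        return hits

    best: dict[tuple[str, str], float] = {}
    unmapped_nodes: set[str] = set()
    n_dropped = 0
    for a, b, w in edges.edges:
        ra, rb = resolve(a), resolve(b)
        if not ra or not rb:
            n_dropped += 1
            if not ra:
                unmapped_nodes.add(a)
            if not rb:
                unmapped_nodes.add(b)
            continue
        for na in ra:
            for nb in rb:
                if na == nb:
                    continue
                key = (na, nb) if na <= nb else (nb, na)
                best[key] = max(best[key], w) if key in best else w
    if ambiguous:
        logger.info("ambiguous external ids duplicated onto multiple names: %s",
                    ambiguous)
    report = {"n_edges_dropped": n_dropped,
              "unmapped_ids": sorted(unmapped_nodes),
              "ambiguous_ids": ambiguous}
    mapped = WeightedEdgeList([(a, b, w) for (a, b), w in sorted(best.items())])
    return mapped, report


def build_intra_graph(mapped: WeightedEdgeList, names: list[str]) -> sp.csr_matrix:
    """Symmetric within-modality adjacency indexed by ``names`` order.

    Features without edges stay as isolated (all-zero) rows — they are never
    dropped from the node set.
    """
    index = {n: i for i, n in enumerate(names)}
    n = len(names)
    rows, cols, vals = [], [], []
    best: dict[tuple[int, int], float] = {}
    for a, b, w in mapped.edges:
        if a not in index or b not in index:
            raise KeyError(f"edge endpoint not in names: {(a, b)}")
        i, j = index[a], index[b]
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        best[key] = max(best.get(key, 0.0), float(w))
    for (i, j), w in best.items():
        rows.extend((i, j))
        cols.extend((j, i))
        vals.extend((w, w))
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def split_symbol(name: str) -> str:
    """Symbol component of a feature name: text after the last underscore."""
    return name.rsplit("_", 1)[-1] if "_" in name else name


def build_gene_protein_links(gene_names: list[str],
                             protein_names: list[str]) -> sp.csr_matrix:
    """Binary Ng x Np matrix: 1 iff the gene's symbol equals the protein's.

    Gene names may be ``ENSGxxx_SYMBOL`` compounds (split on the last
    underscore) or plain symbols; comparison is case-insensitive.
    """
    rows, cols = [], []
    by_symbol: dict[str, list[int]] = {}
    for g, name in enumerate(gene_names):
        by_symbol.setdefault(split_symbol(name).lower(), []).append(g)
    for p, pname in enumerate(protein_names):
        for g in by_symbol.get(split_symbol(pname).lower(), []):
            rows.append(g)
            cols.append(p)
    return sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                         shape=(len(gene_names), len(protein_names)))


def build_cell_gene_graph(counts: ExpressionMatrix,
                          scale: float = LOGNORM_SCALE) -> sp.csr_matrix:
    """Cell-gene bipartite block: ``ln(1 + scale * count / cell_total)``.

    Zero counts carry no edge, so the sparsity pattern equals that of the
    count matrix; the per-cell normalization makes rows invariant to
    library-size rescaling.  All-zero cells yield all-zero rows (warned).
    """
    X = sp.csr_matrix(counts.X, copy=True).astype(float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    n_empty = int(np.sum(totals == 0))
    if n_empty:
        logger.warning("%d cells have zero total counts; their rows are empty",
                       n_empty)
    safe = np.where(totals > 0, totals, 1.0)
    X = sp.diags(1.0 / safe) @ X
    X.data = np.log1p(scale * X.data)
    X.eliminate_zeros()
    return sp.csr_matrix(X)


def assemble_hetero_graph(Ap: sp.spmatrix, Ag: sp.spmatrix, S: sp.spmatrix,
                          A_RNA: sp.spmatrix,
                          protein_names: list[str] | None = None,
                          gene_names: list[str] | None = None,
                          cell_ids: list[str] | None = None) -> HeteroGraph:
    """Bundle the four blocks, validating all shared dimensions."""
    Ap, Ag = sp.csr_matrix(Ap), sp.csr_matrix(Ag)
    S, A_RNA = sp.csr_matrix(S), sp.csr_matrix(A_RNA)
    Np, Ng, Nc = Ap.shape[0], Ag.shape[0], A_RNA.shape[0]
    problems = []
    if Ap.shape != (Np, Np):
        problems.append(f"Ap {Ap.shape} not square")
    if Ag.shape != (Ng, Ng):
        problems.append(f"Ag {Ag.shape} not square")
    if S.shape != (Ng, Np):
        problems.append(f"S {S.shape} != (Ng={Ng}, Np={Np})")
    if A_RNA.shape != (Nc, Ng):
        problems.append(f"A_RNA {A_RNA.shape} has {A_RNA.shape[1]} genes, Ag has {Ng}")
    if problems:
        raise ValueError("block dimension mismatch: " + "; ".join(problems))
    return HeteroGraph(
        protein_names=protein_names or [f"p{i}" for i in range(Np)],
        gene_names=gene_names or [f"g{i}" for i in range(Ng)],
        cell_ids=cell_ids or [f"c{i}" for i in range(Nc)],
        Ap=Ap, Ag=Ag, S=S, A_RNA=A_RNA)


def build_knn_cell_graph(features: np.ndarray, k: int) -> sp.csr_matrix:
    """k-NN cell-cell graph on cosine similarity, symmetrized by union.

    Ablation-only: the default model learns cell-cell structure through
    attention instead.  Ties in similarity are broken by cell index order.
    """
    n = features.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < number of cells {n}")
    F = sk_normalize(np.asarray(features, dtype=float), norm="l2", axis=1)
    C = F @ F.T
    np.fill_diagonal(C, -np.inf)
    rows, cols = [], []
    for i in range(n):
        # stable sort on (-similarity, index) pins tie behaviour
        order = np.lexsort((np.arange(n), -C[i]))
        for j in order[:k]:
            rows.append(i)
            cols.append(int(j))
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    A = A.maximum(A.T)          # union symmetrization
    A.setdiag(0)
    A.eliminate_zeros()
    return sp.csr_matrix(A)


def build_cell_protein_graph(protein: ExpressionMatrix,
                             scale: float = LOGNORM_SCALE) -> sp.csr_matrix:
    """Cell-protein bipartite block weighted by measured protein levels.

    Ablation-only: these edges carry the prediction target and cause the
    exact information leakage the default model excludes.  Built with the
    same normalization scheme as the cell-gene block, on shifted-positive
    levels so the log transform is defined.
    """
    X = protein.toarray()
    X = X - X.min() if X.min() < 0 else X
    em = ExpressionMatrix(sp.csr_matrix(X), protein.cell_ids,
                          protein.feature_names)
    return build_cell_gene_graph(em, scale=scale)


def build_graph_from_dataset(
    rna: ExpressionMatrix,
    protein_names: list[str],
    gene_edges: WeightedEdgeList,
    protein_edges: WeightedEdgeList,
    aliases: IdAliasMap,
    scale: float = LOGNORM_SCALE,
    min_score: float = 0.0,
) -> tuple[HeteroGraph, dict]:
    """End-to-end construction: resolve IDs, build all four blocks, assemble."""
    if min_score > 0:
        gene_edges = WeightedEdgeList([e for e in gene_edges.edges if e[2] >= min_score])
        protein_edges = WeightedEdgeList([e for e in protein_edges.edges if e[2] >= min_score])
    mapped_g, rep_g = map_feature_ids(gene_edges, aliases, rna.feature_names)
    mapped_p, rep_p = map_feature_ids(protein_edges, aliases, protein_names)
    Ag = build_intra_graph(mapped_g, rna.feature_names)
    Ap = build_intra_graph(mapped_p, protein_names)
    S = build_gene_protein_links(rna.feature_names, protein_names)
    A_RNA = build_cell_gene_graph(rna, scale=scale)
    graph = assemble_hetero_graph(Ap, Ag, S, A_RNA,
                                  protein_names=protein_names,
                                  gene_names=rna.feature_names,
                                  cell_ids=rna.cell_ids)
    return graph, {"genes": rep_g, "proteins": rep_p}
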