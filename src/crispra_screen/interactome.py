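"""Ligand-receptor network assembly, phylogenetic homology analysis (PHA),
expression co-clustering and database-overlap set operations.

PHA here uses pairwise global protein alignment (BLOSUM62, affine gaps)
distances d = 1 - identity rather than a full multiple sequence alignment;
neighbor joining on those distances yields the family dendrograms used to
nominate sequence-similar candidate receptors around a validated seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster import hierarchy
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

__all__ = [
    "InteractionEdge",
    "NetworkSummary",
    "build_network",
    "pairwise_identity",
    "distance_matrix",
    "nj_tree",
    "pha_candidates",
    "hierarchical_cluster",
    "correlation_heatmap",
    "database_overlap",
    "ClusterResult",
]

LIBRARIES = ("TM1", "TM2+")
SOURCES = ("Screen", "PHA")
ASSAYS = ("SPR", "CSS")


@dataclass(frozen=True)
class InteractionEdge:
    """One ligand-receptor pair with provenance metadata."""

    ligand: str
    receptor: str
    library: str
    source: str
    assays: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.library not in LIBRARIES:
            raise ValueError(f"library must be one of {LIBRARIES}")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}")
        bad = set(self.assays) - set(ASSAYS)
        if bad:
            raise ValueError(f"unknown assays {sorted(bad)}")

    @property
    def pair(self) -> frozenset:
        return frozenset({self.ligand.upper(), self.receptor.upper()})


@dataclass
class NetworkSummary:
    """Exact set arithmetic over an interaction edge list."""

    n_edges: int
    edges_by_library: dict[str, int]
    edges_by_source: dict[str, int]
    n_ligands: int
    ligands_by_library: dict[str, int]
    ligands: list[str]
    receptors: list[str]
    graph: nx.Graph


def build_network(edges: Sequence[InteractionEdge]) -> NetworkSummary:
    """Summarize an interaction network; rejects duplicate unordered pairs."""
    seen: set[frozenset] = set()
    graph = nx.Graph()
    for edge in edges:
        if edge.pair in seen:
            raise ValueError(
                f"duplicate interaction {edge.ligand}-{edge.receptor}"
            )
        seen.add(edge.pair)
        graph.add_edge(
            edge.ligand,
            edge.receptor,
            library=edge.library,
            source=edge.source,
            assays=",".join(edge.assays),
        )
    by_library = {
        lib: sum(1 for e in edges if e.library == lib) for lib in LIBRARIES
    }
    by_source = {src: sum(1 for e in edges if e.source == src) for src in SOURCES}
    ligands = sorted({e.ligand for e in edges})
    ligands_by_library = {
        lib: len({e.ligand for e in edges if e.library == lib})
        for lib in LIBRARIES
    }
    receptors = sorted({e.receptor for e in edges})
    return NetworkSummary(
        n_edges=len(edges),
        edges_by_library=by_library,
        edges_by_source=by_source,
        n_ligands=len(ligands),
        ligands_by_library=ligands_by_library,
        ligands=ligands,
        receptors=receptors,
        graph=graph,
    )


def edges_from_frame(frame: pd.DataFrame) -> list[InteractionEdge]:
    """Edge list from a TSV-style table (ligand, receptor, library, source,
    assays as comma-separated string)."""
    edges = []
    for row in frame.itertuples(index=False):
        assays = tuple(
            a for a in str(getattr(row, "assays", "")).split(",") if a in ASSAYS
        )
        edges.append(
            InteractionEdge(
                ligand=row.ligand,
                receptor=row.receptor,
                library=row.library,
                source=row.source,
                assays=assays,
            )
        )
    return edges


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical aligned positions over the global alignment
    length (BLOSUM62, gap open 10, gap extend 1)."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner()
    alphabet = set(str(aligner.substitution_matrix.alphabet))
    for seq in (seq_a, seq_b):
        bad = set(seq.upper()) - alphabet
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)}")
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    top, bottom = aln[0], aln[1]
    matches = sum(a == b and a != "-" for a, b in zip(top, bottom))
    return matches / len(top)


def distance_matrix(sequences: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise-alignment distance matrix d = 1 - identity."""
    labels = list(sequences)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = 1.0 - pairwise_identity(
            sequences[labels[i]], sequences[labels[j]]
        )
    return DistanceMatrix(d, ids=labels)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths are clamped to zero.

    On additive distance matrices the tree's tip-to-tip path lengths
    reproduce the input distances exactly.
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(dm)  # validates symmetry / zero diagonal
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def pha_candidates(
    validated_receptor: str,
    family: Mapping[str, str] | DistanceMatrix,
    delta: float = 0.6,
) -> list[tuple[str, float]]:
    """Family members within alignment distance ``delta`` of a validated
    receptor, sorted by distance (the seed itself excluded)."""
    dm = family if isinstance(family, DistanceMatrix) else distance_matrix(family)
    if validated_receptor not in dm.ids:
        raise KeyError(f"{validated_receptor!r} not in the family")
    row = dm[validated_receptor]
    out = [
        (label, float(d))
        for label, d in zip(dm.ids, row)
        if label != validated_receptor and d <= delta
    ]
    return sorted(out, key=lambda t: (t[1], t[0]))


@dataclass
class ClusterResult:
    """Hierarchical clustering output: scipy linkage matrix plus the
    deterministic leaf order."""

    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]


def _correlation_condensed(values: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson r distances between rows; constant rows get
    the maximal distance 2 with a warning."""
    n = values.shape[0]
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            "constant rows have undefined correlation; assigning maximal "
            "distance 2",
            stacklevel=3,
        )
    centered = values - values.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centered, axis=1)
    norm[constant] = 1.0
    unit = centered / norm[:, None]
    corr = unit @ unit.T
    dist = 1.0 - corr
    dist[constant, :] = 2.0
    dist[:, constant] = 2.0
    np.fill_diagonal(dist, 0.0)
    return dist[np.triu_indices(n, k=1)]


def hierarchical_cluster(
    expr: pd.DataFrame,
    axis: str = "genes",
    method: str = "ward",
    metric: str = "correlation",
) -> ClusterResult:
    """Hierarchical clustering of an expression matrix (genes x tissues)
    with Ward linkage on correlation distances.

    ``axis='genes'`` clusters rows, ``axis='tissues'`` clusters columns.
    """
    if axis not in ("genes", "tissues"):
        raise ValueError("axis must be 'genes' or 'tissues'")
    mat = expr if axis == "genes" else expr.T
    if len(mat) < 2:
        raise ValueError("need >= 2 items on the clustered axis")
    values = mat.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression values must be nonnegative")
    if metric == "correlation":
        condensed = _correlation_condensed(values)
    else:
        from scipy.spatial.distance import pdist

        condensed = pdist(values, metric=metric)
    Z = hierarchy.linkage(condensed, method=method)
    order = hierarchy.leaves_list(Z)
    labels = list(mat.index)
    return ClusterResult(
        linkage=Z, labels=labels, leaf_order=[labels[i] for i in order]
    )


def two_way_cluster(expr: pd.DataFrame, method: str = "ward"):
    """Cluster both genes and tissues (two-way mode)."""
    return (
        hierarchical_cluster(expr, "genes", method),
        hierarchical_cluster(expr, "tissues", method),
    )


def correlation_heatmap(expr: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix of genes across tissues."""
    corr = expr.T.corr(method="pearson")
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


def _normalize_pairs(pairs: Iterable) -> set[frozenset]:
    out = set()
    for pair in pairs:
        if isinstance(pair, InteractionEdge):
            out.add(pair.pair)
        else:
            a, b = pair
            out.add(frozenset({str(a).upper(), str(b).upper()}))
    return out


def database_overlap(
    edges: Iterable, external_edge_sets: Mapping[str, Iterable]
) -> dict:
    """Overlap of the screen's interactions with external databases.

    Returns per-database intersection counts and the full Venn partition
    (keys are frozensets of set names, values are exclusive region sizes).
    """
    ours = _normalize_pairs(edges)
    sets = {"screen": ours}
    sets.update({k: _normalize_pairs(v) for k, v in external_edge_sets.items()})
    intersections = {
        name: len(ours & members)
        for name, members in sets.items()
        if name != "screen"
    }
    universe = set().union(*sets.values()) if sets else set()
    venn: dict[frozenset, int] = {}
    names = list(sets)
    for element in universe:
        membership = frozenset(n for n in names if element in sets[n])
        venn[membership] = venn.get(membership, 0) + 1
    return {"intersections": intersections, "venn": venn, "sizes": {
        name: len(members) for name, members in sets.items()
    }}
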