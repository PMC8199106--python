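"""Phyletic-pattern (presence/absence) clustering of genomes.

Genomes are scored 0/1 against reference gene-family sets (e.g.
informational orthologous groups or fold-superfamily domains): 1 if at
least one gene in the genome hits any representative of the family at the
detection thresholds, else 0.  The Euclidean distance between 0/1 rows
(= sqrt of the Hamming distance) feeds agglomerative hierarchical
clustering, whose dendrogram groups genomes by gene content rather than
by any single marker's phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from .errors import ConfigError, DataError
from .homology import (
    PHYLETIC_THRESHOLDS,
    SearchThresholds,
    SubstitutionMatrix,
    search_database,
)
from .io_formats import ProteinRecord, read_fasta

LINKAGE_METHODS = ("single", "complete", "average", "weighted", "centroid", "median", "ward")


@dataclass(frozen=True)
class ReferenceFamilySet:
    """A named collection of gene families with representative sequences."""

    name: str
    families: Mapping[str, tuple[ProteinRecord, ...]]
    expected_size: int | None = None

    def __post_init__(self) -> None:
        for fid, reps in self.families.items():
            if len(reps) < 1:
                raise DataError(f"family {fid!r} has no representative sequences")

    @classmethod
    def from_files(cls, name: str, fasta_path: str | Path, table_path: str | Path):
        """Load representatives from a FASTA plus a family table TSV
        (columns ``family_id``, ``seq_id``)."""
        records = {r.id: r for r in read_fasta(fasta_path)}
        df = pd.read_csv(table_path, sep="\t", dtype=str)
        if not {"family_id", "seq_id"} <= set(df.columns):
            raise DataError(f"{table_path}: family table needs family_id and seq_id columns")
        families: dict[str, list[ProteinRecord]] = {}
        for row in df.itertuples(index=False):
            if row.seq_id not in records:
                raise DataError(f"{table_path}: representative {row.seq_id!r} not in FASTA")
            families.setdefault(row.family_id, []).append(records[row.seq_id])
        return cls(name=name, families={k: tuple(v) for k, v in families.items()})

    def __len__(self) -> int:
        return len(self.families)


@dataclass(frozen=True)
class PhyleticMatrix:
    """Genomes x families 0/1 matrix (rows = genomes, columns = families)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise DataError("phyletic matrix entries must be 0 or 1")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def family_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="genome_id")


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over genomes, heights non-decreasing rootward."""

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray

    def __post_init__(self) -> None:
        heights = self.linkage_matrix[:, 2]
        if (heights < 0).any():
            raise DataError("merge heights must be non-negative")
        if (np.diff(heights) < -1e-9).any():
            raise DataError("merge heights must be non-decreasing rootward")

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def to_newick(self) -> str:
        """Newick string with leaf labels = genome ids and ultrametric
        branch lengths (parent merge height minus child height)."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            inner = ",".join(render(c, node.dist) for c in (node.left, node.right))
            return f"({inner}):{length:g}"

        root = tree
        inner = ",".join(render(c, root.dist) for c in (root.left, root.right))
        return f"({inner});"


def detect_family_presence(
    genome: Sequence[ProteinRecord],
    family_reps: Sequence[ProteinRecord],
    thresholds: SearchThresholds = PHYLETIC_THRESHOLDS,
    matrix: SubstitutionMatrix | None = None,
) -> int:
    """1 if any genome gene hits any family representative at thresholds."""
    if not family_reps:
        raise DataError("family has no representatives")
    for gene in genome:
        if search_database(gene, family_reps, thresholds=thresholds, matrix=matrix):
            return 1
    return 0


def build_phyletic_matrix(
    genomes: Mapping[str, Sequence[ProteinRecord]],
    family_set: ReferenceFamilySet,
    thresholds: SearchThresholds = PHYLETIC_THRESHOLDS,
    matrix: SubstitutionMatrix | None = None,
) -> PhyleticMatrix:
    """Score every genome against every family; all-zero columns are kept
    (absence everywhere is itself a phyletic character)."""
    if len(genomes) < 2:
        raise DataError("need at least two genomes for a phyletic matrix")
    family_ids = list(family_set.families)
    rows = {
        gid: [
            detect_family_presence(genes, family_set.families[fid], thresholds, matrix)
            for fid in family_ids
        ]
        for gid, genes in genomes.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=family_ids).astype(np.int8)
    return PhyleticMatrix(data=df)


def euclidean_distance_matrix(matrix: PhyleticMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between genome rows.

    For 0/1 rows this equals sqrt(Hamming distance in counts)."""
    df = matrix.data if isinstance(matrix, PhyleticMatrix) else matrix
    values = df.to_numpy(dtype=float)
    if not np.isin(values, (0.0, 1.0)).all():
        raise DataError("distance matrix input must be a 0/1 matrix")
    if len(df) < 2:
        raise DataError("need at least two genomes")
    dist = squareform(pdist(values, metric="euclidean"))
    return pd.DataFrame(dist, index=df.index, columns=df.index)


def agglomerative_cluster(distances: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Hierarchical clustering of a genome distance matrix.

    Average linkage is the default (robust to block noise in presence/
    absence data); any scipy linkage method name is accepted.
    """
    if linkage not in LINKAGE_METHODS:
        raise ConfigError(f"unknown linkage {linkage!r}; choose from {LINKAGE_METHODS}")
    values = distances.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T):
        raise DataError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(values), 0):
        raise DataError("distance matrix diagonal must be zero")
    condensed = squareform(values, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(labels=tuple(distances.index), linkage_matrix=Z)


def cut_and_score(
    dendrogram: Dendrogram,
    k: int,
    true_groups: Mapping[str, str],
) -> tuple[dict[str, int], float]:
    """Cut the dendrogram into k clusters and score agreement with a
    reference labeling by the adjusted Rand index (chance-corrected,
    in [-1, 1])."""
    n = len(dendrogram.labels)
    if not 1 <= k <= n:
        raise ConfigError(f"k must be in [1, {n}], got {k}")
    missing = [l for l in dendrogram.labels if l not in true_groups]
    if missing:
        raise DataError(f"true_groups missing label(s): {missing[:3]}")
    flat = hierarchy.cut_tree(dendrogram.linkage_matrix, n_clusters=k).ravel()
    partition = {label: int(c) for label, c in zip(dendrogram.labels, flat)}
    truth = [true_groups[l] for l in dendrogram.labels]
    ari = float(adjusted_rand_score(truth, flat))
    return partition, ari


def select_marker_hits(
    hits: Sequence,
    min_alignment_length: int = 70,
    min_identity_pct: float = 20.0,
    max_evalue: float = 1e-3,
) -> list:
    """Retain hits suitable for conserved-marker (e.g. RNAP II, DNA pol A,
    RNR, TopoIIA, EF-1, ThyA, FEN1, PCNA) ortholog extraction.

    Bounds are inclusive: alignment length >= 70 aa, identity >= 20%,
    e-value <= 0.001 by default.  Downstream multiple alignment and tree
    building are exported to external tools, not performed here.
    """
    kept = []
    for hit in hits:
        length = getattr(hit, "alignment_length", None)
        if length is None:
            raise DataError(f"hit {getattr(hit, 'query_id', '?')} lacks alignment_length")
        if (
            length >= min_alignment_length
            and hit.identity_pct >= min_identity_pct
            and hit.evalue <= max_evalue
        ):
            kept.append(hit)
    return kept
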