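"""Best-hit origin attribution, mosaicism profiles, and rhizome networks.

A gene's origin is the taxonomic group of its single top-scoring hit after
(i) excluding hits from the query's own genus or taxon and (ii) applying
the retention thresholds.  Genes left with no surviving hit are ORFans —
sequences without detectable homologs in the searched database.  Per-genome
label counts and percentages form the mosaicism profile, and the bipartite
gene -> origin-group graph is the rhizome network.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import ConfigError, DataError
from .homology import (
    AlignmentResult,
    RHIZOME_THRESHOLDS,
    SearchThresholds,
    SubstitutionMatrix,
    hit_sort_key,
    passes_thresholds,
    search_database,
)
from .io_formats import ProteinRecord, TaxonomyEntry
from .util import count_percentage

#: Distinguished origin label for genes with no surviving homolog.
ORFAN = "ORFan"


@dataclass(frozen=True)
class SelfTaxonRule:
    """Which reference hits count as the query organism itself.

    The query's own taxon ids are always excluded; ``exclusion_rank``
    additionally widens exclusion to the whole genus (default) or origin
    group.  The genus rank is the default because excluding an entire
    origin group would erase the within-group transfer signal.
    """

    self_taxon_ids: frozenset[str] = frozenset()
    self_genus: str | None = None
    exclusion_rank: str = "genus"

    def __post_init__(self) -> None:
        if not self.self_taxon_ids and self.self_genus is None:
            raise ConfigError("self-taxon rule needs taxon ids and/or a genus")
        if self.exclusion_rank not in ("genus", "taxon_id", "group"):
            raise ConfigError("exclusion_rank must be 'genus', 'taxon_id' or 'group'")


@dataclass(frozen=True)
class GeneAttribution:
    """Per-gene origin call: an origin-group label, or ORFan."""

    gene_id: str
    origin: str
    best_hit: AlignmentResult | None = None

    def __post_init__(self) -> None:
        if (self.origin == ORFAN) != (self.best_hit is None):
            raise DataError(f"gene {self.gene_id!r}: origin/best_hit inconsistency")


@dataclass(frozen=True)
class MosaicismProfile:
    """Per-genome gene counts and percentages by origin label."""

    genome_id: str
    counts: Mapping[str, int]
    total_genes: int
    percentages: Mapping[str, float]

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total_genes:
            raise DataError(f"profile {self.genome_id!r}: counts do not sum to total_genes")
        if abs(sum(self.percentages.values()) - 100.0) > 0.05 * max(len(self.percentages), 1):
            raise DataError(f"profile {self.genome_id!r}: percentages far from 100")


@dataclass(frozen=True)
class RhizomeNetwork:
    """Bipartite gene -> origin-group graph; edge weight = best-hit identity."""

    graph: nx.DiGraph

    @property
    def gene_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "gene"]

    @property
    def group_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "group"]


def _resolve_taxon(hit: AlignmentResult, taxonomy: Mapping[str, TaxonomyEntry]) -> TaxonomyEntry:
    if hit.subject_taxon_id is None or hit.subject_taxon_id not in taxonomy:
        raise DataError(
            f"subject {hit.subject_id!r}: taxon {hit.subject_taxon_id!r} "
            "not resolvable in the taxonomy table"
        )
    return taxonomy[hit.subject_taxon_id]


def exclude_self_hits(
    hits: Sequence[AlignmentResult],
    rule: SelfTaxonRule,
    taxonomy: Mapping[str, TaxonomyEntry],
) -> list[AlignmentResult]:
    """Drop hits from the query's own genus/taxon/group; order preserved."""
    self_genera = {rule.self_genus} if rule.self_genus is not None else set()
    self_groups: set[str] = set()
    for tid in rule.self_taxon_ids:
        if tid in taxonomy:
            self_genera.add(taxonomy[tid].genus)
            self_groups.add(taxonomy[tid].group)
    kept = []
    for hit in hits:
        entry = _resolve_taxon(hit, taxonomy)
        if entry.taxon_id in rule.self_taxon_ids:
            continue
        if rule.exclusion_rank == "genus" and entry.genus in self_genera:
            continue
        if rule.exclusion_rank == "group" and entry.group in self_groups:
            continue
        kept.append(hit)
    return kept


def attribute_gene(
    gene_id: str,
    hits: Sequence[AlignmentResult],
    thresholds: SearchThresholds,
    taxonomy: Mapping[str, TaxonomyEntry],
) -> GeneAttribution:
    """Call one gene's origin from its (already self-excluded) hit list.

    The surviving hits are ordered deterministically (bitscore desc,
    e-value asc, identity desc, subject id) and the top hit's group wins;
    with no survivor the gene is an ORFan.
    """
    surviving = sorted((h for h in hits if passes_thresholds(h, thresholds)), key=hit_sort_key)
    if not surviving:
        return GeneAttribution(gene_id=gene_id, origin=ORFAN, best_hit=None)
    best = surviving[0]
    return GeneAttribution(gene_id=gene_id, origin=_resolve_taxon(best, taxonomy).group, best_hit=best)


def attribute_genome(
    genome: Sequence[ProteinRecord],
    db: Sequence[ProteinRecord],
    taxonomy: Mapping[str, TaxonomyEntry],
    rule: SelfTaxonRule,
    thresholds: SearchThresholds = RHIZOME_THRESHOLDS,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[GeneAttribution]:
    """Attribute every gene of a genome: search, self-exclude, call origin."""
    if not genome:
        raise DataError("genome has no genes")
    attributions = []
    for gene in genome:
        hits = search_database(
            gene, db, thresholds=thresholds, matrix=matrix, gap_open=gap_open, gap_extend=gap_extend
        )
        hits = exclude_self_hits(hits, rule, taxonomy)
        attributions.append(attribute_gene(gene.id, hits, thresholds, taxonomy))
    return attributions


def mosaicism_profile(genome_id: str, attributions: Sequence[GeneAttribution]) -> MosaicismProfile:
    """Counts and half-up-rounded percentages of genes per origin label."""
    if not attributions:
        raise DataError("cannot profile an empty attribution list")
    counts = Counter(a.origin for a in attributions)
    return profile_from_counts(genome_id, counts)


def profile_from_counts(genome_id: str, counts: Mapping[str, int]) -> MosaicismProfile:
    """Build a profile straight from per-label gene counts.

    Useful for recomputing published count -> percentage arithmetic
    without re-running a search.
    """
    if not counts:
        raise DataError("cannot profile empty counts")
    total = sum(counts.values())
    if total <= 0 or any(c < 0 for c in counts.values()):
        raise DataError("counts must be non-negative with a positive total")
    percentages = {label: count_percentage(c, total) for label, c in counts.items()}
    return MosaicismProfile(
        genome_id=genome_id, counts=dict(counts), total_genes=total, percentages=percentages
    )


def combine_origin_shares(profile: MosaicismProfile, labels: Iterable[str]) -> float:
    """Joint percentage of several origin labels, from summed counts.

    Summing counts before the single rounding step keeps the combined
    share exact (rounding two shares separately and adding can drift)."""
    labels = list(labels)
    unknown = [l for l in labels if l not in profile.counts]
    if unknown:
        raise DataError(f"label(s) {unknown} not in profile {profile.genome_id!r}")
    if not labels:
        return 0.0
    return count_percentage(sum(profile.counts[l] for l in set(labels)), profile.total_genes)


def build_rhizome_network(attributions: Sequence[GeneAttribution]) -> RhizomeNetwork:
    """Gene and origin-group nodes; one weighted edge per attributed gene.

    ORFan genes appear as isolated gene nodes (out-degree 0), which is the
    visual signature of unique sequences in a rhizome figure.
    """
    graph = nx.DiGraph()
    for att in attributions:
        graph.add_node(att.gene_id, kind="gene", origin=att.origin)
    for att in attributions:
        if att.best_hit is None:
            continue
        if not graph.has_node(att.origin):
            graph.add_node(att.origin, kind="group")
        graph.add_edge(
            att.gene_id,
            att.origin,
            weight=att.best_hit.identity_pct,
            subject_id=att.best_hit.subject_id,
        )
    return RhizomeNetwork(graph=graph)


def attributions_to_table(attributions: Sequence[GeneAttribution]) -> pd.DataFrame:
    """Per-gene attribution table (gene, origin, best-hit summary)."""
    rows = []
    for att in attributions:
        h = att.best_hit
        rows.append(
            {
                "gene_id": att.gene_id,
                "origin": att.origin,
                "subject_id": h.subject_id if h else "",
                "identity_pct": h.identity_pct if h else "",
                "query_cov_pct": h.query_cov_pct if h else "",
                "evalue": h.evalue if h else "",
            }
        )
    return pd.DataFrame(rows)


def compare_profiles(profiles: Sequence[MosaicismProfile]) -> pd.DataFrame:
    """Pairwise total-variation distance between profile percentage vectors.

    On the 0-100 percentage scale: identical profiles score 0, fully
    disjoint origin compositions score 100.
    """
    if len(profiles) < 2:
        raise DataError("need at least two profiles to compare")
    labels = sorted({l for p in profiles for l in p.percentages})
    ids = [p.genome_id for p in profiles]
    vectors = [[p.percentages.get(l, 0.0) for l in labels] for p in profiles]
    n = len(profiles)
    table = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            tv = 0.5 * sum(abs(a - b) for a, b in zip(vectors[i], vectors[j]))
            table[i][j] = table[j][i] = tv
    return pd.DataFrame(table, index=ids, columns=ids)
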