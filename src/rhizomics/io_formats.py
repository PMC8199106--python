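"""Readers and writers for every external representation the pipeline touches.

Formats: protein FASTA, taxonomy TSV, 12-column tabular hit files (the
blast ``-outfmt 6`` dialect), GEXF networks, Newick dendrograms, and
profile tables.  Taxonomy is carried as an explicit local table rather
than resolved against a live database, so runs are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO

from .errors import ConfigError, DataError
from .util import count_percentage

logger = logging.getLogger(__name__)

#: The 20 standard residues plus the ambiguity code X.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Origin-group labels recognised by default.  Configurable everywhere a
#: taxonomy is read; this set covers cellular domains, the ultra-small
#: symbiont radiations (CPR, DPANN), Asgard archaea, viruses and organelles.
DEFAULT_GROUP_LABELS = (
    "Bacteria",
    "Archaea",
    "DPANN",
    "Asgard",
    "Eukaryota",
    "CPR",
    "Viruses",
    "Mitochondria",
    "Chloroplast",
)


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with its identifier and source taxon."""

    id: str
    sequence: str
    taxon_id: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("protein record id must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if len(self.sequence) < 1:
            raise DataError(f"record {self.id!r}: sequence must be non-empty")
        bad = [(i, c) for i, c in enumerate(self.sequence) if c not in AMINO_ALPHABET]
        if bad:
            i, c = bad[0]
            raise DataError(
                f"record {self.id!r}: residue {c!r} at position {i + 1} is outside "
                "the amino-acid alphabet (20 standard residues plus X)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TaxonomyEntry:
    """Taxonomic context of one reference taxon.

    ``group`` is the origin-group label used for attribution; ``lineage``
    is an ordered, root-first list of rank labels.
    """

    taxon_id: str
    genus: str
    group: str
    lineage: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.lineage:
            raise DataError(f"taxon {self.taxon_id!r}: lineage must be non-empty")


@dataclass(frozen=True)
class HitTableDialect:
    """Column order of the 12-field tabular hit format.

    Coordinates are 1-based inclusive and identity is on the 0-100 scale,
    matching the blast tabular convention so externally computed searches
    can be ingested directly.
    """

    columns: tuple[str, ...] = (
        "query_id",
        "subject_id",
        "identity_pct",
        "alignment_length",
        "mismatches",
        "gap_opens",
        "qstart",
        "qend",
        "sstart",
        "send",
        "evalue",
        "bitscore",
    )

    def __post_init__(self) -> None:
        if len(self.columns) != 12:
            raise ConfigError("hit-table dialect must have exactly 12 columns")


BLAST_TAB = HitTableDialect()

_INT_FIELDS = {"alignment_length", "mismatches", "gap_opens", "qstart", "qend", "sstart", "send"}
_FLOAT_FIELDS = {"identity_pct", "evalue", "bitscore"}


@dataclass(frozen=True)
class HitRecord:
    """One query-vs-subject local alignment summary (one hit-table row)."""

    query_id: str
    subject_id: str
    identity_pct: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0 <= self.identity_pct <= 100:
            raise DataError(f"hit {self.query_id}/{self.subject_id}: identity outside [0, 100]")
        if self.evalue < 0:
            raise DataError(f"hit {self.query_id}/{self.subject_id}: negative e-value")
        if self.alignment_length < 1:
            raise DataError(f"hit {self.query_id}/{self.subject_id}: alignment length < 1")


# ---------------------------------------------------------------------------
# FASTA


def _resolve_taxon(
    rec_id: str,
    description: str,
    taxon_map: Mapping[str, str] | None,
    taxon_token: str,
) -> str | None:
    if taxon_map is not None and rec_id in taxon_map:
        return taxon_map[rec_id]
    prefix = taxon_token + "="
    for token in description.split()[1:]:
        if token.startswith(prefix):
            return token[len(prefix):]
    return None


def read_fasta(
    path: str | Path,
    taxon_map: Mapping[str, str] | None = None,
    taxon_token: str = "taxon",
) -> list[ProteinRecord]:
    """Read a protein FASTA file into validated records, input order preserved.

    The source taxon of each record is resolved from a ``taxon=<id>`` token
    in the header description, or from the sidecar ``taxon_map`` (which
    takes precedence).  Stop codons (``*``) are stripped with a warning.
    Duplicate ids and residues outside the alphabet are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if "*" in seq:
            logger.warning("%s: stripping %d stop codon(s) from %s", path, seq.count("*"), rec.id)
            seq = seq.replace("*", "")
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=seq,
                taxon_id=_resolve_taxon(rec.id, rec.description, taxon_map, taxon_token),
            )
        )
    if not records:
        raise DataError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA; the taxon travels in a ``taxon=`` header token."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if rec.taxon_id is None else f"{rec.id} taxon={rec.taxon_id}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Taxonomy table


def read_taxonomy_table(
    path: str | Path,
    allowed_groups: Sequence[str] = DEFAULT_GROUP_LABELS,
) -> dict[str, TaxonomyEntry]:
    """Read a taxonomy TSV (taxon_id, genus, group, semicolon-joined lineage)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"taxon_id", "genus", "group", "lineage"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing taxonomy column(s): {sorted(missing)}")
    allowed = set(allowed_groups)
    table: dict[str, TaxonomyEntry] = {}
    for row in df.itertuples(index=False):
        if row.taxon_id in table:
            raise DataError(f"{path}: duplicate taxon_id {row.taxon_id!r}")
        if row.group not in allowed:
            raise DataError(
                f"{path}: unknown group {row.group!r} for taxon {row.taxon_id!r}; "
                f"allowed labels: {sorted(allowed)}"
            )
        table[row.taxon_id] = TaxonomyEntry(
            taxon_id=row.taxon_id,
            genus=row.genus,
            group=row.group,
            lineage=tuple(part for part in str(row.lineage).split(";") if part),
        )
    if not table:
        raise DataError(f"{path}: empty taxonomy table")
    return table


def write_taxonomy_table(taxonomy: Mapping[str, TaxonomyEntry], path: str | Path) -> None:
    rows = [
        {
            "taxon_id": e.taxon_id,
            "genus": e.genus,
            "group": e.group,
            "lineage": ";".join(e.lineage),
        }
        for e in taxonomy.values()
    ]
    pd.DataFrame(rows, columns=["taxon_id", "genus", "group", "lineage"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Tabular hits


def read_tabular_hits(path: str | Path, dialect: HitTableDialect = BLAST_TAB) -> list[HitRecord]:
    """Read a 12-column tabular hit file.  An empty file yields an empty list.

    Coverage is deliberately not populated here: external hit tables carry
    no query length, so coverage is reconstructed downstream
    (:func:`rhizomics.homology.attach_coverage`).
    """
    path = Path(path)
    hits: list[HitRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) != 12:
                raise DataError(f"{path}:{lineno}: expected 12 fields, got {len(fields)}")
            kwargs: dict[str, object] = {}
            for name, raw in zip(dialect.columns, fields):
                try:
                    if name in _INT_FIELDS:
                        kwargs[name] = int(raw)
                    elif name in _FLOAT_FIELDS:
                        kwargs[name] = float(raw)
                    else:
                        kwargs[name] = raw
                except ValueError as exc:
                    raise DataError(f"{path}:{lineno}: bad value {raw!r} for {name}") from exc
            try:
                hits.append(HitRecord(**kwargs))  # type: ignore[arg-type]
            except DataError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_tabular_hits(
    hits: Iterable[HitRecord], path: str | Path, dialect: HitTableDialect = BLAST_TAB
) -> None:
    """Write hits in the same 12-column dialect; round-trips losslessly."""
    with Path(path).open("w") as fh:
        for hit in hits:
            values = []
            for name in dialect.columns:
                v = getattr(hit, name)
                values.append(repr(v) if isinstance(v, float) else str(v))
            fh.write("\t".join(values) + "\n")


# ---------------------------------------------------------------------------
# Networks, dendrograms, profiles


def write_gexf(network, path: str | Path) -> None:
    """Export a rhizome network as GEXF 1.2 (consumable by Gephi-class tools)."""
    graph = network.graph if hasattr(network, "graph") else network
    nx.write_gexf(graph, str(path), version="1.2draft")


def write_newick(dendrogram, path: str | Path) -> None:
    Path(path).write_text(dendrogram.to_newick() + "\n")


def write_profile_table(profiles: Sequence, path: str | Path) -> None:
    """Write mosaicism profiles as TSV: one row per genome, per-label
    count and percentage columns over the union of observed labels."""
    labels = sorted({label for p in profiles for label in p.counts})
    rows = []
    for p in profiles:
        row: dict[str, object] = {"genome_id": p.genome_id, "total_genes": p.total_genes}
        for label in labels:
            row[f"{label}_count"] = p.counts.get(label, 0)
            row[f"{label}_pct"] = f"{count_percentage(p.counts.get(label, 0), p.total_genes):.2f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
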