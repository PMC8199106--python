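"""Ground-truthed synthetic data for every pipeline stage.

Three generators: a labeled reference database of random proteins split
into origin groups; mosaic query genomes whose genes are point-mutated
copies of donors drawn with planted group proportions (plus a planted
ORFan fraction of fresh, unrelated sequences); and phyletic 0/1 cohorts
with group-characteristic family blocks.  All generators are pure
functions of their spec including the seed, so reruns are byte-identical.

The mutator applies i.i.d. point substitutions only — no indels — so a
mutated copy keeps its donor's length, realized coverage is 100%, and the
identity threshold is the single binding retention constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .io_formats import ProteinRecord, TaxonomyEntry
from .phyletic import PhyleticMatrix

#: Default origin groups for synthetic reference databases.
DEFAULT_GROUPS = ("Bacteria", "Archaea", "DPANN", "Asgard", "Eukaryota", "CPR", "Viruses")

#: Background residue distribution: uniform over the 20 standard residues.
AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

ORFAN = "ORFan"


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


@dataclass(frozen=True)
class MosaicGenomeSpec:
    """Planted composition of one synthetic mosaic genome.

    ``origin_proportions`` maps origin labels (including ``ORFan``) to
    fractions summing to 1; ``donor_identity_target`` is the expected
    residue identity of mutated donor copies.
    """

    n_genes: int = 935
    origin_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"Bacteria": 0.54, "CPR": 0.30, ORFAN: 0.15, "Archaea": 0.01}
    )
    donor_identity_target: float = 0.9
    gene_length_range: tuple[int, int] = (100, 200)
    seed: int = 0
    genome_id: str = "synthetic_genome"

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        total = sum(self.origin_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"origin proportions must sum to 1 (got {total})")
        if not 0 < self.donor_identity_target <= 1:
            raise ConfigError("donor_identity_target must be in (0, 1]")


@dataclass(frozen=True)
class PhyleticProfileSpec:
    """Planted block structure of a synthetic phyletic cohort."""

    n_groups: int = 5
    genomes_per_group: int = 12
    n_families: int = 200
    p_within: float = 0.9
    p_background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ConfigError("need at least 2 groups")
        if self.n_families < self.n_groups:
            raise ConfigError("need at least one family per group")
        for p in (self.p_within, self.p_background):
            if not 0 <= p <= 1:
                raise ConfigError("presence probabilities must be in [0, 1]")


def generate_reference_db(
    groups: Sequence[str] = DEFAULT_GROUPS,
    sequences_per_group: int = 10,
    length_range: tuple[int, int] = (100, 200),
    seed: int = 0,
) -> tuple[list[ProteinRecord], dict[str, TaxonomyEntry]]:
    """Random labeled reference proteomes: one taxon (with its own genus)
    per origin group, `sequences_per_group` random proteins each."""
    if len(groups) < 2:
        raise ConfigError("need at least 2 origin groups")
    rng = _rng(seed)
    records: list[ProteinRecord] = []
    taxonomy: dict[str, TaxonomyEntry] = {}
    lo, hi = length_range
    for group in groups:
        taxon_id = f"tax_{group}"
        taxonomy[taxon_id] = TaxonomyEntry(
            taxon_id=taxon_id,
            genus=f"Genus{group}",
            group=group,
            lineage=("cellular", group, f"Genus{group}"),
        )
        for j in range(sequences_per_group):
            length = int(rng.integers(lo, hi + 1))
            records.append(
                ProteinRecord(
                    id=f"{group}_ref{j:03d}", sequence=random_protein(rng, length), taxon_id=taxon_id
                )
            )
    return records, taxonomy


def mutate_sequence(seq: str, identity_target: float, seed) -> str:
    """Point-substitute each residue with prob. ``1 - identity_target``,
    drawing the replacement from the 19 other standard residues."""
    if not seq:
        raise DataError("cannot mutate an empty sequence")
    if not 0 < identity_target <= 1:
        raise ConfigError("identity_target must be in (0, 1]")
    rng = _rng(seed)
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < (1.0 - identity_target)
    out = chars.copy()
    for i in np.flatnonzero(hit):
        choices = AMINO_ACIDS[AMINO_ACIDS != chars[i]]
        out[i] = rng.choice(choices)
    return "".join(out)


def largest_remainder_counts(proportions: Mapping[str, float], n: int) -> dict[str, int]:
    """Deterministic apportionment of n items to labels by largest remainder.

    Ties in remainders break toward the earlier label in mapping order, so
    truth counts are reproducible and directly testable.
    """
    labels = list(proportions)
    quotas = {l: proportions[l] * n for l in labels}
    counts = {l: int(np.floor(quotas[l])) for l in labels}
    shortfall = n - sum(counts.values())
    order = sorted(labels, key=lambda l: (-(quotas[l] - counts[l]), labels.index(l)))
    for l in order[:shortfall]:
        counts[l] += 1
    return counts


def generate_mosaic_genome(
    spec: MosaicGenomeSpec,
    db: Sequence[ProteinRecord],
    taxonomy: Mapping[str, TaxonomyEntry],
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Synthesize a mosaic genome and its gene-level truth table.

    Each non-ORFan gene is a mutated copy of a donor drawn uniformly from
    its assigned origin group; ORFan genes are fresh random sequences with
    no database relative.  Returns the gene records (taxon_id =
    ``spec.genome_id``) and a truth table with columns gene_id /
    true_origin / donor_id.
    """
    by_group: dict[str, list[ProteinRecord]] = {}
    for rec in db:
        if rec.taxon_id is None or rec.taxon_id not in taxonomy:
            raise DataError(f"database record {rec.id!r} has no resolvable taxon")
        by_group.setdefault(taxonomy[rec.taxon_id].group, []).append(rec)
    for label in spec.origin_proportions:
        if label != ORFAN and label not in by_group:
            raise ConfigError(f"origin group {label!r} absent from the reference database")

    rng = _rng(spec.seed)
    counts = largest_remainder_counts(spec.origin_proportions, spec.n_genes)
    origins = [label for label in counts for _ in range(counts[label])]
    rng.shuffle(origins)

    lo, hi = spec.gene_length_range
    records: list[ProteinRecord] = []
    truth_rows = []
    width = len(str(spec.n_genes))
    for i, origin in enumerate(origins):
        gene_id = f"gene{i + 1:0{width}d}"
        if origin == ORFAN:
            seq = random_protein(rng, int(rng.integers(lo, hi + 1)))
            donor_id = ""
        else:
            donor = by_group[origin][int(rng.integers(len(by_group[origin])))]
            seq = mutate_sequence(donor.sequence, spec.donor_identity_target, rng)
            donor_id = donor.id
        records.append(ProteinRecord(id=gene_id, sequence=seq, taxon_id=spec.genome_id))
        truth_rows.append({"gene_id": gene_id, "true_origin": origin, "donor_id": donor_id})
    return records, pd.DataFrame(truth_rows)


def generate_phyletic_cohort(
    spec: PhyleticProfileSpec,
) -> tuple[PhyleticMatrix, dict[str, str]]:
    """Block-structured 0/1 cohort: families are split into one
    characteristic block per group; presence is Bernoulli(p_within) in a
    genome's own block and Bernoulli(p_background) elsewhere."""
    rng = _rng(spec.seed)
    family_ids = [f"fam{i:04d}" for i in range(spec.n_families)]
    blocks = np.array_split(np.arange(spec.n_families), spec.n_groups)
    genome_ids: list[str] = []
    truth: dict[str, str] = {}
    rows = np.empty((spec.n_groups * spec.genomes_per_group, spec.n_families), dtype=np.int8)
    r = 0
    for g in range(spec.n_groups):
        group = f"group{g + 1}"
        own = np.zeros(spec.n_families, dtype=bool)
        own[blocks[g]] = True
        for j in range(spec.genomes_per_group):
            gid = f"{group}_genome{j:02d}"
            genome_ids.append(gid)
            truth[gid] = group
            p = np.where(own, spec.p_within, spec.p_background)
            rows[r] = (rng.random(spec.n_families) < p).astype(np.int8)
            r += 1
    df = pd.DataFrame(rows, index=genome_ids, columns=family_ids)
    return PhyleticMatrix(data=df), truth
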