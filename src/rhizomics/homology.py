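"""Scored local-alignment search of query proteins against a labeled reference.

The built-in aligner is affine-gap Smith-Waterman under BLOSUM62 with the
conventional gap open 11 / extend 1 penalties (a gap of length L costs
``open + L * extend``).  E-values follow the Karlin-Altschul form
``E = K * m * n * exp(-lambda * S)`` with published gapped-BLOSUM62
constants, so the standard e-value threshold is applicable to built-in
hits; externally computed tabular hits bypass the estimate entirely and
are interchangeable downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import ConfigError, DataError
from .io_formats import HitRecord, ProteinRecord

__all__ = [
    "SubstitutionMatrix",
    "AlignmentResult",
    "SearchThresholds",
    "RHIZOME_THRESHOLDS",
    "PHYLETIC_THRESHOLDS",
    "MARKER_THRESHOLDS",
    "blosum62",
    "local_align",
    "estimate_evalue",
    "bitscore",
    "search_database",
    "attach_coverage",
    "passes_thresholds",
]

#: Published gapped Karlin-Altschul parameters for BLOSUM62 (open 11 / extend 1).
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric residue-pair score table covering the 20 residues plus X."""

    name: str
    array: substitution_matrices.Array

    def score(self, a: str, b: str) -> int:
        return int(self.array[a, b])


def blosum62(x_score: int = 0) -> SubstitutionMatrix:
    """BLOSUM62 with the ambiguity residue X scoring `x_score` against everything."""
    arr = substitution_matrices.load("BLOSUM62").copy()
    for res in arr.alphabet:
        arr["X", res] = x_score
        arr[res, "X"] = x_score
    return SubstitutionMatrix(name="BLOSUM62", array=arr)


_DEFAULT_MATRIX: SubstitutionMatrix | None = None


def _default_matrix() -> SubstitutionMatrix:
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_MATRIX = blosum62()
    return _DEFAULT_MATRIX


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one local alignment, in hit-table semantics.

    Identity is computed over alignment columns including gap columns;
    coverage is ``100 * aligned query span / query length``.
    """

    query_id: str
    subject_id: str
    score: int
    identity_pct: float
    alignment_length: int
    query_cov_pct: float
    evalue: float
    bitscore: float
    subject_taxon_id: str | None = None


@dataclass(frozen=True)
class SearchThresholds:
    """Hit-retention bounds, applied inclusively.

    ``None`` disables a bound.  The three named presets bundle the
    conventional threshold sets: 20% identity / 30% query coverage /
    e-value 0.001 for mosaicism attribution, 30% identity / e-value 0.001
    for ortholog (family-presence) detection, and 20% identity / 70 aa
    alignment length / e-value 0.001 for conserved-marker retrieval.
    """

    min_identity_pct: float = 20.0
    min_query_cov_pct: float = 30.0
    max_evalue: float | None = 1e-3
    min_alignment_length: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.min_identity_pct <= 100:
            raise ConfigError("min_identity_pct must be in [0, 100]")
        if not 0 <= self.min_query_cov_pct <= 100:
            raise ConfigError("min_query_cov_pct must be in [0, 100]")
        if self.max_evalue is not None and not math.isfinite(self.max_evalue):
            raise ConfigError("max_evalue must be finite (or None)")


RHIZOME_THRESHOLDS = SearchThresholds(20.0, 30.0, 1e-3, None)
PHYLETIC_THRESHOLDS = SearchThresholds(30.0, 0.0, 1e-3, None)
MARKER_THRESHOLDS = SearchThresholds(20.0, 0.0, 1e-3, 70)


def passes_thresholds(result: AlignmentResult, thresholds: SearchThresholds) -> bool:
    if result.identity_pct < thresholds.min_identity_pct:
        return False
    if result.query_cov_pct < thresholds.min_query_cov_pct:
        return False
    if thresholds.max_evalue is not None and result.evalue > thresholds.max_evalue:
        return False
    if (
        thresholds.min_alignment_length is not None
        and result.alignment_length < thresholds.min_alignment_length
    ):
        return False
    return True


def estimate_evalue(
    score: float,
    query_len: int,
    db_residues: int,
    lam: float = DEFAULT_LAMBDA,
    k: float = DEFAULT_K,
) -> float:
    """Karlin-Altschul expect value ``E = K * m * n * exp(-lambda * S)``."""
    if lam <= 0 or k <= 0:
        raise ConfigError("Karlin-Altschul parameters lambda and K must be positive")
    if query_len < 1 or db_residues < 1:
        raise DataError("sequence lengths must be >= 1")
    if score < 0:
        raise DataError("alignment score must be >= 0")
    return k * query_len * db_residues * math.exp(-lam * score)


def bitscore(score: float, lam: float = DEFAULT_LAMBDA, k: float = DEFAULT_K) -> float:
    """Normalised score ``(lambda * S - ln K) / ln 2``."""
    if lam <= 0 or k <= 0:
        raise ConfigError("Karlin-Altschul parameters lambda and K must be positive")
    return (lam * score - math.log(k)) / math.log(2)


def _make_aligner(matrix: SubstitutionMatrix, gap_open: float, gap_extend: float) -> PairwiseAligner:
    if gap_open <= 0 or gap_extend <= 0:
        raise ConfigError("gap penalties must be positive")
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix.array
    # Biopython charges open_gap_score on the first gapped residue, so the
    # blast-style "open + L * extend" cost maps to open+extend / extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(
    query: ProteinRecord,
    subject: ProteinRecord,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    db_residues: int | None = None,
    lam: float = DEFAULT_LAMBDA,
    k: float = DEFAULT_K,
) -> AlignmentResult:
    """Optimal affine-gap Smith-Waterman alignment of `query` vs `subject`.

    ``db_residues`` sets the search-space size used for the e-value; it
    defaults to the subject length for a lone pairwise comparison.
    """
    if len(query) == 0 or len(subject) == 0:
        raise DataError("cannot align empty sequences")
    matrix = matrix or _default_matrix()
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    return _traceback_result(aligner, query, subject, db_residues or len(subject), lam, k)


def _traceback_result(
    aligner: PairwiseAligner,
    query: ProteinRecord,
    subject: ProteinRecord,
    db_residues: int,
    lam: float,
    k: float,
) -> AlignmentResult:
    try:
        best = aligner.align(query.sequence, subject.sequence)[0]
    except IndexError:
        # no residue pair scores positive: the optimal local alignment is
        # empty (score 0); report a zero-width result that fails any
        # meaningful threshold set
        return AlignmentResult(
            query_id=query.id,
            subject_id=subject.id,
            score=0,
            identity_pct=0.0,
            alignment_length=0,
            query_cov_pct=0.0,
            evalue=estimate_evalue(0, len(query), db_residues, lam, k),
            bitscore=bitscore(0, lam, k),
            subject_taxon_id=subject.taxon_id,
        )
    counts = best.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    score = int(round(best.score))
    qcoords = best.coordinates[0]
    span = int(qcoords[-1] - qcoords[0])
    return AlignmentResult(
        query_id=query.id,
        subject_id=subject.id,
        score=score,
        identity_pct=100.0 * counts.identities / aln_len,
        alignment_length=int(aln_len),
        query_cov_pct=100.0 * span / len(query),
        evalue=estimate_evalue(score, len(query), db_residues, lam, k),
        bitscore=bitscore(score, lam, k),
        subject_taxon_id=subject.taxon_id,
    )


def hit_sort_key(result: AlignmentResult):
    """Deterministic hit ordering: bitscore desc, e-value asc, identity
    desc, then lexicographic subject id."""
    return (-result.bitscore, result.evalue, -result.identity_pct, result.subject_id)


def search_database(
    query: ProteinRecord,
    db: Sequence[ProteinRecord],
    thresholds: SearchThresholds = RHIZOME_THRESHOLDS,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    lam: float = DEFAULT_LAMBDA,
    k: float = DEFAULT_K,
) -> list[AlignmentResult]:
    """Align `query` against every database sequence and keep passing hits.

    The e-value is computed against the total residue count of the
    database.  Because E is strictly decreasing in score, subjects whose
    optimal score already falls below the e-value cutoff are skipped
    after a score-only pass, which is result-identical to aligning and
    filtering every pair.  Output order is deterministic
    (:func:`hit_sort_key`) and independent of database order.
    """
    if not db:
        raise DataError("reference database is empty")
    matrix = matrix or _default_matrix()
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    n_residues = sum(len(rec) for rec in db)
    if thresholds.max_evalue is not None and thresholds.max_evalue > 0:
        # smallest score with E <= max_evalue
        min_score = math.log(k * len(query) * n_residues / thresholds.max_evalue) / lam
    else:
        min_score = 0.0
    results: list[AlignmentResult] = []
    for subject in db:
        if len(subject) == 0:
            raise DataError(f"database sequence {subject.id!r} is empty")
        if aligner.score(query.sequence, subject.sequence) < min_score:
            continue
        result = _traceback_result(aligner, query, subject, n_residues, lam, k)
        if passes_thresholds(result, thresholds):
            results.append(result)
    results.sort(key=hit_sort_key)
    return results


def attach_coverage(
    hits: Iterable[HitRecord],
    query_lengths: Mapping[str, int],
    subject_taxa: Mapping[str, str] | None = None,
) -> list[AlignmentResult]:
    """Lift externally computed tabular hits into alignment results.

    Tabular hit files carry no coverage, so it is reconstructed as
    ``100 * (qend - qstart + 1) / query_length`` (coordinates 1-based
    inclusive).  The integer score slot is filled from the rounded
    bitscore — external tools do not report the raw score.
    ``subject_taxa`` optionally maps subject ids to taxon ids so the
    results can feed self-taxon exclusion.
    """
    results: list[AlignmentResult] = []
    for hit in hits:
        if hit.query_id not in query_lengths:
            raise DataError(f"no query length known for {hit.query_id!r}")
        if hit.qend < hit.qstart:
            raise DataError(f"hit {hit.query_id}/{hit.subject_id}: qend < qstart")
        qlen = query_lengths[hit.query_id]
        results.append(
            AlignmentResult(
                query_id=hit.query_id,
                subject_id=hit.subject_id,
                score=int(round(hit.bitscore)),
                identity_pct=hit.identity_pct,
                alignment_length=hit.alignment_length,
                query_cov_pct=100.0 * (hit.qend - hit.qstart + 1) / qlen,
                evalue=hit.evalue,
                bitscore=hit.bitscore,
                subject_taxon_id=None if subject_taxa is None else subject_taxa.get(hit.subject_id),
            )
        )
    return results
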