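"""Bundled pairwise protein aligner and exhaustive all-vs-all search.

The pipeline ships its own optimal local aligner (affine-gap Smith-Waterman
over BLOSUM62) plus Karlin-Altschul score statistics, so a study of a few
small proteomes runs with no external search engine.  The gapped defaults
lambda = 0.267, K = 0.041 for BLOSUM62 with gap existence 11 / extension 1
reproduce the familiar bit-score and e-value scales:

    bitscore = (lambda * raw - ln K) / ln 2
    E        = K * m * n * exp(-lambda * raw)

with m the query length and n the total residue count of the subject set.
There is no heuristic seeding: every query-subject pair is aligned, which is
exactly right for proteome-scale inputs and deliberately wrong for nr-scale
databases (import an external hit table instead).

Alignment length counts gapped columns, so ``pident`` uses the gapped
length and ``length * pident / 100`` equals the number of identical columns
-- the convention of the 12-column tabular hit format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from biotite.sequence.align import SubstitutionMatrix

from . import _kernels
from .sequence_io import ProteinRecord, SimilarityHit

#: Integer coding used by the alignment kernels.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_CODE = {aa: i for i, aa in enumerate(ALPHABET)}


def _blosum62() -> np.ndarray:
    """BLOSUM62 over :data:`ALPHABET`, taken from biotite's standard table."""
    std = SubstitutionMatrix.std_protein_matrix()
    letters = [str(s) for s in std.get_alphabet1()]
    idx = [letters.index(aa) for aa in ALPHABET]
    table = std.score_matrix()[np.ix_(idx, idx)]
    return np.ascontiguousarray(table, dtype=np.int64)


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap costs and Karlin-Altschul constants.

    A gap of length L costs ``gap_open + L * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    matrix: np.ndarray = field(default_factory=_blosum62)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k_const: float = 0.041

    def __post_init__(self) -> None:
        self.matrix = np.ascontiguousarray(self.matrix, dtype=np.int64)
        if self.matrix.shape != (len(ALPHABET), len(ALPHABET)):
            raise ValueError("matrix must cover the 21-letter protein alphabet")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.lam <= 0 or self.k_const <= 0:
            raise ValueError("lambda and K must be positive")


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class AlignmentResult:
    """One optimal local alignment; coordinates 1-based inclusive."""

    score: int
    bitscore: float
    length: int
    identical: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    #: per-column (query_index, subject_index) pairs, 0-based, None for a gap
    columns: list[tuple[int | None, int | None]]

    @property
    def pident(self) -> float:
        return 100.0 * self.identical / self.length


def encode(sequence: str) -> np.ndarray:
    """Encode a protein string for the kernels; unknown residues map to X."""
    x = _CODE["X"]
    return np.fromiter(
        (_CODE.get(c, x) for c in sequence.upper()), dtype=np.int64, count=len(sequence)
    )


def bit_score(raw_score: float, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Normalised (bit) score: (lambda * raw - ln K) / ln 2."""
    return (scheme.lam * raw_score - math.log(scheme.k_const)) / math.log(2.0)


def evalue(
    raw_score: float,
    query_len: int,
    db_len: int,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> float:
    """Expected number of chance alignments scoring >= raw: K * m * n * e^(-lambda*raw)."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be positive")
    return scheme.k_const * query_len * db_len * math.exp(-scheme.lam * raw_score)


def smith_waterman(
    a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> AlignmentResult:
    """Optimal affine-gap local alignment of two protein sequences.

    Traceback is deterministic: ties resolve diagonal > gap-in-subject >
    gap-in-query, anchored at the first maximal cell in row-major order.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    (
        score,
        qstart,
        qend,
        sstart,
        send,
        length,
        identical,
        mismatch,
        gapopen,
        qcols,
        scols,
    ) = _kernels.sw_traceback(
        encode(a), encode(b), scheme.matrix, scheme.gap_open, scheme.gap_extend
    )
    columns = [
        (None if qi < 0 else int(qi), None if sj < 0 else int(sj))
        for qi, sj in zip(qcols, scols)
    ]
    return AlignmentResult(
        score=score,
        bitscore=bit_score(score, scheme),
        length=length,
        identical=identical,
        mismatch=mismatch,
        gapopen=gapopen,
        qstart=qstart,
        qend=qend,
        sstart=sstart,
        send=send,
        columns=columns,
    )


def _pack(records: list[ProteinRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    codes = [encode(r.sequence) for r in records]
    lens = np.array([len(c) for c in codes], dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(lens)[:-1]]).astype(np.int64)
    flat = np.concatenate(codes) if codes else np.empty(0, np.int8)
    return flat, starts, lens


def _hit_from_alignment(
    query: ProteinRecord,
    subject: ProteinRecord,
    aln: AlignmentResult,
    ev: float,
) -> SimilarityHit:
    return SimilarityHit(
        query_id=query.id,
        subject_id=subject.id,
        pident=aln.pident,
        length=aln.length,
        mismatch=aln.mismatch,
        gapopen=aln.gapopen,
        qstart=aln.qstart,
        qend=aln.qend,
        sstart=aln.sstart,
        send=aln.send,
        evalue=ev,
        bitscore=bit_score(aln.score),
    )


def search(
    queries: list[ProteinRecord],
    subjects: list[ProteinRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    max_evalue: float = 1e-5,
) -> list[SimilarityHit]:
    """Exhaustive search of every query against every subject.

    Each query-subject pair is aligned once (score-only pass); pairs whose
    e-value passes ``max_evalue`` get a full traceback to populate the hit
    fields.  Hits are grouped per query in input order and sorted within a
    query by bitscore descending, e-value ascending, subject id ascending.
    The database length entering the e-value is the total residue count of
    ``subjects``.
    """
    if not queries or not subjects:
        raise ValueError("queries and subjects must be non-empty")
    flat, starts, lens = _pack(subjects)
    db_len = int(lens.sum())
    out: list[SimilarityHit] = []
    for query in queries:
        q = encode(query.sequence)
        scores = _kernels.sw_score_many(
            q, flat, starts, lens, scheme.matrix, scheme.gap_open, scheme.gap_extend
        )
        hits: list[SimilarityHit] = []
        for t, raw in enumerate(scores):
            ev = evalue(int(raw), len(query.sequence), db_len, scheme)
            if ev > max_evalue:
                continue
            aln = smith_waterman(query.sequence, subjects[t].sequence, scheme)
            hits.append(_hit_from_alignment(query, subjects[t], aln, ev))
        hits.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
        out.extend(hits)
    return out


def search_pair_bidirectional(
    genome_a: list[ProteinRecord],
    genome_b: list[ProteinRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    max_evalue: float = 1e-5,
) -> tuple[list[SimilarityHit], list[SimilarityHit]]:
    """Both directed searches of a genome pair from one set of alignments.

    Local-alignment scores are symmetric, so the score matrix is computed
    once; the two directions differ only in the database length entering the
    e-value and in the hit orientation.  Returns (hits A->B, hits B->A) with
    the same per-query ordering contract as :func:`search`.
    """
    if not genome_a or not genome_b:
        raise ValueError("both proteomes must be non-empty")
    flat_b, starts_b, lens_b = _pack(genome_b)
    db_b = int(lens_b.sum())
    db_a = sum(len(r.sequence) for r in genome_a)
    ab: list[SimilarityHit] = []
    ba: list[SimilarityHit] = []
    cut = max_evalue
    for rec_a in genome_a:
        q = encode(rec_a.sequence)
        scores = _kernels.sw_score_many(
            q, flat_b, starts_b, lens_b, scheme.matrix, scheme.gap_open, scheme.gap_extend
        )
        for t, raw in enumerate(scores):
            rec_b = genome_b[t]
            ev_ab = evalue(int(raw), len(rec_a.sequence), db_b, scheme)
            ev_ba = evalue(int(raw), len(rec_b.sequence), db_a, scheme)
            if ev_ab > cut and ev_ba > cut:
                continue
            aln = smith_waterman(rec_a.sequence, rec_b.sequence, scheme)
            if ev_ab <= cut:
                ab.append(_hit_from_alignment(rec_a, rec_b, aln, ev_ab))
            if ev_ba <= cut:
                ba.append(
                    SimilarityHit(
                        query_id=rec_b.id,
                        subject_id=rec_a.id,
                        pident=aln.pident,
                        length=aln.length,
                        mismatch=aln.mismatch,
                        gapopen=aln.gapopen,
                        qstart=aln.sstart,
                        qend=aln.send,
                        sstart=aln.qstart,
                        send=aln.qend,
                        evalue=ev_ba,
                        bitscore=aln.bitscore,
                    )
                )
    key = lambda h: (-h.bitscore, h.evalue, h.subject_id)
    order_a = {r.id: i for i, r in enumerate(genome_a)}
    order_b = {r.id: i for i, r in enumerate(genome_b)}
    ab.sort(key=lambda h: (order_a[h.query_id],) + key(h))
    ba.sort(key=lambda h: (order_b[h.query_id],) + key(h))
    return ab, ba
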