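"""Pairwise alignment, isoform clustering and translated (six-frame) search.

Global and local protein alignments use BLOSUM62 with BLAST-style affine gap
costs (a gap of length L costs open + L*extend; defaults 11/1). Identity is
matches divided by full alignment length including gap columns — a
conservative, common convention — and similarity additionally counts columns
whose substitution score is positive ("positives").

The translated search aligns a protein query locally against all six frame
translations of every transcript, which at desk scale replaces seeded
heuristic search while keeping results exact and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .orfs import Transcript, revcomp

__all__ = [
    "AlignmentResult",
    "TranslatedHit",
    "ReciprocalReport",
    "align_global",
    "align_local",
    "cluster_isoforms",
    "translated_search",
    "reciprocal_check",
    "read_protein_fasta",
]


def read_protein_fasta(path) -> dict[str, str]:
    """Read a protein FASTA (e.g. a known-reference set) as an id->sequence
    mapping, preserving file order and rejecting duplicate ids."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        out[rec.id] = seq
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one pairwise alignment."""

    score: float
    aligned_a: str
    aligned_b: str
    identity: float
    similarity: float
    query_coverage: float
    query_span: tuple[int, int] | None = None  # 1-based inclusive on sequence a
    subject_span: tuple[int, int] | None = None

    @property
    def alignment_length(self) -> int:
        return len(self.aligned_a)


@dataclass(frozen=True)
class TranslatedHit:
    """A local hit of a protein query in one reading frame of a transcript."""

    transcript_id: str
    strand: str
    frame: int
    alignment: AlignmentResult
    nt_start: int  # forward-strand 1-based inclusive subject interval
    nt_end: int
    subject_protein: str  # the matched translated segment


@dataclass(frozen=True)
class ReciprocalReport:
    query_home_id: str | None
    forward_hit_id: str | None
    back_hit_id: str | None
    reciprocal: bool
    detail: str = ""


def _make_aligner(
    mode: str,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix if matrix is not None else _BLOSUM62
    # BLAST convention: a gap of length L costs gap_open + gap_extend * L
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _column_stats(aligned_a: str, aligned_b: str, matrix) -> tuple[float, float]:
    """(identity, similarity) over all alignment columns, gaps in denominator."""
    alen = len(aligned_a)
    if alen == 0:
        return 0.0, 0.0
    matches = positives = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            continue
        if x == y:
            matches += 1
            positives += 1
        elif matrix[x, y] > 0:
            positives += 1
    return matches / alen, positives / alen


def _check_residues(seq: str, matrix) -> None:
    alphabet = set(str(matrix.alphabet))
    bad = sorted(set(seq) - alphabet)
    if bad:
        raise ValueError(f"residues {bad} not present in the substitution matrix")


def _result_from_alignment(aln, query: str, matrix) -> AlignmentResult:
    a_str = str(aln[0])
    b_str = str(aln[1])
    identity, similarity = _column_stats(a_str, b_str, matrix)
    blocks_a = aln.aligned[0]
    blocks_b = aln.aligned[1]
    if len(blocks_a):
        qspan = (int(blocks_a[0][0]) + 1, int(blocks_a[-1][1]))
        sspan = (int(blocks_b[0][0]) + 1, int(blocks_b[-1][1]))
        qcov = (qspan[1] - qspan[0] + 1) / len(query)
    else:
        qspan = sspan = None
        qcov = 0.0
    return AlignmentResult(
        score=float(aln.score),
        aligned_a=a_str,
        aligned_b=b_str,
        identity=identity,
        similarity=similarity,
        query_coverage=qcov,
        query_span=qspan,
        subject_span=sspan,
    )


def align_global(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal global (Needleman–Wunsch, affine gaps) alignment of two proteins."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    matrix = matrix if matrix is not None else _BLOSUM62
    _check_residues(a, matrix)
    _check_residues(b, matrix)
    aligner = _make_aligner("global", matrix, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    return _result_from_alignment(aln, a, matrix)


def align_local(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal local (Smith–Waterman, affine gaps) alignment; score >= 0.

    ``query_coverage`` is the aligned span on ``a`` divided by len(a). When no
    residue pair scores positive the result is the empty alignment, score 0.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    matrix = matrix if matrix is not None else _BLOSUM62
    _check_residues(a, matrix)
    _check_residues(b, matrix)
    aligner = _make_aligner("local", matrix, gap_open, gap_extend)
    alignments = aligner.align(a, b)
    if len(alignments) == 0 or alignments.score <= 0:
        return AlignmentResult(0.0, "", "", 0.0, 0.0, 0.0)
    return _result_from_alignment(alignments[0], a, matrix)


def cluster_isoforms(
    proteins: dict[str, str] | Sequence[tuple[str, str]],
    identity_threshold: float = 0.935,
    **align_kwargs,
) -> list[set[str]]:
    """Single-linkage grouping on pairwise global identity >= threshold.

    Returns groups as sets of ids, sorted by (descending size, lexicographic
    smallest member).
    """
    items = list(proteins.items()) if isinstance(proteins, dict) else list(proteins)
    if not items:
        raise ValueError("at least one protein is required")
    ids = [i for i, _ in items]
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            res = align_global(items[i][1], items[j][1], **align_kwargs)
            if res.identity >= identity_threshold:
                parent[find(ids[i])] = find(ids[j])
    groups: dict[str, set[str]] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=lambda g: (-len(g), min(g)))


def translated_search(
    query_protein: str,
    transcripts: Iterable[Transcript],
    min_identity: float | None = None,
    min_score: float = 0.0,
    **align_kwargs,
) -> list[TranslatedHit]:
    """Local alignment of a protein query against all six frames of every
    transcript (TBLASTN-style, exhaustive rather than seeded).

    Hits are sorted by descending score; ``min_identity`` (e.g. 0.35) filters
    on alignment identity when given.
    """
    hits: list[TranslatedHit] = []
    for tr in transcripts:
        L = len(tr.sequence)
        for strand in "+-":
            seq = tr.sequence if strand == "+" else revcomp(tr.sequence)
            for frame in (1, 2, 3):
                coding = seq[frame - 1 :]
                coding = coding[: len(coding) - len(coding) % 3]
                if len(coding) < 3:
                    continue
                protein = str(Seq(coding).translate())
                if not protein:
                    continue
                res = align_local(query_protein, protein, **align_kwargs)
                if res.score <= max(min_score, 0.0) or res.subject_span is None:
                    continue
                if min_identity is not None and res.identity < min_identity:
                    continue
                aa_s, aa_e = res.subject_span  # 1-based on frame translation
                s_start = (frame - 1) + 3 * (aa_s - 1) + 1
                s_end = (frame - 1) + 3 * aa_e
                if strand == "+":
                    nt_start, nt_end = s_start, s_end
                else:
                    nt_start, nt_end = L - s_end + 1, L - s_start + 1
                hits.append(
                    TranslatedHit(
                        transcript_id=tr.id,
                        strand=strand,
                        frame=frame,
                        alignment=res,
                        nt_start=nt_start,
                        nt_end=nt_end,
                        subject_protein=protein[aa_s - 1 : aa_e],
                    )
                )
    hits.sort(key=lambda h: (-h.alignment.score, h.transcript_id, h.strand, h.frame))
    return hits


def reciprocal_check(
    query_protein: str,
    db_a: Sequence[Transcript],
    db_b: Sequence[Transcript],
    **align_kwargs,
) -> ReciprocalReport:
    """Reciprocal-best-hit test between two transcriptome databases.

    The query's home is its best translated hit in ``db_a``; the forward step
    takes the best hit in ``db_b``; the matched subject segment is then
    searched back in ``db_a``. The round trip is reciprocal when it returns
    the home transcript.
    """
    home_hits = translated_search(query_protein, db_a, **align_kwargs)
    home_id = home_hits[0].transcript_id if home_hits else None
    fwd = translated_search(query_protein, db_b, **align_kwargs)
    if not fwd:
        return ReciprocalReport(home_id, None, None, False, "no hit in db_b")
    fwd_hit = fwd[0]
    back = translated_search(fwd_hit.subject_protein, db_a, **align_kwargs)
    if not back:
        return ReciprocalReport(
            home_id, fwd_hit.transcript_id, None, False, "no back-hit in db_a"
        )
    back_id = back[0].transcript_id
    ok = home_id is not None and back_id == home_id
    detail = "" if ok else f"back search returned {back_id!r} instead of {home_id!r}"
    return ReciprocalReport(home_id, fwd_hit.transcript_id, back_id, ok, detail)
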