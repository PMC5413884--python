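"""In-silico tryptic digestion, peptide-to-ORF matching and sequence coverage.

This is the computational core of the discovery procedure: LC-MS/MS peptide
identifications (consumed here as plain peptide lists — spectral scoring is
upstream of this package's boundary) are located by exact substring matching
in six-frame-translated ORFs, and per-ORF sequence coverage is the fraction of
residues inside the merged union of matched intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from pyteomics import parser as _pt_parser

from .orfs import OrfRecord

__all__ = [
    "PeptideEvidence",
    "PeptideFragment",
    "CandidateMatch",
    "tryptic_digest",
    "match_peptides",
    "coverage",
    "merge_intervals",
    "read_evidence",
    "write_evidence",
    "candidate_table",
]

#: trypsin cleaves C-terminal to K/R except when the next residue is proline
TRYPSIN_RULE = r"[KR](?!P)"

#: peptides shorter than this are treated as unmatchable noise by default
MIN_PEPTIDE_LENGTH = 5


@dataclass(frozen=True)
class PeptideEvidence:
    """One identified peptide (MS instruments cannot resolve I from L)."""

    sequence: str
    source: str = ""
    weight: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - set("ACDEFGHIKLMNPQRSTVWY")
        if bad:
            raise ValueError(
                f"peptide {self.sequence!r} contains non-standard residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class PeptideFragment:
    """A digestion product with its 1-based inclusive interval on the parent."""

    sequence: str
    start: int
    end: int
    missed: int = 0


@dataclass
class CandidateMatch:
    """An ORF together with its matched peptide evidence."""

    orf: OrfRecord
    matched_intervals: list[tuple[int, int]] = field(default_factory=list)
    matched_peptides: list[str] = field(default_factory=list)

    @property
    def distinct_peptides(self) -> int:
        return len(set(self.matched_peptides))

    @property
    def coverage(self) -> float:
        return coverage(self.matched_intervals, len(self.orf.protein))


def tryptic_digest(protein: str, missed_cleavages: int = 0) -> list[PeptideFragment]:
    """Tryptic fragments of ``protein`` with their intervals.

    Cleavage occurs after K or R unless followed by P; fragments with up to
    ``missed_cleavages`` internal uncleaved sites are included. Fragments are
    returned sorted by (start, end).
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if not protein:
        return []
    frags = []
    for start0, pep in _pt_parser.icleave(
        protein, TRYPSIN_RULE, missed_cleavages=missed_cleavages, min_length=None
    ):
        missed = sum(
            1
            for i in range(len(pep) - 1)
            if pep[i] in "KR" and pep[i + 1] != "P"
        )
        frags.append(
            PeptideFragment(sequence=pep, start=start0 + 1, end=start0 + len(pep), missed=missed)
        )
    frags.sort(key=lambda f: (f.start, f.end))
    return frags


def _il_collapse(seq: str) -> str:
    return seq.replace("I", "L")


def _find_all(needle: str, haystack: str) -> list[int]:
    """All (possibly overlapping) 0-based start positions of needle in haystack."""
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def match_peptides(
    evidence: Sequence[PeptideEvidence | str],
    orfs: Sequence[OrfRecord],
    min_distinct: int = 2,
    il_equivalent: bool = True,
    min_peptide_length: int = MIN_PEPTIDE_LENGTH,
) -> list[CandidateMatch]:
    """Locate evidence peptides in ORF proteins by exact substring matching.

    Isobaric I/L are equated by default. Every occurrence of every peptide is
    recorded, a peptide matching several ORFs is credited to all of them, and
    ORFs with at least ``min_distinct`` distinct peptide sequences are returned
    as candidates (mirroring the min-two-peptides identification criterion).
    """
    peps: list[PeptideEvidence] = [
        p if isinstance(p, PeptideEvidence) else PeptideEvidence(p) for p in evidence
    ]
    peps = [p for p in peps if len(p.sequence) >= min_peptide_length]
    matches: list[CandidateMatch] = []
    for orf in orfs:
        hay = _il_collapse(orf.protein) if il_equivalent else orf.protein
        cm = CandidateMatch(orf=orf)
        for p in peps:
            needle = _il_collapse(p.sequence) if il_equivalent else p.sequence
            for i in _find_all(needle, hay):
                cm.matched_intervals.append((i + 1, i + len(needle)))
                cm.matched_peptides.append(p.sequence)
        if cm.distinct_peptides >= min_distinct:
            matches.append(cm)
    return matches


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 1-based inclusive intervals into a disjoint sorted union."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if e < s:
            raise ValueError(f"invalid interval ({s}, {e})")
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def coverage(intervals: Iterable[tuple[int, int]], protein_length: int) -> float:
    """Fraction of residues inside the merged union of matched intervals."""
    if protein_length <= 0:
        raise ValueError("protein_length must be positive")
    merged = merge_intervals(intervals)
    if merged and (merged[0][0] < 1 or merged[-1][1] > protein_length):
        raise ValueError("interval outside [1, protein_length]")
    covered = sum(e - s + 1 for s, e in merged)
    return covered / protein_length


def read_evidence(path: str | Path) -> list[PeptideEvidence]:
    """Read peptide evidence: one peptide per line, or TSV with a first column
    of peptides (header line starting with 'peptide' is skipped)."""
    peps: list[PeptideEvidence] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in ("peptide", "sequence"):
                continue
            source = fields[1] if len(fields) > 1 else ""
            peps.append(PeptideEvidence(sequence=fields[0], source=source))
    return peps


def write_evidence(peptides: Sequence[PeptideEvidence], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tsource\n")
        for p in peptides:
            fh.write(f"{p.sequence}\t{p.source}\n")


def candidate_table(matches: Sequence[CandidateMatch]):
    """Candidate report as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for m in matches:
        merged = merge_intervals(m.matched_intervals)
        rows.append(
            {
                "orf_id": m.orf.orf_id,
                "transcript_id": m.orf.transcript_id,
                "distinct_peptides": m.distinct_peptides,
                "coverage_pct": round(100 * m.coverage, 1),
                "intervals": ";".join(f"{s}-{e}" for s, e in merged),
            }
        )
    return pd.DataFrame(rows)
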