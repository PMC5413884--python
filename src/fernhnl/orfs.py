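"""Transcriptome handling: FASTA input, six-frame translation and ORF extraction.

Transcriptome contigs/isotigs are read as :class:`Transcript` records, scanned
in all six reading frames for ATG-initiated open reading frames, and each ORF
is reported with forward-strand coordinates and an average-isotopic predicted
protein mass (the quantity compared against apparent gel-band masses).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from pyteomics import mass as _pt_mass

__all__ = [
    "Transcript",
    "OrfRecord",
    "read_fasta",
    "write_fasta",
    "translate",
    "revcomp",
    "six_frame_orfs",
    "predicted_mass",
    "orf_table",
    "WATER_MASS",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_NT_VALID = re.compile(r"^[ACGTN]*$")

#: Average mass of one water molecule (Da), added once per peptide chain.
WATER_MASS = 18.0153

# Average residue masses derived once from the pyteomics composition tables.
_RESIDUE_MASS: dict[str, float] = {
    aa: _pt_mass.calculate_mass(sequence=aa, average=True) - WATER_MASS
    for aa in AMINO_ACIDS
}


@dataclass(frozen=True)
class Transcript:
    """A nucleotide contig/isotig in canonical uppercase form."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")
        if not _NT_VALID.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(
                f"transcript {self.id!r} contains invalid characters {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfRecord:
    """An ATG-initiated open reading frame.

    Coordinates are 1-based inclusive on the forward strand; ``nt_end``
    includes the stop codon when one is present (``partial`` False). The
    protein never contains the stop symbol.
    """

    transcript_id: str
    strand: str  # '+' or '-'
    frame: int  # 1..3 on the reported strand
    nt_start: int
    nt_end: int
    protein: str
    predicted_mass: float
    partial: bool = False  # True when the ORF runs off the 3' end (no stop)

    @property
    def length_aa(self) -> int:
        return len(self.protein)

    @property
    def orf_id(self) -> str:
        return f"{self.transcript_id}|{self.strand}{self.frame}:{self.nt_start}-{self.nt_end}"


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read a FASTA file into transcripts, preserving order.

    The identifier is the token up to the first whitespace; the remainder of
    the header line is kept as ``description``. Raises on duplicate ids and
    on empty records.
    """
    transcripts: list[Transcript] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        transcripts.append(Transcript(id=rec.id, sequence=seq, description=desc))
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dupes = sorted(i for i, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"duplicate FASTA ids in {path}: {', '.join(dupes)}")
    if not transcripts:
        raise ValueError(f"no FASTA records found in {path}")
    return transcripts


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write (id, sequence) pairs as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def revcomp(nt: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return str(Seq(nt).reverse_complement())


def translate(nt: str, strand: str = "+", frame: int = 1) -> str:
    """Translate one reading frame with the standard genetic code.

    Stops are rendered as ``*``, a trailing partial codon is dropped, and any
    codon containing N translates to ``X``.
    """
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1, 2 or 3, got {frame}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    nt = nt.upper()
    if not _NT_VALID.match(nt):
        bad = sorted(set(nt) - set("ACGTN"))
        raise ValueError(f"invalid nucleotide characters {bad}")
    if strand == "-":
        nt = revcomp(nt)
    coding = nt[frame - 1 :]
    coding = coding[: len(coding) - len(coding) % 3]
    if not coding:
        return ""
    return str(Seq(coding).translate())


def predicted_mass(protein: str) -> float:
    """Average-isotopic mass (Da) of a protein: residue masses plus one water."""
    if not protein:
        raise ValueError("cannot compute the mass of an empty protein")
    try:
        total = sum(_RESIDUE_MASS[aa] for aa in protein)
    except KeyError as exc:
        raise ValueError(
            f"protein contains a residue without a defined mass: {exc.args[0]!r}"
        ) from None
    return total + WATER_MASS


def _frame_orfs(
    protein: str,
    min_len_aa: int,
    allow_x: bool,
) -> list[tuple[int, int, str, bool]]:
    """ORFs on one translated frame: (aa_start, aa_end_excl_stop, protein, partial).

    Longest-per-stop rule: the first ATG after the previous in-frame stop (or
    frame start) opens the single reported ORF for that stop.
    """
    out = []
    segment_start = 0
    n = len(protein)
    i = 0
    while i <= n:
        stop = protein.find("*", segment_start)
        if stop == -1:
            seg_end, partial = n, True
        else:
            seg_end, partial = stop, False
        m = protein.find("M", segment_start, seg_end)
        if m != -1:
            pep = protein[m:seg_end]
            if len(pep) >= min_len_aa and (allow_x or "X" not in pep):
                out.append((m, seg_end, pep, partial))
        if stop == -1:
            break
        segment_start = stop + 1
        i = segment_start
    return out


def six_frame_orfs(
    transcript: Transcript,
    min_len_aa: int = 50,
    allow_n_in_orf: bool = False,
) -> list[OrfRecord]:
    """Extract ATG-to-stop ORFs from all six reading frames.

    An ORF extends from the first ATG after the preceding in-frame stop to the
    next stop codon; ORFs reaching the transcript end without a stop are kept
    and flagged 3'-partial (transcriptome contigs truncate). Coordinates are
    reported on the forward strand, with the stop codon included in the span.
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    L = len(transcript.sequence)
    records: list[OrfRecord] = []
    for strand in "+-":
        seq = transcript.sequence if strand == "+" else revcomp(transcript.sequence)
        for frame in (1, 2, 3):
            offset = frame - 1
            coding = seq[offset:]
            coding = coding[: len(coding) - len(coding) % 3]
            if not coding:
                continue
            protein = str(Seq(coding).translate())
            for aa_start, aa_end, pep, partial in _frame_orfs(
                protein, min_len_aa, allow_n_in_orf
            ):
                # span on the strand-local sequence, stop codon included
                s_start = offset + 3 * aa_start + 1
                s_end = offset + 3 * (aa_end + (0 if partial else 1))
                if strand == "+":
                    nt_start, nt_end = s_start, s_end
                else:
                    nt_start, nt_end = L - s_end + 1, L - s_start + 1
                # X (from N codons) has no defined mass; only reachable when
                # allow_n_in_orf is set.
                mass = float("nan") if "X" in pep else predicted_mass(pep)
                records.append(
                    OrfRecord(
                        transcript_id=transcript.id,
                        strand=strand,
                        frame=frame,
                        nt_start=nt_start,
                        nt_end=nt_end,
                        protein=pep,
                        predicted_mass=mass,
                        partial=partial,
                    )
                )
    records.sort(key=lambda r: (r.nt_start, r.nt_end, r.strand, r.frame))
    return records


def orf_table(orfs: Iterable[OrfRecord]):
    """ORF collection as a pandas DataFrame (TSV-ready report form)."""
    import pandas as pd

    rows = [
        {
            "orf_id": o.orf_id,
            "transcript_id": o.transcript_id,
            "strand": o.strand,
            "frame": o.frame,
            "nt_start": o.nt_start,
            "nt_end": o.nt_end,
            "length_aa": o.length_aa,
            "mass_da": round(o.predicted_mass, 2),
            "partial": o.partial,
        }
        for o in orfs
    ]
    return pd.DataFrame(rows)
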