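"""Seeded synthetic fixtures for the whole discovery pipeline.

The generator emulates the statistical shape of a normalized fern
transcriptome study: a planted target ORF encoding a ~20 kDa protein, a few
isoenzyme variants above 93.5% identity, peptide-supported decoy ORFs that
fail exactly one exclusion filter each (wrong predicted size, signal-peptide
head, or similarity to a known reference protein), neutral decoys that pass
everything, and tryptic peptide evidence whose union covers the target at a
configurable fraction (default 0.72). Everything is deterministic for a fixed
seed, and a ground-truth table records every planted fact so downstream
stages are testable without any downloads.

Planted proteins are assembled from tryptic blocks: internal residues exclude
K/R (and P never follows a cleavage site), and every fragment is at least
five residues, so the in-silico digest of a planted protein is exactly the
block structure. This deviates from a fully uniform residue draw but makes
peptide-coverage arithmetic exact and keeps tests stable; isoenzyme variants
are point substitutions only, so identity bounds are exactly computable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import ranking
from .orfs import Transcript, predicted_mass, revcomp, write_fasta
from .peptides import (
    MIN_PEPTIDE_LENGTH,
    PeptideEvidence,
    merge_intervals,
    tryptic_digest,
    write_evidence,
)

__all__ = [
    "FixtureSpec",
    "FixtureTruth",
    "PlantedPeptide",
    "OrfLabel",
    "generate_transcriptome",
    "generate_peptide_evidence",
    "generate_kinetic_data",
    "generate_toy_structure",
    "SitePreset",
    "write_fixture",
    "MOST_FREQUENT_CODON",
]

# deterministic back-translation: one fixed (most frequent, E. coli usage)
# codon per amino acid; none is a stop, so planted coding regions are clean
MOST_FREQUENT_CODON = {
    "A": "GCG", "R": "CGC", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}

_INTERNAL_AA = "ACDEFGHILMNPQSTVWY"  # 18 residues: no K/R inside a block
_NO_P = _INTERNAL_AA.replace("P", "")


class FixtureError(ValueError):
    """Raised for infeasible fixture specifications."""


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic fixture."""

    seed: int = 0
    n_isotigs: int = 60
    target_length_aa: int = 168  # predicted mass ~20 kDa at mean residue mass
    n_isoenzymes: int = 3
    isoenzyme_max_divergence: float = 0.065  # => identity >= 93.5%
    n_evidence_orfs: int = 36
    n_pass_filters: int = 6
    target_coverage: float = 0.72
    # proportions of the *failing* decoy classes; the neutral count is fixed
    # by n_pass_filters (funnel consistency), so a neutral entry is ignored
    decoy_mix: dict = field(
        default_factory=lambda: {
            "wrong_size": 0.4,
            "signal_peptide": 0.3,
            "known_homolog": 0.3,
        }
    )
    utr_length_range: tuple[int, int] = (20, 120)
    n_references: int = 5

    def __post_init__(self) -> None:
        if not (self.n_pass_filters <= self.n_evidence_orfs <= self.n_isotigs):
            raise FixtureError(
                "require n_pass_filters <= n_evidence_orfs <= n_isotigs "
                f"(got {self.n_pass_filters}, {self.n_evidence_orfs}, {self.n_isotigs})"
            )
        if not (0 < self.target_coverage <= 1):
            raise FixtureError("target_coverage must be in (0, 1]")
        if not (0 <= self.isoenzyme_max_divergence < 0.5):
            raise FixtureError("isoenzyme_max_divergence must be in [0, 0.5)")
        if self.n_pass_filters < 1 + self.n_isoenzymes:
            raise FixtureError(
                "n_pass_filters must cover the target and all isoenzymes "
                f"(need >= {1 + self.n_isoenzymes}, got {self.n_pass_filters})"
            )
        if self.n_isoenzymes < 0 or self.n_references < 1:
            raise FixtureError("n_isoenzymes must be >= 0 and n_references >= 1")
        lo, hi = self.utr_length_range
        if lo < 3 or hi < lo:
            raise FixtureError("utr_length_range must satisfy 3 <= lo <= hi")

    @property
    def n_neutral_decoys(self) -> int:
        return self.n_pass_filters - 1 - self.n_isoenzymes

    @property
    def n_failing_decoys(self) -> int:
        return self.n_evidence_orfs - self.n_pass_filters


@dataclass(frozen=True)
class PlantedPeptide:
    sequence: str
    source_id: str  # transcript id of the source ORF
    start: int  # 1-based inclusive residue interval on the source protein
    end: int


@dataclass
class OrfLabel:
    role: str  # target | isoenzyme | wrong_size | signal_peptide | known_homolog | neutral
    is_target: bool
    has_signal_peptide: bool
    mass_class: str  # in_window | below | above
    homolog_of: str | None
    strand: str
    nt_start: int
    nt_end: int
    protein: str


@dataclass
class FixtureTruth:
    """Ground truth of one generated fixture."""

    seed: int
    target_id: str
    isoenzyme_ids: list[str]
    labels: dict[str, OrfLabel]
    planted_peptides: list[PlantedPeptide]
    known_references: dict[str, str]
    target_coverage_planned: float


def _il(seq: str) -> str:
    return seq.replace("I", "L")


def _blocks_protein(rng: np.random.Generator, length: int, head: str = "M") -> str:
    """A protein of tryptic blocks: head, then fragments of 5-22 residues each
    ending in K/R (except the last), internal residues without K/R, and no P
    right after a cleavage site."""
    if length < len(head) + 5:
        raise FixtureError(f"protein length {length} too short for construction")
    chars = list(head)
    remaining = length - len(head)
    at_fragment_start = False  # head never ends in K/R here
    while remaining > 0:
        fl = int(rng.integers(5, 23))
        if remaining - fl < 5:
            fl = remaining
        frag = []
        for i in range(fl):
            pool = _NO_P if (i == 0 and at_fragment_start) else _INTERNAL_AA
            frag.append(pool[rng.integers(len(pool))])
        if remaining - fl > 0:  # not the final fragment: terminal cleavage site
            frag[-1] = "KR"[rng.integers(2)]
        chars.extend(frag)
        remaining -= fl
        at_fragment_start = True
    return "".join(chars)


def _uniform_protein(rng: np.random.Generator, length: int) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    body = "".join(aas[i] for i in rng.integers(len(aas), size=length - 1))
    return "M" + body


def _mass_class(protein: str, criteria: ranking.ExclusionCriteria) -> str:
    m = predicted_mass(protein)
    target = criteria.target_mass_kda * 1000.0
    if abs(m - target) <= criteria.mass_tolerance * target:
        return "in_window"
    return "below" if m < target else "above"


def _signal_flagged(protein: str) -> bool:
    return ranking.signal_peptide_heuristic(protein)[0]


def _hits_reference(protein: str, references: dict[str, str],
                    criteria: ranking.ExclusionCriteria) -> bool:
    from . import homology

    for ref in references.values():
        res = homology.align_local(protein, ref)
        if (
            res.identity >= criteria.annotation_identity_cutoff
            and res.query_coverage >= criteria.annotation_coverage_cutoff
        ):
            return True
    return False


def _eligible_fragments(protein: str, forbidden_hosts: Sequence[str]):
    """Digest fragments usable as evidence: >= minimum peptide length, unique
    within the (I/L-collapsed) source protein and absent from every already
    planted protein."""
    collapsed = _il(protein)
    out = []
    for frag in tryptic_digest(protein, 0):
        if len(frag.sequence) < MIN_PEPTIDE_LENGTH:
            continue
        cseq = _il(frag.sequence)
        if collapsed.count(cseq) != 1:
            continue
        if any(cseq in _il(host) for host in forbidden_hosts):
            continue
        out.append(frag)
    return out


def _plan_coverage_subset(fragments, protein_length: int, coverage: float):
    """Choose a subset of disjoint tryptic fragments whose total length is
    within one residue of round(coverage * protein_length) (subset-sum DP,
    deterministic). Raises FixtureError naming the achievable maximum."""
    goal = int(round(coverage * protein_length))
    lengths = [len(f.sequence) for f in fragments]
    max_sum = sum(lengths)
    # dp[s] = index list of first-found subset with total s
    dp: dict[int, tuple] = {0: ()}
    for idx, ln in enumerate(lengths):
        additions = {}
        for s, subset in dp.items():
            ns = s + ln
            if ns <= max_sum and ns not in dp and ns not in additions:
                additions[ns] = subset + (idx,)
        dp.update(additions)
    best = None
    for delta in (0, -1, 1):
        if goal + delta in dp:
            best = goal + delta
            break
    if best is None:
        achievable = max(s for s in dp) / protein_length
        raise FixtureError(
            f"coverage {coverage:.3f} unattainable with tryptic fragments; "
            f"achievable maximum is {achievable:.3f}"
        )
    subset = [fragments[i] for i in dp[best]]
    if len(subset) < 2:
        raise FixtureError("coverage plan selects fewer than two peptides")
    return sorted(subset, key=lambda f: f.start)


def _backtranslate(protein: str) -> str:
    return "".join(MOST_FREQUENT_CODON[aa] for aa in protein)


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=length))


_MAX_TRIES = 200


def generate_transcriptome(spec: FixtureSpec) -> tuple[list[Transcript], FixtureTruth]:
    """Generate the synthetic transcriptome and its ground truth.

    Deterministic for a fixed spec+seed (byte-identical FASTA). The planted
    target passes all three exclusion filters, each isoenzyme differs from it
    at no more than floor(isoenzyme_max_divergence x length) positions, and
    the decoys are constructed (and verified against the actual filters) so
    that exactly ``n_pass_filters`` evidence-bearing ORFs survive.
    """
    rng = np.random.default_rng(spec.seed)
    criteria = ranking.ExclusionCriteria()

    # --- known reference proteins (the similarity-exclusion database)
    references: dict[str, str] = {}
    for i in range(spec.n_references):
        for _ in range(_MAX_TRIES):
            prot = _uniform_protein(rng, int(rng.integers(150, 201)))
            if not _signal_flagged(prot):
                break
        references[f"known_ref_{i + 1:02d}"] = prot

    # --- target protein: in the mass window, unflagged, novel, and with an
    # achievable coverage plan
    target_protein = None
    plan = None
    for _ in range(_MAX_TRIES):
        cand = _blocks_protein(rng, spec.target_length_aa)
        if _mass_class(cand, criteria) != "in_window":
            continue
        if _signal_flagged(cand):
            continue
        if _hits_reference(cand, references, criteria):
            continue
        frags = _eligible_fragments(cand, list(references.values()))
        try:
            plan = _plan_coverage_subset(frags, len(cand), spec.target_coverage)
        except FixtureError:
            continue
        target_protein = cand
        break
    if target_protein is None:
        raise FixtureError("could not construct a feasible target protein")

    planted_proteins: list[str] = [target_protein]
    evidence_plan: list[tuple[str, list]] = []  # (role_key, fragments)
    evidence_plan.append(("target", list(plan)))

    # --- isoenzymes: point substitutions only, placed inside selected target
    # peptides so the target keeps strictly more distinct evidence
    kmax = math.floor(spec.isoenzyme_max_divergence * len(target_protein))
    if spec.n_isoenzymes > 0 and kmax < 1:
        raise FixtureError("isoenzyme_max_divergence allows no substitutions")
    iso_proteins: list[str] = []
    iso_evidence: list[list] = []
    iso_mutation_counts: list[int] = []
    for i in range(spec.n_isoenzymes):
        own_n = int(rng.integers(2, 4))  # private peptides per isoenzyme
        for _ in range(_MAX_TRIES):
            k = int(rng.integers(min(own_n + 2, kmax), kmax + 1))
            # mutate strictly more selected target peptides than this variant
            # gets private peptides, so the target keeps the most evidence
            hit_count = min(len(plan), own_n + 2, k)
            hit_frags = list(rng.choice(len(plan), size=hit_count, replace=False))
            prot = list(target_protein)
            mutated_pos: set[int] = set()
            for fi in hit_frags:
                frag = plan[fi]
                # interior positions only: keep the terminal K/R and pos 0 (M)
                lo, hi = frag.start - 1, frag.end - 1
                pos_pool = [p for p in range(max(lo, 1), hi) if p not in mutated_pos]
                if not pos_pool:
                    continue
                p = int(pos_pool[rng.integers(len(pos_pool))])
                orig = prot[p]
                repl_pool = [
                    a for a in _INTERNAL_AA
                    if a != "P" and _il(a) != _il(orig)
                ]
                prot[p] = repl_pool[rng.integers(len(repl_pool))]
                mutated_pos.add(p)
            while len(mutated_pos) < k:
                p = int(rng.integers(1, len(prot)))
                if p in mutated_pos or prot[p] in "KRP":
                    continue
                orig = prot[p]
                repl_pool = [
                    a for a in _INTERNAL_AA
                    if a != "P" and _il(a) != _il(orig)
                ]
                prot[p] = repl_pool[rng.integers(len(repl_pool))]
                mutated_pos.add(p)
            iso = "".join(prot)
            if _signal_flagged(iso) or _mass_class(iso, criteria) != "in_window":
                continue
            if _hits_reference(iso, references, criteria):
                continue
            # private evidence: fragments of the isoenzyme spanning a mutation
            frags = _eligible_fragments(
                iso, [target_protein, *iso_proteins, *references.values()]
            )
            own = [
                f for f in frags
                if any(f.start - 1 <= p <= f.end - 1 for p in mutated_pos)
            ]
            if len(own) < own_n:
                continue
            pick = sorted(
                rng.choice(len(own), size=own_n, replace=False).tolist()
            )
            iso_proteins.append(iso)
            iso_evidence.append([own[j] for j in pick])
            iso_mutation_counts.append(len(mutated_pos))
            break
        else:
            raise FixtureError(f"could not construct isoenzyme {i + 1}")
    planted_proteins.extend(iso_proteins)

    # --- decoys
    mix = {k: float(v) for k, v in spec.decoy_mix.items() if k != "neutral"}
    order = ["wrong_size", "signal_peptide", "known_homolog"]
    weights = np.array([max(mix.get(k, 0.0), 0.0) for k in order], dtype=float)
    if weights.sum() <= 0:
        weights = np.ones(3)
    weights = weights / weights.sum()
    n_fail = spec.n_failing_decoys
    counts = np.floor(weights * n_fail).astype(int)
    remainders = weights * n_fail - counts
    for idx in np.argsort(-remainders):
        if counts.sum() >= n_fail:
            break
        counts[idx] += 1
    decoy_counts = dict(zip(order, counts.tolist()))

    decoys: list[tuple[str, str, str | None]] = []  # (role, protein, homolog_of)

    def _no_planted_peptides(prot: str) -> bool:
        cp = _il(prot)
        planned = [f.sequence for _, fl in evidence_plan for f in fl]
        planned += [f.sequence for fl in iso_evidence for f in fl]
        planned += [f.sequence for _, fl, _ in decoy_evidence for f in fl]
        return not any(_il(s) in cp for s in planned)

    decoy_evidence: list[tuple[str, list, str | None]] = []

    def _pick_evidence(prot: str, n: int):
        frags = _eligible_fragments(
            prot,
            planted_proteins
            + [p for _, p, _ in decoys]
            + list(references.values()),
        )
        if len(frags) < n:
            return None
        pick = sorted(rng.choice(len(frags), size=n, replace=False).tolist())
        return [frags[j] for j in pick]

    def _add_decoy(role: str, builder) -> None:
        for _ in range(_MAX_TRIES):
            prot, homolog_of = builder()
            if prot is None or not _no_planted_peptides(prot):
                continue
            ev = _pick_evidence(prot, int(rng.integers(2, 4)))
            if ev is None:
                continue
            decoys.append((role, prot, homolog_of))
            decoy_evidence.append((role, ev, homolog_of))
            return
        raise FixtureError(f"could not construct a {role} decoy")

    def _build_wrong_size():
        length = int(rng.choice([75, 90, 300, 340]))
        prot = _blocks_protein(rng, length)
        if _mass_class(prot, criteria) == "in_window" or _signal_flagged(prot):
            return None, None
        return prot, None

    def _build_signal():
        h_region = "".join("LIVF"[i] for i in rng.integers(4, size=8))
        head = "MKK" + h_region
        prot = _blocks_protein(rng, spec.target_length_aa, head=head)
        if not _signal_flagged(prot) or _mass_class(prot, criteria) != "in_window":
            return None, None
        return prot, None

    def _build_homolog():
        ref_id = list(references)[int(rng.integers(len(references)))]
        base = list(references[ref_id])
        n_mut = max(1, int(0.15 * len(base)))
        positions = rng.choice(len(base) - 1, size=n_mut, replace=False) + 1
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for p in positions:
            choices = [a for a in aas if a != base[p]]
            base[p] = choices[rng.integers(len(choices))]
        prot = "".join(base)
        if _signal_flagged(prot) or _mass_class(prot, criteria) != "in_window":
            return None, None
        if not _hits_reference(prot, references, criteria):
            return None, None
        return prot, ref_id

    def _build_neutral():
        length = int(rng.integers(150, 190))
        prot = _blocks_protein(rng, length)
        if _mass_class(prot, criteria) != "in_window" or _signal_flagged(prot):
            return None, None
        if _hits_reference(prot, references, criteria):
            return None, None
        return prot, None

    for _ in range(spec.n_neutral_decoys):
        _add_decoy("neutral", _build_neutral)
    for _ in range(decoy_counts["wrong_size"]):
        _add_decoy("wrong_size", _build_wrong_size)
    for _ in range(decoy_counts["signal_peptide"]):
        _add_decoy("signal_peptide", _build_signal)
    for _ in range(decoy_counts["known_homolog"]):
        _add_decoy("known_homolog", _build_homolog)

    # --- assemble transcripts (planted ORFs with UTR flanks, both strands)
    planted: list[tuple[str, str, str | None]] = [("target", target_protein, None)]
    planted += [("isoenzyme", p, None) for p in iso_proteins]
    planted += decoys

    entries: list[dict] = []
    lo, hi = spec.utr_length_range
    for role, prot, homolog_of in planted:
        utr5 = _random_nt(rng, int(rng.integers(lo, hi + 1)))
        utr5 = utr5[:-3] + "TAA"  # in-frame stop right before the start codon
        utr3 = _random_nt(rng, int(rng.integers(lo, hi + 1)))
        cds = _backtranslate(prot) + "TAA"
        seq = utr5 + cds + utr3
        reverse = bool(rng.integers(2))
        if reverse:
            nt_start = len(utr3) + 1
            nt_end = len(utr3) + len(cds)
            seq = revcomp(seq)
            strand = "-"
        else:
            nt_start = len(utr5) + 1
            nt_end = len(utr5) + len(cds)
            strand = "+"
        entries.append(
            {
                "role": role,
                "protein": prot,
                "homolog_of": homolog_of,
                "sequence": seq,
                "strand": strand,
                "nt_start": nt_start,
                "nt_end": nt_end,
            }
        )

    # filler transcripts carry no planted evidence
    all_evidence_seqs = [
        f.sequence for _, fl in evidence_plan for f in fl
    ] + [f.sequence for fl in iso_evidence for f in fl] + [
        f.sequence for _, fl, _ in decoy_evidence for f in fl
    ]

    def _filler_clean(seq: str) -> bool:
        from Bio.Seq import Seq as _Seq

        for s in (seq, revcomp(seq)):
            for off in range(3):
                coding = s[off:]
                coding = coding[: len(coding) - len(coding) % 3]
                if len(coding) < 3:
                    continue
                prot = _il(str(_Seq(coding).translate()))
                if any(_il(e) in prot for e in all_evidence_seqs):
                    return False
        return True

    n_filler = spec.n_isotigs - spec.n_evidence_orfs
    for _ in range(n_filler):
        for _ in range(_MAX_TRIES):
            seq = _random_nt(rng, int(rng.integers(300, 901)))
            if _filler_clean(seq):
                break
        entries.append(
            {
                "role": "filler",
                "protein": None,
                "homolog_of": None,
                "sequence": seq,
                "strand": None,
                "nt_start": None,
                "nt_end": None,
            }
        )

    # shuffle and assign isotig ids
    perm = rng.permutation(len(entries))
    transcripts: list[Transcript] = []
    labels: dict[str, OrfLabel] = {}
    target_id = ""
    isoenzyme_ids: list[str] = []
    id_by_entry: dict[int, str] = {}
    for pos, entry_idx in enumerate(perm.tolist(), start=1):
        e = entries[entry_idx]
        tid = f"isotig{pos:05d}"
        id_by_entry[entry_idx] = tid
        transcripts.append(Transcript(id=tid, sequence=e["sequence"]))
        if e["role"] == "filler":
            continue
        labels[tid] = OrfLabel(
            role=e["role"],
            is_target=e["role"] == "target",
            has_signal_peptide=e["role"] == "signal_peptide",
            mass_class=_mass_class(e["protein"], criteria),
            homolog_of=e["homolog_of"],
            strand=e["strand"],
            nt_start=e["nt_start"],
            nt_end=e["nt_end"],
            protein=e["protein"],
        )
        if e["role"] == "target":
            target_id = tid
        elif e["role"] == "isoenzyme":
            isoenzyme_ids.append(tid)

    # planted peptides with source ids (entries order: target, isos, decoys)
    planted_peptides: list[PlantedPeptide] = []
    tgt_tid = id_by_entry[0]
    for frag in evidence_plan[0][1]:
        planted_peptides.append(
            PlantedPeptide(frag.sequence, tgt_tid, frag.start, frag.end)
        )
    for i, fl in enumerate(iso_evidence):
        tid = id_by_entry[1 + i]
        for frag in fl:
            planted_peptides.append(PlantedPeptide(frag.sequence, tid, frag.start, frag.end))
    for j, (_, fl, _) in enumerate(decoy_evidence):
        tid = id_by_entry[1 + len(iso_proteins) + j]
        for frag in fl:
            planted_peptides.append(PlantedPeptide(frag.sequence, tid, frag.start, frag.end))

    planned_cov = sum(
        p.end - p.start + 1 for p in planted_peptides if p.source_id == tgt_tid
    ) / len(target_protein)

    truth = FixtureTruth(
        seed=spec.seed,
        target_id=target_id,
        isoenzyme_ids=sorted(isoenzyme_ids),
        labels=labels,
        planted_peptides=planted_peptides,
        known_references=references,
        target_coverage_planned=planned_cov,
    )
    return transcripts, truth


def generate_peptide_evidence(
    truth: FixtureTruth, spec: FixtureSpec
) -> list[PeptideEvidence]:
    """Materialise the peptide evidence list planned in the truth table.

    Validates that the union coverage of the planted target matches
    ``spec.target_coverage`` within one residue of rounding; when the spec
    requests a different coverage than was planned, the target subset is
    re-planned from the recorded target protein (raising an explicit error
    naming the achievable maximum when unattainable).
    """
    target_protein = truth.labels[truth.target_id].protein
    L = len(target_protein)
    target_peps = [p for p in truth.planted_peptides if p.source_id == truth.target_id]
    other_peps = [p for p in truth.planted_peptides if p.source_id != truth.target_id]

    union = sum(
        e - s + 1 for s, e in merge_intervals([(p.start, p.end) for p in target_peps])
    )
    if abs(union - round(spec.target_coverage * L)) > 1:
        # isoenzymes legitimately share target peptides; only non-isoform
        # proteins and the reference set are forbidden hosts
        hosts = [
            lab.protein
            for tid, lab in truth.labels.items()
            if tid != truth.target_id and lab.role != "isoenzyme" and lab.protein
        ] + list(truth.known_references.values())
        frags = _eligible_fragments(target_protein, hosts)
        subset = _plan_coverage_subset(frags, L, spec.target_coverage)
        target_peps = [
            PlantedPeptide(f.sequence, truth.target_id, f.start, f.end) for f in subset
        ]

    all_peps = target_peps + other_peps
    rng = np.random.default_rng(spec.seed + 1)
    order = rng.permutation(len(all_peps))
    return [
        PeptideEvidence(sequence=all_peps[i].sequence, source=all_peps[i].source_id)
        for i in order.tolist()
    ]


def generate_kinetic_data(
    km: float,
    vmax: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Michaelis–Menten rates with multiplicative Gaussian noise.

    rate = vmax*S/(km+S) * (1 + eps), eps ~ N(0, noise_sd). noise_sd = 0 gives
    the exact curve. Returns a pandas DataFrame (concentration_mM, rate).
    """
    import pandas as pd

    if km <= 0 or vmax <= 0:
        raise ValueError("km and vmax must be positive")
    s = np.asarray(concentrations, dtype=float)
    if np.any(s < 0):
        raise ValueError("concentrations must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    v = vmax * s / (km + s)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + rng.normal(0.0, noise_sd, size=s.shape))
    return pd.DataFrame({"concentration_mM": s, "rate": v})


@dataclass(frozen=True)
class SitePreset:
    """Distances (A) of the catalytic-residue mimics from the ligand nitrile N."""

    arg_guanidinium: float = 3.5
    asp_carboxyl: float = 2.9
    tyr_hydroxyl: float = 2.6


def generate_toy_structure(
    n_waters: int = 5,
    spacing: float = 2.8,
    site_geometry: SitePreset | None = None,
) -> str:
    """Minimal PDB text: a nitrile ligand, catalytic-residue mimics at preset
    distances, and a linear water chain of ``n_waters`` at ``spacing`` A
    starting near the bridging position."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    preset = site_geometry or SitePreset()
    lines = ["REMARK   2 RESOLUTION.    1.85 ANGSTROMS."]
    serial = 0

    def atom(record, name, resname, chain, resnum, x, y, z, element):
        nonlocal serial
        serial += 1
        lines.append(
            f"{record:<6}{serial:>5} {name:^4} {resname:>3} {chain:1}{resnum:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2}"
        )

    # ligand: a mandelonitrile-like nitrile group at the origin plus ring carbons
    atom("HETATM", "N1", "MXN", "A", 201, 0.0, 0.0, 0.0, "N")
    atom("HETATM", "C1", "MXN", "A", 201, 1.16, 0.0, 0.0, "C")
    atom("HETATM", "C2", "MXN", "A", 201, 2.62, 0.0, 0.0, "C")
    atom("HETATM", "O1", "MXN", "A", 201, 3.10, 1.30, 0.0, "O")
    # catalytic-residue mimics placed at the preset distances from N1
    atom("ATOM", "NH1", "ARG", "A", 69, -preset.arg_guanidinium, 0.0, 0.0, "N")
    atom("ATOM", "NH2", "ARG", "A", 69, -preset.arg_guanidinium - 1.0, 1.0, 0.0, "N")
    atom("ATOM", "CZ", "ARG", "A", 69, -preset.arg_guanidinium - 0.7, 0.3, 0.7, "C")
    atom("ATOM", "OD1", "ASP", "A", 85, 0.0, -preset.asp_carboxyl, 0.0, "O")
    atom("ATOM", "OD2", "ASP", "A", 85, -1.0, -preset.asp_carboxyl - 0.9, 0.0, "O")
    atom("ATOM", "CG", "ASP", "A", 85, -0.5, -preset.asp_carboxyl - 0.5, 0.9, "C")
    atom("ATOM", "OH", "TYR", "A", 101, 0.0, preset.tyr_hydroxyl, 0.0, "O")
    atom("ATOM", "CZ", "TYR", "A", 101, 0.0, preset.tyr_hydroxyl + 1.4, 0.0, "C")
    atom("ATOM", "OH", "TYR", "A", 117, 3.1, 3.9, 1.0, "O")
    # a distant residue that must stay outside a 4 A contact cutoff
    atom("ATOM", "CB", "ALA", "A", 164, 0.0, 0.0, 8.0, "C")
    # water chain: first water bridges Tyr101-OH and Arg69, then the chain
    # leaves the site along +y so each water is farther from the start
    wx, wy, wz = -1.6, 1.9, 0.0
    for i in range(n_waters):
        atom("HETATM", "O", "HOH", "A", 301 + i, wx, wy + i * spacing, wz, "O")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the complete fixture: transcriptome FASTA, peptide
    evidence, known-reference FASTA and ground-truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts, truth = generate_transcriptome(spec)
    evidence = generate_peptide_evidence(truth, spec)

    paths = {
        "transcriptome": outdir / "transcriptome.fasta",
        "evidence": outdir / "evidence.tsv",
        "references": outdir / "known_refs.fasta",
        "truth_orfs": outdir / "truth_orfs.tsv",
        "truth_peptides": outdir / "truth_peptides.tsv",
    }
    write_fasta([(t.id, t.sequence) for t in transcripts], paths["transcriptome"])
    write_evidence(evidence, paths["evidence"])
    write_fasta(truth.known_references.items(), paths["references"])
    with open(paths["truth_orfs"], "w") as fh:
        fh.write(
            "transcript_id\trole\tis_target\thas_signal_peptide\tmass_class\t"
            "homolog_of\tstrand\tnt_start\tnt_end\tprotein\n"
        )
        for tid in sorted(truth.labels):
            lab = truth.labels[tid]
            fh.write(
                f"{tid}\t{lab.role}\t{lab.is_target}\t{lab.has_signal_peptide}\t"
                f"{lab.mass_class}\t{lab.homolog_of or ''}\t{lab.strand}\t"
                f"{lab.nt_start}\t{lab.nt_end}\t{lab.protein}\n"
            )
    with open(paths["truth_peptides"], "w") as fh:
        fh.write(f"# seed={truth.seed}\n")
        fh.write("peptide\tsource_id\tstart\tend\n")
        for p in truth.planted_peptides:
            fh.write(f"{p.sequence}\t{p.source_id}\t{p.start}\t{p.end}\n")
    return paths
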