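"""Exclusion-based candidate ranking.

Peptide-supported ORFs are screened by three independent filters — apparent
gel-band mass window, an N-terminal signal-peptide heuristic, and similarity
to known reference proteins — and the survivors ("finalists") are ordered by
evidence strength. This mirrors a funnel in which dozens of peptide-supported
sequences are reduced to a handful of expression candidates with the most
plausible one ranked first.

The signal-peptide test is an explicit, documented heuristic (charged
n-region followed by a hydrophobic h-region) rather than an external
predictor, so it is deterministic, testable and replaceable via config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from . import homology
from .orfs import OrfRecord
from .peptides import CandidateMatch

__all__ = [
    "ExclusionCriteria",
    "RankedCandidate",
    "BestHit",
    "mass_filter",
    "signal_peptide_heuristic",
    "annotation_exclusion",
    "rank_candidates",
]

logger = logging.getLogger(__name__)


@dataclass
class ExclusionCriteria:
    """Thresholds of the three exclusion filters.

    ``target_mass_kda``/``mass_tolerance``: the gel-band window (a fractional
    window substitutes for a qualitative "approximately 20 kDa" band).
    ``annotation_*_cutoff``: a candidate is excluded when its best local hit
    against any known reference reaches both identity and query coverage
    cutoffs.
    """

    target_mass_kda: float = 20.0
    mass_tolerance: float = 0.25
    exclude_signal_peptides: bool = True
    known_reference_set: dict[str, str] = field(default_factory=dict)
    annotation_identity_cutoff: float = 0.40
    annotation_coverage_cutoff: float = 0.50

    def __post_init__(self) -> None:
        if not (0 < self.mass_tolerance < 1):
            raise ValueError("mass_tolerance must be in (0, 1)")
        for name in ("annotation_identity_cutoff", "annotation_coverage_cutoff"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class BestHit:
    reference_id: str
    identity: float
    query_coverage: float
    score: float


@dataclass
class RankedCandidate:
    candidate: CandidateMatch
    mass_pass: bool
    signal_pass: bool
    annotation_pass: bool
    signal_score: float = 0.0
    best_hit: BestHit | None = None
    rank: int | None = None  # 1-based among finalists, None when excluded

    @property
    def is_finalist(self) -> bool:
        return self.mass_pass and self.signal_pass and self.annotation_pass


def mass_filter(orf: OrfRecord, criteria: ExclusionCriteria) -> bool:
    """Pass iff |predicted mass - target| <= tolerance * target (inclusive)."""
    target = criteria.target_mass_kda * 1000.0
    return abs(orf.predicted_mass - target) <= criteria.mass_tolerance * target


# h-region detection parameters of the heuristic
_N_REGION = 8          # K/R required within the first residues
_SEARCH_SPAN = 30      # whole search window at the N terminus
_H_WINDOW = 8          # hydrophobic window width
_H_THRESHOLD = 2.0     # mean Kyte–Doolittle hydropathy required


def signal_peptide_heuristic(protein: str) -> tuple[bool, float]:
    """Flag putative secretory signal peptides.

    A protein is flagged when, within its first 30 residues, (i) at least one
    K/R occurs in the first 8 residues (charged n-region) and (ii) some window
    of 8 consecutive residues has mean Kyte–Doolittle hydropathy >= 2.0
    (h-region). Returns (flagged, max window hydropathy). Proteins shorter
    than 30 residues are never flagged.
    """
    if len(protein) < _SEARCH_SPAN:
        return False, 0.0
    head = protein[:_SEARCH_SPAN]
    best = float("-inf")
    for i in range(_SEARCH_SPAN - _H_WINDOW + 1):
        window = head[i : i + _H_WINDOW]
        try:
            mean_kd = sum(KYTE_DOOLITTLE[aa] for aa in window) / _H_WINDOW
        except KeyError:
            continue  # X or other non-standard residue: window not scoreable
        best = max(best, mean_kd)
    score = best if best != float("-inf") else 0.0
    has_charge = any(aa in "KR" for aa in head[:_N_REGION])
    return (has_charge and score >= _H_THRESHOLD), score


def annotation_exclusion(
    orf: OrfRecord,
    criteria: ExclusionCriteria,
) -> tuple[bool, BestHit | None]:
    """Pass (True) unless the candidate looks like a known reference protein.

    The candidate fails when its best local alignment against any reference
    reaches both the identity and the query-coverage cutoff. Returns
    (pass_flag, best hit by score).
    """
    if not criteria.known_reference_set:
        raise ValueError("known_reference_set must be non-empty")
    best: BestHit | None = None
    excluded = False
    for ref_id, ref_seq in criteria.known_reference_set.items():
        res = homology.align_local(orf.protein, ref_seq)
        if best is None or res.score > best.score:
            best = BestHit(ref_id, res.identity, res.query_coverage, res.score)
        if (
            res.identity >= criteria.annotation_identity_cutoff
            and res.query_coverage >= criteria.annotation_coverage_cutoff
        ):
            excluded = True
    return (not excluded), best


def rank_candidates(
    candidates: Sequence[CandidateMatch],
    criteria: ExclusionCriteria,
) -> list[RankedCandidate]:
    """Apply all three filters and rank the finalists.

    All candidates are retained with their per-filter flags (excluded ones are
    reported, not dropped). Finalists — candidates passing every filter — are
    ordered by (distinct peptides desc, coverage desc, |mass − target| asc,
    orf id lexicographic), a deterministic total order; rank is None for
    non-finalists.
    """
    target = criteria.target_mass_kda * 1000.0
    ranked: list[RankedCandidate] = []
    for cm in candidates:
        m_ok = mass_filter(cm.orf, criteria)
        flagged, score = signal_peptide_heuristic(cm.orf.protein)
        s_ok = (not flagged) if criteria.exclude_signal_peptides else True
        a_ok, best = annotation_exclusion(cm.orf, criteria)
        rc = RankedCandidate(
            candidate=cm,
            mass_pass=m_ok,
            signal_pass=s_ok,
            annotation_pass=a_ok,
            signal_score=score,
            best_hit=best,
        )
        if not rc.is_finalist:
            reasons = [
                name
                for name, ok in (
                    ("mass", m_ok),
                    ("signal_peptide", s_ok),
                    ("known_homology", a_ok),
                )
                if not ok
            ]
            logger.info(
                "excluded %s (failed: %s)", cm.orf.orf_id, ", ".join(reasons)
            )
        ranked.append(rc)

    def sort_key(rc: RankedCandidate):
        cm = rc.candidate
        return (
            not rc.is_finalist,  # finalists first
            -cm.distinct_peptides,
            -cm.coverage,
            abs(cm.orf.predicted_mass - target),
            cm.orf.orf_id,
        )

    ranked.sort(key=sort_key)
    for pos, rc in enumerate([r for r in ranked if r.is_finalist], start=1):
        rc.rank = pos
    return ranked
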