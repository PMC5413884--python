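"""End-to-end discovery orchestration.

``run_discovery`` executes the fixed stage order — transcriptome → six-frame
ORFs → peptide matching → exclusion ranking → isoform clustering → novelty
report — logging every exclusion decision, and returns a
:class:`DiscoveryReport` whose body regenerates byte-identically from the same
inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

from . import homology, ranking
from .orfs import OrfRecord, Transcript, read_fasta, six_frame_orfs, orf_table, write_fasta
from .peptides import (
    CandidateMatch,
    PeptideEvidence,
    candidate_table,
    match_peptides,
    read_evidence,
)

__all__ = ["RunConfig", "DiscoveryReport", "run_discovery", "novelty_report"]

logger = logging.getLogger(__name__)

_CONFIG_FIELDS = {
    "transcriptome",
    "evidence",
    "known_references",
    "output_dir",
    "min_orf_length_aa",
    "min_distinct_peptides",
    "min_peptide_length",
    "il_equivalent",
    "target_mass_kda",
    "mass_tolerance",
    "exclude_signal_peptides",
    "annotation_identity_cutoff",
    "annotation_coverage_cutoff",
    "isoform_identity_threshold",
    "gap_open",
    "gap_extend",
    "seed",
}


@dataclass
class RunConfig:
    """Validated configuration of one discovery run (unknown keys rejected)."""

    transcriptome: str = ""
    evidence: str = ""
    known_references: str = ""
    output_dir: str = "discovery_out"
    min_orf_length_aa: int = 50
    min_distinct_peptides: int = 2
    min_peptide_length: int = 5
    il_equivalent: bool = True
    target_mass_kda: float = 20.0
    mass_tolerance: float = 0.25
    exclude_signal_peptides: bool = True
    annotation_identity_cutoff: float = 0.40
    annotation_coverage_cutoff: float = 0.50
    isoform_identity_threshold: float = 0.935
    gap_open: float = 11.0
    gap_extend: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class DiscoveryReport:
    stage_counts: dict[str, int]
    ranked: list[ranking.RankedCandidate]
    isoform_groups: list[set[str]]
    novelty: list[dict]
    provenance: dict

    @property
    def finalists(self) -> list[ranking.RankedCandidate]:
        return [r for r in self.ranked if r.is_finalist]

    @property
    def top_candidate(self) -> ranking.RankedCandidate | None:
        return self.finalists[0] if self.finalists else None

    def body_json(self) -> str:
        """Deterministic report body (no timestamps)."""
        payload = {
            "stage_counts": self.stage_counts,
            "provenance": self.provenance,
            "candidates": [
                {
                    "orf_id": r.candidate.orf.orf_id,
                    "transcript_id": r.candidate.orf.transcript_id,
                    "rank": r.rank,
                    "distinct_peptides": r.candidate.distinct_peptides,
                    "coverage_pct": round(100 * r.candidate.coverage, 1),
                    "mass_da": round(r.candidate.orf.predicted_mass, 1),
                    "mass_pass": r.mass_pass,
                    "signal_pass": r.signal_pass,
                    "annotation_pass": r.annotation_pass,
                }
                for r in self.ranked
            ],
            "isoform_groups": [sorted(g) for g in self.isoform_groups],
            "novelty": self.novelty,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def novelty_report(
    finalists: Sequence[ranking.RankedCandidate] | Sequence[CandidateMatch],
    known_set: dict[str, str],
    identity_cutoff: float = 0.40,
    coverage_cutoff: float = 0.50,
) -> list[dict]:
    """Best local hit of every finalist against each known protein class.

    A finalist is flagged ``distinct`` when no known protein reaches both the
    identity and the coverage cutoff — the check that a newly found enzyme is
    unrelated to every known family.
    """
    if not known_set:
        raise ValueError("known_set must be non-empty")
    rows: list[dict] = []
    for item in finalists:
        cm = item.candidate if isinstance(item, ranking.RankedCandidate) else item
        best = None
        distinct = True
        for ref_id, ref_seq in known_set.items():
            res = homology.align_local(cm.orf.protein, ref_seq)
            entry = {
                "reference": ref_id,
                "identity_pct": round(100 * res.identity, 1),
                "similarity_pct": round(100 * res.similarity, 1),
                "coverage_pct": round(100 * res.query_coverage, 1),
                "score": res.score,
            }
            if best is None or res.score > best["score"]:
                best = entry
            if res.identity >= identity_cutoff and res.query_coverage >= coverage_cutoff:
                distinct = False
        rows.append(
            {
                "orf_id": cm.orf.orf_id,
                "best_hit": best,
                "distinct": distinct,
            }
        )
    return rows


def run_discovery(
    config: RunConfig,
    transcripts: Sequence[Transcript] | None = None,
    evidence: Sequence[PeptideEvidence] | None = None,
    known_refs: dict[str, str] | None = None,
    write_outputs: bool = True,
) -> DiscoveryReport:
    """Run the full discovery pipeline.

    Inputs may be given in memory or as the paths in ``config``. Stage order
    is fixed; any stage error aborts with the stage name. When
    ``write_outputs`` is set, TSV/JSON/FASTA reports land in
    ``config.output_dir``.
    """
    counts: dict[str, int] = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"discovery stage {name!r} failed: {exc}") from exc

    if transcripts is None:
        transcripts = stage("read_transcriptome", lambda: read_fasta(config.transcriptome))
    if evidence is None:
        evidence = stage("read_evidence", lambda: read_evidence(config.evidence))
    if known_refs is None:
        known_refs = stage(
            "read_references",
            lambda: homology.read_protein_fasta(config.known_references),
        )
    counts["transcripts"] = len(transcripts)
    counts["evidence_peptides"] = len(evidence)

    orfs: list[OrfRecord] = stage(
        "six_frame_orfs",
        lambda: [
            o
            for t in transcripts
            for o in six_frame_orfs(t, min_len_aa=config.min_orf_length_aa)
        ],
    )
    counts["orfs"] = len(orfs)

    if not evidence:
        logger.warning("no peptide evidence supplied; no candidates to rank")
    matches = stage(
        "match_peptides",
        lambda: match_peptides(
            evidence,
            orfs,
            min_distinct=config.min_distinct_peptides,
            il_equivalent=config.il_equivalent,
            min_peptide_length=config.min_peptide_length,
        ),
    )
    counts["evidence_candidates"] = len(matches)

    criteria = ranking.ExclusionCriteria(
        target_mass_kda=config.target_mass_kda,
        mass_tolerance=config.mass_tolerance,
        exclude_signal_peptides=config.exclude_signal_peptides,
        known_reference_set=known_refs,
        annotation_identity_cutoff=config.annotation_identity_cutoff,
        annotation_coverage_cutoff=config.annotation_coverage_cutoff,
    )
    ranked = stage("rank_candidates", lambda: ranking.rank_candidates(matches, criteria))
    finalists = [r for r in ranked if r.is_finalist]
    counts["finalists"] = len(finalists)

    # isoform clustering among the finalist proteins
    fin_proteins = {r.candidate.orf.orf_id: r.candidate.orf.protein for r in finalists}
    groups = (
        stage(
            "cluster_isoforms",
            lambda: homology.cluster_isoforms(
                fin_proteins,
                identity_threshold=config.isoform_identity_threshold,
                gap_open=config.gap_open,
                gap_extend=config.gap_extend,
            ),
        )
        if fin_proteins
        else []
    )
    counts["isoform_groups"] = len(groups)

    novelty = (
        stage(
            "novelty_report",
            lambda: novelty_report(
                finalists,
                known_refs,
                identity_cutoff=config.annotation_identity_cutoff,
                coverage_cutoff=config.annotation_coverage_cutoff,
            ),
        )
        if finalists
        else []
    )

    report = DiscoveryReport(
        stage_counts=counts,
        ranked=ranked,
        isoform_groups=groups,
        novelty=novelty,
        provenance={
            "config_hash": config.config_hash,
            "seed": config.seed,
            "package": "fernhnl 0.1.0",
        },
    )

    if write_outputs:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        orf_table(orfs).to_csv(outdir / "orfs.tsv", sep="\t", index=False)
        candidate_table([r.candidate for r in ranked]).to_csv(
            outdir / "candidates.tsv", sep="\t", index=False
        )
        (outdir / "report.json").write_text(report.body_json() + "\n")
        if finalists:
            write_fasta(
                [(r.candidate.orf.orf_id, r.candidate.orf.protein) for r in finalists],
                outdir / "finalists.faa",
            )
    return report
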