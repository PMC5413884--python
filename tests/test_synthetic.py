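"""Construction guarantees of the synthetic fixture generator."""

import pytest

from fernhnl.orfs import Transcript, revcomp, six_frame_orfs, translate
from fernhnl.peptides import merge_intervals, tryptic_digest
from fernhnl.synthetic import (
    FixtureError,
    FixtureSpec,
    generate_peptide_evidence,
    generate_transcriptome,
    write_fixture,
)


def test_fixed_seed_gives_byte_identical_fasta(tmp_path):
    p1 = write_fixture(FixtureSpec(seed=3), tmp_path / "a")
    p2 = write_fixture(FixtureSpec(seed=3), tmp_path / "b")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key


def test_different_seed_changes_fixture(tmp_path):
    p1 = write_fixture(FixtureSpec(seed=3), tmp_path / "a")
    p2 = write_fixture(FixtureSpec(seed=4), tmp_path / "b")
    assert p1["transcriptome"].read_bytes() != p2["transcriptome"].read_bytes()


def test_no_isoenzymes_requested():
    spec = FixtureSpec(seed=2, n_isoenzymes=0, n_pass_filters=3)
    _, truth = generate_transcriptome(spec)
    assert truth.isoenzyme_ids == []


def test_infeasible_spec_rejected():
    with pytest.raises(FixtureError):
        FixtureSpec(n_pass_filters=40, n_evidence_orfs=36)
    with pytest.raises(FixtureError):
        FixtureSpec(n_evidence_orfs=100, n_isotigs=60)
    with pytest.raises(FixtureError):
        FixtureSpec(target_coverage=0.0)
    with pytest.raises(FixtureError):
        FixtureSpec(isoenzyme_max_divergence=0.6)
    with pytest.raises(FixtureError):
        FixtureSpec(n_isoenzymes=6, n_pass_filters=6)  # no room for the target


def test_isoenzyme_hamming_identity_bound():
    """Ungapped Hamming count (brute force) confirms every variant stays
    within the mutation budget, hence identity >= 93.5% by construction."""
    spec = FixtureSpec(seed=42)
    _, truth = generate_transcriptome(spec)
    target = truth.labels[truth.target_id].protein
    budget = int(spec.isoenzyme_max_divergence * len(target))
    assert len(truth.isoenzyme_ids) == 3
    for iso_id in truth.isoenzyme_ids:
        iso = truth.labels[iso_id].protein
        assert len(iso) == len(target)
        mismatches = sum(a != b for a, b in zip(target, iso))
        assert 0 < mismatches <= budget
        assert 1 - mismatches / len(target) >= 0.935


def test_target_orf_mass_and_strand_mix(default_fixture):
    _, transcripts, truth, _ = default_fixture
    from fernhnl.orfs import predicted_mass

    target = truth.labels[truth.target_id].protein
    assert abs(predicted_mass(target) - 20000) <= 0.25 * 20000
    strands = {lab.strand for lab in truth.labels.values()}
    assert strands == {"+", "-"}  # planted ORFs on both strands
    frames = {lab.nt_start % 3 for lab in truth.labels.values()}
    assert len(frames) > 1  # not all in frame 1


def test_planted_orfs_are_recovered_exactly(default_fixture):
    """Every planted ORF is found by the six-frame scanner at its recorded
    coordinates with its recorded protein."""
    _, transcripts, truth, _ = default_fixture
    by_id = {t.id: t for t in transcripts}
    for tid, lab in truth.labels.items():
        orfs = six_frame_orfs(by_id[tid], min_len_aa=50)
        hits = [
            o
            for o in orfs
            if o.protein == lab.protein
            and (o.nt_start, o.nt_end, o.strand)
            == (lab.nt_start, lab.nt_end, lab.strand)
        ]
        assert len(hits) == 1, tid


def test_planted_peptides_relocate_uniquely(default_fixture):
    """Exhaustive scan: each planted peptide occurs exactly once in its source
    protein, at the recorded interval."""
    _, transcripts, truth, _ = default_fixture
    for pep in truth.planted_peptides:
        protein = truth.labels[pep.source_id].protein
        il = lambda s: s.replace("I", "L")
        occurrences = [
            i
            for i in range(len(protein) - len(pep.sequence) + 1)
            if il(protein[i : i + len(pep.sequence)]) == il(pep.sequence)
        ]
        assert occurrences == [pep.start - 1]
        assert protein[pep.start - 1 : pep.end] == pep.sequence


def test_exactly_n_evidence_orfs_carry_two_peptides(default_fixture):
    _, _, truth, _ = default_fixture
    spec = FixtureSpec(seed=1)
    by_source: dict[str, set[str]] = {}
    for pep in truth.planted_peptides:
        by_source.setdefault(pep.source_id, set()).add(pep.sequence)
    assert len(by_source) == spec.n_evidence_orfs
    assert all(len(s) >= 2 for s in by_source.values())


def test_evidence_coverage_within_one_residue(default_fixture):
    spec, _, truth, evidence = default_fixture
    target = truth.labels[truth.target_id].protein
    L = len(target)
    # interval-union oracle over the planted target peptides
    intervals = [
        (p.start, p.end)
        for p in truth.planted_peptides
        if p.source_id == truth.target_id
    ]
    union = sum(e - s + 1 for s, e in merge_intervals(intervals))
    assert abs(union - round(spec.target_coverage * L)) <= 1


def test_full_coverage_returns_whole_digest():
    spec = FixtureSpec(seed=5)
    _, truth = generate_transcriptome(spec)
    evidence = generate_peptide_evidence(truth, FixtureSpec(seed=5, target_coverage=1.0))
    target = truth.labels[truth.target_id].protein
    target_peps = {e.sequence for e in evidence if e.source == truth.target_id}
    assert target_peps == {f.sequence for f in tryptic_digest(target, 0)}


def test_unattainable_coverage_names_achievable_maximum():
    spec = FixtureSpec(seed=5)
    _, truth = generate_transcriptome(spec)
    target = truth.labels[truth.target_id].protein
    bad = FixtureSpec(seed=5)
    bad.target_coverage = 2.0  # bypass validation to probe the evidence check
    with pytest.raises(FixtureError, match="achievable maximum"):
        generate_peptide_evidence(truth, bad)


def test_reverse_strand_decoy_peptide_matches_only_its_orf(default_fixture):
    """A peptide planted on a reverse-strand decoy is found in that ORF and
    nowhere else across all six frames of the whole transcriptome."""
    _, transcripts, truth, _ = default_fixture
    rev_decoys = [
        tid
        for tid, lab in truth.labels.items()
        if lab.strand == "-" and lab.role not in ("target", "isoenzyme")
    ]
    assert rev_decoys
    tid = rev_decoys[0]
    pep = next(p for p in truth.planted_peptides if p.source_id == tid)
    il = lambda s: s.replace("I", "L")
    hosts = []
    for t in transcripts:
        for strand in "+-":
            for frame in (1, 2, 3):
                prot = translate(t.sequence, strand, frame)
                if il(pep.sequence) in il(prot):
                    hosts.append(t.id)
    assert hosts == [tid]
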