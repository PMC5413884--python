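"""Pairwise alignment, isoform clustering, translated search."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from Bio.Align import substitution_matrices

from fernhnl.homology import (
    align_global,
    align_local,
    cluster_isoforms,
    reciprocal_check,
    translated_search,
)
from fernhnl.orfs import Transcript, revcomp
from fernhnl.synthetic import MOST_FREQUENT_CODON

B62 = substitution_matrices.load("BLOSUM62")
AA = "ACDEFGHIKLMNPQRSTVWY"

GAP_OPEN, GAP_EXT = 11.0, 1.0  # a gap of length L costs OPEN + L * EXT


def _gotoh_scores(a: str, b: str):
    """Independent affine-gap DP (Gotoh) giving (global, local) optima."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    open_cost = GAP_OPEN + GAP_EXT

    def run(local: bool) -> float:
        M = [[NEG] * (m + 1) for _ in range(n + 1)]
        X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
        Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
        M[0][0] = 0.0
        best = 0.0
        for i in range(n + 1):
            for j in range(m + 1):
                if i > 0:
                    X[i][j] = max(M[i - 1][j] - open_cost, X[i - 1][j] - GAP_EXT,
                                  Y[i - 1][j] - open_cost)
                if j > 0:
                    Y[i][j] = max(M[i][j - 1] - open_cost, Y[i][j - 1] - GAP_EXT,
                                  X[i][j - 1] - open_cost)
                if i > 0 and j > 0:
                    s = B62[a[i - 1], b[j - 1]]
                    prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                    if local:
                        prev = max(prev, 0.0)
                    M[i][j] = prev + s
                if local:
                    best = max(best, M[i][j])
        if local:
            return best
        return max(M[n][m], X[n][m], Y[n][m])

    return run(False), run(True)


# ------------------------------------------------------------------ examples
def test_identity_of_identical_sequences():
    assert align_global("ACDEFG", "ACDEFG").identity == 1.0


def test_single_mismatch_identity():
    res = align_global("ACDEFG", "ACDEFA")
    assert res.identity == pytest.approx(5 / 6)


def test_similarity_counts_positive_substitutions():
    # K/R scores +2 in BLOSUM62: a similar but non-identical column
    res = align_global("AKDEFG", "ARDEFG")
    assert res.identity == pytest.approx(5 / 6)
    assert res.similarity == pytest.approx(1.0)
    assert res.identity <= res.similarity <= 1.0


def test_local_negative_pairs_give_empty_alignment():
    res = align_local("PPPPP", "GGGGG")
    assert res.score == 0.0 and res.aligned_a == ""


def test_local_alignment_spans_embedded_identical_segment():
    core = "WQEVHKLMNDAYFCRISTPG"  # 20-mer
    a = "MMMM" + core + "GGGG"
    b = "TTTT" + core + "AAAA"
    res = align_local(a, b)
    assert res.query_span == (5, 24)
    assert res.identity == 1.0


def test_local_score_nonnegative_always():
    assert align_local("AAAA", "WWWW").score >= 0.0


def test_alignment_rejects_unknown_residues():
    with pytest.raises(ValueError):
        align_global("AC1", "ACD")


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.text(alphabet=AA, min_size=1, max_size=8),
       st.text(alphabet=AA, min_size=1, max_size=8))
def test_scores_match_independent_dp_oracle(a, b):
    g_oracle, l_oracle = _gotoh_scores(a, b)
    assert align_global(a, b).score == pytest.approx(g_oracle)
    assert align_local(a, b).score == pytest.approx(max(l_oracle, 0.0))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.text(alphabet=AA, min_size=1, max_size=12),
       st.text(alphabet=AA, min_size=1, max_size=12))
def test_identity_is_symmetric(a, b):
    assert align_global(a, b).identity == pytest.approx(align_global(b, a).identity)


# ----------------------------------------------------------------- clustering
def test_cluster_all_distinct_at_full_identity_threshold():
    prots = {"a": "ACDEFGHIKL", "b": "ACDEFGHIKV", "c": "WWWWYYYYFF"}
    groups = cluster_isoforms(prots, identity_threshold=1.0)
    assert sorted(map(sorted, groups)) == [["a"], ["b"], ["c"]]


def test_cluster_single_linkage_chains():
    base = "ACDEFGHIKLMNPQRSTVWY" * 2
    a = base
    b = base[:-4] + "WWWW"          # 90% identical to a
    c = base[:-8] + "WWWWWWWW"      # 90% to b, 80% to a
    groups = cluster_isoforms({"a": a, "b": b, "c": c}, identity_threshold=0.85)
    assert sorted(map(sorted, groups)) == [["a", "b", "c"]]


def test_cluster_requires_input():
    with pytest.raises(ValueError):
        cluster_isoforms({})


def test_fixture_isoforms_group_with_target(default_fixture):
    _, _, truth, _ = default_fixture
    prots = {truth.target_id: truth.labels[truth.target_id].protein}
    for i in truth.isoenzyme_ids:
        prots[i] = truth.labels[i].protein
    groups = cluster_isoforms(prots, identity_threshold=0.935)
    assert len(groups) == 1 and len(groups[0]) == 4


# ----------------------------------------------------------- translated search
def _backtranslate(protein: str) -> str:
    return "".join(MOST_FREQUENT_CODON[aa] for aa in protein)


def test_translated_search_finds_reverse_strand_query():
    query = "MWQEVHKDAYFCRISTPGNE"
    cds = _backtranslate(query) + "TAA"
    transcript = Transcript("iso1", revcomp("ACGACG" + cds + "TTGACG"))
    (hit, *_) = translated_search(query, [transcript])
    assert hit.transcript_id == "iso1"
    assert hit.strand == "-"
    assert hit.alignment.identity == 1.0


def test_translated_search_strand_flip_mirrors_hit():
    query = "MWQEVHKDAYFCRISTPGNE"
    seq = "ACGACG" + _backtranslate(query) + "TAATTGACG"
    fwd = translated_search(query, [Transcript("x", seq)])[0]
    rev = translated_search(query, [Transcript("x", revcomp(seq))])[0]
    assert fwd.alignment.score == rev.alignment.score
    assert {fwd.strand, rev.strand} == {"+", "-"}
    assert (fwd.nt_start, fwd.nt_end) == (
        len(seq) - rev.nt_end + 1,
        len(seq) - rev.nt_start + 1,
    )


def test_translated_search_empty_database():
    assert translated_search("MWQEVHK", []) == []


def test_translated_search_identity_filter_on_fixture(default_fixture):
    """Searching the transcriptome with the planted target finds the target
    and its isoenzymes; searching with a known reference finds its planted
    homolog decoys but no neutral decoy (identity > 35%, solid score)."""
    _, transcripts, truth, _ = default_fixture
    target = truth.labels[truth.target_id].protein
    hits = translated_search(target, transcripts, min_identity=0.35, min_score=100)
    hit_ids = {h.transcript_id for h in hits}
    assert {truth.target_id, *truth.isoenzyme_ids} <= hit_ids
    neutral = {t for t, l in truth.labels.items() if l.role == "neutral"}
    assert not (neutral & hit_ids)

    homolog_by_ref = {}
    for tid, lab in truth.labels.items():
        if lab.role == "known_homolog":
            homolog_by_ref.setdefault(lab.homolog_of, set()).add(tid)
    ref_id, decoy_ids = next(iter(sorted(homolog_by_ref.items())))
    ref_hits = translated_search(
        truth.known_references[ref_id], transcripts, min_identity=0.35, min_score=100
    )
    ref_hit_ids = {h.transcript_id for h in ref_hits}
    assert decoy_ids <= ref_hit_ids
    assert not (neutral & ref_hit_ids)
    assert truth.target_id not in ref_hit_ids  # the novel target stays distinct


# -------------------------------------------------------------- reciprocal RBH
def test_reciprocal_when_query_planted_in_both():
    query = "MWQEVHKDAYFCRISTPGNE"
    cds = _backtranslate(query) + "TAA"
    db_a = [Transcript("a1", "ACG" + cds + "AC")]
    db_b = [Transcript("b1", "TT" + cds + "ACG")]
    rep = reciprocal_check(query, db_a, db_b)
    assert rep.reciprocal and rep.back_hit_id == "a1"


def test_non_reciprocal_when_closer_paralog_exists():
    query = "MWQEVHKDAYFCRISTPGNE"
    paralog = "MWQEVHKDAYWWRISTPGNE"  # closer to the db_b subject than query
    subject = "MWQEVHKDAYWWRISTPGNE"
    db_a = [
        Transcript("home", "ACG" + _backtranslate(query) + "TAA"),
        Transcript("paralog", "ACG" + _backtranslate(paralog) + "TAA"),
    ]
    db_b = [Transcript("b1", "TT" + _backtranslate(subject) + "TAAACG")]
    rep = reciprocal_check(query, db_a, db_b)
    assert not rep.reciprocal
    assert rep.back_hit_id == "paralog"


def test_reciprocal_empty_database_reports_no_hit():
    rep = reciprocal_check("MWQEVHK", [Transcript("a", "ATGTGGCAA")], [])
    assert not rep.reciprocal and "no hit" in rep.detail
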