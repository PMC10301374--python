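"""Domain classifiers: alignment anchoring, motif calls, recovery."""

import numpy as np
import pytest

from pkstereo.classify import (
    UnalignableError,
    align_to_reference,
    classify_all,
    classify_at,
    classify_dh,
    classify_er,
    classify_kr,
    diagnostic_positions,
    reference_sequences,
)
from pkstereo.cluster import KRCall
from pkstereo.synth import make_cluster, make_domain, mld_architecture_calls


def test_reference_self_alignment_is_identity():
    ref = reference_sequences()["KR"]
    mapping = align_to_reference(ref, "KR")
    assert all(mapping[p] == p for p in range(1, len(ref) + 1))


def test_internal_deletion_shifts_the_map():
    ref = reference_sequences()["KR"]
    query = ref[:9] + ref[10:]  # delete residue 10
    mapping = align_to_reference(query, "KR")
    unmapped = [p for p, q in mapping.items() if q is None]
    assert len(unmapped) == 1
    assert mapping[1] == 1
    assert mapping[len(ref)] == len(ref) - 1
    # positions after the gap all shift by exactly one
    assert all(mapping[p] == p - 1 for p in range(unmapped[0] + 1, len(ref) + 1))


def test_alignment_score_matches_brute_force_dp():
    """Independent Gotoh affine-gap DP reproduces the aligner's score."""
    from Bio import Align

    ref = reference_sequences()["AT"][:80]
    seq, _ = make_domain("AT", "malonyl", seed=3, mutation_rate=0.15)
    query = seq[:70]
    matrix = Align.substitution_matrices.load("BLOSUM62")
    open_, ext = -10.0, -1.0
    n, m = len(ref), len(query)
    NEG = -1e9
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + ext * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = open_ + ext * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[ref[i - 1], query[j - 1]]
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = best_prev + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + ext, Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + ext, X[i][j - 1] + open_)
    expected = max(M[n][m], X[n][m], Y[n][m])

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = open_
    aligner.extend_gap_score = ext
    assert aligner.score(ref, query) == pytest.approx(expected)


def test_short_query_is_unalignable():
    with pytest.raises(UnalignableError):
        align_to_reference("MKLV", "KR")


@pytest.mark.parametrize(
    "call,expected",
    [("methylmalonyl", "methylmalonyl"), ("malonyl", "malonyl"), ("unknown", "unknown")],
)
def test_at_motif_calls(call, expected):
    seq, _ = make_domain("AT", call, seed=5)
    got = classify_at(seq)
    assert got.specificity == expected
    if expected != "unknown":
        assert got.motif_observed == {"malonyl": "HAFH", "methylmalonyl": "YASH"}[expected]


def test_at_fuzzy_matching_is_opt_in():
    seq, _ = make_domain("AT", "malonyl", seed=5)
    # HAFH -> HASH: one mismatch outside position 1
    hash_seq = seq.replace("HAFH", "HASH")
    assert classify_at(hash_seq).specificity == "unknown"
    fuzzy = classify_at(hash_seq, fuzzy=True)
    assert fuzzy.specificity == "malonyl"
    assert fuzzy.partial_evidence
    # first-position mismatch is never accepted
    aash = seq.replace("HAFH", "AAFH")
    assert classify_at(aash, fuzzy=True).specificity == "unknown"


def test_at_garbage_is_unknown():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300))
    assert classify_at(seq).specificity == "unknown"


@pytest.mark.parametrize("subtype", ["A1", "A2", "B1", "B2", "C1", "C2"])
def test_kr_subtype_recovery(subtype):
    seq, _ = make_domain("KR", subtype, seed=13)
    call = classify_kr(seq)
    assert call.subtype == subtype
    # invariants carried by the call
    assert call.redox_active == (subtype[0] != "C")
    assert call.epimerizing == (subtype[1] == "2")
    assert call.beta_descriptor == {"A": "3S", "B": "3R", "C": "none"}[subtype[0]]


def test_kr_conflicting_fingerprints_resolve_to_b_with_warning():
    seq, _ = make_domain("KR", "B1", seed=2)
    # plant the A-type Trp on top of the LDD-bearing B scaffold
    from pkstereo.classify import diagnostic

    pos = diagnostic("kr-a-fingerprint").start - 1
    conflicted = seq[:pos] + "W" + seq[pos + 1 :]
    findings = []
    call = classify_kr(conflicted, findings)
    assert call.subtype == "B1"
    assert [f.code for f in findings] == ["kr-fingerprint-conflict"]


def test_kr_refuses_to_guess_on_x():
    from pkstereo.classify import UnknownCallError, diagnostic

    seq, _ = make_domain("KR", "B1", seed=2)
    pos = diagnostic("kr-triad-ser").start - 1
    masked = seq[:pos] + "X" + seq[pos + 1 :]
    with pytest.raises(UnknownCallError):
        classify_kr(masked)


@pytest.mark.parametrize("active", [True, False])
def test_dh_activity(active):
    seq, _ = make_domain("DH", active, seed=4)
    call = classify_dh(seq)
    assert call.active == active
    assert call.catalytic_his_present
    assert call.catalytic_asp_present == active


def test_dh_without_either_residue_is_inactive():
    from pkstereo.classify import diagnostic

    seq, _ = make_domain("DH", True, seed=4)
    his = diagnostic("dh-catalytic-his").start - 1
    asp = diagnostic("dh-catalytic-asp").start - 1
    dead = list(seq)
    dead[his] = "A"
    dead[asp] = "A"
    assert not classify_dh("".join(dead)).active


@pytest.mark.parametrize(
    "residue,alpha", [("Y", "2S"), ("V", "2R"), ("X", "not_applicable")]
)
def test_er_residue_44_rule(residue, alpha):
    seq, _ = make_domain("ER", residue, seed=6)
    call = classify_er(seq)
    assert call.active
    assert call.alpha_descriptor_if_methyl == alpha


ALL_CALLS = (
    [("AT", s) for s in ("malonyl", "methylmalonyl")]
    + [("KR", s) for s in ("A1", "A2", "B1", "B2", "C1", "C2")]
    + [("DH", a) for a in (True, False)]
    + [("ER", r) for r in ("Y", "V")]
)


@pytest.mark.parametrize("rate", [0.0, 0.1])
def test_recovery_under_scaffold_mutation(rate):
    """Protected diagnostics keep recovery exact under scaffold noise."""
    for kind, call in ALL_CALLS:
        for seed in (1, 2, 3):
            seq, _ = make_domain(kind, call, seed=seed, mutation_rate=rate)
            if kind == "AT":
                assert classify_at(seq).specificity == call
            elif kind == "KR":
                assert classify_kr(seq).subtype == call
            elif kind == "DH":
                assert classify_dh(seq).active == call
            else:
                assert classify_er(seq).residue_44 == call


def test_classifier_determinism():
    seq, _ = make_domain("KR", "A2", seed=9, mutation_rate=0.1)
    assert classify_kr(seq) == classify_kr(seq)


def test_classify_all_recovers_cluster_truth():
    cluster = make_cluster(mld_architecture_calls(), seed=3)
    truth = {
        m.index: (
            m.at_call.specificity if m.at_call else None,
            m.kr_call.subtype if m.kr_call else None,
            m.dh_call.active if m.dh_call else None,
            m.er_call.residue_44 if m.er_call else None,
        )
        for m in cluster.line.modules
    }
    for m in cluster.line.modules:
        m.at_call = m.kr_call = m.dh_call = m.er_call = None
    findings = []
    classify_all(cluster.line, findings)
    assert findings == []
    for m in cluster.line.modules:
        got = (
            m.at_call.specificity if m.at_call else None,
            m.kr_call.subtype if m.kr_call else None,
            m.dh_call.active if m.dh_call else None,
            m.er_call.residue_44 if m.er_call else None,
        )
        assert got == truth[m.index], f"module {m.index}"


def test_classify_all_is_a_noop_without_sequences(mld_line):
    before = [(m.at_call.specificity if m.at_call else None) for m in mld_line.modules]
    findings = []
    classify_all(mld_line, findings)
    after = [(m.at_call.specificity if m.at_call else None) for m in mld_line.modules]
    assert before == after and findings == []


def test_table_call_wins_over_contradicting_sequence():
    cluster = make_cluster(mld_architecture_calls(), seed=5)
    m4 = cluster.line.module(4)  # table says malonyl
    seq, _ = make_domain("AT", "methylmalonyl", seed=99)
    m4.domain("AT").sequence = seq
    findings = []
    classify_all(cluster.line, findings)
    assert m4.at_call.specificity == "malonyl"
    assert any(f.code == "call-disagreement" and f.module_index == 4 for f in findings)


def test_kr_call_invariants_hold_for_all_subtypes():
    for subtype in ("A1", "A2", "B1", "B2", "C1", "C2"):
        call = KRCall(subtype)
        assert call.redox_active == (subtype not in ("C1", "C2"))
        assert call.epimerizing == (subtype in ("A2", "B2", "C2"))
        if subtype.startswith("A"):
            assert call.beta_descriptor == "3S"
        elif subtype.startswith("B"):
            assert call.beta_descriptor == "3R"
        else:
            assert call.beta_descriptor == "none"
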