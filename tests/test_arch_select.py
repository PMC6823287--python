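"""Domain-architecture selection, identity kernel and redundancy clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from subspec.arch_select import (
    DomainHit, ProteinAnnotation, ArchitectureQuery, DomainTableError,
    parse_domain_table, match_architecture, select_architecture,
    pairwise_identity, greedy_cluster,
    WRONG_ORDER, EXTRA_DOMAIN, OVERLAP, PARTIAL_DOMAIN,
    LONG_INSERTION, LONG_EXTENSION, FRAGMENT,
)
from subspec.synthetic_data import gen_annotation_set, DEFAULT_QUERY_PARAMS


def make_query(**overrides):
    params = dict(DEFAULT_QUERY_PARAMS)
    params.update(overrides)
    return ArchitectureQuery(**params)


# --- parse_domain_table -----------------------------------------------------

def test_parse_two_domain_row():
    table = ("protein_id\tdomain\tstart\tend\n"
             "P1\tSec7\t60\t255\n"
             "P1\tPH\t263\t380\n")
    fasta = ">P1\n" + "A" * 400 + "\n"
    anns, missing = parse_domain_table(table, fasta)
    assert len(anns) == 1 and not missing
    assert [(h.domain_name, h.start, h.end) for h in anns[0].hits] == [
        ("Sec7", 60, 255), ("PH", 263, 380)]


def test_parse_empty_table():
    anns, missing = parse_domain_table("protein_id\tdomain\tstart\tend\n")
    assert anns == [] and missing == []


def test_parse_malformed_coordinate_names_line():
    table = "protein_id\tdomain\tstart\tend\nP1\tPH\t26x\t100\n"
    with pytest.raises(DomainTableError, match="line 2"):
        parse_domain_table(table)


def test_parse_end_before_start_rejected():
    with pytest.raises(DomainTableError):
        parse_domain_table("protein_id\tdomain\tstart\tend\nP1\tPH\t50\t40\n")


def test_parse_reports_missing_sequences():
    table = "protein_id\tdomain\tstart\tend\nP9\tPH\t1\t100\n"
    anns, missing = parse_domain_table(table, ">OTHER\nAAAA\n")
    assert missing == ["P9"]


# --- match_architecture -----------------------------------------------------

def ann(hits, total=None, fragment=False):
    length = total or max(h.end for h in hits) + 10
    return ProteinAnnotation("P", "A" * length, hits, fragment=fragment)


def test_accept_in_range_architecture():
    a = ann([DomainHit("Sec7", 6, 200), DomainHit("PH", 209, 328)], total=338)
    assert match_architecture(a, make_query()) == (True, None)


def test_extra_domain_rejected():
    a = ann([DomainHit("Sec7", 6, 200), DomainHit("X", 210, 260),
             DomainHit("PH", 270, 389)])
    assert match_architecture(a, make_query()) == (False, EXTRA_DOMAIN)


def test_long_linker_rejected_beyond_relaxation():
    # 95-residue linker against a reference of 8 with relaxation 20
    a = ann([DomainHit("Sec7", 6, 200), DomainHit("PH", 296, 415)])
    ok, reason = match_architecture(a, make_query())
    assert (ok, reason) == (False, LONG_INSERTION)


def test_order_sensitivity():
    """Permuting the query domain order flips the verdict on swapped hits."""
    swapped = ann([DomainHit("PH", 6, 125), DomainHit("Sec7", 134, 328)],
                  total=338)
    assert match_architecture(swapped, make_query())[1] == WRONG_ORDER
    reversed_query = make_query(domain_order=["PH", "Sec7"])
    assert match_architecture(swapped, reversed_query) == (True, None)


@pytest.mark.parametrize("code", [WRONG_ORDER, EXTRA_DOMAIN, OVERLAP,
                                  PARTIAL_DOMAIN, LONG_INSERTION,
                                  LONG_EXTENSION, FRAGMENT])
def test_planted_defect_recovers_reason(code):
    panel = gen_annotation_set(n_clean=3, defects={code: 2}, seed=5)
    anns, _ = parse_domain_table(panel.table_tsv, panel.fasta)
    report = select_architecture(anns, make_query())
    for a in anns:
        expected = panel.truth[a.protein_id]
        got = None if a.protein_id in report.accepted else \
            report.rejected[a.protein_id]
        assert got == expected


def test_full_defect_panel_matches_truth(annotation_panel):
    anns, _ = parse_domain_table(annotation_panel.table_tsv,
                                 annotation_panel.fasta)
    report = select_architecture(anns, make_query())
    for a in anns:
        expected = annotation_panel.truth[a.protein_id]
        got = None if a.protein_id in report.accepted else \
            report.rejected[a.protein_id]
        assert got == expected, a.protein_id


# --- pairwise_identity ------------------------------------------------------

def _blosum62():
    from Bio.Align import substitution_matrices
    return substitution_matrices.load("BLOSUM62")


def gotoh_identity(a, b, open_pen=10.0, ext_pen=0.5):
    """Independent affine-gap global DP (Gotoh) with traceback; returns
    identical aligned pairs / min length."""
    mat = _blosum62()
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a aligned to gap)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -open_pen - ext_pen * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -open_pen - ext_pen * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - open_pen, X[i - 1, j] - ext_pen)
            Y[i, j] = max(M[i, j - 1] - open_pen, Y[i, j - 1] - ext_pen)
    # traceback
    i, j = n, m
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    ident = 0
    while i > 0 or j > 0:
        if state == 0:
            if a[i - 1] == b[j - 1] and a[i - 1] != "X":
                ident += 1
            prev = int(np.argmax([M[i - 1, j - 1], X[i - 1, j - 1],
                                  Y[i - 1, j - 1]]))
            i, j, state = i - 1, j - 1, prev
        elif state == 1:
            state = 0 if M[i - 1, j] - open_pen >= X[i - 1, j] - ext_pen else 1
            i -= 1
        else:
            state = 0 if M[i, j - 1] - open_pen >= Y[i, j - 1] - ext_pen else 2
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    return ident / min(n, m)


@pytest.mark.parametrize("a,b,expected", [
    ("ACDEFG", "ACDEFG", 1.0),
    ("ACDEFG", "ACDEFGHH", 1.0),   # terminal extension does not break identity
    ("KKKKKKKKKK", "KKKKKAKKKK", 0.9),
])
def test_identity_examples(a, b, expected):
    assert pairwise_identity(a, b) == pytest.approx(expected)


@pytest.mark.parametrize("a,b", [
    ("MKTAYIAKQR", "MKTAYIAKQR"),
    ("MKTAYIAKQRQISFVK", "MKTAYIGKQRQISF"),
    ("ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWYAAA"),
    ("WWWWKKKKDDDD", "WWWWDDDD"),
])
def test_identity_matches_dp_oracle(a, b):
    assert pairwise_identity(a, b) == pytest.approx(gotoh_identity(a, b))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=30),
       st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=30))
def test_identity_symmetric_and_reflexive(a, b):
    assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))
    assert pairwise_identity(a, a) == pytest.approx(1.0)


def test_identity_rejects_empty():
    with pytest.raises(ValueError):
        pairwise_identity("", "ACD")


# --- greedy_cluster ---------------------------------------------------------

def test_identical_pair_collapses():
    reps, members = greedy_cluster({"a": "MKTAYIAKQR", "b": "MKTAYIAKQR"})
    assert len(reps) == 1
    assert members["a"] == members["b"]


def test_cutoff_is_strict():
    """At identity exactly equal to the cutoff, sequences stay separate."""
    a = "K" * 10
    b = "K" * 9 + "A"          # identity 0.9 exactly
    assert pairwise_identity(a, b) == pytest.approx(0.9)
    reps, _ = greedy_cluster({"a": a, "b": b}, cutoff=0.90)
    assert len(reps) == 2


def test_cutoff_one_merges_subsequences():
    """With min-length denominators, sub/super-sequence pairs reach 1.0 and
    merge even at cutoff just below 1."""
    reps, members = greedy_cluster(
        {"long": "MKTAYIAKQRQISFVKSHFSRQL", "short": "MKTAYIAKQRQISFVK"},
        cutoff=0.999)
    assert len(reps) == 1
    assert members["short"] == "long"   # longest-first representative


def test_cluster_matches_exhaustive_oracle():
    rng = np.random.default_rng(7)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    base = "".join(aa[i] for i in rng.integers(20, size=40))
    seqs = {"s0": base}
    for k in range(1, 8):
        s = list(base)
        for p in rng.choice(40, size=rng.integers(1, 15), replace=False):
            s[p] = aa[int(rng.integers(20))]
        seqs[f"s{k}"] = "".join(s)

    # oracle: same greedy rule over the exhaustive pairwise matrix
    ident = {(x, y): pairwise_identity(seqs[x], seqs[y])
             for x in seqs for y in seqs}
    order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
    oracle_reps, oracle_members = [], {}
    for sid in order:
        for rep in oracle_reps:
            if ident[(sid, rep)] > 0.90:
                oracle_members[sid] = rep
                break
        else:
            oracle_reps.append(sid)
            oracle_members[sid] = sid

    reps, members = greedy_cluster(seqs, 0.90)
    assert reps == oracle_reps
    assert members == oracle_members


def test_duplicates_cluster_in_panel(annotation_panel):
    import io
    from Bio import SeqIO
    seqs = {r.id: str(r.seq)
            for r in SeqIO.parse(io.StringIO(annotation_panel.fasta), "fasta")}
    _, members = greedy_cluster(seqs, 0.90)
    for src, dup in annotation_panel.duplicate_pairs:
        assert members[src] == members[dup]
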