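"""Alignment layer: NW/BLOSUM62 vs an exhaustive oracle, labels, Neff."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoformetrics.align import (
    PairAlignment,
    effective_msa_depth,
    global_align,
    label_regions,
    per_residue_msa_count,
    sequence_identity,
)
from isoformetrics.io import MSA
from isoformetrics.synth import make_msa

# ---------------------------------------------------------------------------
# brute-force oracle: enumerate all monotone alignment paths, score with the
# same BLOSUM62 + affine gap model (open -10 applies to a run's first gap,
# extend -0.5 to each further gap position)


def _enumerate_best_score(a: str, b: str, open_gap=-10.0, extend=-0.5) -> float:
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")

    best = -np.inf

    def rec(i, j, score, last):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + blosum[a[i], b[j]], "m")
        if i < len(a):
            cost = extend if last == "d" else open_gap
            rec(i + 1, j, score + cost, "d")
        if j < len(b):
            cost = extend if last == "i" else open_gap
            rec(i, j + 1, score + cost, "i")

    rec(0, 0, 0.0, None)
    return best


@pytest.mark.parametrize(
    "a,b",
    [
        ("ACDEFG", "ACDE"),
        ("ACDE", "ACDE"),
        ("WWWW", "AAAA"),
        ("MKV", "MPKV"),
        ("A", "ACDEF"),
    ],
)
def test_alignment_score_matches_exhaustive_enumeration(a, b):
    aln = global_align(a, b)
    assert aln.score == pytest.approx(_enumerate_best_score(a, b))


def test_end_gap_example():
    aln = global_align("ACDEFG", "ACDE")
    assert len(aln) == 6
    gap_cols = [c for c in aln.columns if c[1] is None]
    assert len(gap_cols) == 2
    assert sequence_identity(aln) == pytest.approx(4 / 6)


def test_identity_of_identical_sequences():
    aln = global_align("ACDEMKV", "ACDEMKV")
    assert sequence_identity(aln) == 1.0
    assert all(r is not None and i is not None for r, i in aln.columns)


def test_mirror_symmetry():
    aln = global_align("MKVLAW", "MKLAW")
    mirrored = global_align("MKLAW", "MKVLAW")
    assert [(i, r) for r, i in aln.columns] == mirrored.columns


def test_disjoint_alphabet_pair_zero_matches():
    aln = global_align("WWWWW", "GGGGG")
    n_match = sum(
        1 for r, i in aln.columns
        if r and i and aln.ref_seq[r - 1] == aln.iso_seq[i - 1]
    )
    assert n_match == 0


def test_illegal_character_rejected():
    with pytest.raises(ValueError, match="illegal"):
        global_align("AC1E", "ACDE")
    with pytest.raises(ValueError, match="empty"):
        global_align("", "ACDE")


# ---------------------------------------------------------------------------
# region labels


def _manual_alignment(columns, ref_seq, iso_seq):
    return PairAlignment("ref", "iso", ref_seq, iso_seq, columns, score=0.0)


def test_pure_deletion_labelled_missing():
    # ref 1..10 aligned, 11..20 deleted
    cols = [(i, i) for i in range(1, 11)] + [(i, None) for i in range(11, 21)]
    aln = _manual_alignment(cols, "A" * 20, "A" * 10)
    labels = label_regions(aln)
    assert labels.labels[:10] == ["reference_other"] * 10
    assert labels.labels[10:] == ["missing"] * 10


def test_adjacent_indel_runs_are_replacement():
    cols = [(1, 1), (2, None), (3, None), (None, 2), (None, 3), (4, 4)]
    aln = _manual_alignment(cols, "AAAA", "AAAA")
    labels = label_regions(aln).labels
    assert labels == [
        "reference_other", "reference_replaced", "reference_replaced",
        "isoform_replaced", "isoform_replaced", "reference_other",
    ]


def test_no_indels_all_other():
    aln = global_align("MKVAW", "MKVAW")
    assert set(label_regions(aln).labels) == {"reference_other"}


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_labels_partition_all_columns(seed):
    rng = np.random.default_rng(seed)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    a = "".join(rng.choice(list(alphabet), size=rng.integers(5, 25)))
    b = "".join(rng.choice(list(alphabet), size=rng.integers(5, 25)))
    aln = global_align(a, b)
    labels = label_regions(aln)
    assert len(labels.labels) == len(aln.columns)
    assert 0 <= sequence_identity(aln) <= 1


# ---------------------------------------------------------------------------
# effective MSA depth


def test_neff_identical_rows():
    msa = MSA(query="AAAA", rows=["AAAA"] * 5)
    assert effective_msa_depth(msa) == pytest.approx(1.0)


def test_neff_hand_constructed_two_clusters():
    # r1 = r2 identical; r3 unrelated: weights 1/2 + 1/2 + 1 = 2
    msa = MSA(query="AAAAAAAAAA", rows=["AAAAAAAAAA", "AAAAAAAAAA", "WYWYWYWYWY"])
    # brute-force pairwise identity matrix confirms the cluster structure
    assert effective_msa_depth(msa) == pytest.approx(2.0)


def test_neff_all_dissimilar_equals_n():
    msa = make_msa(5, 0.3, seed=1)
    rows = msa.rows
    # verify precondition: all pairwise identities below 0.8
    for i, j in itertools.combinations(range(5), 2):
        ident = sum(x == y for x, y in zip(rows[i], rows[j])) / len(rows[i])
        assert ident < 0.8
    assert effective_msa_depth(msa) == pytest.approx(5.0)


def test_neff_monotone_under_duplication():
    base = make_msa(4, 0.5, seed=3)
    prev = effective_msa_depth(base)
    rows = list(base.rows)
    for _ in range(3):
        rows.append(rows[0])
        now = effective_msa_depth(MSA(query=base.query, rows=rows))
        assert now <= prev + 1e-12
        assert 1.0 <= now <= len(rows)
        prev = now


def test_per_residue_msa_count():
    msa = MSA(query="ACDE", rows=["ACDE", "AC-E", "A--E"])
    np.testing.assert_array_equal(per_residue_msa_count(msa), [3, 2, 1, 3])
    constant = MSA(query="ACDE", rows=["ACDE"] * 4)
    np.testing.assert_array_equal(per_residue_msa_count(constant), [4, 4, 4, 4])
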