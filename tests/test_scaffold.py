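"""Target geometry: regions, palindromes, distances, enumeration."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from megadesign.scaffold import (
    ActivityScore,
    InvalidSequenceError,
    ProteinVariant,
    Target,
    WT_RESIDUES,
    WT_TARGET_SEQ,
    build_palindrome,
    enumerate_region_space,
    extract_regions,
    read_targets_fasta,
    reduce_to_palindromes,
    revcomp,
    substitute_center,
    target_distance,
    targets_to_frame,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)
half_sites = st.text(alphabet="ACGT", min_size=11, max_size=11)


@settings(max_examples=100, deadline=None)
@given(dna)
def test_revcomp_is_an_involution(seq):
    assert revcomp(revcomp(seq)) == seq


def test_region_slicing_of_half_site():
    # right half-site ACGTTGAGCTA: +1,+2 = AC; +3..+5 = GTT; +6,+7 = GA; +8..+11 = GCTA
    t = build_palindrome("ACGTTGAGCTA")
    r = extract_regions(t)
    assert (r.r2N4[2:], r.r5N3, r.r7N2, r.r11N4) == ("AC", "GTT", "GA", "GCTA")
    assert r.r2N4 == "GTAC" and revcomp("GTAC") == "GTAC"


@settings(max_examples=50, deadline=None)
@given(half_sites)
def test_palindrome_construction_and_roundtrip(half):
    t = build_palindrome(half)
    assert len(t.full_seq) == 22
    assert t.is_pseudopalindromic
    assert t.left_half == revcomp(t.right_half)
    # extract_regions then reassembly is the identity
    assert extract_regions(t).to_target() == t
    # symmetric: regions read identically from the reverse complement
    assert extract_regions(Target(revcomp(t.full_seq))) == extract_regions(t)


def test_build_palindrome_is_deterministic_and_validates():
    assert build_palindrome("GTTGAGCTA", "AC") == build_palindrome("GTTGAGCTA", "AC")
    with pytest.raises(InvalidSequenceError):
        build_palindrome("GTT", "AC")
    with pytest.raises(InvalidSequenceError):
        build_palindrome("GTTGAGCTA", "ACG")
    with pytest.raises(InvalidSequenceError):
        build_palindrome("GTTGAGCTN", "AC")


def test_signed_position_lookup():
    t = build_palindrome("ACGTTGAGCTA")
    r = extract_regions(t)
    assert t.base_at(1) == "A" and t.base_at(2) == "C"
    assert "".join(t.base_at(p) for p in (3, 4, 5)) == r.r5N3
    assert "".join(t.base_at(p) for p in (8, 9, 10, 11)) == r.r11N4
    assert t.base_at(-3) == revcomp(t.base_at(3))
    with pytest.raises(ValueError):
        t.base_at(0)


def test_reduce_to_palindromes():
    t = Target("ACGTTGAGCTAGGCATTACGGA")
    left, right = reduce_to_palindromes(t)
    assert left.is_pseudopalindromic and right.is_pseudopalindromic
    assert left.full_seq == t.left_half + revcomp(t.left_half)
    assert right.full_seq == revcomp(t.right_half) + t.right_half
    # left-derived regions equal those computed from revcomp(L) as right half
    expect = extract_regions(build_palindrome(revcomp(t.left_half)))
    assert extract_regions(left) == expect
    # a pseudopalindrome is a fixed point
    p = build_palindrome("ACGTTGAGCTA")
    assert reduce_to_palindromes(p) == (p, p)


def test_substitute_center():
    t = Target(WT_TARGET_SEQ)
    g = substitute_center(t, "GTAC")
    assert extract_regions(g).r2N4 == "GTAC"
    r0, r1 = extract_regions(t), extract_regions(g)
    assert (r0.r5N3, r0.r7N2, r0.r11N4) == (r1.r5N3, r1.r7N2, r1.r11N4)


def test_target_distance_examples_and_properties():
    t1 = build_palindrome("AC" + "GTT" + "GA" + "GCTA", None)
    t2 = build_palindrome("AC" + "GTA" + "GA" + "GCTA", None)
    assert target_distance(t1, t1) == 0
    assert target_distance(t1, t2) == 1  # r11N4+r5N3 differ by one base
    # distance over the full site counts both strands of the mismatch
    assert target_distance(t1, t2, scope=("full",)) == 2
    with pytest.raises(ValueError):
        target_distance(t1, t2, scope=("r9N9",))


@settings(max_examples=60, deadline=None)
@given(st.tuples(half_sites, half_sites, half_sites))
def test_target_distance_is_a_metric(halves):
    a, b, c = (build_palindrome(h) for h in halves)

    def brute(x, y):
        rx, ry = extract_regions(x), extract_regions(y)
        sx, sy = rx.r11N4 + rx.r5N3, ry.r11N4 + ry.r5N3
        return sum(u != v for u, v in zip(sx, sy))

    assert target_distance(a, b) == brute(a, b) == target_distance(b, a)
    assert target_distance(a, c) <= target_distance(a, b) + target_distance(b, c)


def test_enumerate_region_space():
    s5 = enumerate_region_space("5N3")
    s11 = enumerate_region_space("11N4")
    assert len(s5) == 64 and len(s11) == 256
    assert len(set(s5)) == 64 and len(set(s11)) == 256
    assert s5 == sorted(s5) and s11 == sorted(s11)
    assert s5[0] == "AAA" and s5[-1] == "TTT"
    assert s11[0] == "AAAA" and s11[-1] == "TTTT"
    with pytest.raises(ValueError):
        enumerate_region_space("7N2")


def test_target_validation():
    with pytest.raises(InvalidSequenceError):
        Target("ACGT")
    with pytest.raises(InvalidSequenceError):
        Target("N" * 22)
    assert Target("acgttgagctaggcattacgga").full_seq.isupper()


def test_protein_variant_halves_and_validation():
    v = ProteinVariant(WT_RESIDUES)
    assert v.p5_half == ("Q", "R", "R", "D", "I")
    assert v.p11_half == ("N", "S", "Y", "Q", "S")
    assert len(v.key) == 10
    with pytest.raises(ValueError):
        ProteinVariant({44: "Q"})
    with pytest.raises(ValueError):
        ProteinVariant({**WT_RESIDUES, 99: "A"})
    with pytest.raises(ValueError):
        ProteinVariant({**WT_RESIDUES, 44: "Z"})


def test_activity_score_invariants():
    assert ActivityScore(0.9, True).strong
    assert not ActivityScore(0.5, True).strong
    with pytest.raises(ValueError):
        ActivityScore(1.2, True)
    with pytest.raises(ValueError):
        ActivityScore(0.9, False)  # strong implies active


def test_fasta_reader_and_frame(tmp_path):
    t1 = build_palindrome("ACGTTGAGCTA")
    t2 = Target(WT_TARGET_SEQ)
    path = tmp_path / "targets.fa"
    path.write_text(f">t1\n{t1.full_seq.lower()}\n>t2\n{t2.full_seq}\n")
    targets = read_targets_fasta(path)
    assert targets == [t1, t2]
    frame = targets_to_frame(targets)
    assert list(frame["full_seq"]) == [t1.full_seq, t2.full_seq]
    assert frame["pseudopalindromic"].all()
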