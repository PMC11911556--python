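"""PRIM/RPRIM, frequency vectors and AAPIV/RAAPIV against enumeration oracles."""

import numpy as np
import pytest

import m5censemble as m
from m5censemble.position_features import kmer_alphabet
from tests.test_moments import oracle_central, oracle_raw


def oracle_prim(seq, k):
    """All-pairs enumeration over k-mer occurrences, written independently."""
    kmers = kmer_alphabet(k)
    size = len(kmers)
    out = np.zeros((size, size), dtype=int)
    occurrences = [seq[s:s + k] for s in range(len(seq) - k + 1)]
    for i, kmer_i in enumerate(kmers):
        if kmer_i not in occurrences:
            continue
        first = occurrences.index(kmer_i) + 1
        for j, kmer_j in enumerate(kmers):
            for pos0, found in enumerate(occurrences):
                if found == kmer_j and pos0 + 1 > first:
                    out[i, j] += pos0 + 1 - first
    return out


def test_kmer_alphabet_sizes_and_order():
    assert len(kmer_alphabet(1)) == 4
    assert len(kmer_alphabet(2)) == 16
    assert len(kmer_alphabet(3)) == 64
    assert kmer_alphabet(2)[:4] == ("AA", "AC", "AG", "AU")
    assert kmer_alphabet(3)[-1] == "UUU"


def test_kmer_positions_examples():
    pos = m.kmer_positions("ACGU", 2)
    assert pos["AC"] == [1] and pos["CG"] == [2] and pos["GU"] == [3]
    mono = m.kmer_positions("A" * 41, 1)
    assert mono["A"] == list(range(1, 42))
    assert mono["C"] == []


def test_kmer_positions_total_count(random_windows):
    for seq in random_windows[:20]:
        for k in (1, 2, 3):
            total = sum(len(v) for v in m.kmer_positions(seq, k).values())
            assert total == 42 - k


def test_prim_toy_examples():
    p = m.prim("AC", 1)
    a, c, g, u = (kmer_alphabet(1).index(b) for b in "ACGU")
    assert p[a, c] == 1 and p[a, a] == 0
    assert np.all(p[g] == 0) and np.all(p[u] == 0)
    p4 = m.prim("AAAA", 1)
    assert p4[a, a] == 1 + 2 + 3
    assert p4.sum() == 6


@pytest.mark.parametrize("k", [1, 2, 3])
def test_prim_matches_enumeration_oracle(k, random_windows):
    for seq in random_windows[:8]:
        assert np.array_equal(m.prim(seq, k), oracle_prim(seq, k))


@pytest.mark.parametrize("k", [1, 2, 3])
def test_prim_entries_bounded(k, random_windows):
    length = 42 - k
    bound = (length - 1) * length // 2
    for seq in random_windows[:20]:
        p = m.prim(seq, k)
        assert p.min() >= 0 and p.max() <= bound


def test_rprim_is_prim_of_reversed_sequence(random_windows):
    for seq in random_windows[:8]:
        for k in (1, 2, 3):
            assert np.array_equal(
                m.rprim(seq, k), oracle_prim(seq[::-1], k)
            )


def test_rprim_toy_and_palindrome():
    a, c = kmer_alphabet(1).index("A"), kmer_alphabet(1).index("C")
    assert m.rprim("AC", 1)[c, a] == 1
    palindrome = "ACGUGCA"
    assert np.array_equal(m.prim(palindrome, 1), m.rprim(palindrome, 1))


def test_frequency_vector_sums(random_windows):
    for seq in random_windows[:30]:
        assert m.frequency_vector(seq, 1).sum() == 41
        assert m.frequency_vector(seq, 2).sum() == 40
        assert m.frequency_vector(seq, 3).sum() == 39


def test_frequency_vector_examples():
    tri = m.frequency_vector("A" * 41, 3)
    assert tri[kmer_alphabet(3).index("AAA")] == 39
    assert tri.sum() == 39
    di = m.frequency_vector("AACG", 2)
    idx = kmer_alphabet(2).index
    assert di[idx("AA")] == 1 and di[idx("AC")] == 1 and di[idx("CG")] == 1


def test_aapiv_examples():
    mono = m.aapiv("ACGU", 1)
    idx = kmer_alphabet(1).index
    assert [mono[idx(b)] for b in "ACGU"] == [1, 2, 3, 4]
    all_a = m.aapiv("A" * 41, 1)
    assert all_a[idx("A")] == 861
    assert all_a.sum() == 861


@pytest.mark.parametrize("k", [1, 2, 3])
def test_aapiv_position_conservation(k, random_windows):
    expected = sum(range(1, 42 - k + 1))
    for seq in random_windows[:20]:
        assert m.aapiv(seq, k).sum() == expected


def test_aapiv_single_occurrence_shift_monotonicity():
    idx = kmer_alphabet(1).index("C")
    for start in range(10):
        seq = "A" * start + "C" + "A" * (40 - start)
        assert m.aapiv(seq, 1)[idx] == start + 1


def test_raapiv_identities(random_windows):
    idx = kmer_alphabet(1).index
    tau = m.raapiv("ACGU", 1)
    assert [tau[idx(b)] for b in "ACGU"] == [4, 3, 2, 1]
    for seq in random_windows[:20]:
        for k in (1, 2, 3):
            assert np.array_equal(m.raapiv(seq, k), m.aapiv(seq[::-1], k))
            assert m.raapiv(seq, k).sum() == m.aapiv(seq, k).sum()
    palindrome = "ACGUGCA"
    assert np.array_equal(m.raapiv(palindrome, 1), m.aapiv(palindrome, 1))


def test_reduce_matrix_against_oracle(rng):
    mat = rng.integers(0, 50, size=(16, 16)).astype(float)
    reduced = m.reduce_matrix(mat)
    assert reduced.shape == (30,)
    from m5censemble.moments import DEFAULT_ORDERS

    for idx, (u, v) in enumerate(DEFAULT_ORDERS):
        assert reduced[idx] == pytest.approx(oracle_raw(mat, u, v), rel=1e-9)
        assert reduced[10 + idx] == pytest.approx(
            oracle_central(mat, u, v), rel=1e-9, abs=1e-9
        )


def test_reduce_matrix_zero_and_errors():
    assert np.all(m.reduce_matrix(np.zeros((16, 16))) == 0)
    with pytest.raises(ValueError):
        m.reduce_matrix(np.zeros((4, 5)))
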