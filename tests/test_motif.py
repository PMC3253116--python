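import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strandtile.core_model import Genome, GenomeSequence, reverse_complement
from strandtile.motif import (
    IUPAC,
    MotifHit,
    antisense_near_motif,
    containment_probability,
    find_common_kmer,
    iid_containment_probability,
    proximity_sensitivity,
    reverse_complement_iupac,
    scan_iupac,
)


class FakeCall:
    """Minimal stand-in carrying what proximity analysis reads off a call."""

    def __init__(self, gene_id, chrom, strand, origin):
        self.gene_id = gene_id
        self.five_prime_origin = origin
        self.segment = type("S", (), {"chrom": chrom, "strand": strand})()


def test_forkhead_motif_degeneracy():
    for word, expected in (("GTAAACA", 1), ("GTAAATA", 1), ("GTAAAGA", 0)):
        hits = scan_iupac({"c": "TT" + word + "TT"}, "GTAAAYA", both_strands=False)
        assert len(hits) == expected


def test_minus_strand_hit_coordinates():
    seq = reverse_complement("GTAAACA")
    hits = scan_iupac({"c": seq}, "GTAAAYA", both_strands=True)
    assert len(hits) == 1
    h = hits[0]
    assert h.strand == "-"
    # 5' base of the motif on the minus strand = highest plus coordinate
    assert h.start == len(seq) - 1
    # the genomic window read on the minus strand is the motif itself
    assert reverse_complement(seq[h.start - 6 : h.start + 1]) == "GTAAACA"


def test_invalid_iupac_letter_rejected():
    with pytest.raises(ValueError, match="IUPAC"):
        scan_iupac({"c": "ACGT" * 10}, "GTXAAYA")


def naive_scan(seq, motif):
    """Position-by-position oracle, no regex, no automaton."""
    out = []
    m = len(motif)
    for p in range(len(seq) - m + 1):
        if all(seq[p + i] in IUPAC[b] for i, b in enumerate(motif)):
            out.append(("+", p))
    rc = reverse_complement_iupac(motif)
    for p in range(len(seq) - m + 1):
        if all(seq[p + i] in IUPAC[b] for i, b in enumerate(rc)):
            out.append(("-", p + m - 1))
    return sorted(out)


def test_scanner_matches_naive_oracle_on_random_sequence(rng):
    seq = "".join(rng.choice(list("ACGT"), 10_000))
    for motif in ("GTAAAYA", "ACGCTC", "RNCGW"):
        hits = scan_iupac({"c": seq}, motif, both_strands=True)
        got = sorted((h.strand, h.start) for h in hits)
        assert got == naive_scan(seq, motif)


def test_both_strand_scan_equals_scan_of_revcomp(rng):
    seq = "".join(rng.choice(list("ACGT"), 2_000))
    motif = "GTAAAYA"
    both = scan_iupac({"c": seq}, motif, both_strands=True)
    minus_on_fwd = {h.start for h in both if h.strand == "-"}
    plus_on_rc = scan_iupac(
        {"c": reverse_complement(seq)}, motif, both_strands=False
    )
    # a + hit at p on the reverse complement is a - hit at L-1-p on the original
    mapped = {len(seq) - 1 - h.start for h in plus_on_rc}
    assert minus_on_fwd == mapped


def test_hit_rate_on_uniform_sequence_within_binomial_tolerance(rng):
    seq = "".join(rng.choice(list("ACGT"), 200_000))
    hits = scan_iupac({"c": seq}, "GTAAAYA", both_strands=True)
    # per-position match probability 2/4^7 per strand
    expect = 2 * (len(seq) - 6) * 2 / 4**7
    sd = np.sqrt(expect)
    assert abs(len(hits) - expect) < 4 * sd


def test_antisense_near_motif_planted_and_empty():
    calls = [FakeCall("g1", "c", "-", 5_000)]
    near = [MotifHit("GTAAAYA", "c", "-", 5_100)]
    frac, flags = antisense_near_motif(calls, near, window=500)
    assert frac == 1.0 and flags["g1"]
    frac, flags = antisense_near_motif(calls, [], window=500)
    assert frac == 0.0 and not flags["g1"]
    far = [MotifHit("GTAAAYA", "c", "+", 5_700)]
    assert antisense_near_motif(calls, far, window=500)[0] == 0.0
    assert antisense_near_motif([], near, window=500)[0] == 0.0


def test_proximity_sensitivity_monotone_in_window():
    calls = [FakeCall(f"g{i}", "c", "+", 1_000 * i) for i in range(1, 6)]
    hits = [MotifHit("GTAAAYA", "c", "+", 1_000 * i + 300) for i in range(1, 4)]
    report = proximity_sensitivity(calls, hits, windows=(200, 500, 1000))
    assert report[200] <= report[500] <= report[1000]
    assert report[500] == pytest.approx(3 / 5)


def test_common_kmer_finds_planted_hexamer(rng):
    seqs = []
    for _ in range(3):
        s = list(rng.choice(list("ACGT"), 400))
        pos = int(rng.integers(50, 350))
        s[pos : pos + 6] = list("ACGCTC")
        seqs.append("".join(s))
    results = find_common_kmer(seqs, k=6)
    by_kmer = {r.kmer: r for r in results}
    hit = by_kmer["ACGCTC"]
    assert hit.n_sequences_containing == 3 and hit.in_all
    assert 0 < hit.p_value < 0.01
    # in_all k-mers sort ahead of the rest
    n_all = sum(r.in_all for r in results)
    assert all(r.in_all for r in results[:n_all])


def test_common_kmer_single_sequence_trivial_case():
    res = find_common_kmer(["AAAA"], k=4)
    top = {r.kmer: r for r in res}["AAAA"]
    assert top.n_sequences_containing == 1 and top.in_all
    assert top.p_value == pytest.approx(containment_probability("AAAA", 4))


def test_common_kmer_rejects_short_sequences():
    with pytest.raises(ValueError, match="at least k"):
        find_common_kmer(["ACGT", "AC"], k=4)


def test_containment_probability_exact_values():
    # P(no "AA" in L=10 over ACGT) = 641520/4^10 by direct recurrence
    assert containment_probability("AA", 10) == pytest.approx(
        1 - 641_520 / 4**10, rel=1e-12
    )
    # non-self-overlapping word: avoidance count from the same recurrence style
    assert containment_probability("AC", 10) == pytest.approx(
        1 - 564_719 / 4**10, rel=1e-12
    )
    assert containment_probability("AA", 1) == 0.0
    # iid window approximation differs for self-overlapping words
    assert iid_containment_probability("AA", 10) == pytest.approx(
        1 - (15 / 16) ** 9
    )


@given(
    st.text(alphabet="ACGT", min_size=1, max_size=4),
    st.integers(min_value=1, max_value=25),
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_containment_probability_is_a_cdf_in_length(kmer, length):
    """P(contain) lies in [0,1] and can only grow with sequence length."""
    p = containment_probability(kmer, length)
    p_next = containment_probability(kmer, length + 1)
    assert 0.0 <= p <= p_next <= 1.0
    if length < len(kmer):
        assert p == 0.0


def test_containment_probability_both_strands(rng):
    # both-strand containment of a non-palindromic word is scanning for
    # {word, revcomp} on one strand
    p_single = containment_probability("ACG", 8)
    p_both = containment_probability("ACG", 8, both_strands=True)
    assert p_both > p_single
    # palindrome (even k): revcomp equals the word, nothing changes
    assert containment_probability("ACGT", 8, both_strands=True) == pytest.approx(
        containment_probability("ACGT", 8)
    )
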