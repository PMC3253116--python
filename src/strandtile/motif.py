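"""IUPAC motif scanning, antisense-origin proximity, and exhaustive
common-k-mer discovery.

The common-k-mer statistic replaces expectation-maximization motif discovery
with a transparent exhaustive search: every k-mer is scored by the
probability, under an iid background, that it would appear in all m input
sequences.  Containment probabilities are computed exactly with a pattern
automaton and transfer matrix, which accounts for self-overlap of the word
(P(no occurrence) for "AA" differs markedly from the independent-window
approximation); the approximation is available as ``method="iid"``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .core_model import Genome, GenomeSequence, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


@dataclass(frozen=True)
class MotifHit:
    motif: str
    chrom: str
    strand: str
    start: int  # 0-based position of the motif's 5' base on its own strand


@dataclass
class CommonKmerResult:
    kmer: str
    k: int
    n_sequences_containing: int
    in_all: bool
    p_value: float  # probability of presence in all m sequences under background
    background: dict = field(default_factory=dict)


def _validate_motif(motif: str) -> str:
    motif = motif.upper()
    bad = set(motif) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC letters in motif: {sorted(bad)!r}")
    return motif


def reverse_complement_iupac(motif: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[b] for b in reversed(motif.upper()))


def _matches_at(seq: str, pos: int, motif: str) -> bool:
    return all(seq[pos + i] in IUPAC[b] for i, b in enumerate(motif))


def _scan_plus(seq: str, motif: str) -> list[int]:
    m = len(motif)
    sets = [IUPAC[b] for b in motif]
    return [
        p
        for p in range(len(seq) - m + 1)
        if all(seq[p + i] in sets[i] for i in range(m))
    ]


def scan_iupac(
    genome: Genome | GenomeSequence | dict[str, str],
    motif: str,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All genomic positions matching an IUPAC pattern.

    Minus-strand hits are found by scanning the plus sequence with the
    reverse-complement pattern; their ``start`` is the position of the
    motif's 5' base on the minus strand (the highest plus-coordinate of the
    matched window).
    """
    motif = _validate_motif(motif)
    if isinstance(genome, GenomeSequence):
        chroms: dict[str, str] = {genome.chrom_id: genome.sequence}
    elif isinstance(genome, dict):
        chroms = {k: v.upper() for k, v in genome.items()}
    else:
        chroms = {c.chrom_id: c.sequence for c in genome}

    hits: list[MotifHit] = []
    rc = reverse_complement_iupac(motif)
    m = len(motif)
    for chrom, seq in chroms.items():
        for p in _scan_plus(seq, motif):
            hits.append(MotifHit(motif, chrom, "+", p))
        if both_strands:
            for p in _scan_plus(seq, rc):
                hits.append(MotifHit(motif, chrom, "-", p + m - 1))
    return hits


def antisense_near_motif(
    calls: Sequence,
    hits: Sequence[MotifHit],
    window: int = 500,
) -> tuple[float, dict[str, bool]]:
    """Fraction of antisense calls whose 5' origin lies within ``window`` nt
    of any motif hit (either strand), plus per-call flags keyed by gene id."""
    by_chrom: dict[str, np.ndarray] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h.start)  # type: ignore[arg-type]
    by_chrom = {c: np.sort(np.array(v)) for c, v in by_chrom.items()}

    flags: dict[str, bool] = {}
    for call in calls:
        origin = call.five_prime_origin
        pos = by_chrom.get(call.segment.chrom)
        if pos is None or len(pos) == 0:
            near = False
        else:
            i = np.searchsorted(pos, origin)
            near = (i < len(pos) and pos[i] - origin <= window) or (
                i > 0 and origin - pos[i - 1] <= window
            )
        flags[call.gene_id] = bool(near)
    fraction = sum(flags.values()) / len(flags) if flags else 0.0
    return fraction, flags


def proximity_sensitivity(
    calls: Sequence, hits: Sequence[MotifHit], windows: Iterable[int] = (200, 500, 1000)
) -> dict[int, float]:
    """The near-motif fraction across a range of windows, since "close" has
    no canonical distance."""
    return {w: antisense_near_motif(calls, hits, w)[0] for w in windows}


# ------------------------------------------------------- common-k-mer search

_ALPHABET = "ACGT"


def _automaton(patterns: tuple[str, ...]) -> np.ndarray:
    """Aho-Corasick DFA over {A,C,G,T} with one absorbing accept state.

    Returns an integer transition table of shape (n_states, 4); state 0 is
    the root, the last state is the accept sink.
    """
    # trie
    children: list[dict[str, int]] = [{}]
    terminal: list[bool] = [False]
    for pat in patterns:
        node = 0
        for ch in pat:
            if ch not in children[node]:
                children.append({})
                terminal.append(False)
                children[node][ch] = len(children) - 1
            node = children[node][ch]
        terminal[node] = True
    n = len(children)
    fail = [0] * n
    order: list[int] = []
    queue = list(children[0].values())
    for child in queue:
        fail[child] = 0
    while queue:
        node = queue.pop(0)
        order.append(node)
        for ch, nxt in children[node].items():
            queue.append(nxt)
            f = fail[node]
            while f and ch not in children[f]:
                f = fail[f]
            fail[nxt] = children[f].get(ch, 0) if children[f].get(ch, 0) != nxt else 0
            terminal[nxt] = terminal[nxt] or terminal[fail[nxt]]

    accept = n  # absorbing sink
    trans = np.zeros((n + 1, 4), dtype=np.int64)
    for state in range(n):
        for ai, ch in enumerate(_ALPHABET):
            s = state
            while s and ch not in children[s]:
                s = fail[s]
            nxt = children[s].get(ch, 0)
            trans[state, ai] = accept if terminal[nxt] else nxt
    trans[accept, :] = accept
    return trans


@lru_cache(maxsize=100_000)
def containment_probability(
    kmer: str, length: int, both_strands: bool = False,
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> float:
    """Exact P(random iid sequence of ``length`` contains ``kmer``).

    In both-strand mode the event is "kmer or its reverse complement occurs
    in the sequence" (equivalent to the kmer occurring on either strand).
    """
    if length < len(kmer):
        return 0.0
    patterns = (kmer,)
    if both_strands:
        rc = reverse_complement(kmer)
        if rc != kmer:
            patterns = (kmer, rc)
    trans = _automaton(patterns)
    n_states = trans.shape[0]
    p = np.asarray(base_probs)
    # transfer matrix M[s, s'] = P(step s -> s')
    M = np.zeros((n_states, n_states))
    for s in range(n_states):
        for ai in range(4):
            M[s, trans[s, ai]] += p[ai]
    probs = np.zeros(n_states)
    probs[0] = 1.0
    probs = probs @ np.linalg.matrix_power(M, length)
    return float(probs[-1])


def iid_containment_probability(
    kmer: str, length: int, both_strands: bool = False
) -> float:
    """Independent-window approximation q = 1 - (1 - 4^-k)^W."""
    k = len(kmer)
    if length < k:
        return 0.0
    windows = length - k + 1
    if both_strands and reverse_complement(kmer) != kmer:
        windows *= 2
    return 1.0 - (1.0 - 4.0**-k) ** windows


def find_common_kmer(
    sequences: Sequence[str],
    k: int,
    both_strands: bool = False,
    method: str = "exact",
) -> list[CommonKmerResult]:
    """Exhaustive common-word search over all 4^k k-mers.

    For each k-mer, counts the input sequences containing it (exact string
    match; in both-strand mode a sequence also counts if it contains the
    reverse complement) and attaches the background probability that the
    k-mer would be present in *all* m sequences — the significance of a
    word found in every input.  Results are sorted by
    (-n_sequences_containing, p_value, kmer).
    """
    if k < 1 or k > 8:
        raise ValueError("k must be in 1..8")
    sequences = [s.upper() for s in sequences]
    if any(len(s) < k for s in sequences):
        raise ValueError("every sequence must be at least k long")
    if method not in ("exact", "iid"):
        raise ValueError("method must be 'exact' or 'iid'")
    prob_fn = containment_probability if method == "exact" else iid_containment_probability

    present: list[set[str]] = []
    for s in sequences:
        kmers = {s[i : i + k] for i in range(len(s) - k + 1)}
        if both_strands:
            kmers |= {reverse_complement(km) for km in kmers}
        present.append(kmers)

    m = len(sequences)
    lengths = [len(s) for s in sequences]
    results: list[CommonKmerResult] = []
    for combo in itertools.product(_ALPHABET, repeat=k):
        kmer = "".join(combo)
        n_contain = sum(kmer in pset for pset in present)
        p_all = float(np.prod([prob_fn(kmer, L, both_strands) for L in lengths]))
        results.append(
            CommonKmerResult(
                kmer=kmer,
                k=k,
                n_sequences_containing=n_contain,
                in_all=n_contain == m,
                p_value=min(max(p_all, 0.0), 1.0),
                background={
                    "base_probs": [0.25] * 4,
                    "both_strands": both_strands,
                    "method": method,
                },
            )
        )
    results.sort(key=lambda r: (-r.n_sequences_containing, r.p_value, r.kmer))
    return results
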