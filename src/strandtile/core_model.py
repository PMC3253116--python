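"""Domain types shared by every pipeline stage, plus exact-match probe mapping.

Coordinates are 0-based, half-open everywhere in memory.  A probe assigned
strand ``s`` reports RNA transcribed *from* strand ``s``: its signal is sense
signal for genes annotated on ``s`` and antisense signal for genes on the
opposite strand.  This convention is applied consistently by the simulator,
the normalizer and the quantification layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

PROBE_LENGTH = 25

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """A single chromosome: identifier plus DNA over {A,C,G,T,N}."""

    __slots__ = ("chrom_id", "sequence")

    def __init__(self, chrom_id: str, sequence: str):
        sequence = sequence.upper()
        if not sequence:
            raise ValueError(f"chromosome {chrom_id!r}: empty sequence")
        bad = set(sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"chromosome {chrom_id!r}: invalid characters {sorted(bad)!r}"
            )
        self.chrom_id = chrom_id
        self.sequence = sequence

    def __len__(self) -> int:
        return len(self.sequence)

    def __repr__(self) -> str:
        return f"GenomeSequence({self.chrom_id!r}, <{len(self)} nt>)"


class Genome:
    """Mapping of chromosome id -> GenomeSequence with unique ids."""

    def __init__(self, chroms: Iterable[GenomeSequence]):
        self.chroms: dict[str, GenomeSequence] = {}
        for c in chroms:
            if c.chrom_id in self.chroms:
                raise ValueError(f"duplicate chromosome id {c.chrom_id!r}")
            self.chroms[c.chrom_id] = c
        if not self.chroms:
            raise ValueError("empty genome")

    def __getitem__(self, chrom_id: str) -> GenomeSequence:
        return self.chroms[chrom_id]

    def __iter__(self) -> Iterator[GenomeSequence]:
        return iter(self.chroms.values())

    def __contains__(self, chrom_id: str) -> bool:
        return chrom_id in self.chroms

    def __len__(self) -> int:
        return len(self.chroms)


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene.

    ``cds_start``/``cds_end`` span the genomic interval from ATG through the
    stop codon (introns included); ``exons`` are sorted, non-overlapping
    genomic intervals.  The strand determines transcription direction.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...] = ()
    utr3_end: int | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.cds_start < self.cds_end:
            raise ValueError(f"{self.gene_id}: cds_start must be < cds_end")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons."""
        out = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                out.append((e0, s1))
        return tuple(out)

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start (5' end)."""
        return self.cds_start if self.strand == "+" else self.cds_end - 1

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate just past the CDS on the 3' side."""
        return self.cds_end if self.strand == "+" else self.cds_start


@dataclass(frozen=True)
class Probe:
    probe_id: str
    sequence: str
    chrom: str
    strand: str
    start: int
    unique: bool

    def __post_init__(self):
        if len(self.sequence) != PROBE_LENGTH:
            raise ValueError(
                f"probe {self.probe_id}: length {len(self.sequence)} != {PROBE_LENGTH}"
            )

    @property
    def end(self) -> int:
        return self.start + PROBE_LENGTH


class ProbeMap:
    """Probes sorted by (chrom, strand, start), with per-(chrom, strand) views.

    One physical probe sequence that maps at several genomic locations appears
    once per placement, sharing its probe_id; only ``unique=True`` placements
    feed downstream intensity computations.
    """

    def __init__(self, probes: Iterable[Probe], genome: Genome | None = None):
        self.probes: list[Probe] = sorted(
            probes, key=lambda p: (p.chrom, p.strand, p.start)
        )
        if genome is not None:
            for p in self.probes:
                if p.chrom not in genome:
                    raise ValueError(f"probe {p.probe_id}: unknown chrom {p.chrom}")
                if not (0 <= p.start and p.end <= len(genome[p.chrom])):
                    raise ValueError(
                        f"probe {p.probe_id}: footprint outside {p.chrom}"
                    )
        self._by_key: dict[tuple[str, str], list[Probe]] = {}
        for p in self.probes:
            self._by_key.setdefault((p.chrom, p.strand), []).append(p)

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self) -> Iterator[Probe]:
        return iter(self.probes)

    def keys(self) -> list[tuple[str, str]]:
        return sorted(self._by_key)

    def probes_for(self, chrom: str, strand: str, unique_only: bool = True) -> list[Probe]:
        probes = self._by_key.get((chrom, strand), [])
        if unique_only:
            probes = [p for p in probes if p.unique]
        return probes

    def unique_probes(self) -> list[Probe]:
        return [p for p in self.probes if p.unique]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": [p.probe_id for p in self.probes],
                "sequence": [p.sequence for p in self.probes],
                "chrom": [p.chrom for p in self.probes],
                "strand": [p.strand for p in self.probes],
                "start": [p.start for p in self.probes],
                "unique": [p.unique for p in self.probes],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeMap":
        probes = [
            Probe(
                probe_id=str(r.probe_id),
                sequence=str(r.sequence),
                chrom=str(r.chrom),
                strand=str(r.strand),
                start=int(r.start),
                unique=bool(r.unique),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(probes)


@dataclass
class SampleInfo:
    sample: str
    condition: str
    channel: str  # "RNA" or "gDNA"


class IntensityMatrix:
    """Raw linear fluorescence, probes x samples, with sample metadata.

    Values must be strictly positive.  Exactly one gDNA-channel sample is
    required before normalization can run.
    """

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleInfo]):
        sample_names = [s.sample for s in samples]
        if list(values.columns) != sample_names:
            raise ValueError("sample metadata does not match matrix columns")
        if (values.to_numpy() <= 0).any():
            raise ValueError("intensities must be strictly positive")
        self.values = values
        self.samples = {s.sample: s for s in samples}

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    def rna_samples(self) -> list[str]:
        return [n for n, s in self.samples.items() if s.channel == "RNA"]

    def gdna_sample(self) -> str:
        gd = [n for n, s in self.samples.items() if s.channel == "gDNA"]
        if len(gd) != 1:
            raise ValueError(
                f"exactly one gDNA-channel sample required, found {len(gd)}"
            )
        return gd[0]

    def condition_of(self, sample: str) -> str:
        return self.samples[sample].condition


def map_probes(
    probe_sequences: Sequence[str] | Mapping[str, str],
    genome: Genome,
) -> tuple[ProbeMap, int]:
    """Place probes at every exact-match genomic location on either strand.

    A probe matches the + strand at position p when its sequence equals
    genome[p:p+25]; it matches the - strand when it equals the reverse
    complement of that window.  ``unique`` is True iff the probe has exactly
    one placement genome-wide (both strands counted).  Probes with zero
    placements are dropped; the count of dropped probes is returned.

    Parameters
    ----------
    probe_sequences
        Either a list of 25-nt sequences (ids autogenerated as ``probe_%06d``)
        or a mapping probe_id -> sequence.
    """
    if isinstance(probe_sequences, Mapping):
        items = list(probe_sequences.items())
    else:
        items = [(f"probe_{i:06d}", s) for i, s in enumerate(probe_sequences)]
    for pid, seq in items:
        if len(seq) != PROBE_LENGTH:
            raise ValueError(
                f"probe {pid}: length {len(seq)} != {PROBE_LENGTH}"
            )

    # One pass over each chromosome builds a 25-mer -> positions index.
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom in genome:
        seq = chrom.sequence
        for p in range(len(seq) - PROBE_LENGTH + 1):
            index.setdefault(seq[p : p + PROBE_LENGTH], []).append(
                (chrom.chrom_id, p)
            )

    probes: list[Probe] = []
    n_unmapped = 0
    for pid, seq in items:
        seq = seq.upper()
        placements: list[tuple[str, str, int]] = []
        for chrom_id, pos in index.get(seq, ()):
            placements.append((chrom_id, "+", pos))
        for chrom_id, pos in index.get(reverse_complement(seq), ()):
            placements.append((chrom_id, "-", pos))
        if not placements:
            n_unmapped += 1
            continue
        unique = len(placements) == 1
        for chrom_id, strand, pos in placements:
            probes.append(
                Probe(
                    probe_id=pid,
                    sequence=seq,
                    chrom=chrom_id,
                    strand=strand,
                    start=pos,
                    unique=unique,
                )
            )
    return ProbeMap(probes, genome), n_unmapped
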