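"""Segment classification, antisense calling, per-gene strand expression and
the intron/exon splicing index.

Segment taxonomy follows the three-group scheme: sense segments (same-strand
CDS overlap), antisense segments (opposite-strand CDS overlap) and
non-annotated segments.  Each segment receives exactly one primary category
by maximal reciprocal CDS overlap; because a single genomic region can be
sense for one gene and antisense for its opposite-strand neighbor
(mug28/mrp17-style mutual antisense, or a 3'UTR extension spanning two
genes), antisense *calls* are made per (gene, segment) pair rather than from
the primary category alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_model import GeneModel, PROBE_LENGTH, ProbeMap
from .segmentation import Segment

DEFAULT_MIN_OVERLAP = 50
DEFAULT_GAP_TOLERANCE = 100
DEFAULT_ANTISENSE_THRESHOLD = 1.0


@dataclass
class SegmentAnnotation:
    segment: Segment
    category: str  # "sense" | "antisense" | "non_annotated"
    gene_id: str | None
    overlap_fraction: float  # fraction of the assigned gene's CDS covered
    sense_genes: tuple[str, ...] = ()
    antisense_genes: tuple[str, ...] = ()


@dataclass
class AntisenseCall:
    gene_id: str
    segment: Segment
    mean_intensity: float
    origin: str = "unclassified"  # "discrete_unit" | "utr3_extension" | "unclassified"
    covers_full_cds: bool = False

    @property
    def five_prime_origin(self) -> int:
        """Genomic coordinate of the antisense transcript's 5' boundary."""
        s = self.segment
        return s.genomic_start if s.strand == "+" else s.genomic_end


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def segment_mean(segment: Segment, signal, probes: ProbeMap, sample: str) -> float:
    """Arithmetic mean of member-probe log2 values (sum / count)."""
    plist = probes.probes_for(segment.chrom, segment.strand, unique_only=True)
    members = plist[segment.first_probe_index : segment.last_probe_index + 1]
    if not members:
        raise ValueError("segment has no member probes")
    vals = signal.values.loc[[p.probe_id for p in members], sample]
    return float(vals.sum() / len(vals))


def classify_segment(
    segment: Segment,
    genes: Sequence[GeneModel],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> SegmentAnnotation:
    """Assign one category by maximal reciprocal CDS overlap.

    Reciprocal overlap = min(overlap/CDS length, overlap/segment length).
    Ties prefer the same-strand (sense) assignment, then the larger absolute
    overlap, then the lexicographically first gene id.  Segments with no CDS
    overlap of at least ``min_overlap`` nt are non-annotated.
    """
    seg_len = segment.genomic_end - segment.genomic_start
    sense_hits: list[str] = []
    antisense_hits: list[str] = []
    best = None  # (reciprocal, is_sense, overlap, gene)
    for g in genes:
        if g.chrom != segment.chrom:
            continue
        ov = _overlap(segment.genomic_start, segment.genomic_end, g.cds_start, g.cds_end)
        if ov < min_overlap:
            continue
        is_sense = g.strand == segment.strand
        (sense_hits if is_sense else antisense_hits).append(g.gene_id)
        reciprocal = min(ov / (g.cds_end - g.cds_start), ov / seg_len)
        rank = (reciprocal, is_sense, ov)
        if (
            best is None
            or rank > best[:3]
            or (rank == best[:3] and g.gene_id < best[3].gene_id)
        ):
            best = (reciprocal, is_sense, ov, g)
    if best is None:
        return SegmentAnnotation(segment, "non_annotated", None, 0.0)
    reciprocal, is_sense, ov, g = best
    return SegmentAnnotation(
        segment,
        "sense" if is_sense else "antisense",
        g.gene_id,
        ov / (g.cds_end - g.cds_start),
        tuple(sorted(sense_hits)),
        tuple(sorted(antisense_hits)),
    )


def classify_segments(
    segments: Iterable[Segment],
    genes: Sequence[GeneModel],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[SegmentAnnotation]:
    return [classify_segment(s, genes, min_overlap) for s in segments]


def call_antisense(
    annotations: Iterable[SegmentAnnotation],
    genes: Sequence[GeneModel],
    threshold: float = DEFAULT_ANTISENSE_THRESHOLD,
) -> list[AntisenseCall]:
    """Antisense RNA calls: one per (gene, segment) pair.

    A call is made for every gene whose CDS a segment overlaps on the
    opposite strand (>= the classification min_overlap, as recorded in the
    annotation) when the segment mean exceeds ``threshold`` (strict).
    Raising the threshold can only shrink the call set.
    """
    gene_index = {g.gene_id: g for g in genes}
    calls: list[AntisenseCall] = []
    for ann in annotations:
        seg = ann.segment
        if seg.mean_intensity <= threshold:
            continue
        for gid in ann.antisense_genes:
            g = gene_index[gid]
            covers = (
                seg.genomic_start <= g.cds_start and seg.genomic_end >= g.cds_end
            )
            calls.append(
                AntisenseCall(gid, seg, seg.mean_intensity, covers_full_cds=covers)
            )
    return calls


def classify_antisense_origin(
    call: AntisenseCall,
    segments: Sequence[Segment],
    genes: Sequence[GeneModel],
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    low_threshold: float = DEFAULT_ANTISENSE_THRESHOLD,
) -> str:
    """Classify an antisense RNA as a 3'UTR extension or a discrete unit.

    utr3_extension: the antisense segment is continuous with a same-strand
    neighbor's transcript — either the segment itself overlaps that
    neighbor's CDS 5'-ward of the parent gene (the common case where the
    neighbor mRNA and its long 3'UTR segment together), or the neighbor's
    3' CDS end lies within ``gap_tolerance`` nt of the segment's 5'
    boundary.

    discrete_unit: both flanking segments on the same strand are low
    (mean <= ``low_threshold``) or absent — an isolated transcription unit.
    """
    seg = call.segment
    parent = next(g for g in genes if g.gene_id == call.gene_id)
    strand = seg.strand

    for g in genes:
        if g.chrom != seg.chrom or g.strand != strand or g.gene_id == parent.gene_id:
            continue
        upstream_of_parent = (
            g.cds_start < parent.cds_start if strand == "+" else g.cds_end > parent.cds_end
        )
        if not upstream_of_parent:
            continue
        ov = _overlap(seg.genomic_start, seg.genomic_end, g.cds_start, g.cds_end)
        if ov >= min_overlap:
            return "utr3_extension"
        # neighbor's 3' end adjacent to the segment's 5' boundary
        if strand == "+":
            gap = abs(seg.genomic_start - g.cds_end)
        else:
            gap = abs(g.cds_start - seg.genomic_end)
        if gap <= gap_tolerance:
            return "utr3_extension"

    same = sorted(
        (s for s in segments if s.chrom == seg.chrom and s.strand == seg.strand),
        key=lambda s: s.first_probe_index,
    )
    prev = next_ = None
    for s in same:
        if s.last_probe_index == seg.first_probe_index - 1:
            prev = s
        if s.first_probe_index == seg.last_probe_index + 1:
            next_ = s
    flanks_low = all(
        s is None or s.mean_intensity <= low_threshold for s in (prev, next_)
    )
    if flanks_low:
        return "discrete_unit"
    return "unclassified"


def classify_origins(
    calls: Iterable[AntisenseCall],
    segments: Sequence[Segment],
    genes: Sequence[GeneModel],
    **kwargs,
) -> list[AntisenseCall]:
    out = []
    for c in calls:
        c.origin = classify_antisense_origin(c, segments, genes, **kwargs)
        out.append(c)
    return out


# ------------------------------------------------------ per-gene expression

def gene_strand_expression(
    genes: Sequence[GeneModel],
    signal,
    probes: ProbeMap,
    sample: str,
    include_intron_probes: bool = True,
) -> pd.DataFrame:
    """Per-gene mean log2 intensity of unique probes inside the CDS span.

    sense_avg averages probes on the gene's strand whose footprint lies
    fully within [cds_start, cds_end); antisense_avg does the same on the
    opposite strand.  Genes with no eligible probe on a strand get NaN
    (missing), never zero.  With ``include_intron_probes=False`` probes
    overlapping an annotated intron are dropped from both averages.
    """
    col = signal.values[sample]
    rows = {}
    for g in genes:
        rec = {}
        for label, strand in (
            ("sense_avg", g.strand),
            ("antisense_avg", "+" if g.strand == "-" else "-"),
        ):
            plist = probes.probes_for(g.chrom, strand, unique_only=True)
            eligible = [
                p for p in plist if p.start >= g.cds_start and p.end <= g.cds_end
            ]
            if not include_intron_probes:
                eligible = [
                    p
                    for p in eligible
                    if not any(_overlap(p.start, p.end, s, e) for s, e in g.introns)
                ]
            if eligible:
                rec[label] = float(col.loc[[p.probe_id for p in eligible]].mean())
            else:
                rec[label] = np.nan
        rows[g.gene_id] = rec
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    return df


def gene_expression_table(
    genes: Sequence[GeneModel],
    signal,
    probes: ProbeMap,
    include_intron_probes: bool = True,
) -> pd.DataFrame:
    """Wide per-gene table over all samples: <sample>_sense / <sample>_antisense."""
    pieces = {}
    for sample in signal.values.columns:
        df = gene_strand_expression(genes, signal, probes, sample, include_intron_probes)
        pieces[f"{sample}_sense"] = df["sense_avg"]
        pieces[f"{sample}_antisense"] = df["antisense_avg"]
    return pd.DataFrame(pieces)


# ----------------------------------------------------------- splicing index

@dataclass
class SplicingResult:
    gene_id: str
    splicing_index: float | None
    n_intron_probes: int
    n_exon_probes: int
    antisense_avg: float
    label: str  # "spliced" | "unspliced_or_antisense_dominated" | "not_computable"


def splicing_index(
    gene: GeneModel,
    signal,
    probes: ProbeMap,
    sample: str,
    delta: float = 1.0,
) -> SplicingResult:
    """Mean(sense intron probes) - mean(sense exon probes), in log2 units.

    Strongly negative values indicate splicing (intron absent from the
    mature RNA).  A near-zero index is ambiguous on its own: an unspliced
    sense RNA and a covering antisense RNA both flatten the intron/exon
    contrast, so the gene's antisense_avg is reported alongside for
    interpretation.
    """
    col = signal.values[sample]
    plist = probes.probes_for(gene.chrom, gene.strand, unique_only=True)
    intron_probes = [
        p
        for p in plist
        if any(p.start >= s and p.end <= e for s, e in gene.introns)
    ]
    exon_probes = [
        p for p in plist if any(p.start >= s and p.end <= e for s, e in gene.exons)
    ]
    anti = gene_strand_expression([gene], signal, probes, sample).loc[
        gene.gene_id, "antisense_avg"
    ]
    if not intron_probes or not exon_probes:
        return SplicingResult(
            gene.gene_id, None, len(intron_probes), len(exon_probes), float(anti),
            "not_computable",
        )
    si = float(
        col.loc[[p.probe_id for p in intron_probes]].mean()
        - col.loc[[p.probe_id for p in exon_probes]].mean()
    )
    label = "spliced" if si < -delta else "unspliced_or_antisense_dominated"
    return SplicingResult(
        gene.gene_id, si, len(intron_probes), len(exon_probes), float(anti), label
    )
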