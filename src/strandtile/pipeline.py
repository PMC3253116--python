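"""End-to-end orchestration and truth-based evaluation.

``run_simulate`` drives the full chain on generated data:
simulate -> map probes -> normalize against the gDNA channel -> segment ->
classify/call antisense -> per-gene strand expression -> gene-level
statistics -> motif proximity.  The companion metric functions score the
inferred objects against the generator's ground truth.

``analyze_gene_table`` is the gene-table-only path: it consumes a wide
per-gene sense/antisense table (from this pipeline or ingested from a
published per-gene supplementary spreadsheet) and computes the group
selections, differentials, correlations and induction statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as stio
from .analysis import (
    AnalysisConfig,
    delta_correlation,
    differential_sense,
    hypergeometric_enrichment,
    meiotic_induction_status,
    select_high_antisense_low_sense,
    select_new_antisense,
)
from .core_model import Genome, map_probes, PROBE_LENGTH, ProbeMap
from .normalization import NormalizedSignal, normalize_to_gdna
from .quantify import (
    AntisenseCall,
    SegmentAnnotation,
    call_antisense,
    classify_origins,
    classify_segments,
    gene_expression_table,
)
from .segmentation import Segment, SegmentationModel, segment_genome
from .synthetic_data import (
    FORKHEAD_MOTIF,
    GroundTruth,
    SimConfig,
    design_tiling_probes,
    generate_genome_and_annotation,
    probe_coverage,
    simulate_intensities,
)
from . import motif as stmotif


@dataclass
class SimulationRun:
    truth: GroundTruth
    probes: ProbeMap
    n_unmapped: int
    signal: NormalizedSignal
    segments: dict[str, list[Segment]]
    annotations: dict[str, list[SegmentAnnotation]]
    calls: dict[str, list[AntisenseCall]]
    gene_table: pd.DataFrame
    intensities: object = None

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.truth.write(out_dir)
        stio.write_probe_tsv(self.probes, out_dir / "probes.tsv")
        if self.intensities is not None:
            stio.write_intensity_tsv(self.intensities, out_dir / "intensities.tsv")
        self.signal.write(out_dir / "normalized.tsv")
        for sample, segs in self.segments.items():
            stio.write_segments_bed(segs, out_dir / f"segments_{sample}.bed")
        stio.write_gene_expression_tsv(self.gene_table, out_dir / "gene_expression.tsv")
        for sample, calls in self.calls.items():
            pd.DataFrame(
                [
                    {
                        "gene_id": c.gene_id,
                        "chrom": c.segment.chrom,
                        "strand": c.segment.strand,
                        "start": c.segment.genomic_start,
                        "end": c.segment.genomic_end,
                        "mean_intensity": c.mean_intensity,
                        "origin": c.origin,
                        "covers_full_cds": c.covers_full_cds,
                    }
                    for c in calls
                ]
            ).to_csv(out_dir / f"antisense_calls_{sample}.tsv", sep="\t", index=False)


def run_simulate(
    config: SimConfig | None = None,
    segmentation_model: SegmentationModel | None = None,
    analysis_config: AnalysisConfig | None = None,
    samples_to_segment: Sequence[str] = ("veg",),
    keep_intensities: bool = False,
) -> SimulationRun:
    """Generate data from ``config`` and run the full pipeline on it.

    Segmentation (the expensive quadratic step) runs only for the samples in
    ``samples_to_segment``; per-gene strand expression is computed for every
    RNA sample regardless, since it averages probes directly.
    """
    config = config or SimConfig()
    segmentation_model = segmentation_model or SegmentationModel()
    analysis_config = analysis_config or AnalysisConfig()

    truth = generate_genome_and_annotation(config)
    sequences = design_tiling_probes(truth.genome, config.probe_step)
    probes, n_unmapped = map_probes(sequences, truth.genome)
    intensities = simulate_intensities(truth, probes, config)
    signal = normalize_to_gdna(intensities, None, probes, truth.genes)

    segments: dict[str, list[Segment]] = {}
    annotations: dict[str, list[SegmentAnnotation]] = {}
    calls: dict[str, list[AntisenseCall]] = {}
    for sample in samples_to_segment:
        segs = segment_genome(signal, probes, segmentation_model, sample)
        anns = classify_segments(segs, truth.genes)
        sample_calls = call_antisense(
            anns, truth.genes, analysis_config.antisense_call_threshold
        )
        sample_calls = classify_origins(
            sample_calls,
            segs,
            truth.genes,
            low_threshold=analysis_config.antisense_call_threshold,
        )
        segments[sample] = segs
        annotations[sample] = anns
        calls[sample] = sample_calls

    gene_table = gene_expression_table(truth.genes, signal, probes)
    return SimulationRun(
        truth=truth,
        probes=probes,
        n_unmapped=n_unmapped,
        signal=signal,
        segments=segments,
        annotations=annotations,
        calls=calls,
        gene_table=gene_table,
        intensities=intensities if keep_intensities else None,
    )


# --------------------------------------------------------- truth-based metrics

SENSE_CLASSES = {"sense_mRNA", "truncated_sense"}


def probe_truth_labels(
    truth: GroundTruth, probes: ProbeMap, sample: str, floor: float = 0.01
) -> dict[str, str]:
    """Sample-aware expected category of every unique probe.

    A probe is labelled from the planted annotation only where transcription
    is actually present: expressed + inside a same-strand CDS -> sense;
    expressed + inside an opposite-strand CDS -> antisense; everything else
    (background, or expressed signal outside any CDS) -> non_annotated.
    """
    coverage = probe_coverage(truth.transcripts, probes, (sample,))[sample]
    cds_by_strand: dict[str, list[tuple[str, int, int]]] = {"+": [], "-": []}
    for g in truth.genes:
        cds_by_strand[g.strand].append((g.chrom, g.cds_start, g.cds_end))
    labels: dict[str, str] = {}
    for p in probes.unique_probes():
        if coverage.loc[p.probe_id] <= floor:
            labels[p.probe_id] = "non_annotated"
            continue
        opposite = "-" if p.strand == "+" else "+"
        in_same = any(
            c == p.chrom and p.start >= s and p.end <= e
            for c, s, e in cds_by_strand[p.strand]
        )
        in_opp = any(
            c == p.chrom and p.start >= s and p.end <= e
            for c, s, e in cds_by_strand[opposite]
        )
        labels[p.probe_id] = (
            "sense" if in_same else "antisense" if in_opp else "non_annotated"
        )
    return labels


def segment_category_accuracy(
    run: SimulationRun,
    sample: str = "veg",
    expressed_floor: float = 0.5,
    label_share: float = 0.3,
) -> float:
    """Fraction of expressed segments whose category matches the truth.

    Scored over segments with mean intensity above ``expressed_floor``.  A
    segment is counted correct when its category is among the truth labels
    carried by at least ``label_share`` of its probes — merged segments
    spanning a neighbor mRNA and its 3'UTR-extension antisense legitimately
    carry two truth labels.
    """
    labels = probe_truth_labels(run.truth, run.probes, sample)
    n_scored = n_correct = 0
    for ann in run.annotations[sample]:
        seg = ann.segment
        if seg.mean_intensity <= expressed_floor:
            continue
        plist = run.probes.probes_for(seg.chrom, seg.strand, unique_only=True)
        members = plist[seg.first_probe_index : seg.last_probe_index + 1]
        member_labels = pd.Series([labels[p.probe_id] for p in members])
        shares = member_labels.value_counts(normalize=True)
        allowed = set(shares.index[shares >= label_share])
        n_scored += 1
        n_correct += ann.category in allowed
    return n_correct / n_scored if n_scored else float("nan")


def antisense_origin_accuracy(run: SimulationRun, sample: str = "veg") -> float:
    """Accuracy of discrete-unit vs 3'UTR-extension origin classification
    over genes with a planted covering vegetative antisense RNA.  Genes whose
    antisense was not called at all count as errors."""
    expected = {}
    for gid in run.truth.genes_by_architecture("meiotic_discrete"):
        expected[gid] = "discrete_unit"
    for gid in run.truth.genes_by_architecture("meiotic_utr3"):
        expected[gid] = "utr3_extension"
    by_gene: dict[str, AntisenseCall] = {}
    for c in run.calls[sample]:
        cur = by_gene.get(c.gene_id)
        if cur is None or c.segment.n_probes > cur.segment.n_probes:
            by_gene[c.gene_id] = c
    n_correct = sum(
        1
        for gid, want in expected.items()
        if gid in by_gene and by_gene[gid].origin == want
    )
    return n_correct / len(expected) if expected else float("nan")


def antisense_recovery(run: SimulationRun, sample: str = "veg") -> float:
    """Fraction of genes with a planted expressed covering antisense RNA that
    received at least one antisense call."""
    planted = {
        t.parent_gene
        for t in run.truth.transcripts
        if t.covering and t.abundance.get(sample, 0.0) >= 0.2
    }
    called = {c.gene_id for c in run.calls[sample]}
    return len(planted & called) / len(planted) if planted else float("nan")


def twofold_recovery(run: SimulationRun, a: str = "veg", b: str = "mei6h") -> float:
    """Mean measured log2 sense change of the planted two-fold genes."""
    genes = run.truth.genes_by_architecture("twofold")
    diffs = (
        run.gene_table.loc[genes, f"{b}_sense"] - run.gene_table.loc[genes, f"{a}_sense"]
    )
    return float(diffs.mean())


# ------------------------------------------------------------ table analysis

def analyze_gene_table(
    table: pd.DataFrame,
    veg: str = "veg",
    t4: str = "mei4h",
    t6: str = "mei6h",
    mutant: str = "fkh2_mei4",
    cfg: AnalysisConfig | None = None,
    meiotic_genes: pd.Index | None = None,
) -> dict:
    """Gene-level statistics from a wide per-gene sense/antisense table.

    Computes the vegetative medians, the high-antisense/low-sense group, the
    mutant-vs-wild-type sense differential, the new-antisense selection (with
    and without excluding annotated meiotic genes), the sense/antisense
    delta correlation, induction status of the group, and (when a meiotic
    gene set is supplied) its hypergeometric enrichment in the group.
    """
    cfg = cfg or AnalysisConfig()
    out: dict = {}

    def have(sample: str) -> bool:
        return f"{sample}_sense" in table.columns

    v = stio.sample_view(table, veg) if have(veg) else None
    if v is not None:
        out["median_sense_veg"] = float(v["sense_avg"].median())
        out["median_antisense_veg"] = float(v["antisense_avg"].median())
        group = select_high_antisense_low_sense(v, cfg)
        out["high_antisense_low_sense_genes"] = list(group)
        out["n_high_antisense_low_sense"] = len(group)

    if v is not None and have(mutant):
        mu = stio.sample_view(table, mutant)
        diff = differential_sense(mu, v, cfg.differential_delta)
        out["n_mutant_derepressed"] = len(diff)
        out["mutant_derepressed_genes"] = list(diff)

    if v is not None and have(t6):
        s6 = stio.sample_view(table, t6)
        new_as = select_new_antisense(v, s6, cfg)
        out["n_new_antisense"] = len(new_as)
        out["new_antisense_genes"] = list(new_as)
        if meiotic_genes is not None:
            out["n_new_antisense_nonmeiotic"] = len(
                select_new_antisense(v, s6, cfg, exclude=meiotic_genes)
            )
        try:
            out["delta_correlation_all"] = delta_correlation(v, s6)
        except ValueError:
            out["delta_correlation_all"] = None
        if len(new_as) >= 3:
            try:
                out["delta_correlation_new_antisense"] = delta_correlation(
                    v, s6, genes=new_as
                )
            except ValueError:
                out["delta_correlation_new_antisense"] = None

    if v is not None and have(t4) and have(t6):
        group = pd.Index(out.get("high_antisense_low_sense_genes", []))
        if len(group):
            status = meiotic_induction_status(
                v, stio.sample_view(table, t4), stio.sample_view(table, t6), group
            )
            out["n_group_not_induced"] = int((~status).sum())

    if meiotic_genes is not None and v is not None and out.get("n_high_antisense_low_sense"):
        enr = hypergeometric_enrichment(
            set(out["high_antisense_low_sense_genes"]),
            set(meiotic_genes) & set(table.index),
            set(table.index),
        )
        out["group_meiotic_enrichment_p"] = enr.p_value
        out["group_meiotic_fraction"] = enr.k / enr.n if enr.n else None
    return out


def motif_proximity_report(
    run: SimulationRun,
    sample: str = "veg",
    motif: str = FORKHEAD_MOTIF,
    windows: Sequence[int] = (200, 500, 1000),
) -> dict:
    """Fraction of called antisense origins near a forkhead motif, at
    several proximity windows."""
    hits = stmotif.scan_iupac(run.truth.genome, motif, both_strands=True)
    # one call per gene: the longest supporting segment
    by_gene: dict[str, AntisenseCall] = {}
    for c in run.calls[sample]:
        cur = by_gene.get(c.gene_id)
        if cur is None or c.segment.n_probes > cur.segment.n_probes:
            by_gene[c.gene_id] = c
    calls = list(by_gene.values())
    return {
        "n_calls": len(calls),
        "n_motif_hits": len(hits),
        "fractions": stmotif.proximity_sensitivity(calls, hits, windows),
    }
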